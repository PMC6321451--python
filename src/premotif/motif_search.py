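"""IUPAC degenerate motif matching and region-restricted database searches.

Motifs are written in the IUPAC nucleic-acid code (R = G/A, Y = U/C,
M = A/C, K = G/U, S = G/C, W = A/U, H = A/C/U, B = G/U/C, V = G/C/A,
D = G/U/A, N = any).  A search runs either forward (5'->3') or also in the
*reverse* direction, which scans for the reversed motif string — not the
reverse complement: pre-miRNAs are single-stranded, and the option models
protein-binding motifs reported 3'->5'.

Two database searches are provided: a single-motif search and a
two-motif search that categorizes each precursor as matching one motif,
the other, or both (optionally requiring a non-overlapping occurrence
pair).  Both can be restricted to the terminal loop, the linking
sequence, the mature miRNAs, or run on the whole precursor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from premotif.mirbase_io import PrecursorDatabase, normalize_rna
from premotif.structure_regions import Interval, RegionAnnotation

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("GA"),
    "Y": frozenset("UC"),
    "M": frozenset("AC"),
    "K": frozenset("GU"),
    "S": frozenset("GC"),
    "W": frozenset("AU"),
    "H": frozenset("ACU"),
    "B": frozenset("GUC"),
    "V": frozenset("GCA"),
    "D": frozenset("GUA"),
    "N": frozenset("GUAC"),
}

REGIONS = ("loop", "linking", "mature", "whole")
DIRECTIONS = ("forward", "reverse")
DIRECTION_MODES = ("forward", "both")


@dataclass(frozen=True)
class IUPACMotif:
    """A compiled degenerate motif: pattern string plus per-position base sets."""

    pattern: str
    charsets: tuple[frozenset[str], ...]

    def __len__(self) -> int:
        return len(self.pattern)

    def reversed(self) -> "IUPACMotif":
        return IUPACMotif(self.pattern[::-1], self.charsets[::-1])

    @property
    def regex(self) -> re.Pattern:
        return _regex_for(self.charsets)


def _regex_for(charsets: Sequence[frozenset[str]]) -> re.Pattern:
    body = "".join(
        next(iter(cs)) if len(cs) == 1 else "[" + "".join(sorted(cs)) + "]"
        for cs in charsets
    )
    return re.compile(body)


def compile_motif(pattern: str) -> IUPACMotif:
    """Compile an IUPAC pattern (T accepted and normalized to U)."""
    if not pattern:
        raise ValueError("motif pattern must be non-empty")
    norm = normalize_rna(pattern)
    try:
        charsets = tuple(IUPAC_CODES[ch] for ch in norm)
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC symbol {exc.args[0]!r} in motif {pattern!r}")
    return IUPACMotif(norm, charsets)


def find_matches(seq: str, motif: IUPACMotif, direction: str = "forward") -> list[Interval]:
    """All (overlapping) occurrence intervals of the motif in ``seq``.

    ``direction="reverse"`` scans for the reversed motif string.  Results
    are 0-based half-open and sorted by start.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    m = motif if direction == "forward" else motif.reversed()
    w = len(m)
    # lookahead makes overlapping occurrences visible to finditer
    pat = re.compile(f"(?=({m.regex.pattern}))")
    return [(match.start(), match.start() + w) for match in pat.finditer(seq)]


def _merged_matches(seq: str, motif: IUPACMotif, direction_mode: str) -> list[tuple[Interval, str]]:
    """(interval, direction) pairs; both-direction hits deduplicated by interval."""
    if direction_mode not in DIRECTION_MODES:
        raise ValueError(
            f"direction_mode must be one of {DIRECTION_MODES}, got {direction_mode!r}"
        )
    hits = [(iv, "forward") for iv in find_matches(seq, motif, "forward")]
    if direction_mode == "both":
        seen = {iv for iv, _ in hits}
        hits.extend(
            (iv, "reverse")
            for iv in find_matches(seq, motif, "reverse")
            if iv not in seen
        )
    return sorted(hits)


@dataclass(frozen=True)
class MatchHit:
    """One motif occurrence on a precursor, in precursor coordinates."""

    precursor_id: str
    region: str
    direction: str
    start: int
    end: int
    matched_seq: str
    motif: str

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)


@dataclass
class SearchSummary:
    """Outcome of a single-motif database search."""

    hits: list[MatchHit]
    hit_precursors: list[str]
    skipped: list[str]

    @property
    def n_hit_precursors(self) -> int:
        return len(self.hit_precursors)


def _region_hits(
    pre_id: str,
    sequence: str,
    intervals: Iterable[Interval],
    region: str,
    motif: IUPACMotif,
    direction_mode: str,
) -> list[MatchHit]:
    hits = []
    for rs, re_ in intervals:
        sub = sequence[rs:re_]
        for (ms, me), direction in _merged_matches(sub, motif, direction_mode):
            hits.append(
                MatchHit(
                    precursor_id=pre_id,
                    region=region,
                    direction=direction,
                    start=rs + ms,
                    end=rs + me,
                    matched_seq=sub[ms:me],
                    motif=motif.pattern,
                )
            )
    return hits


def search_single(
    db: PrecursorDatabase,
    annotations: dict[str, RegionAnnotation] | None,
    motif: IUPACMotif | str,
    region: str = "loop",
    direction_mode: str = "forward",
) -> SearchSummary:
    """Search every precursor for one motif within a named region.

    Precursors lacking the region (no terminal loop found, no mature
    mapped) are skipped and listed separately, never silently counted as
    non-hits.  The summary reports the precursors with at least one hit.
    """
    if region not in REGIONS:
        raise ValueError(f"region must be one of {REGIONS}, got {region!r}")
    if region != "whole" and annotations is None:
        raise ValueError(f"region {region!r} requires structure annotations")
    if isinstance(motif, str):
        motif = compile_motif(motif)
    hits: list[MatchHit] = []
    hit_precursors: list[str] = []
    skipped: list[str] = []
    for pre in db:
        if region == "whole":
            intervals: list[Interval] = [(0, len(pre))]
        else:
            intervals = annotations[pre.id].region_intervals(region) if pre.id in annotations else []
            if not intervals:
                skipped.append(pre.id)
                continue
        pre_hits = _region_hits(pre.id, pre.sequence, intervals, region, motif, direction_mode)
        if pre_hits:
            hits.extend(pre_hits)
            hit_precursors.append(pre.id)
    return SearchSummary(hits=hits, hit_precursors=hit_precursors, skipped=skipped)


CATEGORIES = ("motif1_only", "motif2_only", "both", "neither")


@dataclass
class PairSearchResult:
    """Outcome of a two-motif search.

    ``categories`` maps each searchable precursor to one of
    ``motif1_only`` / ``motif2_only`` / ``both`` / ``neither`` (mutually
    exclusive, by occurrence presence).  ``both_nonoverlapping`` is the
    subset of ``both`` for which some occurrence pair has disjoint
    intervals; with ``allow_overlap=False`` it is the effective "both"
    list (``both_selected``).
    """

    categories: dict[str, str]  # precursor_id -> category
    both_nonoverlapping: list[str] = field(default_factory=list)
    allow_overlap: bool = True
    hits1: list[MatchHit] = field(default_factory=list)
    hits2: list[MatchHit] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    def precursors_in(self, category: str) -> list[str]:
        if category == "both_nonoverlapping":
            return list(self.both_nonoverlapping)
        return [pid for pid, cat in self.categories.items() if cat == category]

    @property
    def both_selected(self) -> list[str]:
        """The "both" list under the configured overlap policy."""
        if self.allow_overlap:
            return self.precursors_in("both")
        return list(self.both_nonoverlapping)

    @property
    def union_with_any(self) -> list[str]:
        return [pid for pid, cat in self.categories.items() if cat != "neither"]


def _has_disjoint_pair(ivs1: list[Interval], ivs2: list[Interval]) -> bool:
    # overlap is closed-interval intersection being non-empty; "exclude
    # overlap" requires existence of one disjoint occurrence pair
    return any(e1 <= s2 or e2 <= s1 for (s1, e1) in ivs1 for (s2, e2) in ivs2)


def search_pair(
    db: PrecursorDatabase,
    annotations: dict[str, RegionAnnotation] | None,
    motif1: IUPACMotif | str,
    motif2: IUPACMotif | str,
    region: str = "loop",
    direction_mode: str = "forward",
    allow_overlap: bool = True,
) -> PairSearchResult:
    """Search every precursor for two motifs simultaneously.

    Each searchable precursor is categorized as ``both`` (each motif
    occurs at least once; with ``allow_overlap=False`` the category
    additionally requires an occurrence pair with disjoint intervals),
    ``motif1_only``, ``motif2_only``, or ``neither``.
    """
    if isinstance(motif1, str):
        motif1 = compile_motif(motif1)
    if isinstance(motif2, str):
        motif2 = compile_motif(motif2)
    r1 = search_single(db, annotations, motif1, region, direction_mode)
    r2 = search_single(db, annotations, motif2, region, direction_mode)
    set1, set2 = set(r1.hit_precursors), set(r2.hit_precursors)
    categories: dict[str, str] = {}
    by_pre1: dict[str, list[Interval]] = {}
    by_pre2: dict[str, list[Interval]] = {}
    for h in r1.hits:
        by_pre1.setdefault(h.precursor_id, []).append(h.interval)
    for h in r2.hits:
        by_pre2.setdefault(h.precursor_id, []).append(h.interval)
    skipped = set(r1.skipped)
    both_nonoverlapping: list[str] = []
    for pre in db:
        pid = pre.id
        if pid in skipped:
            continue
        in1, in2 = pid in set1, pid in set2
        if in1 and in2:
            categories[pid] = "both"
            if _has_disjoint_pair(by_pre1[pid], by_pre2[pid]):
                both_nonoverlapping.append(pid)
        elif in1:
            categories[pid] = "motif1_only"
        elif in2:
            categories[pid] = "motif2_only"
        else:
            categories[pid] = "neither"
    return PairSearchResult(
        categories=categories,
        both_nonoverlapping=both_nonoverlapping,
        allow_overlap=allow_overlap,
        hits1=r1.hits,
        hits2=r2.hits,
        skipped=sorted(skipped),
    )
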