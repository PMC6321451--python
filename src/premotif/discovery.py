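"""Discriminative discovery of enriched IUPAC motifs.

Given a positive group of precursor (region) sequences and a background
set, the engine enumerates exact words, scores each by a one-sided
Fisher's exact test on sequence-level counts (how many positives vs how
many negatives contain the word at least once), greedily generalizes the
best seeds one position at a time into 2- and 3-base IUPAC classes, and
reports the best motif when its E-value passes the threshold.  The
E-value Bonferroni-corrects the p-value for the size of the IUPAC
pattern space at the motif's width (15^w candidate patterns) — the space
the greedy generalization effectively selects from; a looser correction
would let degenerate patterns overfit label noise.  Reported
motifs are then *erased* — every sequence containing the motif is removed
from both sets — and the search repeats.

The procedure is a word-enumeration discriminative search in the style of
DREME (Bailey 2011), entirely deterministic: identical inputs give
identical ranked output.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from premotif.mirbase_io import PrecursorDatabase, normalize_rna
from premotif.motif_search import (
    IUPAC_CODES,
    IUPACMotif,
    compile_motif,
    find_matches,
)

logger = logging.getLogger(__name__)

# degenerate classes usable during generalization (2- and 3-base sets)
_GENERALIZATION_CLASSES = [
    sym for sym, bases in IUPAC_CODES.items() if len(bases) in (2, 3)
]

_NAME_LINE = re.compile(r"^[A-Za-z]{3}-[A-Za-z0-9*\-]+$")
_SEQ_LINE = re.compile(r"^[ACGUTacgut]+$")


@dataclass(frozen=True)
class ContingencyTable:
    """Sequence-level counts behind one motif's enrichment test."""

    p_with: int
    p_total: int
    n_with: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.p_with <= self.p_total and 0 <= self.n_with <= self.n_total):
            raise ValueError(f"inconsistent contingency table: {self}")


@dataclass(frozen=True)
class DiscoveredMotif:
    """One reported motif with its enrichment statistics.

    ``e_value`` is the enrichment p-value multiplied by the number of
    candidate IUPAC patterns at the motif's width (15^w).
    """

    pattern: str
    table: ContingencyTable
    p_value: float
    e_value: float
    rank: int


def n_candidate_patterns(width: int) -> int:
    """Size of the IUPAC pattern space at a given width (15 letters/position)."""
    return len(IUPAC_CODES) ** width


def fisher_enrichment_p(table: ContingencyTable) -> float:
    """One-sided Fisher's exact test for enrichment in the positive set.

    The p-value is the upper hypergeometric tail: the probability of
    drawing at least ``p_with`` motif-containing sequences when
    ``p_total`` sequences are drawn without replacement from the pooled
    ``p_total + n_total`` sequences of which ``p_with + n_with`` contain
    the motif.  Evaluated through the survival function of the
    hypergeometric distribution (log-gamma based, numerically safe for
    large counts).
    """
    M = table.p_total + table.n_total
    K = table.p_with + table.n_with
    N = table.p_total
    if table.p_with == 0:
        return 1.0
    return float(hypergeom.sf(table.p_with - 1, M, K, N))


def _contains(seq: str, motif: IUPACMotif, direction_mode: str) -> bool:
    if motif.regex.search(seq):
        return True
    if direction_mode == "both":
        return bool(motif.reversed().regex.search(seq))
    return False


def count_sequences_with_motif(
    seqs: Sequence[str], motif: IUPACMotif | str, direction_mode: str = "forward"
) -> int:
    """Number of sequences containing >= 1 occurrence (sequence-level count)."""
    if isinstance(motif, str):
        motif = compile_motif(motif)
    return sum(1 for s in seqs if _contains(s, motif, direction_mode))


def _seed_index(seqs: Sequence[str], width: int, direction_mode: str) -> dict[str, set[int]]:
    """word -> set of sequence indices containing it (forward scan;
    in both-direction mode a sequence also counts if it contains the
    reversed word)."""
    index: dict[str, set[int]] = {}
    for si, seq in enumerate(seqs):
        for pos in range(len(seq) - width + 1):
            word = seq[pos : pos + width]
            index.setdefault(word, set()).add(si)
    if direction_mode == "both":
        forward_only = {w: set(idx) for w, idx in index.items()}
        for word, idx in index.items():
            rev = word[::-1]
            if rev in forward_only:
                idx |= forward_only[rev]
    return index


class _Counter:
    """Memoized sequence-level counting over fixed positive/negative sets."""

    def __init__(self, positives: Sequence[str], negatives: Sequence[str], direction_mode: str):
        self.positives = positives
        self.negatives = negatives
        self.direction_mode = direction_mode
        self._cache: dict[str, ContingencyTable] = {}

    def table(self, pattern: str) -> ContingencyTable:
        cached = self._cache.get(pattern)
        if cached is not None:
            return cached
        motif = compile_motif(pattern)
        t = ContingencyTable(
            p_with=count_sequences_with_motif(self.positives, motif, self.direction_mode),
            p_total=len(self.positives),
            n_with=count_sequences_with_motif(self.negatives, motif, self.direction_mode),
            n_total=len(self.negatives),
        )
        self._cache[pattern] = t
        return t


def _generalize(seed: str, counter: _Counter) -> tuple[str, ContingencyTable, float]:
    """Greedy IUPAC generalization of a seed word.

    At each step every single concrete position is tentatively replaced by
    each 2-/3-base IUPAC class; the variant with the lowest p is kept, and
    the loop stops when no variant improves p.  Generalization can only
    widen the matched set, so p_with and n_with never decrease.
    """
    best = seed
    best_table = counter.table(seed)
    best_p = fisher_enrichment_p(best_table)
    improved = True
    while improved:
        improved = False
        candidates: list[tuple[float, int, str]] = []
        tables: dict[str, ContingencyTable] = {}
        for pos, ch in enumerate(best):
            if len(IUPAC_CODES[ch]) != 1:
                continue
            for cls in _GENERALIZATION_CLASSES:
                if ch not in IUPAC_CODES[cls]:
                    continue
                variant = best[:pos] + cls + best[pos + 1 :]
                t = counter.table(variant)
                # generalization widens the matched set, never narrows it
                assert t.p_with >= best_table.p_with and t.n_with >= best_table.n_with
                tables[variant] = t
                candidates.append((fisher_enrichment_p(t), -t.p_with, variant))
        if candidates:
            p, _, variant = min(candidates)
            if p < best_p:
                best, best_table, best_p = variant, tables[variant], p
                improved = True
    return best, best_table, best_p


def discover_motifs(
    positives: Sequence[str],
    negatives: Sequence[str],
    widths: Iterable[int] = range(3, 9),
    direction_mode: str = "forward",
    e_threshold: float = 0.05,
    max_motifs: int = 10,
    beam_width: int = 8,
    min_seed_positives: int = 2,
) -> list[DiscoveredMotif]:
    """Iteratively discover enriched IUPAC motifs (positives vs negatives).

    Each round enumerates, for every width, all exact words present in at
    least ``min_seed_positives`` positive sequences, scores them with
    :func:`fisher_enrichment_p`, generalizes the ``beam_width`` best seeds
    per width, and reports the best motif overall if its E-value
    (p times the number of candidate IUPAC patterns at its width,
    Bonferroni over the space the generalization selects from) is at most
    ``e_threshold``.  All sequences containing a reported motif are erased
    from both sets before the next round.  Candidates are ranked by
    E-value ascending (so different widths compete on a common scale),
    ties by p, then higher positive count, then lexicographic pattern;
    the whole procedure is deterministic.
    """
    if not positives:
        raise ValueError("positive set is empty")
    if not negatives:
        raise ValueError("negative set is empty")
    positives = [normalize_rna(s) for s in positives]
    negatives = [normalize_rna(s) for s in negatives]
    widths = sorted(set(widths))
    results: list[DiscoveredMotif] = []
    while len(results) < max_motifs and positives:
        counter = _Counter(positives, negatives, direction_mode)
        best_overall: tuple[tuple[float, int, str], str, ContingencyTable, int] | None = None
        for width in widths:
            index = _seed_index(positives, width, direction_mode)
            seeds = {w: idx for w, idx in index.items() if len(idx) >= min_seed_positives}
            if not seeds:
                continue
            scored: list[tuple[float, int, str]] = []
            for word in seeds:
                t = counter.table(word)
                scored.append((fisher_enrichment_p(t), -t.p_with, word))
            scored.sort()
            for _, _, word in scored[:beam_width]:
                pattern, table, p = _generalize(word, counter)
                # widths compete on the E scale: the multiplier grows with
                # width, so raw p would favour long overfit patterns
                e = p * n_candidate_patterns(len(pattern))
                key = (e, p, -table.p_with, pattern)
                if best_overall is None or key < best_overall[0]:
                    best_overall = (key, pattern, table)
        if best_overall is None:
            break
        (e_value, p, _, pattern), _, table = best_overall
        if e_value > e_threshold:
            break
        results.append(
            DiscoveredMotif(
                pattern=pattern,
                table=table,
                p_value=p,
                e_value=e_value,
                rank=len(results) + 1,
            )
        )
        motif = compile_motif(pattern)
        positives = [s for s in positives if not _contains(s, motif, direction_mode)]
        negatives = [s for s in negatives if not _contains(s, motif, direction_mode)]
        if not negatives:
            break
    return results


@dataclass
class ResolvedInputs:
    """Outcome of parsing a positives list: sequences plus bookkeeping."""

    sequences: list[str]
    resolved_names: list[str]
    raw_sequences: int
    unresolved: list[str]


def resolve_inputs(
    lines: Iterable[str],
    db: PrecursorDatabase | None = None,
    annotations=None,
    region: str = "whole",
) -> ResolvedInputs:
    """Turn a user list of precursor names and/or raw sequences into sequences.

    Each non-empty, non-comment line is either a miRBase-style name
    (resolved case-insensitively against the database, ``miR``/``mir``
    spelling ignored) or a raw RNA/DNA sequence.  Unresolvable names are
    reported and the run continues; zero resolvable inputs is an error.
    For names, the chosen region (loop/linking/mature/whole) is extracted
    from the precursor using ``annotations`` when not ``whole``.
    """
    sequences: list[str] = []
    resolved: list[str] = []
    unresolved: list[str] = []
    n_raw = 0
    for raw_line in lines:
        line = raw_line.strip()
        if not line or line.startswith("#"):
            continue
        if _SEQ_LINE.match(line):
            sequences.append(normalize_rna(line))
            n_raw += 1
            continue
        if not _NAME_LINE.match(line):
            unresolved.append(line)
            logger.warning("cannot interpret input line %r", line)
            continue
        if db is None:
            unresolved.append(line)
            continue
        # mature-style names (hsa-miR-96) address the precursor (hsa-mir-96)
        name = line.lower()
        pre = db.get(name)
        if pre is None:
            stripped = re.sub(r"(-5p|-3p|\*)$", "", name)
            pre = db.get(stripped)
        if pre is None:
            unresolved.append(line)
            logger.warning("name %r not found in precursor database", line)
            continue
        if region == "whole":
            sequences.append(pre.sequence)
        else:
            ann = (annotations or {}).get(pre.id)
            intervals = ann.region_intervals(region) if ann else []
            if not intervals:
                unresolved.append(line)
                logger.warning("precursor %s lacks region %r", pre.id, region)
                continue
            sequences.extend(pre.sequence[s:e] for s, e in intervals if e > s)
        resolved.append(pre.id)
    if not sequences:
        raise ValueError("no resolvable inputs: every line failed to parse or resolve")
    return ResolvedInputs(
        sequences=sequences,
        resolved_names=resolved,
        raw_sequences=n_raw,
        unresolved=unresolved,
    )


def motif_to_pfm(
    motif: IUPACMotif | str, matched_site_sequences: Sequence[str]
) -> dict[str, list[int]]:
    """Position frequency matrix over {A, C, G, U} from matched sites.

    All sites must have the motif's length; column sums equal the number
    of sites.
    """
    if isinstance(motif, str):
        motif = compile_motif(motif)
    if not matched_site_sequences:
        raise ValueError("cannot build a PFM from zero sites")
    w = len(motif)
    for s in matched_site_sequences:
        if len(s) != w:
            raise ValueError(f"site {s!r} length differs from motif width {w}")
    pfm = {b: [0] * w for b in "ACGU"}
    for site in matched_site_sequences:
        for i, b in enumerate(normalize_rna(site)):
            pfm[b][i] += 1
    return pfm


def matched_sites(seqs: Sequence[str], motif: IUPACMotif | str, direction_mode: str = "forward") -> list[str]:
    """All matched subsequences across a sequence set (for PFM building)."""
    if isinstance(motif, str):
        motif = compile_motif(motif)
    sites: list[str] = []
    for seq in seqs:
        seq = normalize_rna(seq)
        for s, e in find_matches(seq, motif, "forward"):
            sites.append(seq[s:e])
        if direction_mode == "both":
            for s, e in find_matches(seq, motif, "reverse"):
                sites.append(seq[s:e])
    return sites


def write_meme_minimal(
    motifs: Sequence[tuple[str, dict[str, list[int]]]], path, background: dict[str, float] | None = None
) -> None:
    """Write motifs as MEME minimal motif format (RNA alphabet).

    ``motifs`` is a list of (name, PFM) pairs; PFM columns are normalized
    to letter probabilities.
    """
    bg = background or {b: 0.25 for b in "ACGU"}
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[b]:.3f}" for b in "ACGU") + "\n\n")
        for name, pfm in motifs:
            w = len(next(iter(pfm.values())))
            nsites = sum(pfm[b][0] for b in "ACGU")
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {w} nsites= {nsites}\n"
            )
            for i in range(w):
                col = sum(pfm[b][i] for b in "ACGU")
                fh.write(
                    " ".join(f"{pfm[b][i] / col:8.6f}" for b in "ACGU") + "\n"
                )
            fh.write("\n")
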