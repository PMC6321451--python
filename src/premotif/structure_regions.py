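"""Secondary structure prediction and region decomposition of precursors.

A pre-miRNA folds into a stem-loop whose parts matter differently to
RNA-binding proteins: the apical *terminal loop* (extended here by a 2-nt
overhang into the stem), the *linking sequence* between the two mature
arms, the mature miRNAs themselves, and the structure-predicted
*passenger strand* when only one arm carries an annotated mature miRNA.

Folding goes through a pluggable :class:`FoldEngine` contract (sequence ->
dot-bracket).  The bundled reference engine is a deterministic
maximum-base-pairing (Nussinov-style) folder over the pair set
{A-U, G-C, G-U} with a minimum hairpin loop of 3 nt; an adapter to
ViennaRNA's RNAfold is provided for minimum-free-energy structures.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass
from typing import Protocol

import numpy as np

logger = logging.getLogger(__name__)

CANONICAL_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
                             ("G", "U"), ("U", "G")})
MIN_HAIRPIN_LOOP = 3
MIN_FOLD_LENGTH = 10

Interval = tuple[int, int]


class FoldError(ValueError):
    """Raised when a sequence cannot be folded or decomposed."""


def can_pair(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested secondary structure: dot-bracket string plus partner table."""

    dotbracket: str
    pairs: tuple[int | None, ...]  # partner index per position, None if unpaired

    @classmethod
    def from_dotbracket(cls, dotbracket: str) -> "SecondaryStructure":
        partners: list[int | None] = [None] * len(dotbracket)
        stack: list[int] = []
        for i, ch in enumerate(dotbracket):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                if not stack:
                    raise ValueError("unbalanced dot-bracket string")
                j = stack.pop()
                partners[j], partners[i] = i, j
            elif ch != ".":
                raise ValueError(f"invalid dot-bracket character {ch!r}")
        if stack:
            raise ValueError("unbalanced dot-bracket string")
        return cls(dotbracket, tuple(partners))

    @property
    def n_pairs(self) -> int:
        return self.dotbracket.count("(")

    def __len__(self) -> int:
        return len(self.dotbracket)


class FoldEngine(Protocol):
    """Contract: deterministic map from an RNA sequence to dot-bracket."""

    def fold(self, seq: str) -> str: ...


def _nussinov_matrix(seq: str) -> np.ndarray:
    """Fill the maximum-pairing DP table N[i, j] over 0-based half... inclusive j."""
    n = len(seq)
    N = np.zeros((n + 1, n + 1), dtype=np.int32)  # N[i][j] over inclusive [i, j]
    pairable = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            pairable[i, j] = can_pair(seq[i], seq[j])
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1, j]  # i unpaired
            if pairable[i, j]:
                best = max(best, N[i + 1, j - 1] + 1)
            if span >= 2:
                # bifurcation: split [i, j] into [i, k] + [k+1, j]
                ks = np.arange(i + 1, j)
                split = N[i, ks] + N[ks + 1, j]
                best = max(best, int(split.max()))
            N[i, j] = best
    return N


def _traceback(seq: str, N: np.ndarray, i: int, j: int, paired: list[str]) -> None:
    """Deterministic traceback.

    Preference at each interval: close the (i, j) pair, else split at the
    smallest k whose left part [i, k] holds at least one pair (this also
    covers trailing unpaired tails, with an empty right part), else leave
    i unpaired.
    """
    while i < j:
        if N[i, j] == 0:
            return
        if (
            j - i > MIN_HAIRPIN_LOOP
            and can_pair(seq[i], seq[j])
            and N[i, j] == N[i + 1, j - 1] + 1
        ):
            paired[i], paired[j] = "(", ")"
            i, j = i + 1, j - 1
            continue
        bifurcated = False
        for k in range(i + 1, j):
            if N[i, k] >= 1 and N[i, j] == N[i, k] + N[k + 1, j]:
                _traceback(seq, N, i, k, paired)
                i = k + 1
                bifurcated = True
                break
        if not bifurcated:
            i += 1  # i unpaired


def fold_reference(seq: str, min_length: int = MIN_FOLD_LENGTH) -> str:
    """Maximum base-pairing nested structure (Nussinov), as dot-bracket.

    Pair set {A-U, G-C, G-U}, minimum hairpin loop of 3 unpaired nt, and a
    deterministic traceback (preference: close the (i, j) pair, then the
    smallest bifurcation point with pairs on both sides, then leave i
    unpaired), so a given sequence always yields the same structure.
    """
    if len(seq) < min_length:
        raise FoldError(f"sequence of length {len(seq)} is too short to fold")
    bad = set(seq) - set("ACGU")
    if bad:
        raise FoldError(f"non-RNA characters in sequence: {sorted(bad)}")
    N = _nussinov_matrix(seq)
    paired = ["."] * len(seq)
    _traceback(seq, N, 0, len(seq) - 1, paired)
    return "".join(paired)


class NussinovFold:
    """The bundled reference fold engine (see :func:`fold_reference`)."""

    def fold(self, seq: str) -> str:
        return fold_reference(seq)


class RNAfoldEngine:
    """Adapter to ViennaRNA's ``RNAfold`` executable (MFE structures).

    Requires ``RNAfold`` on PATH; structure-dependent regions then follow
    the thermodynamic model instead of maximum pairing.
    """

    def __init__(self, executable: str = "RNAfold") -> None:
        if shutil.which(executable) is None:
            raise FoldError(f"{executable!r} not found on PATH")
        self.executable = executable

    def fold(self, seq: str) -> str:
        proc = subprocess.run(
            [self.executable, "--noPS"],
            input=seq + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
        # output: sequence line, then "structure (energy)"
        structure_line = proc.stdout.splitlines()[1]
        return structure_line.split()[0]


@dataclass
class RegionAnnotation:
    """Structure-derived regions of one precursor (0-based half-open)."""

    precursor_id: str
    loop: Interval | None = None
    linking: Interval | None = None
    mature_intervals: list[Interval] | None = None
    passenger: Interval | None = None
    passenger_predicted: bool = False
    structure: SecondaryStructure | None = None
    failures: list[str] | None = None

    def region_intervals(self, region: str) -> list[Interval]:
        """Intervals for a named region: loop, linking, mature, or whole."""
        if region == "loop":
            return [self.loop] if self.loop else []
        if region == "linking":
            return [self.linking] if self.linking else []
        if region == "mature":
            return list(self.mature_intervals or [])
        raise ValueError(f"unknown region {region!r}")


def _hairpin_loops(structure: SecondaryStructure) -> list[tuple[Interval, int]]:
    """All hairpin loops: (unpaired run, enclosing-pair count of the stem).

    A hairpin loop is a maximal unpaired run directly closed by a pair
    (i, j) with i < run < j and partner(i) == j.  The enclosing-pair count
    is the number of structure pairs (a, b) with a < run start and
    b >= run end — the stem below the loop plus any outer helices.
    """
    db = structure.dotbracket
    pairs = structure.pairs
    loops: list[tuple[Interval, int]] = []
    n = len(db)
    i = 0
    while i < n:
        if db[i] != ".":
            i += 1
            continue
        j = i
        while j < n and db[j] == ".":
            j += 1
        # unpaired run [i, j); closed iff flanks are a pair of each other
        if i > 0 and j < n and pairs[i - 1] == j:
            enclosing = sum(
                1
                for a, b in enumerate(pairs)
                if b is not None and a < b and a < i and b >= j
            )
            loops.append(((i, j), enclosing))
        i = j
    return loops


def find_terminal_loop(
    structure: SecondaryStructure, overhang: int = 2
) -> Interval:
    """Locate the terminal (apical) loop, extended by a 2-nt overhang.

    Among all hairpin loops the one whose closing stem carries the most
    enclosing base pairs is taken as the terminal loop of the main stem;
    ties break toward the loop whose midpoint is nearest the sequence
    midpoint, then toward the lower start index.  The unpaired run is
    extended by ``overhang`` nt into the stem on each side, clipped to the
    sequence bounds.
    """
    if structure.n_pairs == 0:
        raise FoldError("no stem-loop found (structure has no base pairs)")
    loops = _hairpin_loops(structure)
    if not loops:
        raise FoldError("no hairpin loop found")
    n = len(structure)
    mid = (n - 1) / 2.0

    def key(item: tuple[Interval, int]):
        (start, end), enclosing = item
        loop_mid = (start + end - 1) / 2.0
        return (-enclosing, abs(loop_mid - mid), start)

    (start, end), _ = min(loops, key=key)
    return (max(0, start - overhang), min(n, end + overhang))


def linking_interval(interval_5p: Interval, interval_3p: Interval) -> Interval:
    """Sequence between the 5'-arm and 3'-arm intervals (may be empty)."""
    (s5, e5), (s3, e3) = interval_5p, interval_3p
    if s5 > s3:
        (s5, e5), (s3, e3) = (s3, e3), (s5, e5)
    if e5 > s3:
        raise ValueError(
            f"mature/passenger intervals overlap: [{s5},{e5}) and [{s3},{e3})"
        )
    return (e5, s3)


def predict_passenger(
    structure: SecondaryStructure, mature: Interval, overhang: int = 2
) -> Interval | None:
    """Predict the passenger strand as the duplex partner of a mature miRNA.

    Partners of all paired mature positions are collected; the passenger is
    their spanning interval extended by ``overhang`` nt at its 3' end
    (producing the canonical 2-nt 3' overhang of the miRNA duplex), clipped
    to the sequence bounds and truncated if the extension would collide
    with the mature interval.  Returns None (with a warning) when the
    mature region is entirely unpaired.
    """
    m_start, m_end = mature
    partners = [
        structure.pairs[i] for i in range(m_start, m_end) if structure.pairs[i] is not None
    ]
    if not partners:
        logger.warning("mature interval [%d,%d) is entirely unpaired", m_start, m_end)
        return None
    lo, hi = min(partners), max(partners) + 1
    n = len(structure)
    mature_is_5p = m_start < lo  # partners lie 3' of the mature strand
    if mature_is_5p:
        hi = min(n, hi + overhang)
    else:
        lo = max(0, lo - overhang)
        lo = max(lo, 0)
        # do not run into the mature interval itself
        if hi > m_start >= lo:
            hi = m_start
    if mature_is_5p and lo < m_end:
        lo = m_end
    return (lo, hi)


def annotate_regions(
    db,
    engine: FoldEngine | None = None,
    loop_overhang: int = 2,
) -> dict[str, RegionAnnotation]:
    """Fold every precursor and decompose it into regions.

    Per precursor: fold, locate the terminal loop; with two mature loci
    compute the linking sequence between them; with a single mature locus
    predict the passenger strand from the structure and compute linking
    between mature and passenger.  Failures are recorded per precursor in
    ``RegionAnnotation.failures`` and never abort the batch; the whole
    precursor always remains searchable.
    """
    engine = engine or NussinovFold()
    annotations: dict[str, RegionAnnotation] = {}
    for pre in db:
        ann = RegionAnnotation(precursor_id=pre.id, failures=[])
        loci = sorted(db.loci_for(pre.id), key=lambda l: l.start)
        ann.mature_intervals = [loc.interval for loc in loci]
        try:
            structure = SecondaryStructure.from_dotbracket(engine.fold(pre.sequence))
            ann.structure = structure
        except (FoldError, ValueError, subprocess.SubprocessError) as exc:
            ann.failures.append(f"fold: {exc}")
            annotations[pre.id] = ann
            continue
        try:
            ann.loop = find_terminal_loop(structure, overhang=loop_overhang)
        except FoldError as exc:
            ann.failures.append(f"loop: {exc}")
        if len(loci) >= 2:
            first, last = loci[0], loci[-1]
            try:
                ann.linking = linking_interval(first.interval, last.interval)
            except ValueError as exc:
                ann.failures.append(f"linking: {exc}")
        elif len(loci) == 1:
            passenger = predict_passenger(structure, loci[0].interval)
            if passenger is None:
                ann.failures.append("passenger: mature entirely unpaired")
            else:
                ann.passenger = passenger
                ann.passenger_predicted = True
                try:
                    ann.linking = linking_interval(loci[0].interval, passenger)
                except ValueError as exc:
                    ann.failures.append(f"linking: {exc}")
        annotations[pre.id] = ann
    return annotations


def skipped_ids(annotations: dict[str, RegionAnnotation], region: str) -> list[str]:
    """Precursors lacking the given region (distinct from non-hits)."""
    if region == "whole":
        return []
    return [
        pid for pid, ann in annotations.items() if not ann.region_intervals(region)
    ]


def write_regions_tsv(annotations: dict[str, RegionAnnotation], path) -> None:
    """BED-like TSV export: precursor_id, start0, end0, region_name."""
    with open(path, "w") as fh:
        fh.write("precursor_id\tstart0\tend0\tregion\n")
        for pid, ann in annotations.items():
            rows: list[tuple[int, int, str]] = []
            if ann.loop:
                rows.append((*ann.loop, "loop"))
            if ann.linking:
                rows.append((*ann.linking, "linking"))
            for k, iv in enumerate(ann.mature_intervals or []):
                rows.append((*iv, f"mature_{k + 1}"))
            if ann.passenger:
                rows.append((*ann.passenger, "passenger"))
            for s, e, name in rows:
                fh.write(f"{pid}\t{s}\t{e}\t{name}\n")
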