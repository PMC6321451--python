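"""Deterministic generator of miniature miRBase-like datasets.

Each synthetic precursor is a clean stem-loop: a random 5' arm, a short
apical loop, and the 3' arm built as the reverse complement of the 5' arm
(with optional G-U wobbles injected).  Mature records cover the outer
part of each arm, so the mature-to-precursor substring mapping, the
structure decomposition, and the region-restricted searches all have a
known ground truth.  Motifs can be planted into a chosen region in a
controlled fraction of precursors; every planted interval is recorded in
a truth TSV.

Geometry notes: the apical loop filler is poly-A and the default loop is
a 4-nt (tetraloop-like) run, so no base pair can form inside the loop and
the maximum-pairing reference folder recovers the constructed stem
exactly.  Loop-planted motifs start inside the 2-nt stem overhang of the
searched loop region; planted stem positions are complemented on the 3'
arm, which keeps the hairpin perfect.  All randomness flows from the
single ``seed`` of the spec, so a given spec always produces
byte-identical files.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path

from premotif.mirbase_io import (
    MatureLocus,
    Precursor,
    PrecursorDatabase,
    map_mature_to_precursors,
)
from premotif.motif_search import IUPAC_CODES, compile_motif

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

REGION_CHOICES = ("loop", "linking", "mature", "whole")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``planted_motif`` is an IUPAC pattern planted (as a concrete random
    instantiation) into ``planted_region`` of the first
    ``round(planted_fraction * n_precursors)`` precursors.
    """

    n_precursors: int = 6
    stem_length: int = 22
    loop_length: int = 4
    arms: int = 2
    mature_length: int | None = None  # default: stem_length - 4
    planted_motif: str | None = None
    planted_region: str = "loop"
    planted_fraction: float = 0.5
    wobble_prob: float = 0.1
    seed: int = 0
    species_prefix: str = "syn"

    def __post_init__(self) -> None:
        if self.stem_length < 8:
            raise ValueError("stem_length must be >= 8")
        if self.loop_length < 3:
            raise ValueError("loop_length must be >= 3")
        if self.arms not in (1, 2):
            raise ValueError("arms must be 1 or 2")
        if not (0.0 <= self.planted_fraction <= 1.0):
            raise ValueError("planted_fraction must be within [0, 1]")
        if self.planted_region not in REGION_CHOICES:
            raise ValueError(f"planted_region must be one of {REGION_CHOICES}")
        ml = self.effective_mature_length
        if not (4 <= ml <= self.stem_length):
            raise ValueError("mature_length must be within [4, stem_length]")

    @property
    def effective_mature_length(self) -> int:
        return self.mature_length if self.mature_length is not None else self.stem_length - 4

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class FixtureData:
    """In-memory form of a generated dataset."""

    db: PrecursorDatabase
    matures: list[Precursor]
    truth: list[tuple[str, str, int, int, str]]  # (precursor_id, region, start0, end0, instance)
    planted_ids: list[str] = field(default_factory=list)


def _instantiate(pattern: str, rng: random.Random) -> str:
    motif = compile_motif(pattern)
    return "".join(rng.choice(sorted(IUPAC_CODES[ch])) for ch in motif.pattern)


def _plant_position(spec: FixtureSpec, motif_len: int) -> int:
    """Planting start (0-based, on the final precursor) for each region."""
    stem, loop, ml = spec.stem_length, spec.loop_length, spec.effective_mature_length
    if spec.planted_region == "loop":
        # loop region searched is the unpaired run +/- 2 nt of stem overhang
        start, room = stem - 2, loop + 4
    elif spec.planted_region == "linking":
        # linking spans [mature5p end, mature3p start); plant in its 5' part
        # so the instance never spills into the derived 3' arm
        start, room = ml, (stem + loop) - ml
    elif spec.planted_region == "mature":
        start, room = 2, ml - 2
    else:  # whole
        start, room = 4, stem - 4
    if motif_len > room:
        raise ValueError(
            f"motif of length {motif_len} does not fit in region "
            f"{spec.planted_region!r} (room {room})"
        )
    return start


def build_fixture(spec: FixtureSpec) -> FixtureData:
    """Generate the dataset in memory (see module docstring for geometry)."""
    rng = random.Random(spec.seed)
    db = PrecursorDatabase()
    matures: list[Precursor] = []
    truth: list[tuple[str, str, int, int, str]] = []
    planted_ids: list[str] = []
    n_planted = round(spec.planted_fraction * spec.n_precursors) if spec.planted_motif else 0
    stem, loop_len, ml = spec.stem_length, spec.loop_length, spec.effective_mature_length
    for k in range(spec.n_precursors):
        name = f"{spec.species_prefix}-mir-{k + 1}"
        arm5 = [rng.choice("ACGU") for _ in range(stem)]
        loop = ["A"] * loop_len
        plant_here = spec.planted_motif is not None and k < n_planted
        if plant_here:
            instance = _instantiate(spec.planted_motif, rng)
            start = _plant_position(spec, len(instance))
            for off, base in enumerate(instance):
                pos = start + off
                if pos < stem:
                    arm5[pos] = base
                elif pos < stem + loop_len:
                    loop[pos - stem] = base
                else:
                    raise ValueError("planted motif runs past the apical loop")
        # 3' arm: reverse complement of the (possibly planted) 5' arm,
        # with G-C pairs occasionally relaxed to G-U wobbles
        arm3 = []
        for base in reversed(arm5):
            comp = _COMPLEMENT[base]
            if comp == "C" and rng.random() < spec.wobble_prob:
                comp = "U"
            arm3.append(comp)
        sequence = "".join(arm5) + "".join(loop) + "".join(arm3)
        db.add_precursor(
            Precursor(
                id=name,
                accession=f"SYN{k + 1:07d}",
                sequence=sequence,
                description=f"{name} SYN{k + 1:07d} synthetic stem-loop",
            )
        )
        matures.append(
            Precursor(
                id=f"{name}-5p",
                accession="",
                sequence=sequence[:ml],
                description=f"{name}-5p synthetic mature",
            )
        )
        if spec.arms == 2:
            matures.append(
                Precursor(
                    id=f"{name}-3p",
                    accession="",
                    sequence=sequence[len(sequence) - ml :],
                    description=f"{name}-3p synthetic mature",
                )
            )
        if plant_here:
            truth.append((name, spec.planted_region, start, start + len(instance), instance))
            planted_ids.append(name)
    map_mature_to_precursors(db, matures)
    return FixtureData(db=db, matures=matures, truth=truth, planted_ids=planted_ids)


@dataclass
class DiscoveryBenchmark:
    """Positive/negative sequence sets with a cleanly planted motif.

    The planted motif occurs exactly once in each of the first
    ``n_planted`` positive sequences and in no negative (and no unplanted
    positive) sequence: candidates with a chance occurrence in either
    scan direction are rejected and resampled, so the true contingency
    table of the planted pattern is known by construction.

    Sequences are i.i.d. uniform random RNA rather than folded hairpins:
    discovery is structure-agnostic, and planting into a hairpin would
    always co-plant the pattern's reverse complement on the opposite arm,
    creating a second, unintended enriched motif.
    """

    positives: list[str]
    negatives: list[str]
    planted_indices: list[int]  # indices into positives
    pattern: str


def make_discovery_benchmark(
    pattern: str = "GGAG",
    n_positives: int = 15,
    n_planted: int = 12,
    n_negatives: int = 100,
    seed: int = 0,
    length: int = 70,
) -> DiscoveryBenchmark:
    """Build positive/negative sequence sets for discovery benchmarks."""
    if n_planted > n_positives:
        raise ValueError("n_planted cannot exceed n_positives")
    rng = random.Random(seed)
    motif = compile_motif(pattern)
    lookahead = re.compile(f"(?=({motif.regex.pattern}))")

    def occurrences(seq: str) -> list[int]:
        fwd = [m.start() for m in lookahead.finditer(seq)]
        if motif.reversed().regex.search(seq):
            fwd.append(-1)  # any reverse-direction occurrence disqualifies
        return fwd

    def random_clean() -> str:
        while True:
            seq = "".join(rng.choice("ACGU") for _ in range(length))
            if not occurrences(seq):
                return seq

    def planted() -> str:
        while True:
            seq = list(random_clean())
            start = rng.randrange(length - len(motif) + 1)
            instance = _instantiate(pattern, rng)
            seq[start : start + len(instance)] = instance
            out = "".join(seq)
            if occurrences(out) == [start]:
                return out

    positives = [planted() for _ in range(n_planted)]
    positives += [random_clean() for _ in range(n_positives - n_planted)]
    negatives = [random_clean() for _ in range(n_negatives)]
    return DiscoveryBenchmark(
        positives=positives,
        negatives=negatives,
        planted_indices=list(range(n_planted)),
        pattern=pattern,
    )


@dataclass(frozen=True)
class FixturePaths:
    hairpin: Path
    mature: Path
    truth: Path


def make_fixture(spec: FixtureSpec, outdir: str | Path) -> FixturePaths:
    """Write hairpin FASTA, mature FASTA and truth TSV for a spec.

    The truth TSV uses 1-based inclusive coordinates (file convention);
    identical specs produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = build_fixture(spec)
    hairpin = outdir / "hairpin.fa"
    mature = outdir / "mature.fa"
    truth = outdir / "truth.tsv"
    with open(hairpin, "w") as fh:
        for pre in data.db:
            fh.write(f">{pre.description}\n{pre.sequence}\n")
    with open(mature, "w") as fh:
        for mat in data.matures:
            fh.write(f">{mat.description}\n{mat.sequence}\n")
    with open(truth, "w") as fh:
        fh.write("precursor_id\tregion\tstart\tend\tinstance\n")
        for pid, region, s, e, instance in data.truth:
            fh.write(f"{pid}\t{region}\t{s + 1}\t{e}\t{instance}\n")
    return FixturePaths(hairpin=hairpin, mature=mature, truth=truth)
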