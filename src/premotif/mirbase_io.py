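"""Reading miRBase-style FASTA files and mapping mature miRNAs into precursors.

miRBase distributes precursor (hairpin) and mature miRNA sequences as RNA
FASTA with headers of the form::

    >hsa-let-7a-1 MI0000060 Homo sapiens let-7a-1 stem-loop

The first whitespace-delimited token is the name, the optional second token
the accession.  This module parses such files into a small in-memory
database, locates each mature miRNA inside its precursor(s) by exact
substring matching (an alternative TSV pathway gives exact coordinate
control), and supports filtering by the three-letter species prefix
(``hsa``, ``mmu``, ``ath``, ...).

All internal coordinates are 0-based half-open; files use 1-based inclusive
coordinates.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_INPUT = re.compile(r"^[ACGUTacgut]+$")

Arm = str  # one of "5p", "3p", "unknown"


class FastaParseError(ValueError):
    """Raised when a FASTA record violates the RNA/DNA alphabet contract."""


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA thymine to RNA uracil."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class Precursor:
    """One hairpin record: a pre-miRNA stem-loop sequence.

    ``species_prefix`` is the substring of ``id`` before the first ``-``
    (miRBase's three-letter organism code).
    """

    id: str
    accession: str
    sequence: str
    description: str = ""

    @property
    def species_prefix(self) -> str:
        return self.id.split("-", 1)[0]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureLocus:
    """Position of a mature miRNA within its precursor (0-based half-open)."""

    mature_id: str
    precursor_id: str
    arm: Arm
    start: int
    end: int

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class PrecursorDatabase:
    """Ordered collection of precursors plus mature loci grouped by precursor.

    Precursor ids are unique; every locus refers to a precursor present in
    the database and its interval reproduces the mature sequence.
    """

    precursors: dict[str, Precursor] = field(default_factory=dict)
    loci: dict[str, list[MatureLocus]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.precursors)

    def __iter__(self) -> Iterable[Precursor]:
        return iter(self.precursors.values())

    def __contains__(self, precursor_id: str) -> bool:
        return precursor_id in self.precursors

    def add_precursor(self, precursor: Precursor) -> None:
        if precursor.id in self.precursors:
            raise ValueError(f"duplicate precursor id: {precursor.id!r}")
        self.precursors[precursor.id] = precursor

    def add_locus(self, locus: MatureLocus) -> None:
        pre = self.precursors.get(locus.precursor_id)
        if pre is None:
            raise ValueError(
                f"locus {locus.mature_id!r} refers to unknown precursor "
                f"{locus.precursor_id!r}"
            )
        if not (0 <= locus.start < locus.end <= len(pre)):
            raise ValueError(
                f"locus {locus.mature_id!r} interval [{locus.start},{locus.end}) "
                f"outside precursor {locus.precursor_id!r} of length {len(pre)}"
            )
        self.loci.setdefault(locus.precursor_id, []).append(locus)

    def loci_for(self, precursor_id: str) -> list[MatureLocus]:
        return self.loci.get(precursor_id, [])

    def get(self, precursor_id: str) -> Precursor | None:
        """Case-insensitive lookup by precursor name."""
        hit = self.precursors.get(precursor_id)
        if hit is not None:
            return hit
        lowered = precursor_id.lower()
        for pid, pre in self.precursors.items():
            if pid.lower() == lowered:
                return pre
        return None


def _parse_record(rec: SeqRecord) -> Precursor:
    seq = str(rec.seq)
    if not seq or not _VALID_INPUT.match(seq):
        raise FastaParseError(
            f"record {rec.id!r}: sequence contains characters outside "
            "the RNA/DNA alphabet (A/C/G/U/T)"
        )
    tokens = rec.description.split()
    accession = tokens[1] if len(tokens) > 1 else ""
    return Precursor(
        id=rec.id,
        accession=accession,
        sequence=normalize_rna(seq),
        description=rec.description,
    )


def read_hairpin_fasta(path: str | Path) -> PrecursorDatabase:
    """Read a hairpin FASTA into a :class:`PrecursorDatabase` (no loci yet).

    Sequences are uppercased and T->U normalized; record order is preserved.
    Duplicate ids are a hard error; an empty file yields an empty database
    with a warning.
    """
    db = PrecursorDatabase()
    for rec in SeqIO.parse(str(path), "fasta"):
        db.add_precursor(_parse_record(rec))
    if not db.precursors:
        logger.warning("no FASTA records found in %s", path)
    return db


def read_mature_fasta(path: str | Path) -> list[Precursor]:
    """Read mature miRNA records (same header layout as hairpin files)."""
    return [_parse_record(rec) for rec in SeqIO.parse(str(path), "fasta")]


def write_hairpin_fasta(db: PrecursorDatabase, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description=p.description or p.id)
        for p in db
    ]
    SeqIO.write(records, str(path), "fasta")


_COPY_SUFFIX = re.compile(r"-\d+$")
_ARM_SUFFIX = re.compile(r"(-5p|-3p|\*)$", re.IGNORECASE)


def _mature_stem(mature_id: str) -> tuple[str, Arm]:
    """Strip one trailing -5p/-3p/* from a mature name; report the arm."""
    m = _ARM_SUFFIX.search(mature_id)
    if not m:
        return mature_id.lower(), "unknown"
    suffix = m.group(1).lower()
    arm: Arm = {"-5p": "5p", "-3p": "3p", "*": "unknown"}[suffix]
    return mature_id[: m.start()].lower(), arm


def _precursor_stems(precursor_id: str) -> set[str]:
    """Names a precursor answers to: itself and itself minus one -<digits>."""
    base = precursor_id.lower()
    stems = {base}
    stripped = _COPY_SUFFIX.sub("", base)
    stems.add(stripped)
    return stems


def _all_occurrences(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _pick_occurrence(starts: list[int], needle_len: int, seq_len: int, arm: Arm) -> int:
    # Arms sit at the hairpin extremities: leftmost occurrence for the 5'
    # arm, rightmost for the 3' arm, and for an unknown arm the occurrence
    # whose midpoint lies farthest from the sequence midpoint.
    if arm == "5p":
        return starts[0]
    if arm == "3p":
        return starts[-1]
    mid = seq_len / 2.0
    return max(starts, key=lambda s: (abs(s + needle_len / 2.0 - mid), -s))


def map_mature_to_precursors(
    db: PrecursorDatabase, mature_records: Iterable[Precursor]
) -> PrecursorDatabase:
    """Locate each mature miRNA inside its candidate precursors.

    Candidates are precursors whose id, after stripping a trailing
    ``-<digits>`` copy suffix, equals the mature name after stripping a
    trailing ``-5p``/``-3p`` (or legacy ``*``) suffix; comparison is
    case-insensitive.  Within a candidate, every exact substring occurrence
    of the mature sequence is found and exactly one locus is kept per
    precursor.  Matures with no occurrence anywhere are logged as warnings.
    """
    for mat in mature_records:
        stem, arm = _mature_stem(mat.id)
        placed = False
        for pre in db:
            if stem not in _precursor_stems(pre.id):
                continue
            starts = _all_occurrences(pre.sequence, mat.sequence)
            if not starts:
                continue
            if len(starts) > 1:
                logger.debug(
                    "mature %s occurs %d times in %s; resolved by arm rule",
                    mat.id, len(starts), pre.id,
                )
            start = _pick_occurrence(starts, len(mat.sequence), len(pre), arm)
            db.add_locus(
                MatureLocus(mat.id, pre.id, arm, start, start + len(mat.sequence))
            )
            placed = True
        if not placed:
            logger.warning(
                "mature %s could not be located in any candidate precursor", mat.id
            )
    return db


_TSV_COLUMNS = ["precursor_id", "mature_id", "arm", "start", "end"]


def load_coordinates_tsv(
    path: str | Path, db: PrecursorDatabase | None = None
) -> list[MatureLocus]:
    """Read mature loci from TSV (1-based inclusive coordinates in the file).

    Columns: precursor_id, mature_id, arm, start, end.  Header row required;
    ``#`` comment lines ignored.  When ``db`` is given the coordinates are
    validated against the precursor length.
    """
    loci: list[MatureLocus] = []
    with open(path, newline="") as fh:
        rows = [line for line in fh if not line.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _TSV_COLUMNS:
        raise ValueError(
            f"coordinates TSV must have header {_TSV_COLUMNS}, "
            f"got {reader.fieldnames}"
        )
    for i, row in enumerate(reader, start=2):
        start1, end1 = int(row["start"]), int(row["end"])
        if start1 < 1 or end1 < start1:
            raise ValueError(
                f"row {i}: coordinates must be 1-based inclusive with "
                f"start >= 1 and end >= start (got {start1}, {end1})"
            )
        start0, end0 = start1 - 1, end1
        if db is not None:
            pre = db.precursors.get(row["precursor_id"])
            if pre is None:
                raise ValueError(f"row {i}: unknown precursor {row['precursor_id']!r}")
            if end0 > len(pre):
                raise ValueError(
                    f"row {i}: end {end1} exceeds length {len(pre)} of "
                    f"{row['precursor_id']!r}"
                )
        arm = row["arm"]
        if arm not in ("5p", "3p", "unknown"):
            raise ValueError(f"row {i}: arm must be 5p/3p/unknown, got {arm!r}")
        loci.append(MatureLocus(row["mature_id"], row["precursor_id"], arm, start0, end0))
    return loci


def write_coordinates_tsv(loci: Iterable[MatureLocus], path: str | Path) -> None:
    """Write loci as TSV with 1-based inclusive coordinates (inverse of load)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for loc in loci:
            writer.writerow(
                [loc.precursor_id, loc.mature_id, loc.arm, loc.start + 1, loc.end]
            )


def filter_species(db: PrecursorDatabase, prefix: str) -> PrecursorDatabase:
    """Restrict the database to precursors of one species prefix (e.g. hsa)."""
    out = PrecursorDatabase()
    for pre in db:
        if pre.species_prefix == prefix:
            out.add_precursor(replace(pre))
    for pid, loci in db.loci.items():
        if pid in out.precursors:
            out.loci[pid] = list(loci)
    return out
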