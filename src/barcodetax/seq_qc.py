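"""Sequence I/O, alignment windowing and NUMT/pseudogene screening.

Barcode datasets arrive as FASTA plus a tab-separated sample table
(sample_id, species_label, locality_group).  Records whose species is not
known carry the ``UNKNOWN`` sentinel; locality may be missing.  Mitochondrial
protein-coding barcodes (coxI and friends) are screened for the two classic
NUMT symptoms — internal alignment gaps (indels) and in-frame stop codons —
before any distance is computed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("barcodetax")

#: Sentinel species label for morphologically unidentified samples.
UNKNOWN = "UNKNOWN"

#: IUPAC nucleotide alphabet accepted in barcode alignments.
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

#: NCBI translation table id for the vertebrate mitochondrial code.
VERTEBRATE_MITO = 2

METADATA_COLUMNS = ("sample_id", "species_label", "locality_group")


@dataclass(frozen=True)
class BarcodeRecord:
    """One barcode sequence with its sample-level annotations."""

    sample_id: str
    sequence: str
    species_label: str = UNKNOWN
    locality_group: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - IUPAC_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.sample_id!r}: non-IUPAC characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class BarcodeAlignment:
    """Equal-length barcode records (columns are homologous sites)."""

    records: tuple[BarcodeRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain at least one record")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.length == 0:
            raise ValueError("alignment length must be positive")

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def species_labels(self) -> list[str]:
        return [r.species_label for r in self.records]

    @property
    def locality_groups(self) -> list[str | None]:
        return [r.locality_group for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class QCRecord:
    sample_id: str
    has_internal_gap: bool
    stop_codon_count: int

    @property
    def passed(self) -> bool:
        return not self.has_internal_gap and self.stop_codon_count == 0


@dataclass(frozen=True)
class QCReport:
    """Per-record NUMT screen outcome in the globally chosen reading frame."""

    records: tuple[QCRecord, ...]
    frame_used: int
    genetic_code: int = VERTEBRATE_MITO

    @property
    def all_passed(self) -> bool:
        return all(r.passed for r in self.records)

    def failed_ids(self) -> list[str]:
        return [r.sample_id for r in self.records if not r.passed]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "has_internal_gap": [r.has_internal_gap for r in self.records],
                "stop_codon_count": [r.stop_codon_count for r in self.records],
                "frame_used": self.frame_used,
                "passed": [r.passed for r in self.records],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA and metadata I/O
# ---------------------------------------------------------------------------

def _parse_header(header: str) -> tuple[str, str, str | None]:
    """Split ``sample_id|species_label|locality_group``; trailing fields optional."""
    parts = [p.strip() for p in header.split("|")]
    sample_id = parts[0]
    species = parts[1] if len(parts) > 1 and parts[1] else UNKNOWN
    locality = parts[2] if len(parts) > 2 and parts[2] else None
    return sample_id, species, locality


def read_fasta(path: str | Path) -> list[BarcodeRecord]:
    """Read barcode records from FASTA.

    Headers are parsed as ``sample_id|species|locality``; absent fields
    default to :data:`UNKNOWN` / missing.  Duplicate sample ids are an error.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: expected FASTA header '>' "
                        f"before sequence data"
                    )
                break
    records: list[BarcodeRecord] = []
    seen: dict[str, int] = {}
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        header = seq_rec.description or seq_rec.id
        sample_id, species, locality = _parse_header(header)
        seen[sample_id] = seen.get(sample_id, 0) + 1
        records.append(
            BarcodeRecord(
                sample_id=sample_id,
                sequence=str(seq_rec.seq),
                species_label=species,
                locality_group=locality,
            )
        )
    dupes = sorted(sid for sid, n in seen.items() if n > 1)
    if dupes:
        raise ValueError(f"{path}: duplicate sample ids: {dupes}")
    if not records:
        logger.warning("%s: empty FASTA, no records read", path)
    return records


def write_fasta(records: Iterable[BarcodeRecord], path: str | Path) -> None:
    """Write records with ``sample_id|species|locality`` headers (round-trips)."""
    seq_records = []
    for r in records:
        if r.species_label != UNKNOWN or r.locality_group:
            header = "|".join([r.sample_id, r.species_label, r.locality_group or ""])
        else:
            header = r.sample_id
        seq_records.append(SeqRecord(Seq(r.sequence), id=header, description=""))
    SeqIO.write(seq_records, str(path), "fasta-2line")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the TSV sample table (sample_id, species_label, locality_group)."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(METADATA_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    return table


def merge_metadata(
    records: Sequence[BarcodeRecord], metadata: pd.DataFrame
) -> list[BarcodeRecord]:
    """Overlay table annotations onto records; table values win.

    Rows for sample ids absent from *records* produce a warning; conflicting
    duplicate rows for the same id are an error.
    """
    if metadata.empty:
        return list(records)
    missing = set(METADATA_COLUMNS) - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns {sorted(missing)}")
    dupes = metadata[metadata.duplicated("sample_id", keep=False)]
    for sid, grp in dupes.groupby("sample_id"):
        if grp.drop_duplicates().shape[0] > 1:
            raise ValueError(f"conflicting duplicate metadata rows for {sid!r}")
    by_id = {row.sample_id: row for row in metadata.itertuples(index=False)}
    known = {r.sample_id for r in records}
    for sid in by_id:
        if sid not in known:
            warnings.warn(f"metadata row for unknown sample id {sid!r} ignored")
    merged = []
    for rec in records:
        row = by_id.get(rec.sample_id)
        if row is None:
            merged.append(rec)
            continue
        merged.append(
            replace(
                rec,
                species_label=row.species_label or rec.species_label,
                locality_group=row.locality_group or rec.locality_group,
            )
        )
    return merged


# ---------------------------------------------------------------------------
# Alignment windowing
# ---------------------------------------------------------------------------

def trim_to_common_window(
    records: Sequence[BarcodeRecord], start: int, end: int
) -> BarcodeAlignment:
    """Trim pre-aligned sequences to the half-open column window ``[start, end)``.

    Coordinates are 0-based.  Typical use: cutting a 658-bp amplicon down to
    the common high-quality 556-bp core shared by all samples.
    """
    if not 0 <= start < end:
        raise ValueError(f"invalid window [{start}, {end})")
    for rec in records:
        if end > len(rec.sequence):
            raise ValueError(
                f"window [{start}, {end}) exceeds record {rec.sample_id!r} "
                f"of length {len(rec.sequence)}"
            )
    return BarcodeAlignment(
        tuple(replace(r, sequence=r.sequence[start:end]) for r in records)
    )


def trim_to_shortest(records: Sequence[BarcodeRecord]) -> BarcodeAlignment:
    """Trim every sequence to the length of the shortest one (from column 0)."""
    shortest = min(len(r.sequence) for r in records)
    return trim_to_common_window(records, 0, shortest)


# ---------------------------------------------------------------------------
# NUMT / pseudogene screen
# ---------------------------------------------------------------------------

def _stop_codons(genetic_code: int) -> frozenset[str]:
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    return frozenset(table.stop_codons)


def _count_stops(sequence: str, frame: int, stops: frozenset[str]) -> int:
    n = 0
    for i in range(frame, len(sequence) - 2, 3):
        codon = sequence[i : i + 3]
        if codon in stops:  # codons with gaps/ambiguities never match
            n += 1
    return n


def _has_internal_gap(sequence: str) -> bool:
    stripped = sequence.strip("-")
    return "-" in stripped


def numt_screen(
    alignment: BarcodeAlignment, genetic_code: int = VERTEBRATE_MITO
) -> QCReport:
    """Screen a protein-coding alignment for NUMT symptoms.

    The reading frame (0/1/2) is chosen globally as the one minimising the
    total number of in-frame stop codons summed over all records, ties broken
    by the lowest frame index; a genuine mitochondrial coding alignment has a
    stop-free frame.  Per record the report carries the stop count in that
    frame and whether internal gap characters (indels) are present; a record
    passes iff it has neither.
    """
    stops = _stop_codons(genetic_code)
    totals = [
        sum(_count_stops(r.sequence, f, stops) for r in alignment.records)
        for f in (0, 1, 2)
    ]
    frame = int(min(range(3), key=lambda f: totals[f]))
    qc_records = tuple(
        QCRecord(
            sample_id=r.sample_id,
            has_internal_gap=_has_internal_gap(r.sequence),
            stop_codon_count=_count_stops(r.sequence, frame, stops),
        )
        for r in alignment.records
    )
    return QCReport(records=qc_records, frame_used=frame, genetic_code=genetic_code)


# ---------------------------------------------------------------------------
# Base composition
# ---------------------------------------------------------------------------

def base_composition(alignment: BarcodeAlignment) -> dict[str, float]:
    """Average base frequencies over unambiguous A/C/G/T characters only.

    Gaps and IUPAC ambiguity codes are excluded (consistent with pairwise
    deletion in the distance step).  Returns ``{"A": pi_A, ...}`` summing to 1.
    """
    counts = {b: 0 for b in "ACGT"}
    for rec in alignment.records:
        for base in rec.sequence:
            if base in counts:
                counts[base] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("alignment contains no unambiguous A/C/G/T characters")
    return {b: counts[b] / total for b in "ACGT"}
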