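"""Input layer: aligned COI sequences and specimen metadata.

All downstream computation consumes an :class:`AlignedSequenceSet` (an
aligned, gap-preserving nucleotide matrix keyed by specimen ID) joined with a
specimen table (taxon, decimal-degree coordinates, bioregion code) into a
:class:`Dataset`.  Sequences are read from FASTA via Biopython; metadata from
a tab-separated table whose coordinate columns accept both signed decimal
degrees and the compass style ("N42.430" / "W2.562") used in field tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "AlignedSequenceSet",
    "SpecimenRecord",
    "Dataset",
    "AlignmentError",
    "MetadataError",
    "GENETIC_CODES",
    "read_alignment",
    "write_alignment",
    "read_metadata",
    "join_dataset",
    "screen_reading_frame",
]

#: Nucleotide states treated as unambiguous everywhere downstream.
UNAMBIGUOUS = frozenset("ACGT")

#: Genetic-code aliases -> NCBI translation-table ids.
GENETIC_CODES = {
    "invertebrate-mito": 5,
    "standard": 1,
    "vertebrate-mito": 2,
}


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, duplicate IDs...)."""


class MetadataError(ValueError):
    """Raised for malformed specimen metadata."""


@dataclass(frozen=True)
class AlignedSequenceSet:
    """Equal-length nucleotide rows keyed by unique specimen IDs."""

    records: tuple[tuple[str, str], ...]
    length: int

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "AlignedSequenceSet":
        recs = tuple((str(i), str(s).upper()) for i, s in records)
        if not recs:
            raise AlignmentError("alignment contains no records")
        length = len(recs[0][1])
        if length == 0:
            raise AlignmentError("alignment has zero columns")
        bad = [i for i, s in recs if len(s) != length]
        if bad:
            raise AlignmentError(
                f"rows differ in length from first record ({length} columns): {bad}"
            )
        ids = [i for i, _ in recs]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise AlignmentError(f"duplicate specimen IDs: {dupes}")
        return cls(records=recs, length=length)

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    @property
    def sequences(self) -> list[str]:
        return [s for _, s in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, keep: Sequence[str]) -> "AlignedSequenceSet":
        keep_set = set(keep)
        missing = keep_set - set(self.ids)
        if missing:
            raise AlignmentError(f"IDs not in alignment: {sorted(missing)}")
        return AlignedSequenceSet.from_records(
            [(i, s) for i, s in self.records if i in keep_set]
        )


@dataclass(frozen=True)
class SpecimenRecord:
    specimen_id: str
    taxon: str
    latitude: float | None = None
    longitude: float | None = None
    bioregion: str | None = None

    def __post_init__(self):
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise MetadataError(
                f"{self.specimen_id}: latitude {self.latitude} out of [-90, 90]"
            )
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise MetadataError(
                f"{self.specimen_id}: longitude {self.longitude} out of [-180, 180]"
            )


@dataclass(frozen=True)
class Dataset:
    """One-to-one join of an alignment with its specimen metadata."""

    alignment: AlignedSequenceSet
    metadata: tuple[SpecimenRecord, ...]
    ingroup_taxon: str

    by_id: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "by_id", {m.specimen_id: m for m in self.metadata}
        )

    @property
    def ingroup_ids(self) -> list[str]:
        return [i for i in self.alignment.ids if self.by_id[i].taxon == self.ingroup_taxon]

    @property
    def taxa(self) -> dict[str, str]:
        return {m.specimen_id: m.taxon for m in self.metadata}

    def ingroup_alignment(self) -> AlignedSequenceSet:
        return self.alignment.subset(self.ingroup_ids)


def read_alignment(path: str | Path, format: str = "fasta") -> AlignedSequenceSet:
    """Read an aligned FASTA file; rows are upper-cased and length-checked."""
    if format != "fasta":
        raise ValueError(f"unsupported alignment format: {format!r}")
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return AlignedSequenceSet.from_records(records)


def write_alignment(aln: AlignedSequenceSet, path: str | Path) -> None:
    """Write FASTA preserving record order and sequences byte-for-byte."""
    with open(path, "w") as fh:
        for sid, seq in aln.records:
            fh.write(f">{sid}\n{seq}\n")


def _parse_coordinate(value, kind: str) -> float | None:
    """Parse '42.430', '-2.562', 'N42.430' or 'W2.562' to signed degrees."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    if not text:
        return None
    sign = 1.0
    head = text[0].upper()
    if head in "NSEW":
        if (kind == "latitude" and head not in "NS") or (
            kind == "longitude" and head not in "EW"
        ):
            raise MetadataError(f"compass prefix {head!r} invalid for {kind}")
        sign = -1.0 if head in "SW" else 1.0
        text = text[1:]
    try:
        return sign * float(text)
    except ValueError as exc:
        raise MetadataError(f"cannot parse {kind} value {value!r}") from exc


REQUIRED_COLUMNS = ("specimen_id", "taxon", "latitude", "longitude", "bioregion")


def read_metadata(path: str | Path) -> list[SpecimenRecord]:
    """Read the tab-separated specimen table (header required, '#' comments)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"metadata is missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        bioregion = getattr(row, "bioregion")
        if isinstance(bioregion, str):
            bioregion = bioregion.strip() or None
        elif pd.isna(bioregion):
            bioregion = None
        records.append(
            SpecimenRecord(
                specimen_id=str(row.specimen_id).strip(),
                taxon=str(row.taxon).strip(),
                latitude=_parse_coordinate(row.latitude, "latitude"),
                longitude=_parse_coordinate(row.longitude, "longitude"),
                bioregion=bioregion,
            )
        )
    ids = [r.specimen_id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise MetadataError(f"duplicate specimen IDs in metadata: {dupes}")
    return records


def join_dataset(
    aln: AlignedSequenceSet,
    metadata: Sequence[SpecimenRecord],
    ingroup_taxon: str,
) -> Dataset:
    """Join alignment and metadata; ID sets must match exactly."""
    aln_ids = set(aln.ids)
    meta_ids = {m.specimen_id for m in metadata}
    only_aln = sorted(aln_ids - meta_ids)
    only_meta = sorted(meta_ids - aln_ids)
    if only_aln or only_meta:
        raise MetadataError(
            f"alignment/metadata mismatch: only in alignment {only_aln}, "
            f"only in metadata {only_meta}"
        )
    if ingroup_taxon not in {m.taxon for m in metadata}:
        warnings.warn(
            f"ingroup taxon {ingroup_taxon!r} not present in metadata; "
            "all specimens will be treated as outgroup",
            stacklevel=2,
        )
    return Dataset(alignment=aln, metadata=tuple(metadata), ingroup_taxon=ingroup_taxon)


def _stop_codons(code: str | int) -> frozenset[str]:
    table_id = GENETIC_CODES.get(code, code) if isinstance(code, str) else code
    table = CodonTable.unambiguous_dna_by_id[int(table_id)]
    return frozenset(table.stop_codons)


def screen_reading_frame(
    aln: AlignedSequenceSet, code: str | int = "invertebrate-mito", frame: int = 0
) -> dict[str, int]:
    """Count stop codons per record in the given frame.

    Report-only: a clean protein-coding matrix reports all zeros.  Codons
    containing ambiguity characters are not translatable and are skipped.
    The count includes a terminal stop if one falls inside the row.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    stops = _stop_codons(code)
    out = {}
    for sid, seq in aln.records:
        count = 0
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if set(codon) <= UNAMBIGUOUS and codon in stops:
                count += 1
        out[sid] = count
    return out
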