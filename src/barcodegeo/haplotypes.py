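"""Haplotype collapsing, diversity statistics and regional summaries.

Collapsing follows the "exclude sites with missing data" convention: every
alignment column containing any character outside {A,C,G,T} in any record is
removed dataset-wide, and specimens are grouped by exact identity over the
retained columns.  (p-distances elsewhere use pairwise deletion instead;
the two conventions intentionally coexist.)

Diversity statistics:
  S   segregating (polymorphic) columns, counted over A/C/G/T states;
  eta total mutations, sum over columns of (distinct states - 1);
  Hd  haplotype diversity, (n/(n-1)) (1 - sum (Xi/n)^2)  (Nei 1987);
  pi  nucleotide diversity, the mean over unordered sequence pairs of the
      per-site difference fraction on the complete-data columns.

Polymorphic sites are classified synonymous vs replacement by translating
the majority-state codon against each minor-state codon under the
invertebrate mitochondrial code (by default).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .alignment_io import (
    UNAMBIGUOUS,
    AlignedSequenceSet,
    GENETIC_CODES,
    SpecimenRecord,
)
from .distances import DistanceMatrix

__all__ = [
    "HaplotypeTable",
    "DiversityStats",
    "collapse_haplotypes",
    "diversity_stats",
    "classify_site_change",
    "collapse_nonsynonymous_only",
    "region_frequency_matrix",
    "region_summary",
    "write_popart_nexus",
]


@dataclass(frozen=True)
class HaplotypeTable:
    """Partition of specimens into haplotypes over the retained columns."""

    haplotypes: tuple[tuple[str, str, tuple[str, ...]], ...]  # (id, seq, members)
    retained_sites: tuple[int, ...]  # original 0-based column indices

    @property
    def n(self) -> int:
        return sum(len(members) for _, _, members in self.haplotypes)

    @property
    def s_obs(self) -> int:
        return len(self.haplotypes)

    @property
    def abundances(self) -> np.ndarray:
        return np.array([len(m) for _, _, m in self.haplotypes], dtype=int)

    @property
    def ids(self) -> list[str]:
        return [h for h, _, _ in self.haplotypes]

    def membership(self) -> dict[str, str]:
        """specimen_id -> haplotype_id"""
        return {
            sid: hap for hap, _, members in self.haplotypes for sid in members
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype": self.ids,
                "abundance": self.abundances,
                "members": [",".join(m) for _, _, m in self.haplotypes],
                "sequence": [s for _, s, _ in self.haplotypes],
            }
        )


def _column_matrix(aln: AlignedSequenceSet) -> np.ndarray:
    return np.array([list(s) for s in aln.sequences], dtype="U1")


def _complete_columns(mat: np.ndarray) -> np.ndarray:
    """Boolean mask of columns whose every state is in {A,C,G,T}."""
    ok = np.isin(mat, list(UNAMBIGUOUS))
    return ok.all(axis=0)


def collapse_haplotypes(
    aln: AlignedSequenceSet, missing_policy: str = "exclude-sites"
) -> HaplotypeTable:
    """Group identical rows into haplotypes.

    ``exclude-sites`` drops every column with any ambiguous character before
    grouping; ``strict`` requires a complete matrix and keeps all columns.
    Haplotype IDs (H1, H2, ...) follow first occurrence in the input order.
    """
    mat = _column_matrix(aln)
    complete = _complete_columns(mat)
    if missing_policy == "exclude-sites":
        retained = np.flatnonzero(complete)
    elif missing_policy == "strict":
        if not complete.all():
            bad = np.flatnonzero(~complete)[:5]
            raise ValueError(
                f"strict collapsing requires a complete matrix; ambiguous "
                f"columns include {bad.tolist()}"
            )
        retained = np.arange(mat.shape[1])
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if retained.size == 0:
        raise ValueError("no columns retained after excluding missing data")
    groups: dict[str, list[str]] = {}
    for sid, row in zip(aln.ids, mat[:, retained]):
        key = "".join(row)
        groups.setdefault(key, []).append(sid)
    haplotypes = tuple(
        (f"H{k + 1}", seq, tuple(members))
        for k, (seq, members) in enumerate(groups.items())
    )
    return HaplotypeTable(haplotypes=haplotypes, retained_sites=tuple(retained.tolist()))


def _codon_table(code: str | int) -> CodonTable.CodonTable:
    table_id = GENETIC_CODES.get(code, code) if isinstance(code, str) else code
    return CodonTable.unambiguous_dna_by_id[int(table_id)]


def _translate_codon(codon: str, table: CodonTable.CodonTable) -> str:
    if codon in table.stop_codons:
        return "*"
    return str(Seq(codon).translate(table=table))


def classify_site_change(
    codon_before: str, codon_after: str, code: str | int = "invertebrate-mito"
) -> str:
    """'synonymous' or 'replacement' for two codons differing at one site."""
    codon_before, codon_after = codon_before.upper(), codon_after.upper()
    if len(codon_before) != 3 or len(codon_after) != 3:
        raise ValueError("codons must be trinucleotides")
    diffs = sum(a != b for a, b in zip(codon_before, codon_after))
    if diffs != 1:
        raise ValueError(f"codons must differ at exactly one position (got {diffs})")
    table = _codon_table(code)
    same = _translate_codon(codon_before, table) == _translate_codon(codon_after, table)
    return "synonymous" if same else "replacement"


def _majority_state(column: np.ndarray) -> str | None:
    """Most frequent unambiguous state (ties by alphabet); None if none."""
    counts = Counter(c for c in column if c in UNAMBIGUOUS)
    if not counts:
        return None
    return min(counts, key=lambda s: (-counts[s], s))


def _classify_columns(
    mat: np.ndarray, code: str | int, frame: int
) -> tuple[dict[int, list[str]], np.ndarray]:
    """Per polymorphic column, classify each minor state vs the majority.

    Returns ({column -> list of 'synonymous'/'replacement' per minor state},
    consensus) where consensus is the column-majority sequence used as the
    codon background.  Columns whose codon is incomplete (frame edges) or
    whose codon background contains ambiguity are left unclassified.
    """
    table = _codon_table(code)
    n_cols = mat.shape[1]
    consensus = np.array(
        [(_majority_state(mat[:, c]) or "N") for c in range(n_cols)], dtype="U1"
    )
    result: dict[int, list[str]] = {}
    for c in range(n_cols):
        states = sorted(set(mat[:, c]) & UNAMBIGUOUS)
        if len(states) < 2:
            continue
        major = _majority_state(mat[:, c])
        codon_start = c - ((c - frame) % 3)
        labels = []
        if codon_start < frame or codon_start + 3 > n_cols:
            result[c] = []  # polymorphic but not classifiable
            continue
        background = consensus[codon_start : codon_start + 3].copy()
        offset = c - codon_start
        background[offset] = major
        if not set(background) <= UNAMBIGUOUS:
            result[c] = []
            continue
        for s in states:
            if s == major:
                continue
            mutant = background.copy()
            mutant[offset] = s
            labels.append(
                classify_site_change("".join(background), "".join(mutant), code)
            )
        result[c] = labels
    return result, consensus


@dataclass(frozen=True)
class DiversityStats:
    segregating_sites: int
    total_mutations: int
    haplotype_diversity: float
    nucleotide_diversity: float
    synonymous_changes: int
    replacement_changes: int


def haplotype_diversity(abundances: Sequence[int]) -> float:
    """Nei's Hd with the n/(n-1) small-sample correction."""
    x = np.asarray(abundances, dtype=float)
    n = x.sum()
    if n < 2:
        raise ValueError("haplotype diversity needs at least 2 specimens")
    return float(n / (n - 1) * (1.0 - ((x / n) ** 2).sum()))


def nucleotide_diversity(
    aln: AlignedSequenceSet, bias_corrected: bool = False
) -> float:
    """Mean pairwise per-site difference over the complete-data columns.

    With ``bias_corrected`` the n/(n-1) multiplier is applied on top of the
    plain pairwise mean.
    """
    mat = _column_matrix(aln)
    cols = np.flatnonzero(_complete_columns(mat))
    if cols.size == 0:
        raise ValueError("no complete-data columns")
    sub = mat[:, cols]
    n = sub.shape[0]
    if n < 2:
        raise ValueError("nucleotide diversity needs at least 2 sequences")
    total = 0.0
    for i in range(n):
        diffs = (sub[i + 1 :] != sub[i]).sum(axis=1)
        total += diffs.sum()
    pi = total / (n * (n - 1) / 2) / cols.size
    if bias_corrected:
        pi *= n / (n - 1)
    return float(pi)


def diversity_stats(
    aln: AlignedSequenceSet,
    table: HaplotypeTable | None = None,
    code: str | int = "invertebrate-mito",
    frame: int = 0,
) -> DiversityStats:
    """S, eta, Hd, pi and the synonymous/replacement change totals."""
    if table is None:
        table = collapse_haplotypes(aln)
    mat = _column_matrix(aln)
    n_states = [
        len(set(mat[:, c]) & UNAMBIGUOUS) for c in range(mat.shape[1])
    ]
    segregating = sum(1 for k in n_states if k >= 2)
    eta = sum(k - 1 for k in n_states if k >= 2)
    labels, _ = _classify_columns(mat, code, frame)
    flat = [lab for labs in labels.values() for lab in labs]
    return DiversityStats(
        segregating_sites=segregating,
        total_mutations=eta,
        haplotype_diversity=haplotype_diversity(table.abundances),
        nucleotide_diversity=nucleotide_diversity(aln),
        synonymous_changes=sum(1 for lab in flat if lab == "synonymous"),
        replacement_changes=sum(1 for lab in flat if lab == "replacement"),
    )


def collapse_nonsynonymous_only(
    aln: AlignedSequenceSet,
    code: str | int = "invertebrate-mito",
    frame: int = 0,
    missing_policy: str = "exclude-sites",
) -> HaplotypeTable:
    """Second-pass collapse keeping only replacement variation.

    Every column whose minor states are all synonymous relative to the
    majority codon is masked to the majority state; the masked matrix is
    then collapsed as usual, so only replacement changes separate
    haplotypes.
    """
    mat = _column_matrix(aln)
    labels, _ = _classify_columns(mat, code, frame)
    for c, labs in labels.items():
        if labs and all(lab == "synonymous" for lab in labs):
            major = _majority_state(mat[:, c])
            unamb = np.isin(mat[:, c], list(UNAMBIGUOUS))
            mat[unamb, c] = major
    masked = AlignedSequenceSet.from_records(
        [(sid, "".join(row)) for sid, row in zip(aln.ids, mat)]
    )
    return collapse_haplotypes(masked, missing_policy=missing_policy)


def region_frequency_matrix(
    table: HaplotypeTable, metadata: Sequence[SpecimenRecord] | Mapping[str, str]
) -> pd.DataFrame:
    """Haplotype x bioregion count matrix.

    Members without a bioregion are excluded with a warning; row sums then
    equal haplotype abundances over the specimens that carry a region code.
    """
    if isinstance(metadata, Mapping):
        region_of = dict(metadata)
    else:
        region_of = {m.specimen_id: m.bioregion for m in metadata}
    regions = sorted(
        {r for r in region_of.values() if r}
    )
    counts = pd.DataFrame(0, index=table.ids, columns=regions, dtype=int)
    import warnings as _warnings

    for hap, _, members in table.haplotypes:
        for sid in members:
            region = region_of.get(sid)
            if not region:
                _warnings.warn(f"{sid}: no bioregion; excluded from frequency matrix",
                               stacklevel=2)
                continue
            counts.loc[hap, region] += 1
    return counts


def region_summary(
    table: HaplotypeTable,
    metadata: Sequence[SpecimenRecord],
    dm: DistanceMatrix,
) -> pd.DataFrame:
    """Per-bioregion sample/haplotype counts, rate, mean within-region p.

    Regions with fewer than 2 samples get NaN mean distance.  A 'Total' row
    aggregates over all specimens that carry a region code.
    """
    region_of = {m.specimen_id: m.bioregion for m in metadata}
    member_of = table.membership()
    rows = []
    regions = sorted({r for r in region_of.values() if r})
    for region in regions + ["Total"]:
        sids = [
            s
            for s in member_of
            if region_of.get(s) and (region == "Total" or region_of[s] == region)
        ]
        haps = {member_of[s] for s in sids}
        if len(sids) >= 2:
            idx = [dm.index(s) for s in sids]
            sub = dm.p[np.ix_(idx, idx)]
            mean_p = float(sub[np.triu_indices(len(idx), k=1)].mean())
        else:
            mean_p = float("nan")
        rows.append(
            {
                "bioregion": region,
                "samples": len(sids),
                "haplotypes": len(haps),
                "haplotypes_per_sample": len(haps) / len(sids) if sids else float("nan"),
                "mean_p": mean_p,
            }
        )
    return pd.DataFrame(rows)


def write_popart_nexus(
    table: HaplotypeTable,
    freq: pd.DataFrame,
    path: str | Path,
) -> None:
    """Write a NEXUS file with a TRAITS block (PopART dialect).

    One taxon per haplotype with its representative sequence over the
    retained sites, and per-bioregion counts as comma-separated traits.
    """
    hap_ids = table.ids
    seqs = {h: s for h, s, _ in table.haplotypes}
    nchar = len(table.retained_sites)
    lines = [
        "#NEXUS",
        "",
        "BEGIN TAXA;",
        f"DIMENSIONS NTAX={len(hap_ids)};",
        "TAXLABELS",
        *[f"{h}" for h in hap_ids],
        ";",
        "END;",
        "",
        "BEGIN CHARACTERS;",
        f"DIMENSIONS NCHAR={nchar};",
        "FORMAT DATATYPE=DNA MISSING=? GAP=-;",
        "MATRIX",
        *[f"{h} {seqs[h]}" for h in hap_ids],
        ";",
        "END;",
        "",
        "BEGIN TRAITS;",
        f"  Dimensions NTRAITS={freq.shape[1]};",
        "  Format labels=yes missing=? separator=Comma;",
        "  TraitLabels " + " ".join(freq.columns) + ";",
        "  Matrix",
        *[
            f"{h} " + ",".join(str(int(v)) for v in freq.loc[h])
            for h in hap_ids
        ],
        ";",
        "END;",
        "",
    ]
    Path(path).write_text("\n".join(lines))
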