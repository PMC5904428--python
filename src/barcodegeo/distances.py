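"""Uncorrected p-distances with pairwise deletion, and the barcoding gap.

The p-distance between two aligned rows is the fraction of mismatching
positions among the positions where *both* rows carry an unambiguous base
(A/C/G/T); gaps, N and all other IUPAC ambiguity codes are removed per pair
(pairwise deletion), not per column.  No substitution-model correction is
applied anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment_io import AlignedSequenceSet

__all__ = [
    "DistanceMatrix",
    "SpecimenDistanceSummary",
    "BarcodingGapReport",
    "UndefinedDistanceError",
    "p_distance",
    "distance_matrix",
    "specimen_summary",
    "barcoding_gap",
]


class UndefinedDistanceError(ValueError):
    """No unambiguous site is shared by a sequence pair."""


def _encode(sequences: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Byte-encode rows; return (codes, valid) where valid marks A/C/G/T."""
    arr = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(sequences), -1)
    valid = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    return arr, valid


def p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Uncorrected distance and the number of compared sites for one pair."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    arr, valid = _encode([seq_a.upper(), seq_b.upper()])
    both = valid[0] & valid[1]
    compared = int(both.sum())
    if compared == 0:
        raise UndefinedDistanceError("no unambiguous site shared by the pair")
    mismatches = int(((arr[0] != arr[1]) & both).sum())
    return mismatches / compared, compared


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    p: np.ndarray      # symmetric, zeros on the diagonal
    sites: np.ndarray  # compared-site counts per pair

    def index(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def value(self, id_a: str, id_b: str) -> float:
        return float(self.p[self.index(id_a), self.index(id_b)])

    def pair_table(self) -> pd.DataFrame:
        """Long-format table of all unordered pairs (id_a, id_b, p, sites)."""
        n = len(self.ids)
        ia, ib = np.triu_indices(n, k=1)
        return pd.DataFrame(
            {
                "id_a": [self.ids[i] for i in ia],
                "id_b": [self.ids[j] for j in ib],
                "p": self.p[ia, ib],
                "sites": self.sites[ia, ib].astype(int),
            }
        )

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=list(self.ids), columns=list(self.ids))


def distance_matrix(aln: AlignedSequenceSet) -> DistanceMatrix:
    """All-pairs p-distance with pairwise deletion.

    Mismatch and overlap counts are accumulated with matrix products on the
    valid/mismatch masks, so the 118-row study matrix is instantaneous.
    """
    if len(aln) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    arr, valid = _encode(aln.sequences)
    v = valid.astype(np.float64)
    sites = v @ v.T
    # mismatches over jointly valid sites: total joint sites minus matches
    n, L = arr.shape
    matches = np.zeros((n, n))
    for base in b"ACGT":
        m = (arr == base).astype(np.float64)
        matches += m @ m.T
    mism = sites - matches
    sites_i = np.rint(sites).astype(np.int64)
    if np.any(sites_i[np.triu_indices(n, k=1)] == 0):
        ia, ib = np.where(np.triu(sites_i == 0, k=1))
        pair = (aln.ids[ia[0]], aln.ids[ib[0]])
        raise UndefinedDistanceError(f"pair {pair} shares no unambiguous site")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(sites_i > 0, mism / np.maximum(sites_i, 1), 0.0)
    np.fill_diagonal(p, 0.0)
    p = (p + p.T) / 2.0  # enforce exact symmetry
    return DistanceMatrix(ids=tuple(aln.ids), p=p, sites=sites_i)


@dataclass(frozen=True)
class SpecimenDistanceSummary:
    specimen_id: str
    median_p: float
    max_p: float
    mean_p: float


def specimen_summary(
    dm: DistanceMatrix, ingroup_ids: Sequence[str]
) -> list[SpecimenDistanceSummary]:
    """Per-specimen median/max/mean p-distance to the other ingroup members."""
    idx = [dm.index(i) for i in ingroup_ids]
    if len(idx) < 2:
        raise ValueError("need at least 2 ingroup specimens")
    sub = dm.p[np.ix_(idx, idx)]
    out = []
    for row, sid in enumerate(ingroup_ids):
        others = np.delete(sub[row], row)
        out.append(
            SpecimenDistanceSummary(
                specimen_id=sid,
                median_p=float(np.median(others)),
                max_p=float(others.max()),
                mean_p=float(others.mean()),
            )
        )
    return out


@dataclass(frozen=True)
class BarcodingGapReport:
    focal_taxon: str
    max_intraspecific: float
    min_interspecific: float
    min_interspecific_by_taxon: dict[str, float]
    gap_present: bool
    gap_ratio: float
    intra_distances: np.ndarray
    inter_distances: np.ndarray


def barcoding_gap(
    dm: DistanceMatrix, taxa: Mapping[str, str], focal_taxon: str
) -> BarcodingGapReport:
    """Max intra- vs min inter-specific distance for the focal taxon.

    ``taxa`` maps every matrix ID to a taxon label.  Interspecific minima
    are reported overall and per non-focal taxon; the full labelled distance
    lists are kept for histogram plotting.
    """
    labels = [taxa[i] for i in dm.ids]
    focal = np.array([t == focal_taxon for t in labels])
    if focal.sum() < 2:
        raise ValueError(f"focal taxon {focal_taxon!r} has fewer than 2 specimens")
    if focal.all():
        raise ValueError("no interspecific pairs: only the focal taxon is present")
    n = len(dm.ids)
    iu = np.triu_indices(n, k=1)
    both_focal = focal[iu[0]] & focal[iu[1]]
    cross = focal[iu[0]] ^ focal[iu[1]]
    intra = dm.p[iu][both_focal]
    inter = dm.p[iu][cross]
    by_taxon: dict[str, float] = {}
    for a, b, d in zip(iu[0], iu[1], dm.p[iu]):
        la, lb = labels[a], labels[b]
        if (la == focal_taxon) != (lb == focal_taxon):
            other = lb if la == focal_taxon else la
            if other not in by_taxon or d < by_taxon[other]:
                by_taxon[other] = float(d)
    max_intra = float(intra.max())
    min_inter = float(inter.min())
    return BarcodingGapReport(
        focal_taxon=focal_taxon,
        max_intraspecific=max_intra,
        min_interspecific=min_inter,
        min_interspecific_by_taxon=by_taxon,
        gap_present=min_inter > max_intra,
        gap_ratio=float("inf") if max_intra == 0 else min_inter / max_intra,
        intra_distances=np.sort(intra),
        inter_distances=np.sort(inter),
    )
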