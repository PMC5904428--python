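"""Great-circle distances and the genetic-vs-geographic (IBD) analysis.

Distances use the spherical law of cosines on a sphere of radius 6,367 km
(the Earth radius appropriate for central Europe):

    d = R * arccos(sin p1 sin p2 + cos p1 cos p2 cos(l1 - l2))

which reproduces the published pairwise kilometre values at nearest-km
rounding.  Isolation by distance is summarised by an ordinary least-squares
line of p-distance on kilometres with its coefficient of determination.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .alignment_io import Dataset
from .distances import DistanceMatrix

__all__ = [
    "GeoPoint",
    "TrendFit",
    "EARTH_RADIUS_KM",
    "great_circle_distance",
    "pairwise_geo_table",
    "ibd_trend",
]

EARTH_RADIUS_KM = 6367.0


class GeoPoint(NamedTuple):
    latitude: float
    longitude: float


def great_circle_distance(
    a: GeoPoint | tuple[float, float],
    b: GeoPoint | tuple[float, float],
    radius_km: float = EARTH_RADIUS_KM,
) -> float:
    """Spherical law-of-cosines distance in kilometres.

    The arccos argument is clamped to [-1, 1] so that identical or
    antipodal points never raise on rounding error.
    """
    lat1, lon1 = math.radians(a[0]), math.radians(a[1])
    lat2, lon2 = math.radians(b[0]), math.radians(b[1])
    x = math.sin(lat1) * math.sin(lat2) + math.cos(lat1) * math.cos(lat2) * math.cos(
        lon1 - lon2
    )
    return radius_km * math.acos(min(1.0, max(-1.0, x)))


def pairwise_geo_table(ds: Dataset, dm: DistanceMatrix) -> pd.DataFrame:
    """One row per unordered ingroup pair: km, p-distance and their ratio.

    The ratio (p per km) is NaN for syntopic pairs (0 km).  Specimens
    without coordinates are excluded with a warning.
    """
    ids = []
    for sid in ds.ingroup_ids:
        rec = ds.by_id[sid]
        if rec.latitude is None or rec.longitude is None:
            warnings.warn(f"{sid}: no coordinates; excluded from geographic pairs",
                          stacklevel=2)
            continue
        ids.append(sid)
    rows = []
    for i, id_a in enumerate(ids):
        ra = ds.by_id[id_a]
        for id_b in ids[i + 1 :]:
            rb = ds.by_id[id_b]
            km = great_circle_distance(
                (ra.latitude, ra.longitude), (rb.latitude, rb.longitude)
            )
            p = dm.value(id_a, id_b)
            rows.append((id_a, id_b, km, p, p / km if km > 0 else np.nan))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "geo_km", "p", "ratio"])


@dataclass(frozen=True)
class TrendFit:
    slope: float        # p-distance (fraction) per km
    intercept: float
    r_squared: float


def ibd_trend(pairs: pd.DataFrame | Iterable[tuple[float, float]]) -> TrendFit:
    """OLS fit of p-distance on geographic distance over all pairs."""
    if isinstance(pairs, pd.DataFrame):
        x = pairs["geo_km"].to_numpy(dtype=float)
        y = pairs["p"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(pairs), dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if len(x) < 3:
        raise ValueError("need at least 3 pairs for a trend fit")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate fit: all geographic distances equal")
    if np.allclose(y, y[0]):
        # constant response: slope 0, no variance explained
        return TrendFit(slope=0.0, intercept=float(y[0]), r_squared=0.0)
    res = stats.linregress(x, y)
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
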