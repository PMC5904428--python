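"""Abundance-based richness estimation: Chao1, ACE, rarefaction, extrapolation.

All estimators consume an abundance vector X (counts per haplotype/class).
Notation: n = sum(X), S_obs = number of classes, Fk = number of classes seen
exactly k times.

Chao1 (with the small-sample (n-1)/n multiplier on by default):

  F2 > 0:  S1 = S_obs + A F1^2 / (2 F2),           A = (n-1)/n
  F2 = 0:  S1 = S_obs + A F1 (F1 - 1) / 2

The default variance uses the bias-corrected branch (Chao 1987 / the
EstimateS appendix); the 95% CI applies the log-normal transform to
F0 = S1 - S_obs with z = 1.96, which keeps the lower bound above S_obs.

Rarefaction is the analytic hypergeometric expectation
E[S(m)] = S_obs - sum_i C(n - X_i, m) / C(n, m) (computed in log space),
with the exact hypergeometric variance for the CI.  Extrapolation follows
the standard unseen-class model S(n + m*) = S_obs + F0 (1 - (1 - q)^m*)
with q = F1 / (n F0 + F1), which tends to the Chao1 asymptote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "AbundanceVector",
    "RichnessEstimate",
    "chao1",
    "ace",
    "rarefy_expected",
    "rarefaction_variance",
    "rarefaction_curve",
    "extrapolate",
    "samples_needed",
    "accumulation_curves",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class AbundanceVector:
    """Validated abundance counts with the derived F-statistics."""

    X: np.ndarray

    @classmethod
    def from_counts(cls, counts: Sequence[int]) -> "AbundanceVector":
        x = np.asarray(counts, dtype=int)
        if x.size == 0:
            raise ValueError("abundance vector is empty")
        if (x <= 0).any():
            raise ValueError("abundances must be positive integers")
        return cls(X=x)

    @property
    def n(self) -> int:
        return int(self.X.sum())

    @property
    def s_obs(self) -> int:
        return int(self.X.size)

    def f(self, k: int) -> int:
        return int((self.X == k).sum())

    @property
    def f1(self) -> int:
        return self.f(1)

    @property
    def f2(self) -> int:
        return self.f(2)


def _as_vector(X) -> AbundanceVector:
    return X if isinstance(X, AbundanceVector) else AbundanceVector.from_counts(X)


@dataclass(frozen=True)
class RichnessEstimate:
    s_obs: int
    n: int
    f1: int
    f2: int
    s_chao1: float
    variance: float
    ci_low: float
    ci_high: float

    @property
    def f0_hat(self) -> float:
        return self.s_chao1 - self.s_obs


def chao1(
    X,
    small_sample_correction: bool = True,
    variance_branch: str = "bias-corrected",
    conf: float = 0.95,
) -> RichnessEstimate:
    """Chao1 point estimate, variance and log-normal CI.

    ``variance_branch`` selects 'bias-corrected' (default; reproduces the
    EstimateS output this module is benchmarked against) or 'classic'
    (Chao 1984 variance without the A multipliers).
    """
    v = _as_vector(X)
    n, s_obs, f1, f2 = v.n, v.s_obs, v.f1, v.f2
    a = (n - 1) / n if (small_sample_correction and n > 0) else 1.0
    if f2 > 0:
        f0 = a * f1 * f1 / (2.0 * f2)
    else:
        f0 = a * f1 * (f1 - 1) / 2.0
    est = s_obs + f0

    if f1 == 0:
        var = 0.0
    elif f2 > 0:
        r = f1 / f2
        if variance_branch == "bias-corrected":
            var = f2 * (a * r**2 / 2.0 + a**2 * r**3 + a**2 * r**4 / 4.0)
        elif variance_branch == "classic":
            var = f2 * (r**2 / 2.0 + r**3 + r**4 / 4.0)
        else:
            raise ValueError(f"unknown variance_branch {variance_branch!r}")
    else:
        var = (
            a * f1 * (f1 - 1) / 2.0
            + a**2 * f1 * (2 * f1 - 1) ** 2 / 4.0
            - a**2 * f1**4 / (4.0 * est)
        )

    z = Z_95 if conf == 0.95 else float(-_norm_ppf((1 - conf) / 2))
    if f0 > 0 and var > 0:
        k = math.exp(z * math.sqrt(math.log(1.0 + var / f0**2)))
        ci_low, ci_high = s_obs + f0 / k, s_obs + f0 * k
    else:
        ci_low = ci_high = float(est)
    return RichnessEstimate(
        s_obs=s_obs, n=n, f1=f1, f2=f2,
        s_chao1=float(est), variance=float(var),
        ci_low=float(ci_low), ci_high=float(ci_high),
    )


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))


def ace(X, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator (rare-class cutoff 10).

    With no rare classes the estimator falls back to S_obs.  A rare class
    consisting solely of singletons has coverage 0 and no defined estimate.
    """
    v = _as_vector(X)
    rare = v.X[v.X <= rare_cutoff]
    s_abund = int((v.X > rare_cutoff).sum())
    s_rare = int(rare.size)
    if s_rare == 0:
        return float(v.s_obs)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    coverage = 1.0 - f1 / n_rare
    if coverage == 0.0:
        raise ValueError("ACE undefined: all rare classes are singletons (coverage 0)")
    ssum = sum(k * (k - 1) * int((rare == k).sum()) for k in range(1, rare_cutoff + 1))
    gamma2 = max(
        s_rare / coverage * ssum / (n_rare * (n_rare - 1.0)) - 1.0 if n_rare > 1 else 0.0,
        0.0,
    )
    return float(s_abund + s_rare / coverage + f1 / coverage * gamma2)


def _log_choose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy_expected(X, m: int) -> float:
    """Expected richness in a random subsample of m individuals (m <= n)."""
    v = _as_vector(X)
    if m < 0 or m > v.n:
        raise ValueError(f"m must be in [0, n={v.n}]; use extrapolate for m > n")
    if m == 0:
        return 0.0
    absent = _absence_probs(v, m)
    return float(v.s_obs - absent.sum())


def _absence_probs(v: AbundanceVector, m: int) -> np.ndarray:
    """P(class i absent from a subsample of size m), hypergeometric."""
    n = v.n
    out = np.zeros(v.s_obs)
    keep = n - v.X >= m
    out[keep] = np.exp(_log_choose(n - v.X[keep], m) - _log_choose(n, m))
    return out


def rarefaction_variance(X, m: int) -> float:
    """Exact variance of subsample richness (Heck et al. 1975 form)."""
    v = _as_vector(X)
    if m < 0 or m > v.n:
        raise ValueError("m must be in [0, n]")
    if m in (0, v.n):
        return 0.0
    n = v.n
    a = _absence_probs(v, m)
    var = float((a * (1 - a)).sum())
    # joint absence of class pairs
    x = v.X
    for i in range(len(x)):
        rest = n - x[i] - x[i + 1 :]
        ok = rest >= m
        aij = np.zeros(len(rest))
        aij[ok] = np.exp(_log_choose(rest[ok], m) - _log_choose(n, m))
        var += 2.0 * float((aij - a[i] * a[i + 1 :]).sum())
    return max(var, 0.0)


def extrapolate(X, m_star: int) -> float:
    """Expected richness after m_star additional individuals (unseen-class model)."""
    v = _as_vector(X)
    if m_star < 0:
        raise ValueError("m_star must be >= 0")
    est = chao1(v)
    f0 = est.f0_hat
    if f0 <= 0 or v.f1 == 0:
        return float(v.s_obs)
    q = v.f1 / (v.n * f0 + v.f1)
    return float(v.s_obs + f0 * (1.0 - (1.0 - q) ** m_star))


def rarefaction_curve(
    X,
    max_individuals: int | None = None,
    num_points: int = 40,
) -> "np.recarray":
    """Interpolated + extrapolated expected-richness curve with 95% bands.

    Interpolated points carry the exact hypergeometric variance band;
    extrapolated points carry no analytic band (NaN) — use
    :func:`accumulation_curves` for a resampling band.
    """
    v = _as_vector(X)
    n = v.n
    top = max_individuals if max_individuals is not None else 3 * n
    ms = np.unique(
        np.concatenate(
            [
                np.linspace(0, n, min(num_points, n + 1)).astype(int),
                np.linspace(n, top, max(num_points // 2, 2)).astype(int),
            ]
        )
    )
    rows = []
    for m in ms:
        if m <= n:
            e = rarefy_expected(v, int(m))
            sd = math.sqrt(rarefaction_variance(v, int(m)))
            rows.append((int(m), e, e - Z_95 * sd, e + Z_95 * sd, "interpolated"))
        else:
            e = extrapolate(v, int(m) - n)
            rows.append((int(m), e, np.nan, np.nan, "extrapolated"))
    return np.rec.fromrecords(
        rows, names=["m", "expected_s", "ci_low", "ci_high", "mode"]
    )


def samples_needed(
    X,
    target_s: float | None = None,
    target_fraction: float | None = None,
    cap: int = 10_000_000,
) -> int | None:
    """Smallest total sample size N with extrapolated S(N) >= target.

    ``target_fraction`` expresses the target as a fraction of the Chao1
    asymptote; by default the target is 'within 0.5 haplotypes of the point
    estimate'.  Targets at or above the asymptote (or needing more than
    ``cap`` individuals) return None (unreachable).
    """
    v = _as_vector(X)
    est = chao1(v)
    asymptote = est.s_chao1
    if target_fraction is not None:
        target_s = target_fraction * asymptote
    if target_s is None:
        target_s = asymptote - 0.5
    if target_s <= v.s_obs:
        raise ValueError("target must exceed the observed richness")
    f0 = est.f0_hat
    if f0 <= 0 or v.f1 == 0 or target_s >= asymptote:
        return None
    q = v.f1 / (v.n * f0 + v.f1)
    # invert S(n+m*) = S_obs + F0 (1 - (1-q)^m*)  for m*
    frac = (target_s - v.s_obs) / f0
    m_star = math.ceil(math.log1p(-frac) / math.log1p(-q))
    total = v.n + m_star
    return total if total <= cap else None


def accumulation_curves(
    X,
    runs: int = 100,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Randomised accumulation curves (runs x n matrix of running richness).

    Each run shuffles the individuals of the reference sample and records
    the number of distinct classes after each draw.  Expectations should be
    taken from :func:`rarefy_expected`; this is for plotting envelopes.
    """
    v = _as_vector(X)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    individuals = np.repeat(np.arange(v.s_obs), v.X)
    out = np.empty((runs, v.n), dtype=int)
    for r in range(runs):
        perm = gen.permutation(individuals)
        seen = np.zeros(v.s_obs, dtype=bool)
        count = 0
        for k, cls in enumerate(perm):
            if not seen[cls]:
                seen[cls] = True
                count += 1
            out[r, k] = count
    return out
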