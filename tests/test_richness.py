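import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcodegeo.richness import (
    AbundanceVector,
    accumulation_curves,
    ace,
    chao1,
    extrapolate,
    rarefaction_curve,
    rarefaction_variance,
    rarefy_expected,
    samples_needed,
)

abundance_vectors = st.lists(st.integers(1, 6), min_size=1, max_size=10)


def enumerate_expected_richness(x, m):
    """Exhaustive oracle: average distinct classes over all C(n, m) subsets."""
    individuals = [i for i, c in enumerate(x) for _ in range(c)]
    subsets = list(itertools.combinations(range(len(individuals)), m))
    total = sum(len({individuals[i] for i in sub}) for sub in subsets)
    return total / len(subsets)


class TestChao1:
    def test_no_singletons_means_no_unseen_signal(self):
        est = chao1([3, 2, 5])
        assert est.s_chao1 == est.s_obs == 3
        assert est.ci_low == est.ci_high == 3.0

    def test_hand_evaluated_small_case(self):
        # S_obs=3, n=4, F1=2, F2=1: 3 + (3/4)*4/2 = 4.5
        est = chao1([1, 1, 2])
        assert est.s_chao1 == pytest.approx(4.5)

    def test_without_small_sample_correction(self):
        est = chao1([1, 1, 2], small_sample_correction=False)
        assert est.s_chao1 == pytest.approx(3 + 4 / 2)

    def test_no_doubletons_branch(self):
        est = chao1([1, 1, 1, 3])
        n, f1 = 6, 3
        assert est.s_chao1 == pytest.approx(4 + (n - 1) / n * f1 * (f1 - 1) / 2)

    def test_survey_abundances_reproduce_published_estimate(self, survey_fixture):
        from barcodegeo.haplotypes import collapse_haplotypes

        table = collapse_haplotypes(survey_fixture.alignment)
        est = chao1(table.abundances)
        assert (est.s_obs, est.n, est.f1, est.f2) == (47, 97, 38, 2)
        assert round(est.s_chao1) == 404

    def test_lognormal_ci_hand_derivable_bounds(self):
        # S_obs=47, n=97, F1=38, F2=2 -> the hand-derived log-normal bounds
        est = chao1([17, 15, 10, 4, 3, 3, 3, 2, 2] + [1] * 38)
        f0 = est.s_chao1 - est.s_obs
        from scipy.stats import norm

        z = norm.ppf(0.975)
        k = math.exp(z * math.sqrt(math.log(1 + est.variance / f0**2)))
        assert est.ci_low == pytest.approx(47 + f0 / k, rel=1e-6)
        assert est.ci_high == pytest.approx(47 + f0 * k, rel=1e-6)
        assert round(est.ci_low) == 140
        assert round(est.ci_high) == 1426

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            chao1([])

    @settings(deadline=None, derandomize=True)
    @given(abundance_vectors)
    def test_estimate_never_below_observed(self, x):
        est = chao1(x)
        assert est.s_chao1 >= est.s_obs
        assert est.ci_low <= est.s_chao1 <= est.ci_high

    @settings(deadline=None, derandomize=True)
    @given(abundance_vectors)
    def test_removing_a_singleton_shrinks_unseen_mass(self, x):
        v = AbundanceVector.from_counts(x)
        if v.f1 < 1 or v.s_obs < 2 or v.f2 < 1:
            return
        reduced = list(x)
        reduced.remove(1)
        assert chao1(reduced).f0_hat <= chao1(x).f0_hat + 1e-12


class TestAce:
    def test_no_rare_classes_falls_back_to_observed(self):
        assert ace([11, 12, 40]) == 3.0

    def test_small_case_against_hand_formula(self):
        # X=(1,1,2): S_rare=3, n_rare=4, F1=2, C=0.5,
        # gamma^2 = max(3/0.5 * 2/(4*3) - 1, 0) = 0 -> ACE = 3/0.5 = 6
        assert ace([1, 1, 2]) == pytest.approx(6.0)

    def test_singletons_only_is_undefined(self):
        with pytest.raises(ValueError, match="coverage 0"):
            ace([1, 1, 1])


class TestRarefaction:
    def test_reference_point_and_origin(self):
        x = [5, 3, 1]
        assert rarefy_expected(x, sum(x)) == pytest.approx(3.0)
        assert rarefy_expected(x, 0) == 0.0

    def test_tiny_case_by_subset_enumeration(self):
        # X = (2,1), m = 2: 2 - [C(1,2)/C(3,2) + C(2,2)/C(3,2)] = 5/3
        assert rarefy_expected([2, 1], 2) == pytest.approx(5 / 3)
        assert rarefy_expected([2, 1], 2) == pytest.approx(
            enumerate_expected_richness([2, 1], 2)
        )

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(abundance_vectors, st.data())
    def test_equals_exhaustive_enumeration(self, x, data):
        n = sum(x)
        if n > 12:
            return
        m = data.draw(st.integers(0, n))
        assert rarefy_expected(x, m) == pytest.approx(
            enumerate_expected_richness(x, m) if m else 0.0
        )

    def test_beyond_reference_rejected(self):
        with pytest.raises(ValueError):
            rarefy_expected([2, 1], 4)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(abundance_vectors)
    def test_curve_concave_and_nondecreasing(self, x):
        n = sum(x)
        values = [rarefy_expected(x, m) for m in range(n + 1)]
        diffs = np.diff(values)
        assert (diffs >= -1e-9).all()
        assert (np.diff(diffs) <= 1e-9).all()

    def test_variance_zero_at_endpoints_positive_inside(self):
        x = [4, 2, 1, 1]
        assert rarefaction_variance(x, 0) == 0.0
        assert rarefaction_variance(x, sum(x)) == 0.0
        assert rarefaction_variance(x, 3) > 0.0


class TestExtrapolation:
    def test_zero_additional_individuals(self):
        assert extrapolate([1, 1, 2], 0) == pytest.approx(3.0)

    def test_meets_interpolation_at_reference(self):
        x = [4, 2, 1, 1]
        assert rarefy_expected(x, sum(x)) == pytest.approx(extrapolate(x, 0))

    def test_asymptote_is_chao1(self):
        x = [1, 1, 2]
        assert extrapolate(x, 10_000_000) == pytest.approx(chao1(x).s_chao1, rel=1e-6)

    def test_toy_curve_frozen_values(self):
        # independently derived closed form for X=(1,1,2):
        # F0 = 1.5, q = 2 / (4*1.5 + 2) = 0.25
        # S(n+m*) = 3 + 1.5 (1 - 0.75^m*)
        for m_star in (1, 5, 50):
            expected = 3 + 1.5 * (1 - 0.75**m_star)
            assert extrapolate([1, 1, 2], m_star) == pytest.approx(expected)

    def test_no_singletons_stays_constant(self):
        assert extrapolate([2, 3, 4], 1000) == 3.0

    def test_curve_object_modes(self):
        curve = rarefaction_curve([4, 2, 1, 1], max_individuals=20)
        modes = set(curve.mode)
        assert modes == {"interpolated", "extrapolated"}
        assert (np.diff(curve.expected_s) >= -1e-9).all()


class TestSamplesNeeded:
    def test_grid_search_oracle_agreement(self):
        x = [1, 1, 2]
        target = 0.95 * chao1(x).s_chao1
        n = sum(x)
        needed = samples_needed(x, target_fraction=0.95)
        # dense-grid oracle over the extrapolation curve
        grid = next(
            n + m for m in range(1, 1000) if extrapolate(x, m) >= target
        )
        assert needed == grid

    def test_target_beyond_asymptote_unreachable(self):
        x = [1, 1, 2]
        assert samples_needed(x, target_s=chao1(x).s_chao1 + 1) is None

    def test_target_below_observed_rejected(self):
        with pytest.raises(ValueError):
            samples_needed([1, 1, 2], target_s=2)

    def test_monotone_in_target(self):
        x = [1, 1, 1, 2, 2, 5]
        asym = chao1(x).s_chao1
        n80 = samples_needed(x, target_fraction=0.8)
        n95 = samples_needed(x, target_fraction=0.95)
        assert sum(x) < n80 < n95

    def test_survey_projection_scale(self, survey_fixture):
        # reaching the full published point estimate requires thousands of
        # specimens; reaching the lower CI bound only a few hundred
        from barcodegeo.haplotypes import collapse_haplotypes

        x = collapse_haplotypes(survey_fixture.alignment).abundances
        est = chao1(x)
        near_asymptote = samples_needed(x, target_s=round(est.s_chao1) - 0.5)
        assert near_asymptote is not None and near_asymptote > 5000
        to_lower = samples_needed(x, target_s=est.ci_low)
        assert to_lower is not None and 97 < to_lower < 600


class TestCoverage:
    def test_ci_covers_true_richness_on_geometric_pools(self):
        # Chao1 is a lower-bound-flavoured estimator; assert practical
        # (not nominal) coverage of the log-normal CI
        rng = np.random.default_rng(2024)
        s_true, n = 40, 100
        p = 0.95 ** np.arange(s_true)
        p /= p.sum()
        hits = 0
        for _ in range(200):
            draws = rng.choice(s_true, size=n, p=p)
            x = np.bincount(draws)
            x = x[x > 0]
            est = chao1(x)
            if est.ci_low <= s_true <= est.ci_high:
                hits += 1
        assert hits / 200 >= 0.80


class TestAccumulation:
    def test_seeded_runs_reproducible_and_end_at_s_obs(self):
        x = [5, 3, 1, 1]
        runs_a = accumulation_curves(x, runs=20, rng=1)
        runs_b = accumulation_curves(x, runs=20, rng=1)
        assert (runs_a == runs_b).all()
        assert (runs_a[:, -1] == 4).all()
        assert (np.diff(runs_a, axis=1) >= 0).all()
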