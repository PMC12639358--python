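"""Overlap coefficients, estimator selection, bootstrap CIs, classification."""
import math

import numpy as np
import pytest

from trapdiel import (AnalysisConfig, OverlapModel, classify_overlaps, delta1,
                      delta4, delta_true, estimate_overlap, fit_kde,
                      smoothed_bootstrap_ci)
from trapdiel.circular import ActivityKDE, vonmises_pdf
from trapdiel.overlap import OverlapResults

TWO_PI = 2 * math.pi


def analytic_kde(mu, kappa, grid_size=512):
    """An ActivityKDE whose gridded density is an exact von Mises."""
    grid = np.linspace(0, TWO_PI, grid_size, endpoint=False)
    return ActivityKDE(angles=np.array([mu]), kappa=kappa, adjust=1.0,
                       grid=grid, density=vonmises_pdf(grid, mu, kappa))


class TestDelta1:
    def test_identical_densities(self, rng):
        k = fit_kde(rng.vonmises(1, 2, 50) % TWO_PI, adjust=0.8)
        assert delta1(k, k) == pytest.approx(1.0, abs=1e-6)

    def test_matches_quadrature_for_analytic_pair(self):
        a = analytic_kde(0.0, 20.0)
        b = analytic_kde(math.pi, 20.0)
        truth = delta_true([(1.0, 0.0, 20.0)], [(1.0, math.pi, 20.0)])
        assert delta1(a, b) == pytest.approx(truth, abs=0.01)

    def test_bounded(self, rng):
        for _ in range(5):
            a = fit_kde(rng.uniform(0, TWO_PI, 30), adjust=0.8)
            b = fit_kde(rng.vonmises(2, 5, 40) % TWO_PI, adjust=0.8)
            assert 0.0 <= delta1(a, b) <= 1.0

    def test_mismatched_grids_rejected(self, rng):
        a = fit_kde(rng.uniform(0, TWO_PI, 30), grid_size=64)
        b = fit_kde(rng.uniform(0, TWO_PI, 30), grid_size=128)
        with pytest.raises(ValueError, match="grid"):
            delta1(a, b)


class TestDelta4:
    def test_identical_samples_give_one(self, rng):
        x = rng.vonmises(1, 3, 100) % TWO_PI
        k = fit_kde(x)
        assert delta4(x, x, k, k) == 1.0

    def test_consistency_under_equality(self, rng):
        x = rng.vonmises(2, 3, 2000) % TWO_PI
        y = rng.vonmises(2, 3, 2000) % TWO_PI
        d = delta4(x, y, fit_kde(x), fit_kde(y))
        assert d > 0.95

    def test_symmetry(self, rng):
        x = rng.vonmises(0, 2, 80) % TWO_PI
        y = rng.vonmises(2, 2, 90) % TWO_PI
        kx, ky = fit_kde(x), fit_kde(y)
        assert delta4(x, y, kx, ky) == pytest.approx(delta4(y, x, ky, kx),
                                                     abs=1e-12)


class TestEstimatorSelection:
    @pytest.mark.parametrize("n_a,n_b,expected", [
        (22, 27, "Dhat1"),     # small abundant-species comparison
        (111, 89, "Dhat4"),    # large comparison
        (75, 200, "Dhat4"),    # boundary: the small-sample rule is strict
        (74, 200, "Dhat1"),
    ])
    def test_threshold_rule(self, rng, n_a, n_b, expected):
        a = rng.uniform(0, TWO_PI, n_a)
        b = rng.uniform(0, TWO_PI, n_b)
        assert OverlapModel(a, b).estimator == expected

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            OverlapModel([], [1.0, 2.0])


class TestEstimatorAgreement:
    def test_delta1_delta4_agree_on_large_balanced_samples(self, rng):
        x = rng.vonmises(1.0, 2.0, 2000) % TWO_PI
        y = rng.vonmises(2.0, 2.0, 2000) % TWO_PI
        cfg = AnalysisConfig()
        d1 = delta1(fit_kde(x, cfg.kde_adjust_grid), fit_kde(y, cfg.kde_adjust_grid))
        d4 = delta4(x, y, fit_kde(x), fit_kde(y))
        assert abs(d1 - d4) < 0.05

    def test_delta_increases_toward_one_with_n(self, rng):
        deltas = []
        for n in (50, 200, 2000):
            x = rng.vonmises(1.0, 3.0, n) % TWO_PI
            y = rng.vonmises(1.0, 3.0, n) % TWO_PI
            deltas.append(estimate_overlap(x, y).delta)
        assert deltas[0] < deltas[-1] and deltas[-1] > 0.95

    def test_rotation_invariance(self, rng):
        x = rng.vonmises(1.0, 3.0, 120) % TWO_PI
        y = rng.vonmises(2.5, 2.0, 150) % TWO_PI
        shift = TWO_PI * 16 / 128
        d0 = estimate_overlap(x, y).delta
        d1_ = estimate_overlap((x + shift) % TWO_PI, (y + shift) % TWO_PI).delta
        assert d0 == pytest.approx(d1_, abs=1e-6)


class TestSmoothedBootstrapCI:
    def test_bounds_and_ordering(self, rng):
        """Identical samples: bounds stay in [0, 1] with the upper end near 1.

        The point estimate sits exactly at the boundary (Delta = 1), and a
        percentile bootstrap interval lies strictly inside it because every
        replicate resamples the two sides independently.
        """
        x = rng.vonmises(1, 3, 60) % TWO_PI
        lo, hi = smoothed_bootstrap_ci(x, x.copy(), reps=200, seed=1)
        assert estimate_overlap(x, x.copy()).delta == 1.0
        assert 0.0 <= lo <= hi <= 1.0
        assert hi > 0.9

    def test_same_seed_reproduces(self, rng):
        x = rng.vonmises(0, 2, 50) % TWO_PI
        y = rng.vonmises(1, 2, 55) % TWO_PI
        assert (smoothed_bootstrap_ci(x, y, reps=200, seed=9)
                == smoothed_bootstrap_ci(x, y, reps=200, seed=9))

    def test_too_few_reps_rejected(self, rng):
        x = rng.uniform(0, TWO_PI, 30)
        with pytest.raises(ValueError):
            smoothed_bootstrap_ci(x, x, reps=10)

    def test_bias_corrected_variant_runs(self, rng):
        x = rng.vonmises(0, 2, 50) % TWO_PI
        y = rng.vonmises(1, 2, 50) % TWO_PI
        lo, hi = smoothed_bootstrap_ci(x, y, reps=200, seed=2, method="bc")
        assert 0.0 <= lo < hi <= 1.0


def _result(delta):
    return OverlapResults(unit=f"u{delta}", n_a=10, n_b=10, estimator="Dhat1",
                          delta=delta, ci=None, ci_level=0.95, watson=None)


class TestClassification:
    def test_percentile_convention(self):
        res = [_result(d) for d in (0.5, 0.6, 0.7, 0.8)]
        classify_overlaps(res)
        assert [r.classification for r in res] == ["low", "low", "moderate",
                                                   "high"]

    def test_equal_deltas_all_low(self):
        res = [_result(0.7) for _ in range(4)]
        classify_overlaps(res)
        assert all(r.classification == "low" for r in res)

    def test_rank_invariance_under_monotone_transform(self):
        deltas = [0.21, 0.43, 0.55, 0.62, 0.8, 0.91]
        res_a = [_result(d) for d in deltas]
        res_b = [_result(d**2) for d in deltas]  # strictly monotone on [0,1]
        classify_overlaps(res_a)
        classify_overlaps(res_b)
        assert ([r.classification for r in res_a]
                == [r.classification for r in res_b])

    def test_single_result_left_unset_with_warning(self):
        res = [_result(0.5)]
        with pytest.warns(UserWarning):
            classify_overlaps(res)
        assert res[0].classification is None
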