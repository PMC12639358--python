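"""Von Mises kernel density estimation and Watson U² tests."""
import math

import numpy as np
import pytest

from trapdiel import fit_kde, watson_two_sample, watson_uniformity
from trapdiel.circular import (kernel_concentration, vonmises_kappa_ml,
                               vonmises_pdf, watson_uniformity_statistic)

TWO_PI = 2 * math.pi


class TestKappaEstimation:
    def test_ml_inverts_a1(self):
        from scipy import special
        for kappa in (0.5, 2.0, 8.0, 50.0):
            rbar = special.i1e(kappa) / special.i0e(kappa)
            assert vonmises_kappa_ml(rbar) == pytest.approx(kappa, rel=1e-6)

    def test_plug_in_grows_with_n(self):
        k1 = kernel_concentration(0.6, 50)
        k2 = kernel_concentration(0.6, 500)
        assert k2 > k1
        assert k2 / k1 == pytest.approx(10 ** 0.4, rel=1e-6)


class TestKDE:
    def test_uniform_sample_gives_flat_density(self, rng):
        x = rng.uniform(0, TWO_PI, 5000)
        model = fit_kde(x)
        assert np.max(np.abs(model.density - 1 / TWO_PI)) < 0.02

    def test_density_normalises(self, rng):
        for kappa in (0.5, 4.0, 30.0):
            model = fit_kde(rng.vonmises(1.0, kappa, 200) % TWO_PI)
            assert model.integral() == pytest.approx(1.0, abs=1e-3)
            assert np.all(model.density >= 0)

    def test_mode_recovery(self, rng):
        x = rng.vonmises(math.pi, 4.0, 2000) % TWO_PI
        model = fit_kde(x)
        mode = model.grid[np.argmax(model.density)]
        assert abs(mode - math.pi) < 0.1

    def test_rotation_equivariance(self, rng):
        x = rng.vonmises(1.0, 3.0, 400) % TWO_PI
        shift = TWO_PI * 32 / 128  # whole grid steps, so grids align
        a = fit_kde(x, grid_size=128)
        b = fit_kde((x + shift) % TWO_PI, grid_size=128)
        np.testing.assert_allclose(np.roll(a.density, 32), b.density,
                                   atol=1e-10)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_kde([1.0])

    def test_identical_angles_fall_back_with_warning(self):
        with pytest.warns(UserWarning, match="identical"):
            model = fit_kde([2.0] * 10)
        assert model.grid[np.argmax(model.density)] == pytest.approx(2.0, abs=0.05)


class TestWatsonOneSample:
    def test_equispaced_closed_form(self):
        n = 10
        u = (np.arange(1, n + 1) - 0.5) / n * TWO_PI
        stat = watson_uniformity_statistic(u)[0]
        assert stat == pytest.approx(1 / 120, abs=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            watson_uniformity(np.arange(5, dtype=float))

    def test_rotation_invariance(self, rng):
        x = rng.uniform(0, TWO_PI, 60)
        a = watson_uniformity(x).statistic
        b = watson_uniformity((x + 1.234) % TWO_PI).statistic
        assert a == pytest.approx(b, abs=1e-10)

    def test_power_against_concentrated_sample(self, rng):
        x = rng.vonmises(2.0, 8.0, 100) % TWO_PI
        res = watson_uniformity(x)
        assert res.significant and res.p_value < 1e-3

    def test_type_one_error_calibrated(self, rng):
        """Rejection rate at the nominal 5% level under uniformity."""
        sims, n = 10_000, 50
        u = rng.uniform(0, TWO_PI, (sims, n))
        stats = watson_uniformity_statistic(u)
        mod = (stats - 0.1 / n + 0.1 / n**2) * (1 + 0.8 / n)
        # asymptotic 5% critical value of the limiting distribution
        crit = 0.186785
        rate = np.mean(mod > crit)
        assert abs(rate - 0.05) < 0.01


def watson_two_sample_bruteforce(a, b):
    """O(N^2) reference: eCDF difference evaluated at every pooled point."""
    a, b = np.sort(a), np.sort(b)
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    d = []
    for v in pooled:
        d.append(np.sum(a <= v) / n - np.sum(b <= v) / m)
    d = np.array(d)
    return n * m / (n + m) ** 2 * np.sum((d - d.mean()) ** 2)


class TestWatsonTwoSample:
    def test_matches_bruteforce_on_random_pairs(self, rng):
        for _ in range(100):
            n, m = rng.integers(8, 30, 2)
            a = rng.uniform(0, TWO_PI, n)
            b = rng.vonmises(1.0, rng.uniform(0, 3), m) % TWO_PI
            fast = watson_two_sample(a, b).statistic
            slow = watson_two_sample_bruteforce(a, b)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_symmetric_under_swap(self, rng):
        a = rng.uniform(0, TWO_PI, 25)
        b = rng.uniform(0, TWO_PI, 40)
        assert (watson_two_sample(a, b).statistic
                == pytest.approx(watson_two_sample(b, a).statistic, abs=1e-12))

    def test_identical_samples_minimal_and_not_significant(self, rng):
        a = rng.uniform(0, TWO_PI, 30)
        res = watson_two_sample(a, a.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert not res.significant

    def test_rotation_invariance(self, rng):
        a = rng.uniform(0, TWO_PI, 20)
        b = rng.uniform(0, TWO_PI, 22)
        r1 = watson_two_sample(a, b).statistic
        r2 = watson_two_sample((a + 2.5) % TWO_PI, (b + 2.5) % TWO_PI).statistic
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            watson_two_sample([1.0] * 10, [1.0] * 10)

    def test_type_one_error_calibrated(self, rng):
        """Two-sample rejection rate at the nominal 5% level under the null."""
        sims, n, m = 10_000, 50, 50
        N = n + m
        pooled = rng.uniform(0, 1, (sims, N))
        labels = np.zeros((sims, N), dtype=bool)
        labels[:, :n] = True
        order = np.argsort(pooled, axis=1)
        lab_sorted = np.take_along_axis(labels, order, axis=1)
        d = np.cumsum(lab_sorted, axis=1) / n - np.cumsum(~lab_sorted, axis=1) / m
        stats = n * m / N**2 * ((d - d.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        mod = (stats - 0.1 / N + 0.1 / N**2) * (1 + 0.8 / N)
        rate = np.mean(mod > 0.186785)
        assert abs(rate - 0.05) < 0.01
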