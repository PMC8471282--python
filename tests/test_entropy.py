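import math
from collections import Counter

import numpy as np
import pytest

import ehgpredict as ep
from ehgpredict.entropy import (EntropyParams, bubble_entropy,
                                dispersion_entropy, fuzzy_entropy,
                                optimize_entropy_params, parameter_grid,
                                sample_entropy, spectral_entropy)
from ehgpredict.linear import PSD
from ehgpredict.preprocess import WBW, BandSpec


# ---------------------------------------------------------------------------
# Independent brute-force oracles (explicit double loops / enumeration)
# ---------------------------------------------------------------------------

def sampen_oracle(x, m, r):
    x = np.asarray(x, float)
    rr = r * np.std(x)
    n = len(x)
    L = n - m

    def count(mm):
        c = 0
        for i in range(L):
            for j in range(i + 1, L):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= rr:
                    c += 1
        return c

    b, a = count(m), count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def fuzen_oracle(x, m, r, n_pow):
    x = np.asarray(x, float)
    N = len(x)
    L = N - m

    def phi(mm):
        vecs = []
        for i in range(L):
            v = x[i:i + mm]
            vecs.append(v - v.mean())
        total = 0.0
        for i in range(L):
            for j in range(L):
                if i == j:
                    continue
                d = max(abs(vecs[i][k] - vecs[j][k]) for k in range(mm))
                total += math.exp(-(d ** n_pow) / r)
        return total / (L * (L - 1))

    return math.log(phi(m)) - math.log(phi(m + 1))


def dispen_oracle(x, m, c):
    """Linear mapping + exhaustive pattern enumeration."""
    x = np.asarray(x, float)
    lo, hi = x.min(), x.max()
    z = [min(int((v - lo) / (hi - lo) * c) + 1, c) for v in x]
    patterns = Counter(tuple(z[i:i + m]) for i in range(len(z) - m + 1))
    total = sum(patterns.values())
    return -sum((k / total) * math.log(k / total)
                for k in patterns.values())


def bubben_oracle(x, m):
    x = np.asarray(x, float)

    def renyi(k):
        counts = []
        for i in range(len(x) - k + 1):
            v = x[i:i + k]
            inv = sum(1 for a in range(k) for b in range(a + 1, k)
                      if v[a] > v[b])
            counts.append(inv)
        occ = Counter(counts)
        n = len(counts)
        return -math.log(sum((c / n) ** 2 for c in occ.values()))

    return (renyi(m + 1) - renyi(m)) / math.log((m + 1) / (m - 1))


# ---------------------------------------------------------------------------
# Oracle equivalence on seeded random sequences
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    def test_sample_entropy_matches_bruteforce(self):
        rng = np.random.default_rng(100)
        for _ in range(12):
            x = rng.standard_normal(rng.integers(120, 260))
            got = sample_entropy(x, 3, 0.2)
            want = sampen_oracle(x, 3, 0.2)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-10)

    def test_fuzzy_entropy_matches_bruteforce(self):
        rng = np.random.default_rng(101)
        for _ in range(6):
            x = rng.standard_normal(rng.integers(60, 120))
            got = fuzzy_entropy(x, 5, 0.0077, 3, "exponential")
            assert got == pytest.approx(fuzen_oracle(x, 5, 0.0077, 3),
                                        abs=1e-10)

    def test_dispersion_entropy_matches_enumeration(self):
        rng = np.random.default_rng(102)
        for _ in range(12):
            x = rng.standard_normal(rng.integers(50, 400))
            assert dispersion_entropy(x, 2, 3, "linear") == pytest.approx(
                dispen_oracle(x, 2, 3), abs=1e-10)

    def test_bubble_entropy_matches_inversion_counting(self):
        rng = np.random.default_rng(103)
        for _ in range(8):
            x = rng.standard_normal(rng.integers(120, 260))
            assert bubble_entropy(x, 23) == pytest.approx(
                bubben_oracle(x, 23), abs=1e-10)


# ---------------------------------------------------------------------------
# Exact small cases and degenerate inputs
# ---------------------------------------------------------------------------

class TestTrivialCases:
    def test_constant_series(self):
        x = np.full(200, 5.0)
        assert sample_entropy(x, 2, 0.2) == 0.0
        assert fuzzy_entropy(x, 2, 0.0077, 3) == 0.0
        assert dispersion_entropy(x, 2, 3) == 0.0

    def test_monotone_series_bubble_zero(self):
        assert bubble_entropy(np.arange(100.0), 10) == 0.0
        assert bubble_entropy(-np.arange(100.0) * 2.5, 5) == 0.0

    def test_periodic_binary_sampen_zero(self):
        x = np.tile([0.0, 1.0], 200)
        assert sample_entropy(x, 2, 0.1) == 0.0

    def test_dispen_twelve_sample_toy(self):
        x = np.array([1.0, 3.0, 8.0, 2.0, 5.0, 9.0, 1.5, 4.0, 7.5, 2.5,
                      6.0, 8.5])
        assert dispersion_entropy(x, 2, 3, "linear") == pytest.approx(
            dispen_oracle(x, 2, 3), abs=1e-12)

    def test_dispen_uniform_noise_approaches_max(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(size=5000)
        assert dispersion_entropy(x, 2, 3, "linear") == pytest.approx(
            math.log(9), rel=0.02)

    def test_dispen_needs_cm_below_length(self):
        with pytest.raises(ValueError):
            dispersion_entropy(np.zeros(50), 5, 9)

    def test_bubble_requires_m_at_least_two(self):
        with pytest.raises(ValueError):
            bubble_entropy(np.arange(50.0), 1)


class TestSpectralEntropy:
    def test_flat_in_band_is_one(self):
        f = np.arange(0.0, 5.0, 0.01)
        psd = PSD(freqs=f, power=np.ones(f.size))
        assert spectral_entropy(psd, WBW) == pytest.approx(1.0, abs=1e-12)

    def test_single_tone_concentrated(self):
        f = np.arange(0.0, 5.0, 0.01)
        p = np.zeros(f.size)
        p[np.argmin(np.abs(f - 0.5))] = 1.0
        assert spectral_entropy(PSD(freqs=f, power=p), WBW) <= 0.2

    def test_two_equal_tones(self):
        f = np.arange(0.0, 5.0, 0.01)
        p = np.zeros(f.size)
        p[np.argmin(np.abs(f - 0.5))] = 1.0
        p[np.argmin(np.abs(f - 2.0))] = 1.0
        n_bins = int(np.sum((f >= WBW.low) & (f <= WBW.high)))
        expected = math.log(2) / math.log(n_bins)
        assert spectral_entropy(PSD(freqs=f, power=p), WBW) == pytest.approx(
            expected, abs=1e-9)

    def test_zero_power_missing(self):
        f = np.arange(0.0, 5.0, 0.01)
        psd = PSD(freqs=f, power=np.zeros(f.size))
        assert np.isnan(spectral_entropy(psd, WBW))


# ---------------------------------------------------------------------------
# Invariances and orderings
# ---------------------------------------------------------------------------

class TestInvariances:
    def test_scale_and_offset_invariance(self, rng):
        x = rng.standard_normal(300)
        y = 3.5 * x + 11.0
        assert sample_entropy(y, 2, 0.2) == pytest.approx(
            sample_entropy(x, 2, 0.2), abs=1e-10)
        assert bubble_entropy(y, 10) == pytest.approx(
            bubble_entropy(x, 10), abs=1e-12)
        for mapping in ("linear", "ncdf", "tansig", "logsig", "sorting"):
            assert dispersion_entropy(y, 2, 3, mapping) == pytest.approx(
                dispersion_entropy(x, 2, 3, mapping), abs=1e-10)

    def test_noise_exceeds_sinusoid_at_reference_settings(self, rng):
        t = np.arange(2400) / 20.0
        sin = math.sqrt(2.0) * np.sin(2 * np.pi * 0.45 * t)  # unit variance
        noise = rng.standard_normal(2400)
        assert sample_entropy(noise, 3, 0.15) > sample_entropy(sin, 3, 0.15)
        assert (fuzzy_entropy(noise, 5, 0.0077, 3, normalize=True)
                > fuzzy_entropy(sin, 5, 0.0077, 3, normalize=True))
        assert (dispersion_entropy(noise, 2, 3) > dispersion_entropy(sin, 2, 3))
        assert bubble_entropy(noise, 23) > bubble_entropy(sin, 23)
        psd_n = ep.welch_psd(noise, 20.0)
        psd_s = ep.welch_psd(sin, 20.0)
        assert (spectral_entropy(psd_n, WBW) > spectral_entropy(psd_s, WBW))

    def test_bubble_high_m_variation_bounded(self):
        # at window-length 2400 the swap-count distribution estimate is
        # noisy, so neighbouring high embedding dimensions agree only
        # loosely; the variation stays well below the estimator's range
        diffs = []
        for seed in (1, 2, 3):
            x = np.random.default_rng(seed).standard_normal(2400)
            diffs.append(abs(bubble_entropy(x, 23) - bubble_entropy(x, 26)))
        assert np.mean(diffs) < 0.35

    def test_dispersion_mapping_families_all_finite(self, rng):
        x = rng.standard_normal(500)
        for mapping in ("linear", "ncdf", "tansig", "logsig", "sorting"):
            v = dispersion_entropy(x, 2, 4, mapping)
            assert np.isfinite(v) and v > 0

    def test_fuzzy_membership_families_all_finite(self, rng):
        x = rng.standard_normal(300)
        for fam, (r, n) in ep.entropy.FUZEN_FAMILY_DEFAULTS.items():
            v = fuzzy_entropy(x, 2, r, n, fam, normalize=True)
            assert np.isfinite(v), fam


# ---------------------------------------------------------------------------
# Parameter grids and the separability sweep
# ---------------------------------------------------------------------------

class TestParameterGrids:
    def test_grid_sizes(self):
        assert len(parameter_grid("SampEn")) == 4 * 6
        assert len(parameter_grid("FuzEn")) == 4 * 7
        assert len(parameter_grid("BubbEn")) == 39
        grid = parameter_grid("DispEn", window_len=2400)
        assert all(p.c ** p.m < 2400 for p in grid)

    def test_tau_fixed_to_one(self):
        for est in ("SampEn", "FuzEn", "DispEn"):
            assert all(p.tau == 1 for p in parameter_grid(est, 2400))


class TestSweep:
    def _values(self, rng, shift):
        labels = np.array(["term"] * 12 + ["preterm"] * 12)
        base = rng.standard_normal(24)
        return labels, base + np.where(labels == "preterm", -shift, 0.0)

    def test_singleton_grid_returned(self, rng):
        labels, vals = self._values(rng, 1.0)
        grid = [EntropyParams("SampEn", m=2, r=0.1)]
        res = optimize_entropy_params("SampEn", grid, {grid[0]: vals}, labels)
        assert res.best == grid[0]

    def test_minimum_matches_independent_recomputation(self, rng):
        from scipy.stats import mannwhitneyu

        labels = np.array(["term"] * 15 + ["preterm"] * 15)
        grid = parameter_grid("SampEn")[:8]
        per = {}
        for i, g in enumerate(grid):
            shift = 0.2 * i
            per[g] = rng.standard_normal(30) + np.where(
                labels == "preterm", -shift, 0.0)
        res = optimize_entropy_params("SampEn", grid, per, labels)
        expected = min(
            (mannwhitneyu(v[labels == "term"], v[labels == "preterm"],
                          alternative="two-sided").pvalue, i)
            for i, v in enumerate(per.values()))
        assert res.p_value == pytest.approx(expected[0], abs=1e-9)
        assert res.best == grid[expected[1]]

    def test_tie_break_prefers_smaller_m(self, rng):
        labels = np.array(["term"] * 10 + ["preterm"] * 10)
        vals = rng.standard_normal(20)
        g1 = EntropyParams("BubbEn", m=5)
        g2 = EntropyParams("BubbEn", m=3)
        res = optimize_entropy_params("BubbEn", [g1, g2],
                                      {g1: vals, g2: vals.copy()}, labels)
        assert res.best.m == 3

    def test_all_missing_grid_point_skipped(self, rng):
        labels = np.array(["term"] * 10 + ["preterm"] * 10)
        g1 = EntropyParams("BubbEn", m=2)
        g2 = EntropyParams("BubbEn", m=3)
        vals = rng.standard_normal(20) + np.where(labels == "preterm", 2, 0)
        res = optimize_entropy_params(
            "BubbEn", [g1, g2],
            {g1: np.full(20, np.nan), g2: vals}, labels)
        assert res.best == g2

    def test_single_class_rejected(self, rng):
        g = EntropyParams("BubbEn", m=2)
        with pytest.raises(ValueError):
            optimize_entropy_params("BubbEn", [g],
                                    {g: rng.standard_normal(5)},
                                    np.array(["term"] * 5))
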