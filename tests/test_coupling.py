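import numpy as np
import pandas as pd
import pytest

import popglm as pg
from popglm.coupling import (classify_interaction, compute_coupling_stats,
                             coupling_gain, coupling_weight,
                             fit_epoch_models, fit_time_constant,
                             fit_tuning_curve, pca_kernels,
                             permutation_null, predictive_index,
                             significant_fraction, coupling_vs_tuning,
                             NullDistribution, TuningFit)


class TestKernelSummaries:
    def test_weight_is_kernel_sum(self):
        assert coupling_weight(np.zeros(250)) == 0.0
        assert coupling_weight(np.array([0.2, -0.1, 0.05])) == \
            pytest.approx(0.15)
        assert coupling_weight(-np.ones(10)) < 0  # inhibitory

    def test_gain_is_exp_of_max(self):
        assert coupling_gain(np.zeros(250)) == 1.0
        k = np.zeros(250)
        k[10] = np.log(1.34)
        assert coupling_gain(k) == pytest.approx(1.34)
        k[50] = -5.0  # values below the max do not matter
        assert coupling_gain(k) == pytest.approx(1.34)

    @pytest.mark.parametrize("pair,expected", [
        (("LIP", "LIP"), "LIP-LIP"), (("FEF", "FEF"), "FEF-FEF"),
        (("LIP", "FEF"), "LIP-FEF"), (("FEF", "LIP"), "FEF-LIP"),
        (("SYNTH", "SYNTH"), "SYNTH-SYNTH")])
    def test_directed_interaction_labels(self, pair, expected):
        assert classify_interaction(*pair) == expected

    def test_unknown_area_strict_mode(self):
        with pytest.raises(ValueError):
            classify_interaction("MT", "LIP", strict=True)

    def test_full_session_has_n_times_n_minus_one_pairs(self, small_truth):
        stats = compute_coupling_stats(small_truth)
        assert len(stats) == 3 * 2
        assert set(zip(stats["from"], stats["to"])) == {
            (a, b) for a in small_truth.unit_ids
            for b in small_truth.unit_ids if a != b}


class TestPermutationNull:
    def test_strongly_coupled_pair_exceeds_null(self, small_binned,
                                                small_truth):
        pf = pg.fit_population(small_binned, small_truth.spec)
        stats = compute_coupling_stats(pf)
        null = permutation_null(small_binned, small_truth.spec, n_perm=6,
                                seed=21, warm=pf)
        nm = null.weights.weight.mean()
        ns = null.weights.weight.std(ddof=1)
        w01 = float(stats[(stats["from"] == "u00")
                          & (stats["to"] == "u01")].weight.iloc[0])
        assert w01 > nm + 2 * ns

    def test_null_has_same_pair_set(self, small_binned, small_truth):
        null = permutation_null(small_binned, small_truth.spec, n_perm=2,
                                seed=22)
        pairs = set(zip(null.weights["from"], null.weights["to"]))
        assert pairs == {(a, b) for a in small_truth.unit_ids
                         for b in small_truth.unit_ids if a != b}
        assert null.weights.perm.nunique() == 2

    def test_invalid_n_perm(self, small_binned, small_truth):
        with pytest.raises(ValueError):
            permutation_null(small_binned, small_truth.spec, n_perm=0)


class TestSignificantFraction:
    def _null(self, w):
        return NullDistribution(
            weights=pd.DataFrame({"perm": 0, "from": "a", "to": "b",
                                  "interaction": "SYNTH-SYNTH",
                                  "weight": w, "gain": 1.0}),
            n_perm=1, seed=0)

    def test_gaussian_tail_mass(self, rng):
        null = self._null(rng.normal(size=4000))
        stats = pd.DataFrame({"interaction": "SYNTH-SYNTH",
                              "weight": rng.normal(size=4000)})
        frac = significant_fraction(stats, null)
        assert abs(frac - 0.0228) < 0.012

    def test_all_huge_weights_give_one(self, rng):
        null = self._null(rng.normal(size=500))
        stats = pd.DataFrame({"interaction": "SYNTH-SYNTH",
                              "weight": np.full(50, 100.0)})
        assert significant_fraction(stats, null) == 1.0

    def test_degenerate_null_rejected(self):
        null = self._null(np.zeros(100))
        stats = pd.DataFrame({"interaction": "SYNTH-SYNTH",
                              "weight": [1.0]})
        with pytest.raises(ValueError):
            significant_fraction(stats, null)


class TestPCA:
    def test_rank_one_group(self, rng):
        base = np.sin(np.linspace(0, 3, 250))
        K = np.outer(rng.uniform(0.5, 2.0, 40), base)
        K += rng.normal(scale=1e-4, size=K.shape)
        p = pca_kernels(K)
        assert p.var_fraction[0] > 0.999

    def test_two_orthogonal_shapes_recovered(self, rng):
        t = np.linspace(0, 2 * np.pi, 250)
        s1, s2 = np.sin(t), np.cos(2 * t)
        K = (rng.normal(size=(60, 1)) * s1
             + rng.normal(size=(60, 1)) * s2)
        p = pca_kernels(K)
        assert p.var_fraction[:2].sum() > 0.999
        span = np.vstack([s1, s2])
        for comp in p.components[:2]:
            proj = span.T @ np.linalg.lstsq(span.T, comp, rcond=None)[0]
            np.testing.assert_allclose(proj, comp, atol=1e-6)

    def test_var_fractions_monotone_and_bounded(self, rng):
        K = rng.normal(size=(30, 100))
        p = pca_kernels(K)
        assert np.all(np.diff(p.var_fraction) <= 1e-12)
        assert p.var_fraction.sum() <= 1.0 + 1e-9

    def test_full_reconstruction_exact(self, rng):
        K = rng.normal(size=(12, 50))
        p = pca_kernels(K)
        np.testing.assert_allclose(p.reconstruct(), K, atol=1e-9)

    def test_sign_convention_positive_integral(self, rng):
        K = rng.normal(size=(30, 100)) + 0.3
        p = pca_kernels(K)
        assert p.components[0].sum() >= 0

    def test_too_few_kernels(self):
        with pytest.raises(ValueError):
            pca_kernels(np.zeros((2, 100)))


class TestTimeConstants:
    def test_single_exponential_recovery(self):
        t = np.arange(1, 251, dtype=float)
        tc = fit_time_constant(0.5 * np.exp(-t / 100.0))
        assert not tc.excluded
        assert abs(tc.tau - 100.0) / 100.0 < 0.05

    def test_refractory_kernel_excluded(self):
        k = np.zeros(250)
        k[:3] = -2.0
        tc = fit_time_constant(k)
        assert tc.excluded and "refractory" in tc.reason

    def test_double_exponential_mixture(self):
        t = np.arange(1, 251, dtype=float)
        k = 0.3 * np.exp(-t / 30.0) + 0.2 * np.exp(-t / 200.0)
        tc = fit_time_constant(k)
        assert not tc.excluded
        # reported tau follows the larger-amplitude component
        assert abs(tc.tau - 30.0) / 30.0 < 0.15
        taus = np.sort(tc.tau_pair)
        assert abs(taus[0] - 30.0) / 30.0 < 0.15
        assert abs(taus[1] - 200.0) / 200.0 < 0.15

    def test_noise_kernel_excluded_by_r2(self, rng):
        tc = fit_time_constant(rng.normal(scale=0.2, size=250))
        assert tc.excluded

    def test_short_support_rejected(self):
        with pytest.raises(ValueError):
            fit_time_constant(np.ones(50))


class TestPredictiveIndex:
    @pytest.mark.parametrize("full,red,expected", [
        (0.4, 0.4, 0.0), (0.4, 0.3, 0.25), (0.4, 0.6, 0.0),
        (0.4, -0.4, 1.0)])
    def test_identities_and_clipping(self, full, red, expected):
        assert predictive_index(full, red) == pytest.approx(expected)

    def test_tiny_denominator_flagged(self):
        assert np.isnan(predictive_index(0.0, 0.1))


class TestEpochs:
    def test_unequal_windows_rejected(self, small_binned, small_truth):
        with pytest.raises(ValueError, match="equal length"):
            fit_epoch_models(small_binned, small_truth.spec,
                             {"a": ("target_on", -0.2, 0.0),
                              "b": ("target_off", 0.0, 0.1)})

    def test_stationary_coupling_correlates_across_epochs(
            self, small_binned, small_truth):
        epochs = {"early": ("target_on", -0.05, 0.25),
                  "late": ("go_signal", -0.3, 0.0)}
        fits, weights, comp = fit_epoch_models(small_binned,
                                               small_truth.spec, epochs)
        assert set(fits) == {"early", "late"}
        assert (weights.epoch == "early").sum() == 6
        row = comp.iloc[0]
        assert row.n_pairs == 6
        # the generator's coupling is constant in time: the strongly
        # coupled pair should stand out (top 2 of 6) in both short epochs
        for name in ("early", "late"):
            w = weights[weights.epoch == name].set_index(["from", "to"])
            rank = (w["weight"].rank(ascending=False)
                    .loc[("u00", "u01")])
            assert rank <= 2


class TestTuning:
    def test_circular_gaussian_recovery(self, rng):
        angles = np.arange(0, 360, 45.0)
        truth = TuningFit(120.0, 40.0, 30.0, 5.0)
        resp = (truth.baseline + truth.amplitude
                * np.exp(-0.5 * (((angles - truth.preferred_angle + 180)
                                  % 360 - 180) / truth.width) ** 2))
        resp = resp + rng.normal(scale=0.5, size=len(resp))
        fit = fit_tuning_curve(angles, resp)
        assert fit.reliable
        d = abs((fit.preferred_angle - 120 + 180) % 360 - 180)
        assert d < 10.0

    def test_flat_response_flagged_unreliable(self):
        angles = np.arange(0, 360, 45.0)
        fit = fit_tuning_curve(angles, np.full(8, 12.0))
        assert not fit.reliable

    def test_too_few_angles(self):
        with pytest.raises(ValueError):
            fit_tuning_curve(np.array([0.0, 90.0, 180.0]), np.ones(3))

    def test_coupling_decreases_with_tuning_distance(self):
        # construct pairs whose weight falls off with preferred-angle gap
        units = [f"u{i}" for i in range(8)]
        prefs = np.arange(0, 360, 45.0)
        tunings = {u: TuningFit(p, 40.0, 20.0, 5.0)
                   for u, p in zip(units, prefs)}
        rows = []
        for a in units:
            for b in units:
                if a == b:
                    continue
                d = abs((tunings[a].preferred_angle
                         - tunings[b].preferred_angle + 180) % 360 - 180)
                rows.append({"from": a, "to": b,
                             "interaction": "SYNTH-SYNTH",
                             "weight": 2.0 * np.exp(-d / 60.0),
                             "gain": 1.0})
        rel = coupling_vs_tuning(pd.DataFrame(rows), tunings, n_bins=4)
        means = rel.sort_values("bin_center")["mean"].to_numpy()
        assert np.all(np.diff(means) < 0)
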