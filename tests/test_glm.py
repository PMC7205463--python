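import numpy as np
import pytest

import popglm as pg
from popglm.glm import (ModelSpec, SessionDesign, _fit_glm, build_design,
                        fit_neuron, make_folds, poisson_loglik,
                        predict_rate)
from popglm.spikedata import EventTimes, Session, TrialInfo, Unit


class TestPoissonLoglik:
    def test_zero_counts(self):
        lam = np.array([10.0, 20.0, 10.0])
        assert poisson_loglik(lam, np.zeros(3), 0.001) == pytest.approx(
            -0.001 * lam.sum())

    def test_hand_computed_case(self):
        # counts [0,1,0], dt=1ms, lam=[10,20,10] sp/s
        ll = poisson_loglik(np.array([10.0, 20.0, 10.0]),
                            np.array([0.0, 1.0, 0.0]), 0.001)
        assert ll == pytest.approx(np.log(0.02) - 0.04)

    def test_binwidth_scaling_identity(self, rng):
        lam = rng.uniform(5, 50, 20)
        y = rng.poisson(lam * 0.001).astype(float)
        pen1 = 0.001 * lam.sum()
        pen2 = 0.002 * (lam / 2).sum()
        assert pen1 == pytest.approx(pen2)
        # and the full expression shifts only through the log(dt lam) term
        d = (poisson_loglik(lam, y, 0.001)
             - poisson_loglik(lam / 2, y, 0.002))
        assert d == pytest.approx(0.0, abs=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            poisson_loglik(np.ones(2), np.array([1.0, -1.0]), 0.001)


class TestDesign:
    def test_column_budget_matches_model_structure(self, small_binned,
                                                   small_truth):
        # 8 params x 2 events x 2 conditions + 10 history + 10(n-1) coupling
        dm, y = build_design(small_binned, "u00", small_truth.spec)
        n = small_binned.n_units
        assert dm.X.shape[1] == 8 * 2 * 2 + 10 + 10 * (n - 1)
        assert y.shape[0] == dm.X.shape[0]

    def test_uncoupled_spec_has_no_coupling_columns(self, small_binned,
                                                    small_truth):
        dm, _ = build_design(small_binned, "u00",
                             small_truth.spec.without("coupling"))
        assert not any(k.startswith("coupling") for k in dm.column_map)

    def test_rows_never_mix_trials(self, small_binned, small_truth):
        dm, _ = build_design(small_binned, "u00", small_truth.spec)
        # bin index resets to 0 exactly at each trial boundary
        starts = np.flatnonzero(np.diff(dm.trial_index) != 0) + 1
        assert np.all(dm.bin_index[starts] == 0)

    def test_partner_spike_becomes_shifted_basis_block(self):
        spec = ModelSpec(include_terms=("coupling",))
        trials = [TrialInfo(events=EventTimes(0.01, 0.1, 0.3, 0.8, 0.85),
                            target_xy=[10, 0], condition="IN_RF",
                            duration=1.0)]
        spikes = [[np.array([0.5])], [np.array([0.0001])]]
        sess = Session(units=[Unit("a"), Unit("b")], trials=trials,
                       spikes=spikes)
        binned = pg.bin_spikes(sess)
        dm, _ = build_design(binned, "a", spec)
        basis = spec.hist_basis_set()
        block = dm.columns("coupling:b")
        np.testing.assert_allclose(block[1:1 + basis.n_lags],
                                   basis.B, atol=1e-12)
        assert np.all(block[0] == 0.0)  # strictly causal

    def test_trial_permutation_changes_only_partner_columns(
            self, small_binned, small_truth):
        spec = small_truth.spec
        sd = SessionDesign(small_binned, spec)
        n_valid = len(sd.valid_trials)
        perm = {1: np.roll(np.arange(n_valid), 3),
                2: np.roll(np.arange(n_valid), 7)}
        dm0, y0 = build_design(small_binned, "u00", spec, cache=sd)
        dm1, y1 = build_design(small_binned, "u00", spec, cache=sd,
                               perm=perm)
        np.testing.assert_array_equal(y0, y1)
        s_hist = dm0.column_map["history"]
        np.testing.assert_array_equal(dm0.X[:, s_hist], dm1.X[:, s_hist])
        ntask = 32
        np.testing.assert_array_equal(dm0.X[:, :ntask], dm1.X[:, :ntask])
        assert not np.array_equal(dm0.X, dm1.X)

    def test_identity_permutation_is_a_no_op(self, small_binned,
                                             small_truth):
        sd = SessionDesign(small_binned, small_truth.spec)
        ident = {i: np.arange(len(sd.valid_trials)) for i in range(3)}
        dm0, _ = build_design(small_binned, "u01", small_truth.spec,
                              cache=sd)
        dm1, _ = build_design(small_binned, "u01", small_truth.spec,
                              cache=sd, perm=ident)
        np.testing.assert_array_equal(dm0.X, dm1.X)


@pytest.fixture(scope="module")
def toy_problem():
    rng = np.random.default_rng(0)
    X = rng.normal(scale=0.4, size=(4000, 6))
    w_true = np.array([0.5, -0.3, 0.2, 0.0, 0.4, -0.2])
    eta = X @ w_true - 3.0
    y = rng.poisson(np.exp(eta)).astype(float)
    return X, y


class TestFitting:
    def test_matches_statsmodels_unpenalized(self, toy_problem):
        import statsmodels.api as sm
        X, y = toy_problem
        b, w, ll, _ = _fit_glm(X, y, ridge=0.0)
        res = sm.GLM(y, sm.add_constant(X),
                     family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(b, res.params[0], atol=1e-5)
        np.testing.assert_allclose(w, res.params[1:], atol=1e-5)

    def test_infinite_ridge_shrinks_to_mean_rate(self, toy_problem):
        X, y = toy_problem
        b, w, _, _ = _fit_glm(X, y, ridge=1e9)
        assert np.max(np.abs(w)) < 1e-3
        assert b == pytest.approx(np.log(y.mean()), abs=1e-3)

    def test_intercept_score_equation(self, toy_problem):
        # at the optimum, sum(dt * lambda-hat) equals the spike count
        X, y = toy_problem
        b, w, _, _ = _fit_glm(X, y, ridge=0.0)
        assert np.exp(X @ w + b).sum() == pytest.approx(y.sum(),
                                                        rel=1e-5)

    def test_objective_concavity_at_optimum(self, toy_problem, rng):
        X, y = toy_problem
        ridge = 2.0
        b, w, _, _ = _fit_glm(X, y, ridge=ridge)

        def pen_ll(bb, ww):
            eta = X @ ww + bb
            return y @ eta - np.exp(eta).sum() - ridge * ww @ ww

        best = pen_ll(b, w)
        for _ in range(20):
            db = rng.normal(scale=0.05)
            dw = rng.normal(scale=0.05, size=w.size)
            assert pen_ll(b + db, w + dw) <= best + 1e-9

    def test_fit_neuron_requires_spikes(self, small_binned, small_truth):
        dm, y = build_design(small_binned, "u00", small_truth.spec)
        with pytest.raises(ValueError, match="no spikes"):
            fit_neuron(dm, np.zeros_like(y), small_truth.spec)


class TestPredictRate:
    def test_zero_weights_constant_rate(self, small_binned, small_truth):
        spec = small_truth.spec
        dm, y = build_design(small_binned, "u00", spec)
        nf = pg.fit_neuron(dm, y, spec)
        nf.w = np.zeros_like(nf.w)
        lam = predict_rate(nf, dm)
        np.testing.assert_allclose(lam, np.exp(nf.b) / spec.bin_width)

    def test_hand_built_three_bin_case(self):
        from popglm.glm import DesignMatrix, NeuronFit
        X = np.array([[0.0], [1.0], [2.0]])
        dm = DesignMatrix(X=X, column_map={"history": slice(0, 1)},
                          trial_index=np.zeros(3, int),
                          bin_index=np.arange(3), bin_width=0.001,
                          target_unit="a")
        nf = NeuronFit(unit_id="a", b=-3.0, w=np.array([0.5]),
                       column_map=dm.column_map, spec=ModelSpec(),
                       train_ll=0.0)
        np.testing.assert_allclose(
            predict_rate(nf, dm),
            np.exp(-3.0 + 0.5 * np.array([0, 1, 2])) / 0.001)


class TestScores:
    def test_mean_rate_model_scores_zero_bits(self):
        assert pg.bits_per_spike(-12.3, -12.3, 100) == 0.0

    def test_no_spikes_flagged(self):
        assert np.isnan(pg.bits_per_spike(-1.0, -2.0, 0))

    def test_deviance_explained_limits(self, rng):
        y = rng.poisson(2.0, 200).astype(float)
        mu_null = np.full(200, y.mean())
        # model == null -> 0
        d0 = pg.deviance_explained(mu_null, y, y.mean())
        assert d0 == pytest.approx(0.0, abs=1e-12)
        # near-saturated prediction -> close to 1
        mu_sat = np.where(y > 0, y, 1e-9)
        d1 = pg.deviance_explained(mu_sat, y, y.mean())
        assert d1 == pytest.approx(1.0, abs=1e-6)

    def test_variance_explained_psth_identities(self, rng):
        obs = rng.uniform(0, 50, 100)
        assert pg.variance_explained_psth(obs, obs) == pytest.approx(1.0)
        assert pg.variance_explained_psth(
            np.full(100, obs.mean()), obs) == pytest.approx(0.0)
        pred = obs + rng.normal(0, 5, 100)
        r2 = pg.variance_explained_psth(pred, obs)
        sse = np.sum((obs - pred) ** 2)
        sst = np.sum((obs - obs.mean()) ** 2)
        assert r2 == pytest.approx(1 - sse / sst)


class TestCrossval:
    def test_folds_partition_trials(self):
        folds = make_folds(100, 5, seed=1)
        assert folds.shape == (100,)
        counts = np.bincount(folds)
        assert counts.tolist() == [20] * 5

    def test_folds_deterministic_given_seed(self):
        np.testing.assert_array_equal(make_folds(37, 5, seed=9),
                                      make_folds(37, 5, seed=9))
        assert not np.array_equal(make_folds(37, 5, seed=9),
                                  make_folds(37, 5, seed=10))

    def test_too_few_trials_raises(self):
        with pytest.raises(ValueError):
            make_folds(3, 5, seed=0)

    def test_crossval_fit_scores_present(self, small_binned, small_truth):
        pf = pg.crossval_fit(small_binned, small_truth.spec, k_folds=3,
                             seed=2)
        for nf in pf.fits:
            assert len(nf.fold_scores) == 3
            assert np.isfinite(pg.heldout_bits_per_spike(nf))


class TestSimulation:
    def test_baseline_only_population_is_poisson(self):
        spec = ModelSpec(include_terms=())
        truth = pg.make_ground_truth_population(2, seed=3, spec=spec,
                                                coupling_pairs=None)
        trials = pg.generate_compact_trials(60, seed=4)
        sess = pg.simulate_population(truth, trials, seed=5)
        for i, uid in enumerate(truth.unit_ids):
            rate = np.exp(truth.fit_for(uid).b) / spec.bin_width
            n = sum(len(s) for s in sess.spikes[i])
            expect = rate * 60 * 1.0
            assert abs(n - expect) < 3 * np.sqrt(expect)

    def test_directional_coupling_gives_asymmetric_correlogram(self):
        spec = ModelSpec(include_terms=("history", "coupling"))
        truth = pg.make_ground_truth_population(
            2, seed=6, spec=spec, coupling_pairs=[(0, 1)],
            coupling_amp=1.2, coupling_sign_prob=1.0,
            coupling_tau_range_ms=(10.0, 20.0),
            pos_coupling_budget_ms=20.0)
        trials = pg.generate_compact_trials(150, seed=7)
        sess = pg.simulate_population(truth, trials, seed=8)
        fwd = bwd = 0
        for ti in range(len(trials)):
            a = sess.spikes[0][ti]
            b = sess.spikes[1][ti]
            for t in a:
                fwd += int(np.sum((b > t) & (b <= t + 0.05)))
                bwd += int(np.sum((b < t) & (b >= t - 0.05)))
        assert fwd > 1.2 * bwd

    def test_deterministic_given_seed(self, small_truth):
        trials = pg.generate_compact_trials(5, seed=9)
        s1 = pg.simulate_population(small_truth, trials, seed=10)
        s2 = pg.simulate_population(small_truth, trials, seed=10)
        for a, b in zip(s1.spikes, s2.spikes):
            for x, y in zip(a, b):
                np.testing.assert_array_equal(x, y)

    def test_runaway_rate_aborts(self):
        spec = ModelSpec(include_terms=("history",))
        truth = pg.make_ground_truth_population(1, seed=11, spec=spec,
                                                coupling_pairs=None)
        nf = truth.fits[0]
        nf.w = nf.w * 0 + 3.0  # pathological self-excitation
        trials = pg.generate_compact_trials(5, seed=12)
        with pytest.raises(RuntimeError, match="runaway"):
            pg.simulate_population(truth, trials, seed=13)


class TestGroundTruthGenerator:
    def test_zero_coupling_gives_zero_kernels(self):
        truth = pg.make_ground_truth_population(4, seed=14,
                                                coupling_pairs=None)
        for uid in truth.unit_ids:
            nf = truth.fit_for(uid)
            for name in nf.column_map:
                if name.startswith("coupling:"):
                    assert np.allclose(nf.kernel(name), 0.0)

    def test_area_amplitude_asymmetry_orders_mean_weights(self):
        areas = ["LIP"] * 3 + ["FEF"] * 3
        truth = pg.make_ground_truth_population(
            6, seed=15, areas=areas, coupling_pairs="all",
            coupling_amp={("LIP", "LIP"): 0.3, ("FEF", "FEF"): 0.1},
            coupling_sign_prob=1.0, pos_coupling_budget_ms=100.0)
        sums = {"LIP-LIP": [], "FEF-FEF": []}
        for i, uid in enumerate(truth.unit_ids):
            nf = truth.fit_for(uid)
            for name in nf.column_map:
                if not name.startswith("coupling:"):
                    continue
                j = truth.unit_ids.index(name.split(":")[1])
                key = f"{areas[j]}-{areas[i]}"
                if key in sums:
                    sums[key].append(nf.kernel(name).sum())
        assert np.mean(sums["LIP-LIP"]) > np.mean(sums["FEF-FEF"])

    def test_refractory_history_creates_isi_trough(self, small_truth,
                                                   small_session):
        isis = np.concatenate([np.diff(st) for st in
                               small_session.spikes[0] if len(st) > 1])
        frac_short = np.mean(isis < 0.003)
        assert frac_short < 0.02


def test_cross_trial_leakage_absent(small_binned, small_truth):
    """Rows of the design depend only on within-trial data: reordering
    whole trials permutes row blocks without changing their content."""
    spec = small_truth.spec
    dm, y = build_design(small_binned, "u00", spec)
    sess = small_binned.session
    order = np.roll(np.arange(sess.n_trials), 5)
    reordered = sess.subset_trials(order)
    dm2, y2 = build_design(pg.bin_spikes(reordered), "u00", spec)
    for new_pos, old_trial in enumerate(order):
        a = dm.X[dm.trial_index == old_trial]
        b = dm2.X[dm2.trial_index == new_pos]
        np.testing.assert_allclose(a, b, atol=1e-12)
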