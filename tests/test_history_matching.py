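"""History-matching components: sampling, implausibility, emulators, waves.

The wave machinery is exercised on the analytic toy simulator with reduced
cloud sizes; full-scale settings only change array sizes, not code paths.
"""

import numpy as np
import pytest

import cardiopop.history_matching as hm
from cardiopop.fixtures_and_toy import make_toy_simulator

TOY = make_toy_simulator()
CRITERIA = hm.load_criteria()
APD90 = next(c for c in CRITERIA if c.biomarker == "APD90")


class TestCriteria:
    def test_packaged_defaults_split(self):
        modes = {c.biomarker: c.mode for c in CRITERIA}
        assert modes["APD90"] == "implausibility"
        assert modes["RMP"] == "minmax"
        assert modes["CTD80"] == "minmax"
        assert len(CRITERIA) == 10

    def test_recalibration_stage(self):
        rc = hm.load_criteria(stage="recalibration")
        assert {c.biomarker for c in rc} == {"FTTP", "FTTr", "FTD"}

    def test_invalid_modes_rejected(self):
        with pytest.raises(ValueError):
            hm.CalibrationCriterion("x", "implausibility", mean=1.0, sd=0.0)
        with pytest.raises(ValueError):
            hm.CalibrationCriterion("x", "minmax", min=2.0, max=1.0)

    def test_csv_roundtrip(self, tmp_path):
        import pandas as pd

        with hm.resources.files("cardiopop").joinpath(
                "data/calibration_criteria.csv").open() as fh:
            df = pd.read_csv(fh)
        p = tmp_path / "crit.csv"
        df.to_csv(p, index=False)
        again = hm.load_criteria(p)
        assert [c.biomarker for c in again] == [c.biomarker for c in CRITERIA]


class TestLHS:
    def test_stratification_4x2(self):
        pts = hm.lhs_sample(4, bounds=[[0, 2], [0, 2]], seed=0)
        for col in pts.T:
            strata = np.floor(col / 0.5).astype(int)
            assert sorted(strata) == [0, 1, 2, 3]

    def test_seed_reproducible(self):
        a = hm.lhs_sample(50, seed=3)
        b = hm.lhs_sample(50, seed=3)
        assert np.array_equal(a, b)

    def test_full_design_shape_and_bounds(self):
        pts = hm.lhs_sample(300, seed=1)
        assert pts.shape == (300, 11)
        assert pts.min() >= 0.0 and pts.max() <= 2.0


class TestImplausibility:
    """Hand-evaluated cases of the implausibility measure for the APD90
    criterion (mean 311 ms, sd 49 ms) with zero predictive variance."""

    @pytest.mark.parametrize("pred,expected", [(311.0, 0.0), (360.0, 1.0), (458.0, 3.0)])
    def test_hand_cases(self, pred, expected):
        assert hm.implausibility(pred, 0.0, APD90) == pytest.approx(expected)

    def test_variance_inflates_denominator(self):
        assert hm.implausibility(360.0, 49.0 ** 2, APD90) == pytest.approx(1 / np.sqrt(2))

    def test_degenerate_criterion_raises(self):
        c = hm.CalibrationCriterion("x", "implausibility", mean=1.0, sd=1.0)
        object.__setattr__(c, "sd", 0.0)
        with pytest.raises(ValueError):
            hm.implausibility(1.0, 0.0, c)


class _ExactEmulator:
    """Noise-free stand-in with zero predictive variance (oracle emulator)."""

    def __init__(self, name):
        self.name = name

    def predict(self, X):
        vals = TOY(np.asarray(X))[self.name]
        return np.asarray(vals), np.zeros(len(X))


class TestFilterPoints:
    def test_center_point_kept(self):
        emus = {c.biomarker: _ExactEmulator(c.biomarker) for c in CRITERIA}
        kept, mask = hm.filter_points(np.ones((1, 11)), emus, CRITERIA)
        assert mask[0]

    def test_strict_threshold_boundary(self):
        class Fixed:
            def __init__(self, val):
                self.val = val

            def predict(self, X):
                return np.full(len(X), self.val), np.zeros(len(X))

        emus = {c.biomarker: _ExactEmulator(c.biomarker) for c in CRITERIA}
        # APD90 at exactly 3 sigma is retained, just above is removed
        emus["APD90"] = Fixed(311.0 + 3 * 49.0)
        _, mask = hm.filter_points(np.ones((1, 11)), emus, CRITERIA)
        assert mask[0]
        emus["APD90"] = Fixed(311.0 + 3.01 * 49.0)
        _, mask = hm.filter_points(np.ones((1, 11)), emus, CRITERIA)
        assert not mask[0]

    def test_oracle_filter_matches_truth(self):
        # with exact emulators the filter equals the brute-force ground truth
        # restricted to the implausibility/minmax split
        X = np.random.default_rng(0).uniform(0, 2, (2000, 11))
        emus = {c.biomarker: _ExactEmulator(c.biomarker) for c in CRITERIA}
        _, mask = hm.filter_points(X, emus, CRITERIA)
        truth = TOY.true_plausible_mask(X)
        # toy truth band and criteria band coincide for centered criteria
        agree = (mask == truth).mean()
        assert agree > 0.98


class TestAugment:
    def test_target_not_above_current_returns_input(self):
        pts = np.random.default_rng(0).uniform(0, 2, (20, 11))
        out = hm.augment_points(pts, 10, seed=1)
        assert out is pts

    def test_outputs_within_bounds(self):
        pts = np.full((3, 11), 1.95)  # near the upper bound forces redraws
        out = hm.augment_points(pts, 500, seed=2)
        assert out.shape == (500, 11)
        assert out.min() >= 0.0 and out.max() <= 2.0

    def test_empirical_covariance_near_005I(self):
        center = np.full((1, 11), 1.0)
        out = hm.augment_points(center, 100_001, seed=3)[1:]
        cov = np.cov(out.T)
        diag = np.diag(cov)
        off = cov - np.diag(diag)
        assert np.all(np.abs(diag - 0.05) < 0.005)
        assert np.all(np.abs(off) < 0.005)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            hm.augment_points(np.empty((0, 11)), 10)


class TestEmulators:
    def test_loo_r2_above_095_on_toy(self):
        X = hm.lhs_sample(200, seed=5)
        Y = TOY(X)
        for name in ("APD90", "CTmax"):
            em = hm.EmulatorModel(name, seed=0).fit(X, Y[name])
            r2 = 1.0 - em.loo_rmse ** 2 / np.var(Y[name])
            assert r2 > 0.95, f"{name}: LOO R^2 {r2:.3f}"

    def test_training_point_within_3_sigma(self):
        X = hm.lhs_sample(60, seed=6)
        y = TOY(X)["APD90"]
        em = hm.EmulatorModel("APD90", seed=0).fit(X, y)
        mean, var = em.predict(X)
        noise = np.exp(em.gp.kernel_.k2.theta[0])
        assert np.all(np.abs(mean - y) <= 3.0 * np.sqrt(var + noise) + 1e-6)

    def test_refit_deterministic(self):
        X = hm.lhs_sample(60, seed=7)
        y = TOY(X)["APD90"]
        a = hm.EmulatorModel("APD90", seed=1).fit(X, y)
        b = hm.EmulatorModel("APD90", seed=1).fit(X, y)
        Xq = hm.lhs_sample(20, seed=8)
        assert np.array_equal(a.predict(Xq)[0], b.predict(Xq)[0])

    def test_window_selects_recent_waves(self):
        X = hm.lhs_sample(30, seed=9)
        ydict = {"APD90": TOY(X)["APD90"]}
        training = {w: (X, ydict) for w in range(1, 7)}
        emus = hm.train_emulators(training, current_wave=6, window=4,
                                  biomarkers=["APD90"])
        assert emus["APD90"].training_waves == (3, 4, 5, 6)

    def test_too_few_points_raises(self):
        X = hm.lhs_sample(5, seed=10)
        training = {1: (X, {"APD90": TOY(X)["APD90"]})}
        with pytest.raises(ValueError):
            hm.train_emulators(training, 1, biomarkers=["APD90"])


class TestConvergence:
    def _state(self, wave, surviving):
        return hm.WaveState(wave=wave, training_set={}, cloud=np.empty((0, 11)),
                            counts={"cloud_surviving": surviving})

    def test_tenth_percent_rule(self):
        hist = [self._state(1, 100000), self._state(2, 99999)]
        assert hm.has_converged(hist)

    def test_large_drop_not_converged(self):
        hist = [self._state(1, 100000), self._state(2, 90000)]
        assert not hm.has_converged(hist)

    def test_wave_cap(self):
        hist = [self._state(60, 5)]
        assert hm.has_converged(hist, wave_cap=60)


@pytest.fixture(scope="module")
def toy_history():
    cfg = hm.HMConfig(n_simulators_per_wave=100, candidate_cloud_size=10000,
                      augment_floor=3000, wave_cap=3, seed=11)
    return hm.run_history_matching(TOY, CRITERIA, cfg), cfg


class TestWaves:
    def test_counts_bookkeeping(self, toy_history):
        hist, _ = toy_history
        for st in hist:
            c = st.counts
            assert 0 <= c["cloud_surviving"] <= c["cloud_in"]
            assert 0.0 <= c["acceptance_rate"] <= 1.0
            assert c["simulators_accepted"] <= c["simulators_run"]

    def test_acceptance_rate_rises(self, toy_history):
        hist, _ = toy_history
        assert hist[-1].counts["acceptance_rate"] > hist[0].counts["acceptance_rate"]

    def test_seeded_rerun_bit_identical(self, toy_history):
        hist, cfg = toy_history
        again = hm.run_history_matching(TOY, CRITERIA, cfg)
        assert np.array_equal(hist[-1].cloud, again[-1].cloud)
        assert hist[-1].counts == again[-1].counts

    def test_checkpoint_roundtrip(self, toy_history, tmp_path):
        hist, _ = toy_history
        st = hist[-1]
        st.save(tmp_path)
        back = hm.WaveState.load(tmp_path, st.wave)
        assert np.array_equal(back.cloud, st.cloud)
        assert back.counts == st.counts
        assert back.kernel_thetas.keys() == st.kernel_thetas.keys()

    def test_empty_state_continuation_rejected(self):
        st = hm.WaveState(wave=1, training_set={}, cloud=np.empty((0, 11)),
                          status="empty_nroy")
        with pytest.raises(ValueError):
            hm.run_wave(st, TOY, CRITERIA)


class TestFinalize:
    def test_zero_draw_empty(self, toy_history):
        hist, _ = toy_history
        recs, rate = hm.finalize_initial_population(hist[-1].cloud, 0, TOY,
                                                    CRITERIA, seed=0)
        assert recs == []

    def test_accepted_records_inside_minmax(self, toy_history):
        hist, _ = toy_history
        recs, rate = hm.finalize_initial_population(hist[-1].cloud, 100, TOY,
                                                    CRITERIA, seed=1)
        assert len(recs) == 100
        for rec in recs:
            if rec.accepted:
                assert hm.within_minmax(rec.biomarkers["reference"], CRITERIA)
        assert rate == pytest.approx(
            sum(r.accepted for r in recs) / len(recs))
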