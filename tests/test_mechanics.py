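import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plectolab import mechanics as mech
from plectolab import synthdata as sd
from plectolab.constants import RISE_NM_PER_BP, kbt
from plectolab.datatypes import ForceExtensionCurve

from conftest import assert_rel


class TestWLCForce:
    def test_zero_extension_zero_force(self):
        assert mech.wlc_force(0.0, 1000, 50) == 0.0

    def test_half_extension_hand_value(self):
        # F = 1.25 kBT/P at x/Lc = 0.5
        f = mech.wlc_force(500.0, 1000.0, 50.0, 298.0)
        assert_rel(f, 1.25 * kbt(298.0) / 50.0, 1e-12)
        assert abs(f - 0.103) < 0.001

    def test_monotone_increasing(self):
        x = np.linspace(0, 0.97 * 1000, 300)
        f = mech.wlc_force(x, 1000, 50)
        assert np.all(np.diff(f) > 0)

    def test_domain_error_beyond_contour(self):
        with pytest.raises(ValueError):
            mech.wlc_force(1000.0, 1000.0, 50.0)


class TestWLCFit:
    def test_noiseless_recovery_to_4_significant_figures(self):
        curve, _ = sd.gen_wlc_curve(5300, 52, n_points=200, rel_noise=0.0)
        fit = mech.fit_wlc(curve)
        assert_rel(fit.contour_length_nm, 5300, 1e-4)
        assert_rel(fit.persistence_length_nm, 52, 1e-4)

    def test_stretch_and_release_halves_fit_identically(self):
        stretch, _ = sd.gen_wlc_curve(5300, 52, n_points=100)
        release = ForceExtensionCurve(stretch.extension_nm[::-1],
                                      stretch.force_pN[::-1],
                                      direction="release")
        fa = mech.fit_wlc(stretch)
        fb = mech.fit_wlc(release)
        assert_rel(fa.contour_length_nm, fb.contour_length_nm, 1e-9)
        assert_rel(fa.persistence_length_nm, fb.persistence_length_nm, 1e-9)

    def test_fit_is_scale_equivariant(self):
        # lengths in units of 10 nm with forces rescaled to match the
        # fixed kB*T: both fitted lengths shrink by the same factor
        scale = 10.0
        curve, _ = sd.gen_wlc_curve(5300, 52, n_points=100,
                                    rel_noise=0.02, seed=5)
        fit_nm = mech.fit_wlc(curve)
        scaled = ForceExtensionCurve(curve.extension_nm / scale,
                                     curve.force_pN * scale,
                                     temperature_K=curve.temperature_K)
        fit_s = mech.fit_wlc(scaled)
        assert_rel(fit_s.contour_length_nm * scale,
                   fit_nm.contour_length_nm, 1e-4)
        assert_rel(fit_s.persistence_length_nm * scale,
                   fit_nm.persistence_length_nm, 1e-4)

    def test_too_few_points_rejected(self):
        curve, _ = sd.gen_wlc_curve(5300, 52, n_points=15)
        with pytest.raises(ValueError):
            mech.fit_wlc(curve)


class TestBootstrap:
    def test_noiseless_bootstrap_sd_near_zero(self):
        curve, _ = sd.gen_wlc_curve(5300, 52, n_points=1000)
        bs = mech.bootstrap_wlc(curve, n_boot=50, frac=0.01, seed=0)
        assert bs["sd_Lc_percent"] < 0.01
        assert bs["sd_P_percent"] < 0.01

    def test_bootstrap_sd_monotone_in_noise(self):
        sds = []
        for noise in (0.01, 0.02, 0.05):
            curve, _ = sd.gen_wlc_curve(5300, 52, n_points=1000,
                                        rel_noise=noise, seed=4)
            bs = mech.bootstrap_wlc(curve, n_boot=100, frac=0.01, seed=0)
            sds.append(bs["sd_P_percent"])
        assert sds[0] < sds[1] < sds[2]

    def test_fixed_seed_reproducible(self):
        curve, _ = sd.gen_wlc_curve(5300, 52, n_points=1000,
                                    rel_noise=0.05, seed=4)
        a = mech.bootstrap_wlc(curve, n_boot=50, seed=9)
        b = mech.bootstrap_wlc(curve, n_boot=50, seed=9)
        assert a["sd_Lc_nm"] == b["sd_Lc_nm"]

    def test_replicates_too_small_rejected(self):
        curve, _ = sd.gen_wlc_curve(5300, 52, n_points=100)
        with pytest.raises(ValueError):
            mech.bootstrap_wlc(curve, frac=0.01)


class TestSupercoilDensityAndTorque:
    @pytest.mark.parametrize("turns,expect", [(200, 0.14), (150, 0.11),
                                              (0, 0.0)])
    def test_sigma_on_active_region(self, turns, expect):
        assert round(mech.supercoil_density(turns, 14600), 2) == expect

    @given(turns=st.floats(-500, 500))
    @settings(max_examples=50, deadline=None)
    def test_sigma_antisymmetric(self, turns):
        assert (mech.supercoil_density(turns, 14600)
                == -mech.supercoil_density(-turns, 14600))

    def test_torque_per_turn_printed_value(self):
        tau = mech.torque_per_turn(14600 * RISE_NM_PER_BP, 410.0)
        assert round(tau, 2) == 0.08

    def test_torque_unit_ratio(self):
        assert mech.torque_per_turn(410.0, 410.0) == 1.0

    def test_cumulative_torque_linear(self):
        L = 14600 * RISE_NM_PER_BP
        assert_rel(mech.cumulative_torque(10, 410.0, L),
                   10 * mech.torque_per_turn(L, 410.0), 1e-12)


class TestDriftCorrection:
    def test_linear_drift_removed(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 100, 2000)
        noise = 3.0 * rng.standard_normal(t.size)
        pos = 15.0 * t + noise
        res = mech.drift_correct(t, pos, anchor_times=[0, 50, 100])
        assert np.std(res["corrected"]) < 2 * 3.0
        assert_rel(np.mean(res["velocities_nm_per_s"]), 15.0, 0.05)

    def test_zero_drift_identity(self):
        t = np.linspace(0, 10, 100)
        pos = np.full_like(t, 7.0)
        res = mech.drift_correct(t, pos, anchor_times=[0, 5, 10])
        np.testing.assert_allclose(res["corrected"], pos)

    def test_quadratic_drift_flagged(self):
        t = np.linspace(0, 100, 1000)
        pos = 0.05 * t ** 2
        with pytest.warns(UserWarning, match="linear"):
            res = mech.drift_correct(t, pos, anchor_times=[0, 50, 100])
        assert res["nonlinear_flag"]
        assert res["nonlinearity_nm"] > 50.0

    def test_single_anchor_rejected(self):
        with pytest.raises(ValueError):
            mech.drift_correct([0, 1], [0, 1], anchor_times=[0])


class TestHatCurveAssembly:
    def test_subcritical_classified_symmetric(self):
        hat, _ = sd.gen_hat_curve(0.5, noise_sd_nm=5.0, seed=6)
        built = mech.build_hat_curve(hat.turns, hat.extension_nm,
                                     hat.time_s, hat.segment, 0.5,
                                     Lc_nm=5300.0)
        res = mech.classify_hat_symmetry(built)
        assert res["label"] == "symmetric"
        assert built.fractional_extension.max() < 1.1

    def test_supracritical_negative_plateau(self):
        hat, _ = sd.gen_hat_curve(1.1, noise_sd_nm=5.0, seed=6)
        built = mech.build_hat_curve(hat.turns, hat.extension_nm,
                                     hat.time_s, hat.segment, 1.1)
        assert mech.classify_hat_symmetry(built)["label"] == "asymmetric"

    def test_assembly_idempotent(self):
        hat, _ = sd.gen_hat_curve(0.5, noise_sd_nm=5.0, seed=7)
        drift = 15.0 * hat.time_s
        b1 = mech.build_hat_curve(hat.turns, hat.extension_nm + drift,
                                  hat.time_s, hat.segment, 0.5)
        b2 = mech.build_hat_curve(b1.turns, b1.extension_nm, b1.time_s,
                                  b1.segment, 0.5)
        np.testing.assert_allclose(b2.extension_nm, b1.extension_nm,
                                   atol=1e-9)

    def test_single_sign_warns(self):
        n = 60
        with pytest.warns(UserWarning, match="one rotation sign"):
            mech.build_hat_curve(np.arange(n, dtype=float),
                                 np.full(n, 4000.0),
                                 np.arange(n, dtype=float),
                                 np.zeros(n, int), 0.5)


class TestHatSymmetryScore:
    @staticmethod
    def _hat(ext_pos, ext_neg, turns=None):
        turns = np.arange(1, 101, dtype=float) if turns is None else turns
        all_turns = np.concatenate([[0.0], turns, -turns])
        ext0 = 0.5 * (ext_pos[0] + ext_neg[0])
        ext = np.concatenate([[ext0], ext_pos, ext_neg])
        from plectolab.datatypes import HatCurve
        return HatCurve(all_turns, ext, np.zeros_like(all_turns, dtype=int),
                        np.arange(all_turns.size, dtype=float), 1.0)

    def test_mirror_symmetric_scores_zero(self):
        turns = np.arange(1, 101, dtype=float)
        drop = 4600 - 10 * turns
        hat = self._hat(drop, drop)
        assert mech.classify_hat_symmetry(hat)["score"] < 1e-9

    def test_flat_negative_linear_positive_scores_one(self):
        turns = np.arange(1, 101, dtype=float)
        hat = self._hat(4600 - 10 * turns, np.full(100, 4600.0))
        assert mech.classify_hat_symmetry(hat)["score"] > 0.95

    def test_score_monotone_in_plateau_height(self):
        turns = np.arange(1, 101, dtype=float)
        scores = []
        for plateau_frac in (0.0, 0.3, 0.6, 1.0):
            neg = 4600 - 10 * turns * (1 - plateau_frac)
            hat = self._hat(4600 - 10 * turns, neg)
            scores.append(mech.classify_hat_symmetry(hat)["score"])
        assert np.all(np.diff(scores) > 0)

    def test_score_invariant_to_offset_and_order(self):
        hat, _ = sd.gen_hat_curve(1.1, noise_sd_nm=2.0, seed=8)
        s1 = mech.classify_hat_symmetry(hat)["score"]
        rng = np.random.default_rng(0)
        perm = rng.permutation(hat.turns.size)
        from plectolab.datatypes import HatCurve
        shuffled = HatCurve(hat.turns[perm], hat.extension_nm[perm] + 500.0,
                            hat.segment[perm], hat.time_s[perm], 1.1)
        s2 = mech.classify_hat_symmetry(shuffled)["score"]
        assert abs(s1 - s2) < 1e-9


class TestBucklingDetection:
    def test_knee_located_within_5_turns(self):
        turns = np.arange(0, 200, dtype=float)
        rng = np.random.default_rng(3)
        ext = 4600 - np.maximum(0, turns - 120) * 18 \
            + 5.0 * rng.standard_normal(200)
        res = mech.detect_buckling(turns, ext, window=20)
        assert res is not None
        assert abs(res["buckling_turn"] - 120) <= 5

    def test_constant_slope_returns_none(self):
        turns = np.arange(0, 200, dtype=float)
        rng = np.random.default_rng(4)
        ext = 4600 - 2.0 * turns + 0.5 * rng.standard_normal(200)
        assert mech.detect_buckling(turns, ext) is None

    def test_doubled_post_knee_noise_doubles_fluctuation_ratio(self):
        turns = np.arange(0, 300, dtype=float)
        rng = np.random.default_rng(5)
        noise = np.where(turns >= 150, 10.0, 5.0)
        ext = 4600 - np.maximum(0, turns - 150) * 18 \
            + noise * rng.standard_normal(300)
        res = mech.detect_buckling(turns, ext, window=60)
        assert res is not None
        assert 1.5 < res["fluctuation_ratio"] < 2.6
        assert res["buckled"]
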