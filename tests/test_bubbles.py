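import numpy as np
import pytest

from plectolab import bubbles as bub
from plectolab import synthdata as sd
from plectolab.bubbles import FormatError
from plectolab.datatypes import BasePairTrajectory

from conftest import assert_rel


@pytest.fixture(scope="module")
def baseline():
    traj, _ = sd.gen_bp_param_trajectory(30, 500, dt_ns=0.1, seed=1)
    return bub.relaxed_baseline(traj)


def bubble_oracle(traj, baseline, min_len=3, z=2.0, min_dur=1.0):
    """Naive reference caller: per-frame string scan for disrupted
    runs, then explicit event merging by bp overlap."""
    nf, nb = traj.hbond.shape
    disrupted = ~traj.hbond.copy()
    for p in BasePairTrajectory.PARAMS:
        mu, sd_ = baseline[p]["mean"], baseline[p]["sd"]
        disrupted &= np.abs(getattr(traj, p) - mu) >= z * sd_
    per_frame = []
    for i in range(nf):
        runs, j = [], 0
        while j < nb:
            if disrupted[i, j]:
                k = j
                while k < nb and disrupted[i, k]:
                    k += 1
                if k - j >= min_len:
                    runs.append((j, k))
                j = k
            else:
                j += 1
        per_frame.append(runs)
    events, open_ev = [], []
    for i in range(nf):
        still = []
        taken = set()
        for ev in open_ev:
            hit = None
            for ri, (r0, r1) in enumerate(per_frame[i]):
                if ri in taken:
                    continue
                if r0 < ev["b1"] and ev["b0"] < r1:
                    hit = ri
                    break
            if hit is None:
                events.append(ev)
            else:
                r0, r1 = per_frame[i][hit]
                taken.add(hit)
                ev["b0"], ev["b1"] = min(ev["b0"], r0), max(ev["b1"], r1)
                ev["f1"] = i
                still.append(ev)
        for ri, (r0, r1) in enumerate(per_frame[i]):
            if ri not in taken:
                still.append({"b0": r0, "b1": r1, "f0": i, "f1": i})
        open_ev = still
    events.extend(open_ev)
    out = []
    for ev in events:
        dur = (ev["f1"] - ev["f0"] + 1) * traj.dt_ns
        if dur > min_dur:
            out.append((ev["b0"] + 1, ev["b1"] - ev["b0"],
                        ev["f0"] * traj.dt_ns, dur))
    return sorted(out)


class TestReadWrite:
    def test_round_trip(self, tmp_path):
        traj, _ = sd.gen_bp_param_trajectory(8, 150, dt_ns=0.2, seed=5)
        path = tmp_path / "traj.tsv"
        bub.write_bp_params(traj, path)
        back = bub.read_bp_params(path, dt_ns=0.2)
        np.testing.assert_array_equal(back.hbond, traj.hbond)
        np.testing.assert_allclose(back.propeller, traj.propeller)

    def test_missing_frame_named_in_error(self, tmp_path):
        traj, _ = sd.gen_bp_param_trajectory(4, 120, seed=6)
        path = tmp_path / "traj.tsv"
        bub.write_bp_params(traj, path)
        lines = path.read_text().splitlines()
        # drop one bp record of frame 7
        del lines[1 + 6 * 4 + 2]
        path.write_text("\n".join(lines))
        with pytest.raises(FormatError, match="frame 7"):
            bub.read_bp_params(path)

    def test_nastruct_style_whitespace_table(self, tmp_path):
        path = tmp_path / "nas.dat"
        rows = ["#Frame  BP  Propeller  Opening  Buckle  HB"]
        for fr in (1, 2):
            for bp in (1, 2, 3):
                rows.append(f"{fr}  {bp}  -11.2  1.5  0.3  2")
        path.write_text("\n".join(rows) + "\n")
        traj = bub.read_bp_params(path, dt_ns=0.5)
        assert traj.hbond.shape == (2, 3)
        assert traj.hbond.all()
        assert traj.duration_ns == 1.0

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("frame\tbp\tpropeller\n1\t1\t0.0\n")
        with pytest.raises(FormatError, match="missing"):
            bub.read_bp_params(path)


class TestRelaxedBaseline:
    def test_constant_trajectory_zero_sd(self):
        n = (200, 10)
        traj = BasePairTrajectory(hbond=np.ones(n, bool),
                                  propeller=np.full(n, -11.0),
                                  opening=np.full(n, 2.0),
                                  buckle=np.zeros(n), dt_ns=0.1)
        base = bub.relaxed_baseline(traj)
        assert base["propeller"]["sd"] == 0.0
        assert base["propeller"]["mean"] == -11.0

    def test_gaussian_baseline_recovered_within_2_percent(self):
        traj, _ = sd.gen_bp_param_trajectory(
            40, 3000, baseline_means={"propeller": -12.0, "opening": 2.0,
                                      "buckle": 0.0},
            baseline_sds={"propeller": 8.0, "opening": 4.0, "buckle": 6.0},
            seed=7)
        base = bub.relaxed_baseline(traj)
        assert_rel(base["propeller"]["mean"], -12.0, 0.02)
        assert_rel(base["propeller"]["sd"], 8.0, 0.02)

    def test_terminal_bp_excluded(self):
        traj, _ = sd.gen_bp_param_trajectory(10, 200, seed=8)
        base0 = bub.relaxed_baseline(traj)
        traj.propeller[:, 0] += 1000.0   # perturb terminal bp
        base1 = bub.relaxed_baseline(traj)
        assert base0["propeller"]["mean"] == base1["propeller"]["mean"]

    def test_too_few_frames_rejected(self):
        traj, _ = sd.gen_bp_param_trajectory(10, 150, seed=9)
        short = BasePairTrajectory(hbond=traj.hbond[:50],
                                   propeller=traj.propeller[:50],
                                   opening=traj.opening[:50],
                                   buckle=traj.buckle[:50], dt_ns=0.1)
        with pytest.raises(ValueError):
            bub.relaxed_baseline(short)


class TestDetectBubbles:
    def test_planted_bubble_called_once_with_bounds(self, baseline):
        traj, _ = sd.gen_bp_param_trajectory(
            30, 500, dt_ns=0.1, planted_bubbles=[(10, 4, 20.0, 2.0)],
            seed=2)
        calls = bub.detect_bubbles(traj, baseline)
        assert len(calls) == 1
        c = calls[0]
        assert abs(c.start_bp - 10) <= 1
        assert abs(c.length_bp - 4) <= 1
        assert abs(c.t_start_ns - 20.0) <= 0.1
        assert abs(c.duration_ns - 2.0) <= 0.1

    @pytest.mark.parametrize("bubble", [(10, 2, 20.0, 2.0),
                                        (10, 5, 20.0, 0.5)])
    def test_sub_threshold_disruptions_ignored(self, baseline, bubble):
        traj, _ = sd.gen_bp_param_trajectory(30, 500, dt_ns=0.1,
                                             planted_bubbles=[bubble],
                                             seed=3)
        assert bub.detect_bubbles(traj, baseline) == []

    def test_matches_run_scan_oracle_on_random_grids(self, baseline):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            bubbles = []
            # up to two random non-overlapping planted bubbles
            for start, length in ((int(rng.integers(1, 8)),
                                   int(rng.integers(3, 6))),
                                  (int(rng.integers(12, 16)),
                                   int(rng.integers(3, 5)))):
                t0 = float(rng.integers(0, 60)) * 0.1
                dur = float(rng.integers(11, 40)) * 0.1
                bubbles.append((start, length, t0, dur))
            traj, _ = sd.gen_bp_param_trajectory(
                20, 100, dt_ns=0.1, planted_bubbles=bubbles, seed=seed)
            got = sorted((c.start_bp, c.length_bp, c.t_start_ns,
                          c.duration_ns)
                         for c in bub.detect_bubbles(traj, baseline))
            assert got == bubble_oracle(traj, baseline)

    def test_bad_thresholds_rejected(self, baseline):
        traj, _ = sd.gen_bp_param_trajectory(10, 120, seed=4)
        with pytest.raises(ValueError):
            bub.detect_bubbles(traj, baseline, z_thresh=0.0)


class TestPrevalence:
    @staticmethod
    def _traj_with_bubble(frac):
        nf = 400
        planted = [(5, 4, 0.0, frac * nf * 0.1)] if frac else []
        traj, _ = sd.gen_bp_param_trajectory(20, nf, dt_ns=0.1,
                                             planted_bubbles=planted,
                                             seed=11)
        return traj

    def test_full_window_bubble_is_100_percent(self, baseline):
        traj = self._traj_with_bubble(1.0)
        calls = bub.detect_bubbles(traj, baseline)
        assert bub.bubble_prevalence(traj, calls, 40.0) == 100.0

    def test_no_calls_is_zero(self, baseline):
        traj = self._traj_with_bubble(0.0)
        assert bub.bubble_prevalence(traj, [], 40.0) == 0.0

    def test_half_window_bubble_is_50_percent(self, baseline):
        traj = self._traj_with_bubble(0.5)
        calls = bub.detect_bubbles(traj, baseline)
        assert abs(bub.bubble_prevalence(traj, calls, 40.0) - 50.0) <= 1.0

    def test_window_longer_than_trajectory_rejected(self, baseline):
        traj = self._traj_with_bubble(0.0)
        with pytest.raises(ValueError):
            bub.bubble_prevalence(traj, [], 1000.0)


class TestPrevalenceBootstrap:
    def test_constant_indicator_zero_sd(self):
        assert bub.prevalence_bootstrap(np.ones(5000), seed=0) == 0.0

    def test_matches_binomial_standard_error(self):
        rng = np.random.default_rng(5)
        ind = rng.random(100_000) < 0.5
        sd = bub.prevalence_bootstrap(ind, n_boot=400, frac=0.01, seed=1)
        expect = 100.0 * np.sqrt(0.25 / 1000)
        assert_rel(sd, expect, 0.20)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(6)
        ind = rng.random(2000) < 0.3
        assert (bub.prevalence_bootstrap(ind, seed=3)
                == bub.prevalence_bootstrap(ind, seed=3))

    def test_sd_shrinks_as_fraction_grows(self):
        rng = np.random.default_rng(7)
        ind = rng.random(10_000) < 0.4
        small = bub.prevalence_bootstrap(ind, frac=0.01, seed=0)
        large = bub.prevalence_bootstrap(ind, frac=0.5, seed=0)
        assert large < small

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            bub.prevalence_bootstrap(np.ones(100), frac=0.01)


class TestConvergence:
    def test_constant_series_converges(self):
        assert bub.convergence_curve(np.full(200, 3.3))["converged"]

    def test_linear_ramp_does_not(self):
        assert not bub.convergence_curve(np.linspace(0, 1, 500))["converged"]

    def test_ou_series_converges_after_20_correlation_times(self):
        rng = np.random.default_rng(0)
        tau, n = 50, 20_000    # n = 400 tau
        a = np.exp(-1.0 / tau)
        x = np.empty(n)
        x[0] = 0.0
        noise = rng.standard_normal(n) * np.sqrt(1 - a * a)
        for i in range(1, n):
            x[i] = a * x[i - 1] + noise[i]
        assert bub.convergence_curve(5.0 + x)["converged"]
        assert not bub.convergence_curve(5.0 + x[:5 * tau])["converged"]
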