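"""Synthetic-data generators for every pipeline stage.

Each generator draws from the statistical model its downstream
estimator assumes — Lorentzian trapped-bead noise via an exact
Ornstein-Uhlenbeck update, a driven overdamped rotor with phase lag,
Marko-Siggia force-extension with multiplicative noise, hat-curve
shapes on either side of the critical force, diffusing Gaussian puncta
on a rendered tether, and base-pair-parameter grids with planted
denaturation bubbles — and returns its parameter set as a GroundTruth
record so recovery tests are self-describing.  Identical seed and
parameters give bit-identical output.
"""

from __future__ import annotations

import math

import numpy as np

from .constants import (DEFAULT_TEMPERATURE_K, DEFAULT_VISCOSITY_PA_S,
                        drag_rotational, drag_translational, kbt)
from .datatypes import (BasePairTrajectory, ForceExtensionCurve, GroundTruth,
                        HatCurve, QPDTrace)
from .mechanics import wlc_force

__all__ = [
    "gen_wlc_curve", "gen_trapped_bead_trace", "gen_driven_rotation_trace",
    "gen_hat_curve", "gen_tether_movie", "gen_bp_param_trajectory",
    "gen_brownian_track", "simulate_force_clamp", "AliasingError",
]


class AliasingError(ValueError):
    """Sampling rate too low relative to the trap corner frequency."""


def gen_wlc_curve(Lc_nm: float, P_nm: float, n_points: int = 500,
                  temperature_K: float = DEFAULT_TEMPERATURE_K,
                  rel_noise: float = 0.0, seed: int | None = None,
                  x_min_frac: float = 0.1, x_max_frac: float = 0.95,
                  ) -> tuple[ForceExtensionCurve, GroundTruth]:
    """Marko-Siggia force-extension samples with multiplicative
    Gaussian force noise of s.d. `rel_noise`."""
    if Lc_nm <= 0 or P_nm <= 0 or P_nm >= Lc_nm:
        raise ValueError("require 0 < P < Lc")
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    if not (0 < x_min_frac < x_max_frac <= 0.97):
        raise ValueError("extension fractions must lie in (0, 0.97]")
    x = np.linspace(x_min_frac * Lc_nm, x_max_frac * Lc_nm, n_points)
    f = np.asarray(wlc_force(x, Lc_nm, P_nm, temperature_K))
    if rel_noise > 0:
        rng = np.random.default_rng(seed)
        f = f * (1.0 + rel_noise * rng.standard_normal(n_points))
    curve = ForceExtensionCurve(x, f, temperature_K=temperature_K)
    gt = GroundTruth("gen_wlc_curve", {
        "contour_length_nm": Lc_nm, "persistence_length_nm": P_nm,
        "temperature_K": temperature_K, "rel_noise": rel_noise,
        "seed": seed, "n_points": n_points})
    return curve, gt


def gen_trapped_bead_trace(k_trap_pN_per_um: float,
                           bead_radius_um: float = 1.5,
                           viscosity_Pa_s: float = DEFAULT_VISCOSITY_PA_S,
                           temperature_K: float = DEFAULT_TEMPERATURE_K,
                           fs_hz: float = 50_000.0, duration_s: float = 1.0,
                           seed: int | None = None,
                           ) -> tuple[QPDTrace, GroundTruth]:
    """Overdamped Langevin position of a trapped bead.

    Exact discrete Ornstein-Uhlenbeck update (exponential decay with
    matched stationary variance), so the one-sided power spectrum is
    asymptotically Lorentzian with corner frequency fc = k/(2*pi*gamma)
    and variance kB*T/k at any time step.
    """
    if k_trap_pN_per_um <= 0:
        raise ValueError("trap stiffness must be positive")
    k = k_trap_pN_per_um / 1000.0          # pN/nm
    gamma = drag_translational(bead_radius_um, viscosity_Pa_s)
    fc = k / (2.0 * math.pi * gamma)
    if fs_hz <= 2.0 * fc:
        raise AliasingError(
            f"fs = {fs_hz:.0f} Hz must exceed twice fc = {fc:.1f} Hz")
    n = int(round(duration_s * fs_hz))
    if n < 2 ** 14:
        raise ValueError("need duration*fs >= 2^14 samples")
    dt = 1.0 / fs_hz
    var = kbt(temperature_K) / k           # nm^2
    a = math.exp(-k * dt / gamma)
    s = math.sqrt(var * (1.0 - a * a))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n)
    noise[0] *= math.sqrt(var) / s     # stationary start
    from scipy.signal import lfilter
    x = lfilter([s], [1.0, -a], noise)
    trace = QPDTrace(fs_hz, x, units="nm")
    gt = GroundTruth("gen_trapped_bead_trace", {
        "k_trap_pN_per_um": k_trap_pN_per_um,
        "bead_radius_um": bead_radius_um,
        "viscosity_Pa_s": viscosity_Pa_s,
        "temperature_K": temperature_K,
        "corner_frequency_hz": fc,
        "drag_pN_s_per_nm": gamma,
        "fs_hz": fs_hz, "seed": seed})
    return trace, gt


def gen_driven_rotation_trace(k_theta_pNnm_per_rad: float,
                              bead_radius_um: float = 1.5,
                              viscosity_Pa_s: float = DEFAULT_VISCOSITY_PA_S,
                              drive_freqs_hz=(1, 2, 4, 8),
                              fs_hz: float = 1000.0,
                              duration_s: float = 30.0,
                              drive_torque_pNnm: float = 500.0,
                              noise_sd_rad: float = 0.0,
                              seed: int | None = None,
                              ) -> tuple[QPDTrace, GroundTruth]:
    """Angular response of an overdamped driven rotor.

    For drive torque tau0*cos(2*pi*f*t) the steady-state response is a
    sinusoid lagging the drive by phi with tan(phi) = 2*pi*f*gamma_th /
    k_theta, gamma_th = 8*pi*eta*R^3, so the small-angle phase-vs-
    frequency slope is 2*pi*gamma_th/k_theta.  The drive channel stores
    the summed unit-amplitude drive waveform.
    """
    if k_theta_pNnm_per_rad <= 0:
        raise ValueError("angular stiffness must be positive")
    freqs = np.atleast_1d(np.asarray(drive_freqs_hz, dtype=float))
    if np.any(freqs <= 0.5) or np.any(freqs > 10.0):
        raise ValueError("drive frequencies must lie in (0.5, 10] Hz")
    gamma = drag_rotational(bead_radius_um, viscosity_Pa_s)
    t = np.arange(int(round(duration_s * fs_hz))) / fs_hz
    resp = np.zeros_like(t)
    drive = np.zeros_like(t)
    phases = {}
    for f in freqs:
        w = 2.0 * math.pi * f
        phi = math.atan2(w * gamma, k_theta_pNnm_per_rad)
        amp = drive_torque_pNnm / math.hypot(k_theta_pNnm_per_rad, w * gamma)
        resp += amp * np.cos(w * t - phi)
        drive += np.cos(w * t)
        phases[float(f)] = phi
    if noise_sd_rad > 0:
        rng = np.random.default_rng(seed)
        resp = resp + noise_sd_rad * rng.standard_normal(t.size)
    trace = QPDTrace(fs_hz, resp, drive=drive, units="rad")
    gt = GroundTruth("gen_driven_rotation_trace", {
        "k_theta_pNnm_per_rad": k_theta_pNnm_per_rad,
        "bead_radius_um": bead_radius_um,
        "viscosity_Pa_s": viscosity_Pa_s,
        "drag_rot_pNnm_s": gamma,
        "phase_rad_per_freq": phases,
        "phase_slope_rad_per_hz": 2.0 * math.pi * gamma
                                  / k_theta_pNnm_per_rad,
        "seed": seed})
    return trace, gt


def gen_hat_curve(force_pN: float, Fc_pN: float = 0.65,
                  n_turns_max: int = 200,
                  slope_nm_per_turn: float = 18.0,
                  plateau_extension_nm: float = 4600.0,
                  buckling_turns: int = 30,
                  noise_sd_nm: float = 20.0,
                  samples_per_turn: int = 1,
                  active_bp: int = 14600,
                  seed: int | None = None,
                  ) -> tuple[HatCurve, GroundTruth]:
    """Extension-vs-turns hat curve on either side of the critical
    force.

    Below Fc the curve is symmetric: past the buckling turn count the
    extension falls linearly for both twist signs.  At or above Fc the
    negative side stays on a constant-extension plateau (undertwist is
    absorbed by melting, not plectonemes) while the positive side still
    buckles.  Two time-ordered segments (positive sweep then negative
    sweep) are emitted so drift correction has anchor epochs.
    """
    if n_turns_max < 50:
        raise ValueError("n_turns_max must be >= 50")
    rng = np.random.default_rng(seed)
    n_pts = n_turns_max * samples_per_turn + 1
    up = np.linspace(0, n_turns_max, n_pts)
    turns = np.concatenate([up, -up])
    segment = np.concatenate([np.zeros(n_pts, int), np.ones(n_pts, int)])
    time_s = np.arange(turns.size, dtype=float)

    def ext(n_turns):
        drop = slope_nm_per_turn * np.maximum(
            0.0, np.abs(n_turns) - buckling_turns)
        flat = np.full_like(np.asarray(n_turns, float),
                            plateau_extension_nm)
        below = plateau_extension_nm - drop
        if force_pN >= Fc_pN:
            return np.where(np.asarray(n_turns) < 0, flat, below)
        return below

    extension = ext(turns) + noise_sd_nm * rng.standard_normal(turns.size)
    hat = HatCurve(turns=turns, extension_nm=extension, segment=segment,
                   time_s=time_s, clamp_force_pN=force_pN,
                   active_bp=active_bp)
    gt = GroundTruth("gen_hat_curve", {
        "force_pN": force_pN, "Fc_pN": Fc_pN,
        "slope_nm_per_turn": slope_nm_per_turn,
        "plateau_extension_nm": plateau_extension_nm,
        "buckling_turns": buckling_turns, "noise_sd_nm": noise_sd_nm,
        "symmetric": force_pN < Fc_pN, "seed": seed})
    return hat, gt


def _render_frame(shape, pixel_size_nm, p0, p1, line_photons,
                  puncta_pos_nm, puncta_photons, psf_sigma_nm,
                  oversample: int = 3):
    """Render one noiseless frame: a uniform-intensity line tether plus
    Gaussian puncta.  Image origin top-left, x right, y down, pixel
    centres at integer coordinates; all positions in nm."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.zeros(shape, dtype=float)
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    length = np.linalg.norm(p1 - p0)
    n_seg = max(2, int(oversample * length / pixel_size_nm))
    ts = np.linspace(0.0, 1.0, n_seg)
    pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    s_px = psf_sigma_nm / pixel_size_nm
    norm = 1.0 / (2.0 * math.pi * s_px ** 2)
    per_pt = line_photons / n_seg
    for px, py in pts / pixel_size_nm:
        img += per_pt * norm * np.exp(
            -((xx - px) ** 2 + (yy - py) ** 2) / (2.0 * s_px ** 2))
    for pos, photons in zip(puncta_pos_nm, puncta_photons):
        px, py = np.asarray(pos) / pixel_size_nm
        img += photons * norm * np.exp(
            -((xx - px) ** 2 + (yy - py) ** 2) / (2.0 * s_px ** 2))
    return img


def gen_tether_movie(n_frames: int = 41, frame_interval_s: float = 0.04,
                     pixel_size_nm: float = 55.0,
                     shape: tuple[int, int] = (48, 64),
                     tether_endpoints=((440.0, 1320.0), (3080.0, 1320.0)),
                     puncta=((0.4, 1900.0),),
                     puncta_start_frac=None,
                     psf_sigma_nm: float = 120.0,
                     tether_photons: float = 40_000.0,
                     background: float = 100.0,
                     read_noise_sd: float = 2.0,
                     seed: int | None = None,
                     ) -> tuple[np.ndarray, GroundTruth]:
    """Fluorescence image stack of a tether with diffusing puncta.

    Each punctum is a 2-D Gaussian carrying its bp_fraction of the
    total tether-integrated photon budget and diffusing along the
    tether axis with its own D (reflective at the ends); the remaining
    photons are spread uniformly along the tether line.  Pixel noise is
    Poisson shot noise plus Gaussian read noise; output is uint16.

    puncta: sequence of (bp_fraction, D_nm2_per_s).
    puncta_start_frac: optional start positions (fraction along the
    tether) — default equally spaced interior points.
    """
    h, w = shape
    p0 = np.asarray(tether_endpoints[0], float)
    p1 = np.asarray(tether_endpoints[1], float)
    for p in (p0, p1):
        if not (0 <= p[0] <= (w - 1) * pixel_size_nm
                and 0 <= p[1] <= (h - 1) * pixel_size_nm):
            raise ValueError("tether endpoints must lie inside the field")
    fracs = np.array([p[0] for p in puncta], float)
    Ds = np.array([p[1] for p in puncta], float)
    if fracs.sum() >= 1.0:
        raise ValueError("puncta bp fractions must sum to < 1")
    if np.any(fracs < 0):
        raise ValueError("bp fractions must be non-negative")
    L = float(np.linalg.norm(p1 - p0))
    axis = (p1 - p0) / L
    if puncta_start_frac is None:
        puncta_start_frac = [(i + 1) / (len(puncta) + 1)
                             for i in range(len(puncta))]
    s = np.asarray(puncta_start_frac, float) * L
    rng = np.random.default_rng(seed)
    stack = np.empty((n_frames, h, w), dtype=np.uint16)
    truth_pos = np.empty((n_frames, len(puncta), 2))
    line_photons = tether_photons * (1.0 - fracs.sum())
    for i in range(n_frames):
        pos_nm = p0[None, :] + s[:, None] * axis[None, :]
        truth_pos[i] = pos_nm
        img = _render_frame((h, w), pixel_size_nm, p0, p1, line_photons,
                            pos_nm, tether_photons * fracs, psf_sigma_nm)
        img += background
        noisy = rng.poisson(img).astype(float)
        noisy += read_noise_sd * rng.standard_normal(img.shape)
        stack[i] = np.clip(noisy, 0, 65535).astype(np.uint16)
        # advance 1-D diffusion along the axis, reflective at [0, L]
        step = np.sqrt(2.0 * Ds * frame_interval_s)
        s = s + step * rng.standard_normal(len(puncta))
        s = np.abs(s)
        s = np.where(s > L, 2 * L - s, s)
        s = np.clip(s, 0.0, L)
    gt = GroundTruth("gen_tether_movie", {
        "pixel_size_nm": pixel_size_nm,
        "tether_endpoints": [p0.tolist(), p1.tolist()],
        "bp_fractions": fracs.tolist(),
        "D_nm2_per_s": Ds.tolist(),
        "psf_sigma_nm": psf_sigma_nm,
        "frame_interval_s": frame_interval_s,
        "background": background,
        "positions_nm": truth_pos,
        "seed": seed})
    return stack, gt


def gen_brownian_track(D_nm2_per_s: float, frame_interval_s: float = 0.04,
                       n_frames: int = 41, loc_noise_nm: float = 0.0,
                       seed: int | None = None) -> np.ndarray:
    """Pure 2-D Brownian trajectory (n_frames, 2) in nm with optional
    Gaussian localisation noise — the null model behind the MSD
    regression estimator."""
    rng = np.random.default_rng(seed)
    step = math.sqrt(2.0 * D_nm2_per_s * frame_interval_s)
    pos = np.cumsum(step * rng.standard_normal((n_frames, 2)), axis=0)
    if loc_noise_nm > 0:
        pos = pos + loc_noise_nm * rng.standard_normal(pos.shape)
    return pos


def gen_bp_param_trajectory(n_bp: int, n_frames: int, dt_ns: float = 0.1,
                            baseline_means=None, baseline_sds=None,
                            planted_bubbles=(), displacement_sd: float = 4.0,
                            seed: int | None = None,
                            ) -> tuple[BasePairTrajectory, GroundTruth]:
    """Base-pair-parameter grid with planted denaturation bubbles.

    Background cells draw propeller/opening/buckle from their baseline
    Gaussians with the WC H-bond flag set.  Cells inside a planted
    bubble lose the H-bond flag and have all three parameters displaced
    by `displacement_sd` baseline s.d. (default 4, comfortably past the
    2 s.d. calling threshold).

    planted_bubbles: iterable of (start_bp, length_bp, t_start_ns,
    duration_ns), 1-based start; overlapping bubbles are rejected.
    """
    means = dict(baseline_means or
                 {"propeller": -12.0, "opening": 2.0, "buckle": 0.0})
    sds = dict(baseline_sds or
               {"propeller": 8.0, "opening": 4.0, "buckle": 6.0})
    rng = np.random.default_rng(seed)
    grids = {p: means[p] + sds[p] * rng.standard_normal((n_frames, n_bp))
             for p in BasePairTrajectory.PARAMS}
    hbond = np.ones((n_frames, n_bp), dtype=bool)
    occupied = np.zeros((n_frames, n_bp), dtype=bool)
    for (start_bp, length_bp, t_start_ns, duration_ns) in planted_bubbles:
        f0 = int(round(t_start_ns / dt_ns))
        f1 = int(round((t_start_ns + duration_ns) / dt_ns))
        b0, b1 = start_bp - 1, start_bp - 1 + length_bp
        if not (0 <= b0 < b1 <= n_bp and 0 <= f0 < f1 <= n_frames):
            raise ValueError("planted bubble outside grid bounds")
        if occupied[f0:f1, b0:b1].any():
            raise ValueError("planted bubbles overlap")
        occupied[f0:f1, b0:b1] = True
        hbond[f0:f1, b0:b1] = False
        for p in BasePairTrajectory.PARAMS:
            grids[p][f0:f1, b0:b1] = (
                means[p] + displacement_sd * sds[p]
                + 0.1 * sds[p] * rng.standard_normal((f1 - f0, b1 - b0)))
    traj = BasePairTrajectory(hbond=hbond, dt_ns=dt_ns, **grids)
    gt = GroundTruth("gen_bp_param_trajectory", {
        "n_bp": n_bp, "n_frames": n_frames, "dt_ns": dt_ns,
        "baseline_means": means, "baseline_sds": sds,
        "planted_bubbles": [list(b) for b in planted_bubbles],
        "displacement_sd": displacement_sd, "seed": seed})
    return traj, gt


def simulate_force_clamp(set_force_pN: float,
                         trap_stiffness_pN_per_um: float = 10.0,
                         kp: float = 0.016, ki: float = 0.008,
                         kd: float = 0.0,
                         update_hz: float = 100.0,
                         duration_s: float = 10.0,
                         disturbance=None,
                         noise_sd_pN: float = 0.0,
                         seed: int | None = None) -> dict:
    """Discrete force-clamp feedback loop (simulation only).

    At every update the stage moves by the control output times
    (force error / trap stiffness) — the proportional term implements
    "reposition by (set - measured)/stiffness" — plus integral and
    derivative terms.  The measured force responds instantaneously to
    stage position (stiff-plant approximation): F = k*(x_stage) +
    disturbance(t) + noise.  Diverging loops raise with a diagnostic.

    disturbance: None, or callable t -> pN offset.
    Returns time, stage position (um), measured force (pN), and the
    settling time into the +/-0.1 pN band after the last disturbance
    onset.
    """
    if trap_stiffness_pN_per_um <= 0:
        raise ValueError("stiffness must be positive")
    k = trap_stiffness_pN_per_um
    dt = 1.0 / update_hz
    n = int(round(duration_s * update_hz))
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt
    x = set_force_pN / k          # start at setpoint
    integ = 0.0
    prev_err = 0.0
    stage = np.empty(n)
    force = np.empty(n)
    for i in range(n):
        d = disturbance(t[i]) if disturbance is not None else 0.0
        noise = noise_sd_pN * rng.standard_normal() if noise_sd_pN else 0.0
        f_meas = k * x + d + noise
        force[i] = f_meas
        stage[i] = x
        err = set_force_pN - f_meas
        integ += err * dt
        deriv = (err - prev_err) / dt
        prev_err = err
        x = x + (kp * err + ki * integ + kd * deriv) / k
        if abs(x) > 1e6 or not np.isfinite(x):
            raise RuntimeError(
                f"force clamp diverged at t={t[i]:.2f}s "
                f"(gains kp={kp}, ki={ki}, kd={kd} unstable)")
    # settling time: last excursion outside +/-0.1 pN
    out = np.abs(force - set_force_pN) > 0.1
    settle = float(t[np.max(np.flatnonzero(out))] if out.any() else 0.0)
    return {"time_s": t, "stage_um": stage, "force_pN": force,
            "settling_time_s": settle}
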