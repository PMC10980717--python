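"""DNA mechanics: worm-like-chain fitting with bootstrap errors,
supercoiling density, torque, hat-curve assembly with drift correction
and buckling detection.

The elasticity model is the inextensible Marko-Siggia interpolation

    F(x) = (kB*T / P) * [ 1 / (4 (1 - x/Lc)^2) - 1/4 + x/Lc ]

with contour length Lc and persistence length P.  Forces in this
instrument stay below ~10 pN, well inside the entropic regime, so no
enthalpic stretch-modulus term is included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .constants import (HELICAL_REPEAT_BP, RISE_NM_PER_BP, kbt)
from .datatypes import ForceExtensionCurve, HatCurve

__all__ = [
    "WLCFit", "TorsionState", "wlc_force", "fit_wlc", "bootstrap_wlc",
    "supercoil_density", "torque_per_turn", "cumulative_torque",
    "drift_correct", "build_hat_curve", "classify_hat_symmetry",
    "detect_buckling", "FitError",
]


class FitError(RuntimeError):
    """Raised when a least-squares fit fails; carries residuals."""

    def __init__(self, msg, residuals=None):
        super().__init__(msg)
        self.residuals = residuals


@dataclass
class WLCFit:
    contour_length_nm: float
    persistence_length_nm: float
    bootstrap_sd_Lc: float = 0.0
    bootstrap_sd_P: float = 0.0
    n_half_cycles: int = 1

    def __post_init__(self):
        if not (0 < self.persistence_length_nm < self.contour_length_nm):
            raise ValueError("require 0 < P < Lc")


@dataclass
class TorsionState:
    """Torsional bookkeeping for one supercoiling state."""

    turns: float
    active_bp: int
    helical_repeat: float = HELICAL_REPEAT_BP
    torsional_modulus_C_pNnm: float = 410.0
    rise_nm_per_bp: float = RISE_NM_PER_BP

    @property
    def sigma(self) -> float:
        return supercoil_density(self.turns, self.active_bp,
                                 self.helical_repeat)

    @property
    def length_nm(self) -> float:
        return self.active_bp * self.rise_nm_per_bp

    @property
    def torque_pNnm(self) -> float:
        return cumulative_torque(self.turns,
                                 self.torsional_modulus_C_pNnm,
                                 self.length_nm)


def wlc_force(x_nm, Lc_nm: float, P_nm: float,
              temperature_K: float = 310.0):
    """Marko-Siggia interpolation force (pN) at extension x (nm).

    Valid on 0 <= x < Lc; raises for x >= Lc.
    """
    if Lc_nm <= 0 or P_nm <= 0:
        raise ValueError("Lc and P must be positive")
    x = np.asarray(x_nm, dtype=float)
    if np.any(x < 0) or np.any(x >= Lc_nm):
        raise ValueError("extension must satisfy 0 <= x < Lc")
    z = x / Lc_nm
    f = (kbt(temperature_K) / P_nm) * (0.25 / (1.0 - z) ** 2 - 0.25 + z)
    return f if f.ndim else float(f)


def _fit_one(x: np.ndarray, f: np.ndarray, T: float) -> tuple[float, float]:
    xmax = float(x.max())

    def model(xx, Lc, P):
        z = np.clip(xx / Lc, 0.0, 0.999)
        return (kbt(T) / P) * (0.25 / (1.0 - z) ** 2 - 0.25 + z)

    p0 = (max(xmax / 0.9, xmax * 1.01 + 1.0), 50.0)
    try:
        popt, _ = optimize.curve_fit(
            model, x, f, p0=p0,
            bounds=([xmax * 1.0001, 0.1], [np.inf, np.inf]),
            maxfev=20000)
    except (RuntimeError, ValueError) as e:
        raise FitError(f"WLC fit did not converge: {e}",
                       residuals=f - model(x, *p0)) from e
    return float(popt[0]), float(popt[1])


def fit_wlc(curve: ForceExtensionCurve | list[ForceExtensionCurve]) -> WLCFit:
    """Least-squares (Lc, P) fit of one or more half cycles.

    When several half cycles are supplied each is fitted separately and
    the parameter estimates averaged.
    """
    curves = curve if isinstance(curve, (list, tuple)) else [curve]
    fits = []
    for c in curves:
        x, f = c.extension_nm, c.force_pN
        if x.size < 20:
            raise ValueError("need >= 20 points for a WLC fit")
        if (x.max() - x.min()) < 0.5 * x.max():
            raise ValueError("extensions must span >= 50% of their range")
        fits.append(_fit_one(x, f, c.temperature_K))
    Lc = float(np.mean([p[0] for p in fits]))
    P = float(np.mean([p[1] for p in fits]))
    return WLCFit(Lc, P, n_half_cycles=len(fits))


def bootstrap_wlc(curve: ForceExtensionCurve, n_boot: int = 1000,
                  frac: float = 0.01, seed: int | None = None) -> dict:
    """Bootstrap s.d. of the WLC parameters.

    Each replicate refits a random `frac` subsample of the data; the
    spread of the replicate estimates is reported absolutely and as a
    percentage of the full-data point estimate.
    """
    n = len(curve)
    m = int(round(frac * n))
    if m < 5:
        raise ValueError("frac*n_points must be >= 5")
    rng = np.random.default_rng(seed)
    point = fit_wlc(curve)
    Ls, Ps = [], []
    for _ in range(n_boot):
        idx = rng.choice(n, size=m, replace=False)
        idx.sort()
        x, f = curve.extension_nm[idx], curve.force_pN[idx]
        try:
            Lc, P = _fit_one(x, f, curve.temperature_K)
        except FitError:
            continue
        Ls.append(Lc)
        Ps.append(P)
    if len(Ls) < max(10, n_boot // 10):
        raise FitError("too few bootstrap replicates converged")
    sd_Lc, sd_P = float(np.std(Ls)), float(np.std(Ps))
    return {
        "sd_Lc_nm": sd_Lc,
        "sd_P_nm": sd_P,
        "sd_Lc_percent": 100.0 * sd_Lc / point.contour_length_nm,
        "sd_P_percent": 100.0 * sd_P / point.persistence_length_nm,
        "n_replicates": len(Ls),
        "point_estimate": point,
    }


def supercoil_density(turns: float, active_bp: int,
                      helical_repeat: float = HELICAL_REPEAT_BP) -> float:
    """Supercoiling density sigma = turns / (active_bp / helical_repeat).

    Applied bead rotations divided by the number of helical turns in
    the relaxed (torsionally active) region; sign preserved.
    """
    if active_bp <= 0:
        raise ValueError("active_bp must be positive")
    return turns * helical_repeat / active_bp


def torque_per_turn(L_nm: float, C_pNnm: float = 410.0) -> float:
    """Torque added per complete bead rotation, tau = C / L (pN*nm)."""
    if L_nm <= 0:
        raise ValueError("length must be positive")
    return C_pNnm / L_nm


def cumulative_torque(turns: float, C_pNnm: float = 410.0,
                      L_nm: float = 14600 * RISE_NM_PER_BP) -> float:
    """Cumulative torque after `turns` rotations: turns * C / L."""
    return turns * torque_per_turn(L_nm, C_pNnm)


def drift_correct(time_s, positions, anchor_times,
                  nonlinearity_tol_nm: float = 50.0) -> dict:
    """Piecewise-linear drift correction against anchor epochs.

    Anchors are time points at which the system revisits a common
    reference state (e.g. sigma = 0 between hat-curve segments), so any
    position difference between them is drift.  Drift is interpolated
    linearly between anchors and subtracted; before the first and after
    the last anchor the adjacent segment velocity is extrapolated.

    positions may be (n,) or (n, n_axes).  Returns corrected positions,
    per-segment velocities (nm/s per axis) and a nonlinearity flag: if
    the anchor displacements deviate from a single global linear trend
    by more than `nonlinearity_tol_nm`, the drift is not well modelled
    as piecewise linear between these anchors.
    """
    t = np.asarray(time_s, dtype=float)
    pos = np.asarray(positions, dtype=float)
    squeeze = pos.ndim == 1
    if squeeze:
        pos = pos[:, None]
    ta = np.sort(np.asarray(anchor_times, dtype=float))
    if ta.size < 2:
        raise ValueError("need >= 2 anchor epochs to estimate drift")
    # anchor positions by interpolation of the raw series
    pa = np.column_stack([np.interp(ta, t, pos[:, j])
                          for j in range(pos.shape[1])])
    disp = pa - pa[0]
    drift = np.column_stack([np.interp(t, ta, disp[:, j])
                             for j in range(pos.shape[1])])
    # extrapolate outside anchor span with edge-segment velocity
    v_seg = np.diff(disp, axis=0) / np.diff(ta)[:, None]
    before, after = t < ta[0], t > ta[-1]
    drift[before] = disp[0] + (t[before, None] - ta[0]) * v_seg[0]
    drift[after] = disp[-1] + (t[after, None] - ta[-1]) * v_seg[-1]
    corrected = pos - drift
    # nonlinearity: residual of anchors about one global linear trend
    resid = []
    for j in range(pos.shape[1]):
        coef = np.polyfit(ta, disp[:, j], 1)
        resid.append(np.max(np.abs(disp[:, j] - np.polyval(coef, ta))))
    nonlin = float(np.max(resid))
    flagged = nonlin > nonlinearity_tol_nm
    if flagged:
        warnings.warn("anchor displacements deviate from linear drift by "
                      f"{nonlin:.1f} nm; piecewise model may under-fit",
                      stacklevel=2)
    return {
        "corrected": corrected[:, 0] if squeeze else corrected,
        "velocities_nm_per_s": v_seg[:, 0] if squeeze else v_seg,
        "nonlinearity_nm": nonlin,
        "nonlinear_flag": flagged,
    }


def build_hat_curve(turns, extension_nm, time_s, segment, clamp_force_pN,
                    Lc_nm: float | None = None, active_bp: int = 14600,
                    helical_repeat: float = HELICAL_REPEAT_BP) -> HatCurve:
    """Assemble a drift-corrected, segment-labelled hat curve.

    Drift anchors are the samples nearest zero turns within each
    segment: every segment revisits the torsionally relaxed state, so
    extension there is a common reference.  If only one anchor exists
    (single segment) the data are returned uncorrected.  Running the
    assembly on already-corrected data is idempotent because the anchor
    displacements are then zero.
    """
    turns = np.asarray(turns, dtype=float)
    ext = np.asarray(extension_nm, dtype=float)
    t = np.asarray(time_s, dtype=float)
    seg = np.asarray(segment, dtype=int)
    if turns.max() <= 0 or turns.min() >= 0:
        warnings.warn("hat curve covers only one rotation sign; "
                      "symmetry classification will be partial",
                      stacklevel=2)
    anchors = []
    for s in np.unique(seg):
        idx = np.flatnonzero(seg == s)
        anchors.append(t[idx[np.argmin(np.abs(turns[idx]))]])
    anchors = sorted(anchors)
    corrected = ext
    if len(anchors) >= 2:
        corrected = drift_correct(t, ext, anchors)["corrected"]
    return HatCurve(turns=turns, extension_nm=corrected, segment=seg,
                    time_s=t, clamp_force_pN=clamp_force_pN,
                    active_bp=active_bp, helical_repeat=helical_repeat,
                    contour_length_nm=Lc_nm, drift_corrected=True)


def classify_hat_symmetry(hat: HatCurve, threshold: float = 0.25,
                          n_bins: int = 25) -> dict:
    """Symmetry score of a hat curve about sigma = 0.

    Both rotation signs are interpolated onto a common |turns| grid.
    With per-sign extension drops d+(u) = ext(0) - ext(+u) and d-(u),
    score = sum |d+ - d-| / sum max(d+, d-): 0 for a mirror-symmetric
    curve, -> 1 when one side stays on a plateau while the other drops.
    Invariant to a uniform extension offset and to time order.
    """
    pos = hat.turns > 0
    neg = hat.turns < 0
    if not pos.any() or not neg.any():
        raise ValueError("need samples at both rotation signs")
    umax = min(hat.turns[pos].max(), -hat.turns[neg].min())
    grid = np.linspace(0, umax, n_bins)
    op = np.argsort(hat.turns[pos])
    on = np.argsort(-hat.turns[neg])
    ext_p = np.interp(grid, hat.turns[pos][op], hat.extension_nm[pos][op])
    ext_n = np.interp(grid, -hat.turns[neg][on], hat.extension_nm[neg][on])
    ext0 = 0.5 * (ext_p[0] + ext_n[0])
    dp = ext0 - ext_p
    dn = ext0 - ext_n
    denom = np.sum(np.maximum(np.abs(dp), np.abs(dn)))
    score = 0.0 if denom <= 0 else float(np.sum(np.abs(dp - dn)) / denom)
    score = min(score, 1.0)
    return {"score": score,
            "label": "asymmetric" if score > threshold else "symmetric",
            "threshold": threshold}


def detect_buckling(turns, extension_nm, window: int = 10,
                    ratio_threshold: float = 1.5,
                    min_slope_change: float = 0.5) -> dict | None:
    """Locate the buckling transition in extension vs turns.

    A two-segment piecewise-linear model is fitted by exhaustive
    breakpoint search; the knee is accepted when the post-knee slope
    steepens by more than `min_slope_change` (fractional) relative to
    the baseline.  The fluctuation ratio is the post/pre s.d. of the
    detrended residuals in `window`-sized flanks; `buckled` requires
    ratio >= ratio_threshold.  Returns None when no change-point
    exists.
    """
    x = np.asarray(turns, dtype=float)
    y = np.asarray(extension_nm, dtype=float)
    n = x.size
    if n < 3 * window:
        raise ValueError("need >= 3 windows of data before a candidate")
    best = None
    for k in range(window, n - window):
        c1 = np.polyfit(x[:k], y[:k], 1)
        c2 = np.polyfit(x[k:], y[k:], 1)
        sse = (np.sum((y[:k] - np.polyval(c1, x[:k])) ** 2)
               + np.sum((y[k:] - np.polyval(c2, x[k:])) ** 2))
        if best is None or sse < best[0]:
            best = (sse, k, c1[0], c2[0])
    sse2, k, s1, s2 = best
    c0 = np.polyfit(x, y, 1)
    sse1 = np.sum((y - np.polyval(c0, x)) ** 2)
    scale = max(abs(s1), abs(s2), 1e-12)
    slope_change = abs(s2 - s1) / scale
    if slope_change < min_slope_change or sse2 > 0.8 * sse1:
        return None
    pre = y[max(0, k - window):k]
    post = y[k:k + window]
    xpre = x[max(0, k - window):k]
    xpost = x[k:k + window]
    sd_pre = np.std(pre - np.polyval(np.polyfit(xpre, pre, 1), xpre))
    sd_post = np.std(post - np.polyval(np.polyfit(xpost, post, 1), xpost))
    ratio = float(sd_post / sd_pre) if sd_pre > 0 else np.inf
    return {"buckling_turn": float(x[k]), "index": int(k),
            "fluctuation_ratio": ratio,
            "buckled": bool(ratio >= ratio_threshold),
            "slope_pre": float(s1), "slope_post": float(s2)}
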