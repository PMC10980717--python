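"""Trap and rotor calibration from QPD traces.

Trap stiffness comes from the corner frequency of a Lorentzian fitted
to the trapped-bead power spectrum, k = 2*pi*fc*gamma.  Angular
stiffness comes from the phase lag of bead rotation behind the coil
drive: for an overdamped rotor tan(phi) = 2*pi*f*gamma_th/k_theta, so
in the small-angle regime phi is linear in drive frequency with slope
2*pi*gamma_th/k_theta and k_theta = 2*pi*gamma_th/|slope|.

Note on the 2*pi: the phase-vs-frequency slope is quoted per Hz, while
the rotor drag enters per angular frequency, so converting the slope
to k_theta requires the factor 2*pi; it is included here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .constants import DEFAULT_VISCOSITY_PA_S, drag_rotational, \
    drag_translational
from .datatypes import QPDTrace

__all__ = [
    "TrapCalibration", "AngularCalibration", "CalibrationError",
    "fit_power_spectrum", "phase_shift", "fit_angular_stiffness",
    "low_freq_power_fraction", "low_freq_percent_change",
]


class CalibrationError(RuntimeError):
    def __init__(self, msg, residuals=None):
        super().__init__(msg)
        self.residuals = residuals


@dataclass
class TrapCalibration:
    corner_frequency_hz: float
    trap_stiffness_pN_per_um: float
    drag_coefficient_pN_s_per_nm: float
    fit_cov: np.ndarray | None = None

    def __post_init__(self):
        if (self.corner_frequency_hz <= 0
                or self.trap_stiffness_pN_per_um <= 0
                or self.drag_coefficient_pN_s_per_nm <= 0):
            raise ValueError("calibration values must be positive")


@dataclass
class AngularCalibration:
    phase_slope_rad_per_hz: float   # signed
    k_theta_pNnm_per_rad: float
    bead_radius_um: float
    viscosity_Pa_s: float
    r_squared: float = 1.0

    def __post_init__(self):
        if self.k_theta_pNnm_per_rad <= 0:
            raise ValueError("k_theta must be positive")


def _welch_psd(trace: QPDTrace, nperseg: int = 2 ** 13):
    """One-sided Welch spectrum: Hann window, 50% overlap."""
    nperseg = min(nperseg, len(trace))
    # no per-segment detrending: it would strip genuine power below
    # 1/T_segment and break Parseval on low-corner-frequency traces
    return signal.welch(trace.position, fs=trace.fs_hz, window="hann",
                        nperseg=nperseg, noverlap=nperseg // 2,
                        detrend=False)


def fit_power_spectrum(trace: QPDTrace, fit_band_hz=(5.0, 5000.0),
                       bead_radius_um: float = 1.5,
                       viscosity_Pa_s: float = DEFAULT_VISCOSITY_PA_S,
                       nperseg: int = 2 ** 13) -> TrapCalibration:
    """Fit S(f) = A/(fc^2 + f^2) to the trapped-bead power spectrum.

    Welch-averaged periodogram, relative (multiplicative) residuals —
    appropriate because spectral estimate errors scale with the mean.
    Stiffness follows from the Stokes drag of the given bead.
    """
    if len(trace) < 2 ** 14:
        raise ValueError("trace must contain >= 2^14 samples")
    f, S = _welch_psd(trace, nperseg)
    lo, hi = fit_band_hz
    m = (f >= lo) & (f <= hi)
    if m.sum() < 10:
        raise ValueError("fit band contains too few spectral points")
    f, S = f[m], S[m]

    def residual(p):
        A, fc = p
        model = A / (fc ** 2 + f ** 2)
        return (S - model) / model

    plateau = float(np.median(S[: max(3, S.size // 20)]))
    fc0 = float(f[np.argmin(np.abs(S - plateau / 2))])
    fc0 = min(max(fc0, lo * 2), hi / 2)
    res = optimize.least_squares(residual, x0=[plateau * fc0 ** 2, fc0],
                                 bounds=([0, lo / 10], [np.inf, hi * 10]))
    if not res.success:
        raise CalibrationError("Lorentzian fit did not converge",
                               residuals=res.fun)
    A, fc = res.x
    # covariance from the Jacobian at the solution
    try:
        cov = (np.linalg.inv(res.jac.T @ res.jac)
               * 2 * res.cost / max(1, f.size - 2))
        fc_sd = math.sqrt(cov[1, 1])
    except np.linalg.LinAlgError:
        cov, fc_sd = None, np.inf
    if fc > 0.8 * hi or fc < 1.25 * lo or fc_sd > 0.5 * fc:
        raise CalibrationError(
            f"corner frequency unconstrained (fc={fc:.1f} Hz, "
            f"sd={fc_sd:.1f}); spectrum has no knee in the fit band",
            residuals=res.fun)
    gamma = drag_translational(bead_radius_um, viscosity_Pa_s)
    k = 2.0 * math.pi * fc * gamma          # pN/nm
    return TrapCalibration(corner_frequency_hz=float(fc),
                           trap_stiffness_pN_per_um=k * 1000.0,
                           drag_coefficient_pN_s_per_nm=gamma,
                           fit_cov=cov)


def _lockin_phase(resp, drive, fs, f0):
    """Phase lag of resp behind drive at f0 via quadrature projection."""
    t = np.arange(resp.size) / fs
    ref = np.exp(-2j * math.pi * f0 * t)
    zr = np.sum(resp * ref)
    zd = np.sum(drive * ref)
    return float(-np.angle(zr / zd))    # positive = response lags drive


def phase_shift(response: QPDTrace, drive_freq_hz: float,
                band_hz: float = 0.5, min_snr: float = 3.0) -> float:
    """Phase lag (rad) of the response behind the drive at one drive
    frequency.

    The band-passed response is correlated with its own time reverse:
    for A*cos(2*pi*f*t + phi) the correlation peaks at lag
    -2*phi/(2*pi*f), encoding twice the phase with reduced noise.  The
    pi-ambiguity and sign are resolved against a quadrature projection
    onto the drive channel.  Lag of response behind drive is positive.
    """
    if response.drive is None:
        raise ValueError("trace has no drive channel")
    n = len(response)
    fs = response.fs_hz
    if n / fs < 10.0 / drive_freq_hz:
        raise ValueError("trace must contain >= 10 drive periods")
    # SNR gate: drive-frequency power vs neighbouring background
    spec = np.abs(np.fft.rfft(response.position - response.position.mean()))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    i0 = int(np.argmin(np.abs(freqs - drive_freq_hz)))
    nb = slice(max(1, i0 - 50), i0 + 50)
    bg = np.median(np.delete(spec[nb], np.arange(
        max(0, i0 - 2 - nb.start), min(100, i0 + 3 - nb.start))))
    if bg > 0 and spec[i0] / bg < min_snr:
        raise CalibrationError(
            f"SNR {spec[i0]/bg:.1f} < {min_snr} at {drive_freq_hz} Hz")
    # band-pass by FFT masking
    X = np.fft.rfft(response.position)
    mask = np.abs(freqs - drive_freq_hz) <= band_hz
    r = np.fft.irfft(X * mask, n)
    # correlate with the time-reversed signal (= autoconvolution):
    # c[m] ~ env(m) * cos(w*m*dt + 2*phi), env triangular about m0=n-1
    c = signal.fftconvolve(r, r, mode="full")
    dt = 1.0 / fs
    w = 2.0 * math.pi * drive_freq_hz
    m0 = n - 1
    half = max(2, int(round(fs / drive_freq_hz / 2)))
    sl = slice(m0 - half, m0 + half + 1)
    env = n - np.abs(np.arange(sl.start, sl.stop) - m0)
    cl = c[sl] / env                    # remove envelope bias
    k = int(np.argmax(cl))
    m_pk = float(sl.start + k)
    if 0 < k < cl.size - 1:             # parabolic sub-sample refinement
        denom = cl[k - 1] - 2 * cl[k] + cl[k + 1]
        if denom != 0:
            m_pk += 0.5 * (cl[k - 1] - cl[k + 1]) / denom
    # response = cos(w*t - phi) -> c peaks where w*m*dt = 2*phi (mod 2pi)
    phi_mag = (w * m_pk * dt / 2.0) % math.pi    # phase modulo pi
    ref = _lockin_phase(response.position, response.drive, fs,
                        drive_freq_hz)
    candidates = phi_mag + math.pi * np.arange(-3, 4)
    return float(candidates[np.argmin(np.abs(candidates - ref))])


def fit_angular_stiffness(phases, bead_radius_um: float = 1.5,
                          viscosity_Pa_s: float = DEFAULT_VISCOSITY_PA_S,
                          min_r_squared: float = 0.9) -> AngularCalibration:
    """Linear regression of phase vs drive frequency; k_theta =
    2*pi*8*pi*eta*R^3 / |slope|.

    phases: iterable of (freq_hz, phase_rad) in the small-angle regime
    (|phi| < 0.7 rad).
    """
    pts = [(f, p) for f, p in phases]
    if len(pts) < 3:
        raise ValueError("need >= 3 (frequency, phase) points")
    f = np.array([p[0] for p in pts])
    ph = np.array([p[1] for p in pts])
    if np.any(np.abs(ph) >= 0.7):
        raise ValueError("phases outside the small-angle regime "
                         "(|phi| < 0.7 rad)")
    slope, icept = np.polyfit(f, ph, 1)
    pred = slope * f + icept
    ss_res = np.sum((ph - pred) ** 2)
    ss_tot = np.sum((ph - ph.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if r2 < min_r_squared:
        raise CalibrationError(f"phase regression R^2 = {r2:.3f} < "
                               f"{min_r_squared}")
    gamma = drag_rotational(bead_radius_um, viscosity_Pa_s)
    k_theta = 2.0 * math.pi * gamma / abs(slope)
    return AngularCalibration(phase_slope_rad_per_hz=float(slope),
                              k_theta_pNnm_per_rad=float(k_theta),
                              bead_radius_um=bead_radius_um,
                              viscosity_Pa_s=viscosity_Pa_s,
                              r_squared=float(r2))


def low_freq_power_fraction(trace: QPDTrace, f_cut_hz: float = 60.0,
                            nperseg: int = 2 ** 13) -> float:
    """Fraction of total one-sided spectral power below f_cut (DC
    excluded)."""
    if trace.fs_hz <= 2.0 * f_cut_hz:
        raise ValueError("sampling rate must exceed 2*f_cut")
    f, S = _welch_psd(trace, nperseg)
    S = S[1:]
    f = f[1:]
    total = np.sum(S)
    if total <= 0:
        return 0.0
    return float(np.sum(S[f < f_cut_hz]) / total)


def low_freq_percent_change(trace_a: QPDTrace, trace_b: QPDTrace,
                            f_cut_hz: float = 60.0) -> float:
    """Percent change in the <f_cut power fraction from trace_a to
    trace_b (e.g. pre- vs during buckling)."""
    a = low_freq_power_fraction(trace_a, f_cut_hz)
    b = low_freq_power_fraction(trace_b, f_cut_hz)
    if a == 0:
        raise ValueError("reference trace has zero low-frequency power")
    return 100.0 * (b - a) / a
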