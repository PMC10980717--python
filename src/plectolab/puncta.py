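"""Detection, tracking and quantification of fluorescent puncta
(plectonemes) on tether images.

Puncta are found as local maxima above background, refined by 2-D
Gaussian least squares, and linked frame-to-frame by greedy nearest
neighbour.  Per-punctum bp content is the background-corrected punctum
intensity over the background-corrected whole-tether intensity.
Mobility is summarised by 1-D rms frame-to-frame displacements
parallel/perpendicular to the tether axis and by an MSD-regression
diffusion coefficient (<r^2> = 4*D*lag*dt through the origin).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .datatypes import PunctumTrack

__all__ = [
    "DiffusionSummary", "track_puncta", "punctum_bp_fraction",
    "rmsd_components", "estimate_D", "ratio_of_D", "line_profile_fwhm",
]

DEFAULT_PIXEL_SIZE_NM = 55.0


@dataclass
class DiffusionSummary:
    rmsd_parallel_nm: float
    rmsd_perp_nm: float
    rmsd_tot_nm: float
    D_nm2_per_s: float | None = None
    D_ci95_nm2_per_s: tuple[float, float] | None = None
    frame_interval_s: float | None = None
    nonlinear_msd: bool = False


def _gauss2d(params, xx, yy):
    A, x0, y0, sx, sy, off = params
    return off + A * np.exp(-((xx - x0) ** 2 / (2 * sx ** 2)
                              + (yy - y0) ** 2 / (2 * sy ** 2)))


def _fit_gaussian(img, cx, cy, win, s0):
    """2-D Gaussian refinement around an integer-pixel candidate.

    Returns (x0, y0, integrated, offset, loc_sd) in pixel units or
    None when the fit fails."""
    h, w = img.shape
    x0, x1 = max(0, cx - win), min(w, cx + win + 1)
    y0, y1 = max(0, cy - win), min(h, cy + win + 1)
    sub = img[y0:y1, x0:x1].astype(float)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    off0 = float(np.percentile(sub, 20))
    A0 = float(sub.max() - off0)
    p0 = [max(A0, 1e-3), cx, cy, s0, s0, off0]

    def resid(p):
        return (_gauss2d(p, xx, yy) - sub).ravel()

    try:
        res = optimize.least_squares(
            resid, p0,
            bounds=([0, x0, y0, 0.3, 0.3, -np.inf],
                    [np.inf, x1, y1, 10 * s0, 10 * s0, np.inf]))
    except ValueError:
        return None
    if not res.success:
        return None
    A, px, py, sx, sy, off = res.x
    integrated = 2.0 * math.pi * A * sx * sy
    # localisation s.d. from the Jacobian (x0 parameter)
    dof = max(1, res.fun.size - 6)
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * 2 * res.cost / dof
        loc_sd = math.sqrt(max(cov[1, 1], 0.0))
    except np.linalg.LinAlgError:
        loc_sd = np.nan
    return px, py, integrated, off, loc_sd, sx, sy


def _detect_frame(img, psf_sigma_px, threshold_sd):
    """Candidate puncta in one frame: local maxima above background +
    threshold_sd * robust noise, after mild smoothing."""
    sm = ndimage.gaussian_filter(img.astype(float), psf_sigma_px / 2)
    bg = np.median(sm)
    noise = 1.4826 * np.median(np.abs(sm - bg)) + 1e-12
    mx = ndimage.maximum_filter(sm, size=max(3, int(3 * psf_sigma_px)))
    cand = (sm == mx) & (sm > bg + threshold_sd * noise)
    ys, xs = np.nonzero(cand)
    order = np.argsort(sm[ys, xs])[::-1]
    return list(zip(xs[order], ys[order]))


def track_puncta(stack, pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
                 expected_psf_sigma_nm: float = 120.0,
                 link_radius_nm: float = 500.0,
                 threshold_sd: float = 6.0,
                 max_eccentricity: float = 2.5,
                 tether_endpoints=None) -> list[PunctumTrack]:
    """Detect and link puncta through an image stack.

    Per frame: local-maximum detection above background, then 2-D
    Gaussian least-squares refinement giving sub-pixel position,
    integrated background-corrected intensity and a localisation
    precision from the fit covariance.  Fits more elongated than
    `max_eccentricity` are discarded — they are ridge maxima of the
    tether line itself, not puncta.  Detections are linked by greedy
    nearest neighbour within `link_radius_nm`; when two candidates fall
    inside the radius the tie is broken by intensity similarity and the
    match flagged (stored on the returned track as `ambiguous_links`).
    Returns an empty list when nothing is detected.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, h, w)")
    s_px = expected_psf_sigma_nm / pixel_size_nm
    win = max(3, int(round(3 * s_px)))
    detections = []       # per frame: list of dicts
    for i, img in enumerate(stack):
        dets = []
        for cx, cy in _detect_frame(img, s_px, threshold_sd):
            fit = _fit_gaussian(img, int(cx), int(cy), win, s_px)
            if fit is None:
                continue
            px, py, integ, off, loc_sd, sx, sy = fit
            if max(sx, sy) / min(sx, sy) > max_eccentricity:
                continue            # tether-line ridge, not a punctum
            if any((px - d["x"]) ** 2 + (py - d["y"]) ** 2 < s_px ** 2
                   for d in dets):
                continue            # duplicate maximum of same punctum
            dets.append({"x": px, "y": py, "I": integ, "bg": off,
                         "sd": loc_sd})
        detections.append(dets)

    # greedy nearest-neighbour linking
    link_px = link_radius_nm / pixel_size_nm
    tracks: list[dict] = []
    ambiguous: list[bool] = []
    for i, dets in enumerate(detections):
        unmatched = list(range(len(dets)))
        for ti, tr in enumerate(tracks):
            if tr["frames"][-1] != i - 1:
                continue
            lx, ly = tr["x"][-1], tr["y"][-1]
            cand = [(j, math.hypot(dets[j]["x"] - lx, dets[j]["y"] - ly))
                    for j in unmatched]
            cand = [(j, d) for j, d in cand if d <= link_px]
            if not cand:
                continue
            if len(cand) > 1:
                # tie-break by intensity similarity
                li = tr["I"][-1]
                cand.sort(key=lambda jd: abs(dets[jd[0]]["I"] - li))
                ambiguous[ti] = True
            else:
                cand.sort(key=lambda jd: jd[1])
            j = cand[0][0]
            unmatched.remove(j)
            d = dets[j]
            tr["frames"].append(i)
            for k_src, k_dst in (("x", "x"), ("y", "y"), ("I", "I"),
                                 ("bg", "bg"), ("sd", "sd")):
                tr[k_dst].append(d[k_src])
        for j in unmatched:
            d = dets[j]
            tracks.append({"frames": [i], "x": [d["x"]], "y": [d["y"]],
                           "I": [d["I"]], "bg": [d["bg"]],
                           "sd": [d["sd"]]})
            ambiguous.append(False)

    out = []
    for tr, amb in zip(tracks, ambiguous):
        t = PunctumTrack(
            frame=np.array(tr["frames"]),
            x_nm=np.array(tr["x"]) * pixel_size_nm,
            y_nm=np.array(tr["y"]) * pixel_size_nm,
            intensity=np.array(tr["I"]),
            background=np.array(tr["bg"]),
            fit_sd_nm=np.array(tr["sd"]) * pixel_size_nm,
            tether_axis=tether_endpoints)
        t.ambiguous_links = amb
        out.append(t)
    return out


def _tether_mask(shape, endpoints, pixel_size_nm, band_nm):
    h, w = shape
    p0 = np.asarray(endpoints[0], float) / pixel_size_nm
    p1 = np.asarray(endpoints[1], float) / pixel_size_nm
    yy, xx = np.mgrid[0:h, 0:w]
    d = p1 - p0
    L2 = d @ d
    t = ((xx - p0[0]) * d[0] + (yy - p0[1]) * d[1]) / L2
    t = np.clip(t, 0, 1)
    dist = np.hypot(xx - (p0[0] + t * d[0]), yy - (p0[1] + t * d[1]))
    return dist <= band_nm / pixel_size_nm


def punctum_bp_fraction(track: PunctumTrack, stack,
                        tether_endpoints=None,
                        pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
                        punctum_radius_nm: float = 360.0,
                        band_nm: float = 360.0,
                        construct_bp: int | None = None) -> dict:
    """Fraction of the tether's fluorescence carried by one punctum.

    Per frame: camera background (median of off-tether pixels) is
    subtracted everywhere; the whole-tether sum is taken over a band of
    half-width `band_nm` around the tether axis; the punctum sum over a
    disc of `punctum_radius_nm` is additionally corrected for the
    tether line running through it, using the median per-column line
    intensity measured away from the punctum.  With `construct_bp`
    given, the mean fraction is also converted to bp content.
    """
    endpoints = tether_endpoints or track.tether_axis
    if endpoints is None:
        raise ValueError("tether endpoints required")
    stack = np.asarray(stack, dtype=float)
    h, w = stack.shape[1:]
    mask = _tether_mask((h, w), endpoints, pixel_size_nm, band_nm)
    off = ~ndimage.binary_dilation(mask, iterations=3)
    yy, xx = np.mgrid[0:h, 0:w]
    p0 = np.asarray(endpoints[0], float) / pixel_size_nm
    p1 = np.asarray(endpoints[1], float) / pixel_size_nm
    d = p1 - p0
    L_px = np.linalg.norm(d)
    # axial column index (px) of every pixel along the tether
    tcol = np.rint(((xx - p0[0]) * d[0] + (yy - p0[1]) * d[1])
                   / L_px).astype(int)
    fracs = []
    r_px = punctum_radius_nm / pixel_size_nm
    for fi, x, y in zip(track.frame, track.x_nm, track.y_nm):
        img = stack[fi]
        bg = np.median(img[off]) if off.any() else 0.0
        corr = img - bg
        tether_sum = float(np.sum(corr[mask]))
        if tether_sum <= 0:
            raise ValueError("whole-tether intensity <= 0 after background "
                             "correction")
        disc = ((xx - x / pixel_size_nm) ** 2
                + (yy - y / pixel_size_nm) ** 2) <= r_px ** 2
        punctum_sum = float(np.sum(corr[disc & mask]))
        # subtract the tether line running through the disc: median
        # per-column band intensity away from the punctum
        away = mask & ~ndimage.binary_dilation(disc, iterations=2)
        if away.any():
            cols_away = tcol[away]
            sums = np.bincount(cols_away - cols_away.min(),
                               weights=corr[away])
            counts = np.bincount(cols_away - cols_away.min())
            line_per_col = float(np.median(sums[counts > 0]
                                           [1:-1] if (counts > 0).sum() > 2
                                           else sums[counts > 0]))
            n_cols = len(np.unique(tcol[disc & mask]))
            punctum_sum -= line_per_col * n_cols
        fracs.append(min(max(punctum_sum / tether_sum, 0.0), 1.0))
    fracs = np.asarray(fracs)
    out = {"fraction_per_frame": fracs, "mean_fraction": float(fracs.mean())}
    if construct_bp is not None:
        out["bp_content"] = float(fracs.mean() * construct_bp)
    return out


def _axis_unit(track: PunctumTrack, tether_axis=None) -> np.ndarray:
    axis = tether_axis or track.tether_axis
    if axis is None:
        raise ValueError("tether axis required")
    v = np.asarray(axis[1], float) - np.asarray(axis[0], float)
    L = np.linalg.norm(v)
    if L == 0:
        raise ValueError("degenerate tether axis (zero length)")
    return v / L


def rmsd_components(track: PunctumTrack, tether_axis=None,
                    frame_interval_s: float | None = None
                    ) -> DiffusionSummary:
    """1-D rms frame-to-frame displacements parallel and perpendicular
    to the tether axis; total is the quadrature sum."""
    if len(track) < 2:
        raise ValueError("need >= 2 frames")
    u = _axis_unit(track, tether_axis)
    n = np.array([-u[1], u[0]])
    d = np.diff(track.positions(), axis=0)
    par = d @ u
    perp = d @ n
    r_par = float(np.sqrt(np.mean(par ** 2)))
    r_perp = float(np.sqrt(np.mean(perp ** 2)))
    return DiffusionSummary(rmsd_parallel_nm=r_par, rmsd_perp_nm=r_perp,
                            rmsd_tot_nm=float(math.hypot(r_par, r_perp)),
                            frame_interval_s=frame_interval_s)


def msd_curve(positions: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-averaged MSD at lags 1..max_lag for an (n, 2) track."""
    pos = np.asarray(positions, float)
    return np.array([np.mean(np.sum((pos[lag:] - pos[:-lag]) ** 2, axis=1))
                     for lag in range(1, max_lag + 1)])


def estimate_D(track, frame_interval_s: float, max_lag: int = 5) -> dict:
    """Diffusion coefficient from MSD regression through the origin.

    MSD(lag) is fitted against 4*D*lag*dt by ordinary least squares
    with zero intercept; the CI comes from the regression.  A ballistic
    (quadratic-in-lag) component triggers the `nonlinear` flag.
    Negative estimates are clamped to zero with a warning.

    `track` may be a PunctumTrack or an (n, 2) position array in nm.
    """
    pos = track.positions() if isinstance(track, PunctumTrack) \
        else np.asarray(track, float)
    if pos.shape[0] <= max_lag + 1:
        raise ValueError("track length must exceed max_lag + 1")
    msd = msd_curve(pos, max_lag)
    x = 4.0 * np.arange(1, max_lag + 1) * frame_interval_s
    D = float(np.sum(msd * x) / np.sum(x * x))
    resid = msd - D * x
    dof = max(1, max_lag - 1)
    var_D = float(np.sum(resid ** 2) / dof / np.sum(x * x))
    half = 1.96 * math.sqrt(var_D)
    nonlinear = False
    if max_lag >= 3:
        # quadratic term significance: MSD ~ a*lag + b*lag^2
        lag = np.arange(1, max_lag + 1, dtype=float)
        Amat = np.column_stack([lag, lag ** 2])
        coef, res_q, *_ = np.linalg.lstsq(Amat, msd, rcond=None)
        ss_q = float(res_q[0]) if res_q.size else 0.0
        sigma2 = ss_q / max(1, max_lag - 2)
        cov = np.linalg.inv(Amat.T @ Amat) * max(sigma2, 1e-30)
        tval = abs(coef[1]) / math.sqrt(max(cov[1, 1], 1e-30))
        nonlinear = bool(tval > 3.0 and coef[1] > 0
                         and coef[1] * max_lag > 0.2 * abs(coef[0]))
    if D < 0:
        warnings.warn("negative fitted D clamped to 0", stacklevel=2)
        D = 0.0
    return {"D_nm2_per_s": D, "ci95": (D - half, D + half),
            "msd_nm2": msd, "nonlinear": nonlinear}


def ratio_of_D(D_pos: float, D_neg: float) -> dict:
    """Quotient of diffusion coefficients (e.g. positive vs negative
    supercoiling), with a nearest-integer rounding helper for
    reporting."""
    if D_neg <= 0:
        raise ValueError("denominator D must be positive")
    r = D_pos / D_neg
    return {"ratio": r, "rounded": int(round(r))}


def line_profile_fwhm(image, tether_endpoints,
                      pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
                      band_nm: float = 1000.0,
                      n_axial: int = 40, exclude_frac: float = 0.1,
                      noise_floor_sd: float = 3.0) -> dict:
    """FWHM of perpendicular intensity line profiles along the tether.

    At `n_axial` axial positions (excluding `exclude_frac` at each end,
    where the beads dominate) a profile perpendicular to the tether
    axis is interpolated over +/-band_nm, background-subtracted using
    its outer 20%, and its FWHM found by linear interpolation at half
    maximum.  Positions whose peak is below `noise_floor_sd` times the
    background noise are returned as NaN and counted in `n_undefined`.
    """
    img = np.asarray(image, float)
    p0 = np.asarray(tether_endpoints[0], float)
    p1 = np.asarray(tether_endpoints[1], float)
    u = (p1 - p0) / np.linalg.norm(p1 - p0)
    nvec = np.array([-u[1], u[0]])
    ts = np.linspace(exclude_frac, 1 - exclude_frac, n_axial)
    offs = np.linspace(-band_nm, band_nm, 81)
    fwhms = np.full(n_axial, np.nan)
    for i, t in enumerate(ts):
        c = p0 + t * (p1 - p0)
        pts = (c[None, :] + offs[:, None] * nvec[None, :]) / pixel_size_nm
        prof = ndimage.map_coordinates(img, [pts[:, 1], pts[:, 0]],
                                       order=1, mode="nearest")
        edge = np.r_[prof[: len(prof) // 5], prof[-len(prof) // 5:]]
        bg = float(np.median(edge))
        noise = float(np.std(edge)) + 1e-12
        prof = prof - bg
        pk = int(np.argmax(prof))
        if prof[pk] < noise_floor_sd * noise:
            continue
        half = prof[pk] / 2.0
        # walk out from the peak to the half-maximum crossings
        left = right = None
        for j in range(pk, 0, -1):
            if prof[j - 1] <= half <= prof[j]:
                fl = (half - prof[j - 1]) / (prof[j] - prof[j - 1])
                left = offs[j - 1] + fl * (offs[j] - offs[j - 1])
                break
        for j in range(pk, len(prof) - 1):
            if prof[j + 1] <= half <= prof[j]:
                fl = (prof[j] - half) / (prof[j] - prof[j + 1])
                right = offs[j] + fl * (offs[j + 1] - offs[j])
                break
        if left is not None and right is not None:
            fwhms[i] = right - left
    valid = ~np.isnan(fwhms)
    return {"axial_fraction": ts, "fwhm_nm": fwhms,
            "mean_fwhm_nm": float(np.nanmean(fwhms)) if valid.any()
            else float("nan"),
            "n_undefined": int((~valid).sum())}
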