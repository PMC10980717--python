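"""Denaturation-bubble analysis of base-pair-parameter trajectories.

A bubble is a run of >= 3 consecutive bp that have lost their WC
H-bonds and whose three angular parameters (propeller twist, opening,
buckle) all deviate >= 2 s.d. from the relaxed-DNA baseline, persisting
for more than 1 ns.  Prevalence is the percentage of frames in the
final analysis window containing at least one bubble, with a bootstrap
standard deviation.
"""

from __future__ import annotations

from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import BasePairTrajectory, BubbleCall

__all__ = [
    "read_bp_params", "write_bp_params", "relaxed_baseline",
    "detect_bubbles", "bubble_prevalence", "prevalence_bootstrap",
    "convergence_curve", "FormatError",
]


class FormatError(ValueError):
    pass


_COLUMN_ALIASES = {
    "frame": "frame", "#frame": "frame",
    "bp": "bp", "basepair": "bp", "pair": "bp",
    "propeller": "propeller", "prop": "propeller",
    "opening": "opening", "open": "opening",
    "buckle": "buckle",
    "hb": "hbonds", "hbonds": "hbonds", "wc_hb": "hbonds",
}


def read_bp_params(path, dt_ns: float = 0.1) -> BasePairTrajectory:
    """Read a per-frame, per-bp structural-parameter table.

    Accepts a plain headered TSV or the whitespace-separated dialect
    written by nucleic-acid trajectory analysis tools (a '#Frame'-style
    header).  Requires columns for frame, bp index, propeller, opening,
    buckle and WC H-bond count; the H-bond flag is count >= 1.  The
    grid must be rectangular — every frame must report every bp.
    """
    text = Path(path).read_text()
    first = text.splitlines()[0]
    sep = "\t" if "\t" in first else r"\s+"
    df = pd.read_csv(StringIO(text), sep=sep)
    df.columns = [_COLUMN_ALIASES.get(c.strip().lower().lstrip("#"),
                                      c.strip().lower())
                  for c in df.columns]
    needed = {"frame", "bp", "propeller", "opening", "buckle", "hbonds"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"missing columns: {sorted(missing)}")
    frames = np.sort(df["frame"].unique())
    bps = np.sort(df["bp"].unique())
    counts = df.groupby("frame")["bp"].nunique()
    bad = counts[counts != bps.size]
    if len(bad):
        raise FormatError(
            f"ragged grid: frame {bad.index[0]} has {bad.iloc[0]} bp "
            f"records, expected {bps.size}")
    if len(df) != frames.size * bps.size:
        raise FormatError("duplicate (frame, bp) records present")
    df = df.sort_values(["frame", "bp"])
    shape = (frames.size, bps.size)
    return BasePairTrajectory(
        hbond=(df["hbonds"].to_numpy() >= 1).reshape(shape),
        propeller=df["propeller"].to_numpy().reshape(shape),
        opening=df["opening"].to_numpy().reshape(shape),
        buckle=df["buckle"].to_numpy().reshape(shape),
        dt_ns=dt_ns)


def write_bp_params(traj: BasePairTrajectory, path) -> None:
    """Write the TSV dialect `read_bp_params` reads back."""
    nf, nb = traj.hbond.shape
    frame = np.repeat(np.arange(1, nf + 1), nb)
    bp = np.tile(np.arange(1, nb + 1), nf)
    pd.DataFrame({
        "frame": frame, "bp": bp,
        "propeller": traj.propeller.ravel(),
        "opening": traj.opening.ravel(),
        "buckle": traj.buckle.ravel(),
        "hbonds": traj.hbond.ravel().astype(int),
    }).to_csv(path, sep="\t", index=False)


def relaxed_baseline(traj: BasePairTrajectory,
                     exclude_terminal_bp: int = 2) -> dict:
    """Per-parameter global mean and s.d. from a relaxed (sigma = 0)
    trajectory, excluding the frayed terminal bp at each end."""
    if traj.n_frames < 100:
        raise ValueError("baseline needs >= 100 frames")
    sl = slice(exclude_terminal_bp, traj.n_bp - exclude_terminal_bp)
    out = {}
    for p in BasePairTrajectory.PARAMS:
        vals = getattr(traj, p)[:, sl]
        out[p] = {"mean": float(vals.mean()), "sd": float(vals.std())}
    return out


def _disrupted_grid(traj: BasePairTrajectory, baseline: dict,
                    z_thresh: float, mode: str) -> np.ndarray:
    """Boolean (frames x bp) grid: no WC H-bond AND angular parameters
    deviate >= z_thresh s.d. from baseline ('all' three jointly by
    default; 'any' as a configurable alternative)."""
    devs = []
    for p in BasePairTrajectory.PARAMS:
        mu, sd = baseline[p]["mean"], baseline[p]["sd"]
        devs.append(np.abs(getattr(traj, p) - mu) >= z_thresh * sd)
    stacked = np.stack(devs)
    angular = stacked.all(axis=0) if mode == "all" else stacked.any(axis=0)
    return ~traj.hbond & angular


def detect_bubbles(traj: BasePairTrajectory, baseline: dict,
                   min_len_bp: int = 3, z_thresh: float = 2.0,
                   min_dur_ns: float = 1.0,
                   angular_mode: str = "all") -> list[BubbleCall]:
    """Call denaturation bubbles from a trajectory.

    Per frame, maximal runs of >= `min_len_bp` disrupted bp are
    candidate bubbles; candidates sharing >= 1 bp between consecutive
    frames are merged into one event (a gap of a full frame ends the
    event); events lasting more than `min_dur_ns` are returned.
    """
    if min_len_bp <= 0 or z_thresh <= 0 or min_dur_ns <= 0:
        raise ValueError("thresholds must be positive")
    if angular_mode not in ("all", "any"):
        raise ValueError("angular_mode must be 'all' or 'any'")
    grid = _disrupted_grid(traj, baseline, z_thresh, angular_mode)
    nf, nb = grid.shape

    def frame_runs(row) -> list[tuple[int, int]]:
        runs = []
        start = None
        for j in range(nb):
            if row[j] and start is None:
                start = j
            elif not row[j] and start is not None:
                if j - start >= min_len_bp:
                    runs.append((start, j))
                start = None
        if start is not None and nb - start >= min_len_bp:
            runs.append((start, nb))
        return runs

    calls: list[BubbleCall] = []
    # active: list of [start_bp0, end_bp0, first_frame, last_frame]
    active: list[list[int]] = []
    for i in range(nf):
        runs = frame_runs(grid[i])
        next_active: list[list[int]] = []
        used = [False] * len(runs)
        for ev in active:
            matched = False
            for ri, (r0, r1) in enumerate(runs):
                if used[ri]:
                    continue
                if r0 < ev[1] and ev[0] < r1:     # bp overlap
                    ev[0] = min(ev[0], r0)
                    ev[1] = max(ev[1], r1)
                    ev[3] = i
                    used[ri] = True
                    matched = True
                    break
            if matched:
                next_active.append(ev)
            else:
                _finalise(ev, traj, calls, min_dur_ns)
        for ri, (r0, r1) in enumerate(runs):
            if not used[ri]:
                next_active.append([r0, r1, i, i])
        active = next_active
    for ev in active:
        _finalise(ev, traj, calls, min_dur_ns)
    calls.sort(key=lambda c: (c.t_start_ns, c.start_bp))
    return calls


def _finalise(ev, traj, calls, min_dur_ns):
    duration = (ev[3] - ev[2] + 1) * traj.dt_ns
    if duration > min_dur_ns:
        calls.append(BubbleCall(start_bp=ev[0] + 1,
                                length_bp=ev[1] - ev[0],
                                t_start_ns=ev[2] * traj.dt_ns,
                                duration_ns=duration))


def bubble_frame_indicator(traj: BasePairTrajectory,
                           calls: list[BubbleCall]) -> np.ndarray:
    """Boolean per-frame indicator: frame lies inside >= 1 bubble."""
    ind = np.zeros(traj.n_frames, dtype=bool)
    for c in calls:
        f0 = int(round(c.t_start_ns / traj.dt_ns))
        f1 = f0 + int(round(c.duration_ns / traj.dt_ns))
        ind[f0:f1] = True
    return ind


def bubble_prevalence(traj: BasePairTrajectory, calls: list[BubbleCall],
                      analysis_window_ns: float = 400.0) -> float:
    """Percent of frames with >= 1 bubble over the final window."""
    if analysis_window_ns > traj.duration_ns:
        raise ValueError("analysis window longer than the trajectory")
    nw = int(round(analysis_window_ns / traj.dt_ns))
    ind = bubble_frame_indicator(traj, calls)[-nw:]
    return 100.0 * float(ind.mean())


def prevalence_bootstrap(indicator, n_boot: int = 200, frac: float = 0.01,
                         seed: int | None = None) -> float:
    """Bootstrap s.d. of the prevalence: resample `frac` of the
    per-frame indicator `n_boot` times."""
    ind = np.asarray(indicator, dtype=float)
    m = int(round(frac * ind.size))
    if m < 10:
        raise ValueError("frac*n_frames must be >= 10")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        reps[i] = ind[rng.integers(0, ind.size, size=m)].mean()
    return float(np.std(reps) * 100.0)


def convergence_curve(series, tolerance: float = 0.02) -> dict:
    """Cumulative running mean of an end-to-end-distance series with a
    convergence flag: converged when the running mean drifts by less
    than `tolerance` (fractional) over the final quarter."""
    y = np.asarray(series, float)
    if y.size < 100:
        raise ValueError("series must have >= 100 samples")
    running = np.cumsum(y) / np.arange(1, y.size + 1)
    q = running[-y.size // 4:]
    scale = abs(running[-1]) if running[-1] != 0 else 1.0
    drift = float((q.max() - q.min()) / scale)
    return {"running_mean": running, "drift": drift,
            "converged": bool(drift < tolerance)}
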