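"""Shared data containers used across the pipeline stages.

These are deliberately thin: numpy arrays with metadata, serialisable
to headered TSV / CSV / JSON so that every intermediate product of the
pipeline is inspectable as plain text.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


def _asarray(x, dtype=float) -> np.ndarray:
    return np.asarray(x, dtype=dtype)


@dataclass
class GroundTruth:
    """Parameter set a synthetic generator used, persisted next to its
    output so recovery tests are self-describing."""

    generator: str
    params: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"generator": self.generator, "params": self.params},
            indent=2, default=_json_default))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(d["generator"], d["params"])


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serialisable: {type(o)}")


@dataclass
class ForceExtensionCurve:
    """Paired extension (nm) / force (pN) samples from one
    stretch-release half cycle."""

    extension_nm: np.ndarray
    force_pN: np.ndarray
    direction: str = "stretch"  # stretch | release
    temperature_K: float = 310.0

    def __post_init__(self):
        self.extension_nm = _asarray(self.extension_nm)
        self.force_pN = _asarray(self.force_pN)
        if self.extension_nm.shape != self.force_pN.shape:
            raise ValueError("extension and force arrays differ in length")
        if np.any(self.extension_nm < 0):
            raise ValueError("extensions must be non-negative")
        if self.direction not in ("stretch", "release"):
            raise ValueError("direction must be 'stretch' or 'release'")

    def __len__(self):
        return self.extension_nm.size

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"extension_nm": self.extension_nm,
                      "force_pN": self.force_pN}).to_csv(path, sep="\t",
                                                         index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, **kw) -> "ForceExtensionCurve":
        df = pd.read_csv(path, sep="\t")
        return cls(df["extension_nm"].to_numpy(),
                   df["force_pN"].to_numpy(), **kw)


@dataclass
class QPDTrace:
    """Detector time series at fixed sampling rate, optionally with a
    coil-drive channel (for angular calibration)."""

    fs_hz: float
    position: np.ndarray          # nm for trapped-bead traces, rad for rotor
    drive: np.ndarray | None = None
    units: str = "nm"

    def __post_init__(self):
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        self.position = _asarray(self.position)
        if self.drive is not None:
            self.drive = _asarray(self.drive)
            if self.drive.shape != self.position.shape:
                raise ValueError("drive channel length mismatch")

    def __len__(self):
        return self.position.size

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.position.size) / self.fs_hz

    def to_tsv(self, path: str | Path) -> None:
        cols = {"time_s": self.time_s, "value": self.position}
        if self.drive is not None:
            cols["drive"] = self.drive
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, units: str = "nm") -> "QPDTrace":
        df = pd.read_csv(path, sep="\t")
        t = df["time_s"].to_numpy()
        fs = 1.0 / float(np.median(np.diff(t)))
        drive = df["drive"].to_numpy() if "drive" in df else None
        return cls(fs, df["value"].to_numpy(), drive, units=units)

    def to_hdf5(self, path: str | Path, group: str = "trace") -> None:
        import h5py
        with h5py.File(path, "a") as f:
            g = f.require_group(group)
            for k in ("position", "drive"):
                if k in g:
                    del g[k]
            g.attrs["fs_hz"] = self.fs_hz
            g.attrs["units"] = self.units
            g.create_dataset("position", data=self.position)
            if self.drive is not None:
                g.create_dataset("drive", data=self.drive)

    @classmethod
    def from_hdf5(cls, path: str | Path, group: str = "trace") -> "QPDTrace":
        import h5py
        with h5py.File(path, "r") as f:
            g = f[group]
            drive = g["drive"][...] if "drive" in g else None
            return cls(float(g.attrs["fs_hz"]), g["position"][...], drive,
                       units=str(g.attrs.get("units", "nm")))


@dataclass
class HatCurve:
    """Extension vs applied turns at fixed clamp force, segmented by
    rotation direction."""

    turns: np.ndarray
    extension_nm: np.ndarray
    segment: np.ndarray            # integer segment id per sample
    time_s: np.ndarray
    clamp_force_pN: float
    active_bp: int = 14600
    helical_repeat: float = 10.5
    contour_length_nm: float | None = None
    drift_corrected: bool = False

    def __post_init__(self):
        self.turns = _asarray(self.turns)
        self.extension_nm = _asarray(self.extension_nm)
        self.segment = _asarray(self.segment, dtype=int)
        self.time_s = _asarray(self.time_s)
        n = self.turns.size
        for a in (self.extension_nm, self.segment, self.time_s):
            if a.size != n:
                raise ValueError("hat-curve arrays differ in length")

    @property
    def sigma(self) -> np.ndarray:
        return self.turns * self.helical_repeat / self.active_bp

    @property
    def fractional_extension(self) -> np.ndarray | None:
        if self.contour_length_nm is None:
            return None
        return self.extension_nm / self.contour_length_nm

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.time_s, "turns": self.turns,
                      "sigma": self.sigma,
                      "extension_nm": self.extension_nm,
                      "segment": self.segment}).to_csv(path, sep="\t",
                                                       index=False)


@dataclass
class PunctumTrack:
    """Sub-pixel trajectory of one fluorescent punctum on a tether."""

    frame: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    intensity: np.ndarray          # integrated, background-corrected
    background: np.ndarray
    fit_sd_nm: np.ndarray
    tether_axis: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self):
        self.frame = _asarray(self.frame, dtype=int)
        for name in ("x_nm", "y_nm", "intensity", "background", "fit_sd_nm"):
            setattr(self, name, _asarray(getattr(self, name)))

    def __len__(self):
        return self.frame.size

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x_nm, self.y_nm])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"frame": self.frame, "x_nm": self.x_nm,
                      "y_nm": self.y_nm, "intensity": self.intensity,
                      "background": self.background,
                      "fit_sd_nm": self.fit_sd_nm}).to_csv(path, index=False)


@dataclass
class BasePairTrajectory:
    """Per-frame, per-bp record of WC H-bond presence and the three
    angular base-pair parameters.  bp indices are 1-based."""

    hbond: np.ndarray      # (n_frames, n_bp) bool
    propeller: np.ndarray  # degrees
    opening: np.ndarray
    buckle: np.ndarray
    dt_ns: float

    PARAMS = ("propeller", "opening", "buckle")

    def __post_init__(self):
        self.hbond = np.asarray(self.hbond, dtype=bool)
        for p in self.PARAMS:
            setattr(self, p, _asarray(getattr(self, p)))
            if getattr(self, p).shape != self.hbond.shape:
                raise ValueError(f"{p} grid shape mismatch")
        if self.hbond.ndim != 2:
            raise ValueError("trajectory grid must be 2-D (frames x bp)")
        if self.dt_ns <= 0:
            raise ValueError("dt_ns must be positive")

    @property
    def n_frames(self) -> int:
        return self.hbond.shape[0]

    @property
    def n_bp(self) -> int:
        return self.hbond.shape[1]

    @property
    def duration_ns(self) -> float:
        return self.n_frames * self.dt_ns


@dataclass
class BubbleCall:
    """One denaturation-bubble event called from a trajectory."""

    start_bp: int       # 1-based, inclusive
    length_bp: int
    t_start_ns: float
    duration_ns: float

    def __post_init__(self):
        if self.length_bp < 3:
            raise ValueError("bubbles are >=3 consecutive bp by definition")
        if self.duration_ns <= 0:
            raise ValueError("duration must be positive")

    @property
    def end_bp(self) -> int:
        return self.start_bp + self.length_bp - 1


def dataclass_to_json(obj, path: str | Path) -> None:
    """Serialise any of the result dataclasses to JSON."""
    Path(path).write_text(json.dumps(dataclasses.asdict(obj), indent=2,
                                     default=_json_default))
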