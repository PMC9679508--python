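"""Core domain types and plain-text trial-bundle I/O.

A *trial* is one in-hand trot pass: synchronized 3D marker trajectories
(default 200 Hz) and multi-channel surface EMG (default 2000 Hz) plus
metadata describing the condition (baseline or induced fore-/hindlimb
lameness) and the side of induction.

A trial bundle on disk is a directory holding

* ``meta.json``    -- subject_id, trial_id, condition, induction_side, fs_kin, fs_emg
* ``markers.csv``  -- ``time,<marker>_x,<marker>_y,<marker>_z,...`` in mm,
  empty cells mark missing (occluded) samples
* ``emg.csv``      -- ``time,<muscle>_<side>,...`` in mV

Coordinate convention: x is the direction of travel (cranial positive),
z is vertical (up positive), y is left lateral; units are millimetres.
Kinematics and EMG share t = 0; sample k of a signal maps to time k/fs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import IngestError, SchemaError, SynchronizationError

CONDITIONS = ("baseline1", "baseline2", "iFL", "iHL")
SIDES = ("left", "right")
INDUCTION_SIDES = ("left", "right", "none")

MUSCLES = ("triceps", "latissimus", "gluteal", "biceps", "semitendinosus")

#: Anatomical marker registry (axial landmarks plus bilateral limb chains).
KNOWN_MARKERS = frozenset(
    ["poll", "withers_T6", "tubera_sacrale"]
    + [f"{base}_{s}" for s in ("L", "R") for base in (
        "tuber_coxae", "spina_scapulae", "greater_tubercle", "elbow", "carpus",
        "mcp", "greater_trochanter", "stifle", "tarsus", "mtp")]
    + ["hoof_FL", "hoof_FR", "hoof_HL", "hoof_HR"]
)

HOOF_MARKERS = {"FL": "hoof_FL", "FR": "hoof_FR", "HL": "hoof_HL", "HR": "hoof_HR"}


@dataclass
class TrialMeta:
    """Metadata for one pass/condition."""

    subject_id: str
    condition: str
    induction_side: str = "none"
    fs_kin: float = 200.0
    fs_emg: float = 2000.0
    trial_id: str = ""

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise SchemaError(f"unknown condition {self.condition!r}")
        if self.induction_side not in INDUCTION_SIDES:
            raise SchemaError(f"unknown induction side {self.induction_side!r}")
        if self.condition.startswith("baseline") and self.induction_side != "none":
            raise SchemaError("baseline conditions must have induction_side='none'")
        ratio = self.fs_emg / self.fs_kin
        if abs(ratio - round(ratio)) > 1e-9:
            raise SchemaError(
                f"fs_emg ({self.fs_emg}) must be an integer multiple of fs_kin ({self.fs_kin})"
            )


@dataclass
class MarkerTrajectory:
    """One marker's (x, y, z) samples in mm at fs_kin; NaN rows are missing.

    ``missing`` is the authoritative occlusion mask; samples where
    ``missing`` is True are NaN and must never be silently filled.
    """

    name: str
    xyz: np.ndarray  # (n, 3) float, mm
    missing: np.ndarray = None  # (n,) bool

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise SchemaError(f"marker {self.name}: xyz must be (n, 3)")
        if self.missing is None:
            self.missing = np.any(~np.isfinite(self.xyz), axis=1)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape[0] != self.xyz.shape[0]:
            raise SchemaError(f"marker {self.name}: mask length mismatch")
        self.xyz[self.missing] = np.nan
        if not np.all(np.isfinite(self.xyz[~self.missing])):
            raise SchemaError(f"marker {self.name}: non-finite present samples")

    def __len__(self):
        return self.xyz.shape[0]

    def component(self, axis: str) -> np.ndarray:
        return self.xyz[:, "xyz".index(axis)]


@dataclass
class EMGChannel:
    """One bipolar sEMG channel (mV at fs_emg)."""

    muscle: str
    side: str
    samples: np.ndarray

    def __post_init__(self):
        if self.muscle not in MUSCLES:
            raise SchemaError(f"unknown muscle {self.muscle!r}")
        if self.side not in SIDES:
            raise SchemaError(f"unknown side {self.side!r}")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise SchemaError(f"channel {self.name}: non-finite samples")

    @property
    def name(self) -> str:
        return f"{self.muscle}_{self.side}"

    def __len__(self):
        return self.samples.shape[0]


@dataclass
class Trial:
    """Synchronized markers + EMG + metadata for one pass."""

    meta: TrialMeta
    markers: dict = field(default_factory=dict)  # name -> MarkerTrajectory
    emg: dict = field(default_factory=dict)      # "muscle_side" -> EMGChannel

    def __post_init__(self):
        self.validate()

    @property
    def n_kin(self) -> int:
        return len(next(iter(self.markers.values()))) if self.markers else 0

    @property
    def n_emg(self) -> int:
        return len(next(iter(self.emg.values()))) if self.emg else 0

    @property
    def duration(self) -> float:
        """Trial duration in seconds (kinematic time base)."""
        return self.n_kin / self.meta.fs_kin

    @property
    def t_kin(self) -> np.ndarray:
        return np.arange(self.n_kin) / self.meta.fs_kin

    @property
    def t_emg(self) -> np.ndarray:
        return np.arange(self.n_emg) / self.meta.fs_emg

    def validate(self):
        lengths = {len(m) for m in self.markers.values()}
        if len(lengths) > 1:
            raise SynchronizationError(f"marker lengths differ: {sorted(lengths)}")
        lengths = {len(c) for c in self.emg.values()}
        if len(lengths) > 1:
            raise SynchronizationError(f"EMG lengths differ: {sorted(lengths)}")
        if self.markers and self.emg:
            dk = self.n_kin / self.meta.fs_kin
            de = self.n_emg / self.meta.fs_emg
            if abs(dk - de) > 1.0 / self.meta.fs_kin + 1e-9:
                raise SynchronizationError(
                    f"kinematics cover {dk:.4f} s but EMG covers {de:.4f} s "
                    f"(tolerance one kinematic frame)"
                )


def _missing_runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of contiguous True runs (stop exclusive)."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    for start, stop in zip(idx[::2], idx[1::2]):
        yield int(start), int(stop)


def interpolate_gaps(traj: MarkerTrajectory, max_gap: int = 10) -> MarkerTrajectory:
    """Fill occlusion gaps of at most ``max_gap`` frames by cubic interpolation.

    Each coordinate is interpolated independently with a cubic spline fitted
    through the present samples, so gaps inside polynomial trajectories up to
    degree 3 are filled exactly.  Runs longer than ``max_gap`` frames, and
    runs touching the record boundary (no flanking data), remain masked;
    strides overlapping them are flagged downstream via the surviving NaNs.
    """
    mask = traj.missing.copy()
    xyz = traj.xyz.copy()
    present = np.flatnonzero(~mask)
    if present.size == 0:
        return MarkerTrajectory(traj.name, xyz, mask)
    fill = np.zeros_like(mask)
    for start, stop in _missing_runs(mask):
        if stop - start > max_gap:
            continue
        if start == 0 or stop == len(mask):
            continue  # boundary gap: no flanking data on one side
        fill[start:stop] = True
    if fill.any():
        idx = np.flatnonzero(fill)
        for j in range(3):
            y = xyz[~mask, j]
            if present.size >= 4:
                f = CubicSpline(present, y)
            else:
                f = lambda q, p=present, yy=y: np.interp(q, p, yy)
            xyz[idx, j] = f(idx)
        mask[idx] = False
    return MarkerTrajectory(traj.name, xyz, mask)


# ---------------------------------------------------------------------------
# bundle I/O

_META = "meta.json"
_MARKERS = "markers.csv"
_EMG = "emg.csv"
_FLOAT_FMT = "%.17g"


def write_trial(trial: Trial, bundle_path) -> None:
    """Serialize a trial to a bundle directory (created if absent).

    Numeric fields are written at full float precision so that
    ``load_trial(write_trial(t)) == t`` field-for-field, and two writes of
    the same trial are byte-identical.
    """
    path = Path(bundle_path)
    try:
        path.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IngestError(f"cannot create bundle directory {path}: {exc}") from exc

    meta = dataclasses.asdict(trial.meta)
    (path / _META).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    cols = {"time": trial.t_kin}
    for name in sorted(trial.markers):
        m = trial.markers[name]
        for j, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = m.xyz[:, j]
    pd.DataFrame(cols).to_csv(path / _MARKERS, index=False,
                              float_format=_FLOAT_FMT, na_rep="")

    cols = {"time": trial.t_emg}
    for name in sorted(trial.emg):
        cols[name] = trial.emg[name].samples
    pd.DataFrame(cols).to_csv(path / _EMG, index=False, float_format=_FLOAT_FMT)


def load_trial(bundle_path) -> Trial:
    """Read a trial bundle written by :func:`write_trial`.

    Missing marker samples are carried as the occlusion mask (NaN), never
    filled.  Raises :class:`IngestError` naming any missing file,
    :class:`SchemaError` for unknown labels, and
    :class:`SynchronizationError` for mismatched record durations.
    """
    path = Path(bundle_path)
    for fname in (_META, _MARKERS, _EMG):
        if not (path / fname).is_file():
            raise IngestError(f"bundle {path} is missing required file {fname!r}")

    meta = TrialMeta(**json.loads((path / _META).read_text()))

    mdf = pd.read_csv(path / _MARKERS, float_precision="round_trip")
    names = []
    for col in mdf.columns:
        if col == "time":
            continue
        if not col.endswith(("_x", "_y", "_z")):
            raise SchemaError(f"malformed marker column {col!r}")
        names.append(col[:-2])
    markers = {}
    for name in dict.fromkeys(names):
        if name not in KNOWN_MARKERS:
            raise SchemaError(f"unknown marker label {name!r}")
        xyz = np.column_stack([mdf[f"{name}_{ax}"].to_numpy(float) for ax in "xyz"])
        markers[name] = MarkerTrajectory(name, xyz)

    edf = pd.read_csv(path / _EMG, float_precision="round_trip")
    emg = {}
    for col in edf.columns:
        if col == "time":
            continue
        muscle, _, side = col.rpartition("_")
        if muscle not in MUSCLES or side not in SIDES:
            raise SchemaError(f"unknown EMG channel label {col!r}")
        emg[col] = EMGChannel(muscle, side, edf[col].to_numpy(float))

    return Trial(meta, markers, emg)
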