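"""Gait events, stride segmentation, asymmetry indices, angles, and
101-node time normalization.

Motion asymmetry is quantified per stride from the vertical displacement
of three upper-body landmarks.  In symmetric trot each landmark traces two
minima and two maxima per stride; unilateral lameness makes the two halves
unequal.  ``MinDiff`` is the left-limb-associated minimum minus the
right-limb-associated one (``MaxDiff`` analogously on maxima; association
by the stance half of the respective limb -- forelimbs for poll and
withers, hindlimbs for the pelvis).  ``Hip Hike`` is the difference
between left and right tubera coxae upward excursion during the
ipsilateral hindlimb's swing phase.  Sufficient induced lameness shows up
as |MinDiff| of the poll above roughly 13 mm (forelimb) or of the pelvis
above 5 mm (hindlimb); see :mod:`gaitemg.discrete`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from ._filters import zero_phase
from .errors import ConfigurationError, InsufficientStridesError
from .io_model import HOOF_MARKERS, MarkerTrajectory, Trial

LOWPASS_CUTOFF_HZ = 10.0       # kinematic smoothing (Butterworth 4th order)
ADAPTIVE_HP_FACTOR = 0.5       # high-pass cutoff = 0.5 x stride frequency
IMPACT_HEIGHT_FRACTION = 0.05  # hoof-height threshold for impact candidates
N_NODES = 101                  # nodes per time-normalized stride


@dataclass
class GaitEvents:
    """Impact and derived lift-off times per limb, seconds."""

    impacts: dict   # limb ("FL","FR","HL","HR") -> increasing np.ndarray
    liftoffs: dict  # limb -> increasing np.ndarray

    def stride_windows(self, limb: str):
        """Half-open [impact_i, impact_{i+1}) windows for ``limb``."""
        t = self.impacts[limb]
        return list(zip(t[:-1], t[1:]))


@dataclass
class NormalizedStride:
    """A stride resampled onto 101 equally spaced nodes."""

    values: np.ndarray
    trial_id: str = ""
    stride_index: int = -1
    variable: str = ""
    valid: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_NODES,):
            raise ConfigurationError("normalized stride must have exactly 101 nodes")


def lowpass_kinematics(traj: MarkerTrajectory, fs: float,
                       cutoff_hz: float = LOWPASS_CUTOFF_HZ) -> MarkerTrajectory:
    """Zero-phase 4th-order Butterworth low-pass (default 10 Hz) per coordinate.

    Gaps must already be interpolated or masked; masked stretches stay NaN.
    """
    xyz = traj.xyz.copy()
    ok = ~traj.missing
    if ok.any():
        xyz[ok] = zero_phase(traj.xyz[ok], cutoff_hz, fs, axis=0)
    return MarkerTrajectory(traj.name, xyz, traj.missing.copy())


def adaptive_highpass(displacement: np.ndarray, stride_frequency: float,
                      fs: float) -> np.ndarray:
    """High-pass a vertical displacement series at 0.5 x stride frequency.

    Removes DC and inter-stride drift while preserving the stride
    fundamental and its asymmetry-bearing two-per-stride harmonic.  The
    cutoff sits well below the signal band, so the filter's settling time
    spans whole strides; to keep edge transients out of the first and last
    strides the record is extended with phase-aligned cyclic copies of its
    edge strides (the signal is near-periodic at the known stride period)
    before zero-phase filtering, then cropped.
    """
    if stride_frequency <= 0:
        raise ConfigurationError("stride frequency must be positive")
    x = np.asarray(displacement, dtype=float)
    cutoff = ADAPTIVE_HP_FACTOR * stride_frequency
    period = int(round(fs / stride_frequency))
    n = x.size
    if period < 4 or n < period:
        return zero_phase(x, cutoff, fs, btype="high")
    pad = int(3 * fs / cutoff)
    left = x[(np.arange(-pad, 0) % period)]
    right = x[n - period + (np.arange(pad) % period)]
    ext = np.concatenate([left, x, right])
    return zero_phase(ext, cutoff, fs, btype="high")[pad:pad + n]


#: fraction of the hoof's vertical range used to time the approach/leave
#: crossings that are extrapolated to ground contact
IMPACT_CROSSING_FRACTION = 0.15


def detect_hindlimb_impacts(trial: Trial, min_height_range_mm: float = 10.0,
                            lowpass: bool = True) -> GaitEvents:
    """Detect hoof impact (and derived lift-off) times for all four limbs.

    Candidate ground-contact dips are runs of hoof height below 5% of its
    vertical range.  The hoof descends with nearly constant velocity just
    before contact, so the impact is located by the downward crossing of a
    15%-of-range level preceding the dip, linearly extrapolated to the
    stance floor (the dip's median height); lift-off is derived
    symmetrically from the upward crossing after the dip.  This avoids the
    bias a low-pass filter puts on the touchdown corner itself.  Dips
    touching the record boundary are discarded; a limb with fewer than 3
    impacts raises :class:`InsufficientStridesError`.
    """
    fs = trial.meta.fs_kin
    impacts, liftoffs = {}, {}
    for limb, marker in HOOF_MARKERS.items():
        traj = trial.markers[marker]
        z = traj.component("z")
        if np.isnan(z).any():
            z = np.where(np.isnan(z), np.nanmedian(z), z)
        if lowpass:
            z = zero_phase(z, LOWPASS_CUTOFF_HZ, fs)
        zrange = z.max() - z.min()
        if zrange < min_height_range_mm:
            raise InsufficientStridesError(
                f"{limb}: hoof height range {zrange:.1f} mm too small to contain strides")
        thr_loc = z.min() + IMPACT_HEIGHT_FRACTION * zrange
        thr_det = z.min() + IMPACT_CROSSING_FRACTION * zrange
        below = z < thr_loc
        d = np.diff(below.astype(int))
        starts = np.flatnonzero(d > 0) + 1
        stops = np.flatnonzero(d < 0) + 1
        times, offs = [], []
        for s in starts:
            e = stops[stops > s]
            if e.size == 0:
                continue  # dip runs off the end of the record
            e = int(e[0])
            floor = float(np.median(z[s:e]))
            t_imp = _extrapolated_crossing(z, s, thr_det, floor, fs, direction=-1)
            if t_imp is None:
                continue
            t_off = _extrapolated_crossing(z, e - 1, thr_det, floor, fs, direction=+1)
            times.append(t_imp)
            if t_off is not None:
                offs.append(t_off)
        if len(times) < 3:
            raise InsufficientStridesError(
                f"{limb}: only {len(times)} impacts detected (need >= 3)")
        impacts[limb] = np.asarray(times)
        liftoffs[limb] = np.asarray(offs)
    return GaitEvents(impacts, liftoffs)


def _extrapolated_crossing(z, start, level, floor, fs, direction):
    """Time the hoof reaches the stance floor, from the ``level`` crossing
    just before (direction=-1) or after (+1) index ``start``."""
    i = start
    n = len(z)
    while 0 < i < n - 1 and z[i] < level:
        i += direction
    if i <= 0 or i >= n - 1:
        return None  # crossing runs off the record
    j = i - direction  # z[i] >= level > z[j]
    if z[i] == z[j]:
        return None
    frac = (z[i] - level) / (z[i] - z[j])
    t_cross = (i + frac * (j - i)) / fs
    slope = abs(z[i] - z[j]) * fs
    # descending: contact happens after the crossing; ascending: before
    return t_cross - direction * (level - floor) / slope


def stride_speed(trial: Trial, events: GaitEvents,
                 reference_limb: str = "HL") -> np.ndarray:
    """Per-stride mean horizontal speed (m/s) of the tubera sacrale marker.

    Speed is the smoothed differentiation (central differences after the
    10 Hz low-pass) of the marker's horizontal coordinates.  Strides whose
    window contains no valid samples get NaN.
    """
    fs = trial.meta.fs_kin
    traj = lowpass_kinematics(trial.markers["tubera_sacrale"], fs)
    x, y = traj.component("x"), traj.component("y")
    vx, vy = np.gradient(x) * fs, np.gradient(y) * fs
    sp = np.hypot(vx, vy) / 1000.0  # mm/s -> m/s
    t = trial.t_kin
    out = []
    for t0, t1 in events.stride_windows(reference_limb):
        sel = (t >= t0) & (t < t1)
        vals = sp[sel]
        vals = vals[np.isfinite(vals)]
        out.append(float(vals.mean()) if vals.size else np.nan)
    return np.asarray(out)


def time_normalize(t: np.ndarray, y: np.ndarray, window,
                   trial_id: str = "", stride_index: int = -1,
                   variable: str = "") -> NormalizedStride:
    """Linearly interpolate one stride onto 101 equally spaced nodes.

    Node 0 and node 100 fall exactly on the two segmentation events.  A
    window containing masked (NaN) data is returned flagged invalid.
    """
    t0, t1 = window
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ConfigurationError("stride window outside series span")
    nodes = np.linspace(t0, t1, N_NODES)
    vals = np.interp(nodes, t, y)
    sel = (t >= t0 - 1.0 / max(len(t), 1)) & (t <= t1 + 1e-9)
    valid = not np.isnan(y[sel]).any()
    return NormalizedStride(np.where(np.isfinite(vals), vals, np.nan),
                            trial_id, stride_index, variable, valid)


# ---------------------------------------------------------------------------
# asymmetry indices

_LANDMARKS = {"poll": ("poll", "fore"), "withers": ("withers_T6", "fore"),
              "pelvis": ("tubera_sacrale", "hind")}


def _two_extrema(seg: np.ndarray, kind: str):
    """Indices of exactly two interior minima or maxima, else None."""
    y = -seg if kind == "min" else seg
    prominence = 0.02 * (seg.max() - seg.min() + 1e-12)
    peaks, _ = find_peaks(y, prominence=prominence)
    if peaks.size != 2:
        return None
    return peaks


def asymmetry_indices(trial: Trial, events: GaitEvents,
                      reference_limb: str = "HL") -> pd.DataFrame:
    """Per-stride MinDiff/MaxDiff (poll, withers, pelvis), Hip Hike,
    stride duration and speed.

    The landmark displacements are low-passed at 10 Hz and then high-pass
    filtered with a cutoff adapted to the measured stride frequency before
    extrema are extracted.  A stride missing one of its four extrema for a
    landmark gets NaN for that landmark's indices and is flagged in the
    ``excluded`` column.  Index signs flip under left/right relabelling of
    the input (antisymmetry).
    """
    fs = trial.meta.fs_kin
    windows = events.stride_windows(reference_limb)
    if not windows:
        raise InsufficientStridesError("no stride windows")
    durations = np.array([t1 - t0 for t0, t1 in windows])
    stride_freq = 1.0 / durations.mean()
    t = trial.t_kin

    filtered = {}
    for lm, (marker, _) in _LANDMARKS.items():
        z = lowpass_kinematics(trial.markers[marker], fs).component("z")
        if np.isnan(z).all():
            filtered[lm] = z
            continue
        zf = np.where(np.isnan(z), np.nanmedian(z), z)
        filtered[lm] = adaptive_highpass(zf, stride_freq, fs)
        filtered[lm][np.isnan(z)] = np.nan

    tc = {s: lowpass_kinematics(trial.markers[f"tuber_coxae_{s}"], fs).component("z")
          for s in ("L", "R")}
    speeds = stride_speed(trial, events, reference_limb)

    rows = []
    for k, (t0, t1) in enumerate(windows):
        row = {"trial_id": trial.meta.trial_id, "stride_index": k,
               "stride_duration": t1 - t0, "stride_speed": speeds[k],
               "excluded": False}
        for lm, (marker, assoc) in _LANDMARKS.items():
            sel = (t >= t0) & (t < t1)
            seg = filtered[lm][sel]
            ts = t[sel]
            mn = mx = None
            if seg.size > 4 and not np.isnan(seg).any():
                mn = _two_extrema(seg, "min")
                mx = _two_extrema(seg, "max")
            if mn is None or mx is None:
                row[f"min_diff_{lm}"] = np.nan
                row[f"max_diff_{lm}"] = np.nan
                row["excluded"] = True
                continue
            pair = ("FL", "FR") if assoc == "fore" else ("HL", "HR")
            for kind, idx in (("min", mn), ("max", mx)):
                sides = [_stance_side(events, pair, ts[i]) for i in idx]
                if set(sides) != {"left", "right"}:
                    row[f"{kind}_diff_{lm}"] = np.nan
                    row["excluded"] = True
                    continue
                left_i = idx[sides.index("left")]
                right_i = idx[sides.index("right")]
                row[f"{kind}_diff_{lm}"] = float(seg[left_i] - seg[right_i])
        row["hip_hike"] = _hip_hike(tc, events, t, t0, t1)
        rows.append(row)
    return pd.DataFrame(rows)


def _stance_side(events: GaitEvents, pair, te: float) -> str:
    """Side of the limb pair whose stance the extremum at ``te`` belongs to:
    the limb with the most recent impact at or before ``te``."""
    left_limb, right_limb = pair
    recent = {}
    for key, limb in (("left", left_limb), ("right", right_limb)):
        imp = events.impacts[limb]
        prev = imp[imp <= te]
        recent[key] = prev[-1] if prev.size else -np.inf
    return "left" if recent["left"] >= recent["right"] else "right"


def _hip_hike(tc: dict, events: GaitEvents, t: np.ndarray,
              t0: float, t1: float) -> float:
    """Left minus right tuber coxae upward excursion during the ipsilateral
    hindlimb's swing phase (full swing window starting within the stride)."""
    exc = {}
    for side, limb in (("L", "HL"), ("R", "HR")):
        lo = events.liftoffs[limb]
        lo = lo[(lo >= t0) & (lo < t1)]
        if lo.size == 0:
            return np.nan
        start = lo[0]
        nxt = events.impacts[limb]
        nxt = nxt[nxt > start]
        if nxt.size == 0:
            return np.nan
        end = nxt[0]
        sel = (t >= start) & (t < end)
        seg = tc[side][sel]
        if seg.size == 0 or np.isnan(seg).any():
            return np.nan
        exc[side] = float(seg.max() - seg.min())
    return exc["L"] - exc["R"]


# ---------------------------------------------------------------------------
# joint and limb angles

#: joint -> (proximal marker, vertex marker, distal marker); per-side names
#: get the _L/_R suffix appended.
_JOINTS = {
    "shoulder": ("spina_scapulae", "greater_tubercle", "elbow"),
    "elbow": ("greater_tubercle", "elbow", "carpus"),
    "hip": ("tuber_coxae", "greater_trochanter", "stifle"),
    "stifle": ("greater_trochanter", "stifle", "tarsus"),
    "tarsus": ("stifle", "tarsus", "mtp"),
}
_PRORETRACTION = {"forelimb": ("spina_scapulae", "mcp"),
                  "hindlimb": ("tuber_coxae", "mtp")}


@dataclass
class JointAngleSet:
    """Continuous sagittal joint and limb pro-retraction angles per side.

    ``angles`` maps e.g. ``"elbow_L"`` or ``"forelimb_proret_R"`` to a
    time series in degrees; joint angles are interior segment-to-segment
    angles in (0, 360), pro-retraction is signed with protraction
    (distal end cranial of proximal, relative to the trunk line) positive.
    ``static_reference`` holds the same quantities evaluated on the static
    trial.
    """

    angles: dict
    static_reference: dict = field(default_factory=dict)
    fs: float = 200.0


def _sagittal_angle(prox, vertex, dist):
    """Interior angle at the vertex in the x-z plane, degrees in (0, 360)."""
    v1 = prox - vertex
    v2 = dist - vertex
    a1 = np.arctan2(v1[:, 2], v1[:, 0])
    a2 = np.arctan2(v2[:, 2], v2[:, 0])
    ang = np.degrees((a1 - a2) % (2 * np.pi))
    return ang


def _proretraction_angle(trunk_cranial, prox, dist):
    """Signed limb angle vs the trunk-normal; protraction positive."""
    u = trunk_cranial / np.linalg.norm(trunk_cranial, axis=1, keepdims=True)
    v = dist - prox
    w = np.column_stack([u[:, 2], np.zeros(len(u)), -u[:, 0]])  # trunk-down
    comp_u = np.einsum("ij,ij->i", v[:, [0, 2]], u[:, [0, 2]])
    comp_w = np.einsum("ij,ij->i", v[:, [0, 2]], w[:, [0, 2]])
    return np.degrees(np.arctan2(comp_u, comp_w))


def _angles_of(trial: Trial) -> dict:
    sxz = {name: m.xyz for name, m in trial.markers.items()}
    trunk = sxz["withers_T6"] - sxz["tubera_sacrale"]  # caudal -> cranial line
    out = {}
    for side in ("L", "R"):
        for joint, (p, v, d) in _JOINTS.items():
            out[f"{joint}_{side}"] = _sagittal_angle(
                sxz[f"{p}_{side}"], sxz[f"{v}_{side}"], sxz[f"{d}_{side}"])
        for limb, (p, d) in _PRORETRACTION.items():
            out[f"{limb}_proret_{side}"] = _proretraction_angle(
                trunk, sxz[f"{p}_{side}"], sxz[f"{d}_{side}"])
    return out


def joint_and_limb_angles(trial: Trial, static_trial: Trial) -> JointAngleSet:
    """Sagittal-plane joint angles and limb pro-retraction angles.

    Angles are the interior angles between adjacent segment vectors in the
    x-z plane (collinear segments read 180 deg, perpendicular 90 deg).
    The static trial defines the reference pose: with two-marker sagittal
    segments the calibration offset is identically zero, so evaluating the
    static trial returns its own reference angles; the references are
    carried in ``static_reference`` for reporting.  Samples with missing
    markers come out NaN.
    """
    angles = _angles_of(trial)
    static = {k: float(np.nanmedian(v)) for k, v in _angles_of(static_trial).items()}
    return JointAngleSet(angles, static, trial.meta.fs_kin)
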