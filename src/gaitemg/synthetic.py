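"""Synthetic trot trials with known ground truth.

The generator emulates the structure of an over-ground trot pass recorded
with synchronized motion capture (200 Hz) and surface EMG (2000 Hz), for a
baseline condition and for induced fore-/hindlimb lameness:

* Upper-body landmarks (poll, withers, pelvis) move vertically with the
  trot's two-oscillations-per-stride waveform.  Left/right asymmetry is
  injected by adding a one-period raised-cosine bump centred on the
  targeted extremum (half-width = 1/4 stride), which changes that extremum
  by exactly the bump height while leaving the other three extrema of the
  stride untouched -- so injected MinDiff/MaxDiff equal the bump heights by
  construction.
* Tubera coxae traces carry an extra swing-phase bump producing the
  injected Hip Hike.
* Hoof trajectories are flat during stance and a sine arc during swing, so
  ground contact starts at the true impact times.
* Each EMG channel is band-limited (20-450 Hz) Gaussian noise amplitude
  modulated by per-stride burst envelopes plus a noise floor, segmented by
  the contralateral hindlimb's strides (the segmentation the analysis
  uses).

Trot is a two-beat diagonal gait: the left hind + right fore pair impacts
at stride phase 0 and the right hind + left fore pair at phase 0.5; the
stance fraction is 0.45.  Identical seeds give identical trials.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

from ._filters import zero_phase
from .errors import ConfigurationError
from .io_model import EMGChannel, MarkerTrajectory, MUSCLES, Trial, TrialMeta

#: stride-phase of each limb's impact (left hind is the reference limb)
LIMB_PHASE = {"HL": 0.0, "FR": 0.0, "HR": 0.5, "FL": 0.5}
DUTY_FACTOR = 0.45  # stance fraction of the stride

#: stride-phase centres of the landmark extrema associated with the LEFT limb
#: (minimum, maximum).  Poll and withers asymmetry is carried by the
#: forelimbs (left fore impacts at phase 0.5), the pelvis by the hindlimbs
#: (left hind impacts at phase 0).
_LEFT_EXTREMA = {
    "poll": (7 / 8, 5 / 8),
    "withers": (7 / 8, 5 / 8),
    "pelvis": (3 / 8, 1 / 8),
}

_LANDMARK_MARKER = {"poll": "poll", "withers": "withers_T6", "pelvis": "tubera_sacrale"}


@dataclass(frozen=True)
class Burst:
    """One activation burst in % of the muscle's segmentation stride."""

    onset_pct: float
    offset_pct: float
    amplitude: float  # mV, modulation-envelope peak

    def validate(self):
        if not (0 <= self.onset_pct < self.offset_pct <= 100):
            raise ConfigurationError(
                f"burst must satisfy 0 <= onset < offset <= 100, got "
                f"({self.onset_pct}, {self.offset_pct})"
            )
        if self.amplitude <= 0:
            raise ConfigurationError("burst amplitude must be positive")


@dataclass
class LamenessScenario:
    """Full parameterization of one synthetic trial."""

    stride_duration_mean: float = 0.77   # s
    stride_duration_cv: float = 0.03     # fractional stride-to-stride jitter
    n_strides: int = 20
    speed: float = 3.5                   # m/s
    displacement_amp: dict = field(
        default_factory=lambda: {"poll": 55.0, "withers": 30.0, "pelvis": 45.0})  # mm
    min_diff_inject: dict = field(
        default_factory=lambda: {"poll": 0.0, "withers": 0.0, "pelvis": 0.0})     # mm
    max_diff_inject: dict = field(
        default_factory=lambda: {"poll": 0.0, "withers": 0.0, "pelvis": 0.0})     # mm
    hip_hike_inject: float = 0.0         # mm
    burst_spec: dict = None              # (muscle, side) -> tuple[Burst, ...]
    emg_noise_floor: float = 0.05        # fraction of the largest burst amplitude
    kinematic_noise_sd: float = 1.0      # mm, white noise on every coordinate
    seed: int = 0
    condition: str = "baseline1"
    induction_side: str = "none"
    subject_id: str = "sim"

    def __post_init__(self):
        if self.burst_spec is None:
            self.burst_spec = default_burst_spec()
        self.validate()

    def validate(self):
        if self.n_strides < 3:
            raise ConfigurationError("n_strides must be >= 3")
        if self.stride_duration_mean <= 0 or self.speed <= 0:
            raise ConfigurationError("stride duration and speed must be positive")
        if self.stride_duration_cv < 0 or self.kinematic_noise_sd < 0:
            raise ConfigurationError("noise parameters must be non-negative")
        if not (0 <= self.emg_noise_floor < 1):
            raise ConfigurationError("emg_noise_floor must be in [0, 1)")
        for amp in self.displacement_amp.values():
            if amp <= 0:
                raise ConfigurationError("displacement amplitudes must be positive")
        for bursts in self.burst_spec.values():
            for b in bursts:
                b.validate()


@dataclass
class GroundTruth:
    """Everything the analysis pipeline should recover from a trial."""

    impact_times: dict        # limb -> array of true impact times (s)
    liftoff_times: dict       # limb -> array of true lift-off times (s)
    min_diff: dict            # landmark -> injected MinDiff (mm)
    max_diff: dict            # landmark -> injected MaxDiff (mm)
    hip_hike: float           # injected Hip Hike (mm)
    emg_bursts: dict          # "muscle_side" -> per-stride list of burst dicts
    seg_windows: dict         # "muscle_side" -> list of (t0, t1) stride windows
    stride_boundaries: np.ndarray  # reference-limb (left hind) impact times

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["impact_times"] = {k: list(v) for k, v in self.impact_times.items()}
        d["liftoff_times"] = {k: list(v) for k, v in self.liftoff_times.items()}
        d["seg_windows"] = {k: [list(w) for w in v] for k, v in self.seg_windows.items()}
        d["stride_boundaries"] = list(self.stride_boundaries)
        return d


def default_burst_spec() -> dict:
    """Stylized trot activity windows, in % of the segmentation stride.

    The segmentation stride of each muscle runs between impacts of the
    contralateral hindlimb, so the muscle's own limb impacts at 0% (fore
    muscles, diagonal pair) or 50% (hind muscles).  Fore muscles burst in
    late swing approaching impact; hind muscles from late swing through
    stance; semitendinosus carries a second early-swing burst and
    latissimus a short burst at the beginning of swing, to exercise
    multi-burst detection.
    """
    base = {
        "triceps": (Burst(78, 98, 0.10),),
        "latissimus": (Burst(78, 98, 0.10), Burst(48, 58, 0.07)),
        "gluteal": (Burst(30, 55, 0.10),),
        "biceps": (Burst(28, 68, 0.10),),
        "semitendinosus": (Burst(30, 62, 0.10), Burst(2, 22, 0.08)),
    }
    return {(m, s): base[m] for m in MUSCLES for s in ("left", "right")}


def _scale_bursts(spec, muscle, side, amp_scale=1.0, shift=0.0):
    out = []
    for b in spec[(muscle, side)]:
        on = min(max(b.onset_pct + shift, 0.0), 99.0)
        off = min(max(b.offset_pct + shift, on + 1.0), 100.0)
        out.append(Burst(on, off, b.amplitude * amp_scale))
    return tuple(out)


#: per-condition ARV-style amplitude ratios (induced / baseline) applied to
#: the default 0.1 mV bursts.  LS = left (inductions are simulated on the
#: left), NLS = right.
_IFL_SCALES = {
    ("biceps", "right"): 1.39, ("biceps", "left"): 1.08,
    ("gluteal", "right"): 1.67, ("gluteal", "left"): 1.28,
    ("semitendinosus", "right"): 1.41, ("semitendinosus", "left"): 1.22,
    ("triceps", "right"): 0.90, ("triceps", "left"): 1.24,
    ("latissimus", "right"): 0.92, ("latissimus", "left"): 1.11,
}
_IHL_SCALES = {
    ("biceps", "right"): 3.60, ("biceps", "left"): 1.44,
    ("gluteal", "right"): 1.15, ("gluteal", "left"): 1.41,
    ("semitendinosus", "right"): 1.95, ("semitendinosus", "left"): 1.88,
    ("triceps", "right"): 1.43, ("triceps", "left"): 1.06,
    ("latissimus", "right"): 1.06, ("latissimus", "left"): 1.23,
}
_IFL_SHIFTS = {
    ("biceps", "right"): 4.0, ("gluteal", "right"): 4.0,
    ("semitendinosus", "right"): 4.0, ("gluteal", "left"): -4.0,
    ("semitendinosus", "left"): -4.0, ("triceps", "right"): -5.0,
    ("triceps", "left"): 4.0,
}
_IHL_SHIFTS = {
    ("biceps", "right"): -4.0, ("gluteal", "right"): -4.0,
    ("semitendinosus", "right"): -4.0, ("semitendinosus", "left"): -4.0,
    ("triceps", "left"): -4.0, ("latissimus", "left"): -4.0,
}


def scenario_preset(name: str) -> LamenessScenario:
    """Named study conditions.

    ``baseline`` is a symmetric trot (stride 0.77 s); ``iFL_moderate``
    injects the head-dominant asymmetry of a moderate forelimb induction
    (poll MinDiff -53.73 mm, withers MinDiff -13.14 mm, stride 0.75 s) and
    ``iHL_moderate`` the pelvis-dominant pattern of a hindlimb induction
    (pelvis MinDiff -22.25 mm, MaxDiff -27.87 mm, Hip Hike -61.73 mm,
    stride 0.71 s), with burst amplitudes rescaled per muscle and side.
    """
    base_spec = default_burst_spec()
    if name == "baseline":
        return LamenessScenario()
    if name == "iFL_moderate":
        spec = {
            (m, s): _scale_bursts(base_spec, m, s, _IFL_SCALES[(m, s)],
                                  _IFL_SHIFTS.get((m, s), 0.0))
            for m in MUSCLES for s in ("left", "right")
        }
        return LamenessScenario(
            stride_duration_mean=0.75,
            min_diff_inject={"poll": -53.73, "withers": -13.14, "pelvis": 2.22},
            max_diff_inject={"poll": -22.29, "withers": 0.0, "pelvis": 5.61},
            hip_hike_inject=13.17,
            burst_spec=spec,
            condition="iFL",
            induction_side="left",
        )
    if name == "iHL_moderate":
        spec = {
            (m, s): _scale_bursts(base_spec, m, s, _IHL_SCALES[(m, s)],
                                  _IHL_SHIFTS.get((m, s), 0.0))
            for m in MUSCLES for s in ("left", "right")
        }
        return LamenessScenario(
            stride_duration_mean=0.71,
            min_diff_inject={"poll": -8.13, "withers": 13.04, "pelvis": -22.25},
            max_diff_inject={"poll": -9.08, "withers": 0.0, "pelvis": -27.87},
            hip_hike_inject=-61.73,
            burst_spec=spec,
            condition="iHL",
            induction_side="left",
        )
    raise ConfigurationError(f"unknown scenario preset {name!r}")


# ---------------------------------------------------------------------------
# burst envelopes

def _burst_profile(p: np.ndarray, onset: float, offset: float, taper: float) -> np.ndarray:
    """Raised-cosine-edged burst window evaluated at positions ``p`` (same
    units as onset/offset); zero outside [onset, offset], unit plateau."""
    y = np.zeros_like(p, dtype=float)
    inside = (p > onset) & (p < offset)
    u = p[inside]
    w = np.ones_like(u)
    rise = u < onset + taper
    w[rise] = 0.5 * (1 - np.cos(np.pi * (u[rise] - onset) / taper))
    fall = u > offset - taper
    w[fall] = np.minimum(
        w[fall], 0.5 * (1 - np.cos(np.pi * (offset - u[fall]) / taper)))
    y[inside] = w
    return y


def burst_taper(onset_pct: float, offset_pct: float, taper_pct: float = 3.0) -> float:
    """Edge-taper width in % stride: 3% of stride, capped at a quarter of
    the burst so short bursts keep a plateau."""
    return min(taper_pct, 0.25 * ((offset_pct - onset_pct) % 100 or 100))


def make_burst_envelope(onset_pct: float, offset_pct: float, amplitude: float,
                        stride_samples: int, taper_pct: float = 3.0) -> np.ndarray:
    """Smooth burst envelope over one stride of ``stride_samples`` samples.

    The envelope is zero outside [onset, offset] % of the stride, rises and
    falls with raised-cosine edges inside the support, and peaks at
    ``amplitude``.  Samples are treated as covering half-open intervals, so
    sample i sits at (i + 0.5)/n of the stride.  If ``onset_pct >
    offset_pct`` the burst wraps across the stride boundary.
    """
    if amplitude <= 0:
        raise ConfigurationError("burst amplitude must be positive")
    p = (np.arange(stride_samples) + 0.5) * 100.0 / stride_samples
    taper = burst_taper(onset_pct, offset_pct, taper_pct)
    if onset_pct < offset_pct:
        return amplitude * _burst_profile(p, onset_pct, offset_pct, taper)
    # wrapping burst: evaluate the unwrapped support on p and p + 100
    y = _burst_profile(p, onset_pct, offset_pct + 100.0, taper)
    y += _burst_profile(p + 100.0, onset_pct, offset_pct + 100.0, taper)
    return amplitude * y


def _hann_bump(phase: np.ndarray, center: float, halfwidth: float = 0.25) -> np.ndarray:
    """Periodic unit Hann bump on stride phase, zero with zero slope at
    ``|phase - center| >= halfwidth`` (mod 1)."""
    d = (phase - center + 0.5) % 1.0 - 0.5
    out = np.zeros_like(phase, dtype=float)
    m = np.abs(d) < halfwidth
    out[m] = 0.5 * (1 + np.cos(np.pi * d[m] / halfwidth))
    return out


# ---------------------------------------------------------------------------
# trial synthesis

def _stride_plan(scenario: LamenessScenario, rng: np.random.Generator):
    """Reference-limb impact times and a continuous stride-phase function.

    Stride-to-stride durations are lognormal with the configured CV
    (positive, mildly right-skewed, like real stride timing).  Returns
    (boundaries, t_of_phase, phase_of_t) where phases are in strides.
    """
    n = scenario.n_strides
    m, cv = scenario.stride_duration_mean, scenario.stride_duration_cv
    if cv > 0:
        sigma2 = np.log(1 + cv ** 2)
        durations = rng.lognormal(np.log(m) - sigma2 / 2, np.sqrt(sigma2), n)
    else:
        durations = np.full(n, m)
    lead = 0.75 * durations[0]
    tail = 0.75 * durations[-1]
    boundaries = lead + np.concatenate(([0.0], np.cumsum(durations)))
    total = boundaries[-1] + tail
    # phase knots: extrapolate the edge strides across the lead-in/out
    t_knots = np.concatenate(([0.0], boundaries, [total]))
    ph_knots = np.concatenate(([-lead / durations[0]], np.arange(n + 1),
                               [n + tail / durations[-1]]))
    return boundaries, total, t_knots, ph_knots


def _phase(t, t_knots, ph_knots):
    return np.interp(t, t_knots, ph_knots)


def _time_at_phase(ph, t_knots, ph_knots):
    return np.interp(ph, ph_knots, t_knots)


def _landmark_wave(phase, landmark, scenario):
    A = scenario.displacement_amp[landmark]
    z = A * np.sin(4 * np.pi * phase)
    min_c, max_c = _LEFT_EXTREMA[landmark]
    d_min = scenario.min_diff_inject.get(landmark, 0.0)
    d_max = scenario.max_diff_inject.get(landmark, 0.0)
    if d_min:
        z = z + d_min * _hann_bump(phase, min_c)
    if d_max:
        z = z + d_max * _hann_bump(phase, max_c)
    return z


def _hoof_tracks(phase, limb, step_mm, swing_height=90.0):
    psi = phase - LIMB_PHASE[limb]
    frac = psi % 1.0
    swing = frac >= DUTY_FACTOR
    u = np.zeros_like(frac)
    u[swing] = (frac[swing] - DUTY_FACTOR) / (1 - DUTY_FACTOR)
    z = swing_height * np.sin(np.pi * u) * swing
    x = step_mm * (np.floor(psi) + u - np.sin(2 * np.pi * u) / (2 * np.pi))
    return x, z


_FORE_CHAIN = (  # (marker base, segment length mm, base deg, lambda weight, flex amp deg, flex phase)
    ("greater_tubercle", 350.0, -20.0, 0.3, 4.0, 0.5),
    ("elbow", 320.0, 10.0, 0.8, 8.0, 1.0),
    ("carpus", 350.0, 0.0, 0.9, 12.0, 1.4),
    ("mcp", 280.0, 0.0, 1.0, 15.0, 1.7),
)
_HIND_CHAIN = (
    ("greater_trochanter", 250.0, 15.0, 0.3, 5.0, 0.4),
    ("stifle", 400.0, -10.0, 0.7, 8.0, 0.9),
    ("tarsus", 380.0, 20.0, 0.9, 10.0, 1.3),
    ("mtp", 300.0, 0.0, 1.0, 12.0, 1.8),
)
_PRORETRACTION_AMP = 15.0  # deg, whole-limb swing about the trunk line


def _limb_chain(chain, origin_xyz, psi, animate=True):
    """Build distal markers from prescribed sagittal segment angles.

    Segment direction is (sin g, 0, -cos g) for angle g from vertical
    (cranial positive); the whole-limb pro-retraction term lam = 15 deg *
    cos(2 pi psi) peaks (protraction) at impact.
    """
    out = {}
    lam = _PRORETRACTION_AMP * np.cos(2 * np.pi * psi) if animate else 0.0
    pos = origin_xyz
    for name, length, base, wl, famp, fph in chain:
        g = base + wl * lam
        if animate:
            g = g + famp * np.sin(2 * np.pi * psi + fph)
        g = np.deg2rad(g)
        d = np.stack([np.sin(g) * np.ones_like(psi),
                      np.zeros_like(psi),
                      -np.cos(g) * np.ones_like(psi)], axis=1)
        pos = pos + length * d
        out[name] = pos
    return out


def _trunk(x, z0, zwave, y=0.0):
    n = len(x)
    return np.column_stack([x, np.full(n, y), z0 + zwave])


def simulate_trial(scenario: LamenessScenario):
    """Generate one synchronized trial and its ground truth.

    Returns ``(Trial, GroundTruth)``.  Identical scenarios (including seed)
    produce identical output.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    fs_kin, fs_emg = 200.0, 2000.0
    boundaries, total, t_knots, ph_knots = _stride_plan(scenario, rng)
    n_kin = int(round(total * fs_kin))
    n_emg = int(round(n_kin / fs_kin * fs_emg))
    t_kin = np.arange(n_kin) / fs_kin
    phase = _phase(t_kin, t_knots, ph_knots)
    speed_mm = scenario.speed * 1000.0
    x_trunk = speed_mm * t_kin
    step = speed_mm * scenario.stride_duration_mean

    markers = {}
    markers["poll"] = _trunk(x_trunk + 2200.0, 1700.0,
                             _landmark_wave(phase, "poll", scenario))
    markers["withers_T6"] = _trunk(x_trunk + 1300.0, 1650.0,
                                   _landmark_wave(phase, "withers", scenario))
    markers["tubera_sacrale"] = _trunk(x_trunk, 1520.0,
                                       _landmark_wave(phase, "pelvis", scenario))

    # tubera coxae: pelvis-like base plus the swing-phase hike bump on the
    # injected side (positive inject = left, negative = right)
    a_tc = 0.6 * scenario.displacement_amp["pelvis"]
    h = scenario.hip_hike_inject
    for side, sign, hike, center in (("L", 1.0, max(h, 0.0), 5 / 8),
                                     ("R", -1.0, max(-h, 0.0), 1 / 8)):
        z = a_tc * np.sin(4 * np.pi * phase) + hike * _hann_bump(phase, center)
        markers[f"tuber_coxae_{side}"] = _trunk(x_trunk - 100.0, 1500.0, z,
                                                y=sign * 150.0)

    for limb, y in (("FL", 120.0), ("FR", -120.0), ("HL", 150.0), ("HR", -150.0)):
        xoff = 1300.0 if limb[0] == "F" else -100.0
        hx, hz = _hoof_tracks(phase, limb, step)
        n = len(hx)
        markers[f"hoof_{limb}"] = np.column_stack(
            [hx + xoff, np.full(n, y), hz])

    # limb chains for joint angles: fore from the spina scapulae, hind from
    # the tuber coxae, both riding on the trunk
    scap_wave = 15.0 * np.sin(4 * np.pi * phase)
    for side, ysign, limb in (("L", 1.0, "FL"), ("R", -1.0, "FR")):
        origin = _trunk(x_trunk + 1250.0, 1480.0, scap_wave, y=ysign * 100.0)
        markers[f"spina_scapulae_{side}"] = origin
        psi = phase - LIMB_PHASE[limb]
        for name, pos in _limb_chain(_FORE_CHAIN, origin, psi).items():
            markers[f"{name}_{side}"] = pos
    for side, ysign, limb in (("L", 1.0, "HL"), ("R", -1.0, "HR")):
        origin = markers[f"tuber_coxae_{side}"]
        psi = phase - LIMB_PHASE[limb]
        for name, pos in _limb_chain(_HIND_CHAIN, origin, psi).items():
            markers[f"{name}_{side}"] = pos

    if scenario.kinematic_noise_sd > 0:
        for name in sorted(markers):
            markers[name] = markers[name] + rng.normal(
                0.0, scenario.kinematic_noise_sd, markers[name].shape)

    marker_objs = {name: MarkerTrajectory(name, xyz)
                   for name, xyz in markers.items()}

    # ---- ground-truth gait events -------------------------------------
    ph_lo = ph_knots[0] + 1e-9
    ph_hi = ph_knots[-1] - 1e-9
    impacts, liftoffs = {}, {}
    for limb, delta in LIMB_PHASE.items():
        ks = np.arange(np.ceil(ph_lo - delta), np.floor(ph_hi - delta) + 1)
        impacts[limb] = _time_at_phase(ks + delta, t_knots, ph_knots)
        lo = ks + delta + DUTY_FACTOR
        lo = lo[lo <= ph_hi]
        liftoffs[limb] = _time_at_phase(lo, t_knots, ph_knots)

    # ---- EMG synthesis -------------------------------------------------
    t_emg = np.arange(n_emg) / fs_emg
    emg, emg_truth, seg_windows = {}, {}, {}
    for muscle in MUSCLES:
        for side in ("left", "right"):
            seg_limb = "HR" if side == "left" else "HL"
            times = impacts[seg_limb]
            windows = list(zip(times[:-1], times[1:]))
            bursts = scenario.burst_spec[(muscle, side)]
            floor = scenario.emg_noise_floor * max(b.amplitude for b in bursts)
            modulator = np.full(n_emg, floor)
            for (t0, t1) in windows:
                sel = (t_emg >= t0) & (t_emg < t1)
                p = (t_emg[sel] - t0) / (t1 - t0) * 100.0
                for b in bursts:
                    taper = burst_taper(b.onset_pct, b.offset_pct)
                    modulator[sel] += b.amplitude * _burst_profile(
                        p, b.onset_pct, b.offset_pct, taper)
            carrier = zero_phase(rng.standard_normal(n_emg), (20.0, 450.0),
                                 fs_emg, btype="bandpass")
            carrier /= carrier.std()
            samples = modulator * carrier + 0.01  # small DC offset, as in raw sEMG
            emg[f"{muscle}_{side}"] = EMGChannel(muscle, side, samples)
            emg_truth[f"{muscle}_{side}"] = _operational_bursts(
                t_emg, modulator, windows,
                min_dur=0.05 * scenario.stride_duration_mean)
            seg_windows[f"{muscle}_{side}"] = windows

    meta = TrialMeta(subject_id=scenario.subject_id, condition=scenario.condition,
                     induction_side=scenario.induction_side,
                     fs_kin=fs_kin, fs_emg=fs_emg,
                     trial_id=f"{scenario.condition}_seed{scenario.seed}")
    trial = Trial(meta, marker_objs, emg)
    truth = GroundTruth(
        impact_times=impacts,
        liftoff_times=liftoffs,
        min_diff=dict(scenario.min_diff_inject),
        max_diff=dict(scenario.max_diff_inject),
        hip_hike=scenario.hip_hike_inject,
        emg_bursts=emg_truth,
        seg_windows=seg_windows,
        stride_boundaries=boundaries,
    )
    return trial, truth


def _operational_bursts(t_emg, modulator, windows, min_dur: float,
                        fs: float = 2000.0, envelope_hz: float = 10.0):
    """Per-stride ground-truth activation timings.

    Activation onset/offset are *defined* on the enveloped signal with
    both thresholds of the double-threshold rule: the crossing of 10% of
    the peak of the 10 Hz linear envelope, with sub-threshold dips shorter
    than the timing threshold merged and bursts shorter than it dropped.
    The truth is therefore obtained by applying that definition to the
    noise-free modulation profile (``min_dur`` = 5% of the scenario's mean
    stride duration, in seconds).
    """
    from .semg import _merge_dips, _runs  # shared run/merge primitives

    modulator = np.clip(zero_phase(modulator, envelope_hz, fs), 0.0, None)
    thr = 0.10 * modulator.max()
    per_stride = []
    for (t0, t1) in windows:
        sel = (t_emg >= t0) & (t_emg < t1)
        m = modulator[sel]
        tt = t_emg[sel]
        runs = _merge_dips(_runs(m > thr), tt, min_dur)
        rec = []
        for s, e in runs:
            if (e - s) / fs < min_dur:
                continue
            rec.append({
                "onset_pct": float((tt[s] - t0) / (t1 - t0) * 100.0),
                "offset_pct": float((tt[e - 1] - t0) / (t1 - t0) * 100.0),
                "amplitude": float(m[s:e].max()),
            })
        per_stride.append(rec)
    return per_stride


def simulate_static(scenario: LamenessScenario, duration: float = 1.0):
    """A standing-pose trial (no motion) for joint-angle referencing."""
    rng = np.random.default_rng(scenario.seed + 1)
    fs_kin, fs_emg = 200.0, 2000.0
    n_kin = int(round(duration * fs_kin))
    n_emg = int(round(duration * fs_emg))
    zeros = np.zeros(n_kin)
    markers = {}
    markers["poll"] = _trunk(np.full(n_kin, 2200.0), 1700.0, zeros)
    markers["withers_T6"] = _trunk(np.full(n_kin, 1300.0), 1650.0, zeros)
    markers["tubera_sacrale"] = _trunk(np.full(n_kin, 0.0), 1520.0, zeros)
    for side, ysign in (("L", 1.0), ("R", -1.0)):
        markers[f"tuber_coxae_{side}"] = _trunk(
            np.full(n_kin, -100.0), 1500.0, zeros, y=ysign * 150.0)
        origin = _trunk(np.full(n_kin, 1250.0), 1480.0, zeros, y=ysign * 100.0)
        markers[f"spina_scapulae_{side}"] = origin
        for name, pos in _limb_chain(_FORE_CHAIN, origin, zeros, animate=False).items():
            markers[f"{name}_{side}"] = pos
        for name, pos in _limb_chain(_HIND_CHAIN, markers[f"tuber_coxae_{side}"],
                                     zeros, animate=False).items():
            markers[f"{name}_{side}"] = pos
    for limb, y in (("FL", 120.0), ("FR", -120.0), ("HL", 150.0), ("HR", -150.0)):
        xoff = 1300.0 if limb[0] == "F" else -100.0
        markers[f"hoof_{limb}"] = np.column_stack(
            [np.full(n_kin, xoff), np.full(n_kin, y), np.zeros(n_kin)])
    marker_objs = {n: MarkerTrajectory(n, xyz) for n, xyz in markers.items()}
    emg = {f"{m}_{s}": EMGChannel(m, s, 0.001 * rng.standard_normal(n_emg))
           for m in MUSCLES for s in ("left", "right")}
    meta = TrialMeta(subject_id=scenario.subject_id, condition="baseline1",
                     induction_side="none", trial_id="static")
    return Trial(meta, marker_objs, emg)


def noiseless(scenario: LamenessScenario) -> LamenessScenario:
    """Copy of a scenario with kinematic noise and the EMG floor removed."""
    return replace(scenario, kinematic_noise_sd=0.0, emg_noise_floor=0.0,
                   stride_duration_cv=0.0)
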