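"""Surface-EMG conditioning, stride ARV, RVC normalization, and
double-threshold activation detection.

The conditioning chain is: DC-offset removal, zero-phase 4th-order
Butterworth high-pass at 40 Hz (movement-artifact suppression), full-wave
rectification, and two linear envelopes of the rectified signal (25 Hz for
amplitude-normalized stride curves, 10 Hz for activation timing).

Amplitude summaries are per-stride average rectified values (ARV) with the
stride of the *contralateral* hindlimb as the temporal domain (in trot the
contralateral hind impacts together with the muscle's own forelimb, so the
muscle's limb cycle starts at 0% of the segmentation stride).  ARVs are
normalized to a reference voluntary contraction (RVC): the maximum
non-outlier baseline-stride value for that muscle and side, so induced
conditions may exceed 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._filters import zero_phase
from .errors import ConfigurationError, NormalizationError
from .io_model import EMGChannel

HIGHPASS_HZ = 40.0
ENVELOPE_NORM_HZ = 25.0   # envelope for amplitude-normalized stride curves
ENVELOPE_TIMING_HZ = 10.0  # envelope for activation timing
OUTLIER_SD = 2.0
AMP_FRACTION = 0.10       # activation amplitude threshold, fraction of peak
TIMING_FRACTION = 0.05    # minimum burst duration, fraction of baseline stride


@dataclass
class ProcessedEMG:
    """Conditioned versions of one channel, all at the input rate."""

    muscle: str
    side: str
    fs: float
    filtered: np.ndarray    # DC-removed, 40 Hz high-passed, mV
    rectified: np.ndarray   # |filtered|
    envelope25: np.ndarray  # 25 Hz linear envelope of rectified
    envelope10: np.ndarray  # 10 Hz linear envelope of rectified

    @property
    def name(self):
        return f"{self.muscle}_{self.side}"


def preprocess_emg(raw: EMGChannel, fs: float) -> ProcessedEMG:
    """Run the full conditioning chain on one raw channel.

    Envelopes are clipped at zero: zero-phase low-passing a rectified
    signal can undershoot slightly, and downstream thresholds assume
    non-negative envelopes.
    """
    if fs < 2 * HIGHPASS_HZ:
        raise ConfigurationError(f"fs={fs} Hz too low for the 40 Hz high-pass")
    x = raw.samples - raw.samples.mean()
    filtered = zero_phase(x, HIGHPASS_HZ, fs, btype="high")
    rectified = np.abs(filtered)
    env25 = np.clip(zero_phase(rectified, ENVELOPE_NORM_HZ, fs), 0.0, None)
    env10 = np.clip(zero_phase(rectified, ENVELOPE_TIMING_HZ, fs), 0.0, None)
    return ProcessedEMG(raw.muscle, raw.side, fs, filtered, rectified, env25, env10)


def segmentation_limb(side: str) -> str:
    """Contralateral hindlimb used for stride segmentation of a channel."""
    return "HR" if side == "left" else "HL"


def stride_arv(proc: ProcessedEMG, stride_windows, subject_id: str = "",
               condition: str = "") -> pd.DataFrame:
    """Per-stride ARV (mean of the rectified signal over each window).

    ``stride_windows`` must come from the hindlimb contralateral to the
    channel's side.  Also records each stride's peak 25 Hz envelope value
    (used later for the envelope RVC).
    """
    t = np.arange(len(proc.rectified)) / proc.fs
    rows = []
    for k, (t0, t1) in enumerate(stride_windows):
        sel = (t >= t0) & (t < t1)
        if not sel.any():
            raise ConfigurationError(f"empty stride window [{t0}, {t1})")
        rows.append({
            "subject": subject_id, "condition": condition,
            "muscle": proc.muscle, "side": proc.side, "stride_index": k,
            "arv_raw": float(proc.rectified[sel].mean()),
            "env25_peak": float(proc.envelope25[sel].max()),
            "outlier": False,
        })
    return pd.DataFrame(rows)


def flag_arv_outliers(records: pd.DataFrame, value_col: str = "arv_raw",
                      flag_col: str = "outlier") -> pd.DataFrame:
    """Flag values strictly outside mean +/- 2 SD within each
    (subject, muscle, side, condition) group.

    SD uses the n-1 estimator; a single pass, no re-iteration; groups
    smaller than 3 are left unflagged.  Values at exactly the limits are
    kept (strictly-outside rule).
    """
    out = records.copy()
    out[flag_col] = False
    for _, idx in out.groupby(["subject", "muscle", "side", "condition"]).groups.items():
        vals = out.loc[idx, value_col]
        if len(vals) < 3:
            continue
        mu, sd = vals.mean(), vals.std(ddof=1)
        out.loc[idx, flag_col] = (vals < mu - OUTLIER_SD * sd) | (vals > mu + OUTLIER_SD * sd)
    return out


def arv_rvc(baseline_records: pd.DataFrame) -> dict:
    """ARV reference per (muscle, side): max non-outlier baseline ARV."""
    ok = baseline_records[~baseline_records["outlier"]]
    rvc = {}
    for (muscle, side), grp in ok.groupby(["muscle", "side"]):
        rvc[(muscle, side)] = float(grp["arv_raw"].max())
    return rvc


def envelope_rvc(baseline_records: pd.DataFrame) -> dict:
    """Envelope reference per (muscle, side): max baseline stride peak of
    the 25 Hz envelope after excluding ARV outliers *and* a second 2-SD
    outlier pass on the peak amplitudes themselves."""
    ok = baseline_records[~baseline_records["outlier"]].copy()
    ok = flag_arv_outliers(ok, value_col="env25_peak", flag_col="peak_outlier")
    ok = ok[~ok["peak_outlier"]]
    rvc = {}
    for (muscle, side), grp in ok.groupby(["muscle", "side"]):
        rvc[(muscle, side)] = float(grp["env25_peak"].max())
    return rvc


def rvc_normalize(records: pd.DataFrame, rvc: dict,
                  value_col: str = "arv_raw", out_col: str = "arv_norm_pct") -> pd.DataFrame:
    """Express values as a percentage of the (muscle, side) reference.

    Induced-condition values may exceed 100% (the RVC is submaximal).
    Raises :class:`NormalizationError` if a channel has no reference.
    """
    out = records.copy()
    pct = np.empty(len(out))
    for i, (_, row) in enumerate(out.iterrows()):
        key = (row["muscle"], row["side"])
        if key not in rvc or rvc[key] <= 0:
            raise NormalizationError(f"no surviving baseline strides for {key}")
        pct[i] = 100.0 * row[value_col] / rvc[key]
    out[out_col] = pct
    return out


# ---------------------------------------------------------------------------
# double-threshold activation detection

@dataclass
class ActivationEvents:
    """Detected bursts per stride: onset/offset/duration in % stride."""

    records: pd.DataFrame  # stride_index, burst_index, onset_pct, offset_pct, duration_pct

    @property
    def burst_count(self) -> int:
        return len(self.records)

    def strides(self):
        return self.records.groupby("stride_index")


def detect_activation(envelope10: np.ndarray, fs: float, stride_windows,
                      baseline_mean_stride_duration: float,
                      amp_fraction: float = AMP_FRACTION,
                      timing_fraction: float = TIMING_FRACTION) -> ActivationEvents:
    """Double-threshold burst detector on the 10 Hz envelope.

    A sample is a candidate when the envelope exceeds ``amp_fraction`` of
    the signal's peak envelope value (per-trial peak; relative, so the
    detector is invariant to positive rescaling).  Within each stride,
    sub-threshold dips shorter than ``timing_fraction`` of the baseline
    mean stride duration are merged into the surrounding burst, then
    candidate bursts shorter than that same timing threshold are
    discarded.  ``amp_fraction`` may be adjusted by +/-0.05 per channel via
    configuration; it is never auto-adjusted.  A flat-zero envelope yields
    zero bursts (not an error).
    """
    if not (0 < amp_fraction < 1):
        raise ConfigurationError("amp_fraction must be in (0, 1)")
    if baseline_mean_stride_duration <= 0:
        raise ConfigurationError("baseline mean stride duration must be positive")
    peak = float(np.max(envelope10)) if len(envelope10) else 0.0
    t = np.arange(len(envelope10)) / fs
    min_dur = timing_fraction * baseline_mean_stride_duration  # seconds
    rows = []
    for k, (t0, t1) in enumerate(stride_windows):
        sel = (t >= t0) & (t < t1)
        seg = envelope10[sel]
        ts = t[sel]
        if seg.size == 0 or peak <= 0:
            continue
        active = seg > amp_fraction * peak
        runs = _runs(active)
        runs = _merge_dips(runs, ts, min_dur)
        # burst duration counted in whole samples so that a burst spanning
        # exactly the timing threshold is retained despite float rounding
        for j, (s, e) in enumerate(r for r in runs
                                   if (r[1] - r[0]) / fs >= min_dur):
            onset = (ts[s] - t0) / (t1 - t0) * 100.0
            offset = (ts[e - 1] - t0) / (t1 - t0) * 100.0
            rows.append({"stride_index": k, "burst_index": j,
                         "onset_pct": onset, "offset_pct": offset,
                         "duration_pct": offset - onset})
    cols = ["stride_index", "burst_index", "onset_pct", "offset_pct", "duration_pct"]
    return ActivationEvents(pd.DataFrame(rows, columns=cols))


def _runs(mask: np.ndarray):
    """(start, stop) pairs of contiguous True runs, stop exclusive."""
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d > 0) + 1)
    stops = list(np.flatnonzero(d < 0) + 1)
    if mask.size and mask[0]:
        starts.insert(0, 0)
    if mask.size and mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _merge_dips(runs, ts, min_dur):
    """Merge consecutive runs separated by gaps shorter than ``min_dur``."""
    if not runs:
        return runs
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        gap = ts[s] - ts[merged[-1][1] - 1]
        if gap < min_dur:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [tuple(r) for r in merged]
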