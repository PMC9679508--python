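"""Zero-phase Butterworth filtering shared by the kinematic and sEMG chains.

All filters in the pipeline are 4th-order Butterworth designs applied
forward-backward (``sosfiltfilt``), i.e. zero phase lag and a squared
magnitude response.  Zero-phase filtering is essential here: activation
onsets and kinematic events are compared across signals filtered with
different cutoffs, so any phase lag would bias timing estimates.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .errors import ConfigurationError, FilteringError


def butter_sos(cutoff_hz, fs: float, btype: str = "low", order: int = 4):
    """Design a Butterworth filter in second-order sections.

    ``cutoff_hz`` may be a scalar (low/high-pass) or a 2-sequence (band-pass).
    Raises :class:`ConfigurationError` if any cutoff reaches the Nyquist
    frequency.
    """
    nyq = fs / 2.0
    c = np.atleast_1d(np.asarray(cutoff_hz, dtype=float))
    if np.any(c <= 0) or np.any(c >= nyq):
        raise ConfigurationError(
            f"cutoff {cutoff_hz} Hz outside (0, {nyq}) Hz at fs={fs} Hz"
        )
    wn = c / nyq
    return signal.butter(order, wn if wn.size > 1 else wn[0], btype=btype, output="sos")


def zero_phase(x, cutoff_hz, fs: float, btype: str = "low", order: int = 4, axis: int = -1):
    """Forward-backward (zero-phase) Butterworth filter along ``axis``.

    The edge padding is scaled to the filter's settling time (three time
    constants of the lowest cutoff); the default pad of ``sosfiltfilt`` is
    far too short for the sub-hertz high-pass used on displacement data
    and would leak transients into the first and last strides.
    """
    sos = butter_sos(cutoff_hz, fs, btype=btype, order=order)
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    settle = 3 * (2 * sos.shape[0] + 1)  # sosfiltfilt's own minimum pad
    if n <= settle:
        raise FilteringError(
            f"signal of {n} samples shorter than the {settle}-sample settling length")
    padlen = min(n - 2, max(settle, int(3 * fs / np.min(cutoff_hz))))
    try:
        return signal.sosfiltfilt(sos, x, axis=axis, padlen=padlen)
    except ValueError as exc:  # signal shorter than the settling pad
        raise FilteringError(str(exc)) from exc
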