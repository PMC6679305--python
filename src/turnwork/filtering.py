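"""Zero-lag Butterworth filtering shared by the mocap and IMU stages."""
from __future__ import annotations

import numpy as np
from scipy import signal as sps


def zero_lag_lowpass(x, fs: float, fc: float, order: int = 2):
    """Forward-backward (zero phase) Butterworth low-pass filter.

    The filter is applied once forward and once backward, which cancels the
    phase response: a sinusoid below the cut-off passes with zero group
    delay.  The effective magnitude response is the squared single-pass
    response, so the -3 dB point of one pass becomes -6 dB.

    Parameters
    ----------
    x : array-like
        Signal (filtered along the last axis).
    fs : float
        Sampling rate, Hz.
    fc : float
        Cut-off frequency of the underlying causal design, Hz; must be
        below the Nyquist frequency.
    order : int
        Order of the underlying causal Butterworth filter.
    """
    x = np.asarray(x, dtype=float)
    if not fc < fs / 2.0:
        raise ValueError(f"cut-off {fc} Hz must be below Nyquist ({fs / 2.0} Hz)")
    if fc <= 0:
        raise ValueError("cut-off must be positive")
    sos = sps.butter(order, fc, btype="low", fs=fs, output="sos")
    # extend the reflective padding to ~3 time constants of the cut-off so
    # that slow filters (e.g. 0.5 Hz on 512 Hz data) settle before the data
    padlen = int(min(x.shape[-1] - 1, max(3 * fs / fc, 24)))
    return sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen)
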