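"""Zero-phase Butterworth / notch conditioning chain.

Signals are filtered forward-backward (`sosfiltfilt`) so the chain is
phase-free; because two passes double the attenuation, the Butterworth
cutoffs are pre-warped by the standard two-pass correction factor
``(sqrt(2)-1)^(1/(2n))`` so the -3 dB point of the *combined* response
stays at the requested cutoff. Sections default to order 2
(12 dB/octave per pass).
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = ["butterworth_chain"]


def _corrected(cutoff: float, order: int, kind: str) -> float:
    c = (np.sqrt(2.0) - 1.0) ** (1.0 / (2.0 * order))
    return cutoff / c if kind == "low" else cutoff * c


def butterworth_chain(
    x: np.ndarray,
    fs: float,
    lowpass_hz: float | None = None,
    highpass_hz: float | None = None,
    notch_hz: float | None = None,
    order: int = 2,
    notch_q: float = 30.0,
    correct_cutoff: bool = True,
) -> np.ndarray:
    """Apply the requested cascade (notch, then high-pass, then low-pass).

    Parameters
    ----------
    x : array
        Uniformly sampled trace.
    fs : float
        Sampling rate in Hz.
    lowpass_hz, highpass_hz, notch_hz : float, optional
        Cutoff / notch frequencies; each must lie below Nyquist.
    order : int
        Butterworth section order (2 gives a 12 dB/octave slope per pass).
    notch_q : float
        Quality factor of the IIR notch.
    correct_cutoff : bool
        Pre-warp cutoffs so the two-pass -3 dB point sits at the request.
    """
    x = np.asarray(x, dtype=float)
    nyq = fs / 2.0
    for name, f in (("lowpass", lowpass_hz), ("highpass", highpass_hz), ("notch", notch_hz)):
        if f is not None and f >= nyq:
            raise ValueError(f"{name} frequency {f} Hz >= Nyquist {nyq} Hz")
    y = x
    if notch_hz is not None:
        b, a = signal.iirnotch(notch_hz, Q=notch_q, fs=fs)
        y = signal.filtfilt(b, a, y)
    if highpass_hz is not None:
        fc = _corrected(highpass_hz, order, "high") if correct_cutoff else highpass_hz
        sos = signal.butter(order, fc, btype="highpass", fs=fs, output="sos")
        y = signal.sosfiltfilt(sos, y)
    if lowpass_hz is not None:
        fc = _corrected(lowpass_hz, order, "low") if correct_cutoff else lowpass_hz
        fc = min(fc, 0.999 * nyq)
        sos = signal.butter(order, fc, btype="lowpass", fs=fs, output="sos")
        y = signal.sosfiltfilt(sos, y)
    return y
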