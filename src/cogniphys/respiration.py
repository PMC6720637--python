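"""Respiratory metrics from strain-gauge volume traces.

Breathing rate (BR, breaths/min), tidal volume (TV, mL, peak-to-trough
per cycle) and minute ventilation (MV = BR x mean TV, L/min) from a
quasi-periodic volume trace. Cycles are located by alternating
peak/trough detection on the 1 Hz low-pass-filtered trace with a 1 s
minimum spacing (breathing rates below 60/min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .filters import butterworth_chain

__all__ = ["RespirationSignal", "RespSummary", "respiration_metrics"]


@dataclass
class RespirationSignal:
    """Volume trace: t in seconds (strictly increasing), volume in mL."""

    t: np.ndarray
    volume: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if len(self.t) != len(self.volume):
            raise ValueError("t and volume lengths differ")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class RespSummary:
    br: float  # breaths/min
    tv_mean: float  # mL
    mv: float  # L/min
    cycles: list[tuple[float, float, float]]  # (t_peak, t_trough, tv_i)


def respiration_metrics(
    resp: RespirationSignal,
    lowpass_hz: float = 1.0,
    min_cycle_spacing: float = 1.0,
) -> RespSummary:
    """Cycle-by-cycle BR / TV / MV summary.

    Each cycle pairs a detected peak with the most recent preceding
    trough; ``TV_i`` is the filtered peak-to-trough excursion. BR is the
    reciprocal mean peak-to-peak period (unbiased by partial cycles at
    the record edges); MV is ``BR * mean(TV) / 1000``.
    """
    fs = resp.sampling_rate
    v = resp.volume
    if fs > 2.5 * lowpass_hz:
        v = butterworth_chain(v, fs=fs, lowpass_hz=lowpass_hz, order=4)
    rng = float(v.max() - v.min())
    if rng <= 0:
        raise ValueError("no cycles: flat trace")
    dist = max(1, int(min_cycle_spacing * fs))
    prom = 0.1 * rng
    peaks, _ = signal.find_peaks(v, distance=dist, prominence=prom)
    troughs, _ = signal.find_peaks(-v, distance=dist, prominence=prom)
    cycles: list[tuple[float, float, float]] = []
    for p in peaks:
        prior = troughs[troughs < p]
        if prior.size:
            tr = prior[-1]
            cycles.append((float(resp.t[p]), float(resp.t[tr]), float(v[p] - v[tr])))
    if len(cycles) < 2 or len(peaks) < 2:
        raise ValueError("no cycles: fewer than 2 detectable breaths")
    period = float(np.mean(np.diff(resp.t[peaks])))
    br = 60.0 / period
    tv_mean = float(np.mean([c[2] for c in cycles]))
    return RespSummary(br=br, tv_mean=tv_mean, mv=br * tv_mean / 1000.0, cycles=cycles)
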