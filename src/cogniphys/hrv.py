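"""Heart-rate-variability metrics from inter-beat (RR) interval series.

Time-domain (SDRR, SDNN, RMSSD, pNN50), frequency-domain (band powers of
the RR tachogram over the standard ULF/VLF/LF/HF bands) and geometric
(Poincare SD1/SD2 with the fitted ellipse) summaries. The cardiac entry
point is the RR series itself; R-peak detection from raw ECG is out of
scope.

Frequency analysis of the unevenly sampled tachogram is available through
two selectable estimators: a Lomb-Scargle periodogram evaluated directly
on beat-stamped intervals, and cubic-spline resampling at 4 Hz followed by
a Welch periodogram. For stationary tachograms the two agree closely; the
choice is configuration, not substance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import interpolate, signal

logger = logging.getLogger(__name__)

__all__ = [
    "RRSeries",
    "NNSeries",
    "HRVTimeDomain",
    "HRVFrequencyDomain",
    "PoincareSummary",
    "BANDS",
    "clean_nn",
    "hrv_time_domain",
    "hrv_frequency_domain",
    "poincare_summary",
    "poincare_windows",
]

#: Standard tachogram frequency bands in Hz (lower, upper].
BANDS: dict[str, tuple[float, float]] = {
    "ulf": (0.0, 0.003),
    "vlf": (0.003, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.4),
}


@dataclass
class RRSeries:
    """Inter-beat intervals in milliseconds."""

    rr: np.ndarray

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if self.rr.size == 0:
            raise ValueError("empty RR series")
        if np.any(self.rr <= 0):
            raise ValueError("RR intervals must be > 0")

    @property
    def t_onset(self) -> np.ndarray:
        """Cumulative beat times in seconds (end of each interval)."""
        return np.cumsum(self.rr) / 1000.0

    @property
    def duration(self) -> float:
        return float(self.rr.sum() / 1000.0)

    def __len__(self) -> int:
        return len(self.rr)


@dataclass
class NNSeries:
    """Normal-to-normal intervals (RR with abnormal beats removed)."""

    nn: np.ndarray
    rejected_count: int = 0

    def __post_init__(self) -> None:
        self.nn = np.asarray(self.nn, dtype=float)

    def __len__(self) -> int:
        return len(self.nn)


@dataclass(frozen=True)
class HRVTimeDomain:
    mean_hr: float  # beats/min
    sdrr: float  # ms
    sdnn: float  # ms
    rmssd: float  # ms
    pnn50: float  # %


@dataclass(frozen=True)
class HRVFrequencyDomain:
    ulf: float  # ms^2
    vlf: float  # ms^2
    lf: float  # ms^2
    hf: float  # ms^2
    lf_pct: float  # % of total 0-0.4 Hz power
    hf_pct: float  # %
    lf_hf: float  # LF/HF ratio expressed in %
    method: str = "lomb"
    notes: tuple[str, ...] = ()


@dataclass
class PoincareSummary:
    """SD1/SD2 dispersion of the RR(i+1)-vs-RR(i) scatter."""

    sd1: float  # ms
    sd2: float  # ms
    centre: tuple[float, float]  # (mean RR_i, mean RR_{i+1}) in ms

    def ellipse(self, n_points: int = 100) -> np.ndarray:
        """Points of the fitted ellipse, rotated pi/4 about the centre.

        Returns an (n_points, 2) array traced over theta in (0, 2*pi).
        """
        theta = np.linspace(0, 2 * np.pi, n_points, endpoint=False)[1:]
        rot = np.array(
            [
                [np.cos(np.pi / 4), -np.sin(np.pi / 4)],
                [np.sin(np.pi / 4), np.cos(np.pi / 4)],
            ]
        )
        body = np.vstack([self.sd2 * np.cos(theta), self.sd1 * np.sin(theta)])
        pts = 2.0 * rot @ body
        return pts.T + np.asarray(self.centre)


# ---------------------------------------------------------------------------


def clean_nn(
    rr: RRSeries,
    bounds: tuple[float, float] = (300.0, 2000.0),
    max_rel_jump: float = 0.3,
) -> NNSeries:
    """Remove abnormal beats, yielding a normal-to-normal series.

    An interval is rejected when it falls outside ``bounds`` (ms) or
    deviates from the median of its 5 nearest neighbours by more than
    ``max_rel_jump`` (relative). A rejection fraction above 20% is
    logged as a warning.
    """
    x = rr.rr
    n = len(x)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        if not (bounds[0] <= x[i] <= bounds[1]):
            keep[i] = False
            continue
        lo, hi = max(0, i - 2), min(n, i + 3)
        neigh = np.delete(x[lo:hi], i - lo)
        if neigh.size:
            med = float(np.median(neigh))
            if med > 0 and abs(x[i] - med) / med > max_rel_jump:
                keep[i] = False
    rejected = int(n - keep.sum())
    if rejected > 0.2 * n:
        logger.warning("clean_nn rejected %d of %d intervals (>20%%)", rejected, n)
    return NNSeries(nn=x[keep], rejected_count=rejected)


def hrv_time_domain(rr: RRSeries, nn: NNSeries | None = None) -> HRVTimeDomain:
    """Time-domain HRV metrics.

    Mean heart rate is 60 over the mean RR interval in seconds; SDRR and
    SDNN use the sample (n-1) denominator; RMSSD averages the n-1 squared
    successive RR differences; pNN50 counts strict ``> 50 ms`` successive
    NN differences. With a single interval the dispersion metrics are
    reported as NaN while the heart rate is still computed.
    """
    x = rr.rr
    nn_x = nn.nn if nn is not None else x
    mean_hr = 60.0 / (float(x.mean()) / 1000.0)
    if len(x) < 2:
        return HRVTimeDomain(mean_hr, np.nan, np.nan, np.nan, np.nan)
    sdrr = float(np.std(x, ddof=1))
    sdnn = float(np.std(nn_x, ddof=1)) if len(nn_x) >= 2 else np.nan
    rmssd = float(np.sqrt(np.mean(np.diff(x) ** 2)))
    if len(nn_x) >= 2:
        dn = np.abs(np.diff(nn_x))
        pnn50 = 100.0 * float(np.mean(dn > 50.0))
    else:
        pnn50 = np.nan
    return HRVTimeDomain(mean_hr, sdrr, sdnn, rmssd, pnn50)


def _lomb_band_powers(t: np.ndarray, y: np.ndarray) -> dict[str, float]:
    n = len(y)
    span = float(t[-1] - t[0])
    var = float(y.var())
    if var < 1e-12:
        return {b: 0.0 for b in BANDS}
    df = 1.0 / (10.0 * span)
    f_nyq = max(0.5, n / (2.0 * span))
    freqs = np.arange(df, f_nyq + df, df)
    pgram = signal.lombscargle(t, y, 2 * np.pi * freqs)
    # scale so the integral over the full grid equals the series variance
    alpha = var / float(pgram.sum() * df)
    out = {}
    for name, (lo, hi) in BANDS.items():
        mask = (freqs > lo) & (freqs <= hi)
        out[name] = float(alpha * pgram[mask].sum() * df)
    return out


def _welch_band_powers(t: np.ndarray, y: np.ndarray, fs: float = 4.0) -> dict[str, float]:
    var = float(y.var())
    if var < 1e-12:
        return {b: 0.0 for b in BANDS}
    cs = interpolate.CubicSpline(t, y)
    tu = np.arange(t[0], t[-1], 1.0 / fs)
    yu = cs(tu)
    yu = yu - yu.mean()
    nperseg = int(min(len(yu), 1024))
    f, pxx = signal.welch(yu, fs=fs, nperseg=nperseg)
    # normalise so the full-spectrum integral equals the variance of the
    # original beat-stamped series (same convention as the Lomb estimator);
    # undoes the slight broadband attenuation of spline resampling
    total = float(np.trapezoid(pxx, f))
    if total > 0:
        pxx = pxx * (var / total)
    out = {}
    for name, (lo, hi) in BANDS.items():
        mask = (f > lo) & (f <= hi)
        out[name] = float(np.trapezoid(pxx[mask], f[mask])) if mask.sum() > 1 else 0.0
    return out


def hrv_frequency_domain(
    rr: RRSeries, method: Literal["lomb", "welch"] = "lomb"
) -> HRVFrequencyDomain:
    """Band powers of the RR tachogram over the standard bands.

    LF and HF (and their derived ratios) require at least a 2-minute
    record; ULF and VLF require at least 5 minutes and are reported NaN
    with a note below that. Relative powers are taken against the total
    0-0.4 Hz power.
    """
    t = rr.t_onset
    y = rr.rr - rr.rr.mean()
    span = float(t[-1] - t[0])
    notes: list[str] = []
    if span < 120.0:
        raise ValueError(
            f"record of {span:.0f} s too short for LF/HF analysis (needs >= 120 s)"
        )
    if method == "lomb":
        powers = _lomb_band_powers(t, y)
    elif method == "welch":
        powers = _welch_band_powers(t, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    if span < 300.0:
        powers["ulf"] = np.nan
        powers["vlf"] = np.nan
        notes.append("ulf/vlf absent: record shorter than 5 minutes")
    total = np.nansum([powers[b] for b in BANDS])
    lf, hf = powers["lf"], powers["hf"]
    lf_pct = 100.0 * lf / total if total > 0 else 0.0
    hf_pct = 100.0 * hf / total if total > 0 else 0.0
    lf_hf = 100.0 * lf / hf if hf > 0 else np.nan
    return HRVFrequencyDomain(
        ulf=powers["ulf"],
        vlf=powers["vlf"],
        lf=lf,
        hf=hf,
        lf_pct=lf_pct,
        hf_pct=hf_pct,
        lf_hf=lf_hf,
        method=method,
        notes=tuple(notes),
    )


def poincare_summary(rr: RRSeries) -> PoincareSummary:
    """Whole-record Poincare summary.

    ``SD1 = sqrt(0.5 * Var(RR_i - RR_{i+1}))`` and
    ``SD2 = sqrt(0.5 * Var(RR_i + RR_{i+1}))`` with the sample (n-1)
    variance; the ellipse is centred at the scatter mean.
    """
    x = rr.rr
    if len(x) < 3:
        raise ValueError("need at least 3 intervals")
    a, b = x[:-1], x[1:]
    sd1 = float(np.sqrt(0.5 * np.var(a - b, ddof=1)))
    sd2 = float(np.sqrt(0.5 * np.var(a + b, ddof=1)))
    return PoincareSummary(sd1=sd1, sd2=sd2, centre=(float(a.mean()), float(b.mean())))


def poincare_windows(
    rr: RRSeries, window: float = 30.0, step: float | None = None
) -> list[tuple[float, PoincareSummary]]:
    """Sliding-window Poincare summaries, ``(window start s, summary)`` pairs."""
    if step is None:
        step = window
    t = rr.t_onset
    out = []
    t0 = 0.0
    while t0 + window <= t[-1] + 1e-9:
        mask = (t > t0) & (t <= t0 + window)
        if mask.sum() >= 3:
            out.append((t0, poincare_summary(RRSeries(rr.rr[mask]))))
        t0 += step
    return out
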