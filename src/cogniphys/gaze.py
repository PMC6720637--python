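"""Oculomotor event detection and gaze-derived workload metrics.

The raw input is a :class:`GazeStream` of screen-referenced gaze angles in
degrees sampled at a declared rate. From it the module detects blinks
(runs of lost tracking), fixations (dispersion-threshold identification,
I-DT), saccades (velocity-threshold runs with physiological duration
bounds) and region-of-interest dwells, and computes the scan-path summary
statistics used in operator-workload studies: transition matrices, visual
(gaze transition) entropy, the nearest-neighbour index, the
explore/exploit ratio, pupil-dilation spectral power and blink statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "GazeStream",
    "FixationEvent",
    "SaccadeEvent",
    "DwellEvent",
    "BlinkEvent",
    "ROI",
    "ROILayout",
    "TransitionMatrix",
    "detect_blinks",
    "detect_fixations",
    "detect_saccades",
    "time_to_first_fixation",
    "explore_exploit_ratio",
    "segment_dwells",
    "transition_matrix",
    "visual_entropy",
    "nearest_neighbour_index",
    "pupil_spectral_power",
    "blink_metrics",
]


@dataclass
class GazeStream:
    """Timestamped gaze samples.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing.
    x, y : array of float
        Gaze angle in degrees (x rightward, y upward, screen-referenced).
    valid : array of bool
        False during blinks / tracking loss.
    sampling_rate : float
        Declared rate in Hz; must be consistent with the median
        inter-sample gap within 10%.
    pupil_radius : array of float, optional
        Pupil radius in mm; NaN where unavailable.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    sampling_rate: float
    pupil_radius: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.pupil_radius is not None:
            self.pupil_radius = np.asarray(self.pupil_radius, dtype=float)
        n = len(self.t)
        for name in ("x", "y", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length {len(getattr(self, name))} != t length {n}")
        if self.pupil_radius is not None and len(self.pupil_radius) != n:
            raise ValueError("pupil_radius length mismatch")
        if n == 0:
            raise ValueError("no samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if n > 1:
            gaps = np.diff(self.t)
            if np.any(gaps <= 0):
                raise ValueError("t must be strictly increasing")
            med = float(np.median(gaps))
            if abs(med - 1.0 / self.sampling_rate) > 0.1 / self.sampling_rate:
                raise ValueError(
                    f"declared sampling_rate {self.sampling_rate} Hz inconsistent with "
                    f"median inter-sample gap {med:.6g} s"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        """Record span in seconds (one sample period past the last stamp)."""
        return float(self.t[-1] - self.t[0]) + self.dt


@dataclass(frozen=True)
class FixationEvent:
    t_start: float
    t_end: float
    centroid_x: float
    centroid_y: float
    dispersion: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("fixation duration must be > 0")


@dataclass(frozen=True)
class SaccadeEvent:
    t_start: float
    t_end: float
    amplitude: float
    mean_velocity: float
    peak_velocity: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class DwellEvent:
    roi_id: str
    t_start: float
    t_end: float
    n_fixations: int

    def __post_init__(self) -> None:
        if self.t_end < self.t_start + 0.03:
            raise ValueError("dwell must last at least 30 ms")


@dataclass(frozen=True)
class BlinkEvent:
    t_start: float
    t_end: float
    partial: bool = False

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("blink duration must be > 0")


@dataclass(frozen=True)
class ROI:
    roi_id: str
    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def contains(self, x: float, y: float) -> bool:
        # closed on min edges, open on max edges
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max


@dataclass
class ROILayout:
    rois: list[ROI]

    def __post_init__(self) -> None:
        ids = [r.roi_id for r in self.rois]
        if len(set(ids)) != len(ids):
            raise ValueError("ROI ids must be unique")
        for i, a in enumerate(self.rois):
            for b in self.rois[i + 1 :]:
                if (a.x_min < b.x_max and b.x_min < a.x_max
                        and a.y_min < b.y_max and b.y_min < a.y_max):
                    raise ValueError(f"ROIs {a.roi_id} and {b.roi_id} overlap")

    @property
    def ids(self) -> list[str]:
        return [r.roi_id for r in self.rois]

    def locate(self, x: float, y: float) -> str | None:
        """ROI containing (x, y), lowest-indexed first; None if outside all."""
        for r in self.rois:
            if r.contains(x, y):
                return r.roi_id
        return None


@dataclass
class TransitionMatrix:
    """One-way ROI transition probabilities with zero diagonal."""

    roi_ids: list[str]
    P: np.ndarray
    fixation_probs: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.fixation_probs = np.asarray(self.fixation_probs, dtype=float)
        m = len(self.roi_ids)
        if self.P.shape != (m, m):
            raise ValueError("P must be square over roi_ids")
        if np.any(np.abs(np.diag(self.P)) > 0):
            raise ValueError("diagonal of P must be zero")
        if np.any((self.P < 0) | (self.P > 1)):
            raise ValueError("P entries must lie in [0, 1]")
        rows = self.P.sum(axis=1)
        if np.any((rows > 1e-9) & (np.abs(rows - 1) > 1e-9)):
            raise ValueError("each row with transitions must sum to 1")
        if abs(self.fixation_probs.sum() - 1) > 1e-9:
            raise ValueError("fixation_probs must sum to 1")


# ---------------------------------------------------------------------------
# event detection


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop inclusive."""
    out: list[tuple[int, int]] = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    stops = np.r_[idx[breaks], idx[-1]]
    return list(zip(starts.tolist(), stops.tolist()))


def detect_blinks(stream: GazeStream, max_gap: float = 0.5) -> list[BlinkEvent]:
    """Blinks as maximal invalid runs no longer than ``max_gap`` seconds.

    Runs of lost tracking longer than ``max_gap`` are classified as
    tracking loss, not blinks, and are not returned.
    """
    if len(stream) == 0:
        raise ValueError("no samples")
    lost = ~stream.valid
    if stream.pupil_radius is not None:
        lost = lost | ~np.isfinite(stream.pupil_radius)
    events = []
    for i0, i1 in _runs(lost):
        t_start = float(stream.t[i0])
        t_end = float(stream.t[i1]) + stream.dt
        if t_end - t_start <= max_gap:
            events.append(BlinkEvent(t_start=t_start, t_end=t_end))
    return events


def _dispersion(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.hypot(x.max() - x.min(), y.max() - y.min()))


def detect_fixations(
    stream: GazeStream,
    d_max: float = 1.0,
    min_duration: float = 0.1,
) -> list[FixationEvent]:
    """Dispersion-threshold (I-DT) fixation identification.

    A window of valid samples is grown while its dispersion
    ``sqrt((xmax-xmin)^2 + (ymax-ymin)^2)`` stays below ``d_max``; windows
    shorter than ``min_duration`` are discarded. Invalid (blink) samples
    are ignored.
    """
    if d_max <= 0 or min_duration <= 0:
        raise ValueError("d_max and min_duration must be > 0")
    v = stream.valid
    t, x, y = stream.t[v], stream.x[v], stream.y[v]
    dt = stream.dt
    n = len(t)
    events: list[FixationEvent] = []
    i = 0
    while i < n:
        # smallest window [i, j] covering min_duration
        j = int(np.searchsorted(t, t[i] + min_duration - dt - 1e-12))
        if j >= n:
            break
        if _dispersion(x[i : j + 1], y[i : j + 1]) >= d_max:
            i += 1
            continue
        # grow with running extrema
        xmin = x[i : j + 1].min(); xmax = x[i : j + 1].max()
        ymin = y[i : j + 1].min(); ymax = y[i : j + 1].max()
        while j + 1 < n:
            nxmin = min(xmin, x[j + 1]); nxmax = max(xmax, x[j + 1])
            nymin = min(ymin, y[j + 1]); nymax = max(ymax, y[j + 1])
            if np.hypot(nxmax - nxmin, nymax - nymin) >= d_max:
                break
            xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
            j += 1
        events.append(
            FixationEvent(
                t_start=float(t[i]),
                t_end=float(t[j]) + dt,
                centroid_x=float(x[i : j + 1].mean()),
                centroid_y=float(y[i : j + 1].mean()),
                dispersion=float(np.hypot(xmax - xmin, ymax - ymin)),
                duration=float(t[j]) + dt - float(t[i]),
            )
        )
        i = j + 1
    return events


def time_to_first_fixation(fixations: Sequence[FixationEvent], t0: float) -> float:
    """Latency from ``t0`` to the onset of the first fixation."""
    if not fixations:
        raise ValueError("no fixations")
    return fixations[0].t_start - t0


def gaze_velocity(stream: GazeStream, median_width: int = 3) -> np.ndarray:
    """Angular speed in deg/s via central differences + median filter."""
    t, x, y = stream.t, stream.x, stream.y
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    v = np.hypot(vx, vy)
    if median_width > 1 and len(v) >= median_width:
        v = signal.medfilt(v, kernel_size=median_width)
    return v


def detect_saccades(
    stream: GazeStream,
    v_threshold: float = 30.0,
    dur_bounds: tuple[float, float] = (0.03, 0.08),
) -> list[SaccadeEvent]:
    """Velocity-threshold saccade detection.

    Maximal runs with filtered speed >= ``v_threshold`` deg/s whose span
    lies within ``dur_bounds`` (30-80 ms by default) are returned.
    Mean velocity is amplitude/duration; runs touching invalid samples
    are dropped.
    """
    if stream.sampling_rate < 60:
        logger.warning(
            "sampling rate %.1f Hz < 60 Hz: saccade velocities are low-confidence",
            stream.sampling_rate,
        )
    v = gaze_velocity(stream)
    events: list[SaccadeEvent] = []
    for i0, i1 in _runs(v >= v_threshold):
        if i1 == i0:
            continue
        if not stream.valid[i0 : i1 + 1].all():
            continue
        duration = float(stream.t[i1] - stream.t[i0])
        if not (dur_bounds[0] <= duration <= dur_bounds[1]):
            continue
        amplitude = float(
            np.hypot(stream.x[i1] - stream.x[i0], stream.y[i1] - stream.y[i0])
        )
        events.append(
            SaccadeEvent(
                t_start=float(stream.t[i0]),
                t_end=float(stream.t[i1]),
                amplitude=amplitude,
                mean_velocity=amplitude / duration,
                peak_velocity=float(v[i0 : i1 + 1].max()),
            )
        )
    return events


def explore_exploit_ratio(
    fixations: Sequence[FixationEvent],
    saccades: Sequence[SaccadeEvent],
    long_fix_threshold: float = 0.5,
) -> float:
    """(saccade count + fixation count) / long-fixation count.

    A "long" fixation lasts at least ``long_fix_threshold`` seconds.
    """
    if long_fix_threshold <= 0:
        raise ValueError("long_fix_threshold must be > 0")
    n_long = sum(1 for f in fixations if f.duration >= long_fix_threshold)
    if n_long == 0:
        raise ZeroDivisionError("undefined ratio: no long fixations")
    return (len(saccades) + len(fixations)) / n_long


def segment_dwells(
    fixations: Sequence[FixationEvent], rois: ROILayout
) -> list[DwellEvent]:
    """Merge consecutive same-ROI fixations into dwells.

    Fixations whose centroid falls outside every ROI break the run and
    produce no dwell.
    """
    dwells: list[DwellEvent] = []
    cur_roi: str | None = None
    cur: list[FixationEvent] = []

    def flush() -> None:
        nonlocal cur, cur_roi
        if cur_roi is not None and cur:
            dwells.append(
                DwellEvent(
                    roi_id=cur_roi,
                    t_start=cur[0].t_start,
                    t_end=cur[-1].t_end,
                    n_fixations=len(cur),
                )
            )
        cur, cur_roi = [], None

    for f in fixations:
        roi = rois.locate(f.centroid_x, f.centroid_y)
        if roi is None:
            flush()
            continue
        if roi != cur_roi:
            flush()
            cur_roi = roi
        cur.append(f)
    flush()
    return dwells


def transition_matrix(dwells: Sequence[DwellEvent], rois: ROILayout) -> TransitionMatrix:
    """One-way transition probabilities between consecutive dwells.

    ``P[i, j]`` is the count of i->j transitions over all transitions
    leaving ROI i; self-transitions are impossible by dwell construction,
    matching the zero diagonal. ``fixation_probs`` weights each ROI by
    its total fixation count.
    """
    ids = rois.ids
    index = {r: k for k, r in enumerate(ids)}
    m = len(ids)
    counts = np.zeros((m, m))
    for a, b in zip(dwells[:-1], dwells[1:]):
        counts[index[a.roi_id], index[b.roi_id]] += 1
    row = counts.sum(axis=1, keepdims=True)
    P = np.divide(counts, row, out=np.zeros_like(counts), where=row > 0)
    fix = np.zeros(m)
    for d in dwells:
        fix[index[d.roi_id]] += d.n_fixations
    total = fix.sum()
    fixation_probs = fix / total if total > 0 else np.full(m, 1.0 / m)
    return TransitionMatrix(roi_ids=list(ids), P=P, fixation_probs=fixation_probs)


def visual_entropy(tm: TransitionMatrix) -> float:
    """Gaze transition entropy H = -sum_i p(X_i) sum_j P_ij log2 P_ij, in bits."""
    P = tm.P
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log2(P), 0.0)
    row_entropy = -terms.sum(axis=1)
    return float(np.dot(tm.fixation_probs, row_entropy))


def nearest_neighbour_index(
    fixations: Sequence[FixationEvent], area: float | None = None
) -> float:
    """Nearest-neighbour index of the fixation centroid pattern.

    Ratio of the observed mean nearest-neighbour distance to the
    complete-spatial-randomness expectation ``0.5 * sqrt(area / N)``.
    ``area`` defaults to the bounding box of the centroids.
    """
    pts = np.array([[f.centroid_x, f.centroid_y] for f in fixations], dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 fixations")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    r_a = float(d[:, 1].mean())
    if r_a == 0.0:
        return 0.0
    if area is None:
        area = float(np.ptp(pts[:, 0]) * np.ptp(pts[:, 1]))
    if area <= 0:
        raise ValueError("area must be > 0")
    r_e = 0.5 * np.sqrt(area / len(pts))
    return r_a / r_e


def pupil_spectral_power(
    stream: GazeStream, band: tuple[float, float] = (2.0, 6.0)
) -> float:
    """Pupil-radius spectral power integrated over ``band`` (Hz).

    Welch periodogram (Hann window, 4 s segments, 50% overlap) of the
    pupil-radius trace with blink gaps linearly interpolated; the
    one-sided density is integrated over the band. Units: radius^2.
    """
    if stream.pupil_radius is None:
        raise ValueError("stream has no pupil channel")
    fs = stream.sampling_rate
    if fs <= 2 * band[1]:
        raise ValueError(f"sampling rate {fs} Hz below Nyquist for {band[1]} Hz")
    r = stream.pupil_radius.copy()
    good = stream.valid & np.isfinite(r)
    if not good.any():
        raise ValueError("no valid pupil samples")
    r = np.interp(stream.t, stream.t[good], r[good])
    nperseg = int(min(4 * fs, len(r)))
    f, pxx = signal.welch(r, fs=fs, nperseg=nperseg, detrend="constant")
    mask = (f >= band[0]) & (f <= band[1])
    if mask.sum() < 2:
        raise ValueError("record too short to resolve the band")
    return float(np.trapezoid(pxx[mask], f[mask]))


def blink_metrics(blinks: Sequence[BlinkEvent], t_span: float) -> dict[str, float]:
    """Blink rate (blinks/min) and percent eye closure over ``t_span`` seconds."""
    if t_span <= 0:
        raise ValueError("t_span must be > 0")
    closure = sum(b.duration for b in blinks)
    return {
        "blink_rate": len(blinks) / t_span * 60.0,
        "percent_closure": 100.0 * closure / t_span,
    }
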