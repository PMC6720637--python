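"""Seeded synthetic generators for gaze, cardiac, respiratory and paired
sensor data.

Each generator draws every random quantity from a single explicit seed
(no global state), returns the exact ground truth it realised, and is
engineered so the corresponding detector in this package recovers that
ground truth within a statistically predictable tolerance — the
round-trip property the test suite leans on.

What is emulated: the fixation-saccade-blink renewal structure of gaze
recordings, RR series with controllable low/high-frequency spectral
content and beat-to-beat jitter plus optional ectopic (halved) beats,
quasi-sinusoidal respiration volume, reference-vs-degraded sensor pairs,
and cluster-centred heart-rate/breathing-rate workload sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .characterise import PairedSeries
from .fuzzy.examples import CLUSTER_CENTRES
from .gaze import GazeStream, ROILayout
from .hrv import RRSeries
from .respiration import RespirationSignal

__all__ = [
    "GazeScenarioSpec",
    "CardioScenarioSpec",
    "RespScenarioSpec",
    "WorkloadScenarioSpec",
    "simulate_gaze",
    "simulate_rr",
    "simulate_respiration",
    "simulate_sensor_pair",
    "simulate_workload_session",
]


@dataclass
class GazeScenarioSpec:
    rois: ROILayout
    fixation_duration_mean: float = 0.3  # s
    fixation_duration_sd: float = 0.1  # s
    transition_probs: np.ndarray | None = None  # row-stochastic, zero diagonal
    saccade_peak_velocity: float = 300.0  # deg/s
    blink_rate: float = 10.0  # blinks/min
    blink_duration_mean: float = 0.15  # s
    pupil_baseline: float = 3.0  # mm
    pupil_noise_sd: float = 0.05  # mm
    fixation_jitter_sd: float = 0.05  # deg, intra-fixation tremor
    sampling_rate: float = 250.0  # Hz
    duration: float = 60.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.fixation_duration_mean, self.blink_duration_mean, self.duration) <= 0:
            raise ValueError("durations must be > 0")
        if self.blink_rate < 0 or self.saccade_peak_velocity <= 0:
            raise ValueError("rates must be positive")
        m = len(self.rois.rois)
        if self.transition_probs is None:
            P = np.full((m, m), 1.0 / (m - 1) if m > 1 else 0.0)
            np.fill_diagonal(P, 0.0)
            self.transition_probs = P
        else:
            self.transition_probs = np.asarray(self.transition_probs, dtype=float)
            if np.any(np.abs(np.diag(self.transition_probs)) > 0):
                raise ValueError("transition_probs diagonal must be zero")
            if not np.allclose(self.transition_probs.sum(axis=1), 1.0):
                raise ValueError("transition_probs rows must sum to 1")


def simulate_gaze(spec: GazeScenarioSpec) -> tuple[GazeStream, dict]:
    """Fixation-saccade-blink renewal process over the spec's ROIs.

    Returns the sampled stream and a ground-truth log with every
    generated fixation, saccade and blink, and the realised ROI
    sequence.
    """
    rng = np.random.default_rng(spec.seed)
    rois = spec.rois.rois
    centres = np.array([[(r.x_min + r.x_max) / 2, (r.y_min + r.y_max) / 2] for r in rois])
    m = len(rois)

    # --- continuous-time event timeline -----------------------------------
    fixations, saccades, roi_seq = [], [], []
    t = 0.0
    roi = int(rng.integers(m))
    pos = centres[roi]
    while t < spec.duration:
        dur = max(0.12, rng.normal(spec.fixation_duration_mean, spec.fixation_duration_sd))
        t_end = min(t + dur, spec.duration)
        fixations.append(
            {"t_start": t, "t_end": t_end, "roi": rois[roi].roi_id,
             "x": float(pos[0]), "y": float(pos[1])}
        )
        roi_seq.append(rois[roi].roi_id)
        t = t_end
        if t >= spec.duration or m < 2:
            break
        nxt = int(rng.choice(m, p=spec.transition_probs[roi]))
        target = centres[nxt]
        amp = float(np.linalg.norm(target - pos))
        sdur = float(np.clip(amp / spec.saccade_peak_velocity, 0.03, 0.08))
        if t + sdur >= spec.duration:
            break
        saccades.append(
            {"t_start": t, "t_end": t + sdur, "amplitude": amp,
             "from": rois[roi].roi_id, "to": rois[nxt].roi_id}
        )
        t += sdur
        roi, pos = nxt, target

    # --- blinks: Poisson arrivals thinned to avoid saccades ----------------
    blinks = []
    if spec.blink_rate > 0:
        tb = 0.0
        while True:
            tb += rng.exponential(60.0 / spec.blink_rate)
            if tb >= spec.duration:
                break
            bdur = max(
                0.05, rng.normal(spec.blink_duration_mean, 0.2 * spec.blink_duration_mean)
            )
            if tb + bdur >= spec.duration:
                continue
            if any(s["t_start"] - bdur < tb < s["t_end"] for s in saccades):
                continue
            if blinks and tb < blinks[-1]["t_end"] + 0.1:
                continue
            blinks.append({"t_start": tb, "t_end": tb + bdur})

    # --- sample onto the regular grid --------------------------------------
    fs = spec.sampling_rate
    ts = np.arange(0.0, spec.duration, 1.0 / fs)
    x = np.empty_like(ts)
    y = np.empty_like(ts)
    for f in fixations:
        mask = (ts >= f["t_start"]) & (ts < f["t_end"])
        n = int(mask.sum())
        x[mask] = f["x"] + rng.normal(0, spec.fixation_jitter_sd, n)
        y[mask] = f["y"] + rng.normal(0, spec.fixation_jitter_sd, n)
    for s, f0, f1 in zip(saccades, fixations[:-1], fixations[1:]):
        mask = (ts >= s["t_start"]) & (ts < s["t_end"])
        frac = (ts[mask] - s["t_start"]) / (s["t_end"] - s["t_start"])
        x[mask] = f0["x"] + frac * (f1["x"] - f0["x"])
        y[mask] = f0["y"] + frac * (f1["y"] - f0["y"])
    # anything past the last event holds the last position
    tail = ts >= max(
        fixations[-1]["t_end"], saccades[-1]["t_end"] if saccades else 0.0
    )
    if tail.any():
        x[tail], y[tail] = fixations[-1]["x"], fixations[-1]["y"]

    valid = np.ones_like(ts, dtype=bool)
    pupil = spec.pupil_baseline + rng.normal(0, spec.pupil_noise_sd, len(ts))
    for b in blinks:
        mask = (ts >= b["t_start"]) & (ts < b["t_end"])
        valid[mask] = False
        pupil[mask] = np.nan

    stream = GazeStream(
        t=ts, x=x, y=y, valid=valid, sampling_rate=fs, pupil_radius=pupil
    )
    truth = {
        "fixations": fixations,
        "saccades": saccades,
        "blinks": blinks,
        "roi_sequence": roi_seq,
        "n_blinks": len(blinks),
    }
    return stream, truth


@dataclass
class CardioScenarioSpec:
    mean_rr: float = 800.0  # ms
    lf_amp: float = 25.0  # ms, at lf_freq
    hf_amp: float = 25.0  # ms, at hf_freq
    lf_freq: float = 0.1  # Hz (inside the 0.04-0.15 Hz band)
    hf_freq: float = 0.3  # Hz (inside the 0.15-0.4 Hz band)
    jitter_sd: float = 5.0  # ms, white beat-to-beat noise
    duration: float = 300.0  # s
    ectopic_rate: float = 0.0  # per-beat halving probability
    seed: int = 0

    def __post_init__(self) -> None:
        if not 300 < self.mean_rr < 2000:
            raise ValueError("mean_rr must lie in (300, 2000) ms")
        if not 0.04 <= self.lf_freq <= 0.15:
            raise ValueError("lf_freq must lie in the LF band")
        if not 0.15 < self.hf_freq <= 0.4:
            raise ValueError("hf_freq must lie in the HF band")


def simulate_rr(spec: CardioScenarioSpec) -> tuple[RRSeries, dict]:
    """RR tachogram with sinusoidal LF/HF modulation and white jitter.

    ``RR_i = mean_rr + lf_amp sin(2 pi lf_freq t_i) + hf_amp sin(2 pi
    hf_freq t_i) + noise``; ectopic beats appear as halved intervals with
    probability ``ectopic_rate``. Ground truth carries the closed-form
    modulation band powers (amp^2 / 2).
    """
    rng = np.random.default_rng(spec.seed)
    rr, t, n_ectopic = [], 0.0, 0
    while t < spec.duration:
        val = (
            spec.mean_rr
            + spec.lf_amp * np.sin(2 * np.pi * spec.lf_freq * t)
            + spec.hf_amp * np.sin(2 * np.pi * spec.hf_freq * t)
            + rng.normal(0, spec.jitter_sd)
        )
        val = max(val, 200.0)
        if spec.ectopic_rate > 0 and rng.random() < spec.ectopic_rate:
            val /= 2.0
            n_ectopic += 1
        rr.append(val)
        t += val / 1000.0
    truth = {
        "lf_power": spec.lf_amp**2 / 2.0,
        "hf_power": spec.hf_amp**2 / 2.0,
        "n_ectopic": n_ectopic,
        "n_beats": len(rr),
    }
    return RRSeries(np.array(rr)), truth


@dataclass
class RespScenarioSpec:
    br: float = 15.0  # breaths/min
    tv: float = 500.0  # mL peak-to-trough tidal volume
    drift: float = 0.0  # mL/s baseline drift
    noise_sd: float = 0.0  # mL
    duration: float = 60.0  # s
    sampling_rate: float = 25.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if not 4 < self.br < 60:
            raise ValueError("br must lie in (4, 60) breaths/min")


def simulate_respiration(spec: RespScenarioSpec) -> RespirationSignal:
    """Quasi-sinusoidal volume trace at the spec'd rate and tidal volume."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration, 1.0 / spec.sampling_rate)
    v = (
        spec.tv / 2.0 * np.sin(2 * np.pi * spec.br / 60.0 * t)
        + spec.drift * t
        + rng.normal(0, spec.noise_sd, len(t))
    )
    return RespirationSignal(t=t, volume=v)


def simulate_sensor_pair(
    t: np.ndarray,
    truth: np.ndarray,
    bias: float = 0.0,
    noise_sd: float = 0.0,
    latency: float = 0.0,
    seed: int = 0,
) -> PairedSeries:
    """Degrade a reference series into a simulated test-device reading.

    ``measured(t) = truth(t - latency) + bias + N(0, noise_sd)``.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(t, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if truth.size == 0:
        raise ValueError("empty series")
    measured = np.interp(t - latency, t, truth) + bias + rng.normal(0, noise_sd, len(t))
    return PairedSeries(reference=truth, measured=measured, t=t, alignment="simulated")


@dataclass
class WorkloadScenarioSpec:
    states: list[tuple[str, float]] = field(
        default_factory=lambda: [("low", 200.0), ("mid", 200.0), ("high", 200.0)]
    )
    cluster_centres: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CLUSTER_CENTRES)
    )
    hr_sd: float = 1.5  # beats/min within-state scatter
    br_sd: float = 0.5  # breaths/min
    sampling_rate: float = 1.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        for label, dur in self.states:
            if dur <= 0:
                raise ValueError("state durations must be > 0")
            if label not in self.cluster_centres:
                raise ValueError(f"state label {label!r} not in cluster_centres")


def simulate_workload_session(spec: WorkloadScenarioSpec) -> pd.DataFrame:
    """Labelled HR/BR feature table from per-state cluster centres.

    Each state contributes Gaussian HR/BR draws around its cluster
    centre for its duration; columns are ``t, HR, BR, label``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    t0 = 0.0
    for label, dur in spec.states:
        hr_c, br_c = spec.cluster_centres[label]
        ts = np.arange(t0, t0 + dur, 1.0 / spec.sampling_rate)
        hr = hr_c + rng.normal(0, spec.hr_sd, len(ts))
        br = br_c + rng.normal(0, spec.br_sd, len(ts))
        rows.append(pd.DataFrame({"t": ts, "HR": hr, "BR": br, "label": label}))
        t0 += dur
    if not rows:
        return pd.DataFrame(columns=["t", "HR", "BR", "label"])
    return pd.concat(rows, ignore_index=True)
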