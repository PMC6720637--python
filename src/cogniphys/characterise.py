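"""Sensor performance characterisation statistics.

Eye-tracker precision (RMS angular scatter of a fixation cluster about
its mean), accuracy (angular offset of the cluster mean from the true
target), dynamic 2-sigma accuracy from a lognormal error fit,
field-of-view uncertainty propagation, blink-detection error rate, and
test-vs-reference validity (RMS error and product-moment correlation).

Angular distances use the Euclidean approximation in (x, y) gaze-angle
degrees, which is accurate to better than 1% for the sub-20-degree
eccentricities these protocols use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FixationCluster",
    "PairedSeries",
    "CharacterisationReport",
    "gaze_precision",
    "gaze_accuracy",
    "two_sigma_dynamic_accuracy",
    "fov_uncertainty",
    "blink_rate_error",
    "validity",
    "align_pair",
]


@dataclass
class FixationCluster:
    """Gaze samples collected while fixating one known target."""

    samples: np.ndarray  # (n, 2) gaze angles in degrees
    target: tuple[float, float] | None = None  # true angular location

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[1] != 2:
            raise ValueError("samples must be (n, 2) gaze angles")
        if len(self.samples) < 2:
            raise ValueError("cluster needs at least 2 samples")

    @property
    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)


@dataclass
class PairedSeries:
    """Test-device values aligned against a reference device."""

    reference: np.ndarray
    measured: np.ndarray
    t: np.ndarray | None = None
    alignment: str = "pre-aligned"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.measured = np.asarray(self.measured, dtype=float)
        if len(self.reference) != len(self.measured):
            raise ValueError("reference and measured lengths differ")
        if len(self.reference) < 2:
            raise ValueError("need at least 2 paired samples")


@dataclass
class CharacterisationReport:
    precision_rms: float | None = None  # degrees
    accuracy_mean: float | None = None  # degrees
    accuracy_components: tuple[float, float] | None = None  # signed (dx, dy)
    two_sigma_accuracy: float | None = None  # degrees
    rms_error: float | None = None  # reference units
    cc: float | None = None
    cc_note: str | None = None
    blr_error: float | None = None  # fraction
    fov_sigma: float | None = None


def align_pair(
    t_ref: np.ndarray,
    ref: np.ndarray,
    t_meas: np.ndarray,
    meas: np.ndarray,
    max_lag: float = 0.5,
) -> PairedSeries:
    """Nearest-timestamp join of two streams; unmatched samples dropped."""
    t_ref = np.asarray(t_ref, dtype=float)
    t_meas = np.asarray(t_meas, dtype=float)
    idx = np.searchsorted(t_meas, t_ref)
    idx = np.clip(idx, 1, len(t_meas) - 1)
    left, right = t_meas[idx - 1], t_meas[idx]
    nearest = np.where(t_ref - left <= right - t_ref, idx - 1, idx)
    lag = np.abs(t_meas[nearest] - t_ref)
    keep = lag <= max_lag
    return PairedSeries(
        reference=np.asarray(ref, dtype=float)[keep],
        measured=np.asarray(meas, dtype=float)[keep],
        t=t_ref[keep],
        alignment=f"nearest-timestamp, max lag {max_lag} s",
        n_dropped=int((~keep).sum()),
    )


def gaze_precision(cluster: FixationCluster) -> float:
    """RMS angular distance of cluster samples from the cluster mean, degrees."""
    d = np.linalg.norm(cluster.samples - cluster.mean, axis=1)
    return float(np.sqrt(np.mean(d**2)))


def gaze_accuracy(cluster: FixationCluster) -> float:
    """Angular distance of the cluster mean from the true target, degrees."""
    if cluster.target is None:
        raise ValueError("cluster target unknown")
    return float(np.linalg.norm(cluster.mean - np.asarray(cluster.target)))


def two_sigma_dynamic_accuracy(errors: np.ndarray) -> float:
    """2-sigma accuracy bound from a lognormal fit of tracking errors.

    A lognormal is fitted by maximum likelihood to the (strictly
    positive) angular errors and ``exp(mu + 2*sigma)`` is returned — the
    value below which about 95% of the fitted error mass lies.
    """
    e = np.asarray(errors, dtype=float)
    bad = np.flatnonzero(e <= 0)
    if bad.size:
        raise ValueError(f"non-positive errors at indices {bad.tolist()}")
    if len(e) < 20:
        raise ValueError("need at least 20 errors for a stable fit")
    log_e = np.log(e)
    mu, sigma = float(log_e.mean()), float(log_e.std(ddof=0))
    return float(np.exp(mu + 2.0 * sigma))


def fov_uncertainty(
    l: float,
    d: float,
    sigma_l: float,
    sigma_d: float,
    sigma_ld: float = 0.0,
) -> float:
    """Scene-camera field-of-view uncertainty.

    ``sqrt(sigma_l^2 + (l/d)^2 sigma_d^2 - 2 (l/d) sigma_ld) / (d (1 + (l/2d)^2))``
    for an object of known size ``l`` at distance ``d``; the covariance
    ``sigma_ld`` defaults to zero (the conservative choice).
    """
    if d <= 0:
        raise ValueError("d must be > 0")
    if sigma_l < 0 or sigma_d < 0:
        raise ValueError("sigmas must be >= 0")
    radicand = sigma_l**2 + (l / d) ** 2 * sigma_d**2 - 2.0 * (l / d) * sigma_ld
    if radicand < 0:
        raise ValueError("negative radicand: covariance too large for these sigmas")
    return float(np.sqrt(radicand) / (d * (1.0 + (l / (2.0 * d)) ** 2)))


def blink_rate_error(false_pos: int, false_neg: int, total_blinks: int) -> float:
    """(false positives + false negatives) / total true blinks."""
    if total_blinks <= 0:
        raise ValueError("total_blinks must be > 0")
    return (false_pos + false_neg) / total_blinks


def validity(pair: PairedSeries) -> CharacterisationReport:
    """Test-vs-reference validity: RMS error and Pearson correlation."""
    ref, meas = pair.reference, pair.measured
    rms = float(np.sqrt(np.mean((ref - meas) ** 2)))
    report = CharacterisationReport(rms_error=rms)
    if np.var(ref) == 0 or np.var(meas) == 0:
        report.cc = None
        report.cc_note = "correlation undefined: zero variance in a series"
    else:
        report.cc = float(stats.pearsonr(ref, meas).statistic)
    return report
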