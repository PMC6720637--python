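"""Sense-to-estimate orchestration: features per epoch, then fuzzy inference.

The session is cut into sliding epochs (default 60 s window, 10 s step);
heart rate is computed from the RR intervals falling in each epoch and
breathing rate from the respiration trace, and the pair is fed to the
Sugeno model together with their measurement sigmas. The report embeds
the exact configuration used so a rerun with the same manifest is
identical.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass

import numpy as np

from . import __version__
from .config import RunConfig
from .fuzzy import RuleCoverageError, SugenoModel, UncertainValue, propagate_uncertainty
from .gaze import (
    GazeStream,
    ROILayout,
    blink_metrics,
    detect_blinks,
    detect_fixations,
    detect_saccades,
    nearest_neighbour_index,
    pupil_spectral_power,
    segment_dwells,
    time_to_first_fixation,
    transition_matrix,
    visual_entropy,
)
from .hrv import RRSeries, clean_nn, hrv_frequency_domain, hrv_time_domain, poincare_summary
from .respiration import RespirationSignal, respiration_metrics

__all__ = ["PipelineError", "gaze_report", "run_pipeline"]


class PipelineError(RuntimeError):
    """Wraps a stage failure with the stage name attached."""


def gaze_report(
    stream: GazeStream, rois: ROILayout | None = None, config: RunConfig | None = None
) -> dict:
    """All gaze metrics of the stream as a flat JSON-ready dict."""
    cfg = config or RunConfig()
    blinks = detect_blinks(stream, max_gap=cfg.blink_max_gap)
    fixations = detect_fixations(stream, d_max=cfg.d_max, min_duration=cfg.min_fix_duration)
    saccades = detect_saccades(
        stream, v_threshold=cfg.v_threshold, dur_bounds=cfg.saccade_dur_bounds
    )
    report: dict = {
        "n_fixations": len(fixations),
        "n_saccades": len(saccades),
        "n_blinks": len(blinks),
        **blink_metrics(blinks, t_span=stream.duration),
    }
    if fixations:
        report["time_to_first_fixation"] = time_to_first_fixation(fixations, t0=stream.t[0])
        report["mean_fixation_duration"] = float(
            np.mean([f.duration for f in fixations])
        )
    if len(fixations) >= 2:
        report["nni"] = nearest_neighbour_index(fixations)
    n_long = sum(1 for f in fixations if f.duration >= cfg.long_fix_threshold)
    if n_long:
        report["explore_exploit_ratio"] = (len(saccades) + len(fixations)) / n_long
    if rois is not None:
        dwells = segment_dwells(fixations, rois)
        tm = transition_matrix(dwells, rois)
        report["n_dwells"] = len(dwells)
        report["visual_entropy_bits"] = visual_entropy(tm)
        report["transition_matrix"] = tm.P.tolist()
    if stream.pupil_radius is not None and stream.sampling_rate > 2 * cfg.pupil_band[1]:
        report["pupil_band_power"] = pupil_spectral_power(stream, band=cfg.pupil_band)
    return report


def _epoch_features(
    t0: float,
    t1: float,
    rr: RRSeries | None,
    resp: RespirationSignal | None,
) -> dict | None:
    feats: dict = {}
    if rr is not None:
        tb = rr.t_onset
        mask = (tb >= t0) & (tb < t1)
        if mask.sum() >= 2:
            feats["HR"] = 60.0 / (float(rr.rr[mask].mean()) / 1000.0)
    if resp is not None:
        mask = (resp.t >= t0) & (resp.t < t1)
        if mask.sum() >= 2:
            try:
                feats["BR"] = respiration_metrics(
                    RespirationSignal(resp.t[mask], resp.volume[mask])
                ).br
            except ValueError:
                pass
    return feats or None


def run_pipeline(
    config: RunConfig,
    model: SugenoModel,
    rr: RRSeries | None = None,
    resp: RespirationSignal | None = None,
    gaze: GazeStream | None = None,
    rois: ROILayout | None = None,
    sigmas: dict[str, float] | None = None,
    seed: int = 0,
) -> dict:
    """Extract features per modality, infer the state per epoch, report.

    Returns a dict with per-epoch state estimates, whole-record feature
    summaries, and a manifest (config hash, seed, versions).
    """
    if rr is None and resp is None and gaze is None:
        raise PipelineError("no modalities: provide at least one input stream")

    report: dict = {}
    try:
        if gaze is not None:
            report["gaze"] = gaze_report(gaze, rois=rois, config=config)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"gaze feature stage failed: {e}") from e
    try:
        if rr is not None:
            nn = clean_nn(rr, bounds=config.nn_bounds, max_rel_jump=config.nn_max_rel_jump)
            td = hrv_time_domain(rr, nn)
            report["hrv_time"] = td.__dict__
            if rr.duration >= 120:
                report["hrv_frequency"] = hrv_frequency_domain(
                    rr, method=config.psd_method
                ).__dict__
            if len(rr) >= 3:
                ps = poincare_summary(rr)
                report["poincare"] = {"sd1": ps.sd1, "sd2": ps.sd2}
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"cardiac feature stage failed: {e}") from e
    try:
        if resp is not None:
            rs = respiration_metrics(resp)
            report["respiration"] = {"br": rs.br, "tv_mean": rs.tv_mean, "mv": rs.mv}
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"respiration feature stage failed: {e}") from e

    # per-epoch state inference
    sigmas = sigmas or {}
    spans = []
    if rr is not None:
        spans.append(rr.duration)
    if resp is not None:
        spans.append(float(resp.t[-1] - resp.t[0]))
    if gaze is not None:
        spans.append(gaze.duration)
    total = min(spans)
    epochs = []
    t0 = 0.0
    try:
        while t0 + config.window_s <= total + 1e-9:
            feats = _epoch_features(t0, t0 + config.window_s, rr, resp)
            if feats is not None and all(n in feats for n in model.input_names):
                x = [
                    UncertainValue(feats[n], sigmas.get(n, 0.0)) for n in model.input_names
                ]
                try:
                    est = propagate_uncertainty(model, x)
                    epochs.append(
                        {
                            "t_start": t0,
                            "t_end": t0 + config.window_s,
                            "features": feats,
                            "state": est.value,
                            "sigma": est.sigma,
                        }
                    )
                except RuleCoverageError:
                    epochs.append(
                        {
                            "t_start": t0,
                            "t_end": t0 + config.window_s,
                            "features": feats,
                            "state": None,
                            "sigma": None,
                        }
                    )
            t0 += config.step_s
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"inference stage failed: {e}") from e
    report["epochs"] = epochs

    cfg_yaml = config.to_yaml()
    report["manifest"] = {
        "config": config.model_dump(),
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": seed,
        "state_name": model.state_name,
        "versions": {
            "cogniphys": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
        },
    }
    return report
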