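import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogniphys.gaze import (
    GazeStream,
    ROI,
    ROILayout,
    TransitionMatrix,
    blink_metrics,
    detect_blinks,
    detect_fixations,
    detect_saccades,
    explore_exploit_ratio,
    nearest_neighbour_index,
    pupil_spectral_power,
    segment_dwells,
    time_to_first_fixation,
    transition_matrix,
    visual_entropy,
)


def make_stream(x, y, fs=100.0, valid=None, pupil=None):
    x = np.asarray(x, dtype=float)
    t = np.arange(len(x)) / fs
    if valid is None:
        valid = np.ones(len(x), dtype=bool)
    return GazeStream(t=t, x=x, y=np.asarray(y, dtype=float), valid=valid,
                      sampling_rate=fs, pupil_radius=pupil)


# ---------------------------------------------------------------- stream


def test_stream_validation():
    with pytest.raises(ValueError, match="length"):
        GazeStream(t=np.arange(3) / 100, x=np.zeros(2), y=np.zeros(3),
                   valid=np.ones(3, bool), sampling_rate=100.0)
    with pytest.raises(ValueError, match="inconsistent"):
        GazeStream(t=np.arange(3) / 50, x=np.zeros(3), y=np.zeros(3),
                   valid=np.ones(3, bool), sampling_rate=100.0)
    with pytest.raises(ValueError, match="increasing"):
        GazeStream(t=np.array([0.0, 0.02, 0.01]), x=np.zeros(3), y=np.zeros(3),
                   valid=np.ones(3, bool), sampling_rate=100.0)


# ---------------------------------------------------------------- blinks


def test_blink_duration_convention():
    # 15 invalid samples at 100 Hz -> one 0.15 s blink
    valid = np.ones(100, dtype=bool)
    valid[20:35] = False
    s = make_stream(np.zeros(100), np.zeros(100), fs=100.0, valid=valid)
    blinks = detect_blinks(s)
    assert len(blinks) == 1
    assert blinks[0].t_start == pytest.approx(0.20)
    assert blinks[0].duration == pytest.approx(0.15)


def test_blink_max_gap_excludes_tracking_loss():
    valid = np.ones(200, dtype=bool)
    valid[10:20] = False    # 0.10 s blink
    valid[100:180] = False  # 0.80 s loss, > default 0.5 s gap
    s = make_stream(np.zeros(200), np.zeros(200), fs=100.0, valid=valid)
    blinks = detect_blinks(s)
    assert len(blinks) == 1
    assert blinks[0].duration == pytest.approx(0.10)


def test_blink_metrics_hand_case():
    from cogniphys.gaze import BlinkEvent

    blinks = [BlinkEvent(1.0, 1.2), BlinkEvent(5.0, 5.1)]
    m = blink_metrics(blinks, t_span=60.0)
    assert m["blink_rate"] == pytest.approx(2.0)
    assert m["percent_closure"] == pytest.approx(100 * 0.3 / 60)


# ---------------------------------------------------------------- fixations


def test_fixation_duration_convention():
    # 1 s at (5,5), then 1 s at (15,5): two fixations of 1.0 s each
    x = np.r_[np.full(100, 5.0), np.full(100, 15.0)]
    s = make_stream(x, np.full(200, 5.0), fs=100.0)
    fx = detect_fixations(s)
    assert len(fx) == 2
    for f, cx in zip(fx, (5.0, 15.0)):
        assert f.duration == pytest.approx(1.0)
        assert f.centroid_x == pytest.approx(cx)
        assert f.centroid_y == pytest.approx(5.0)


def test_fixation_below_min_duration_discarded():
    # 5 samples at 100 Hz = 0.05 s < 0.1 s default
    x = np.r_[np.full(5, 0.0), np.linspace(5, 50, 20)]
    s = make_stream(x, np.zeros(25), fs=100.0)
    assert detect_fixations(s) == []


def test_fixation_bridges_blink_gap():
    # a blink inside a steady fixation does not split it
    x = np.full(100, 5.0)
    valid = np.ones(100, dtype=bool)
    valid[40:55] = False
    s = make_stream(x, x, fs=100.0, valid=valid)
    fx = detect_fixations(s)
    assert len(fx) == 1
    assert fx[0].t_start == pytest.approx(0.0)


def _idt_oracle(t, x, y, d_max, min_duration, dt):
    """Literal I-DT reference implementation."""
    events = []
    n = len(t)
    i = 0
    while i < n:
        j = i
        while j < n and t[j] < t[i] + min_duration - dt - 1e-12:
            j += 1
        if j >= n:
            break
        disp = np.hypot(x[i:j + 1].max() - x[i:j + 1].min(),
                        y[i:j + 1].max() - y[i:j + 1].min())
        if disp >= d_max:
            i += 1
            continue
        while j + 1 < n:
            disp2 = np.hypot(x[i:j + 2].max() - x[i:j + 2].min(),
                             y[i:j + 2].max() - y[i:j + 2].min())
            if disp2 >= d_max:
                break
            j += 1
        events.append((i, j))
        i = j + 1
    return events


@settings(max_examples=60, deadline=None)
@given(st.integers(0, 10_000), st.integers(30, 200))
def test_fixation_matches_bruteforce_oracle(seed, n):
    rng = np.random.default_rng(seed)
    # random walk with occasional jumps: both fixation-like and saccade-like spans
    steps = rng.normal(0, 0.08, size=(n, 2))
    jumps = rng.random(n) < 0.05
    steps[jumps] += rng.normal(0, 5.0, size=(jumps.sum(), 2))
    xy = np.cumsum(steps, axis=0)
    s = make_stream(xy[:, 0], xy[:, 1], fs=100.0)
    got = detect_fixations(s, d_max=1.0, min_duration=0.1)
    exp = _idt_oracle(s.t, s.x, s.y, 1.0, 0.1, s.dt)
    assert len(got) == len(exp)
    for f, (i, j) in zip(got, exp):
        assert f.t_start == pytest.approx(s.t[i])
        assert f.t_end == pytest.approx(s.t[j] + s.dt)
        assert f.centroid_x == pytest.approx(s.x[i:j + 1].mean())


# ---------------------------------------------------------------- saccades


def _saccade_trace(fs=250.0):
    """10 deg jump over 11 samples (0.04 s) between two fixations."""
    n_fix = 125
    ramp = np.linspace(0.0, 10.0, 11)
    x = np.r_[np.zeros(n_fix), ramp[1:-1], np.full(n_fix, 10.0)]
    return make_stream(x, np.zeros_like(x), fs=fs)


def test_saccade_hand_case():
    s = _saccade_trace()
    sc = detect_saccades(s)
    assert len(sc) == 1
    ev = sc[0]
    assert ev.duration == pytest.approx(0.04, abs=1e-9)
    assert ev.amplitude == pytest.approx(10.0, abs=0.5)
    assert ev.mean_velocity == pytest.approx(ev.amplitude / ev.duration)
    assert ev.peak_velocity >= ev.mean_velocity


def test_saccade_duration_bounds():
    # 3-sample jump at 250 Hz = 8 ms < 30 ms lower bound -> rejected
    x = np.r_[np.zeros(125), np.array([3.0, 6.0]), np.full(125, 9.0)]
    s = make_stream(x, np.zeros_like(x), fs=250.0)
    assert detect_saccades(s) == []


def test_saccade_touching_blink_dropped():
    s = _saccade_trace()
    valid = s.valid.copy()
    valid[128] = True  # sanity
    valid[130] = False  # inside the ramp
    s2 = GazeStream(s.t, s.x, s.y, valid, s.sampling_rate)
    assert detect_saccades(s2) == []


# ---------------------------------------------------------------- scan path


def test_time_to_first_fixation():
    x = np.r_[np.linspace(0, 50, 50), np.full(100, 50.0)]
    s = make_stream(x, np.zeros_like(x), fs=100.0)
    fx = detect_fixations(s)
    assert fx
    assert time_to_first_fixation(fx, t0=s.t[0]) == pytest.approx(fx[0].t_start)


def test_explore_exploit_ratio():
    from cogniphys.gaze import FixationEvent, SaccadeEvent

    fx = [FixationEvent(0, 0.6, 0, 0, 0.1, 0.6), FixationEvent(1, 1.2, 0, 0, 0.1, 0.2)]
    sc = [SaccadeEvent(0.6, 0.64, 5, 125, 200)]
    assert explore_exploit_ratio(fx, sc) == pytest.approx(3.0)
    with pytest.raises(ZeroDivisionError):
        explore_exploit_ratio([fx[1]], sc)


def _fix(cx, cy, t0):
    from cogniphys.gaze import FixationEvent

    return FixationEvent(t0, t0 + 0.3, cx, cy, 0.1, 0.3)


def test_dwells_merge_and_break(rois):
    fxs = [_fix(5, 5, 0.0), _fix(6, 5, 0.5), _fix(15, 5, 1.0),
           _fix(50, 50, 1.5), _fix(5, 15, 2.0)]
    dwells = segment_dwells(fxs, rois)
    assert [d.roi_id for d in dwells] == ["pfd", "nav", "radio"]
    assert dwells[0].n_fixations == 2
    assert dwells[0].t_start == 0.0 and dwells[0].t_end == pytest.approx(0.8)


def test_transition_matrix_properties(rois):
    fxs = [_fix(5, 5, 0.0), _fix(15, 5, 0.5), _fix(5, 5, 1.0),
           _fix(5, 15, 1.5), _fix(5, 5, 2.0)]
    tm = transition_matrix(segment_dwells(fxs, rois), rois)
    assert np.all(np.diag(tm.P) == 0)
    rows = tm.P.sum(axis=1)
    assert np.allclose(rows[rows > 0], 1.0)
    # pfd visited 3x -> leaves twice: once to nav, once to radio
    assert tm.P[0] == pytest.approx([0.0, 0.5, 0.5])


def test_visual_entropy_hand_case():
    tm = TransitionMatrix(
        roi_ids=["a", "b", "c"],
        P=np.array([[0.0, 0.9, 0.1], [0.1, 0.0, 0.9], [0.0, 0.0, 0.0]]),
        fixation_probs=np.array([0.5, 0.5, 0.0]),
    )
    expected = -(0.9 * np.log2(0.9) + 0.1 * np.log2(0.1))  # both rows identical
    assert visual_entropy(tm) == pytest.approx(expected)
    assert visual_entropy(tm) == pytest.approx(0.4690, abs=1e-4)


def test_visual_entropy_deterministic_scan_is_zero(rois):
    fxs = []
    for i in range(6):
        fxs += [_fix(5, 5, 2 * i), _fix(15, 5, 2 * i + 1)]
    tm = transition_matrix(segment_dwells(fxs, rois), rois)
    assert visual_entropy(tm) == pytest.approx(0.0)


def test_nni_grid_vs_clustered():
    # regular grid disperses (NNI > 1); collapsing clusters lowers it
    gx, gy = np.meshgrid(np.arange(6), np.arange(6))
    grid = [_fix(float(a), float(b), i) for i, (a, b) in
            enumerate(zip(gx.ravel(), gy.ravel()))]
    nni_grid = nearest_neighbour_index(grid, area=25.0)
    assert nni_grid > 1.5
    rng = np.random.default_rng(0)
    pts = np.r_[rng.normal(0, 0.05, (18, 2)), rng.normal(4, 0.05, (18, 2))]
    clustered = [_fix(p[0], p[1], i) for i, p in enumerate(pts)]
    assert nearest_neighbour_index(clustered, area=25.0) < nni_grid / 2


def test_nni_csr_expectation(rng):
    # uniform points in a unit square: NNI near 1
    pts = rng.random((400, 2))
    fxs = [_fix(p[0], p[1], i) for i, p in enumerate(pts)]
    assert nearest_neighbour_index(fxs, area=1.0) == pytest.approx(1.0, abs=0.15)


# ---------------------------------------------------------------- pupil


def test_pupil_band_power_tone():
    fs, dur = 100.0, 120.0
    t = np.arange(int(fs * dur)) / fs
    in_band = 3.0 + 0.2 * np.sin(2 * np.pi * 4.0 * t)
    out_band = 3.0 + 0.2 * np.sin(2 * np.pi * 0.5 * t)
    p_in = pupil_spectral_power(make_stream(np.zeros_like(t), np.zeros_like(t),
                                            fs=fs, pupil=in_band))
    p_out = pupil_spectral_power(make_stream(np.zeros_like(t), np.zeros_like(t),
                                             fs=fs, pupil=out_band))
    assert p_in == pytest.approx(0.2**2 / 2, rel=0.05)
    assert p_out < 0.05 * p_in


def test_pupil_requires_channel():
    s = make_stream(np.zeros(100), np.zeros(100), fs=100.0)
    with pytest.raises(ValueError, match="pupil"):
        pupil_spectral_power(s)


# ---------------------------------------------------------------- rois


def test_roi_edges_and_priority():
    layout = ROILayout([ROI("a", 0, 10, 0, 10), ROI("b", 10, 20, 0, 10)])
    assert layout.locate(10.0, 5.0) == "b"   # min edge closed
    assert layout.locate(9.999, 5.0) == "a"  # max edge open
    assert layout.locate(25.0, 5.0) is None
    with pytest.raises(ValueError, match="overlap"):
        ROILayout([ROI("a", 0, 10, 0, 10), ROI("b", 5, 15, 0, 10)])
    with pytest.raises(ValueError, match="unique"):
        ROILayout([ROI("a", 0, 10, 0, 10), ROI("a", 10, 20, 0, 10)])
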