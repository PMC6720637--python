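import numpy as np
import pandas as pd
import pytest

from cogniphys.fuzzy import (
    FuzzyInput,
    Gaussian,
    RuleCoverageError,
    Sigmoid,
    SugenoModel,
    SugenoRule,
    Trapezoid,
    UncertainValue,
    calibrate,
    fit,
    membership_from_dict,
    propagate_uncertainty,
    uncertainty_surface,
    workload_model,
)
from cogniphys.fuzzy.examples import CLUSTER_CENTRES, RULE_OUTPUTS


# ---------------------------------------------------------------- membership


def test_trapezoid_nodes_and_validation():
    mf = Trapezoid(0.0, 1.0, 2.0, 4.0)
    assert mf(-1.0) == 0.0 and mf(5.0) == 0.0
    assert mf(0.5) == pytest.approx(0.5)
    assert mf(1.5) == 1.0
    assert mf(3.0) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        Trapezoid(1.0, 0.0, 2.0, 4.0)  # a > b
    with pytest.raises(ValueError):
        Trapezoid(0.0, 1.0, 1.0, 1.0)  # c == d


def test_gaussian_and_sigmoid():
    g = Gaussian(c=5.0, sigma=2.0)
    assert g(5.0) == 1.0
    assert g(7.0) == pytest.approx(np.exp(-0.5))
    with pytest.raises(ValueError):
        Gaussian(c=0.0, sigma=0.0)
    s = Sigmoid(a=2.0, c=1.0)
    assert s(1.0) == pytest.approx(0.5)
    assert s(100.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        Sigmoid(a=0.0, c=1.0)


@pytest.mark.parametrize("mf", [
    Trapezoid(0.0, 1.0, 2.0, 4.0),
    Gaussian(c=5.0, sigma=2.0),
    Sigmoid(a=1.5, c=0.5),
])
def test_derivative_matches_numerical(mf):
    # sample away from the trapezoid kinks where the derivative jumps
    xs = np.array([-0.7, 0.31, 1.53, 2.77, 3.21, 4.9, 6.1])
    h = 1e-6
    num = (mf(xs + h) - mf(xs - h)) / (2 * h)
    np.testing.assert_allclose(mf.derivative(xs), num, atol=1e-5)


def test_membership_serialisation_roundtrip():
    for mf in (Trapezoid(0, 1, 2, 4), Gaussian(5, 2), Sigmoid(1.5, 0.5)):
        back = membership_from_dict(mf.to_dict())
        assert back == mf


# ---------------------------------------------------------------- inference


def two_rule_model(order0=True):
    mfs = {"lo": Trapezoid(-1.0, 0.0, 1.0, 2.0), "hi": Trapezoid(1.0, 2.0, 3.0, 4.0)}
    inputs = [FuzzyInput("x", "a.u.", mfs)]
    if order0:
        rules = [SugenoRule({"x": "lo"}, [10.0, 0.0]),
                 SugenoRule({"x": "hi"}, [20.0, 0.0])]
    else:
        rules = [SugenoRule({"x": "lo"}, [1.0, 2.0]),
                 SugenoRule({"x": "hi"}, [3.0, -1.0])]
    return SugenoModel(inputs, rules, state_name="s")


def test_infer_weighted_average_hand_case():
    m = two_rule_model()
    # at x = 1.5: mu_lo = 0.5, mu_hi = 0.5 -> output midway
    est = m.infer({"x": 1.5})
    assert est.value == pytest.approx(15.0)
    np.testing.assert_allclose(est.normalized_weights, [0.5, 0.5])
    # deep inside 'lo' only
    assert m.infer({"x": 0.5}).value == pytest.approx(10.0)


def test_first_order_consequent():
    m = two_rule_model(order0=False)
    # only rule 'lo' fires at x=0.5 -> f = 1 + 2*0.5
    assert m.infer({"x": 0.5}).value == pytest.approx(2.0)


def test_coverage_error():
    m = two_rule_model()
    with pytest.raises(RuleCoverageError):
        m.infer({"x": 10.0})


def test_dont_care_antecedent():
    mfs = {"lo": Trapezoid(-1.0, 0.0, 1.0, 2.0)}
    m = SugenoModel(
        [FuzzyInput("x", "", mfs), FuzzyInput("y", "", {"any": Gaussian(0, 1)})],
        [SugenoRule({"x": "lo"}, [7.0, 0.0, 0.0])],  # y unreferenced
    )
    assert m.infer({"x": 0.5, "y": 123.0}).value == pytest.approx(7.0)


def test_rule_validation():
    mfs = {"lo": Trapezoid(-1, 0, 1, 2)}
    with pytest.raises(ValueError, match="unknown membership"):
        SugenoModel([FuzzyInput("x", "", mfs)], [SugenoRule({"x": "nope"}, [0, 0])])
    with pytest.raises(ValueError, match="unknown input"):
        SugenoModel([FuzzyInput("x", "", mfs)], [SugenoRule({"z": "lo"}, [0, 0])])
    with pytest.raises(ValueError, match="coefficients"):
        SugenoModel([FuzzyInput("x", "", mfs)], [SugenoRule({"x": "lo"}, [0.0])])


def test_model_serialisation_roundtrip():
    m = workload_model(mf_family="gaussian")
    back = SugenoModel.from_json(m.to_json())
    rng = np.random.default_rng(0)
    for _ in range(20):
        x = {"HR": rng.uniform(62, 69), "BR": rng.uniform(11, 16)}
        assert back(x) == m(x)  # bit-identical round trip


# ---------------------------------------------------------------- examples


@pytest.mark.parametrize("family", ["gaussian", "trapezoid"])
def test_workload_crisp_outputs(family):
    m = workload_model(mf_family=family, rule_alignment="printed")
    # each point fires exactly one rule of the printed three-rule base
    # compact trapezoid supports give exact outputs; gaussian tails leak
    # up to ~1e-2 of firing strength into the neighbouring rules, so there
    # the property is dominance of the intended rule, not exactness
    tol = 1e-12 if family == "trapezoid" else 2e-2
    for k, ((hr_lab, br_lab), out) in enumerate(zip(
        [("high", "low"), ("mid", "mid"), ("low", "high")], RULE_OUTPUTS
    )):
        hr = CLUSTER_CENTRES[hr_lab][0]
        br = CLUSTER_CENTRES[br_lab][1]
        est = m.infer({"HR": hr, "BR": br})
        assert est.value == pytest.approx(out, abs=tol)
        assert est.normalized_weights[k] > 0.95


def test_cluster_alignment_hits_centres():
    m = workload_model(mf_family="gaussian", rule_alignment="clusters")
    for label, out in zip(["high", "mid", "low"], RULE_OUTPUTS):
        hr, br = CLUSTER_CENTRES[label]
        assert m({"HR": hr, "BR": br}) == pytest.approx(out, abs=5e-3)


# ---------------------------------------------------------------- calibration


def _session(n=600, noise=0.0, seed=0):
    from cogniphys.simulate import WorkloadScenarioSpec, simulate_workload_session

    df = simulate_workload_session(WorkloadScenarioSpec(seed=seed))
    assert len(df) == n
    gen = workload_model(mf_family="gaussian", rule_alignment="clusters")
    y = np.array([gen({"HR": h, "BR": b}) for h, b in zip(df.HR, df.BR)])
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, size=len(y))
    return df[["HR", "BR"]], y


def test_calibration_exact_recovery_noiseless():
    X, y = _session()
    res = fit(workload_model(mf_family="gaussian", rule_alignment="clusters"), X, y)
    np.testing.assert_allclose(res.params, RULE_OUTPUTS, atol=1e-6)
    assert res.rmse < 1e-8
    assert res.rsquared == pytest.approx(1.0, abs=1e-9)


def test_calibration_noisy_recovery():
    X, y = _session(noise=0.05)
    res = fit(workload_model(mf_family="gaussian", rule_alignment="clusters"), X, y)
    np.testing.assert_allclose(res.params, RULE_OUTPUTS, atol=0.1)
    assert np.all(res.bse > 0)


def test_calibration_results_api():
    X, y = _session()
    res = fit(workload_model(mf_family="gaussian", rule_alignment="clusters"), X, y)
    assert res.nobs == 600
    assert len(res.param_names) == len(res.params)
    frame = res.params_frame()
    assert {"coef", "std err"} <= set(frame.columns)
    text = res.summary()
    assert "rmse" in text.lower() or "RMSE" in text
    pred = res.predict(X)
    assert np.sqrt(np.mean((pred - y) ** 2)) < 1e-8


def test_calibrate_returns_model():
    X, y = _session()
    m = calibrate(workload_model(mf_family="gaussian", rule_alignment="clusters"), X, y)
    assert isinstance(m, SugenoModel)
    assert m({"HR": CLUSTER_CENTRES["high"][0], "BR": CLUSTER_CENTRES["high"][1]}) == (
        pytest.approx(1.0, abs=1e-3)
    )


def test_calibration_never_firing_rule_raises():
    mfs = {"lo": Trapezoid(-1.0, 0.0, 1.0, 2.0), "far": Trapezoid(100.0, 101.0, 102.0, 103.0)}
    m = SugenoModel(
        [FuzzyInput("x", "", mfs)],
        [SugenoRule({"x": "lo"}, [0.0, 0.0]), SugenoRule({"x": "far"}, [0.0, 0.0])],
    )
    X = pd.DataFrame({"x": np.linspace(0.0, 1.0, 50)})
    with pytest.raises(np.linalg.LinAlgError, match="far|rule"):
        fit(m, X, np.ones(50))


def test_first_order_calibration():
    m = two_rule_model(order0=False)
    rng = np.random.default_rng(1)
    X = pd.DataFrame({"x": rng.uniform(-0.5, 3.5, 300)})
    y = np.array([m({"x": v}) for v in X.x])
    init = two_rule_model(order0=True)
    res = fit(init, X, y, order=1)
    assert res.rmse < 1e-8
    np.testing.assert_allclose(sorted(res.params), sorted([1.0, 2.0, 3.0, -1.0]), atol=1e-6)


# ---------------------------------------------------------------- uncertainty


def test_zero_sigma_gives_zero_sigma():
    m = workload_model(mf_family="gaussian", rule_alignment="clusters")
    est = propagate_uncertainty(m, [UncertainValue(64.9, 0.0), UncertainValue(14.6, 0.0)])
    assert est.sigma == 0.0
    assert est.value == pytest.approx(0.5, abs=5e-3)


def test_single_rule_first_order_sigma_closed_form():
    # one always-on rule, first-order consequent: sigma = |p1| * sigma_x
    mfs = {"all": Trapezoid(-100.0, -99.0, 99.0, 100.0)}
    m = SugenoModel([FuzzyInput("x", "", mfs)], [SugenoRule({"x": "all"}, [1.0, 3.0])])
    est = propagate_uncertainty(m, [UncertainValue(0.0, 0.5)])
    assert est.sigma == pytest.approx(1.5)


def test_first_order_sigma_matches_mc_small_sigma():
    m = workload_model(mf_family="gaussian", rule_alignment="clusters")
    x0, s0 = (65.0, 13.0), (0.05, 0.02)
    est = propagate_uncertainty(
        m, [UncertainValue(x0[0], s0[0]), UncertainValue(x0[1], s0[1])]
    )
    rng = np.random.default_rng(7)
    draws = rng.normal(size=(40_000, 2))
    mc = [m({"HR": x0[0] + s0[0] * a, "BR": x0[1] + s0[1] * b}) for a, b in draws]
    assert est.sigma == pytest.approx(float(np.std(mc)), rel=0.1)


def test_rule_weight_sigmas_exposed():
    m = workload_model(mf_family="gaussian", rule_alignment="clusters")
    est = propagate_uncertainty(m, [UncertainValue(65.0, 5.5), UncertainValue(13.0, 1.6)])
    assert est.rule_weight_sigmas is not None
    assert len(est.rule_weight_sigmas) == len(m.rules)
    assert np.all(est.rule_weight_sigmas >= 0)


def test_uncertainty_surface_frame():
    m = workload_model(mf_family="gaussian", rule_alignment="clusters")
    surf = uncertainty_surface(
        m,
        {"HR": np.linspace(62, 70, 9), "BR": np.linspace(10, 16, 7)},
        {"HR": 5.5, "BR": 1.6},
    )
    assert len(surf) == 63
    assert {"HR", "BR", "value", "sigma"} <= set(surf.columns)
    assert (surf.sigma >= 0).all()


def test_negative_sigma_rejected():
    with pytest.raises(ValueError):
        UncertainValue(1.0, -0.1)
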