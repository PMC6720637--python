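"""Worked mental-workload (MWL) model from heart-rate / breathing-rate clusters.

An air-traffic-management scenario yields per-state cluster centres for
heart rate (beats/min) and breathing rate (breaths/min); the bundled
three-rule zeroth-order Sugeno system maps those two features to a
workload score on [0.1, 1]:

    IF HR is high AND BR is low  THEN MWL = 1
    IF HR is mid  AND BR is mid  THEN MWL = 0.5
    IF HR is low  AND BR is high THEN MWL = 0.1

Note the rule base pairs high HR with *low* BR even though the
highest-workload cluster has the highest BR; ``rule_alignment="clusters"``
instead pairs like-labelled clusters (high HR with high BR), which is the
variant a calibration run against the cluster-labelled data recovers.

Membership spreads are not part of the cluster table; by default each
Gaussian spread (or trapezoid support) is set from half the distance to
the nearest neighbouring centre on the same input, which keeps adjacent
sets separable without gaps.
"""

from __future__ import annotations

import numpy as np

from .membership import Gaussian, MembershipFunction, Trapezoid
from .model import FuzzyInput, SugenoModel, SugenoRule

__all__ = ["CLUSTER_CENTRES", "workload_model"]

#: per-state (HR beats/min, BR breaths/min) cluster centres of the worked example
CLUSTER_CENTRES: dict[str, tuple[float, float]] = {
    "low": (63.2, 11.5),
    "mid": (64.9, 14.6),
    "high": (68.3, 15.3),
}

#: workload score of each rule, ordered (high-HR rule, mid, low)
RULE_OUTPUTS: tuple[float, float, float] = (1.0, 0.5, 0.1)


def _half_nn_spread(centres: np.ndarray) -> np.ndarray:
    s = np.empty_like(centres)
    for i, ci in enumerate(centres):
        d = np.abs(centres - ci)
        d[i] = np.inf
        s[i] = d.min() / 2.0
    return s


def _sets(
    centres: dict[str, float], family: str
) -> dict[str, MembershipFunction]:
    labels = list(centres)
    c = np.array([centres[l] for l in labels], dtype=float)
    spread = _half_nn_spread(c)
    out: dict[str, MembershipFunction] = {}
    for l, ci, si in zip(labels, c, spread):
        if family == "gaussian":
            out[l] = Gaussian(c=float(ci), sigma=float(si))
        elif family == "trapezoid":
            # compact disjoint support of half-width = spread (= half the
            # nearest-neighbour distance), plateau over the inner half
            out[l] = Trapezoid(
                a=float(ci - si), b=float(ci - si / 2), c=float(ci + si / 2), d=float(ci + si)
            )
        else:
            raise ValueError(f"unsupported family {family!r}")
    return out


def workload_model(
    mf_family: str = "gaussian",
    rule_alignment: str = "printed",
    centres: dict[str, tuple[float, float]] | None = None,
) -> SugenoModel:
    """Build the three-rule HR/BR mental-workload Sugeno system.

    Parameters
    ----------
    mf_family : {"gaussian", "trapezoid"}
        Gaussian sets overlap smoothly (needed for uncertainty
        propagation); trapezoid sets have compact disjoint supports, so
        exactly one rule fires near each cluster centre.
    rule_alignment : {"printed", "clusters"}
        "printed" pairs high HR with low BR as quoted above; "clusters"
        pairs like-labelled HR and BR sets.
    centres : mapping label -> (hr, br), optional
        Cluster centres; defaults to :data:`CLUSTER_CENTRES`.
    """
    centres = centres or CLUSTER_CENTRES
    hr = {l: c[0] for l, c in centres.items()}
    br = {l: c[1] for l, c in centres.items()}
    inputs = [
        FuzzyInput(name="HR", unit="beats/min", mfs=_sets(hr, mf_family)),
        FuzzyInput(name="BR", unit="breaths/min", mfs=_sets(br, mf_family)),
    ]
    if rule_alignment == "printed":
        pairs = [("high", "low"), ("mid", "mid"), ("low", "high")]
    elif rule_alignment == "clusters":
        pairs = [("high", "high"), ("mid", "mid"), ("low", "low")]
    else:
        raise ValueError(f"unknown rule_alignment {rule_alignment!r}")
    rules = [
        SugenoRule(antecedent={"HR": h, "BR": b}, coeffs=np.array([out, 0.0, 0.0]))
        for (h, b), out in zip(pairs, RULE_OUTPUTS)
    ]
    return SugenoModel(inputs=inputs, rules=rules, state_name="MWL")
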