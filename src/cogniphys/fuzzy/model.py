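"""Sugeno-type fuzzy inference expressed as a trainable layered network.

The model holds, per input, an inventory of labelled membership functions
and a set of rules whose antecedents reference those labels and whose
consequents are polynomials ``f_k = p_k0 + sum_i p_ki x_i`` (zeroth-order
when all slopes are zero). Inference runs the classic five layers: the
inputs are fuzzified, each rule's firing strength is the product of its
antecedent memberships (product AND), strengths are normalized, and the
crisp output is the normalized-weight average of the rule consequents.

``SugenoModel.fit`` calibrates the consequents (and optionally the
membership parameters) against labelled data and returns a results object
with estimates, standard errors and a summary table; see
:mod:`cogniphys.fuzzy.calibration`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .membership import MembershipFunction, membership_from_dict

__all__ = [
    "RuleCoverageError",
    "FuzzyInput",
    "SugenoRule",
    "StateEstimate",
    "SugenoModel",
]


class RuleCoverageError(ValueError):
    """Raised when every rule's firing strength is zero at the given input."""


@dataclass
class FuzzyInput:
    """One model input: a name, a unit and its labelled fuzzy sets."""

    name: str
    unit: str
    mfs: dict[str, MembershipFunction]


@dataclass
class SugenoRule:
    """IF-part label per input (missing = don't care) and consequent coeffs.

    ``coeffs`` is ``[p0, p1, ..., p_n]`` over the model's input order; a
    zeroth-order rule has all slopes zero.
    """

    antecedent: dict[str, str]
    coeffs: np.ndarray

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)

    def consequent(self, x: np.ndarray) -> float:
        return float(self.coeffs[0] + np.dot(self.coeffs[1:], x))

    @property
    def is_zeroth_order(self) -> bool:
        return bool(np.all(self.coeffs[1:] == 0))


@dataclass
class StateEstimate:
    """Crisp state value with optional 1-sigma uncertainty and diagnostics."""

    state_name: str
    value: float
    sigma: float | None
    firing_strengths: np.ndarray
    normalized_weights: np.ndarray
    rule_weight_sigmas: np.ndarray | None = None


class SugenoModel:
    """Sugeno fuzzy system: membership inventories + rule base.

    Parameters
    ----------
    inputs : sequence of FuzzyInput
        Ordered inputs; rule antecedents reference their MF labels.
    rules : sequence of SugenoRule
        At least one rule; every referenced label must exist.
    state_name : str
        Name of the estimated state (e.g. ``"MWL"``).
    """

    def __init__(
        self,
        inputs: Sequence[FuzzyInput],
        rules: Sequence[SugenoRule],
        state_name: str = "state",
    ) -> None:
        if not rules:
            raise ValueError("model needs at least one rule")
        self.inputs = list(inputs)
        self.rules = list(rules)
        self.state_name = state_name
        names = {inp.name for inp in self.inputs}
        for k, rule in enumerate(self.rules):
            if len(rule.coeffs) != 1 + len(self.inputs):
                raise ValueError(
                    f"rule {k}: expected {1 + len(self.inputs)} coefficients, got {len(rule.coeffs)}"
                )
            for name, label in rule.antecedent.items():
                if name not in names:
                    raise ValueError(f"rule {k} references unknown input {name!r}")
                inp = next(i for i in self.inputs if i.name == name)
                if label not in inp.mfs:
                    raise ValueError(
                        f"rule {k} references unknown membership {label!r} of input {name!r}"
                    )

    # -- inference ----------------------------------------------------------

    @property
    def input_names(self) -> list[str]:
        return [i.name for i in self.inputs]

    def _as_vector(self, x) -> np.ndarray:
        if isinstance(x, Mapping):
            x = [x[name] for name in self.input_names]
        x = np.asarray(x, dtype=float)
        if x.shape != (len(self.inputs),):
            raise ValueError(
                f"input dimension {x.shape} does not match model inputs {len(self.inputs)}"
            )
        return x

    def memberships(self, x) -> np.ndarray:
        """Per-rule, per-input membership degrees (don't-care inputs give 1)."""
        x = self._as_vector(x)
        mu = np.ones((len(self.rules), len(self.inputs)))
        for k, rule in enumerate(self.rules):
            for i, inp in enumerate(self.inputs):
                label = rule.antecedent.get(inp.name)
                if label is not None:
                    mu[k, i] = float(inp.mfs[label](x[i]))
        return mu

    def firing_strengths(self, x) -> np.ndarray:
        """Product-AND rule firing strengths w_k."""
        return self.memberships(x).prod(axis=1)

    def infer(self, x) -> StateEstimate:
        """Crisp output: normalized-firing-strength weighted consequent average."""
        xv = self._as_vector(x)
        w = self.firing_strengths(xv)
        total = w.sum()
        if total == 0:
            raise RuleCoverageError("input outside rule coverage")
        wbar = w / total
        f = np.array([r.consequent(xv) for r in self.rules])
        return StateEstimate(
            state_name=self.state_name,
            value=float(np.dot(wbar, f)),
            sigma=None,
            firing_strengths=w,
            normalized_weights=wbar,
        )

    def __call__(self, x) -> float:
        return self.infer(x).value

    # -- calibration / uncertainty (delegated) ------------------------------

    def fit(self, X, y, **kwargs):
        """Calibrate against data; see :func:`cogniphys.fuzzy.calibration.fit`."""
        from .calibration import fit

        return fit(self, X, y, **kwargs)

    def propagate(self, x, **kwargs) -> StateEstimate:
        """Uncertainty-aware inference; see :mod:`cogniphys.fuzzy.uncertainty`."""
        from .uncertainty import propagate_uncertainty

        return propagate_uncertainty(self, x, **kwargs)

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "state_name": self.state_name,
            "inputs": [
                {
                    "name": inp.name,
                    "unit": inp.unit,
                    "mfs": [
                        {"label": label, **mf.to_dict()} for label, mf in inp.mfs.items()
                    ],
                }
                for inp in self.inputs
            ],
            "rules": [
                {"antecedent": dict(r.antecedent), "coeffs": r.coeffs.tolist()}
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SugenoModel":
        inputs = [
            FuzzyInput(
                name=i["name"],
                unit=i.get("unit", ""),
                mfs={m["label"]: membership_from_dict(m) for m in i["mfs"]},
            )
            for i in d["inputs"]
        ]
        rules = [
            SugenoRule(antecedent=dict(r["antecedent"]), coeffs=np.asarray(r["coeffs"]))
            for r in d["rules"]
        ]
        return cls(inputs=inputs, rules=rules, state_name=d.get("state_name", "state"))

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "SugenoModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))

    def copy(self) -> "SugenoModel":
        return SugenoModel.from_dict(self.to_dict())
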