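"""First-order propagation of input uncertainty through Sugeno inference.

Inputs carry 1-sigma uncertainties (:class:`UncertainValue`). The output
sigma is obtained by the delta method: the gradient of the crisp output
through fuzzification, the normalization quotient and the weighted
consequent average is evaluated analytically, and the input sigmas are
propagated along it (inputs treated as independent). Each rule's
normalized-weight sigma is exposed as a diagnostic.

Because the normalized weights share the same inputs and sum to one,
their first-order perturbations are strongly anti-correlated; combining
per-rule terms as if independent can misstate the output sigma even in
the small-sigma limit, so the default combines them through the exact
first-order gradient. A layer-wise combination that treats the supplied
per-rule weight sigmas as independent is available by passing
``sigma_wbar`` explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .model import RuleCoverageError, StateEstimate, SugenoModel

__all__ = ["UncertainValue", "propagate_uncertainty", "uncertainty_surface"]


@dataclass(frozen=True)
class UncertainValue:
    """Point estimate with a 1-sigma uncertainty in the same units."""

    value: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _weight_jacobian(model: SugenoModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(w, dwbar/dx): normalized-weight Jacobian, shape (K, n_inputs)."""
    mu = model.memberships(x)  # (K, n_in)
    K, n_in = mu.shape
    w = mu.prod(axis=1)
    total = w.sum()
    if total == 0:
        raise RuleCoverageError("input outside rule coverage")
    dw = np.zeros((K, n_in))
    for k, rule in enumerate(model.rules):
        for i, inp in enumerate(model.inputs):
            label = rule.antecedent.get(inp.name)
            if label is None:
                continue
            others = np.prod(np.delete(mu[k], i))
            dw[k, i] = others * float(inp.mfs[label].derivative(x[i]))
    wbar = w / total
    col = dw.sum(axis=0)  # d(total)/dx_i
    dwbar = (dw - wbar[:, None] * col[None, :]) / total
    return w, dwbar


def propagate_uncertainty(
    model: SugenoModel,
    x: Sequence[UncertainValue],
    sigma_wbar: np.ndarray | None = None,
) -> StateEstimate:
    """Infer the state and its 1-sigma uncertainty at an uncertain input.

    Parameters
    ----------
    x : sequence of UncertainValue, ordered as the model's inputs.
    sigma_wbar : array of shape (K,), optional
        Externally supplied per-rule normalized-weight sigmas. When
        given, the output sigma combines the per-rule consequent terms
        ``(f_k * sigma_wbar_k)^2`` and the direct consequent-slope terms
        as independent contributions (layer-wise replay); by default the
        weight sigmas are derived internally and combined through the
        exact first-order gradient.
    """
    vals = np.array([u.value for u in x], dtype=float)
    sig = np.array([u.sigma for u in x], dtype=float)
    if np.any(sig < 0):
        raise ValueError("input sigmas must be >= 0")
    w, dwbar = _weight_jacobian(model, vals)
    wbar = w / w.sum()
    f = np.array([r.consequent(vals) for r in model.rules])
    P = np.array([r.coeffs[1:] for r in model.rules])  # (K, n_in) slopes
    value = float(np.dot(wbar, f))
    rule_weight_sigmas = np.sqrt(((dwbar * sig[None, :]) ** 2).sum(axis=1))

    if sigma_wbar is not None:
        sigma_wbar = np.asarray(sigma_wbar, dtype=float)
        term_rules = float(((f * sigma_wbar) ** 2).sum())
        term_inputs = float((wbar**2 * ((P * sig[None, :]) ** 2).sum(axis=1)).sum())
        sigma = float(np.sqrt(term_rules + term_inputs))
    else:
        # d y / d x_i through weights and first-order consequents
        grad = (f[:, None] * dwbar).sum(axis=0) + (wbar[:, None] * P).sum(axis=0)
        sigma = float(np.sqrt(((grad * sig) ** 2).sum()))

    return StateEstimate(
        state_name=model.state_name,
        value=value,
        sigma=sigma,
        firing_strengths=w,
        normalized_weights=wbar,
        rule_weight_sigmas=rule_weight_sigmas,
    )


def uncertainty_surface(
    model: SugenoModel,
    grid: dict[str, np.ndarray],
    sigmas: dict[str, float],
) -> pd.DataFrame:
    """Tabulate value and sigma over a grid of input combinations.

    One row per grid point with the input values, the crisp ``value`` and
    the propagated ``sigma``; points outside rule coverage get NaN. The
    sigma maxima sit where rules conflict (between adjacent set centres),
    not at the centres themselves.
    """
    names = model.input_names
    axes = [np.asarray(grid[n], dtype=float) for n in names]
    if any(a.size == 0 for a in axes):
        raise ValueError("grid must be non-empty for every input")
    rows = []
    for combo in product(*axes):
        rec = dict(zip(names, combo))
        try:
            est = propagate_uncertainty(
                model, [UncertainValue(v, sigmas[n]) for n, v in zip(names, combo)]
            )
            rec["value"], rec["sigma"] = est.value, est.sigma
        except RuleCoverageError:
            rec["value"], rec["sigma"] = np.nan, np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
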