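"""Offline calibration of a Sugeno fuzzy system against labelled data.

Two-stage hybrid scheme:

1. **Consequents** — with the premise (membership) parameters fixed, the
   crisp output is linear in the consequent coefficients, so they are
   identified by ordinary least squares on the normalized-firing-strength
   design matrix. Standard errors follow from the usual linear-model
   covariance.
2. **Premises** (optional) — Gaussian membership centres and spreads are
   refined by bounded Nelder-Mead on the residual sum of squares, with
   the consequents re-solved at every candidate premise (nested least
   squares). The refinement is deterministic given its starting point.

``fit`` returns a :class:`SugenoCalibrationResults` carrying the fitted
model, per-rule coefficient estimates with uncertainties, fit diagnostics
and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .membership import Gaussian
from .model import SugenoModel, SugenoRule

__all__ = ["SugenoCalibrationResults", "fit", "calibrate"]

#: rules whose maximum normalized firing strength over the sample falls
#: below this are unidentifiable from the data
_MIN_FIRING = 1e-6


def _design_matrix(model: SugenoModel, X: np.ndarray, order: int) -> np.ndarray:
    n, n_in = X.shape
    K = len(model.rules)
    p_per_rule = 1 if order == 0 else 1 + n_in
    D = np.zeros((n, K * p_per_rule))
    max_wbar = np.zeros(K)
    for s in range(n):
        w = model.firing_strengths(X[s])
        total = w.sum()
        if total == 0:
            continue
        wbar = w / total
        max_wbar = np.maximum(max_wbar, wbar)
        for k in range(K):
            j = k * p_per_rule
            D[s, j] = wbar[k]
            if order == 1:
                D[s, j + 1 : j + 1 + n_in] = wbar[k] * X[s]
    weak = [k for k in range(K) if max_wbar[k] < _MIN_FIRING]
    if weak:
        raise np.linalg.LinAlgError(
            "rank-deficient design: rules "
            + ", ".join(str(k) for k in weak)
            + " never fire appreciably over the training data"
        )
    return D


def _solve_consequents(
    model: SugenoModel, X: np.ndarray, y: np.ndarray, order: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares consequents; returns (params, bse, residuals)."""
    D = _design_matrix(model, X, order)
    n, p = D.shape
    if np.linalg.matrix_rank(D) < p:
        raise np.linalg.LinAlgError(
            "rank-deficient design: consequent coefficients are not jointly "
            "identifiable from the training data"
        )
    params, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ params
    dof = max(n - p, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.pinv(D.T @ D)
    bse = np.sqrt(np.diag(cov))
    return params, bse, resid


def _install_consequents(model: SugenoModel, params: np.ndarray, order: int) -> None:
    n_in = len(model.inputs)
    p_per_rule = 1 if order == 0 else 1 + n_in
    for k, rule in enumerate(model.rules):
        coeffs = np.zeros(1 + n_in)
        chunk = params[k * p_per_rule : (k + 1) * p_per_rule]
        coeffs[: len(chunk)] = chunk
        rule.coeffs = coeffs


@dataclass
class SugenoCalibrationResults:
    """Estimates, uncertainties and diagnostics of a calibration run."""

    model: SugenoModel
    params: np.ndarray
    bse: np.ndarray
    param_names: list[str]
    nobs: int
    rmse: float
    rsquared: float
    order: int
    premises_refined: bool
    n_premise_iterations: int = 0

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "std err": self.bse}, index=self.param_names
        )

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return np.array([self.model.infer(row).value for row in X])

    def summary(self) -> str:
        head = [
            f"{'Sugeno fuzzy calibration':^60}",
            "=" * 60,
            f"State:            {self.model.state_name}",
            f"No. observations: {self.nobs}",
            f"No. rules:        {len(self.model.rules)}",
            f"Consequent order: {self.order}",
            f"Premises refined: {self.premises_refined}"
            + (f" ({self.n_premise_iterations} iterations)" if self.premises_refined else ""),
            f"RMSE:             {self.rmse:.6g}",
            f"R-squared:        {self.rsquared:.6g}",
            "-" * 60,
        ]
        table = self.params_frame().to_string(float_format=lambda v: f"{v: .6g}")
        return "\n".join(head) + "\n" + table + "\n" + "=" * 60


def fit(
    model: SugenoModel,
    X,
    y,
    order: int = 0,
    refine_premises: bool = False,
    seed: int = 0,
    maxiter: int = 200,
    tol: float = 1e-8,
) -> SugenoCalibrationResults:
    """Calibrate ``model`` against features ``X`` and targets ``y``.

    Parameters
    ----------
    X : (n, n_inputs) array or DataFrame with the model's input columns
    y : (n,) array of target state values
    order : {0, 1}
        Consequent polynomial order to fit.
    refine_premises : bool
        Also refine Gaussian membership centres/spreads (slower).
    seed : int
        Retained for interface stability; the procedure is deterministic.
    maxiter, tol : Nelder-Mead budget for the premise refinement.
    """
    if isinstance(X, pd.DataFrame):
        X = X[model.input_names].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if order not in (0, 1):
        raise ValueError("order must be 0 or 1")
    work = model.copy()
    n_iter = 0

    if refine_premises:
        gaussians = [
            (i_inp, label)
            for i_inp, inp in enumerate(work.inputs)
            for label, mf in inp.mfs.items()
            if isinstance(mf, Gaussian)
        ]
        if gaussians:
            x0, bounds = [], []
            for i_inp, label in gaussians:
                mf = work.inputs[i_inp].mfs[label]
                x0 += [mf.c, mf.sigma]
                span = float(np.ptp(X[:, i_inp])) or 1.0
                bounds += [
                    (mf.c - span, mf.c + span),
                    (max(mf.sigma / 10.0, 1e-6), mf.sigma * 10.0),
                ]

            def objective(theta: np.ndarray) -> float:
                for j, (i_inp, label) in enumerate(gaussians):
                    work.inputs[i_inp].mfs[label] = Gaussian(
                        c=float(theta[2 * j]), sigma=float(theta[2 * j + 1])
                    )
                try:
                    _, _, resid = _solve_consequents(work, X, y, order)
                except np.linalg.LinAlgError:
                    return np.inf
                return float(resid @ resid)

            res = optimize.minimize(
                objective,
                np.asarray(x0),
                method="Nelder-Mead",
                bounds=bounds,
                options={"maxiter": maxiter, "xatol": tol, "fatol": tol},
            )
            objective(res.x)  # leave the best premises installed
            n_iter = int(res.nit)

    params, bse, resid = _solve_consequents(work, X, y, order)
    _install_consequents(work, params, order)
    names = []
    for k in range(len(work.rules)):
        names.append(f"rule{k}:p0")
        if order == 1:
            names += [f"rule{k}:p_{nm}" for nm in work.input_names]
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(resid @ resid)
    return SugenoCalibrationResults(
        model=work,
        params=params,
        bse=bse,
        param_names=names,
        nobs=len(y),
        rmse=float(np.sqrt(ss_res / len(y))),
        rsquared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        order=order,
        premises_refined=refine_premises,
        n_premise_iterations=n_iter,
    )


def calibrate(model: SugenoModel, X, y, **kwargs) -> SugenoModel:
    """Convenience wrapper returning the calibrated model itself."""
    return fit(model, X, y, **kwargs).model
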