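"""Model/Results front end for partially linear group-bridge regression.

`PartiallyLinearGroupBridge` holds the data (response, grouped covariates,
scalar index) and the spline specification; `fit` runs the penalized LQA
solver — tuning (lambda, gamma) by leave-one-out CV when they are not
given — and returns a `GroupBridgeResults` with the grouped coefficient
estimates, the spline estimate of the smooth term, post-selection standard
errors and a text summary.
"""

from __future__ import annotations

import numpy as np

from . import core, tuning
from .basis import SplineBasisSpec, evaluate_f
from .core import FitControls, FitResult
from .design import ProfiledDesign, make_design

__all__ = ["PartiallyLinearGroupBridge", "GroupBridgeResults"]

_METHOD_NAMES = {"agb": "Adaptive group bridge", "gb": "Group bridge", "gl": "Group lasso"}


class PartiallyLinearGroupBridge:
    """Partially linear model ``y = x' beta + f(u) + eps`` with grouped selection.

    Parameters
    ----------
    y : array_like, shape (n,)
        Response.
    X : array_like, shape (n, sum(group_sizes))
        Grouped covariates, columns ordered group by group.
    u : array_like, shape (n,)
        Scalar index of the smooth term, scaled to [0, 1].
    group_sizes : sequence of int
        Number of columns in each covariate group.
    basis_spec : SplineBasisSpec, optional
        Spline space for f; cubic with 7 basis functions by default.
    group_names : sequence of str, optional
        Labels used in summaries.

    Examples
    --------
    >>> model = PartiallyLinearGroupBridge(y, X, u, group_sizes=[3, 3, 3])
    >>> res = model.fit(method="agb")          # CV-tuned (lambda, gamma)
    >>> print(res.summary())
    """

    def __init__(self, y, X, u, group_sizes, basis_spec=None, group_names=None):
        self.design: ProfiledDesign = make_design(y, X, u, group_sizes, basis_spec)
        if group_names is None:
            group_names = [f"g{j + 1}" for j in range(self.design.n_groups)]
        if len(group_names) != self.design.n_groups:
            raise ValueError("need one name per group")
        self.group_names = list(group_names)

    @classmethod
    def from_dataframe(
        cls,
        data,
        group_map: dict[str, list[str]],
        response: str = "Y",
        index: str = "U",
        basis_spec=None,
    ) -> "PartiallyLinearGroupBridge":
        """Build from a DataFrame and a {group name: column list} mapping."""
        cols = [c for cols_ in group_map.values() for c in cols_]
        missing = [c for c in cols + [response, index] if c not in data.columns]
        if missing:
            raise KeyError(f"columns not found in data: {missing}")
        sizes = [len(v) for v in group_map.values()]
        return cls(
            data[response].to_numpy(dtype=float),
            data[cols].to_numpy(dtype=float),
            data[index].to_numpy(dtype=float),
            sizes,
            basis_spec=basis_spec,
            group_names=list(group_map.keys()),
        )

    def fit(
        self,
        method: str = "agb",
        lam: float | None = None,
        gamma: float | None = None,
        lambda_grid=None,
        gamma_grid=None,
        controls: FitControls | None = None,
        denominator_power: int = 1,
    ) -> "GroupBridgeResults":
        """Fit by penalized LQA; CV-tune any tuning parameter left None.

        ``method`` is one of ``"agb"`` (adaptive weights, gamma tuned over
        (0, 1]), ``"gb"`` (constant weights, concave gamma, default 0.5)
        or ``"gl"`` (group lasso, gamma = 1).
        """
        controls = controls or FitControls()
        if method not in _METHOD_NAMES:
            raise ValueError(f"unknown method {method!r}")
        cv = None
        if method == "gl":
            gamma = 1.0
        if lam is None or (gamma is None and method != "gl"):
            if gamma is not None:
                gamma_grid = (gamma,)
            elif method == "gb" and gamma_grid is None:
                gamma_grid = (0.5,)
            if lam is not None:
                lambda_grid = (lam,)
            cv = tuning.select_tuning(
                self.design,
                lambda_values=lambda_grid,
                gamma_values=gamma_grid,
                controls=controls,
                method=method,
                denominator_power=denominator_power,
            )
            lam, gamma = cv.best_lambda, cv.best_gamma
        elif gamma is None:
            gamma = 1.0 if method == "gl" else 0.5
        fit = tuning._fit_for_method(self.design, method, lam, gamma, controls)
        return GroupBridgeResults(self, fit, method, lam, gamma, cv)

    def fit_ols(self) -> "GroupBridgeResults":
        """Unpenalized profiled least-squares fit (no selection)."""
        controls = FitControls()
        beta0 = core.ols_init(self.design)
        penalty = core.PenaltySpec.constant(0.0, 1.0, self.design.n_groups)
        fit = core.fit_penalized(self.design, penalty, beta0, controls)
        return GroupBridgeResults(self, fit, "ols", 0.0, 1.0, None)


class GroupBridgeResults:
    """Fitted partially linear group-bridge model.

    Attributes
    ----------
    params : ndarray
        Stacked coefficient estimates (exact zeros in removed groups).
    alpha : ndarray
        Spline coefficients of the smooth-term estimate.
    selected_groups : ndarray of int
        Indices of groups kept in the model.
    cv : CVGrid or None
        The CV surface when tuning was data-driven.
    """

    def __init__(self, model, fit: FitResult, method, lam, gamma, cv):
        self.model = model
        self._fit = fit
        self.method = method
        self.lambda_ = float(lam)
        self.gamma = float(gamma)
        self.cv = cv

    # -- estimates -----------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        return self._fit.beta

    @property
    def alpha(self) -> np.ndarray:
        return self._fit.alpha

    @property
    def selected_groups(self) -> np.ndarray:
        return self._fit.selected_groups

    @property
    def selected_group_names(self) -> list[str]:
        return [self.model.group_names[j] for j in self._fit.selected_groups]

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def n_iter(self) -> int:
        return self._fit.n_iter

    @property
    def objective_trace(self) -> np.ndarray:
        return self._fit.objective_trace

    def group_norms(self) -> np.ndarray:
        return self.model.design.group_norms(self._fit.beta)

    # -- diagnostics ---------------------------------------------------
    @property
    def fittedvalues(self) -> np.ndarray:
        d = self.model.design
        return d.X @ self.params + d.basis.Z @ self.alpha

    @property
    def resid(self) -> np.ndarray:
        return self.model.design.y - self.fittedvalues

    @property
    def df_model(self) -> int:
        d = self.model.design
        k = sum(int(d.group_sizes[j]) for j in self.selected_groups)
        return k + d.basis.spec.q_n

    @property
    def scale(self) -> float:
        """Residual variance estimate sigma^2_hat = RSS / (n - df)."""
        d = self.model.design
        dof = max(d.n - self.df_model, 1)
        r = self.resid
        return float(r @ r) / dof

    def bse(self) -> np.ndarray:
        """Post-selection standard errors for the stacked coefficients.

        Based on the oracle approximation: the selected submodel's
        profiled least-squares covariance ``sigma^2 (X*_A' X*_A)^{-1}``.
        Entries for removed groups are 0.  These ignore selection and
        shrinkage and should be read as oracle-model standard errors.
        """
        d = self.model.design
        se = np.zeros(d.p_total)
        if len(self.selected_groups) == 0:
            return se
        idx = np.concatenate(
            [np.arange(s.start, s.stop) for s in (d.slices[j] for j in self.selected_groups)]
        )
        cov = self.scale * np.linalg.inv(d.gram[np.ix_(idx, idx)])
        se[idx] = np.sqrt(np.diag(cov))
        return se

    # -- prediction ----------------------------------------------------
    def predict(self, X, u) -> np.ndarray:
        """Predict ``x' beta_hat + f_hat(u)`` at new covariates and index."""
        X = np.asarray(X, dtype=float)
        return X @ self.params + self.f_hat(u)

    def f_hat(self, u) -> np.ndarray:
        """Evaluate the spline estimate of the smooth term at ``u``."""
        return evaluate_f(self.alpha, u, self.model.design.basis.spec)

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        d = self.model.design
        se = self.bse()
        lines = []
        title = f"Partially linear model — {_METHOD_NAMES.get(self.method, 'OLS')}"
        lines.append(title)
        lines.append("=" * 72)
        lines.append(
            f"n obs: {d.n:<10} groups: {d.n_groups:<8} "
            f"covariates: {d.p_total:<8} spline dim q_n: {d.basis.spec.q_n}"
        )
        lines.append(
            f"lambda: {self.lambda_:<12.5g} gamma: {self.gamma:<8.3g} "
            f"iterations: {self.n_iter:<6} converged: {self.converged}"
        )
        lines.append(
            f"selected groups: {len(self.selected_groups)}/{d.n_groups} "
            f"{self.selected_group_names}"
        )
        lines.append(f"residual scale sigma^2_hat: {self.scale:.5g}")
        lines.append("-" * 72)
        lines.append(f"{'group':<12}{'coef':<12}{'estimate':>12}{'std err':>12}")
        for j, s in enumerate(d.slices):
            name = self.model.group_names[j]
            for k, col in enumerate(range(s.start, s.stop)):
                lab = name if k == 0 else ""
                sek = f"{se[col]:.4f}" if se[col] > 0 else "--"
                lines.append(
                    f"{lab:<12}{'x' + str(col + 1):<12}"
                    f"{self.params[col]:>12.4f}{sek:>12}"
                )
        lines.append("=" * 72)
        lines.append(
            "Std errs are post-selection (oracle-submodel) approximations."
        )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<GroupBridgeResults method={self.method} "
            f"selected={len(self.selected_groups)}/{self.model.design.n_groups} "
            f"converged={self.converged}>"
        )
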