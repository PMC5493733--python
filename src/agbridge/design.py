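"""Profiled design: grouped covariates residualized against the spline span."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisMatrix, SplineBasisSpec, build_basis

__all__ = ["ProfiledDesign", "make_design", "group_slices"]


def group_slices(group_sizes: np.ndarray) -> list[slice]:
    """Column slices of the covariate matrix, one per group, in order."""
    ends = np.cumsum(group_sizes)
    starts = ends - group_sizes
    return [slice(int(s), int(e)) for s, e in zip(starts, ends)]


@dataclass
class ProfiledDesign:
    """Workspace of the profiled objective.

    Carries the raw data (``y``, grouped ``X``, index ``u``), the spline
    basis, and the residualized arrays ``y_star = (I-H) y`` and
    ``X_star = (I-H) X`` in which the spline coefficients have been
    profiled out.  The Gram matrix ``X_star' X_star`` and the moment
    vector ``X_star' y_star`` are cached since every LQA step and every
    CV evaluation reuses them.
    """

    y: np.ndarray
    X: np.ndarray
    u: np.ndarray
    group_sizes: np.ndarray
    basis: BasisMatrix
    y_star: np.ndarray
    X_star: np.ndarray
    gram: np.ndarray = field(init=False)
    moment: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if int(np.sum(self.group_sizes)) != self.X.shape[1]:
            raise ValueError(
                "group sizes must sum to the number of covariate columns"
            )
        if np.any(self.group_sizes < 1):
            raise ValueError("every group must contain at least one covariate")
        self.gram = self.X_star.T @ self.X_star
        self.moment = self.X_star.T @ self.y_star

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    @property
    def p_total(self) -> int:
        return self.X.shape[1]

    @property
    def slices(self) -> list[slice]:
        return group_slices(self.group_sizes)

    def group_norms(self, beta: np.ndarray) -> np.ndarray:
        """Euclidean norm of each coefficient group."""
        beta = np.asarray(beta, dtype=float).ravel()
        return np.array([np.linalg.norm(beta[s]) for s in self.slices])


def make_design(
    y: np.ndarray,
    X: np.ndarray,
    u: np.ndarray,
    group_sizes,
    spec: SplineBasisSpec | None = None,
) -> ProfiledDesign:
    """Assemble a :class:`ProfiledDesign` from raw arrays.

    Builds the B-spline basis at the observed index values and residualizes
    both the response and every covariate column against its span.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-d array")
    u = np.asarray(u, dtype=float).ravel()
    if not (y.shape[0] == X.shape[0] == u.shape[0]):
        raise ValueError("y, X and u must have matching first dimensions")
    group_sizes = np.asarray(group_sizes, dtype=int).ravel()
    basis = build_basis(u, spec)
    return ProfiledDesign(
        y=y,
        X=X,
        u=u,
        group_sizes=group_sizes,
        basis=basis,
        y_star=basis.residualize(y),
        X_star=basis.residualize(X),
    )
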