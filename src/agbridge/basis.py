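"""Normalized B-spline basis for the nonparametric component.

The partially linear model ``Y = x'beta + f(U) + eps`` approximates the
smooth function ``f`` on [0, 1] in a polynomial-spline sieve space spanned
by ``q_n`` normalized B-spline basis functions ``B_1..B_{q_n}``.  With
``Z`` the n x q_n matrix of basis evaluations at the observed index values,
the spline coefficients can be profiled out of the least-squares problem
through the projection ``H = Z (Z'Z)^{-1} Z'``; everything downstream only
needs the residualizer ``I - H``, which this module applies through a thin
QR factorization of ``Z`` rather than ever forming ``H`` densely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import lstsq, qr

__all__ = [
    "SplineBasisSpec",
    "BasisMatrix",
    "build_basis",
    "residualize",
    "solve_alpha",
    "evaluate_f",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplineBasisSpec:
    """Specification of the spline sieve space on [0, 1].

    Parameters
    ----------
    degree_m : int
        Spline order (degree + 1); cubic splines have ``degree_m = 4``.
    q_n : int
        Dimension of the spline space, i.e. number of basis functions.
        Must satisfy ``q_n >= degree_m``; the number of interior knots is
        ``q_n - degree_m``.
    knots : ndarray
        Full nondecreasing knot vector on [0, 1] with boundary knots of
        multiplicity ``degree_m``.  Built automatically (equally spaced
        interior knots) when not supplied.
    """

    degree_m: int = 4
    q_n: int = 7
    knots: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.degree_m < 2:
            raise ValueError("spline order degree_m must be >= 2")
        if self.q_n < self.degree_m:
            raise ValueError(
                f"q_n={self.q_n} must be >= spline order degree_m={self.degree_m}"
            )
        if self.knots is None:
            n_interior = self.q_n - self.degree_m
            interior = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
            knots = np.concatenate(
                [np.zeros(self.degree_m), interior, np.ones(self.degree_m)]
            )
            object.__setattr__(self, "knots", knots)
        else:
            knots = np.asarray(self.knots, dtype=float)
            if np.any(np.diff(knots) < 0):
                raise ValueError("knot vector must be nondecreasing")
            if len(knots) != self.q_n + self.degree_m:
                raise ValueError(
                    "knot vector length must equal q_n + degree_m "
                    f"({self.q_n + self.degree_m}), got {len(knots)}"
                )
            object.__setattr__(self, "knots", knots)

    @property
    def degree(self) -> int:
        """Polynomial degree (order minus one)."""
        return self.degree_m - 1

    def design_matrix(self, u: np.ndarray) -> np.ndarray:
        """Evaluate all basis functions at ``u`` (rows sum to one)."""
        u = _check_domain(np.asarray(u, dtype=float))
        return BSpline.design_matrix(
            u, self.knots, self.degree, extrapolate=False
        ).toarray()


def _check_domain(u: np.ndarray) -> np.ndarray:
    if u.ndim != 1:
        u = np.ravel(u)
    if np.any(~np.isfinite(u)) or np.any(u < 0.0) or np.any(u > 1.0):
        raise ValueError("index variable U must lie in [0, 1]")
    return u


class BasisMatrix:
    """Basis evaluations ``Z`` plus a factorized projection residualizer.

    Holds the thin QR factorization ``Z = Q R`` so that the projection
    ``H = Q Q'`` and the residualizer ``I - H`` can be applied to any
    conformable matrix in O(n q_n k) without forming ``H``.
    """

    def __init__(self, Z: np.ndarray, spec: SplineBasisSpec):
        Z = np.asarray(Z, dtype=float)
        if Z.ndim != 2 or Z.shape[1] != spec.q_n:
            raise ValueError("Z must be n x q_n")
        if Z.shape[0] < spec.q_n:
            raise np.linalg.LinAlgError(
                f"need n >= q_n basis functions (n={Z.shape[0]}, q_n={spec.q_n}); "
                "Z'Z is singular"
            )
        self.Z = Z
        self.spec = spec
        Q, R = qr(Z, mode="economic")
        diag = np.abs(np.diag(R))
        if np.any(diag < 1e-12 * diag.max()):
            raise np.linalg.LinAlgError(
                "spline design matrix is numerically rank deficient; "
                "check that U values cover the knot span"
            )
        self._Q = Q
        self._R = R

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    def project(self, M: np.ndarray) -> np.ndarray:
        """Apply ``H = Z (Z'Z)^{-1} Z'`` to ``M``."""
        M = self._conform(M)
        return self._Q @ (self._Q.T @ M)

    def residualize(self, M: np.ndarray) -> np.ndarray:
        """Apply ``I - H`` to ``M`` (columnwise projection residuals)."""
        M = self._conform(M)
        return M - self._Q @ (self._Q.T @ M)

    def _conform(self, M: np.ndarray) -> np.ndarray:
        M = np.asarray(M, dtype=float)
        rows = M.shape[0]
        if rows != self.n:
            raise ValueError(
                f"row mismatch: basis has n={self.n}, argument has {rows} rows"
            )
        return M


def build_basis(u: np.ndarray, spec: SplineBasisSpec | None = None) -> BasisMatrix:
    """Build the basis matrix ``Z`` with rows ``B(U_i)'`` and its residualizer.

    Raises
    ------
    ValueError
        If any ``u`` falls outside [0, 1].
    numpy.linalg.LinAlgError
        If ``n < q_n`` (the Gram matrix ``Z'Z`` would be singular).
    """
    spec = spec or SplineBasisSpec()
    return BasisMatrix(spec.design_matrix(u), spec)


def residualize(M: np.ndarray, basis: BasisMatrix) -> np.ndarray:
    """Return ``(I - H) M`` for the projection onto the spline span."""
    return basis.residualize(M)


def solve_alpha(
    y: np.ndarray,
    X: np.ndarray | None,
    beta: np.ndarray | None,
    basis: BasisMatrix,
) -> np.ndarray:
    """Solve the spline normal equations ``Z'Z alpha = Z'(Y - X beta)``.

    Given the parametric coefficients this is the profiled least-squares
    solve for the spline coefficients; ``X``/``beta`` may be None for a
    pure nonparametric fit.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != basis.n:
        raise ValueError("response length does not match basis rows")
    resid = y
    if X is not None and beta is not None:
        X = np.asarray(X, dtype=float)
        beta = np.asarray(beta, dtype=float).ravel()
        resid = y - X @ beta
    # Z = Q R  =>  alpha = R^{-1} Q' resid; fall back to lstsq when R is
    # ill-conditioned enough that triangular solve would amplify noise.
    rhs = basis._Q.T @ resid
    try:
        from scipy.linalg import solve_triangular

        return solve_triangular(basis._R, rhs)
    except np.linalg.LinAlgError:  # pragma: no cover - jitter path
        logger.warning("triangular solve failed; using least-squares fallback")
        alpha, *_ = lstsq(basis.Z, resid)
        return alpha


def evaluate_f(
    alpha: np.ndarray, u: np.ndarray, spec: SplineBasisSpec
) -> np.ndarray:
    """Evaluate the spline estimate ``f_hat(u) = B(u)' alpha`` pointwise."""
    alpha = np.asarray(alpha, dtype=float).ravel()
    if alpha.shape[0] != spec.q_n:
        raise ValueError("alpha length must equal q_n")
    return spec.design_matrix(u) @ alpha
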