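"""Penalized profiled objective and the LQA group-selection solver.

The estimator minimizes, over the parametric coefficients beta,

    Q_n(beta) = || (I - H)(Y - X beta) ||^2  +  sum_j lambda_j ||beta_j||^gamma,

where H projects onto the spline span of the index variable and the sum
runs over coefficient groups.  For gamma <= 1 the penalty is concave in the
group norm; whole groups are removed from the model.  Minimization uses
iterated local quadratic approximation (LQA): the penalty term
``lambda_j t^gamma`` is replaced by its tangent in ``t^2`` at the current
group norm, turning each step into a ridge solve on the active groups, and
any group whose norm falls below a hard threshold (1e-3 by default) is set
exactly to zero and permanently dropped.  The tangent construction makes
each step a majorize-minimize step, so the objective is nonincreasing
along the iterate path.

Penalty variants:

* adaptive group bridge (AGB): lambda_j = lambda / ||beta_j^(0)|| built
  from the profiled OLS initial estimate, gamma in (0, 1];
* group bridge (GB): constant lambda_j = lambda, gamma < 1;
* group lasso (GL): constant lambda_j = lambda, gamma = 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve, lstsq

from .basis import solve_alpha
from .design import ProfiledDesign

__all__ = [
    "PenaltySpec",
    "FitControls",
    "FitResult",
    "profiled_objective",
    "ols_init",
    "lqa_weight_matrix",
    "fit_penalized",
    "fit_agb",
    "fit_group_bridge",
    "fit_group_lasso",
]

logger = logging.getLogger(__name__)

#: groups whose initial norm falls below this are given the capped
#: adaptive weight lambda / ADAPTIVE_NORM_FLOOR instead of dividing by ~0
ADAPTIVE_NORM_FLOOR = 1e-8


@dataclass(frozen=True)
class PenaltySpec:
    """Group-bridge penalty ``sum_j lambda_j ||beta_j||^gamma``.

    ``mode`` records whether the per-group weights are adaptive
    (``lambda_j = lambda / ||beta_j^(0)||``) or constant (= lambda).
    """

    gamma: float
    lambda_per_group: np.ndarray
    mode: str = "constant"
    lambda_scalar: float | None = None

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("penalty exponent gamma must be positive")
        lam = np.asarray(self.lambda_per_group, dtype=float).ravel()
        if np.any(lam < 0):
            raise ValueError("per-group penalties must be nonnegative")
        object.__setattr__(self, "lambda_per_group", lam)
        if self.mode not in ("adaptive", "constant"):
            raise ValueError("mode must be 'adaptive' or 'constant'")

    @classmethod
    def constant(cls, lambda_scalar: float, gamma: float, n_groups: int) -> "PenaltySpec":
        return cls(
            gamma=gamma,
            lambda_per_group=np.full(n_groups, float(lambda_scalar)),
            mode="constant",
            lambda_scalar=float(lambda_scalar),
        )

    @classmethod
    def adaptive(
        cls, lambda_scalar: float, gamma: float, init_group_norms: np.ndarray
    ) -> "PenaltySpec":
        """Adaptive weights from an initial estimate's group norms.

        Norms below ``ADAPTIVE_NORM_FLOOR`` are floored (weight capped)
        rather than divided through, keeping the objective finite; such
        groups are then almost surely thresholded out during fitting.
        """
        norms = np.asarray(init_group_norms, dtype=float).ravel()
        small = norms < ADAPTIVE_NORM_FLOOR
        if np.any(small):
            warnings.warn(
                f"{int(small.sum())} group(s) have near-zero initial norm; "
                "capping their adaptive penalty weight",
                stacklevel=2,
            )
        return cls(
            gamma=gamma,
            lambda_per_group=float(lambda_scalar)
            / np.maximum(norms, ADAPTIVE_NORM_FLOOR),
            mode="adaptive",
            lambda_scalar=float(lambda_scalar),
        )


@dataclass(frozen=True)
class FitControls:
    """Iteration controls for the LQA solver."""

    tol: float = 1e-6
    max_iter: int = 200
    zero_threshold: float = 1e-3


@dataclass
class FitResult:
    """Output of a penalized (or OLS) fit.

    ``beta`` is the full stacked coefficient vector with exact zeros in
    thresholded groups; ``selected_groups`` indexes groups with nonzero
    norm; ``objective_trace`` holds Q_n at the initial point and after
    every LQA iteration.
    """

    beta: np.ndarray
    alpha: np.ndarray
    selected_groups: np.ndarray
    n_iter: int
    converged: bool
    objective_trace: np.ndarray
    penalty: PenaltySpec | None = None
    used_pseudo_solve: bool = False
    group_sizes: np.ndarray | None = None

    @property
    def n_selected(self) -> int:
        return len(self.selected_groups)

    def group_norms(self) -> np.ndarray:
        sizes = self.group_sizes
        if sizes is None:
            raise ValueError("group sizes not recorded on this result")
        ends = np.cumsum(sizes)
        starts = ends - sizes
        return np.array(
            [np.linalg.norm(self.beta[s:e]) for s, e in zip(starts, ends)]
        )


def profiled_objective(
    beta: np.ndarray, design: ProfiledDesign, penalty: PenaltySpec
) -> float:
    """Evaluate ``Q_n(beta) = ||y* - X* beta||^2 + sum_j lambda_j ||beta_j||^gamma``."""
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.shape[0] != design.p_total:
        raise ValueError("beta length does not match design")
    resid = design.y_star - design.X_star @ beta
    norms = design.group_norms(beta)
    return float(resid @ resid + np.sum(penalty.lambda_per_group * norms ** penalty.gamma))


def _solve_spd(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, bool]:
    """Solve ``A x = b`` for symmetric positive-definite A, falling back to
    a least-squares pseudo-solution when the factorization fails."""
    try:
        c = cho_factor(A, lower=True, check_finite=False)
        return cho_solve(c, b, check_finite=False), False
    except (LinAlgError, np.linalg.LinAlgError):
        x, *_ = lstsq(A, b)
        return x, True


def ols_init(design: ProfiledDesign) -> np.ndarray:
    """Profiled ordinary least squares: argmin ||y* - X* beta||^2.

    Used as the LQA starting point and as the source of the adaptive
    penalty weights.  Requires ``X*'X*`` to be nonsingular (n > P).
    """
    G = design.gram
    # condition check: OLS init must be trustworthy, not a pseudo-solution
    eigmin = np.linalg.eigvalsh(G)[0]
    if eigmin <= 1e-10 * max(1.0, np.trace(G) / G.shape[0]):
        raise LinAlgError(
            "X*'X* is singular or near-singular; profiled OLS initialization "
            "is not available (need n > total number of covariates). "
            "Consider a ridge initialization."
        )
    beta, _ = _solve_spd(G, design.moment)
    return beta


def lqa_weight_matrix(
    beta_current: np.ndarray,
    penalty: PenaltySpec,
    design: ProfiledDesign,
    active_groups: np.ndarray | None = None,
    zero_threshold: float = 1e-3,
) -> np.ndarray:
    """Per-coordinate LQA weights ``lambda_j * gamma * ||beta_j||^(gamma-2)``.

    Returns the diagonal of the block weight matrix for the active groups,
    each group's scalar repeated ``d_j`` times.  Every active group must
    have norm at or above ``zero_threshold``: the solver drops groups
    before calling this, and a near-zero norm here would blow up the
    ``gamma - 2`` power.
    """
    beta_current = np.asarray(beta_current, dtype=float).ravel()
    norms = design.group_norms(beta_current)
    if active_groups is None:
        active_groups = np.arange(design.n_groups)
    sizes = design.group_sizes
    entries = []
    for j in active_groups:
        t = norms[j]
        if t < zero_threshold:
            raise ValueError(
                f"group {j} is active but has norm {t:.2e} below the zero "
                "threshold; drop it before building LQA weights"
            )
        w = penalty.lambda_per_group[j] * penalty.gamma * t ** (penalty.gamma - 2.0)
        entries.append(np.full(sizes[j], w))
    if not entries:
        return np.empty(0)
    return np.concatenate(entries)


def _active_index(design: ProfiledDesign, active_groups: np.ndarray) -> np.ndarray:
    slices = design.slices
    if len(active_groups) == 0:
        return np.empty(0, dtype=int)
    return np.concatenate([np.arange(s.start, s.stop) for s in (slices[j] for j in active_groups)])


def fit_penalized(
    design: ProfiledDesign,
    penalty: PenaltySpec,
    init: np.ndarray,
    controls: FitControls | None = None,
) -> FitResult:
    """Minimize the penalized profiled objective by iterated LQA.

    Each iteration solves the ridge system

        [X*'X* + (1/2) diag(lambda_j gamma ||beta_j||^(gamma-2))] beta = X*'y*

    restricted to the active groups (the tangent-majorizer step for the
    concave penalty), then zeroes and permanently removes any group whose
    norm falls below ``controls.zero_threshold``.  Stops when the max-norm
    change of beta drops below ``controls.tol`` or at ``max_iter``.
    """
    controls = controls or FitControls()
    init = np.asarray(init, dtype=float).ravel()
    if init.shape[0] != design.p_total:
        raise ValueError("init length does not match design")

    norms = design.group_norms(init)
    active = np.flatnonzero(norms >= controls.zero_threshold)
    beta = np.zeros(design.p_total)
    idx = _active_index(design, active)
    beta[idx] = init[idx]

    trace = [profiled_objective(beta, design, penalty)]
    used_pseudo = False
    converged = False
    n_iter = 0

    unpenalized = np.all(penalty.lambda_per_group == 0)

    for n_iter in range(1, controls.max_iter + 1):
        if len(active) == 0:
            converged = True
            break
        idx = _active_index(design, active)
        G = design.gram[np.ix_(idx, idx)]
        b = design.moment[idx]
        if unpenalized:
            A = G
        else:
            w = lqa_weight_matrix(
                beta, penalty, design, active, controls.zero_threshold
            )
            A = G + 0.5 * np.diag(w)
        sol, pseudo = _solve_spd(A, b)
        used_pseudo = used_pseudo or pseudo

        new_beta = np.zeros(design.p_total)
        new_beta[idx] = sol
        # hard group thresholding: small groups leave the model for good
        new_norms = design.group_norms(new_beta)
        keep = []
        for j in active:
            if new_norms[j] < controls.zero_threshold:
                new_beta[design.slices[j]] = 0.0
            else:
                keep.append(j)
        new_active = np.asarray(keep, dtype=int)

        delta = np.max(np.abs(new_beta - beta)) if design.p_total else 0.0
        beta, active = new_beta, new_active
        trace.append(profiled_objective(beta, design, penalty))
        if delta < controls.tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"LQA did not converge in {controls.max_iter} iterations", stacklevel=2
        )
    alpha = solve_alpha(design.y, design.X, beta, design.basis)
    return FitResult(
        beta=beta,
        alpha=alpha,
        selected_groups=np.asarray(active, dtype=int),
        n_iter=n_iter,
        converged=converged,
        objective_trace=np.asarray(trace),
        penalty=penalty,
        used_pseudo_solve=used_pseudo,
        group_sizes=design.group_sizes,
    )


def fit_agb(
    design: ProfiledDesign,
    lambda_scalar: float,
    gamma: float,
    controls: FitControls | None = None,
) -> FitResult:
    """Adaptive group bridge fit.

    Builds adaptive weights ``lambda_j = lambda / ||beta_j^(0)||`` from the
    profiled OLS estimate and runs the LQA solver starting from that same
    OLS vector.
    """
    beta0 = ols_init(design)
    penalty = PenaltySpec.adaptive(lambda_scalar, gamma, design.group_norms(beta0))
    return fit_penalized(design, penalty, beta0, controls)


def fit_group_bridge(
    design: ProfiledDesign,
    lambda_scalar: float,
    gamma: float = 0.5,
    controls: FitControls | None = None,
) -> FitResult:
    """Group bridge fit: constant per-group weight, concave exponent."""
    beta0 = ols_init(design)
    penalty = PenaltySpec.constant(lambda_scalar, gamma, design.n_groups)
    return fit_penalized(design, penalty, beta0, controls)


def fit_group_lasso(
    design: ProfiledDesign,
    lambda_scalar: float,
    controls: FitControls | None = None,
) -> FitResult:
    """Group lasso fit: the gamma = 1 boundary of the bridge family."""
    return fit_group_bridge(design, lambda_scalar, gamma=1.0, controls=controls)
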