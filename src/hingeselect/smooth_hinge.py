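"""Smooth-hinge (modified-logistic) SVM loss and the penalized fitting engine.

The hinge loss ``n^-1 sum (1 - y_i x_i'beta)_+`` has a nondifferentiable kink,
so fitting replaces it with the softplus-type surrogate

    L_gamma(beta) = (n*gamma)^-1 sum log(1 + exp(gamma * (1 - y_i x_i'beta)))

which upper-bounds the hinge by at most ``log(2)/gamma`` per observation and
converges to it as gamma grows.  On top of this smooth loss the engine fits

* ridge / unpenalized models with a damped Newton method,
* LASSO models with FISTA (proximal gradient with momentum),
* TLP / SCAD / MCP models with an outer difference-of-convex loop that
  linearizes the concave part of the penalty at the current iterate (each
  outer step is a weighted-l1 FISTA solve).

A gamma continuation schedule (default 5 -> 10 -> 25 -> 50) warm-starts each
stage so the sharp final surrogate is never attacked from a cold start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .penalties import PenaltySpec, penalty_derivative, penalty_value

__all__ = [
    "DesignMatrix",
    "FitConfig",
    "FitResult",
    "hinge_loss",
    "mlr_loss",
    "fit_penalized",
    "select_lambda_cv",
    "selected_support",
    "default_lambda_grid",
]

logger = logging.getLogger(__name__)


def default_lambda_grid() -> np.ndarray:
    """The lambda grid (2^0 ... 2^-10) x 1e-3, descending (11 values)."""
    return (2.0 ** -np.arange(11)) * 1e-3


@dataclass(frozen=True)
class DesignMatrix:
    """n x (p+1) design whose first column is the all-ones intercept term."""

    values: np.ndarray
    column_names: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "column_names", tuple(self.column_names))
        if v.ndim != 2:
            raise ValueError("design must be 2-D")
        if v.shape[1] != len(self.column_names) + 1:
            raise ValueError(
                f"design has {v.shape[1]} columns but {len(self.column_names)} names "
                "(+1 intercept) were given"
            )
        if not np.allclose(v[:, 0], 1.0):
            raise ValueError("first design column must be the constant intercept 1")
        if not np.isfinite(v).all():
            raise ValueError("design contains missing or non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings.

    gamma is the final smoothness of the surrogate loss; gamma_schedule is the
    warm-start continuation path ending at gamma.  lambda_grid is used by
    cross-validated lambda selection.  tau doubles as the default support
    threshold: under TLP any coefficient past tau sits on the penalty plateau
    and is considered selected.
    """

    gamma: float = 50.0
    gamma_schedule: Sequence[float] = (5.0, 10.0, 25.0, 50.0)
    tol: float = 1e-6
    max_iter: int = 500
    inner_max_iter: int = 2000
    inner_tol: float = 1e-9
    lambda_grid: np.ndarray = field(default_factory=default_lambda_grid)
    tau: float = 1e-4
    seed: int = 0
    penalize_intercept: bool = False

    def __post_init__(self):
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        grid = np.asarray(self.lambda_grid, dtype=float)
        if grid.size == 0 or np.any(grid <= 0):
            raise ValueError("lambda_grid must be nonempty and positive")
        object.__setattr__(self, "lambda_grid", grid)


@dataclass
class FitResult:
    """Outcome of a penalized fit."""

    beta: np.ndarray
    column_names: tuple
    support: set
    objective_trace: np.ndarray
    lambda_used: float
    converged: bool
    penalty_kind: str


def _margins(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return 1.0 - y * (X @ beta)


def hinge_loss(X, y, beta) -> float:
    """Average hinge loss n^-1 sum (1 - y_i x_i'beta)_+."""
    X, y, beta = _coerce(X, y, beta)
    m = _margins(X, y, beta)
    return float(np.maximum(m, 0.0).mean())


def mlr_loss(X, y, beta, gamma: float) -> float:
    """Smooth surrogate (n*gamma)^-1 sum softplus(gamma*(1 - y_i x_i'beta)).

    Evaluated with log1p/exp identities so it never overflows: for large
    positive arguments softplus(z) = z + log1p(exp(-z)).
    """
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    X, y, beta = _coerce(X, y, beta)
    z = gamma * _margins(X, y, beta)
    return float(np.logaddexp(0.0, z).mean() / gamma)


def _coerce(X, y, beta):
    X = X.values if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.shape[0] != y.shape[0] or X.shape[1] != beta.shape[0]:
        raise ValueError(
            f"shape mismatch: X {X.shape}, y {y.shape}, beta {beta.shape}"
        )
    return X, y, beta


def _loss_grad(X, y, beta, gamma):
    """Value and gradient of the smooth surrogate loss."""
    n = len(y)
    z = gamma * _margins(X, y, beta)
    val = float(np.logaddexp(0.0, z).sum() / (n * gamma))
    s = expit(z)
    grad = -(X.T @ (y * s)) / n
    return val, grad


def _loss_only(X, y, beta, gamma):
    n = len(y)
    z = gamma * _margins(X, y, beta)
    return float(np.logaddexp(0.0, z).sum() / (n * gamma))


def _newton_smooth(X, y, beta0, gamma, ridge_lam, pen_mask, tol, max_iter):
    """Damped Newton on mlr_loss + ridge_lam * sum(beta[pen_mask]**2).

    Returns (beta, trace, converged).  The Hessian is (gamma/n) X' D X with
    D = s(1-s) <= 1/4; a small Levenberg damping keeps it solvable in the
    separable / flat regime.
    """
    n, p = X.shape
    beta = beta0.copy()
    reg = 2.0 * ridge_lam * pen_mask

    def objective(b):
        val, _ = _loss_grad(X, y, b, gamma)
        return val + ridge_lam * float(np.sum((b * pen_mask) ** 2))

    obj = objective(beta)
    trace = [obj]
    converged = False
    for _ in range(max_iter):
        z = gamma * _margins(X, y, beta)
        s = expit(z)
        grad = -(X.T @ (y * s)) / n + reg * beta
        w = s * (1.0 - s)
        H = (gamma / n) * (X.T @ (X * w[:, None]))
        H[np.arange(p), np.arange(p)] += reg + 1e-10
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad
        # backtracking line search
        t, new_obj = 1.0, None
        for _ls in range(40):
            cand = beta - t * step
            new_obj = objective(cand)
            if new_obj <= obj - 1e-4 * t * float(grad @ step):
                break
            t *= 0.5
        if new_obj is None or new_obj > obj:
            converged = np.linalg.norm(grad) < 1e-4
            break
        beta = beta - t * step
        rel = (obj - new_obj) / max(abs(obj), 1e-12)
        obj = new_obj
        trace.append(obj)
        if rel < tol:
            converged = True
            break
    return beta, np.asarray(trace), converged


def _lipschitz(X, gamma):
    smax = np.linalg.norm(X, 2)
    return gamma * smax**2 / (4.0 * X.shape[0])


def _fista_weighted_l1(X, y, beta0, gamma, weights, tol, max_iter, L=None,
                       check_every: int = 4):
    """Minimize mlr_loss + sum(weights * |beta|) by FISTA with restart.

    weights is a per-coordinate nonnegative vector (0 for the intercept).
    The objective is monitored every ``check_every`` iterations (with restart
    of the momentum on increase); the best iterate seen is returned, so the
    objective never exceeds its starting value.
    """
    if L is None:
        L = _lipschitz(X, gamma)
    step = 1.0 / L

    def objective(b):
        return _loss_only(X, y, b, gamma) + float(weights @ np.abs(b))

    beta = beta0.copy()
    z = beta.copy()
    t_mom = 1.0
    best_obj = objective(beta)
    best_beta = beta.copy()
    prev_checked = best_obj
    it = 0
    while it < max_iter:
        _, grad = _loss_grad(X, y, z, gamma)
        cand = z - step * grad
        cand = np.sign(cand) * np.maximum(np.abs(cand) - step * weights, 0.0)
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2)) / 2.0
        z = cand + ((t_mom - 1.0) / t_next) * (cand - beta)
        beta, t_mom = cand, t_next
        it += 1
        if it % check_every == 0 or it == max_iter:
            obj = objective(beta)
            if obj > prev_checked:  # momentum overshoot: restart from best
                z = best_beta.copy()
                beta = best_beta.copy()
                t_mom = 1.0
                prev_checked = best_obj
                continue
            rel = (prev_checked - obj) / max(abs(prev_checked), 1e-12)
            if obj < best_obj:
                best_obj = obj
                best_beta = beta.copy()
            prev_checked = obj
            if rel < tol:
                break
    return best_beta, best_obj, it


def _full_objective(X, y, beta, gamma, penalty: PenaltySpec, pen_mask):
    val, _ = _loss_grad(X, y, beta, gamma)
    pen = np.asarray(penalty_value(np.abs(beta), penalty)) * pen_mask
    return val + float(pen.sum())


def fit_penalized(
    X,
    y,
    penalty: PenaltySpec,
    config: FitConfig | None = None,
    beta0: np.ndarray | None = None,
) -> FitResult:
    """Fit the smooth-hinge SVM with the given penalty.

    Nonconvex penalties (tlp/scad/mcp) are handled by an outer DC loop that
    replaces the penalty with its local linearization weight
    ``P'(|beta_current|) * |beta|`` and solves each weighted-l1 subproblem with
    FISTA; the true penalized objective is monotonically nonincreasing across
    outer iterations.  ``beta0`` warm-starts at the final gamma (skipping the
    continuation schedule), which the cross-validation loops exploit.
    """
    config = config or FitConfig()
    names = None
    if isinstance(X, DesignMatrix):
        names = X.column_names
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if names is None:
        names = tuple(f"x{j}" for j in range(1, X.shape[1]))
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on n")
    if not np.isfinite(X).all():
        raise ValueError("design contains missing values; complete cases are required")
    classes = np.unique(y)
    if not np.array_equal(np.sort(classes), [-1.0, 1.0]):
        raise ValueError("y must contain both classes coded -1/+1")

    p = X.shape[1]
    pen_mask = np.ones(p)
    if not config.penalize_intercept:
        pen_mask[0] = 0.0

    if beta0 is not None:
        schedule = [config.gamma]
        beta = np.asarray(beta0, dtype=float).copy()
    else:
        schedule = [g for g in config.gamma_schedule if g < config.gamma] + [config.gamma]
        beta = np.zeros(p)

    trace = np.empty(0)
    converged = True
    for gamma in schedule:
        is_final = gamma == schedule[-1]
        if penalty.kind == "ridge" or penalty.lam == 0.0:
            lam = penalty.lam if penalty.kind == "ridge" else 0.0
            beta, tr, ok = _newton_smooth(
                X, y, beta, gamma, lam, pen_mask, config.tol, config.max_iter
            )
            if is_final:
                trace, converged = tr, ok
        elif penalty.kind == "lasso":
            weights = penalty.lam * pen_mask
            obj0 = _full_objective(X, y, beta, gamma, penalty, pen_mask)
            inner = config.inner_max_iter if is_final else min(300, config.inner_max_iter)
            beta, obj, _it = _fista_weighted_l1(
                X, y, beta, gamma, weights, config.inner_tol, inner
            )
            if is_final:
                trace = np.asarray([obj0, min(obj, obj0)])
                converged = True
        else:  # nonconvex: DC / local linear approximation loop
            L = _lipschitz(X, gamma)
            objs = [_full_objective(X, y, beta, gamma, penalty, pen_mask)]
            ok = False
            # continuation stages only warm-start: rough, cheap solves there
            outer_cap = config.max_iter if is_final else 5
            inner_cap = config.inner_max_iter if is_final else 200
            inner_budget = 10 * config.inner_max_iter  # hard stop for crawling
            spent = 0
            for _ in range(outer_cap):
                weights = np.asarray(
                    penalty_derivative(np.abs(beta), penalty)
                ) * pen_mask
                inner = min(inner_cap, inner_budget - spent)
                if inner <= 0:
                    break
                beta, _, used = _fista_weighted_l1(
                    X, y, beta, gamma, weights,
                    config.inner_tol, inner, L=L,
                )
                spent += used
                obj = _full_objective(X, y, beta, gamma, penalty, pen_mask)
                objs.append(min(obj, objs[-1]))
                rel = (objs[-2] - obj) / max(abs(objs[-2]), 1e-12)
                if rel < config.tol:
                    ok = True
                    break
            if is_final:
                trace = np.asarray(objs)
                converged = ok
    if not converged:
        logger.warning("fit_penalized did not converge within max_iter (penalty=%s)", penalty.kind)

    thresh = config.tau if penalty.kind == "tlp" else 1e-6
    support = {names[j - 1] for j in range(1, p) if abs(beta[j]) > thresh}
    return FitResult(
        beta=beta,
        column_names=names,
        support=support,
        objective_trace=trace,
        lambda_used=penalty.lam,
        converged=converged,
        penalty_kind=penalty.kind,
    )


def selected_support(fit: FitResult, threshold: float | None = None) -> set:
    """Names of the non-intercept coefficients with |beta_j| > threshold.

    The default threshold is tau (1e-4): under TLP the penalty is flat past
    tau, so anything beyond it sits on the plateau and counts as selected.
    """
    if threshold is None:
        threshold = 1e-4
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    return {
        fit.column_names[j - 1]
        for j in range(1, len(fit.beta))
        if abs(fit.beta[j]) > threshold
    }


def _make_spec(kind: str, lam: float, config: FitConfig) -> PenaltySpec:
    if kind == "tlp":
        return PenaltySpec("tlp", lam, tau=config.tau)
    return PenaltySpec(kind, lam)


def _cv_fold_indices(n: int, n_folds: int | None, seed: int):
    """LOO (n_folds=None) or seeded balanced K-fold index sets."""
    if n_folds is None or n_folds >= n:
        return [np.array([i]) for i in range(n)]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(perm[k::n_folds]) for k in range(n_folds)]


def select_lambda_cv(
    X,
    y,
    penalty_kind: str = "tlp",
    config: FitConfig | None = None,
    n_folds: int | None = None,
):
    """Pick lambda from the grid by cross-validated accuracy.

    Leave-one-out by default (``n_folds=None``); ties break toward the larger
    lambda, i.e. the sparser model.  Returns ``(lambda_used, cv_curve)`` where
    ``cv_curve`` holds one accuracy per grid value, in grid order.
    """
    config = config or FitConfig()
    names = X.column_names if isinstance(X, DesignMatrix) else None
    Xv = X.values if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = Xv.shape[0]
    if n < 3:
        raise ValueError("cross-validation needs at least 3 subjects")
    grid = np.sort(np.asarray(config.lambda_grid, dtype=float))[::-1]
    folds = _cv_fold_indices(n, n_folds, config.seed)

    cv_curve = np.zeros(len(grid))
    full_beta = None
    for gi, lam in enumerate(grid):
        spec = _make_spec(penalty_kind, lam, config)
        full = fit_penalized(Xv, y, spec, config, beta0=full_beta)
        full_beta = full.beta
        correct = 0
        for idx in folds:
            mask = np.ones(n, dtype=bool)
            mask[idx] = False
            ytr = y[mask]
            if len(np.unique(ytr)) < 2:
                pred = np.sign(ytr.sum()) or 1.0
                correct += int(np.sum(y[idx] == pred))
                continue
            fold_fit = fit_penalized(Xv[mask], ytr, spec, config, beta0=full_beta)
            scores = Xv[idx] @ fold_fit.beta
            pred = np.where(scores >= 0, 1.0, -1.0)
            correct += int(np.sum(pred == y[idx]))
        cv_curve[gi] = correct / n
    best = int(np.argmax(cv_curve))  # first max in descending grid = largest lambda
    lam_used = float(grid[best])
    if names is not None:
        logger.info("select_lambda_cv: lambda=%.3g, accuracy=%.3f", lam_used, cv_curve[best])
    return lam_used, cv_curve
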