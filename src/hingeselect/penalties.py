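"""Sparsity-inducing penalty functions for coefficient shrinkage and selection.

Implements the closed forms of the LASSO, SCAD, MCP, TLP and ridge penalties
together with the difference-of-convex (DC) decomposition P = g - h that the
nonconvex optimizer linearizes.  All functions act on the *magnitude* of a
coefficient, so callers pass ``abs(beta)``.

Conventions
-----------
* TLP (truncated lasso penalty): ``P(t) = lam * min(t / tau, 1)`` — bounded by
  ``lam``; coefficients past ``tau`` sit on a flat plateau and incur a constant
  cost, which is what makes it behave like a continuous best-subset penalty.
* SCAD uses the continuity-forced constant branch ``(a + 1) * lam**2 / 2`` for
  ``t > a*lam`` (the value the quadratic middle branch attains at ``a*lam``).
* MCP: ``P(t) = lam*t - t**2/(2a)`` for ``t <= a*lam``, then ``a*lam**2/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "PenaltySpec",
    "DCDecomposition",
    "penalty_value",
    "penalty_derivative",
    "penalty_dc_parts",
]

_KINDS = ("lasso", "scad", "mcp", "tlp", "ridge")

_DEFAULT_A = {"scad": 3.7, "mcp": 3.0}


@dataclass(frozen=True)
class PenaltySpec:
    """Which penalty to apply and with what parameters.

    Parameters
    ----------
    kind:
        One of ``lasso``, ``scad``, ``mcp``, ``tlp``, ``ridge``.
    lam:
        Regularization strength λ ≥ 0.
    tau:
        TLP truncation level τ > 0 (ignored otherwise).  Default 1e-4.
    a:
        Concavity parameter for SCAD (a > 2, default 3.7) and MCP
        (a > 1, default 3.0).
    """

    kind: str
    lam: float
    tau: float = 1e-4
    a: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown penalty kind {self.kind!r}; expected one of {_KINDS}")
        if not np.isfinite(self.lam) or self.lam < 0:
            raise ValueError(f"lam must be a nonnegative real, got {self.lam}")
        if self.kind == "tlp" and not (np.isfinite(self.tau) and self.tau > 0):
            raise ValueError(f"tlp requires tau > 0, got {self.tau}")
        if self.kind in ("scad", "mcp"):
            a = self.a
            if np.isnan(a):
                a = _DEFAULT_A[self.kind]
                object.__setattr__(self, "a", a)
            lower = 2.0 if self.kind == "scad" else 1.0
            if not a > lower:
                raise ValueError(f"{self.kind} requires a > {lower} for continuity, got {a}")

    @property
    def is_convex(self) -> bool:
        return self.kind in ("lasso", "ridge")


def _check_magnitude(beta_abs):
    t = np.asarray(beta_abs, dtype=float)
    if np.any(t < 0):
        raise ValueError("penalty_value expects |beta|; got a negative magnitude")
    return t


def penalty_value(beta_abs, spec: PenaltySpec):
    """Evaluate P_λ(|β|) elementwise.  Scalar in → scalar out."""
    t = _check_magnitude(beta_abs)
    lam, a, tau = spec.lam, spec.a, spec.tau
    if spec.kind == "lasso":
        out = lam * t
    elif spec.kind == "ridge":
        out = lam * t**2
    elif spec.kind == "tlp":
        out = lam * np.minimum(t / tau, 1.0)
    elif spec.kind == "scad":
        out = np.where(
            t <= lam,
            lam * t,
            np.where(
                t <= a * lam,
                (2 * a * lam * t - t**2 - lam**2) / (2 * (a - 1)),
                (a + 1) * lam**2 / 2,
            ),
        )
    else:  # mcp
        out = np.where(t <= a * lam, lam * t - t**2 / (2 * a), a * lam**2 / 2)
    return out if out.ndim else float(out)


def penalty_derivative(beta_abs, spec: PenaltySpec):
    """dP/dt at t = |β| (right derivative at kinks).

    For the nonconvex penalties this is the per-coordinate weight the DC /
    local-linear-approximation step places on |β|.
    """
    t = _check_magnitude(beta_abs)
    lam, a, tau = spec.lam, spec.a, spec.tau
    if spec.kind == "lasso":
        out = np.full_like(t, lam)
    elif spec.kind == "ridge":
        out = 2 * lam * t
    elif spec.kind == "tlp":
        out = np.where(t < tau, lam / tau, 0.0)
    elif spec.kind == "scad":
        out = np.where(t <= lam, lam, np.maximum(a * lam - t, 0.0) / (a - 1))
    else:  # mcp
        out = np.maximum(lam - t / a, 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DCDecomposition:
    """P = g - h with g, h convex; h is the concave correction the DCA linearizes.

    ``g`` is the tightest multiple-of-|t| majorant: slope λ/τ for TLP, λ for
    SCAD/MCP.  ``h_prime`` is a subgradient of h usable for linearization.
    """

    g: Callable
    h: Callable
    g_slope: float
    h_prime: Callable


def penalty_dc_parts(spec: PenaltySpec) -> DCDecomposition:
    """DC decomposition of a nonconvex penalty.

    Raises
    ------
    ValueError
        For convex kinds (lasso/ridge) where no decomposition is needed.
    """
    if spec.is_convex:
        raise ValueError(f"penalty {spec.kind!r} is convex; DC decomposition not applicable")
    slope = spec.lam / spec.tau if spec.kind == "tlp" else spec.lam

    def g(t):
        t = _check_magnitude(t)
        out = slope * t
        return out if out.ndim else float(out)

    def h(t):
        t = _check_magnitude(t)
        out = slope * t - np.asarray(penalty_value(t, spec))
        return out if out.ndim else float(out)

    def h_prime(t):
        t = _check_magnitude(t)
        out = slope - np.asarray(penalty_derivative(t, spec))
        return out if out.ndim else float(out)

    return DCDecomposition(g=g, h=h, g_slope=slope, h_prime=h_prime)
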