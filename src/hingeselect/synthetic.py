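"""Seeded generator of cohort-like tables with known ground truth.

Every downstream stage (screening, penalized selection, stepwise building,
the overfitting test) is exercised against data whose informative variables
are known.  Features come from a block-equicorrelated multivariate normal;
the binary outcome is a thresholded latent score

    score = sum_j beta_j x_j  +  sum_k amp_k f_k(x_k)  +  logistic noise

with f_k one of three unit-variance smooth shapes (quadratic, sigmoid,
cubic).  The threshold (intercept) is calibrated on an internal draw so the
positive-class fraction matches the requested balance in expectation —
by default 34/91, the steroid-resistant share of the motivating cohort.
Missingness is applied completely at random per variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocessing import CohortTable

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "presets", "write_cohort_csv"]

_SQRT2 = np.sqrt(2.0)
_SQRT15 = np.sqrt(15.0)
_TANH2_SD = 0.7262575

#: unit-variance smooth shapes for nonlinear effects (input ~ N(0,1))
SHAPES = {
    "quadratic": lambda x: (x**2 - 1.0) / _SQRT2,
    "sigmoid": lambda x: np.tanh(2.0 * x) / _TANH2_SD,
    "cubic": lambda x: x**3 / _SQRT15,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """A fully stated synthetic-cohort world.

    ``linear_effects``: variable -> coefficient on the latent score.
    ``nonlinear_effects``: variable -> (shape tag, amplitude in sd units).
    ``block_sizes``/``rho``: equicorrelated feature blocks (trailing
    variables form a final block); rho in [0, 1).
    ``class_balance``: expected positive (+1) fraction.
    ``missing_rates``: variable -> MCAR missingness probability.
    """

    n_subjects: int = 91
    n_variables: int = 20
    block_sizes: Sequence[int] = ()
    rho: float = 0.0
    linear_effects: Mapping[str, float] = field(default_factory=dict)
    nonlinear_effects: Mapping[str, tuple] = field(default_factory=dict)
    class_balance: float = 34 / 91
    noise_scale: float = 1.0
    label_noise: float = 0.0
    missing_rates: Mapping[str, float] = field(default_factory=dict)
    variable_names: Sequence[str] = ()
    seed: int = 0

    def __post_init__(self):
        if set(self.linear_effects) & set(self.nonlinear_effects):
            raise ValueError("linear and nonlinear signal sets must be disjoint")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        for r in list(self.missing_rates.values()) + [self.label_noise]:
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")
        if sum(self.block_sizes) > self.n_variables:
            raise ValueError("block sizes exceed n_variables")
        names = list(self.variable_names) or [
            f"X{j + 1:02d}" for j in range(self.n_variables)
        ]
        if len(names) != self.n_variables:
            raise ValueError("variable_names length must equal n_variables")
        unknown = (set(self.linear_effects) | set(self.nonlinear_effects)
                   | set(self.missing_rates)) - set(names)
        if unknown:
            raise ValueError(f"signal/missingness refers to unknown variables: {sorted(unknown)}")
        for shape, _amp in self.nonlinear_effects.values():
            if shape not in SHAPES:
                raise ValueError(f"unknown shape {shape!r}; expected one of {sorted(SHAPES)}")
        object.__setattr__(self, "variable_names", tuple(names))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted."""

    linear_signals: dict
    nonlinear_signals: dict
    intercept: float

    @property
    def signal_variables(self) -> set:
        return set(self.linear_signals) | set(self.nonlinear_signals)


def _draw_features(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    p = spec.n_variables
    X = np.empty((n, p))
    sizes = list(spec.block_sizes)
    if (rem := p - sum(sizes)) > 0:
        sizes.append(rem)
    start = 0
    for size in sizes:
        e = rng.standard_normal((n, size))
        if spec.rho > 0 and size > 1:
            g = rng.standard_normal((n, 1))
            X[:, start:start + size] = (
                np.sqrt(spec.rho) * g + np.sqrt(1.0 - spec.rho) * e
            )
        else:
            X[:, start:start + size] = e
        start += size
    return X


def _latent(spec: SyntheticSpec, X: np.ndarray, names, rng) -> np.ndarray:
    idx = {name: j for j, name in enumerate(names)}
    score = np.zeros(len(X))
    for name, coef in spec.linear_effects.items():
        score += coef * X[:, idx[name]]
    for name, (shape, amp) in spec.nonlinear_effects.items():
        score += amp * SHAPES[shape](X[:, idx[name]])
    score += rng.logistic(scale=spec.noise_scale, size=len(X))
    return score


def generate(spec: SyntheticSpec, seed: int | None = None):
    """Draw one cohort.  Returns ``(CohortTable, GroundTruth)``.

    Identical (spec, seed) pairs give byte-identical tables.  The intercept
    is set to the (1 - balance) quantile of the latent score estimated on a
    4000-draw calibration sample, so the class balance holds in expectation
    rather than exactly per draw.
    """
    if seed is None:
        seed = spec.seed
    ss = np.random.SeedSequence(seed)
    rng_cal, rng_data, rng_miss, rng_flip = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    names = spec.variable_names

    Xcal = _draw_features(spec, 4000, rng_cal)
    cal_score = _latent(spec, Xcal, names, rng_cal)
    intercept = -float(np.quantile(cal_score, 1.0 - spec.class_balance))

    X = _draw_features(spec, spec.n_subjects, rng_data)
    score = _latent(spec, X, names, rng_data) + intercept
    y = np.where(score > 0, 1, -1).astype(np.int8)
    if spec.label_noise > 0:
        flip = rng_flip.random(spec.n_subjects) < spec.label_noise
        y[flip] = -y[flip]
    if len(np.unique(y)) < 2:
        raise ValueError("infeasible balance: generated cohort is single-class")

    data = pd.DataFrame(X, columns=list(names),
                        index=[f"S{i + 1:03d}" for i in range(spec.n_subjects)])
    for name, rate in spec.missing_rates.items():
        if rate > 0:
            holes = rng_miss.random(spec.n_subjects) < rate
            data.loc[holes, name] = np.nan
    labels = pd.Series(y, index=data.index, name="outcome")
    truth = GroundTruth(
        linear_signals=dict(spec.linear_effects),
        nonlinear_signals=dict(spec.nonlinear_effects),
        intercept=intercept,
    )
    return CohortTable(data=data, labels=labels), truth


# ---------------------------------------------------------------------------
# Presets: each is a fully stated world, fixed once.

def presets() -> dict:
    """Named synthetic worlds.

    * ``null`` — no signal at all; calibration input for screening and the
      overfitting test.
    * ``linear5`` — five strong linear effects echoing the roles of L%, N%,
      ALB (protective, negative) and C4, Vcl (risk, positive); 15 correlated
      decoys.  Cohort-sized (n=91).
    * ``mixed8`` — two linear + six nonlinear signals echoing the reduced
      clinical model's composition; n=300 because a design-stage power
      analysis showed six mutually competing nonlinear effects cap each
      variable's marginal R^2 near 1/7 of the latent variance, and only
      n≈300 delivers the per-variable screening power needed to flag all six.
    * ``cohort_shaped`` — 91 subjects x 87 variables, 9 of them with 60%
      missingness (so the >50% filter leaves 78), class balance 34:57.
    """
    linear5_names = ["L_pct", "N_pct", "ALB", "C4", "Vcl"] + [
        f"X{j:02d}" for j in range(6, 21)
    ]
    linear5 = SyntheticSpec(
        n_subjects=91,
        n_variables=20,
        block_sizes=(4, 4, 4, 4, 4),
        rho=0.3,
        linear_effects={"L_pct": -2.0, "N_pct": -2.5, "ALB": -1.5, "C4": 1.8, "Vcl": 1.5},
        variable_names=linear5_names,
    )
    mixed8_names = ["N_pct", "Vcl", "ESR", "u_OB", "IgA", "CHOL", "AST", "PT_prolonged"] + [
        f"X{j:02d}" for j in range(9, 31)
    ]
    mixed8 = SyntheticSpec(
        n_subjects=300,
        n_variables=30,
        rho=0.0,
        linear_effects={"N_pct": -1.5, "Vcl": 1.2},
        nonlinear_effects={
            "ESR": ("sigmoid", 2.0),
            "u_OB": ("quadratic", 2.0),
            "IgA": ("quadratic", 2.0),
            "CHOL": ("sigmoid", 2.0),
            "AST": ("cubic", 3.0),
            "PT_prolonged": ("cubic", 3.0),
        },
        variable_names=mixed8_names,
    )
    null = SyntheticSpec(n_subjects=91, n_variables=20, rho=0.0)
    cohort_names = [f"V{j:02d}" for j in range(1, 88)]
    cohort_shaped = SyntheticSpec(
        n_subjects=91,
        n_variables=87,
        block_sizes=(10, 10, 10, 10, 10),
        rho=0.4,
        linear_effects={"V01": -1.5, "V11": -2.0, "V21": -1.0, "V31": 1.2, "V41": 0.9},
        nonlinear_effects={
            "V51": ("sigmoid", 1.5),
            "V52": ("quadratic", 1.5),
            "V61": ("cubic", 1.5),
            "V62": ("sigmoid", 1.5),
            "V71": ("quadratic", 1.5),
            "V72": ("cubic", 1.5),
        },
        missing_rates={**{f"V{j:02d}": 0.6 for j in range(79, 88)},
                       **{f"V{j:02d}": 0.05 for j in range(42, 51)}},
        variable_names=cohort_names,
    )
    return {
        "null": null,
        "linear5": linear5,
        "mixed8": mixed8,
        "cohort_shaped": cohort_shaped,
    }


def write_cohort_csv(table: CohortTable, path) -> None:
    """Write a cohort in the input CSV dialect (labels as a class column)."""
    out = table.data.copy()
    out.insert(
        0, "outcome",
        np.where(table.labels == 1, table.positive_class, table.negative_class),
    )
    out.index.name = "subject"
    out.to_csv(path, na_rep="NA")
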