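"""Published SRNS-model coefficient fixtures (read-only).

Two models reported for the motivating 91-child nephrotic-syndrome cohort
are shipped as frozen coefficient sets so their printed formulas can be
evaluated and tested:

* a 5-variable linear SVM over standardized L%, N%, ALB, C4 and the
  vinculin autoantibody (Vcl);
* a reduced 8-variable model with N% and Vcl linear and six order-4
  B-spline blocks (ESR, u-OB, IgA, CHOL, AST, prolonged PT).

These are formula fixtures, NOT clinical predictors: the original cohort's
standardization constants and spline domains were never published, so the
spline basis values must be supplied by the caller (they default to zero,
which isolates the intercept + linear part of the formula).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["PublishedModel", "full_linear_model", "reduced_model"]


@dataclass(frozen=True)
class PublishedModel:
    """A frozen score formula: intercept + linear terms + spline-block dots."""

    name: str
    intercept: float
    linear_coefs: Mapping[str, float]
    spline_coefs: Mapping[str, tuple] = field(default_factory=dict)

    def decision(
        self,
        linear_inputs: Mapping[str, float] | None = None,
        spline_basis: Mapping[str, np.ndarray] | None = None,
    ) -> float:
        """Evaluate the score on standardized inputs.

        Unspecified linear inputs are 0 (the standardized mean); unspecified
        spline blocks contribute 0.
        """
        linear_inputs = linear_inputs or {}
        spline_basis = spline_basis or {}
        unknown = set(linear_inputs) - set(self.linear_coefs)
        unknown |= set(spline_basis) - set(self.spline_coefs)
        if unknown:
            raise KeyError(f"unknown model variables: {sorted(unknown)}")
        score = self.intercept
        for v, c in self.linear_coefs.items():
            score += c * float(linear_inputs.get(v, 0.0))
        for v, coefs in self.spline_coefs.items():
            basis = np.asarray(spline_basis.get(v, np.zeros(len(coefs))), dtype=float)
            if basis.shape != (len(coefs),):
                raise ValueError(f"spline basis for {v!r} must have length {len(coefs)}")
            score += float(basis @ np.asarray(coefs))
        return float(score)

    def classify(self, *args, **kwargs) -> int:
        """+1 = SRNS (steroid-resistant), -1 = SSNS; score 0 maps to +1."""
        return 1 if self.decision(*args, **kwargs) >= 0 else -1


def full_linear_model() -> PublishedModel:
    """The 5-variable linear SVM selected by the penalized (MLR+TLP) stage.

    score = 0.2527 - 0.4493 L% - 0.7948 N% - 0.2683 ALB + 0.2879 C4
            + 0.0925 Vcl
    """
    return PublishedModel(
        name="full_linear_5var",
        intercept=0.2527,
        linear_coefs={
            "L%": -0.4493,
            "N%": -0.7948,
            "ALB": -0.2683,
            "C4": 0.2879,
            "Vcl": 0.0925,
        },
    )


def reduced_model() -> PublishedModel:
    """The reduced 8-variable model: 2 linear terms + 6 order-4 spline blocks."""
    return PublishedModel(
        name="reduced_8var",
        intercept=0.440,
        linear_coefs={"N%": -0.1516, "Vcl": 0.0845},
        spline_coefs={
            "ESR": (-0.1802, 2.8125, 0.8125, 0.5181),
            "u-OB": (1.9623, -2.5043, 2.3149, -0.4819),
            "IgA": (1.9071, -4.0454, 2.4880, -0.5299),
            "CHOL": (-0.8849, -2.2604, 1.5635, -0.5050),
            "AST": (3.2336, -4.3389, 3.1936, 1.2667),
            "prolonged PT": (-3.6318, 1.8816, -1.2195, -1.9774),
        },
    )
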