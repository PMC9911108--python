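"""B-spline basis evaluation shared by screening and model building.

Order-s basis with NO interior knots: the knot vector repeats the domain
endpoints s times each, giving exactly s basis columns (the Bernstein-like
polynomial basis of degree s-1 on [lo, hi]).  Rows sum to one everywhere in
the domain; values outside the domain are clamped to the boundary rather
than extrapolated.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline


def bspline_basis(x, lo: float, hi: float, order: int) -> np.ndarray:
    """Evaluate the order-``order`` no-interior-knot basis at ``x``.

    Returns an (len(x), order) dense array.  Degenerate domains (lo == hi)
    yield the constant first basis function.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if not hi >= lo:
        raise ValueError(f"invalid domain [{lo}, {hi}]")
    if hi == lo:
        out = np.zeros((len(x), order))
        out[:, 0] = 1.0
        return out
    xc = np.clip(x, lo, hi)
    t = np.concatenate([np.full(order, lo), np.full(order, hi)])
    return BSpline.design_matrix(xc, t, order - 1, extrapolate=False).toarray()
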