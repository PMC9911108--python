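"""Model-free marginal and pairwise-joint variable screening.

Screens each variable (or pair) for association with the binary outcome
without assuming a model for the effect.  The default statistic is the R^2
of a B-spline regression of the class indicator on the variable — order 4
with no interior knots marginally, an order-3 tensor-product surface for
pairs — with significance from label permutations:

    p = (#{permuted statistic >= observed} + 1) / (n_perm + 1)

The statistic is deliberately pluggable (``statistic=`` hook): it is a
documented stand-in playing the role of a nonparametric screener that is
sensitive to smooth nonlinear effects, and a different marginal-association
statistic can be swapped in without touching the pipeline (the p < 0.05
gate, the T1/T2 joint taxonomy, and the downstream handling stay fixed).

Joint pairs are classified by the marginal results: T1 if neither member
shows a marginal effect, T2 if exactly one does; pairs whose members are
both marginally selected are excluded from the taxonomy.  Mirroring the
motivating analysis, joint pairs are reported but not fed into the final
model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Callable

import numpy as np
import pandas as pd

from ._splines import bspline_basis
from .preprocessing import CohortTable

__all__ = ["ScreeningResult", "marginal_screen", "joint_screen"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreeningResult:
    """Per-variable (or per-pair) screening records, sorted by p ascending.

    ``records`` columns: name, name2 (pairs only, else ""), statistic,
    p_value, effect_kind in {marginal, joint_T1, joint_T2}, selected.
    """

    records: pd.DataFrame
    alpha: float
    n_perm: int

    def selected_names(self) -> list:
        sel = self.records[self.records["selected"]]
        return sel["name"].tolist()

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _spline_r2_batch(B: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """R^2 of regressing every column of Y on basis B (shared design)."""
    coef, *_ = np.linalg.lstsq(B, Y, rcond=None)
    resid = Y - B @ coef
    ss_res = np.einsum("ij,ij->j", resid, resid)
    centered = Y - Y.mean(axis=0)
    ss_tot = np.einsum("ij,ij->j", centered, centered)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    return np.where(ss_tot > 0, np.clip(r2, 0.0, 1.0), 0.0)


def _default_marginal_statistic(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Order-4, no-interior-knot B-spline regression R^2 (vectorized over Y)."""
    B = bspline_basis(x, float(x.min()), float(x.max()), order=4)
    return _spline_r2_batch(B, Y)


def _perm_matrix(y01: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    cols = [y01] + [rng.permutation(y01) for _ in range(n_perm)]
    return np.column_stack(cols)


def marginal_screen(
    table: CohortTable,
    n_perm: int = 199,
    seed: int = 0,
    alpha: float = 0.05,
    min_complete: int = 20,
    statistic: Callable | None = None,
    bh_adjust: bool = False,
) -> ScreeningResult:
    """Screen every variable for a marginal effect on the outcome.

    Uses pairwise-complete observations per variable; permutes labels within
    that subset.  ``bh_adjust=True`` switches the selection gate from the raw
    p < alpha rule (the default, matching the motivating analysis) to
    Benjamini-Hochberg at level alpha.
    """
    stat_fn = statistic or _default_marginal_statistic
    ss = np.random.SeedSequence(seed)
    rows = []
    for var, child in zip(table.variables, ss.spawn(len(table.variables))):
        x_all = table.data[var].to_numpy(dtype=float)
        obs = np.isfinite(x_all)
        x = x_all[obs]
        y01 = ((table.labels.to_numpy()[obs] + 1) // 2).astype(float)
        if obs.sum() < min_complete:
            logger.warning(
                "marginal_screen: %r skipped (%d complete pairs < %d)",
                var, int(obs.sum()), min_complete,
            )
            continue
        if np.ptp(x) == 0.0:
            rows.append((var, "", 0.0, 1.0, "marginal"))
            continue
        rng = np.random.default_rng(child)
        Y = _perm_matrix(y01, n_perm, rng)
        stats = stat_fn(x, Y)
        p = (np.sum(stats[1:] >= stats[0]) + 1.0) / (n_perm + 1.0)
        rows.append((var, "", float(stats[0]), float(p), "marginal"))
    rec = pd.DataFrame(rows, columns=["name", "name2", "statistic", "p_value", "effect_kind"])
    rec["selected"] = _select(rec["p_value"].to_numpy(), alpha, bh_adjust)
    rec = rec.sort_values(["p_value", "name"], kind="stable").reset_index(drop=True)
    return ScreeningResult(records=rec, alpha=alpha, n_perm=n_perm)


def _select(p: np.ndarray, alpha: float, bh: bool) -> np.ndarray:
    if not bh:
        return p < alpha
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1.0)
    passed = np.minimum.accumulate(ranked[::-1])[::-1] <= alpha
    out = np.zeros(m, dtype=bool)
    out[order] = passed
    return out


def _pair_statistic(x1: np.ndarray, x2: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Tensor-product order-3 surface R^2 minus the larger single-axis R^2."""
    B1 = bspline_basis(x1, float(x1.min()), float(x1.max()), order=3)
    B2 = bspline_basis(x2, float(x2.min()), float(x2.max()), order=3)
    B12 = np.einsum("ni,nj->nij", B1, B2).reshape(len(x1), -1)
    r2_joint = _spline_r2_batch(B12, Y)
    r2_single = np.maximum(_spline_r2_batch(B1, Y), _spline_r2_batch(B2, Y))
    return np.maximum(r2_joint - r2_single, 0.0)


def joint_screen(
    table: CohortTable,
    marginal: ScreeningResult,
    n_perm: int = 199,
    seed: int = 0,
    alpha: float = 0.05,
    min_complete: int = 20,
    pairs=None,
) -> ScreeningResult:
    """Screen variable pairs for a joint effect beyond the stronger margin.

    Pairs whose members are both marginally selected are excluded (the joint
    taxonomy only covers T1 = neither marginal, T2 = exactly one marginal).
    ``pairs`` restricts the scan to an explicit list of 2-tuples.
    """
    marg = marginal.records.set_index("name")["selected"].to_dict()
    if pairs is None:
        pairs = [
            (a, b) for a, b in combinations(table.variables, 2)
            if not (marg.get(a, False) and marg.get(b, False))
        ]
    else:
        pairs = [tuple(p) for p in pairs
                 if not (marg.get(p[0], False) and marg.get(p[1], False))]
    ss = np.random.SeedSequence(seed)
    rows = []
    for (a, b), child in zip(pairs, ss.spawn(max(len(pairs), 1))):
        xa_all = table.data[a].to_numpy(dtype=float)
        xb_all = table.data[b].to_numpy(dtype=float)
        obs = np.isfinite(xa_all) & np.isfinite(xb_all)
        if obs.sum() < min_complete:
            logger.warning("joint_screen: pair (%r, %r) skipped (too few complete rows)", a, b)
            continue
        xa, xb = xa_all[obs], xb_all[obs]
        if np.ptp(xa) == 0.0 or np.ptp(xb) == 0.0:
            rows.append((a, b, 0.0, 1.0, "joint_T1"))
            continue
        y01 = ((table.labels.to_numpy()[obs] + 1) // 2).astype(float)
        rng = np.random.default_rng(child)
        Y = _perm_matrix(y01, n_perm, rng)
        stats = _pair_statistic(xa, xb, Y)
        p = (np.sum(stats[1:] >= stats[0]) + 1.0) / (n_perm + 1.0)
        kind = "joint_T2" if (marg.get(a, False) ^ marg.get(b, False)) else "joint_T1"
        rows.append((a, b, float(stats[0]), float(p), kind))
    rec = pd.DataFrame(rows, columns=["name", "name2", "statistic", "p_value", "effect_kind"])
    rec["selected"] = rec["p_value"].to_numpy() < alpha if len(rec) else np.zeros(0, bool)
    rec = rec.sort_values(["p_value", "name", "name2"], kind="stable").reset_index(drop=True)
    return ScreeningResult(records=rec, alpha=alpha, n_perm=n_perm)
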