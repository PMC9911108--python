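"""Mixed linear / B-spline feature designs and stepwise model growth.

Variables chosen by the penalized linear stage enter the final ridge
smooth-hinge SVM as plain standardized columns; variables flagged by the
nonparametric screen enter as order-s B-spline blocks (s in {2,3,4}, no
interior knots, so a block contributes exactly s columns).  The final model
is grown greedily: starting from the best single-variable model, at each
step the candidate whose addition maximizes leave-one-out cross-validated
accuracy is added, until nothing improves or ``max_vars`` is reached.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._splines import bspline_basis
from .preprocessing import CohortTable, complete_cases, standardize
from .smooth_hinge import DesignMatrix, FitConfig, PenaltySpec, fit_penalized

__all__ = [
    "FeatureEntry",
    "FeatureMap",
    "TrainedModel",
    "PredictionError",
    "build_design",
    "fit_final_svm",
    "predict",
    "stepwise_forward",
    "select_spline_order",
    "correlation_matrix",
]

logger = logging.getLogger(__name__)

_ALLOWED_ORDERS = (2, 3, 4)


class PredictionError(KeyError):
    """A required model variable is absent from the row being scored."""


@dataclass(frozen=True)
class FeatureEntry:
    """One variable's encoding: linear term or an order-s B-spline block."""

    name: str
    encoding: str  # "linear" | "bspline"
    order: int | None = None
    domain: tuple | None = None

    def __post_init__(self):
        if self.encoding not in ("linear", "bspline"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if self.encoding == "bspline":
            if self.order not in _ALLOWED_ORDERS:
                raise ValueError(f"spline order must be in {_ALLOWED_ORDERS}, got {self.order}")
            if self.domain is not None and not (
                np.isfinite(self.domain[0]) and np.isfinite(self.domain[1])
                and self.domain[1] >= self.domain[0]
            ):
                raise ValueError(f"invalid domain {self.domain}")

    @property
    def n_columns(self) -> int:
        return 1 if self.encoding == "linear" else int(self.order)


@dataclass(frozen=True)
class FeatureMap:
    """Ordered list of per-variable encodings defining the SVM design."""

    entries: tuple

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(self.entries))
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variables in feature map")

    @classmethod
    def from_encodings(cls, encodings: Mapping, order=None) -> "FeatureMap":
        """Build from ``{name: "linear" | ("bspline", s)}`` preserving order."""
        entries = []
        for name, enc in encodings.items():
            if enc == "linear":
                entries.append(FeatureEntry(name, "linear"))
            else:
                _, s = enc
                entries.append(FeatureEntry(name, "bspline", order=int(s)))
        return cls(tuple(entries))

    @property
    def variables(self) -> list:
        return [e.name for e in self.entries]

    def with_domains_from(self, table: CohortTable) -> "FeatureMap":
        """Fill spline domains from the observed [min, max] of each variable."""
        out = []
        for e in self.entries:
            if e.encoding == "bspline" and e.domain is None:
                col = table.data[e.name]
                out.append(replace(e, domain=(float(col.min()), float(col.max()))))
            else:
                out.append(e)
        return FeatureMap(tuple(out))


def build_design(table: CohortTable, fmap: FeatureMap) -> DesignMatrix:
    """Intercept + one column per linear entry + s columns per spline block.

    Spline domains must be resolved (``with_domains_from``); out-of-domain
    values are clamped to the boundary.  Subjects must be complete on the
    map's variables (apply :func:`~hingeselect.preprocessing.complete_cases`
    first).
    """
    if not fmap.entries:
        raise ValueError("feature map is empty")
    n = table.n_subjects
    cols, names = [np.ones((n, 1))], []
    for e in fmap.entries:
        x = table.data[e.name].to_numpy(dtype=float)
        if e.encoding == "linear":
            cols.append(x[:, None])
            names.append(e.name)
        else:
            if e.domain is None:
                raise ValueError(f"spline entry {e.name!r} has no domain; resolve it first")
            cols.append(bspline_basis(x, e.domain[0], e.domain[1], e.order))
            names.extend(f"{e.name}:bs{e.order}:{k + 1}" for k in range(e.order))
    return DesignMatrix(values=np.hstack(cols), column_names=tuple(names))


@dataclass(frozen=True)
class TrainedModel:
    """A fitted ridge smooth-hinge SVM over a mixed feature map.

    Scores are ``intercept + sum(linear) + sum(spline-block dot products)``
    on standardized inputs; class = sign(score) with 0 mapped to +1 (the
    positive / steroid-resistant class).
    """

    feature_map: FeatureMap
    intercept: float
    linear_coefs: Mapping[str, float]
    spline_coefs: Mapping[str, np.ndarray]
    standardization: Mapping[str, tuple] = field(default_factory=dict)
    positive_class: str = "SRNS"
    negative_class: str = "SSNS"
    ridge_lambda: float = 1e-3

    def decision(self, row: Mapping) -> float:
        score = self.intercept
        for e in self.feature_map.entries:
            if e.name not in row:
                raise PredictionError(f"variable {e.name!r} missing from input row")
            mu, sd = self.standardization.get(e.name, (0.0, 1.0))
            z = (float(row[e.name]) - mu) / sd
            if e.encoding == "linear":
                score += self.linear_coefs[e.name] * z
            else:
                basis = bspline_basis(z, e.domain[0], e.domain[1], e.order)[0]
                score += float(basis @ np.asarray(self.spline_coefs[e.name]))
        return float(score)

    def predict(self, row: Mapping):
        score = self.decision(row)
        cls = 1 if score >= 0 else -1
        return score, cls

    # -- lossless JSON round trip ------------------------------------------
    def to_json(self) -> str:
        payload = {
            "schema_version": 1,
            "positive_class": self.positive_class,
            "negative_class": self.negative_class,
            "ridge_lambda": self.ridge_lambda,
            "intercept": self.intercept,
            "feature_map": [
                {"name": e.name, "encoding": e.encoding, "order": e.order,
                 "domain": list(e.domain) if e.domain else None}
                for e in self.feature_map.entries
            ],
            "linear_coefs": dict(self.linear_coefs),
            "spline_coefs": {k: list(map(float, v)) for k, v in self.spline_coefs.items()},
            "standardization": {k: list(v) for k, v in self.standardization.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        d = json.loads(text)
        if d.get("schema_version") != 1:
            raise ValueError(f"unsupported model schema version {d.get('schema_version')!r}")
        fmap = FeatureMap(tuple(
            FeatureEntry(e["name"], e["encoding"], e["order"],
                         tuple(e["domain"]) if e["domain"] else None)
            for e in d["feature_map"]
        ))
        return cls(
            feature_map=fmap,
            intercept=float(d["intercept"]),
            linear_coefs={k: float(v) for k, v in d["linear_coefs"].items()},
            spline_coefs={k: np.asarray(v, dtype=float) for k, v in d["spline_coefs"].items()},
            standardization={k: tuple(v) for k, v in d["standardization"].items()},
            positive_class=d["positive_class"],
            negative_class=d["negative_class"],
            ridge_lambda=float(d["ridge_lambda"]),
        )


def predict(model: TrainedModel, row: Mapping):
    """Score one subject: returns ``(score, class)`` with class in {-1, +1}."""
    return model.predict(row)


def fit_final_svm(
    design: DesignMatrix,
    y,
    ridge_lambda: float = 1e-3,
    feature_map: FeatureMap | None = None,
    standardization: Mapping | None = None,
    config: FitConfig | None = None,
    positive_class: str = "SRNS",
    negative_class: str = "SSNS",
) -> TrainedModel:
    """Ridge-penalized smooth-hinge fit on a prebuilt design.

    Without an explicit feature map every design column is treated as a
    linear term.  Coefficients are unpacked into per-variable blocks.
    """
    fit = fit_penalized(design, y, PenaltySpec("ridge", ridge_lambda), config)
    beta = fit.beta
    if feature_map is None:
        feature_map = FeatureMap(tuple(FeatureEntry(n, "linear") for n in design.column_names))
    linear, spline = {}, {}
    k = 1
    for e in feature_map.entries:
        if e.encoding == "linear":
            linear[e.name] = float(beta[k])
            k += 1
        else:
            spline[e.name] = beta[k:k + e.order].copy()
            k += e.order
    if k != len(beta):
        raise ValueError("feature map does not match design dimensions")
    return TrainedModel(
        feature_map=feature_map,
        intercept=float(beta[0]),
        linear_coefs=linear,
        spline_coefs=spline,
        standardization=dict(standardization or {}),
        positive_class=positive_class,
        negative_class=negative_class,
        ridge_lambda=ridge_lambda,
    )


def train_model(
    table: CohortTable,
    fmap: FeatureMap,
    ridge_lambda: float = 1e-3,
    config: FitConfig | None = None,
) -> TrainedModel:
    """Complete-case + standardize + design + ridge fit, in one call.

    The stored standardization parameters and spline domains make the model
    applicable to raw (unstandardized) new subjects.
    """
    cc = complete_cases(table, fmap.variables)
    std = standardize(cc)
    resolved = fmap.with_domains_from(std)
    design = build_design(std, resolved)
    params = {v: std.standardization[v] for v in fmap.variables}
    return fit_final_svm(
        design, std.labels.to_numpy(dtype=float), ridge_lambda,
        feature_map=resolved, standardization=params, config=config,
        positive_class=table.positive_class, negative_class=table.negative_class,
    )


def _encoding_entry(name: str, encodings: Mapping) -> FeatureEntry:
    enc = encodings[name]
    if enc == "linear":
        return FeatureEntry(name, "linear")
    _, s = enc
    return FeatureEntry(name, "bspline", order=int(s))


def stepwise_forward(
    table: CohortTable,
    candidates: Sequence[str],
    encodings: Mapping,
    max_vars: int,
    ridge_lambda: float = 1e-3,
    config: FitConfig | None = None,
):
    """Greedy forward growth under LOO-CV accuracy.

    ``encodings`` fixes each candidate's representation before the search
    (``"linear"`` or ``("bspline", s)``).  Deterministic: ties break toward
    the earlier candidate in ``candidates``.  Returns ``(TrainedModel,
    trace)`` where trace lists (step, added variable, LOO-CV accuracy).
    """
    from .validation import loo_cv  # local import avoids a module cycle

    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate variables")
    chosen: list = []
    trace_rows = []
    best_acc = -np.inf
    while candidates and len(chosen) < max_vars:
        step_best = None
        for cand in candidates:
            fmap = FeatureMap(tuple(
                _encoding_entry(v, encodings) for v in chosen + [cand]
            ))
            res = loo_cv(table, fmap, ridge_lambda=ridge_lambda, config=config)
            if step_best is None or res.accuracy > step_best[1]:
                step_best = (cand, res.accuracy)
        cand, acc = step_best
        if acc <= best_acc:
            break
        chosen.append(cand)
        candidates.remove(cand)
        best_acc = acc
        trace_rows.append({"step": len(chosen), "added": cand, "loo_accuracy": acc})
        logger.info("stepwise_forward: step %d added %r (LOO-CV %.3f)", len(chosen), cand, acc)
    fmap = FeatureMap(tuple(_encoding_entry(v, encodings) for v in chosen))
    model = train_model(table, fmap, ridge_lambda=ridge_lambda, config=config)
    return model, pd.DataFrame(trace_rows)


def select_spline_order(
    table: CohortTable,
    variable: str,
    orders: Sequence[int] = (2, 3, 4),
    overfit_alpha: float = 0.05,
    B: int = 99,
    seed: int = 0,
    ridge_lambda: float = 1e-3,
    config: FitConfig | None = None,
) -> int | None:
    """Pick the B-spline order for one variable under overfitting control.

    Among candidate orders, keep those whose single-variable model passes the
    permutation overfitting test (p <= overfit_alpha) and return the one with
    the best LOO-CV accuracy, ties resolving to the smaller order.  Returns
    ``None`` when no order passes the gate (the variable should be dropped).
    """
    from .validation import loo_cv, overfit_test

    results = []
    for s in sorted(orders):
        if s not in _ALLOWED_ORDERS:
            raise ValueError(f"order {s} not in {_ALLOWED_ORDERS}")
        fmap = FeatureMap((FeatureEntry(variable, "bspline", order=s),))
        acc = loo_cv(table, fmap, ridge_lambda=ridge_lambda, config=config).accuracy
        p = overfit_test(table, fmap, B=B, seed=seed,
                         ridge_lambda=ridge_lambda, config=config).p_value
        results.append((s, acc, p))
    eligible = [(s, acc) for s, acc, p in results if p <= overfit_alpha]
    if not eligible:
        logger.warning("select_spline_order: no stable order for %r; dropping", variable)
        return None
    best_acc = max(acc for _, acc in eligible)
    return min(s for s, acc in eligible if acc == best_acc)


def correlation_matrix(
    table: CohortTable,
    variables: Sequence[str],
    heatmap_path=None,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations, optionally rendered as a heatmap.

    Constant columns get correlation 0 with every other variable (and 1 with
    themselves), with a warning.
    """
    variables = list(variables)
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    sub = table.data[variables]
    corr = sub.corr(method="pearson", min_periods=2)
    constant = [v for v in variables if sub[v].std(ddof=0) == 0 or sub[v].notna().sum() < 2]
    if constant:
        logger.warning("correlation_matrix: constant columns %s set to 0", constant)
        for v in constant:
            corr.loc[v, :] = 0.0
            corr.loc[:, v] = 0.0
            corr.loc[v, v] = 1.0
    corr = corr.fillna(0.0)
    if heatmap_path is not None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(variables)),) * 2)
        im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(variables)), variables, rotation=90, fontsize=7)
        ax.set_yticks(range(len(variables)), variables, fontsize=7)
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        fig.savefig(heatmap_path, dpi=150)
        plt.close(fig)
    return corr
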