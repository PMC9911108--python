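"""Cohort table ingestion, missingness filtering, standardization, labels.

A :class:`CohortTable` is a subjects-by-variables pandas frame with NaN
marking missing cells, plus a -1/+1 label per subject (by default +1 = SRNS,
the steroid-resistant class).  All operations are pure: they return new
tables and never mutate their input.  Deliberately no imputation — subjects
with missing values on model variables are dropped (complete-case analysis),
because imputation on a cohort this small induces bias of unknown direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "CohortLoadError",
    "load_cohort",
    "drop_high_missing",
    "standardize",
    "complete_cases",
]

logger = logging.getLogger(__name__)


class CohortLoadError(ValueError):
    """Raised when an input CSV violates the cohort dialect."""


@dataclass(frozen=True)
class CohortTable:
    """Subjects x variables with a binary label and optional scaling params.

    ``data``: float frame indexed by subject id, NaN = missing.
    ``labels``: aligned Series in {-1, +1}.
    ``standardization``: variable -> (mean, sd) once :func:`standardize` ran.
    """

    data: pd.DataFrame
    labels: pd.Series
    positive_class: str = "SRNS"
    negative_class: str = "SSNS"
    standardization: Mapping[str, tuple] | None = None

    def __post_init__(self):
        if not self.data.index.equals(self.labels.index):
            raise ValueError("data and labels must share the same subject index")
        vals = set(pd.unique(self.labels))
        if not vals <= {-1, 1}:
            raise ValueError(f"labels must be coded -1/+1, got {sorted(vals)}")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def variables(self) -> list:
        return list(self.data.columns)

    def missing_rate(self) -> pd.Series:
        return self.data.isna().mean()

    def class_counts(self) -> tuple:
        """(n_positive, n_negative)."""
        return int((self.labels == 1).sum()), int((self.labels == -1).sum())


def load_cohort(path, label_column: str, positive_class: str = "SRNS") -> CohortTable:
    """Read the cohort CSV dialect.

    UTF-8 comma-separated, header row, first column = subject id, "NA" or an
    empty cell = missing.  The label column must have exactly two levels;
    ``positive_class`` maps to +1, the other level to -1.
    """
    df = pd.read_csv(path, index_col=0)
    if label_column not in df.columns:
        raise CohortLoadError(f"label column {label_column!r} not found in {list(df.columns)}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise CohortLoadError(f"duplicate subject ids: {dups}")
    raw_labels = df[label_column]
    if raw_labels.isna().any():
        missing = df.index[raw_labels.isna()].tolist()
        raise CohortLoadError(f"missing labels for subjects {missing}")
    levels = sorted(map(str, pd.unique(raw_labels.astype(str))))
    if len(levels) != 2:
        raise CohortLoadError(f"label column must have exactly 2 levels, got {levels}")
    if str(positive_class) not in levels:
        raise CohortLoadError(f"positive class {positive_class!r} not among levels {levels}")
    negative = next(l for l in levels if l != str(positive_class))
    labels = raw_labels.astype(str).map(
        {str(positive_class): 1, negative: -1}
    ).astype(np.int8)

    features = df.drop(columns=[label_column])
    numeric = pd.DataFrame(index=features.index)
    for col in features.columns:
        coerced = pd.to_numeric(features[col], errors="coerce")
        bad = coerced.isna() & features[col].notna()
        if bad.any():
            row = features.index[bad][0]
            raise CohortLoadError(
                f"non-numeric cell in column {col!r}, subject {row!r}: "
                f"{features.loc[row, col]!r}"
            )
        numeric[col] = coerced.astype(float)
    return CohortTable(
        data=numeric, labels=labels,
        positive_class=str(positive_class), negative_class=negative,
    )


def drop_high_missing(table: CohortTable, max_missing_rate: float = 0.5) -> CohortTable:
    """Remove variables whose missing fraction strictly exceeds the cutoff.

    The boundary is kept: a variable missing exactly 50% of cells survives the
    default cutoff.
    """
    if not 0 < max_missing_rate <= 1:
        raise ValueError("max_missing_rate must be in (0, 1]")
    rates = table.missing_rate()
    dropped = rates.index[rates > max_missing_rate].tolist()
    if dropped:
        logger.info(
            "drop_high_missing: removed %d/%d variables above %.0f%% missing: %s",
            len(dropped), len(rates), 100 * max_missing_rate, dropped,
        )
    return replace(table, data=table.data.drop(columns=dropped))


def standardize(table: CohortTable) -> CohortTable:
    """Scale each variable to mean 0, variance 1 over its observed entries.

    Population variance (divide by n) for bit-reproducibility.  Zero-variance
    columns are left untouched with a warning; their stored scale is (mean, 1)
    so applying the parameters is a no-op shift of zero spread.
    """
    out = table.data.copy()
    params = {}
    for col in out.columns:
        x = out[col]
        mu = float(x.mean())
        sd = float(x.std(ddof=0))
        if not np.isfinite(sd) or sd == 0.0:
            logger.warning("standardize: column %r has zero variance; left unscaled", col)
            params[col] = (0.0, 1.0)
            continue
        out[col] = (x - mu) / sd
        params[col] = (mu, sd)
    return replace(table, data=out, standardization=params)


def apply_standardization(values: Mapping, params: Mapping) -> dict:
    """Apply stored (mean, sd) parameters to a raw variable->value mapping."""
    out = {}
    for name, v in values.items():
        mu, sd = params.get(name, (0.0, 1.0))
        out[name] = (v - mu) / sd
    return out


def complete_cases(table: CohortTable, variables: Sequence) -> CohortTable:
    """Keep subjects fully observed on ``variables`` (empty list = no-op)."""
    variables = list(variables)
    unknown = [v for v in variables if v not in table.data.columns]
    if unknown:
        raise ValueError(f"unknown variables: {unknown}")
    if not variables:
        return table
    keep = table.data[variables].notna().all(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("complete_cases: removed %d/%d subjects with holes in %s",
                    n_drop, len(keep), variables)
    if not keep.any():
        raise ValueError("no subjects are fully observed on the requested variables")
    return replace(table, data=table.data.loc[keep], labels=table.labels.loc[keep])
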