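"""Apply criteria to a feature table, rank by overall desirability, select.

The feature table is a pandas DataFrame with one row per feature (probe set,
gene, protein, ...) indexed by a unique feature ID, and one column per
statistic (log fold-change, average expression, p-value, standard deviation,
marker correlation, annotation flags, ...).

A :class:`Criterion` binds one column to one desirability function and an
importance weight.  ``apply_criteria`` produces the per-feature,
per-criterion desirability matrix; ``rank_features`` collapses it to the
overall desirability and a 1-based rank; ``select`` takes the head of the
list by threshold or count; ``comparison_rank`` reproduces the conventional
single-statistic ordering (e.g. "rank when sorted by p-value") for
side-by-side comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import functions as fn
from .aggregate import overall_desirability
from .errors import ConfigError

__all__ = [
    "Criterion",
    "QuantileCut",
    "apply_criteria",
    "rank_features",
    "rank_table",
    "select",
    "comparison_rank",
    "Prefilter",
]


@dataclass(frozen=True)
class QuantileCut:
    """Placeholder cut point resolved from the data distribution.

    ``QuantileCut(0.9)`` becomes the 90th percentile of the bound column at
    the moment the criterion is applied to a table.  This is how "the top
    10% gets maximum desirability"-style criteria, and preset cut points not
    fixed in advance, are expressed declaratively.
    """

    q: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q <= 1.0):
            raise ConfigError([f"quantile fraction must be in [0, 1], got {self.q}"])


@dataclass(frozen=True)
class Criterion:
    """One selection criterion: a column, a desirability spec, and a weight."""

    name: str
    column: str
    spec: object  # MonotoneSpec | PlateauSpec | CategoricalSpec | SigmoidSpec
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.weight) and self.weight >= 0):
            raise ConfigError(
                [f"criterion {self.name!r}: weight must be finite and >= 0"]
            )

    def resolve(self, table: pd.DataFrame) -> "Criterion":
        """Return a copy with any :class:`QuantileCut` cut points replaced by
        data-scale values from this table's column."""
        cut_fields = [
            f for f in ("cut1", "cut2", "cut3", "cut4", "midpoint")
            if hasattr(self.spec, f)
        ]
        pending = {
            f: getattr(self.spec, f)
            for f in cut_fields
            if isinstance(getattr(self.spec, f), QuantileCut)
        }
        if not pending:
            return self
        values = pd.to_numeric(table[self.column], errors="coerce")
        resolved = {
            f: fn.quantile_cuts(values, qc.q)[0] for f, qc in pending.items()
        }
        return replace(self, spec=replace(self.spec, **resolved))


def _check_columns(table: pd.DataFrame, criteria: Sequence[Criterion]) -> None:
    problems = []
    if len(criteria) == 0:
        problems.append("no criteria given")
    for c in criteria:
        if c.column not in table.columns:
            problems.append(
                f"criterion {c.name!r}: column {c.column!r} not in table"
            )
            continue
        numeric_needed = not isinstance(c.spec, fn.CategoricalSpec)
        if numeric_needed and not pd.api.types.is_numeric_dtype(table[c.column]):
            problems.append(
                f"criterion {c.name!r}: column {c.column!r} is not numeric "
                f"but function {type(c.spec).__name__} requires numbers"
            )
    if problems:
        raise ConfigError(problems)


def apply_criteria(
    table: pd.DataFrame, criteria: Sequence[Criterion]
) -> pd.DataFrame:
    """Map every criterion's column onto the 0-1 desirability scale.

    Returns a DataFrame of per-criterion desirabilities (columns ``d_<name>``)
    aligned to the table's index.  Missing data yield missing desirabilities.
    Column names are matched exactly (case-sensitive); mismatches raise a
    :class:`ConfigError` naming every offending criterion.
    """
    criteria = list(criteria)
    _check_columns(table, criteria)
    out = {}
    for c in criteria:
        c = c.resolve(table)
        col = table[c.column]
        if isinstance(c.spec, fn.CategoricalSpec):
            d = fn.d_cat(col, c.spec)
        else:
            d = fn.desirability(col.to_numpy(dtype=float), c.spec)
        out[f"d_{c.name}"] = np.asarray(d, dtype=float)
    return pd.DataFrame(out, index=table.index)


def rank_features(
    matrix: pd.DataFrame, weights: Sequence[float]
) -> pd.DataFrame:
    """Rank features by the weighted geometric mean of their desirabilities.

    ``matrix`` is the per-criterion desirability matrix from
    :func:`apply_criteria`; ``weights`` aligns with its columns.  The result
    keeps the per-criterion columns and adds ``overall_D``, ``rank``
    (1 = most desirable; ties broken by ascending feature ID for a
    deterministic, reproducible ordering) and ``evidence_count`` (number of
    observed, positively weighted criteria per feature).
    """
    w = np.asarray(list(weights), dtype=float)
    values = matrix.to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[1] != w.size:
        raise ConfigError(
            [f"{values.shape[1]} desirability columns but {w.size} weights"]
        )
    D = overall_desirability(values, w)
    evidence = ((~np.isnan(values)) & (w > 0)[None, :]).sum(axis=1)

    out = matrix.copy()
    out["overall_D"] = D
    out["evidence_count"] = evidence
    order = (
        out.assign(_id=out.index.astype(str))
        .sort_values(
            by=["overall_D", "_id"],
            ascending=[False, True],
            kind="stable",
            na_position="last",
        )
        .index
    )
    out = out.loc[order]
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def rank_table(
    table: pd.DataFrame,
    criteria: Sequence[Criterion],
    keep_columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """End-to-end ranking: criteria -> desirability matrix -> ranked table.

    ``keep_columns`` (default: all input columns) are carried over from the
    feature table into the ranked output for context.
    """
    criteria = list(criteria)
    matrix = apply_criteria(table, criteria)
    ranked = rank_features(matrix, [c.weight for c in criteria])
    keep = list(table.columns) if keep_columns is None else list(keep_columns)
    missing = [c for c in keep if c not in table.columns]
    if missing:
        raise ConfigError([f"keep column {c!r} not in table" for c in missing])
    return table[keep].join(ranked, how="right").loc[ranked.index]


def select(
    ranked: pd.DataFrame,
    threshold: Optional[float] = None,
    k: Optional[int] = None,
) -> pd.DataFrame:
    """Head of a ranked table: ``overall_D`` strictly above a threshold, or
    the top ``k`` rows.  Exactly one of the two must be given; ``k`` larger
    than the table is clamped."""
    if (threshold is None) == (k is None):
        raise ConfigError(["give exactly one of threshold or k"])
    if threshold is not None:
        if not (0.0 <= threshold <= 1.0):
            raise ConfigError([f"threshold must be in [0, 1], got {threshold}"])
        mask = ranked["overall_D"].to_numpy() > threshold
        return ranked.loc[mask]
    if k < 1:
        raise ConfigError([f"k must be a positive integer, got {k}"])
    return ranked.head(int(k))


@dataclass(frozen=True)
class Prefilter:
    """Keep-condition applied before a comparison ranking.

    Features failing the condition get a missing comparison rank, mirroring
    the common practice of discarding low-expressed / low-variance features
    before a p-value ordering.
    """

    column: str
    op: str
    value: float

    _OPS = {
        "<": np.less,
        "<=": np.less_equal,
        ">": np.greater,
        ">=": np.greater_equal,
        "==": np.equal,
        "!=": np.not_equal,
    }

    def __post_init__(self) -> None:
        if self.op not in self._OPS:
            raise ConfigError(
                [f"unknown prefilter operator {self.op!r} "
                 f"(expected one of {sorted(self._OPS)})"]
            )

    def mask(self, table: pd.DataFrame) -> np.ndarray:
        if self.column not in table.columns:
            raise ConfigError([f"prefilter column {self.column!r} not in table"])
        vals = pd.to_numeric(table[self.column], errors="coerce").to_numpy()
        with np.errstate(invalid="ignore"):
            keep = self._OPS[self.op](vals, self.value)
        return keep & ~np.isnan(vals)


def comparison_rank(
    table: pd.DataFrame,
    column: str,
    ascending: bool = True,
    prefilters: Optional[Sequence[Prefilter]] = None,
) -> pd.Series:
    """Rank features by a single statistic, the conventional baseline.

    Returns a float Series aligned to the table: rank 1 is the best value of
    ``column`` among features surviving all prefilters; filtered-out features
    (and missing values) get NaN.  Ties share the smallest rank ("min"
    method).
    """
    if column not in table.columns:
        raise ConfigError([f"comparison column {column!r} not in table"])
    if not pd.api.types.is_numeric_dtype(table[column]):
        raise ConfigError([f"comparison column {column!r} is not numeric"])
    keep = np.ones(len(table), dtype=bool)
    for pf in prefilters or []:
        keep &= pf.mask(table)
    vals = table[column].where(pd.Series(keep, index=table.index))
    ranks = vals.rank(ascending=ascending, method="min", na_option="keep")
    ranks.name = f"{column}_rank"
    return ranks
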