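"""Combine per-criterion desirabilities into an overall desirability.

The overall desirability of a feature is the weighted geometric mean of its
per-criterion desirabilities,

    D = exp( sum_i w_i ln d_i / sum_i w_i ),

where the weights ``w_i`` encode the relative importance of the criteria:
only weight ratios matter, not absolute values.  A geometric mean is used so
that a single unacceptable criterion (d_i = 0, positive weight) drives the
overall desirability to exactly 0, regardless of the other criteria.

Missing desirabilities are excluded together with their weights before the
mean is taken, which is equivalent to renormalising the remaining weights to
sum to one: criteria (or experiments) without an observation do not
influence the ranking, and the observed ones keep their relative importance.
The same rule applies recursively at the experiment level for data fusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidWeightsError

__all__ = [
    "overall_desirability",
    "effective_weights",
    "Experiment",
    "ExperimentManifest",
    "combine_hierarchical",
]


def _validate_weights(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 1:
        raise InvalidWeightsError("weights must be one-dimensional")
    if not np.all(np.isfinite(w)):
        raise InvalidWeightsError("weights must be finite")
    if np.any(w < 0):
        raise InvalidWeightsError("weights must be non-negative")
    if not np.any(w > 0):
        raise InvalidWeightsError("at least one weight must be positive")
    return w


def overall_desirability(d, w):
    """Weighted geometric mean of desirabilities, with missing-value handling.

    Parameters
    ----------
    d
        Desirabilities in [0, 1] (NaN marks a missing observation).  Either a
        single row of length ``n_criteria`` or a 2-D array
        ``(n_features, n_criteria)``.
    w
        Non-negative weights, one per criterion; at least one positive.

    Returns
    -------
    float or ndarray
        Overall desirability per row.  Exactly 0 when any observed,
        positively weighted desirability is 0 (zero-weight criteria are
        excluded outright, so their values -- even 0 -- never matter).
        NaN when every positively weighted criterion is missing.
    """
    w = _validate_weights(w)
    d_arr = np.asarray(d, dtype=float)
    single_row = d_arr.ndim == 1
    d2 = np.atleast_2d(d_arr)
    if d2.shape[1] != w.size:
        raise InvalidWeightsError(
            f"{d2.shape[1]} desirabilities but {w.size} weights"
        )
    with np.errstate(invalid="ignore"):
        if np.any((d2 < 0) | (d2 > 1)):
            raise ValueError("desirabilities must lie in [0, 1] or be NaN")

    active = (~np.isnan(d2)) & (w > 0)[None, :]
    wsum = np.where(active, w[None, :], 0.0).sum(axis=1)

    # log-space mean over active criteria; zeros handled by short-circuit to
    # avoid any -inf arithmetic leaking into the result
    has_zero = np.any(active & (d2 == 0.0), axis=1)
    safe = np.where(active & (d2 > 0), d2, 1.0)
    logsum = (np.log(safe) * w[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.exp(logsum / wsum)
    out = np.clip(out, 0.0, 1.0)
    out[has_zero] = 0.0
    out[wsum == 0.0] = np.nan

    if single_row:
        return float(out[0])
    return out


def effective_weights(w, missing_mask=None) -> np.ndarray:
    """Normalise weights to sum to 1 over the observed criteria.

    Missing criteria receive weight 0; the observed criteria keep their
    pairwise weight ratios.  This is the renormalisation implicitly performed
    by :func:`overall_desirability` when desirabilities are missing.
    """
    w = _validate_weights(w)
    if missing_mask is None:
        missing_mask = np.zeros(w.size, dtype=bool)
    missing_mask = np.asarray(missing_mask, dtype=bool)
    if missing_mask.shape != w.shape:
        raise InvalidWeightsError("missing mask must match the weight vector")
    eff = np.where(missing_mask, 0.0, w)
    total = eff.sum()
    if total == 0:
        raise InvalidWeightsError("all observed weights are zero")
    return eff / total


@dataclass(frozen=True)
class Experiment:
    """One experiment's overall desirabilities, keyed by feature ID."""

    name: str
    desirability: pd.Series
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not isinstance(self.desirability, pd.Series):
            object.__setattr__(
                self, "desirability", pd.Series(self.desirability, dtype=float)
            )
        if not np.isfinite(self.weight) or self.weight < 0:
            raise InvalidWeightsError(
                f"experiment {self.name!r}: weight must be finite and >= 0"
            )
        if self.desirability.index.has_duplicates:
            raise ConfigError(
                f"experiment {self.name!r}: duplicate feature IDs"
            )


@dataclass
class ExperimentManifest:
    """Set of experiments to fuse into a second-level ranking.

    Weights reflect each experiment's relevance, importance, or quality.
    """

    experiments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.experiments:
            raise ConfigError("experiment manifest is empty")
        weights = np.array([e.weight for e in self.experiments], dtype=float)
        _validate_weights(weights)


def combine_hierarchical(manifest: ExperimentManifest) -> pd.DataFrame:
    """Fuse experiment-level desirabilities into a second-level ranking.

    Features are joined by ID across experiments (outer join); a feature
    absent from an experiment is missing there and that experiment's weight
    is renormalised away for it.  Returns a DataFrame indexed by feature ID
    with columns ``overall_D`` (second-level desirability), ``evidence_count``
    (number of experiments with an observation) and ``rank`` (1 = most
    desirable; ties broken by feature ID).
    """
    cols = {e.name: e.desirability.astype(float) for e in manifest.experiments}
    mat = pd.DataFrame(cols)  # outer join on the union of feature IDs
    w = np.array([e.weight for e in manifest.experiments], dtype=float)

    values = mat.to_numpy()
    fused = overall_desirability(values, w)
    evidence = (~np.isnan(values)).sum(axis=1)

    out = pd.DataFrame(
        {"overall_D": fused, "evidence_count": evidence}, index=mat.index
    )
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
    out.index.name = mat.index.name or "feature_id"
    out["rank"] = np.arange(1, len(out) + 1)
    return out
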