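"""Rank-stability analysis under perturbation of cut points and weights.

Cut points and weights are judgement calls, so it is worth checking how much
the final list depends on them.  The analysis jitters chosen parameters
uniformly within a stated magnitude, recomputes the full ranking for each
draw, and summarises stability as

* Jaccard overlap between each draw's top-k and the baseline top-k,
* Spearman rank correlation between each draw's overall desirabilities and
  the baseline ones,
* per-feature selection frequency (fraction of draws in which the feature
  makes the top-k).

Weights are jittered relatively (a weight's meaning is its ratio to the
others) and cut points absolutely in data units.  A draw that breaks a spec
invariant is repaired -- perturbed cuts re-sorted, weights and desirability
bounds clamped -- rather than discarded, so the perturbation coverage is not
biased toward mild draws; repairs are counted in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import functions as fn
from .errors import ConfigError
from .pipeline import Criterion, QuantileCut, rank_table, select

__all__ = [
    "PerturbationTarget",
    "PerturbationPlan",
    "default_plan",
    "StabilityReport",
    "perturb_and_rank",
]

_CUT_FIELDS = ("cut1", "cut2", "cut3", "cut4")


@dataclass(frozen=True)
class PerturbationTarget:
    """One parameter to jitter: ``criterion.parameter`` within +/-magnitude.

    ``mode`` is ``"relative"`` (value scaled by ``1 + magnitude*u``) or
    ``"absolute"`` (value shifted by ``magnitude*u``), with ``u ~ U(-1, 1)``.
    If unset, weights default to relative and everything else to absolute.
    """

    criterion: str
    parameter: str
    magnitude: float
    mode: Optional[str] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.magnitude) or self.magnitude < 0:
            raise ConfigError(
                [f"{self.criterion}.{self.parameter}: magnitude must be "
                 f"finite and >= 0, got {self.magnitude}"]
            )
        if self.mode not in (None, "relative", "absolute"):
            raise ConfigError(
                [f"{self.criterion}.{self.parameter}: unknown mode {self.mode!r}"]
            )

    @property
    def effective_mode(self) -> str:
        if self.mode is not None:
            return self.mode
        return "relative" if self.parameter == "weight" else "absolute"


@dataclass(frozen=True)
class PerturbationPlan:
    """Targets, number of Monte Carlo draws, and the seed that fixes them."""

    targets: tuple
    n_draws: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        if self.n_draws < 1:
            raise ConfigError([f"n_draws must be >= 1, got {self.n_draws}"])
        if not self.targets:
            raise ConfigError(["perturbation plan has no targets"])


def default_plan(
    criteria: Sequence[Criterion],
    weight_rel: float = 0.1,
    cut_frac: float = 0.1,
    n_draws: int = 100,
    seed: int = 0,
) -> PerturbationPlan:
    """Jitter every weight (relatively) and every numeric cut point
    (absolutely, by ``cut_frac`` of the criterion's cut span)."""
    targets = []
    for c in criteria:
        targets.append(PerturbationTarget(c.name, "weight", weight_rel))
        cuts = [
            getattr(c.spec, f)
            for f in _CUT_FIELDS
            if hasattr(c.spec, f) and not isinstance(getattr(c.spec, f), QuantileCut)
        ]
        if cuts:
            span = max(cuts) - min(cuts)
            mag = cut_frac * (span if span > 0 else max(abs(cuts[0]), 1.0))
            for f in _CUT_FIELDS:
                if hasattr(c.spec, f) and not isinstance(
                    getattr(c.spec, f), QuantileCut
                ):
                    targets.append(PerturbationTarget(c.name, f, mag))
    return PerturbationPlan(tuple(targets), n_draws=n_draws, seed=seed)


@dataclass
class StabilityReport:
    """Stability statistics over all perturbation draws."""

    jaccard: np.ndarray            # per-draw top-k overlap with baseline
    rank_corr: np.ndarray          # per-draw Spearman corr with baseline D
    selection_freq: pd.Series      # per-feature fraction of draws in top-k
    baseline_selection: tuple      # baseline top-k feature IDs
    k: int
    n_draws: int
    n_repairs: int = 0             # draws-x-parameters clamped back to validity
    plan: Optional[PerturbationPlan] = field(default=None, repr=False)

    def summary(self) -> dict:
        return {
            "k": self.k,
            "n_draws": self.n_draws,
            "jaccard_min": float(np.min(self.jaccard)),
            "jaccard_mean": float(np.mean(self.jaccard)),
            "rank_corr_min": float(np.min(self.rank_corr)),
            "rank_corr_mean": float(np.mean(self.rank_corr)),
            "n_repairs": int(self.n_repairs),
        }


def _perturb_criteria(criteria, plan, rng):
    """One draw: jitter every targeted parameter, repairing invariant
    violations (sorted cuts, clamped weights/bounds).  Returns the perturbed
    criteria and the number of repairs."""
    by_name = {c.name: c for c in criteria}
    changes: dict[str, dict[str, float]] = {c.name: {} for c in criteria}
    for t in plan.targets:
        if t.criterion not in by_name:
            raise ConfigError(
                [f"perturbation target {t.criterion!r}: no such criterion"]
            )
        c = by_name[t.criterion]
        if t.parameter == "weight":
            value = c.weight
        elif hasattr(c.spec, t.parameter):
            value = getattr(c.spec, t.parameter)
        else:
            raise ConfigError(
                [f"criterion {t.criterion!r} has no parameter {t.parameter!r}"]
            )
        u = rng.uniform(-1.0, 1.0)
        if t.effective_mode == "relative":
            new = value * (1.0 + t.magnitude * u)
        else:
            new = value + t.magnitude * u
        changes[t.criterion][t.parameter] = new

    repaired = 0
    out = []
    for c in criteria:
        ch = dict(changes[c.name])
        weight = ch.pop("weight", c.weight)
        if weight < 0:
            weight = 0.0
            repaired += 1
        # repair the perturbed field values *before* constructing the spec,
        # which validates its invariants on construction
        fields = {
            f: ch.get(f, getattr(c.spec, f))
            for f in ("cut1", "cut2", "cut3", "cut4", "midpoint", "steepness",
                      "des_min", "des_max", "scale")
            if hasattr(c.spec, f)
        }
        cut_names = [f for f in _CUT_FIELDS if f in fields]
        cuts = [fields[f] for f in cut_names]
        if cuts and not any(isinstance(v, QuantileCut) for v in cuts):
            if cuts != sorted(cuts):
                fields.update(zip(cut_names, sorted(cuts)))
                repaired += 1
        for bound in ("des_min", "des_max"):
            if bound in fields and not 0.0 <= fields[bound] <= 1.0:
                fields[bound] = float(np.clip(fields[bound], 0.0, 1.0))
                repaired += 1
        if "des_min" in fields and fields["des_min"] > fields["des_max"]:
            fields["des_min"], fields["des_max"] = (
                fields["des_max"], fields["des_min"]
            )
            repaired += 1
        if "scale" in fields and fields["scale"] <= 0:
            fields["scale"] = 1e-6
            repaired += 1
        if "steepness" in fields and fields["steepness"] == 0:
            fields["steepness"] = 1e-6
            repaired += 1
        spec = c.spec if not fields else replace(c.spec, **fields)
        out.append(Criterion(c.name, c.column, spec, weight))
    if all(c.weight == 0 for c in out):
        # keep the draw valid: restore the original weights
        out = [replace(c, weight=o.weight) for c, o in zip(out, criteria)]
        repaired += 1
    return out, repaired


def perturb_and_rank(
    table: pd.DataFrame,
    criteria: Sequence[Criterion],
    plan: PerturbationPlan,
    threshold: Optional[float] = None,
    k: Optional[int] = None,
) -> StabilityReport:
    """Monte Carlo rank-stability analysis.

    The baseline selection is the rows with overall desirability above
    ``threshold`` (if given) or the top ``k`` rows (default k=10); per draw,
    overlap is measured on top-k sets with k equal to the baseline selection
    size.  Fully reproducible: the same table, criteria, and plan (including
    its seed) give an identical report.
    """
    criteria = [c.resolve(table) for c in criteria]
    baseline = rank_table(table, criteria)
    if threshold is not None:
        base_sel = select(baseline, threshold=threshold)
        if len(base_sel) == 0:
            raise ConfigError(
                [f"no feature exceeds the baseline threshold {threshold}"]
            )
        k_eff = len(base_sel)
    else:
        k_eff = int(k) if k is not None else 10
        base_sel = select(baseline, k=k_eff)
    base_set = set(base_sel.index)
    base_D = baseline["overall_D"].reindex(table.index).to_numpy()

    rng = np.random.default_rng(plan.seed)
    jaccard = np.empty(plan.n_draws)
    rank_corr = np.empty(plan.n_draws)
    counts = pd.Series(0.0, index=table.index)
    repairs = 0

    for j in range(plan.n_draws):
        drawn, rep = _perturb_criteria(criteria, plan, rng)
        repairs += rep
        ranked = rank_table(table, drawn)
        top = set(select(ranked, k=k_eff).index)
        jaccard[j] = len(top & base_set) / len(top | base_set)
        counts[list(top)] += 1.0
        draw_D = ranked["overall_D"].reindex(table.index).to_numpy()
        if np.array_equal(
            np.nan_to_num(draw_D, nan=-1.0), np.nan_to_num(base_D, nan=-1.0)
        ):
            rank_corr[j] = 1.0
        else:
            rank_corr[j] = stats.spearmanr(
                base_D, draw_D, nan_policy="omit"
            ).statistic

    return StabilityReport(
        jaccard=jaccard,
        rank_corr=rank_corr,
        selection_freq=counts / plan.n_draws,
        baseline_selection=tuple(base_sel.index),
        k=k_eff,
        n_draws=plan.n_draws,
        n_repairs=repairs,
        plan=plan,
    )
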