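"""Synthetic two-group differential-expression tables with planted signal.

The generator emulates the statistical shape of a processed microarray /
RNA-seq result set so the whole ranking pipeline can be exercised and
benchmarked without any external data:

* per-feature baseline (log2) expression drawn from a right-skewed gamma so
  the mean-expression histogram looks like a log-scale array;
* a fraction of features differentially expressed between two groups, half
  up- and half down-shifted by a fixed log2 effect;
* a shared latent "proliferation-like" factor loading a subset of features,
  with one designated marker feature, so a per-feature marker correlation
  exists;
* a binary annotation column (e.g. membership in an inflammation gene set);
* Welch two-sample p-values, log fold-changes, average expression, and
  standard deviations computed from the simulated expression matrix itself,
  exactly as a practitioner would compute them.

A subset of the differentially expressed features is *planted*: constructed
to satisfy every prioritisation criterion at once (true effect, high
baseline expression, no loading on the latent factor, annotated).  Planted
features are the ground truth for recovery benchmarks: under a strong,
low-noise signal a sensible criteria set must place all of them at the top
of the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import functions as fn
from .errors import ConfigError
from .pipeline import Criterion, QuantileCut, comparison_rank, rank_table, select

__all__ = [
    "SimulationConfig",
    "simulate_table",
    "default_criteria",
    "strong_signal_config",
    "null_config",
    "RecoveryResult",
    "recovery_benchmark",
]

_MARKER_LOADING = 2.0
_FACTOR_LOADING = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated two-group experiment.

    Parameters
    ----------
    n_features, n_per_group
        Table size and samples per group (at least 2 per group).
    prop_de
        Fraction of features with a true group difference (0 gives a pure
        null table).
    effect_size
        Absolute log2 shift of differentially expressed features.
    noise_sd
        Per-sample Gaussian noise standard deviation (log2 units).
    baseline_loc, baseline_spread
        Baseline log2 expression is ``baseline_loc + Gamma(shape=2,
        scale=baseline_spread)`` -- right-skewed, mostly within the usual
        4-14 log2 intensity range at the defaults.
    prop_annotated
        Background annotation rate among non-planted features.
    prop_planted
        Fraction of the differentially expressed features constructed to be
        fully desirable (annotated, high baseline, unloaded).
    marker_corr_structure
        Fraction of non-planted features tied to the latent factor.
    seed
        Seed for all randomness; identical configs reproduce byte-identical
        tables.
    """

    n_features: int = 10_000
    n_per_group: int = 10
    prop_de: float = 0.1
    effect_size: float = 2.0
    noise_sd: float = 0.5
    baseline_loc: float = 4.0
    baseline_spread: float = 1.5
    prop_annotated: float = 0.1
    prop_planted: float = 0.25
    marker_corr_structure: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_features < 2:
            problems.append("n_features must be at least 2")
        if self.n_per_group < 2:
            problems.append("n_per_group must be at least 2")
        for name in ("prop_de", "prop_annotated", "prop_planted",
                     "marker_corr_structure"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                problems.append(f"{name} must be in [0, 1], got {v}")
        for name in ("effect_size", "noise_sd", "baseline_spread"):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                problems.append(f"{name} must be positive, got {v}")
        if problems:
            raise ConfigError(problems)


def strong_signal_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Strong, well-separated signal: the recovery oracle scenario.

    Background annotation is switched off so the annotation criterion is
    exclusive to the planted subset; with a 4-sigma effect per sample every
    planted feature then dominates every non-planted one by construction.
    """
    params = dict(
        n_features=10_000, n_per_group=10, prop_de=0.1, effect_size=2.0,
        noise_sd=0.5, prop_annotated=0.0, prop_planted=0.25, seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """No true signal: every feature is null, no planted subset.

    The latent factor is switched off too: it makes features exchangeable
    and independent, so the p-value distribution is exactly uniform in the
    usual i.i.d. sense -- the property a null calibration check relies on.
    (With latent structure, p-values are still uniform marginally but
    correlated across loaded features, inflating the finite-sample
    variability of any calibration statistic.)
    """
    params = dict(
        n_features=10_000, n_per_group=10, prop_de=0.0, prop_planted=0.0,
        marker_corr_structure=0.0, seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def simulate_table(config: SimulationConfig):
    """Simulate one experiment and summarise it feature-wise.

    Returns
    -------
    (table, truth)
        ``table``: DataFrame indexed by feature ID with columns ``logFC``,
        ``AveExpr``, ``p_value``, ``SD``, ``marker_corr``,
        ``abs_marker_corr``, ``annotated`` -- the statistics a
        differential-expression analysis would hand to the ranking.
        ``truth``: per-feature generative ground truth (``is_de``,
        ``de_sign``, ``is_planted``, ``baseline``, ``loading``,
        ``is_marker``).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_features
    m = config.n_per_group

    baseline = config.baseline_loc + rng.gamma(2.0, config.baseline_spread, n)

    order = rng.permutation(n)
    n_de = int(round(config.prop_de * n))
    n_planted = int(round(config.prop_planted * n_de))
    de_idx = order[:n_de]
    planted_idx = de_idx[:n_planted]

    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True
    is_planted = np.zeros(n, dtype=bool)
    is_planted[planted_idx] = True

    de_sign = np.zeros(n, dtype=int)
    signs = np.ones(n_de, dtype=int)
    signs[n_de // 2:] = -1
    rng.shuffle(signs)
    de_sign[de_idx] = signs

    # planted features sit in the upper tail of the baseline distribution
    if n_planted:
        u = rng.uniform(0.85, 0.995, n_planted)
        baseline[planted_idx] = config.baseline_loc + stats.gamma.ppf(
            u, a=2.0, scale=config.baseline_spread
        )

    loading = np.zeros(n)
    loadable = ~is_planted
    loaded = loadable & (rng.random(n) < config.marker_corr_structure)
    loading[loaded] = _FACTOR_LOADING
    if loaded.any():
        marker = int(np.flatnonzero(loaded)[0])
    elif loadable.any():
        marker = int(np.flatnonzero(loadable)[0])
    else:  # pathological all-planted config; any feature can host the marker
        marker = 0
    loading[marker] = _MARKER_LOADING

    annotated = (rng.random(n) < config.prop_annotated).astype(int)
    annotated[planted_idx] = 1

    z = rng.standard_normal(2 * m)  # latent factor score per sample
    noise = rng.normal(0.0, config.noise_sd, (n, 2 * m))
    expr = baseline[:, None] + loading[:, None] * z[None, :] + noise
    expr[:, m:] += (de_sign * config.effect_size)[:, None]

    g1, g2 = expr[:, :m], expr[:, m:]
    logfc = g2.mean(axis=1) - g1.mean(axis=1)
    ave = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=1)
    pvals = stats.ttest_ind(g2, g1, axis=1, equal_var=False).pvalue

    centred = expr - ave[:, None]
    mc = centred[marker]
    denom = np.sqrt((centred ** 2).sum(axis=1) * (mc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = centred @ mc / denom

    ids = pd.Index(
        [f"f{i:06d}" for i in range(n)], name="feature_id"
    )
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "AveExpr": ave,
            "p_value": pvals,
            "SD": sd,
            "marker_corr": corr,
            "abs_marker_corr": np.abs(corr),
            "annotated": annotated,
        },
        index=ids,
    )
    truth = pd.DataFrame(
        {
            "is_de": is_de,
            "de_sign": de_sign,
            "is_planted": is_planted,
            "baseline": baseline,
            "loading": loading,
            "is_marker": np.arange(n) == marker,
        },
        index=ids,
    )
    return table, truth


def default_criteria(effect_size: float = 2.0) -> list[Criterion]:
    """Six-criterion prioritisation scheme for simulated tables.

    Mirrors the canonical breast-cancer scheme: p-value and fold-change as
    the driving criteria (weight 1), average expression and variability as
    soft filters (weight 0.1, small non-zero floor so they deprioritise
    rather than exclude), low absolute marker correlation at half weight
    (floor 0.2, same rationale), and the annotation as a categorical
    criterion (1 if annotated, else 0.2).  Fold-change cuts scale with the
    expected effect; expression/variability cuts are taken from the data
    distribution at apply time.
    """
    half = effect_size / 2.0
    return [
        Criterion(
            "p_value", "p_value",
            fn.MonotoneSpec(1e-4, 0.1, direction="low"), weight=1.0,
        ),
        Criterion(
            "fold_change", "logFC",
            fn.PlateauSpec(-half, -half / 4, half / 4, half, direction="ends"),
            weight=1.0,
        ),
        Criterion(
            "average_expression", "AveExpr",
            fn.MonotoneSpec(QuantileCut(0.25), QuantileCut(0.90),
                            des_min=0.1, direction="high"),
            weight=0.1,
        ),
        Criterion(
            "expression_sd", "SD",
            fn.MonotoneSpec(QuantileCut(0.25), QuantileCut(0.90),
                            des_min=0.1, direction="high"),
            weight=0.1,
        ),
        Criterion(
            "marker_independence", "abs_marker_corr",
            fn.MonotoneSpec(0.3, 1.0, des_min=0.2, direction="low"),
            weight=0.5,
        ),
        Criterion(
            "annotated", "annotated",
            fn.CategoricalSpec({1: 1.0, 0: 0.2}), weight=1.0,
        ),
    ]


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of a planted-feature recovery benchmark."""

    recovery: float          # fraction of reference features in the top k
    k: int
    n_reference: int
    chance_level: float      # k / n_features
    top_ids: tuple           # feature IDs of the top k by overall D
    reference_ids: tuple     # planted (or random, under the null) features
    n_top_beyond_p_top: int  # top-k features outside the top-k by p-value


def recovery_benchmark(
    config: SimulationConfig,
    criteria: Optional[Sequence[Criterion]] = None,
    k: Optional[int] = None,
) -> RecoveryResult:
    """Run the full ranking on a simulated table and score recovery.

    The reference set is the planted features; ``k`` defaults to their
    number.  Under a null configuration (no planted features) a random
    reference set of size ``k`` is drawn instead, so the statistic has a
    well-defined chance level of ``k / n_features``.

    Also counts how many of the top-``k`` features by overall desirability
    fall outside the top-``k`` by p-value alone: multi-criteria selection is
    not simply a re-ordering of the smallest p-values.
    """
    table, truth = simulate_table(config)
    criteria = list(criteria) if criteria is not None else default_criteria(
        config.effect_size
    )
    ranked = rank_table(table, criteria)

    planted = truth.index[truth["is_planted"]]
    if len(planted):
        reference = planted
        k_eff = int(k) if k is not None else len(planted)
    else:
        if k is None:
            raise ConfigError(
                ["k is required when the configuration plants no features"]
            )
        k_eff = int(k)
        rng = np.random.default_rng([config.seed, 17])
        reference = pd.Index(
            rng.choice(truth.index.to_numpy(), size=k_eff, replace=False)
        )
    if k_eff < len(planted):
        raise ConfigError(
            [f"k={k_eff} is smaller than the {len(planted)} planted features"]
        )

    top = select(ranked, k=k_eff)
    top_ids = top.index
    recovery = len(top_ids.intersection(reference)) / len(reference)

    p_ranks = comparison_rank(table, "p_value", ascending=True)
    p_top = set(p_ranks.nsmallest(k_eff).index)
    beyond = sum(1 for f in top_ids if f not in p_top)

    return RecoveryResult(
        recovery=float(recovery),
        k=k_eff,
        n_reference=len(reference),
        chance_level=k_eff / config.n_features,
        top_ids=tuple(top_ids),
        reference_ids=tuple(reference),
        n_top_beyond_p_top=int(beyond),
    )
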