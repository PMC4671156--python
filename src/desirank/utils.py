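"""Small numeric helpers used in documentation and reports."""

from __future__ import annotations

__all__ = ["joint_power", "fold_change"]


def joint_power(power: float, n_comparisons: int) -> float:
    """Probability of detecting an effect in every one of several
    independent comparisons at the given per-comparison power.

    This is the arithmetic behind the case against hard-threshold Venn
    diagram intersections: at power 0.7 per comparison, the power to detect
    a gene in all three comparisons is only ``0.7**3 = 0.343``.
    """
    if not 0.0 <= power <= 1.0:
        raise ValueError(f"power must be in [0, 1], got {power}")
    if n_comparisons < 1:
        raise ValueError(f"n_comparisons must be >= 1, got {n_comparisons}")
    return power ** n_comparisons


def fold_change(log2_fc: float) -> float:
    """Linear-scale fold change from a log2 fold-change (2**logFC)."""
    return 2.0 ** log2_fc
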