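"""Side-by-side validation against a prepared benchmark expression table.

The canonical worked example is a public breast-cancer Affymetrix study
(GEO accession GDS1329, basal vs. luminal groups).  Downloading the
accession and fitting the differential-expression model that produces the
input columns happen *outside* this package; this module consumes the
resulting per-probe-set table (p-values, log fold-changes, average
expression, SD, PCNA correlation, inflammation annotation) and recomputes
the headline summary numbers of that analysis so they can be compared with
the published ones:

* differentially expressed probe sets at FDR < 0.05,
* probe sets removed by the mean-expression / SD prefilter used for the
  p-value comparison ranking,
* probe sets with overall desirability above the selection threshold,
* the top-10 table sorted by overall desirability (with p-value ranks).
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .config import RunConfig
from .errors import ConfigError
from .pipeline import comparison_rank, rank_table, select

__all__ = ["run_accession_validation"]


def run_accession_validation(
    table: pd.DataFrame,
    run_config: RunConfig,
    fdr_column: str = "FDR",
    fdr_cutoff: float = 0.05,
    top_n: int = 10,
    gene_column: Optional[str] = "Gene",
) -> dict:
    """Rank a prepared benchmark table and report the comparison summary.

    ``table`` must contain every column the criteria reference, plus an FDR
    (adjusted p-value) column; it is indexed by probe set / feature ID.
    Returns a dict with the counts described in the module docstring and a
    ``top_table`` DataFrame for visual comparison.
    """
    missing = [
        c.column for c in run_config.criteria if c.column not in table.columns
    ]
    if fdr_column not in table.columns:
        missing.append(fdr_column)
    if missing:
        raise ConfigError(
            [f"required column {c!r} missing from the prepared table"
             for c in missing]
        )

    ranked = rank_table(table, run_config.criteria)
    output = run_config.output
    threshold = output.threshold if output.threshold is not None else 0.7
    selected = select(ranked, threshold=threshold)

    report: dict = {
        "n_features": int(len(table)),
        "de_count_fdr": int((table[fdr_column] < fdr_cutoff).sum()),
        "fdr_cutoff": fdr_cutoff,
        "selection_threshold": threshold,
        "selected_count": int(len(selected)),
    }

    comp = output.comparison
    if comp is not None:
        keep = pd.Series(True, index=table.index)
        for pf in comp.prefilters:
            keep &= pd.Series(pf.mask(table), index=table.index)
        report["prefilter_removed_count"] = int((~keep).sum())
        ranks = comparison_rank(
            table, comp.column, ascending=comp.ascending,
            prefilters=comp.prefilters,
        )
        ranked = ranked.join(ranks.rename("comparison_rank"))

    top = ranked.head(top_n)
    cols = [c for c in (gene_column, "logFC", "AveExpr", "p_value",
                        "comparison_rank", "overall_D") if c in top.columns]
    report["top_table"] = top[cols].copy()
    return report
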