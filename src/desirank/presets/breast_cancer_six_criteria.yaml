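# Six-criterion prioritisation scheme for a two-group (basal vs. luminal)
# breast-cancer differential-expression table.
#
# The p-value and log2 fold-change drive the ranking (weight 1); average
# expression and expression variability are nonspecific soft filters
# (weight 0.1); absolute correlation with the proliferation marker PCNA is
# half as important as the driving criteria (weight 0.5); annotation to an
# inflammation GO term is a categorical criterion (desirability 1 if
# annotated, 0.2 otherwise -- a non-zero floor deprioritises rather than
# removes, since database annotation may be incomplete or erroneous).
#
# Only the p-value cut points are fixed in advance (d = 1 below 1e-4, d = 0
# above 0.1).  The remaining cut points are choose-from-data-distribution
# values, written here as quantile placeholders ("q:<fraction>") that are
# resolved against the input table when the criteria are applied; replace
# them with data-scale numbers to pin them down.  The weight of the
# annotation criterion is likewise a user choice.
#
# Expected input columns: p_value, logFC, AveExpr, SD, abs_PCNA_corr,
# inflammation (0/1).

feature_id: Probeset

criteria:
  - name: p_value
    column: p_value
    function: low
    cut1: 0.0001
    cut2: 0.1
    weight: 1.0

  - name: fold_change
    column: logFC
    function: ends
    cut1: "q:0.05"      # choose from data distribution
    cut2: "q:0.25"      # choose from data distribution
    cut3: "q:0.75"      # choose from data distribution
    cut4: "q:0.95"      # choose from data distribution
    weight: 1.0

  - name: average_expression
    column: AveExpr
    function: high
    cut1: "q:0.25"      # choose from data distribution
    cut2: "q:0.75"      # choose from data distribution
    weight: 0.1

  - name: expression_sd
    column: SD
    function: high
    cut1: "q:0.25"      # choose from data distribution
    cut2: "q:0.75"      # choose from data distribution
    weight: 0.1

  - name: pcna_independence
    column: abs_PCNA_corr
    function: low
    cut1: "q:0.25"      # choose from data distribution
    cut2: "q:0.75"      # choose from data distribution
    weight: 0.5

  - name: inflammation_go
    column: inflammation
    function: categorical
    mapping:
      "1": 1.0
      "0": 0.2
    default: 0.2
    weight: 1.0         # annotation weight is a user choice

output:
  threshold: 0.7
  comparison_rank:
    column: p_value
    ascending: true
    prefilters:
      - {column: AveExpr, op: ">=", value: 6.0}
      - {column: SD, op: ">=", value: 0.25}
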