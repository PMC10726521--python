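"""Reference summary tables from a 204-genotype chile pepper diversity panel.

These are the printed inputs of a multi-environment (two-location) trial of
yield, phenology and plant-morphology traits genotyped at 14,922 SNPs:
per-trait broad-sense heritabilities, mean 10-fold cross-validated
prediction accuracies for six genomic-selection models on the whole marker
set and on a 7,690-marker LD-pruned subset, and the population / selected
means that feed the response-to-selection arithmetic at a 10% selection
intensity (top 20 of 204 candidates).  They serve as fixed numeric inputs
for the selection-response and rank-correlation analyses, and as a realism
reference for the synthetic generator.
"""

from __future__ import annotations

import pandas as pd

TRAITS = ["FPD", "FT", "GRN", "PHT", "PWDTH", "RED", "TPW", "TYP"]

TRAIT_NAMES = {
    "FPD": "first pod date",
    "FT": "flowering time",
    "GRN": "mature green yield",
    "PHT": "plant height",
    "PWDTH": "plant width",
    "RED": "mature red yield",
    "TPW": "ten pod weight",
    "TYP": "total yield per plant",
}

#: Broad-sense heritability per trait (trial-level, across two locations).
BROAD_SENSE_H2 = {
    "FPD": 0.73, "FT": 0.73, "GRN": 0.58, "PHT": 0.61,
    "PWDTH": 0.41, "RED": 0.20, "TPW": 0.88, "TYP": 0.20,
}

#: Mean CV accuracy per trait x model, whole 14,922-marker set.
ACCURACY_WHOLE = pd.DataFrame(
    {
        "BRR":    [0.77, 0.75, 0.06, 0.70, 0.61, 0.31, 0.68, 0.33],
        "GBLUP":  [0.77, 0.76, 0.05, 0.69, 0.62, 0.29, 0.71, 0.31],
        "RRBLUP": [0.77, 0.75, 0.02, 0.69, 0.60, 0.31, 0.74, 0.29],
        "CNN":    [0.75, 0.75, 0.02, 0.72, 0.61, 0.37, 0.65, 0.30],
        "MLP":    [0.74, 0.76, 0.05, 0.73, 0.60, 0.33, 0.67, 0.25],
        "RF":     [0.76, 0.75, 0.04, 0.72, 0.60, 0.30, 0.68, 0.29],
    },
    index=TRAITS,
)

#: Mean CV accuracy per trait x model, 7,690-marker LD-pruned subset.
ACCURACY_SUBSET = pd.DataFrame(
    {
        "BRR":    [0.77, 0.76, 0.10, 0.72, 0.61, 0.33, 0.69, 0.32],
        "GBLUP":  [0.77, 0.76, 0.03, 0.70, 0.61, 0.30, 0.71, 0.32],
        "RRBLUP": [0.77, 0.76, 0.02, 0.71, 0.62, 0.29, 0.72, 0.31],
        "CNN":    [0.75, 0.76, 0.03, 0.72, 0.60, 0.35, 0.67, 0.30],
        "MLP":    [0.77, 0.76, 0.05, 0.73, 0.60, 0.34, 0.70, 0.32],
        "RF":     [0.76, 0.75, 0.07, 0.72, 0.60, 0.30, 0.72, 0.32],
    },
    index=TRAITS,
)

#: Selection-response inputs for the four yield traits: trial H2 (as used in
#: that table, which carries 0.32 for mature red), the population mean, and
#: the selected-set phenotypic means under each strategy at 10% intensity.
SELECTION_INPUTS = pd.DataFrame(
    [
        # trait, H2, mean_pop, mean_PS, mean_GS, mean_PSGS, n_PSGS
        ("GRN", 0.58, 0.34, 0.35, 0.35, 0.36, 11),
        ("RED", 0.32, 0.50, 0.69, 0.57, 0.71, 9),
        ("TPW", 0.88, 0.36, 0.77, 0.76, 0.80, 17),
        ("TYP", 0.20, 0.82, 1.11, 1.02, 1.21, 9),
    ],
    columns=["trait", "H2", "mean_pop", "mean_PS", "mean_GS", "mean_PSGS", "n_PSGS"],
).set_index("trait")

N_GENOTYPES = 204
N_MARKERS_WHOLE = 14_922
N_MARKERS_SUBSET = 7_690
PRUNE_WINDOW_BP = 200_000
PRUNE_R2_MAX = 0.25
SELECTION_FRACTION = 0.10


def mean_accuracy_across_models(marker_set: str = "whole") -> pd.Series:
    """Per-trait accuracy averaged over the six models."""
    table = ACCURACY_WHOLE if marker_set == "whole" else ACCURACY_SUBSET
    return table.mean(axis=1)


def selection_response_table(rounded_percent: bool = True) -> pd.DataFrame:
    """Recompute the published selection-response arithmetic from its inputs.

    For each yield trait and strategy: S = selected mean - population mean,
    R = H2 * S, and percent change vs PS under the rounded-R convention.
    """
    from .selection import percent_change, response

    rows = []
    for trait, row in SELECTION_INPUTS.iterrows():
        S = {s: row[f"mean_{k}"] - row["mean_pop"] for s, k in
             (("PS", "PS"), ("GS", "GS"), ("PS+GS", "PSGS"))}
        R = {s: response(row["H2"], S[s]) for s in S}
        for strategy in ("PS", "GS", "PS+GS"):
            rows.append(
                {
                    "trait": trait,
                    "strategy": strategy,
                    "H2": row["H2"],
                    "mean_without_selection": row["mean_pop"],
                    "mean_with_selection": row[f"mean_{ {'PS':'PS','GS':'GS','PS+GS':'PSGS'}[strategy] }"],
                    "S": S[strategy],
                    "R": R[strategy],
                    "pct_change_vs_PS": 0.0 if strategy == "PS" else percent_change(
                        R[strategy], R["PS"], rounded=rounded_percent
                    ),
                }
            )
    return pd.DataFrame(rows)
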