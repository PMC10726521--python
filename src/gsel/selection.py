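"""Selection strategies and realized response to selection.

Three strategies over a panel of candidates: phenotypic selection (PS, top
fraction by adjusted phenotype/BLUP), genomic selection (GS, top fraction by
GEBV) and the integrated PS+GS (the intersection of the two top sets).  For
each, the realized selection differential S is the mean of the selected set
minus the population mean, and the expected response follows the breeder's
equation with realized differentials, R = H2 * S.

Percent change relative to PS is computed, by default, from R values rounded
to two decimals with the result rounded to the nearest integer percent —
the convention under which small published response tables are internally
consistent; ``rounded=False`` switches to exact arithmetic (where H2 cancels
and the percent change reduces to 100*(S_strategy - S_PS)/S_PS).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STRATEGIES = ("PS", "GS", "PS+GS")


def select_top(values: pd.Series, fraction: float = 0.10, highest: bool = True) -> list[str]:
    """Ids of the top ``fraction`` of candidates (at least one).

    Ties at the cutoff resolve to the lexicographically smaller id; set
    ``highest=False`` for traits where lower values are better.
    """
    if len(values) == 0:
        raise ValueError("no candidates to select from")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"selection fraction must be in (0, 1]; got {fraction}")
    n_selected = max(int(np.floor(fraction * len(values))), 1)
    sign = -1.0 if highest else 1.0
    order = sorted(values.items(), key=lambda kv: (sign * kv[1], kv[0]))
    return [k for k, _ in order[:n_selected]]


def integrated_selection(blups: pd.Series, gebvs: pd.Series, fraction: float = 0.10,
                         highest: bool = True) -> list[str]:
    """PS+GS: candidates in both the top-fraction BLUP and top-fraction GEBV sets."""
    ps = set(select_top(blups, fraction, highest))
    gs = set(select_top(gebvs, fraction, highest))
    return sorted(ps & gs)


def selection_differential(pop_values: pd.Series, selected_ids: list[str]) -> float:
    """S = mean over the selected candidates minus the population mean."""
    if len(selected_ids) == 0:
        return float("nan")
    return float(pop_values.loc[list(selected_ids)].mean() - pop_values.mean())


def response(H2: float, S: float) -> float:
    """Breeder's equation with realized differential: R = H2 * S."""
    if not (0.0 <= H2 <= 1.0):
        raise ValueError(f"H2 must be in [0, 1]; got {H2}")
    return H2 * S


def percent_change(R_strategy: float, R_PS: float, rounded: bool = True) -> float:
    """Percent change of a strategy's response relative to PS.

    With ``rounded=True`` both responses are first rounded to 2 decimals and
    the ratio is rounded to the nearest integer percent.
    """
    if rounded:
        R_strategy, R_PS = round(R_strategy, 2), round(R_PS, 2)
    if R_PS == 0:
        return float("nan")
    pct = 100.0 * (R_strategy - R_PS) / R_PS
    return float(round(pct)) if rounded else float(pct)


def build_report(
    blups: pd.DataFrame,
    gebvs: pd.DataFrame,
    H2: dict[str, float],
    fraction: float = 0.10,
    highest: bool = True,
    rounded_percent: bool = True,
) -> pd.DataFrame:
    """Selection-response table: one row per trait x strategy.

    ``blups`` and ``gebvs`` are individuals x traits tables sharing an index;
    ``H2`` maps each trait to its broad-sense heritability.  Columns: the
    population mean, selected-set mean, S, R, percent change vs PS, and the
    selected-candidate count with its fraction of the top-set size.
    """
    traits = [t for t in blups.columns if t in gebvs.columns]
    missing = set(traits) - set(H2)
    if missing:
        raise ValueError(f"missing H2 for traits: {sorted(missing)}")
    rows = []
    for trait in traits:
        pv = blups[trait].dropna()
        gv = gebvs[trait].reindex(pv.index).dropna()
        pv = pv.reindex(gv.index)
        n_top = max(int(np.floor(fraction * len(pv))), 1)
        sets = {
            "PS": select_top(pv, fraction, highest),
            "GS": select_top(gv, fraction, highest),
        }
        sets["PS+GS"] = sorted(set(sets["PS"]) & set(sets["GS"]))
        S = {s: selection_differential(pv, ids) for s, ids in sets.items()}
        R = {s: response(H2[trait], S[s]) if np.isfinite(S[s]) else float("nan") for s in sets}
        for strategy in STRATEGIES:
            ids = sets[strategy]
            rows.append(
                {
                    "trait": trait,
                    "strategy": strategy,
                    "H2": H2[trait],
                    "mean_without_selection": float(pv.mean()),
                    "mean_with_selection": float(pv.loc[ids].mean()) if ids else float("nan"),
                    "S": S[strategy],
                    "R": R[strategy],
                    "pct_change_vs_PS": 0.0 if strategy == "PS" else percent_change(
                        R[strategy], R["PS"], rounded=rounded_percent
                    ),
                    "n_selected": len(ids),
                    "pct_selected_of_top": 100.0 * len(ids) / n_top,
                }
            )
    return pd.DataFrame(rows)
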