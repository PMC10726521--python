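#!/usr/bin/env python
"""QC-filter the simulated panel and derive the LD-pruned marker subset.

Missing calls are injected first so the call-rate filters have work to do;
pruning uses a 200-kb window at r2 > 0.25 and the retained set is audited
exhaustively.  Writes the clean genotypes, the pruned marker list and the
QC report under results/.
"""

from pathlib import Path

import pandas as pd

from gsel import MarkerMap, audit_prune, impute_missing, qc_filter, read_numeric, window_prune
from gsel.synthetic import inject_missing

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    geno = read_numeric(DATA / "panel.geno.tsv")
    mdf = pd.read_csv(DATA / "panel.map.tsv", sep="\t")
    gmap = MarkerMap(list(mdf["marker_id"].astype(str)), mdf["chromosome"].to_numpy(),
                     mdf["position_bp"].to_numpy())

    raw = inject_missing(geno, rate=0.02, seed=77)
    clean, report = qc_filter(raw, maf_min=0.01, marker_call_rate_min=0.95,
                              sample_call_rate_min=0.50)
    print(f"QC: markers {report.n_markers_in} -> {report.n_markers_out} "
          f"({len(report.removed_markers)} removed), samples "
          f"{report.n_samples_in} -> {report.n_samples_out}")
    reasons = pd.Series(list(report.removed_markers.values())).value_counts()
    for reason, count in reasons.items():
        print(f"  removed for {reason}: {count}")
    report.to_frame().to_csv(OUT / "qc_report.tsv", sep="\t", index=False)

    imputed = impute_missing(clean)
    gmap_qc = gmap.subset(imputed.marker_ids)
    prune = window_prune(imputed, gmap_qc, window_bp=200_000, r2_max=0.25)
    violations = audit_prune(imputed, gmap_qc, prune)
    print(f"prune: retained {len(prune.retained_marker_ids)} / {imputed.n_markers} markers "
          f"(200 kb window, r2 > 0.25); audit violations: {len(violations)}")
    assert not violations, "pruning post-condition violated"
    prune.to_frame().to_csv(OUT / "prune_result.tsv", sep="\t", index=False)

    from gsel import write_numeric

    write_numeric(imputed, OUT / "panel.qc.geno.tsv")
    write_numeric(imputed.subset(marker_ids=prune.retained_marker_ids),
                  OUT / "panel.pruned.geno.tsv")
    print(f"wrote clean + pruned genotype matrices under {OUT}/")


if __name__ == "__main__":
    main()
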