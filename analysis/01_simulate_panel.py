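#!/usr/bin/env python
"""Simulate the study panel: 204 genotypes, mapped SNPs with block LD, and
four yield-like traits with known architecture.

Writes genotypes (numeric + HapMap), the marker map, per-environment trial
phenotypes and adjusted (BLUP-like) values, plus the trait truth table,
under results/data/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gsel import SimConfig, simulate_environment_trials, simulate_genotypes, simulate_trait
from gsel.genotype_io import write_hapmap, write_numeric

OUT = Path("results/data")
SEED = 20240

# Four traits spanning the heritability range of yield and yield components:
# (name, n_qtl, genomic h2, trial-level H2, GxE share)
TRAITS = [
    ("green_yield", 80, 0.05, 0.58, 0.5),
    ("red_yield", 80, 0.10, 0.32, 0.5),
    ("ten_pod_weight", 120, 0.80, 0.88, 0.2),
    ("total_yield", 80, 0.10, 0.20, 0.8),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimConfig(n_individuals=204, n_chromosomes=6, markers_per_chromosome=250,
                       chromosome_length_bp=11_250_000, ld_decay_rho=0.9, seed=SEED)
    geno, gmap = simulate_genotypes(config)
    write_numeric(geno, OUT / "panel.geno.tsv")
    write_hapmap(geno, gmap, OUT / "panel.hmp.txt")
    gmap.to_frame().to_csv(OUT / "panel.map.tsv", sep="\t", index=False)
    print(f"panel: {geno.n_individuals} genotypes x {geno.n_markers} markers, "
          f"mean MAF {geno.minor_allele_frequencies().mean():.3f}")

    truth_rows = []
    trial_frames = []
    adjusted = {}
    for i, (name, n_qtl, h2, H2, gxe) in enumerate(TRAITS):
        truth = simulate_trait(geno, n_qtl, h2, seed=SEED + 10 + i, gxe_ratio=gxe)
        trials, adj = simulate_environment_trials(
            truth, geno.individual_ids, n_env=2, n_rep=1, target_H2=H2,
            seed=SEED + 50 + i, trait=name)
        trial_frames.append(trials)
        adjusted[name] = adj.set_index("genotype_id")["value"]
        truth_rows.append({"trait": name, "n_qtl": n_qtl, "target_h2": h2,
                           "realized_h2": round(truth.realized_h2, 4),
                           "target_H2": H2, "gxe_ratio": gxe,
                           "var_breeding_values": round(float(np.var(truth.true_breeding_values)), 4)})
        pd.DataFrame({"genotype_id": geno.individual_ids,
                      "breeding_value": truth.true_breeding_values}).to_csv(
            OUT / f"truth_bv_{name}.tsv", sep="\t", index=False)
        print(f"trait {name}: {n_qtl} QTL, realized h2 {truth.realized_h2:.3f}, target H2 {H2}")

    pd.concat(trial_frames, ignore_index=True).to_csv(OUT / "trials.tsv", sep="\t", index=False)
    pd.DataFrame(adjusted).rename_axis("genotype_id").to_csv(OUT / "blups.tsv", sep="\t")
    pd.DataFrame(truth_rows).to_csv(OUT / "trait_truth.tsv", sep="\t", index=False)
    (OUT / "sim_config.json").write_text(json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v) for k, v in config.__dict__.items()},
        indent=2))
    print(f"wrote panel + {len(TRAITS)} traits under {OUT}/")


if __name__ == "__main__":
    main()
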