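"""Config-driven orchestration of the full genomic-selection analysis.

One :func:`run` call takes a :class:`RunConfig` (simulate a panel or load
genotype/phenotype files), then walks the stages in order: QC -> optional
LD pruning -> kinship -> per-trait model fits (GEBVs) -> cross-validated
accuracies -> heritability -> GEBV summaries -> selection-response report,
writing each artifact as TSV plus a machine-readable run manifest.  A single
global seed fans out to per-stage seeds by fixed offsets so that adding a
model or trait does not perturb the randomness of earlier stages.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .crossval import accuracy_pivot, cv_accuracy, gebv_report
from .genotype_io import (
    GenotypeMatrix,
    impute_missing,
    qc_filter,
    read_hapmap,
    read_numeric,
)
from .heritability import genomic_h2
from .kinship import vanraden_g
from .ld import window_prune
from .models import (
    SUPPORTED_MODELS,
    BRRPriors,
    MLModelSpec,
    fit_brr,
    fit_gblup,
    fit_ml,
    fit_rrblup,
)
from .selection import build_report
from .synthetic import SimConfig, inject_missing, simulate_genotypes, simulate_trait, simulate_environment_trials

log = logging.getLogger("gsel")

# Per-stage seed offsets from the global seed.
_SEED_OFFSETS = {"simulate": 11, "traits": 211, "missing": 307, "models": 401, "cv": 701}


@dataclass
class TraitSpec:
    """One simulated trait: architecture and trial design."""

    name: str = "trait"
    n_qtl: int = 100
    target_h2: float = 0.5
    target_H2: float = 0.6
    gxe_ratio: float = 0.3
    n_env: int = 2
    n_rep: int = 1


@dataclass
class RunConfig:
    mode: str = "simulate"                      # "simulate" | "files"
    sim: SimConfig = field(default_factory=SimConfig)
    traits: list[TraitSpec] = field(default_factory=lambda: [TraitSpec()])
    genotype_file: str | None = None            # numeric TSV or HapMap (.hmp.txt)
    phenotype_file: str | None = None           # tidy BLUP TSV: genotype_id, trait, value
    missing_rate: float = 0.0
    qc: dict = field(default_factory=lambda: {"maf_min": 0.01, "marker_call_rate_min": 0.95,
                                              "sample_call_rate_min": 0.50})
    prune: dict | None = field(default_factory=lambda: {"window_bp": 200_000, "r2_max": 0.25})
    models: list[str] = field(default_factory=lambda: ["rrblup", "gblup"])
    cv: dict = field(default_factory=lambda: {"k": 10, "n_iterations": 10})
    selection_fraction: float = 0.10
    out_dir: str = "results/run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError(f"mode must be 'simulate' or 'files'; got {self.mode!r}")
        bad = [m for m in self.models if m not in SUPPORTED_MODELS]
        if bad:
            raise ValueError(f"unsupported models {bad}; choose from {SUPPORTED_MODELS}")
        if self.mode == "files":
            for path in (self.genotype_file, self.phenotype_file):
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"file mode requires existing input files; missing {path!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" in raw:
            raw["sim"] = SimConfig(**raw["sim"])
        if "traits" in raw:
            raw["traits"] = [TraitSpec(**t) for t in raw["traits"]]
        return cls(**raw)


def _fit_model_gebvs(model: str, geno: GenotypeMatrix, y: pd.Series, K, seed: int) -> pd.Series:
    if model == "rrblup":
        return fit_rrblup(geno, y).gebvs
    if model == "gblup":
        return fit_gblup(K, y).gebvs
    if model == "brr":
        return fit_brr(geno, y, BRRPriors(), seed=seed).gebvs
    return fit_ml(geno, y, MLModelSpec(family=model), seed=seed).gebvs


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the artifact directory."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "setup"
    try:
        # ---- inputs -----------------------------------------------------
        stage = "input"
        truths = {}
        if config.mode == "simulate":
            sim = SimConfig(**{**config.sim.__dict__, "seed": config.seed + _SEED_OFFSETS["simulate"]})
            geno, gmap = simulate_genotypes(sim)
            if config.missing_rate > 0:
                geno = inject_missing(geno, config.missing_rate, config.seed + _SEED_OFFSETS["missing"])
            blups = {}
            for i, spec in enumerate(config.traits):
                tseed = config.seed + _SEED_OFFSETS["traits"] + 13 * i
                truth = simulate_trait(impute_missing(geno) if config.missing_rate else geno,
                                       spec.n_qtl, spec.target_h2, tseed, gxe_ratio=spec.gxe_ratio)
                _, adjusted = simulate_environment_trials(
                    truth, geno.individual_ids, spec.n_env, spec.n_rep, spec.target_H2,
                    tseed + 1, trait=spec.name)
                truths[spec.name] = truth
                blups[spec.name] = adjusted.set_index("genotype_id")["value"]
            pheno = pd.DataFrame(blups)
        else:
            gpath = str(config.genotype_file)
            if gpath.endswith((".hmp.txt", ".hapmap", ".hmp")):
                geno, gmap = read_hapmap(gpath)
            else:
                geno, gmap = read_numeric(gpath), None
            tidy = pd.read_csv(config.phenotype_file, sep="\t")
            pheno = tidy.pivot_table(index="genotype_id", columns="trait", values="value")

        # ---- QC ---------------------------------------------------------
        stage = "qc"
        geno, qc_report = qc_filter(geno, **config.qc)
        qc_report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        geno = impute_missing(geno)
        pheno = pheno.reindex(geno.individual_ids)

        marker_sets = {"whole": geno}
        # ---- LD pruning -------------------------------------------------
        if config.prune is not None and gmap is not None:
            stage = "prune"
            gmap_qc = gmap.subset(geno.marker_ids)
            prune = window_prune(geno, gmap_qc, **config.prune)
            prune.to_frame().to_csv(out / "prune_result.tsv", sep="\t", index=False)
            marker_sets["subset"] = geno.subset(marker_ids=prune.retained_marker_ids)
            log.info("prune: retained %d / %d markers", len(prune.retained_marker_ids), geno.n_markers)

        # ---- kinship ----------------------------------------------------
        stage = "kinship"
        kinships = {name: vanraden_g(g) for name, g in marker_sets.items()}
        kinships["whole"].write_tsv(out / "kinship_whole.tsv")

        # ---- model fits (GEBVs on the full panel) -----------------------
        stage = "fit"
        gebv_frames = {}
        for set_name, g in marker_sets.items():
            for model in config.models:
                cols = {}
                for trait in pheno.columns:
                    y = pheno[trait].dropna()
                    gg = g.subset(individual_ids=list(y.index))
                    cols[trait] = _fit_model_gebvs(model, gg, y, kinships[set_name],
                                                   config.seed + _SEED_OFFSETS["models"])
                frame = pd.DataFrame(cols)
                frame.to_csv(out / f"gebv_{model}_{set_name}.tsv", sep="\t")
                gebv_frames[(model, set_name)] = frame

        # ---- cross-validation -------------------------------------------
        stage = "cv"
        cv_results = []
        for set_name, g in marker_sets.items():
            for model in config.models:
                for trait in pheno.columns:
                    y = pheno[trait].dropna()
                    gg = g.subset(individual_ids=list(y.index))
                    cv_results.append(
                        cv_accuracy(model, gg, y, k=config.cv.get("k", 10),
                                    n_iterations=config.cv.get("n_iterations", 10),
                                    seed=config.seed + _SEED_OFFSETS["cv"],
                                    trait=trait, marker_set=set_name)
                    )
        cv_table = pd.concat([r.to_frame() for r in cv_results], ignore_index=True)
        cv_table.to_csv(out / "cv_accuracy.tsv", sep="\t", index=False)
        accuracy_pivot(cv_results).to_csv(out / "accuracy_pivot.tsv", sep="\t", index=False)

        # ---- heritability ----------------------------------------------
        stage = "heritability"
        herit_rows = []
        for trait in pheno.columns:
            y = pheno[trait].dropna()
            h2, vc = genomic_h2(kinships["whole"], y)
            row = {"trait": trait, "h2_genomic": h2,
                   "sigma2_a": vc.sigma2_a, "sigma2_e": vc.sigma2_e}
            if trait in truths:
                row["target_h2"] = truths[trait].target_h2
            herit_rows.append(row)
        herit = pd.DataFrame(herit_rows)
        herit.to_csv(out / "heritability.tsv", sep="\t", index=False)

        # ---- GEBV summary + selection response --------------------------
        stage = "report"
        first_model = config.models[0]
        gebvs = gebv_frames[(first_model, "whole")]
        report = gebv_report(gebvs)
        report["summary"].to_csv(out / "gebv_summary.tsv", sep="\t", index=False)
        report["correlations"].to_csv(out / "gebv_correlations.tsv", sep="\t", index=False)

        H2_map = {}
        for spec in (config.traits if config.mode == "simulate" else []):
            H2_map[spec.name] = spec.target_H2
        if not H2_map:  # file mode: fall back to genomic h2 as the heritability weight
            H2_map = dict(zip(herit["trait"], herit["h2_genomic"]))
        selection = build_report(pheno, gebvs, H2_map, fraction=config.selection_fraction)
        selection.to_csv(out / "selection_response.tsv", sep="\t", index=False)

        # ---- manifest ---------------------------------------------------
        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "stage_seed_offsets": _SEED_OFFSETS,
            "mode": config.mode,
            "models": config.models,
            "qc": config.qc,
            "prune": config.prune,
            "cv": config.cv,
            "selection_fraction": config.selection_fraction,
            "n_individuals": geno.n_individuals,
            "n_markers": {k: g.n_markers for k, g in marker_sets.items()},
            "elapsed_s": round(time.time() - t0, 2),
        }
        if config.mode == "simulate":
            manifest["sim"] = {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in config.sim.__dict__.items()}
            manifest["traits"] = [t.__dict__ for t in config.traits]
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
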