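"""Synthetic diversity-panel generator with known truth.

Every downstream stage (QC, LD pruning, kinship, prediction models,
cross-validation, selection response) is exercised against data from this
module, where the additive architecture, variance components and therefore
the true breeding values are known exactly.

Genotypes: each haplotype is a latent stationary AR(1) Gaussian process along
the chromosome, thresholded at the allele-frequency quantile; two independent
haplotypes are summed to a 0/1/2 dosage.  The AR(1) coefficient
``ld_decay_rho`` sets the correlation between adjacent markers' latent
variables, so linkage disequilibrium decays geometrically with marker
distance — tunable, position-indexed LD without a coalescent engine.

Traits: additive QTL effects drawn N(0,1) at uniformly placed marker subsets
(the infinitesimal-model assumption of the ridge-type predictors being
tested), residual variance scaled to hit a target narrow-sense heritability.
Multi-environment trials add a genotype-by-environment interaction and
plot residuals scaled to a target broad-sense heritability
H2 = s2_G / (s2_G + s2_GE/n_env + s2_e/(n_env*n_rep)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, MarkerMap


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Panel-simulation settings.

    Defaults emulate a diversity panel of ~200 genotypes scored at a few
    thousand mapped SNPs with substantial long-range LD (adjacent-marker
    latent correlation 0.9 at ~45 kb spacing gives multi-megabase LD blocks,
    of the order reported for pepper diversity panels).
    """

    n_individuals: int = 204
    n_chromosomes: int = 12
    markers_per_chromosome: int = 250
    chromosome_length_bp: int = 11_250_000
    ld_decay_rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_individuals, self.n_chromosomes, self.markers_per_chromosome, self.chromosome_length_bp) < 1:
            raise ConfigError("all counts must be >= 1")
        if not (0.0 <= self.ld_decay_rho < 1.0):
            raise ConfigError(f"ld_decay_rho must be in [0, 1); got {self.ld_decay_rho}")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < low < high <= 0.5; got {self.maf_range}")
        if self.markers_per_chromosome > self.chromosome_length_bp:
            raise ConfigError("more markers than base pairs on a chromosome")


@dataclass
class TraitTruth:
    """Known additive architecture of one simulated trait."""

    qtl_marker_ids: list[str]
    qtl_effects: np.ndarray
    true_breeding_values: np.ndarray
    phenotype: np.ndarray          # single-trial phenotype = BV + residual
    target_h2: float
    realized_h2: float
    gxe_ratio: float = 0.3         # s2_GE / s2_G carried into multi-environment trials
    target_H2: float | None = None

    def __post_init__(self) -> None:
        if self.target_h2 > 0 and np.var(self.true_breeding_values) <= 0:
            raise ConfigError("true breeding values are constant despite target_h2 > 0")


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, MarkerMap]:
    """Simulate a dosage matrix and its physical map.

    Marker positions are evenly spaced with uniform jitter, strictly
    increasing within each chromosome; per-marker allele frequencies are
    drawn uniformly over ``maf_range``.
    """
    rng = np.random.default_rng(config.seed)
    n, m_chr, n_chr = config.n_individuals, config.markers_per_chromosome, config.n_chromosomes
    m = n_chr * m_chr
    rho = config.ld_decay_rho

    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    # Quantile thresholds: latent z < Phi^{-1}(p) -> carry the coded allele.
    from scipy.stats import norm

    thresholds = norm.ppf(p)

    dosages = np.empty((n, m), dtype=float)
    innov_sd = np.sqrt(1.0 - rho * rho)
    for hap in range(2):
        z = np.empty((n, m))
        for c in range(n_chr):
            sl = slice(c * m_chr, (c + 1) * m_chr)
            eps = rng.standard_normal((n, m_chr))
            zc = np.empty((n, m_chr))
            zc[:, 0] = eps[:, 0]
            for j in range(1, m_chr):
                zc[:, j] = rho * zc[:, j - 1] + innov_sd * eps[:, j]
            z[:, sl] = zc
        alleles = (z < thresholds).astype(float)
        if hap == 0:
            dosages = alleles
        else:
            dosages = dosages + alleles

    marker_ids = []
    chroms = []
    positions = []
    spacing = config.chromosome_length_bp / m_chr
    for c in range(n_chr):
        base = np.arange(m_chr) * spacing
        jitter = rng.uniform(0.05, 0.95, size=m_chr) * spacing
        pos = np.floor(base + jitter).astype(np.int64) + 1
        pos = np.maximum.accumulate(pos)  # guard against jitter-induced ties
        pos += np.arange(m_chr)           # strict increase
        chrom = f"chr{c + 1:02d}"
        for j in range(m_chr):
            marker_ids.append(f"{chrom}_m{j + 1:04d}")
            chroms.append(chrom)
            positions.append(pos[j])

    geno = GenotypeMatrix([f"ind{i + 1:04d}" for i in range(n)], marker_ids, dosages)
    gmap = MarkerMap(marker_ids, np.array(chroms, dtype=object), np.array(positions))
    return geno, gmap


def simulate_trait(
    geno: GenotypeMatrix,
    n_qtl: int,
    target_h2: float,
    seed: int,
    gxe_ratio: float = 0.3,
) -> TraitTruth:
    """Simulate an additive trait on an existing panel.

    QTL are placed uniformly at random among the markers; effects are drawn
    N(0,1) on centered dosages.  The residual variance is scaled against the
    realized breeding-value variance so that Var(BV)/Var(phenotype) hits
    ``target_h2`` in expectation over the residual draw.
    """
    if not (0.0 <= target_h2 <= 1.0):
        raise ConfigError(f"target_h2 must be in [0, 1]; got {target_h2}")
    if n_qtl < 1 or n_qtl > geno.n_markers:
        raise ConfigError(f"n_qtl must be in [1, {geno.n_markers}]; got {n_qtl}")
    if gxe_ratio < 0:
        raise ConfigError("gxe_ratio must be >= 0")
    rng = np.random.default_rng(seed)

    qtl_idx = np.sort(rng.choice(geno.n_markers, size=n_qtl, replace=False))
    effects = rng.standard_normal(n_qtl)
    Wq = geno.dosages[:, qtl_idx] - geno.dosages[:, qtl_idx].mean(axis=0)
    bv = Wq @ effects
    var_bv = float(np.var(bv))
    if var_bv <= 0:
        # All sampled QTL monomorphic (possible only on tiny toys): jitter-free flat trait.
        bv = np.zeros(geno.n_individuals)

    if target_h2 == 0.0:
        # No genetic signal in the phenotype; BVs are kept for oracle use.
        noise_sd = np.sqrt(var_bv) if var_bv > 0 else 1.0
        phenotype = rng.standard_normal(geno.n_individuals) * noise_sd
        realized = 0.0
    elif target_h2 == 1.0:
        phenotype = bv.copy()
        realized = 1.0
    else:
        sigma2_e = var_bv * (1.0 - target_h2) / target_h2
        resid = rng.standard_normal(geno.n_individuals) * np.sqrt(sigma2_e)
        phenotype = bv + resid
        realized = var_bv / (var_bv + float(np.var(resid))) if var_bv > 0 else 0.0

    return TraitTruth(
        qtl_marker_ids=[geno.marker_ids[j] for j in qtl_idx],
        qtl_effects=effects,
        true_breeding_values=bv,
        phenotype=phenotype,
        target_h2=target_h2,
        realized_h2=float(realized),
        gxe_ratio=gxe_ratio,
    )


def simulate_environment_trials(
    truth: TraitTruth,
    individual_ids: list[str],
    n_env: int,
    n_rep: int,
    target_H2: float,
    seed: int,
    trait: str = "trait",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate multi-environment trial phenotypes around known breeding values.

    Returns ``(trials, adjusted)``:

    * ``trials`` — tidy table (genotype_id, environment, rep, trait, value)
      with value = mu + g_i + ge_ie + e_ier, where ge ~ N(0, s2_GE) with
      s2_GE = gxe_ratio * s2_G and e ~ N(0, s2_e) solved from the target
      broad-sense heritability H2 = s2_G/(s2_G + s2_GE/n + s2_e/(n r)).
    * ``adjusted`` — per-genotype BLUP-like value: the across-environment
      mean shrunk toward the grand mean by the (injected) H2 — an emulation
      of an augmented-design BLUP, not a reproduction of one.
    """
    if n_env < 1 or n_rep < 1:
        raise ConfigError("n_env and n_rep must be >= 1")
    if not (0.0 < target_H2 <= 1.0):
        raise ConfigError(f"target_H2 must be in (0, 1]; got {target_H2}")
    g = np.asarray(truth.true_breeding_values, dtype=float)
    if len(individual_ids) != len(g):
        raise ConfigError("individual_ids length does not match breeding values")
    s2_G = float(np.var(g))
    if s2_G <= 0:
        raise ConfigError("breeding values are constant; multi-environment trial is degenerate")
    s2_GE = truth.gxe_ratio * s2_G
    # Solve s2_e from the H2 identity; infeasible if GxE alone exceeds the target.
    s2_e = n_env * n_rep * (s2_G / target_H2 - s2_G - s2_GE / n_env)
    if s2_e < -1e-12:
        max_H2 = s2_G / (s2_G + s2_GE / n_env)
        raise ConfigError(
            f"target_H2={target_H2} infeasible with gxe_ratio={truth.gxe_ratio} "
            f"and n_env={n_env} (max attainable {max_H2:.3f})"
        )
    s2_e = max(s2_e, 0.0)

    rng = np.random.default_rng(seed)
    n = len(g)
    ge = rng.standard_normal((n, n_env)) * np.sqrt(s2_GE)
    rows = []
    for e in range(n_env):
        env = f"env{e + 1}"
        for r in range(n_rep):
            resid = rng.standard_normal(n) * np.sqrt(s2_e)
            values = g + ge[:, e] + resid
            for i, gid in enumerate(individual_ids):
                rows.append((gid, env, r + 1, trait, values[i]))
    trials = pd.DataFrame(rows, columns=["genotype_id", "environment", "rep", "trait", "value"])

    means = trials.groupby("genotype_id", sort=False)["value"].mean()
    means = means.reindex(individual_ids)
    grand = float(means.mean())
    realized_H2 = s2_G / (s2_G + s2_GE / n_env + s2_e / (n_env * n_rep))
    adjusted = pd.DataFrame(
        {
            "genotype_id": individual_ids,
            "trait": trait,
            "value": grand + realized_H2 * (means.to_numpy() - grand),
        }
    )
    return trials, adjusted


def inject_missing(geno: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set a random ``rate`` fraction of calls to missing (for QC exercises)."""
    if not (0.0 <= rate < 1.0):
        raise ConfigError(f"missing rate must be in [0, 1); got {rate}")
    rng = np.random.default_rng(seed)
    dos = geno.dosages.copy()
    mask = rng.random(dos.shape) < rate
    dos[mask] = np.nan
    return GenotypeMatrix(list(geno.individual_ids), list(geno.marker_ids), dos)
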