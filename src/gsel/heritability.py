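"""Broad-sense and genomic heritability.

Broad-sense H2 across multi-environment trials follows
H2 = s2_G / (s2_G + s2_GE/n + s2_e/(n r)) with n environments and r
replicates; the variance components are accepted as inputs (trial-model
fitting is upstream of this package).  Genomic h2 = s2_A / (s2_A + s2_e)
comes from the single-kernel REML fit on a genomic relationship matrix,
through the same spectral core used by the prediction models so the two
report consistent variance components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._reml import reml_fit
from .kinship import KinshipMatrix
from .models import VarianceComponents


@dataclass
class TrialVarianceComponents:
    sigma2_G: float
    sigma2_GE: float
    sigma2_e: float
    n_env: int
    n_rep: int

    def __post_init__(self) -> None:
        if min(self.sigma2_G, self.sigma2_GE, self.sigma2_e) < 0:
            raise ValueError("variance components must be >= 0")
        if self.n_env < 1 or self.n_rep < 1:
            raise ValueError("environment and replicate counts must be >= 1")


def broad_sense_h2(vc: TrialVarianceComponents) -> float:
    """H2 = s2_G / (s2_G + s2_GE/n + s2_e/(n r))."""
    denom = vc.sigma2_G + vc.sigma2_GE / vc.n_env + vc.sigma2_e / (vc.n_env * vc.n_rep)
    if denom <= 0:
        raise ValueError("all variance components are zero; H2 undefined")
    return vc.sigma2_G / denom


def genomic_h2(K: KinshipMatrix, pheno) -> tuple[float, VarianceComponents]:
    """REML genomic heritability on a relationship matrix.

    ``pheno``: Series indexed by individual id (aligned to K) or an array in
    K's order.  Returns (h2, variance components); h2 is guaranteed in [0,1].
    """
    if isinstance(pheno, pd.Series):
        ids = list(pheno.index.astype(str))
        y = pheno.to_numpy(dtype=float)
        Kmat = K.subset(ids)
    else:
        y = np.asarray(pheno, dtype=float)
        Kmat = K.values
    if len(y) < 20:
        raise ValueError("need at least 20 individuals for a stable REML h2")
    res = reml_fit(Kmat, y)
    vc = VarianceComponents(res.sigma2_g, res.sigma2_e)
    return float(np.clip(res.h2, 0.0, 1.0)), vc


def genomic_h2_profile(K: KinshipMatrix, pheno, grid: np.ndarray | None = None) -> pd.DataFrame:
    """Restricted log-likelihood over an h2 grid (brute-force REML oracle)."""
    if isinstance(pheno, pd.Series):
        Kmat = K.subset(list(pheno.index.astype(str)))
        y = pheno.to_numpy(dtype=float)
    else:
        Kmat, y = K.values, np.asarray(pheno, dtype=float)
    if grid is None:
        grid = np.arange(0.0, 1.0001, 0.001)
    # One eigendecomposition serves the whole grid.
    from ._reml import _LOG_DELTA_HI, _LOG_DELTA_LO, _profile_neg2_reml

    d, U = np.linalg.eigh((Kmat + Kmat.T) / 2.0)
    d = np.maximum(d, 0.0)
    yt, xt = U.T @ y, U.T @ np.ones(len(y))
    scale = np.log(max(np.mean(d), 1e-300))
    ll = []
    for h in np.asarray(grid, dtype=float):
        if h <= 0.0:
            log_delta = _LOG_DELTA_HI + scale
        elif h >= 1.0:
            log_delta = _LOG_DELTA_LO + scale
        else:
            log_delta = np.log((1.0 - h) / h)
        ll.append(-0.5 * _profile_neg2_reml(log_delta, d, yt, xt))
    return pd.DataFrame({"h2": grid, "restricted_loglik": ll})


def heritability_table(components: dict[str, TrialVarianceComponents]) -> pd.DataFrame:
    """Per-trait broad-sense heritability table (trait, H2)."""
    return pd.DataFrame(
        {"trait": list(components), "H2": [broad_sense_h2(v) for v in components.values()]}
    )
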