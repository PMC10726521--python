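"""Genomic relationship matrix (VanRaden method 1).

G = W W' / (2 * sum_k p_k (1 - p_k)), where W is the dosage matrix with each
column centered by twice the observed allele frequency 2 p_k.  Under
Hardy-Weinberg equilibrium the diagonal averages 1 + f (f the mean
inbreeding), so diag(G) ~ 1 for an outbred panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeError, GenotypeMatrix


@dataclass
class KinshipMatrix:
    individual_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"kinship shape {self.values.shape} does not match {n} ids")

    def subset(self, row_ids: list[str], col_ids: list[str] | None = None) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.individual_ids)}
        rows = [idx[s] for s in row_ids]
        cols = rows if col_ids is None else [idx[s] for s in col_ids]
        return self.values[np.ix_(rows, cols)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individual_ids, columns=self.individual_ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


def vanraden_g(geno: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix from a complete dosage matrix.

    Monomorphic markers carry no relationship information: their centered
    column is zero and they are excluded from the 2*sum(p(1-p)) denominator.
    """
    if not geno.is_complete():
        raise GenotypeError("kinship requires a complete (imputed) dosage matrix")
    p = geno.dosages.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if poly.sum() < 2:
        raise GenotypeError("need at least 2 polymorphic markers for kinship")
    W = geno.dosages[:, poly] - 2.0 * p[poly]
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0  # enforce exact symmetry against fp round-off
    return KinshipMatrix(list(geno.individual_ids), G)
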