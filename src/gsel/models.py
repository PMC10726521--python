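"""Genomic prediction models.

Three linear mixed-model fitters are implemented from their equations:

* RRBLUP — y = 1*mu + W a + e with a ~ N(0, sigma2_a I); REML variance
  components via the shared spectral core on the kernel W W', marker effects
  recovered through the ridge identity a = W'(W W' + lambda I)^{-1}(y - mu).
* GBLUP — y = 1*mu + g + e with g ~ N(0, G sigma2_g); held-out individuals
  predicted by the BLUP conditional expectation
  g_test = G_ts (G_tt + lambda I)^{-1} (y - mu).
  With G built from the same centered dosages, GBLUP and RRBLUP produce
  identical GEBVs — the module's central internal consistency check.
* BRR — Bayesian ridge regression by scalar Gibbs sampling: Gaussian marker
  effects with a common variance, scaled-inverse-chi-square priors on both
  the effect and residual variances, posterior means over post-burn-in draws.

The machine-learning stage (random forest, multilayer perceptron, 1-D CNN)
wraps scikit-learn regressors (and :mod:`gsel.neural` for the CNN) behind a
grid search that holds out 20% of the training data for hyperparameter
scoring by mean-squared error, then refits the winner on the full training
set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._reml import REMLResult, reml_fit
from .genotype_io import GenotypeError, GenotypeMatrix
from .kinship import KinshipMatrix

SUPPORTED_MODELS = ("rrblup", "gblup", "brr", "rf", "mlp", "cnn")


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float

    def __post_init__(self) -> None:
        if self.sigma2_a < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be >= 0")

    @property
    def lam(self) -> float:
        """Shrinkage ratio sigma2_e / sigma2_a (inf when sigma2_a = 0)."""
        return self.sigma2_e / self.sigma2_a if self.sigma2_a > 0 else np.inf

    @property
    def h2(self) -> float:
        total = self.sigma2_a + self.sigma2_e
        return self.sigma2_a / total if total > 0 else 0.0


@dataclass
class BRRPriors:
    """Gibbs-chain length and scaled-inverse-chi-square hyperpriors.

    The prior scales default to splitting the sample phenotypic variance
    50/50 between the marker and residual terms (set at fit time when left
    as None); prior degrees of freedom are mild at 5.
    """

    n_iter: int = 1000
    burn_in: int = 200
    df_beta: float = 5.0
    df_e: float = 5.0
    scale_beta: float | None = None
    scale_e: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.df_beta <= 0 or self.df_e <= 0:
            raise ValueError("prior df must be > 0")


@dataclass
class ModelFit:
    """One trained prediction model and everything needed to apply it."""

    model: str
    mu: float
    gebvs: pd.Series                      # indexed by individual id, includes mu
    marker_effects: np.ndarray | None = None
    marker_ids: list[str] | None = None
    center: np.ndarray | None = None      # per-marker centering (2p) for new dosage rows
    variance: VarianceComponents | None = None
    hyperparameters: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    _predictor: object = None             # fitted learner for ML families

    def predict(self, geno: GenotypeMatrix) -> pd.Series:
        """GEBVs for new individuals (marker-effect and ML models only)."""
        if self.marker_ids is not None and geno.marker_ids != self.marker_ids:
            geno = geno.subset(marker_ids=self.marker_ids)
        if self.marker_effects is not None:
            W = geno.dosages - self.center
            return pd.Series(self.mu + W @ self.marker_effects, index=geno.individual_ids)
        if self._predictor is not None:
            return pd.Series(self._predictor.predict(geno.dosages), index=geno.individual_ids)
        raise ValueError(f"{self.model}: no marker effects or predictor available; "
                         "held-out GEBVs must be requested at fit time")


def _check_training(geno: GenotypeMatrix, y: np.ndarray) -> None:
    if not geno.is_complete():
        raise GenotypeError("models require a complete (imputed) dosage matrix")
    if len(y) != geno.n_individuals:
        raise ValueError("phenotype length does not match genotype rows")
    if len(y) < 10:
        raise ValueError("need at least 10 training records")


def _as_array(pheno, ids: list[str]) -> np.ndarray:
    if isinstance(pheno, pd.Series):
        return pheno.reindex(ids).to_numpy(dtype=float)
    return np.asarray(pheno, dtype=float)


# ---------------------------------------------------------------------------
# RRBLUP
# ---------------------------------------------------------------------------

def fit_rrblup(geno_train: GenotypeMatrix, pheno_train) -> ModelFit:
    """Ridge-regression BLUP with REML variance components."""
    y = _as_array(pheno_train, geno_train.individual_ids)
    _check_training(geno_train, y)
    center = geno_train.dosages.mean(axis=0)  # 2p per marker
    W = geno_train.dosages - center
    K = W @ W.T
    res: REMLResult = reml_fit(K, y)
    if np.isinf(res.delta) or res.sigma2_g == 0:
        effects = np.zeros(geno_train.n_markers)
    else:
        n = len(y)
        effects = W.T @ np.linalg.solve(K + res.delta * np.eye(n), y - res.mu)
    gebvs = pd.Series(res.mu + W @ effects, index=geno_train.individual_ids)
    return ModelFit(
        model="rrblup",
        mu=res.mu,
        gebvs=gebvs,
        marker_effects=effects,
        marker_ids=list(geno_train.marker_ids),
        center=center,
        variance=VarianceComponents(res.sigma2_g, res.sigma2_e),
        diagnostics={"reml_converged": res.converged, "reml_evals": res.n_iter,
                     "lambda": res.delta},
    )


# ---------------------------------------------------------------------------
# GBLUP
# ---------------------------------------------------------------------------

def fit_gblup(K: KinshipMatrix, pheno_train, predict_ids: list[str] | None = None,
              ridge: float = 0.0) -> ModelFit:
    """GBLUP on a genomic relationship matrix.

    ``pheno_train`` must be a Series indexed by individual id (its index
    defines the training set), or an array aligned to ``K.individual_ids``.
    ``predict_ids`` are held-out individuals covered by K whose GEBVs come
    from the conditional expectation given the training records.
    """
    if isinstance(pheno_train, pd.Series):
        train_ids = list(pheno_train.index.astype(str))
        y = pheno_train.to_numpy(dtype=float)
    else:
        train_ids = list(K.individual_ids)
        y = np.asarray(pheno_train, dtype=float)
    missing = set(train_ids) - set(K.individual_ids)
    if missing:
        raise ValueError(f"kinship does not cover training ids, e.g. {sorted(missing)[0]!r}")
    K_tt = K.subset(train_ids)
    if ridge:
        K_tt = K_tt + ridge * np.eye(len(train_ids))
    res = reml_fit(K_tt, y)

    gebv = {tid: res.mu + g for tid, g in zip(train_ids, res.fitted_g)}
    if predict_ids:
        missing = set(predict_ids) - set(K.individual_ids)
        if missing:
            raise ValueError(f"kinship does not cover predict ids, e.g. {sorted(missing)[0]!r}")
        if np.isinf(res.delta):
            g_test = np.zeros(len(predict_ids))
        else:
            K_ts = K.subset(predict_ids, train_ids)
            n = len(train_ids)
            try:
                g_test = K_ts @ np.linalg.solve(K_tt + res.delta * np.eye(n), y - res.mu)
            except np.linalg.LinAlgError:
                # Stabilise a numerically singular system with a small ridge.
                g_test = K_ts @ np.linalg.solve(K_tt + (res.delta + 1e-6) * np.eye(n), y - res.mu)
        for pid, g in zip(predict_ids, g_test):
            gebv[pid] = res.mu + g

    order = train_ids + [p for p in (predict_ids or []) if p not in set(train_ids)]
    return ModelFit(
        model="gblup",
        mu=res.mu,
        gebvs=pd.Series({i: gebv[i] for i in order}),
        variance=VarianceComponents(res.sigma2_g, res.sigma2_e),
        diagnostics={"reml_converged": res.converged, "reml_evals": res.n_iter,
                     "lambda": res.delta},
    )


# ---------------------------------------------------------------------------
# Bayesian ridge regression
# ---------------------------------------------------------------------------

def fit_brr(
    geno_train: GenotypeMatrix,
    pheno_train,
    priors: BRRPriors | None = None,
    seed: int = 0,
    fixed_variances: tuple[float, float] | None = None,
    store_effect_samples: bool = False,
) -> ModelFit:
    """Bayesian ridge regression by scalar Gibbs sampling.

    ``fixed_variances=(sigma2_beta, sigma2_e)`` freezes the variance draws
    (degenerate priors), under which the effect posterior is exactly the
    ridge solution — used as the sampler's correctness oracle.
    """
    priors = priors or BRRPriors()
    y = _as_array(pheno_train, geno_train.individual_ids)
    _check_training(geno_train, y)
    rng = np.random.default_rng(seed)

    center = geno_train.dosages.mean(axis=0)
    W = geno_train.dosages - center
    n, m = W.shape
    col_ss = np.einsum("ij,ij->j", W, W)
    active = col_ss > 0  # monomorphic markers stay at effect 0
    vy = float(np.var(y))

    scale_beta = priors.scale_beta
    if scale_beta is None:
        msx = float(col_ss.sum()) / n if col_ss.sum() > 0 else 1.0
        scale_beta = (0.5 * vy) / msx if vy > 0 else 1e-4
    scale_e = priors.scale_e if priors.scale_e is not None else (0.5 * vy if vy > 0 else 1e-4)

    mu = float(np.mean(y))
    beta = np.zeros(m)
    sigma2_beta, sigma2_e = (fixed_variances if fixed_variances else (scale_beta, scale_e))
    if sigma2_beta <= 0 or sigma2_e <= 0:
        raise ValueError("variances must be positive")
    resid = y - mu  # running residual y - mu - W beta

    keep = priors.n_iter - priors.burn_in
    sum_mu = 0.0
    sum_beta = np.zeros(m)
    sum_s2b = 0.0
    sum_s2e = 0.0
    samples = np.empty((keep, m)) if store_effect_samples else None
    active_idx = np.where(active)[0]

    for it in range(priors.n_iter):
        # mu | rest
        offset = float(np.mean(resid)) + mu
        mu_new = rng.normal(offset, np.sqrt(sigma2_e / n))
        resid += mu - mu_new
        mu = mu_new
        # beta_j | rest, scalar updates in fixed order
        lam = sigma2_e / sigma2_beta
        for j in active_idx:
            wj = W[:, j]
            rhs = wj @ resid + col_ss[j] * beta[j]
            prec = col_ss[j] + lam
            b_new = rng.normal(rhs / prec, np.sqrt(sigma2_e / prec))
            resid += wj * (beta[j] - b_new)
            beta[j] = b_new
        if fixed_variances is None:
            # scaled-inv-chi2 full conditionals
            df_b = priors.df_beta + active.sum()
            ss_b = priors.df_beta * scale_beta + float(beta @ beta)
            sigma2_beta = ss_b / rng.chisquare(df_b)
            df_e = priors.df_e + n
            ss_e = priors.df_e * scale_e + float(resid @ resid)
            sigma2_e = ss_e / rng.chisquare(df_e)
            if not (np.isfinite(sigma2_beta) and np.isfinite(sigma2_e)):
                raise RuntimeError("non-finite variance draw: check prior configuration")
        if it >= priors.burn_in:
            t = it - priors.burn_in
            sum_mu += mu
            sum_beta += beta
            sum_s2b += sigma2_beta
            sum_s2e += sigma2_e
            if store_effect_samples:
                samples[t] = beta

    mu_hat = sum_mu / keep
    beta_hat = sum_beta / keep
    diagnostics = {"n_iter": priors.n_iter, "burn_in": priors.burn_in, "seed": seed,
                   "scale_beta": scale_beta, "scale_e": scale_e}
    if store_effect_samples:
        diagnostics["effect_samples"] = samples
    return ModelFit(
        model="brr",
        mu=mu_hat,
        gebvs=pd.Series(mu_hat + W @ beta_hat, index=geno_train.individual_ids),
        marker_effects=beta_hat,
        marker_ids=list(geno_train.marker_ids),
        center=center,
        variance=VarianceComponents(sum_s2b / keep, sum_s2e / keep),
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Machine-learning stage
# ---------------------------------------------------------------------------

#: The full hyperparameter grids as enumerated for each learner family.
FULL_GRIDS = {
    "rf": {
        "n_estimators": [200, 300, 500, 1000],
        "max_features": ["auto", "sqrt"],
        "max_depth": [40, 60, 80, 100],
    },
    "mlp": {
        "hidden_layers": [1, 4, 6, 8, 10],
        "neurons": [10, 19, 38, 50, 62, 98, 112, 150],
        "activation": ["relu", "linear", "tanh", "identity", "logistic"],
        "solver": ["lbfgs", "sgd", "adam"],
        "learning_rate": ["constant", "adaptive"],
        "alpha": [0.0001, 0.001, 0.01],
    },
    "cnn": {
        "n_filters": [16, 32, 64, 128],
        "dropout": [0.20],
    },
}

#: Reduced desk-scale grids used by default; the full grids sit behind a flag.
DEFAULT_GRIDS = {
    "rf": {"n_estimators": [200, 500], "max_features": ["auto", "sqrt"], "max_depth": [40, 80]},
    "mlp": {"hidden_layers": [1, 4], "neurons": [19, 50], "activation": ["relu"],
            "solver": ["adam"], "learning_rate": ["constant"], "alpha": [0.001]},
    "cnn": {"n_filters": [16, 32], "dropout": [0.20]},
}


@dataclass
class MLModelSpec:
    family: str
    grid: dict[str, list] | None = None
    full_grid: bool = False
    tune_fraction: float = 0.8  # share of training data used to fit grid candidates

    def __post_init__(self) -> None:
        if self.family not in ("rf", "mlp", "cnn"):
            raise ValueError(f"unknown ML family {self.family!r}")
        if self.grid is None:
            self.grid = dict(FULL_GRIDS[self.family] if self.full_grid else DEFAULT_GRIDS[self.family])
        if any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("empty hyperparameter grid")
        if not (0.0 < self.tune_fraction < 1.0):
            raise ValueError("tune_fraction must be in (0, 1)")


def _make_learner(family: str, params: dict, seed: int):
    if family == "rf":
        from sklearn.ensemble import RandomForestRegressor

        max_features = params.get("max_features", "auto")
        if max_features == "auto":  # regression convention: all features
            max_features = 1.0
        return RandomForestRegressor(
            n_estimators=params.get("n_estimators", 500),
            max_features=max_features,
            max_depth=params.get("max_depth"),
            random_state=seed,
            n_jobs=1,
        )
    if family == "mlp":
        from sklearn.neural_network import MLPRegressor

        activation = params.get("activation", "relu")
        if activation == "linear":
            activation = "identity"
        return MLPRegressor(
            hidden_layer_sizes=tuple([params.get("neurons", 50)] * params.get("hidden_layers", 1)),
            activation=activation,
            solver=params.get("solver", "adam"),
            learning_rate=params.get("learning_rate", "constant"),
            alpha=params.get("alpha", 1e-4),
            max_iter=800,
            random_state=seed,
        )
    if family == "cnn":
        from .neural import CNNRegressor

        return CNNRegressor(
            n_filters=params.get("n_filters", 16),
            dropout=params.get("dropout", 0.2),
            random_state=seed,
        )
    raise ValueError(family)


def fit_ml(
    geno_train: GenotypeMatrix,
    pheno_train,
    spec: MLModelSpec,
    seed: int = 0,
    predict_geno: GenotypeMatrix | None = None,
) -> ModelFit:
    """Grid-searched learner fit: tune on an 80/20 split of the training data
    by MSE, refit the best configuration on the full training set."""
    y = _as_array(pheno_train, geno_train.individual_ids)
    _check_training(geno_train, y)
    X = geno_train.dosages
    rng = np.random.default_rng(seed)
    n = len(y)
    order = rng.permutation(n)
    n_tune = max(int(round(spec.tune_fraction * n)), 2)
    n_tune = min(n_tune, n - 1)
    tune_idx, val_idx = order[:n_tune], order[n_tune:]

    keys = sorted(spec.grid)
    best = None
    results = []
    for combo in itertools.product(*(spec.grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        learner = _make_learner(spec.family, params, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter on small grids
            try:
                learner.fit(X[tune_idx], y[tune_idx])
                mse = float(np.mean((learner.predict(X[val_idx]) - y[val_idx]) ** 2))
            except Exception as exc:  # a failing grid point is scored out
                results.append((params, np.inf, str(exc)))
                continue
        results.append((params, mse, None))
        if best is None or mse < best[1]:
            best = (params, mse)
    if best is None:
        raise RuntimeError(f"{spec.family}: every grid point failed to fit")

    final = _make_learner(spec.family, best[0], seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)
    gebvs = pd.Series(final.predict(X), index=geno_train.individual_ids)
    if predict_geno is not None:
        held_out = pd.Series(final.predict(predict_geno.dosages), index=predict_geno.individual_ids)
        gebvs = pd.concat([gebvs, held_out])
    return ModelFit(
        model=spec.family,
        mu=float(np.mean(y)),
        gebvs=gebvs,
        marker_ids=list(geno_train.marker_ids),
        hyperparameters=best[0],
        diagnostics={"grid_mse": [(p, m) for p, m, _ in results], "val_mse": best[1]},
        _predictor=final,
    )
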