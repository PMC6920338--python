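"""Replicated K-fold cross-validation and broad-sense heritability.

Prediction ability is the Pearson correlation between observed and
predicted phenotypes of held-out hybrids.  Broad-sense heritability is
estimated from a completely randomized block design (CRBD) with locations
as blocks: y_jk = mu + alpha_j + beta_k + eps_jk, blocks fixed, hybrid
effects random, h2 = sigma2_G / (sigma2_G + sigma2_E).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import KinshipMatrix
from .mixed_model import MixedModelData, blup_predict, eigendecompose, fit_reml

__all__ = [
    "CVResult",
    "VarianceComponents",
    "kfold_partition",
    "prediction_ability",
    "cross_validate",
    "fit_crbd",
]


@dataclass
class CVResult:
    """Replicated K-fold cross-validation output for one or more traits."""

    fold_assignments: np.ndarray          # replicates x individuals
    predicted: dict[str, np.ndarray]      # trait -> replicates x individuals
    ability_per_replicate: pd.DataFrame   # rows replicates, columns traits
    ability_mean: pd.Series               # per-trait mean over replicates

    @property
    def n_replicates(self) -> int:
        return self.fold_assignments.shape[0]


@dataclass
class VarianceComponents:
    """CRBD variance components and broad-sense heritability.

    ``sigma2_G_raw`` keeps a possibly negative moment estimate; ``sigma2_G``
    is truncated at 0 and used for ``h2_broad``.
    """

    sigma2_G: float
    sigma2_E: float
    h2_broad: float
    grand_mean: float
    block_effects: np.ndarray
    sigma2_G_raw: float
    ms_genotype: float
    ms_error: float
    n_hybrids: int
    n_blocks: int


def kfold_partition(n: int, k: int, seed: int) -> np.ndarray:
    """Random fold labels 0..k-1 for n individuals; fold sizes differ by at
    most one; deterministic given the seed."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        labels[chunk] = fold
    return labels


def prediction_ability(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Pearson correlation between observed and predicted values."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size != y_pred.size:
        raise ValueError("observed and predicted vectors differ in length")
    if y_obs.size < 3:
        raise ValueError("need at least 3 pairs to compute prediction ability")
    if np.std(y_obs) == 0 or np.std(y_pred) == 0:
        raise ValueError("prediction ability undefined: zero variance")
    return float(stats.pearsonr(y_obs, y_pred).statistic)


def cross_validate(
    K: KinshipMatrix,
    pheno: pd.DataFrame | np.ndarray,
    k: int = 10,
    replicates: int = 10,
    seed: int = 0,
) -> CVResult:
    """Replicated K-fold CV of GBLUP prediction ability.

    ``pheno``: one column per trait, rows aligned with (or indexed by) the
    kinship individual ids.  Each replicate r uses partition seed
    ``seed + r``; every fold is predicted by a model refit on the remaining
    folds, with kinship sub-blocks taken from the one full-sample K.
    """
    if isinstance(pheno, pd.DataFrame):
        if not pheno.index.equals(pd.RangeIndex(len(pheno))):
            pheno = pheno.loc[K.individual_ids]
        traits = list(pheno.columns)
        Y = pheno.to_numpy(dtype=float)
    else:
        Y = np.atleast_2d(np.asarray(pheno, dtype=float))
        if Y.shape[0] == 1:
            Y = Y.T
        traits = [f"trait{j + 1}" for j in range(Y.shape[1])]
    n = K.n
    if Y.shape[0] != n:
        raise ValueError("phenotype rows do not match kinship dimension")
    folds = np.empty((replicates, n), dtype=int)
    predicted = {t: np.full((replicates, n), np.nan) for t in traits}
    abilities = np.full((replicates, len(traits)), np.nan)
    for r in range(replicates):
        labels = kfold_partition(n, k, seed + r)
        folds[r] = labels
        for fold in range(k):
            test = np.flatnonzero(labels == fold)
            train = np.flatnonzero(labels != fold)
            K11 = KinshipMatrix(K.values[np.ix_(train, train)],
                                [K.individual_ids[i] for i in train],
                                K.n_markers_used)
            K21 = K.values[np.ix_(test, train)]
            eig = eigendecompose(K11)
            for j, t in enumerate(traits):
                y_train = Y[train, j]
                try:
                    data = MixedModelData(y=y_train, K=K11)
                    fit = fit_reml(data, eigen=eig)
                    pred = blup_predict(fit, data, K21, eigen=eig)
                except (ValueError, np.linalg.LinAlgError) as e:
                    warnings.warn(f"replicate {r} fold {fold} trait {t}: "
                                  f"fit failed ({e}); fold skipped", stacklevel=2)
                    continue
                predicted[t][r, test] = pred.y_hat[:, 0]
        for j, t in enumerate(traits):
            mask = ~np.isnan(predicted[t][r])
            if mask.sum() >= 3:
                abilities[r, j] = prediction_ability(Y[mask, j], predicted[t][r, mask])
    ability_df = pd.DataFrame(abilities, columns=traits,
                              index=pd.RangeIndex(replicates, name="replicate"))
    return CVResult(fold_assignments=folds, predicted=predicted,
                    ability_per_replicate=ability_df,
                    ability_mean=ability_df.mean(axis=0))


def _crbd_moments(Y: np.ndarray) -> tuple[float, float, float, float, np.ndarray, float]:
    """Expected-mean-squares decomposition of an n x b two-way layout
    without replication (hybrids random, blocks fixed)."""
    n, b = Y.shape
    grand = float(Y.mean())
    row_mean = Y.mean(axis=1)
    col_mean = Y.mean(axis=0)
    ms_g = b * float(np.sum((row_mean - grand) ** 2)) / (n - 1)
    resid = Y - row_mean[:, None] - col_mean[None, :] + grand
    ms_e = float(np.sum(resid**2)) / ((n - 1) * (b - 1))
    sigma2_g_raw = (ms_g - ms_e) / b
    return ms_g, ms_e, sigma2_g_raw, grand, col_mean - grand, float(ms_e)


def fit_crbd(
    pheno_two_blocks: pd.DataFrame | np.ndarray,
    method: str = "moments",
) -> VarianceComponents:
    """Variance components and broad-sense heritability from a CRBD.

    Input: hybrids in rows, blocks (locations) in columns; rows with any
    missing block are dropped with a warning.  ``method='moments'`` uses the
    expected-mean-squares equations MS_G = sigma2_E + b sigma2_G,
    MS_E = sigma2_E; ``method='reml'`` maximizes the restricted likelihood
    of the same model (block effects fixed).
    """
    if isinstance(pheno_two_blocks, pd.DataFrame):
        Y = pheno_two_blocks.to_numpy(dtype=float)
    else:
        Y = np.atleast_2d(np.asarray(pheno_two_blocks, dtype=float))
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("need at least two blocks to separate genetic and "
                         "residual variance")
    complete = ~np.isnan(Y).any(axis=1)
    if not complete.all():
        warnings.warn(f"dropping {int((~complete).sum())} hybrids missing in some block",
                      stacklevel=2)
        Y = Y[complete]
    n, b = Y.shape
    if n < 2:
        raise ValueError("need at least two hybrids")
    ms_g, ms_e, s2g_raw, grand, blocks, s2e = _crbd_moments(Y)
    if method == "reml":
        s2g_raw, s2e = _crbd_reml(Y, start=(max(s2g_raw, 1e-8), max(s2e, 1e-8)))
    elif method != "moments":
        raise ValueError(f"unknown method {method!r}")
    s2g = max(s2g_raw, 0.0)
    total = s2g + s2e
    h2 = s2g / total if total > 0 else 1.0
    return VarianceComponents(sigma2_G=s2g, sigma2_E=s2e, h2_broad=h2,
                              grand_mean=grand, block_effects=blocks,
                              sigma2_G_raw=s2g_raw, ms_genotype=ms_g,
                              ms_error=ms_e, n_hybrids=n, n_blocks=b)


def _crbd_reml(Y: np.ndarray, start: tuple[float, float]) -> tuple[float, float]:
    """REML for the two-way layout: profile likelihood over the variance
    ratio gamma = sigma2_G / sigma2_E using the balanced-design sufficient
    statistics (row means and residual contrasts)."""
    n, b = Y.shape
    grand = Y.mean()
    row_mean = Y.mean(axis=1)
    col_mean = Y.mean(axis=0)
    ss_rows = float(np.sum((row_mean - grand) ** 2))       # df n-1, var sG + sE/b
    resid = Y - row_mean[:, None] - col_mean[None, :] + grand
    ss_err = float(np.sum(resid**2))                        # df (n-1)(b-1), var sE

    df1, df2 = n - 1, (n - 1) * (b - 1)

    def negll(log_gamma: float) -> float:
        g = float(np.exp(log_gamma))
        v1 = g + 1.0 / b                                    # (sG + sE/b)/sE
        # profile sigma2_E
        s2e = (ss_rows / v1 + ss_err) / (df1 + df2)
        return 0.5 * (df1 * np.log(v1) + (df1 + df2) * np.log(s2e))

    res = optimize.minimize_scalar(negll, bounds=(np.log(1e-10), np.log(1e10)),
                                   method="bounded", options={"xatol": 1e-12})
    g = float(np.exp(res.x))
    v1 = g + 1.0 / b
    s2e = (ss_rows / v1 + ss_err) / (df1 + df2)
    return g * s2e, s2e
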