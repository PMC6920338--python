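"""Breeding index: trait standardization, weighted index, extreme-set
selection and a PCA summary of predicted-trait matrices.

The breeding index of hybrid j is I_j = sum_k w_k * z_jk, where z_jk is the
predicted value of trait k standardized across the candidate set and the
weights w_k are proportions summing to one.  The default weights are the
ten-trait rice set: yield 0.40; the four yield components PN, GN, SSR 0.10
each and KGW 0.05; 0.05 for each remaining trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IndexWeights",
    "BreedingIndexResult",
    "DEFAULT_RICE_WEIGHTS",
    "standardize",
    "breeding_index",
    "select_extremes",
    "pca_summary",
]

#: Ten-trait rice breeding-index weights (proportions): yield (YD) 0.4;
#: panicle number (PN), grains/panicle (GN), seed-setting rate (SSR) 0.1;
#: 1000-grain weight (KGW), heading date (HD), plant height (PH), panicle
#: length (PL), grain width (GW), grain length (GL) 0.05 each.
DEFAULT_RICE_WEIGHTS: dict[str, float] = {
    "YD": 0.40, "PN": 0.10, "GN": 0.10, "SSR": 0.10, "KGW": 0.05,
    "HD": 0.05, "PH": 0.05, "PL": 0.05, "GW": 0.05, "GL": 0.05,
}


@dataclass
class IndexWeights:
    """Ordered trait weights; non-negative proportions summing to 1."""

    trait_names: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if len(self.trait_names) != self.weights.size:
            raise ValueError("trait names and weights differ in length")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {self.weights.sum()!r}")

    @classmethod
    def default_rice(cls) -> "IndexWeights":
        return cls(list(DEFAULT_RICE_WEIGHTS), np.array(list(DEFAULT_RICE_WEIGHTS.values())))


@dataclass
class BreedingIndexResult:
    hybrid_ids: list[str]
    index_scores: np.ndarray
    standardized_traits: pd.DataFrame


def standardize(predicted: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Per-trait z-scores across the candidate hybrid set.

    The population standard deviation (ddof=0) is the default; the
    reference population is the set being ranked.
    """
    if len(predicted) < 2:
        raise ValueError("need at least 2 hybrids to standardize")
    values = predicted.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=ddof)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance trait(s): {[predicted.columns[i] for i in zero]}")
    z = (values - values.mean(axis=0)) / sd
    return pd.DataFrame(z, index=predicted.index, columns=predicted.columns)


def breeding_index(
    standardized: pd.DataFrame, weights: IndexWeights | None = None
) -> BreedingIndexResult:
    """Weighted index I_j = sum_k w_k z_jk over standardized traits."""
    if weights is None:
        weights = IndexWeights.default_rice()
    missing = [t for t in weights.trait_names if t not in standardized.columns]
    if missing:
        raise ValueError(f"traits named in weights missing from input: {missing}")
    Z = standardized[weights.trait_names].to_numpy(dtype=float)
    scores = Z @ weights.weights
    return BreedingIndexResult(
        hybrid_ids=[str(i) for i in standardized.index],
        index_scores=scores,
        standardized_traits=standardized,
    )


def select_extremes(
    result: BreedingIndexResult, n_top: int, n_bottom: int
) -> tuple[list[str], list[str]]:
    """Ids of the highest- and lowest-index hybrids.

    Ties are broken by lexicographic hybrid id; the returned sets must be
    disjoint, otherwise (too few candidates, or ties straddling both ends)
    an error is raised.
    """
    n = len(result.hybrid_ids)
    if n_top + n_bottom > n:
        raise ValueError(f"cannot select {n_top}+{n_bottom} from {n} hybrids")
    pairs = list(zip(result.index_scores, result.hybrid_ids))
    top = [h for _, h in sorted(pairs, key=lambda p: (-p[0], p[1]))[:n_top]]
    bottom = [h for _, h in sorted(pairs, key=lambda p: (p[0], p[1]))[:n_bottom]]
    if set(top) & set(bottom):
        raise ValueError("top and bottom selections overlap (tied scores)")
    return top, bottom


def pca_summary(
    predicted: pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the column-standardized predicted-trait matrix.

    Returns (scores, eigenvalues): eigenvalues of the trait correlation
    matrix (non-increasing, summing to the number of traits) and the
    component scores for the first ``n_components`` axes.
    """
    p = predicted.shape[1]
    if n_components is None:
        n_components = p
    if n_components > p:
        raise ValueError("n_components exceeds number of traits")
    Z = standardize(predicted).to_numpy()
    n = Z.shape[0]
    # eigenvalues of Z'Z/n = correlation matrix (population convention)
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = s**2 / n
    scores = Z @ Vt.T[:, :n_components]
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=predicted.index, columns=cols), eigvals
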