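"""Synthetic inbred parents, crosses and polygenic phenotypes.

The generator emulates the structure the hybrid-prediction pipeline
assumes: fully inbred biallelic parents with a configurable minor-allele-
frequency spectrum, F1 hybrids whose genotype code is the parental mean,
and phenotypes with additive (optionally dominance and genotype-by-
environment) polygenic architecture at a target broad-sense heritability.

Two heritability conventions are supported, because the uncentered kinship
K = (1/m) sum Z_k Z_k' makes them differ:

* ``simulate_phenotypes`` calibrates the residual variance against the
  *realized* variance of genetic values, so designed broad-sense
  heritability matches what a CRBD analysis estimates.
* ``simulate_polygenic`` draws directly from the GBLUP model with
  lambda = h2 / ((1 - h2) kbar), kbar = mean diagonal of K, so the genomic
  heritability lambda*kbar / (lambda*kbar + 1) equals the target; this is
  the convention under which REML recovers h2.

Markers are drawn independently (no linkage map): nothing downstream uses
positional information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .designs import Cross, ParentPanel, half_diallel
from .genotypes import (GenotypeMatrix, KinshipMatrix, build_hybrid_matrix,
                        compute_kinship, dominance_codes)

__all__ = [
    "SimulationConfig",
    "TrainTestBundle",
    "simulate_parents",
    "simulate_phenotypes",
    "simulate_polygenic",
    "make_training_and_test",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Defaults describe a desk-scale analogue of a dense hybrid crossing
    program: 50 inbred parents, 800 biallelic markers with post-QC minor
    allele frequencies in [0.1, 0.5], half-diallel crosses, a polygenic
    trait at broad-sense heritability 0.8.
    """

    n_parents: int = 50
    m_markers: int = 800
    maf_low: float = 0.1
    maf_high: float = 0.5
    residual_het_rate: float = 0.0
    missing_rate: float = 0.0
    h2_target: float = 0.8
    dominance_share: float = 0.0
    gxe_share: float = 0.0
    n_environments: int = 1
    n_train_hybrids: int = 400
    n_test_hybrids: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("residual_het_rate", "missing_rate", "h2_target",
                     "dominance_share", "gxe_share"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dominance_share + self.gxe_share > 1:
            raise ValueError("dominance_share + gxe_share must be <= 1")
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.n_environments < 1:
            raise ValueError("n_environments must be >= 1")


@dataclass
class TrainTestBundle:
    """End-to-end fixture: parents, training hybrids with phenotypes, and
    test hybrids with true genetic values."""

    parents: GenotypeMatrix
    train: GenotypeMatrix
    test: GenotypeMatrix
    pheno_train: pd.DataFrame        # columns: one per environment
    truth_train: np.ndarray          # genetic values (env-averaged)
    truth_test: np.ndarray
    K: KinshipMatrix                 # kinship over train + test hybrids
    config: SimulationConfig


def simulate_parents(config: SimulationConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw a panel of inbred parents.

    Per marker, the frequency p of the +1 allele is uniform on
    [maf_low, maf_high]; each parent is homozygous (+1 with probability p,
    else -1) unless residually heterozygous (code 0) with probability
    ``residual_het_rate``; genotypes are masked missing at ``missing_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m, n = config.m_markers, config.n_parents
    p = rng.uniform(config.maf_low, config.maf_high, size=m)
    codes = np.where(rng.random((m, n)) < p[:, None], 1.0, -1.0)
    if config.residual_het_rate > 0:
        codes[rng.random((m, n)) < config.residual_het_rate] = 0.0
    if config.missing_rate > 0:
        codes[rng.random((m, n)) < config.missing_rate] = np.nan
    ids = [f"P{i + 1:03d}" for i in range(n)]
    markers = [f"M{j + 1:05d}" for j in range(m)]
    return GenotypeMatrix(codes, markers, ids)


def _unit_var(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Center and scale a realized effect vector to unit population variance."""
    sd = x.std()
    if sd == 0:
        # degenerate draw (e.g. monomorphic panel); resample from noise
        x = rng.standard_normal(x.size)
        sd = x.std()
    return (x - x.mean()) / sd


def simulate_phenotypes(
    hybrids: GenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Polygenic phenotypes for a hybrid panel, one column per environment.

    Genetic values combine additive (marker effects on Z codes), dominance
    (effects on heterozygosity codes 1-|Z|) and environment-specific
    additive deviations in the proportions requested by the config, scaled
    to unit realized genetic variance; the residual SD is then set from the
    realized genetic variance so the designed broad-sense heritability
    equals ``h2_target``.  Returns (phenotypes, true genetic values) where
    the truth is the environment-average genetic value.
    """
    if hybrids.has_missing():
        raise ValueError("hybrid genotypes must be complete (impute first)")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    Z = hybrids.codes
    m, n = Z.shape
    ds, gs = config.dominance_share, config.gxe_share
    add_share = 1.0 - ds - gs
    if config.h2_target > 0 and add_share + ds + gs == 0:
        raise ValueError("h2_target > 0 requires a non-zero genetic variance share")
    gamma = rng.normal(0.0, 1.0 / np.sqrt(m), size=m)
    g_add = _unit_var(Z.T @ gamma, rng)
    g_main = np.sqrt(add_share) * g_add
    if ds > 0:
        delta = rng.normal(0.0, 1.0 / np.sqrt(m), size=m)
        g_dom = _unit_var(dominance_codes(Z).T @ delta, rng)
        g_main = g_main + np.sqrt(ds) * g_dom
    E = config.n_environments
    g_by_env = np.tile(g_main[:, None], (1, E)).astype(float)
    if gs > 0:
        for e in range(E):
            gamma_e = rng.normal(0.0, 1.0 / np.sqrt(m), size=m)
            g_by_env[:, e] += np.sqrt(gs) * _unit_var(Z.T @ gamma_e, rng)
    # residual variance from realized genetic variance: h2 = vg/(vg+ve)
    vg = float(np.mean(g_by_env.var(axis=0)))
    h2 = config.h2_target
    if h2 >= 1.0:
        sigma_e = 0.0
    elif h2 <= 0.0:
        # pure-noise trait: no genetic signal at all
        g_by_env[:] = 0.0
        sigma_e = 1.0
    else:
        sigma_e = float(np.sqrt(vg * (1.0 - h2) / h2))
    y = g_by_env + rng.normal(0.0, sigma_e, size=(n, E)) if sigma_e > 0 else g_by_env.copy()
    cols = [f"env{e + 1}" for e in range(E)]
    pheno = pd.DataFrame(y, index=hybrids.individual_ids, columns=cols)
    return pheno, g_by_env.mean(axis=1)


def simulate_polygenic(
    hybrids: GenotypeMatrix,
    h2: float,
    rng: np.random.Generator | int | None = None,
    K: KinshipMatrix | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Draw one trait exactly from the GBLUP model at genomic heritability h2.

    Marker effects gamma_k ~ N(0, phi2/m) with phi2 = lambda (sigma2 = 1)
    and lambda = h2 / ((1 - h2) kbar); returns (y, genetic values, lambda).
    """
    if not 0 <= h2 < 1:
        raise ValueError("h2 must be in [0, 1)")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    Z = hybrids.codes
    if np.isnan(Z).any():
        raise ValueError("hybrid genotypes must be complete")
    m, n = Z.shape
    if K is None:
        K = compute_kinship(hybrids)
    kbar = float(np.mean(np.diag(K.values)))
    lam = h2 / ((1.0 - h2) * kbar) if h2 > 0 else 0.0
    gamma = rng.normal(0.0, np.sqrt(lam / m) if lam > 0 else 0.0, size=m)
    g = Z.T @ gamma
    y = g + rng.standard_normal(n)
    return y, g, lam


def make_training_and_test(
    config: SimulationConfig, design: str = "disjoint"
) -> TrainTestBundle:
    """Simulate parents, cross them, and split hybrids into training and
    test populations.

    ``design='disjoint'`` crosses two disjoint parent subsets (the test
    hybrids share no parents with training, as in an independent validation
    panel); ``design='shared'`` samples both hybrid sets from one
    half-diallel over all parents.  Marker effects are drawn once for the
    combined panel so training and test genetic values are consistent.
    """
    rng = np.random.default_rng(config.seed)
    parents = simulate_parents(config, rng)
    ids = parents.individual_ids
    panel = ParentPanel(ids, {p: "simulated" for p in ids})
    if design == "disjoint":
        cut = max(2, int(round(len(ids) * 0.7)))
        panel_a = ParentPanel(ids[:cut], {p: "simulated" for p in ids[:cut]})
        panel_b = ParentPanel(ids[cut:], {p: "simulated" for p in ids[cut:]})
        train_pool = half_diallel(panel_a)
        test_pool = half_diallel(panel_b)
    elif design == "shared":
        pool = half_diallel(panel)
        order = rng.permutation(len(pool))
        n_tot = config.n_train_hybrids + config.n_test_hybrids
        if n_tot > len(pool):
            raise ValueError(f"requested {n_tot} hybrids but the diallel has {len(pool)}")
        train_pool = [pool[i] for i in order[: config.n_train_hybrids]]
        test_pool = [pool[i] for i in order[config.n_train_hybrids: n_tot]]
    else:
        raise ValueError(f"unknown design {design!r}")

    def sample(pool: list[Cross], k: int) -> list[tuple[str, str]]:
        if k > len(pool):
            raise ValueError(f"requested {k} hybrids but only {len(pool)} crosses exist")
        idx = rng.choice(len(pool), size=k, replace=False)
        return [(pool[i].female, pool[i].male) for i in idx]

    if design == "disjoint":
        train_crosses = sample(train_pool, config.n_train_hybrids)
        test_crosses = sample(test_pool, config.n_test_hybrids)
    else:
        train_crosses = [(c.female, c.male) for c in train_pool]
        test_crosses = [(c.female, c.male) for c in test_pool]
    train = build_hybrid_matrix(parents, train_crosses)
    test = build_hybrid_matrix(parents, test_crosses)
    combined = GenotypeMatrix(
        np.hstack([train.codes, test.codes]),
        list(parents.marker_ids),
        train.individual_ids + test.individual_ids,
    )
    pheno_all, truth_all = simulate_phenotypes(combined, config, rng)
    n1 = train.n_individuals
    K = compute_kinship(combined)
    return TrainTestBundle(
        parents=parents, train=train, test=test,
        pheno_train=pheno_all.iloc[:n1],
        truth_train=truth_all[:n1], truth_test=truth_all[n1:],
        K=K, config=config,
    )
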