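"""End-to-end pipeline: filter -> hybrids -> kinship -> fit -> cv ->
predict -> index, with every intermediate artifact written to disk.

The pipeline runs either on simulated inputs (a `simulate:` block in the
config) or on user files (training-hybrid genotypes + phenotypes, plus an
optional parent panel and cross list for the prediction set).  All stages
are deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .evaluation import cross_validate
from .genotypes import (GenotypeMatrix, MarkerFilterSpec, build_hybrid_matrix,
                        compute_kinship, filter_markers, impute_mean)
from .mixed_model import MixedModelData, blup_predict, eigendecompose, fit_reml
from .selection import IndexWeights, breeding_index, select_extremes, standardize
from .simulate import SimulationConfig, simulate_parents, simulate_phenotypes
from .designs import ParentPanel, half_diallel

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("hybridgs")


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`; see the YAML example in the
    package README."""

    outdir: str = "hybridgs_out"
    seed: int = 0
    # either a simulation block ...
    simulate: dict | None = None
    n_traits: int = 3
    # ... or input files
    genotypes: str | None = None          # training-hybrid genotype table/VCF
    phenotypes: str | None = None         # phenotype CSV (hybrid_id + traits)
    parents: str | None = None            # parent genotypes for the test set
    crosses: str | None = None            # cross list to predict
    # stages
    filter: dict = field(default_factory=dict)
    model: str = "additive"
    cv: dict | None = None                # {"k": 10, "replicates": 10}
    index: dict = field(default_factory=dict)   # {"top": int, "bottom": int, "weights": path}
    json_log: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown pipeline config keys: {sorted(bad)}")
        return cls(**raw)

    def __post_init__(self) -> None:
        if self.model not in {"additive", "AD", "GxE"}:
            raise ValueError(f"model must be additive|AD|GxE, got {self.model!r}")
        if self.simulate is None and (self.genotypes is None or self.phenotypes is None):
            raise ValueError("config needs either a 'simulate' block or "
                             "'genotypes' and 'phenotypes' paths")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the stage log.

    Artifacts written under ``config.outdir``: filtered genotypes, cross
    list, kinship, per-trait fit summary, CV report, predictions and the
    breeding-index table.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    log: list[dict] = []

    def stage(name: str, **counts):
        entry = {"stage": name, "time": time.time(), **counts}
        log.append(entry)
        logger.info("stage %s: %s", name, counts)

    try:
        if config.simulate is not None:
            sim = SimulationConfig(seed=config.seed, **config.simulate)
            parents = simulate_parents(sim, rng)
            stage("simulate_parents", n_parents=parents.n_individuals,
                  m_markers=parents.n_markers)
            parents_f, report = filter_markers(parents, MarkerFilterSpec(**config.filter))
            stage("filter", kept=report.n_kept, failed_maf=report.n_failed_maf,
                  failed_missing=report.n_failed_missing)
            if parents_f.has_missing():
                parents_f = impute_mean(parents_f)
                stage("impute")
            panel = ParentPanel(parents_f.individual_ids,
                                {p: "simulated" for p in parents_f.individual_ids})
            pool = half_diallel(panel)
            n_tot = sim.n_train_hybrids + sim.n_test_hybrids
            if n_tot > len(pool):
                raise ValueError(f"diallel of {len(pool)} crosses cannot supply {n_tot} hybrids")
            order = rng.permutation(len(pool))
            train_crosses = [(pool[i].female, pool[i].male) for i in order[: sim.n_train_hybrids]]
            test_crosses = [(pool[i].female, pool[i].male)
                            for i in order[sim.n_train_hybrids: n_tot]]
            hio.write_crosses([pool[i] for i in order[:n_tot]], out / "crosses.csv")
            train = build_hybrid_matrix(parents_f, train_crosses)
            test = build_hybrid_matrix(parents_f, test_crosses)
            stage("hybrids", n_train=train.n_individuals, n_test=test.n_individuals)
            pheno = pd.DataFrame(index=pd.Index(train.individual_ids, name="hybrid_id"))
            for t in range(config.n_traits):
                tbl, _ = simulate_phenotypes(train, sim, rng)
                pheno[f"T{t + 1}"] = tbl.mean(axis=1).to_numpy()
            pheno.to_csv(out / "phenotypes.csv", float_format=hio.FLOAT_FMT)
        else:
            train = hio.read_genotypes(config.genotypes)
            pheno = hio.read_phenotypes(config.phenotypes)
            pheno = pheno.select_dtypes(include=[np.number])
            stage("load", n_hybrids=train.n_individuals, m_markers=train.n_markers,
                  n_traits=pheno.shape[1])
            train, report = filter_markers(train, MarkerFilterSpec(**config.filter))
            stage("filter", kept=report.n_kept, failed_maf=report.n_failed_maf,
                  failed_missing=report.n_failed_missing)
            if train.has_missing():
                train = impute_mean(train)
                stage("impute")
            test = None
            if config.parents and config.crosses:
                parent_G = hio.read_genotypes(config.parents)
                keep = [m for m in parent_G.marker_ids if m in set(train.marker_ids)]
                crosses = [(c.female, c.male) for c in hio.read_crosses(config.crosses)]
                test = build_hybrid_matrix(parent_G, crosses)
                stage("hybrids", n_test=test.n_individuals, shared_markers=len(keep))
            pheno = pheno.loc[train.individual_ids]

        hio.write_genotype_table(train, out / "genotypes_filtered.csv")

        if test is not None:
            combined = GenotypeMatrix(
                np.hstack([train.codes, test.codes]),
                list(train.marker_ids),
                train.individual_ids + test.individual_ids,
                code_domain="continuous" if (train.code_domain == "continuous"
                                             or test.code_domain == "continuous") else "grid",
            )
        else:
            combined = train
        K = compute_kinship(combined)
        hio.write_kinship(K, out / "kinship.csv")
        stage("kinship", n=K.n, m=K.n_markers_used)

        K11 = K.submatrix(train.individual_ids)
        eig = eigendecompose(K11)
        traits = list(pheno.columns)
        rows = []
        fits = {}
        for t in traits:
            data = MixedModelData(y=pheno[t].to_numpy(), K=K11)
            fit = fit_reml(data, eigen=eig)
            fits[t] = (fit, data)
            rows.append({"trait": t, "lambda": fit.lambda_hat,
                         "beta": float(fit.beta_hat[0]), "sigma2": fit.sigma2_hat,
                         "phi2": fit.phi2_hat, "loglik": fit.restricted_loglik,
                         "converged": fit.converged})
        pd.DataFrame(rows).to_csv(out / "fit_summary.csv", index=False,
                                  float_format=hio.FLOAT_FMT)
        stage("fit", n_traits=len(traits))

        if config.cv:
            cv = cross_validate(K11, pheno, k=int(config.cv.get("k", 10)),
                                replicates=int(config.cv.get("replicates", 10)),
                                seed=config.seed)
            cv.ability_per_replicate.to_csv(out / "cv_ability.csv",
                                            float_format=hio.FLOAT_FMT)
            summary = pd.DataFrame({"mean_ability": cv.ability_mean,
                                    "sd": cv.ability_per_replicate.std(axis=0)})
            summary.to_csv(out / "cv_summary.csv", float_format=hio.FLOAT_FMT)
            stage("cv", **{t: round(float(v), 4) for t, v in cv.ability_mean.items()})

        if test is not None:
            K21 = K.block(test.individual_ids, train.individual_ids)
            pred = pd.DataFrame(index=pd.Index(test.individual_ids, name="hybrid_id"))
            for t in traits:
                fit, data = fits[t]
                pr = blup_predict(fit, data, K21, hybrid_ids=test.individual_ids,
                                  trait_name=t, eigen=eig)
                pred[t] = pr.y_hat[:, 0]
            pred.to_csv(out / "predictions.csv", float_format=hio.FLOAT_FMT)
            stage("predict", n_test=len(pred))

            weights_path = config.index.get("weights")
            if weights_path:
                weights = hio.read_weights(weights_path)
            else:
                w = np.full(len(traits), 1.0 / len(traits))
                weights = IndexWeights(traits, w / w.sum())
            z = standardize(pred)
            bi = breeding_index(z, weights)
            n_top = int(config.index.get("top", min(10, len(pred) // 2)))
            n_bottom = int(config.index.get("bottom", n_top))
            top, bottom = select_extremes(bi, n_top, n_bottom)
            ranks = pd.Series(bi.index_scores, index=pred.index).rank(ascending=False,
                                                                      method="first")
            table = pd.DataFrame({
                "hybrid_id": bi.hybrid_ids,
                "index": bi.index_scores,
                "rank": ranks.to_numpy(dtype=int),
                "selected_top": [h in set(top) for h in bi.hybrid_ids],
                "selected_bottom": [h in set(bottom) for h in bi.hybrid_ids],
            })
            table.to_csv(out / "index.csv", index=False, float_format=hio.FLOAT_FMT)
            stage("index", n_top=len(top), n_bottom=len(bottom))
    finally:
        if config.json_log:
            with open(out / "pipeline_log.json", "w", encoding="utf-8") as fh:
                json.dump(log, fh, indent=2)
    return {"stages": log, "outdir": str(out)}
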