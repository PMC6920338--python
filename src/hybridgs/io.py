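"""Readers and writers for the package's tabular formats, plus VCF input.

Tabular genotype dialect: comma- or tab-separated, first column the marker
id, header row of individual ids, cells in {-1, -0.5, 0, 0.5, 1, NA}.
VCF input is read-only: biallelic SNPs only, GT mapped REF/REF -> -1,
heterozygote -> 0, ALT/ALT -> 1, missing -> NA.  All CSV output is UTF-8
with NA for missing and 17 significant digits so round-trips are bit-stable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .designs import Cross, ParentPanel
from .genotypes import GenotypeMatrix, KinshipMatrix
from .selection import IndexWeights

__all__ = [
    "read_genotypes",
    "read_genotype_table",
    "read_vcf",
    "write_genotype_table",
    "read_kinship",
    "write_kinship",
    "read_phenotypes",
    "read_parent_panel",
    "write_parent_panel",
    "read_crosses",
    "write_crosses",
    "read_weights",
]

logger = logging.getLogger("hybridgs")

FLOAT_FMT = "%.17g"


def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_genotype_table(path: str | Path, code_domain: str = "grid") -> GenotypeMatrix:
    """Read the tabular genotype dialect (markers x individuals)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0, na_values=["NA"])
    codes = df.to_numpy(dtype=float)
    return GenotypeMatrix(codes, [str(i) for i in df.index],
                          [str(c) for c in df.columns], code_domain=code_domain)


def write_genotype_table(G: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(G.codes, index=G.marker_ids, columns=G.individual_ids)
    df.index.name = "marker_id"
    df.to_csv(path, na_rep="NA", float_format=FLOAT_FMT)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into numeric codes.

    Multi-allelic and non-SNP records are skipped (counts logged).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    rows, marker_ids, chroms, poss = [], [], [], []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            n_skipped += 1
            continue
        gt = np.asarray(variant.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        codes = np.where(gt == 3, np.nan, gt - 1.0)
        rows.append(codes)
        marker_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
    vcf.close()
    if n_skipped:
        logger.info("skipped %d multi-allelic/non-SNP records", n_skipped)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    return GenotypeMatrix(np.vstack(rows), marker_ids, individuals,
                          chrom=chroms, pos=np.asarray(poss))


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF or the tabular dialect (format inferred from
    the extension unless given)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() in {".vcf", ".gz", ".bcf"} else "table"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "table":
        return read_genotype_table(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_kinship(K: KinshipMatrix, path: str | Path) -> None:
    df = pd.DataFrame(K.values, index=K.individual_ids, columns=K.individual_ids)
    df.index.name = f"n_markers={K.n_markers_used}"
    df.to_csv(path, float_format=FLOAT_FMT)


def read_kinship(path: str | Path) -> KinshipMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    m = 0
    if df.index.name and "=" in str(df.index.name):
        m = int(str(df.index.name).split("=")[1])
    return KinshipMatrix(df.to_numpy(dtype=float), [str(c) for c in df.columns], m)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype CSV: hybrid_id column, optional environment column, one
    column per trait; NA for missing."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), na_values=["NA"])
    if "hybrid_id" not in df.columns:
        raise ValueError(f"{path}: phenotype table needs a 'hybrid_id' column")
    return df.set_index("hybrid_id")


def read_parent_panel(path: str | Path) -> ParentPanel:
    df = pd.read_csv(path)
    required = {"parent_id", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"panel CSV needs columns {sorted(required)}")
    ids = [str(p) for p in df["parent_id"]]
    group = dict(zip(ids, (str(g) for g in df["group"])))
    maint = {}
    if "is_maintainer" in df.columns:
        maint = dict(zip(ids, df["is_maintainer"].astype(bool)))
    return ParentPanel(ids, group, maint)


def write_parent_panel(panel: ParentPanel, path: str | Path) -> None:
    pd.DataFrame({
        "parent_id": panel.parent_ids,
        "group": [panel.group[p] for p in panel.parent_ids],
        "is_maintainer": [panel.is_maintainer[p] for p in panel.parent_ids],
    }).to_csv(path, index=False)


def write_crosses(crosses: list[Cross], path: str | Path) -> None:
    pd.DataFrame(crosses, columns=["hybrid_id", "female", "male"]).to_csv(path, index=False)


def read_crosses(path: str | Path) -> list[Cross]:
    df = pd.read_csv(path)
    if {"female", "male"} <= set(df.columns):
        from .genotypes import hybrid_id as mk
        return [Cross(str(r.get("hybrid_id")) if "hybrid_id" in df.columns else mk(r["female"], r["male"]),
                      str(r["female"]), str(r["male"]))
                for _, r in df.iterrows()]
    raise ValueError(f"{path}: cross list needs 'female' and 'male' columns")


def read_weights(path: str | Path) -> IndexWeights:
    """Index weights from YAML ({trait: weight}) or CSV (trait, weight)."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of trait -> weight")
        names = [str(k) for k in data]
        w = np.array([float(v) for v in data.values()])
    else:
        df = pd.read_csv(path)
        names = [str(t) for t in df["trait"]]
        w = df["weight"].to_numpy(dtype=float)
    return IndexWeights(names, w)
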