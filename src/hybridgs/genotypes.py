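"""Genotype coding, in-silico hybrid deduction, marker QC and kinship matrices.

Inbred parental lines are coded per marker as -1 (one homozygote), 0
(heterozygote, only from residual heterozygosity) and 1 (the other
homozygote).  An F1 hybrid's code is the mean of its parents' codes, so
hybrid panels live on the grid {-1, -0.5, 0, 0.5, 1}.  The kinship matrix
used throughout is the uncentered cross-product K = (1/m) sum_k Z_k Z_k^T
over coded markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "MarkerFilterSpec",
    "KinshipMatrix",
    "FilterReport",
    "InvalidGenotypeError",
    "deduce_hybrid_code",
    "build_hybrid_matrix",
    "filter_markers",
    "impute_mean",
    "compute_kinship",
    "compute_dominance_kinship",
    "hybrid_id",
]

#: Legal genotype codes for hybrids (parents use the subset {-1, 0, 1}).
VALID_CODES = (-1.0, -0.5, 0.0, 0.5, 1.0)
PARENT_CODES = (-1.0, 0.0, 1.0)


class InvalidGenotypeError(ValueError):
    """A genotype code outside the permitted set was encountered."""


def _check_codes(codes: np.ndarray, allowed: tuple[float, ...]) -> None:
    finite = codes[~np.isnan(codes)]
    if finite.size and not np.isin(finite, allowed).all():
        bad = np.unique(finite[~np.isin(finite, allowed)])
        raise InvalidGenotypeError(
            f"genotype codes outside allowed set {allowed}: {bad[:5]}"
        )


@dataclass
class GenotypeMatrix:
    """Numeric genotype codes, markers in rows and individuals in columns.

    Missing genotypes are NaN.  ``chrom``/``pos`` are optional 1-based
    coordinates; nothing downstream requires them.
    """

    codes: np.ndarray
    marker_ids: list[str]
    individual_ids: list[str]
    chrom: list[str] | None = None
    pos: np.ndarray | None = None
    #: "grid" restricts codes to {-1,-0.5,0,0.5,1}; "continuous" allows any
    #: value in [-1, 1] (mean-imputed matrices).
    code_domain: str = "grid"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D (markers x individuals) array")
        m, n = self.codes.shape
        self.marker_ids = [str(x) for x in self.marker_ids]
        self.individual_ids = [str(x) for x in self.individual_ids]
        if len(self.marker_ids) != m:
            raise ValueError(f"{len(self.marker_ids)} marker ids for {m} rows")
        if len(self.individual_ids) != n:
            raise ValueError(f"{len(self.individual_ids)} individual ids for {n} columns")
        if len(set(self.marker_ids)) != m:
            raise ValueError("marker ids are not unique")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids are not unique")
        if self.code_domain == "grid":
            _check_codes(self.codes, VALID_CODES)
        elif self.code_domain == "continuous":
            finite = self.codes[~np.isnan(self.codes)]
            if finite.size and (np.abs(finite) > 1 + 1e-12).any():
                raise InvalidGenotypeError("continuous codes must lie in [-1, 1]")
        else:
            raise ValueError(f"unknown code_domain: {self.code_domain!r}")

    @property
    def n_markers(self) -> int:
        return self.codes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[1]

    def column(self, individual_id: str) -> np.ndarray:
        try:
            j = self.individual_ids.index(individual_id)
        except ValueError:
            raise KeyError(f"unknown individual id: {individual_id!r}") from None
        return self.codes[:, j]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.codes).any())


@dataclass(frozen=True)
class MarkerFilterSpec:
    """QC thresholds: keep markers with MAF strictly above ``maf_min`` and a
    missing fraction at most ``missing_max``."""

    maf_min: float = 0.1
    missing_max: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if not 0 <= self.missing_max <= 1:
            raise ValueError("missing_max must be in [0, 1]")


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_failed_maf: int
    n_failed_missing: int


@dataclass
class KinshipMatrix:
    """Marker-inferred relationship matrix with block access by individual id."""

    values: np.ndarray
    individual_ids: list[str]
    n_markers_used: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match individual ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8 * max(1.0, np.abs(self.values).max())):
            raise ValueError("kinship matrix is not symmetric")
        # enforce exact symmetry so eigh sees a clean input
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def is_psd(self, rtol: float = 1e-8) -> bool:
        ev = np.linalg.eigvalsh(self.values)
        return bool(ev[0] >= -rtol * max(ev[-1], 1e-300))

    def _indices(self, ids: list[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.individual_ids)}
        try:
            return np.array([lookup[g] for g in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"individual id not in kinship matrix: {e.args[0]!r}") from None

    def block(self, row_ids: list[str], col_ids: list[str]) -> np.ndarray:
        """Sub-block K[rows, cols], e.g. K21 = block(test_ids, train_ids)."""
        r = self._indices(row_ids)
        c = self._indices(col_ids)
        return self.values[np.ix_(r, c)]

    def submatrix(self, ids: list[str]) -> "KinshipMatrix":
        idx = self._indices(ids)
        return KinshipMatrix(self.values[np.ix_(idx, idx)], list(ids), self.n_markers_used)


def deduce_hybrid_code(parent1_code: float, parent2_code: float) -> float:
    """Genotype code of an F1 hybrid at one locus: the parental mean.

    A1A1 (-1) x A1A2 (0) gives (-1+0)/2 = -0.5; A2A2 (1) x A1A2 (0) gives
    0.5; either parent missing (NaN) makes the hybrid missing.
    """
    p1, p2 = float(parent1_code), float(parent2_code)
    if np.isnan(p1) or np.isnan(p2):
        return float("nan")
    for c in (p1, p2):
        if c not in PARENT_CODES:
            raise InvalidGenotypeError(f"parental genotype code must be in {PARENT_CODES}, got {c}")
    return (p1 + p2) / 2.0


def hybrid_id(parent1: str, parent2: str) -> str:
    """Deterministic hybrid name: ids sorted and joined with '_x_'."""
    a, b = sorted((str(parent1), str(parent2)))
    return f"{a}_x_{b}"


def build_hybrid_matrix(
    parents: GenotypeMatrix, crosses: list[tuple[str, str]]
) -> GenotypeMatrix:
    """Deduce the genotype matrix of F1 hybrids from their inbred parents.

    One column per cross, computed marker-wise as the parental mean code.
    Duplicate crosses (in either order) are dropped with a warning.
    """
    _check_codes(parents.codes, PARENT_CODES)
    seen: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    for p1, p2 in crosses:
        hid = hybrid_id(p1, p2)
        if hid in seen:
            warnings.warn(f"duplicate cross {p1} x {p2} dropped", stacklevel=2)
            continue
        seen[hid] = (str(p1), str(p2))
        order.append(hid)
    if not order:
        raise ValueError("no crosses supplied")
    lookup = {g: i for i, g in enumerate(parents.individual_ids)}
    cols = np.empty((parents.n_markers, len(order)))
    for j, hid in enumerate(order):
        p1, p2 = seen[hid]
        for p in (p1, p2):
            if p not in lookup:
                raise KeyError(f"unknown parent id in cross list: {p!r}")
        cols[:, j] = (parents.codes[:, lookup[p1]] + parents.codes[:, lookup[p2]]) / 2.0
    return GenotypeMatrix(cols, list(parents.marker_ids), order,
                          chrom=parents.chrom, pos=parents.pos)


def allele_frequency(codes: np.ndarray) -> np.ndarray:
    """Per-marker frequency of the +1 allele, p = (mean code + 1) / 2."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(codes, axis=1)
    return (mean + 1.0) / 2.0


def filter_markers(
    G: GenotypeMatrix, spec: MarkerFilterSpec = MarkerFilterSpec()
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop markers with MAF <= ``maf_min`` (strict keep) or missingness
    above ``missing_max``; returns the filtered matrix and a report."""
    if G.n_markers == 0:
        raise ValueError("empty genotype matrix")
    missing_frac = np.isnan(G.codes).mean(axis=1)
    p = allele_frequency(G.codes)
    p = np.where(np.isnan(p), 0.0, p)  # all-missing marker: MAF 0, also fails missingness
    maf = np.minimum(p, 1.0 - p)
    pass_maf = maf > spec.maf_min
    pass_missing = missing_frac <= spec.missing_max
    keep = pass_maf & pass_missing
    report = FilterReport(
        n_input=G.n_markers,
        n_kept=int(keep.sum()),
        n_failed_maf=int((~pass_maf).sum()),
        n_failed_missing=int((~pass_missing).sum()),
    )
    if report.n_kept == 0:
        raise ValueError("marker filtering removed all markers (empty panel)")
    idx = np.flatnonzero(keep)
    out = GenotypeMatrix(
        G.codes[idx],
        [G.marker_ids[i] for i in idx],
        list(G.individual_ids),
        chrom=[G.chrom[i] for i in idx] if G.chrom is not None else None,
        pos=G.pos[idx] if G.pos is not None else None,
        code_domain=G.code_domain,
    )
    return out, report


def impute_mean(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing genotypes by the marker's mean non-missing code."""
    codes = G.codes.copy()
    nan_mask = np.isnan(codes)
    if not nan_mask.any():
        return GenotypeMatrix(codes, list(G.marker_ids), list(G.individual_ids),
                              chrom=G.chrom, pos=G.pos, code_domain=G.code_domain)
    all_missing = nan_mask.all(axis=1)
    if all_missing.any():
        bad = [G.marker_ids[i] for i in np.flatnonzero(all_missing)[:5]]
        raise ValueError(f"markers entirely missing (should have been filtered): {bad}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        row_mean = np.nanmean(codes, axis=1)
    codes[nan_mask] = np.broadcast_to(row_mean[:, None], codes.shape)[nan_mask]
    return GenotypeMatrix(codes, list(G.marker_ids), list(G.individual_ids),
                          chrom=G.chrom, pos=G.pos, code_domain="continuous")


def _cross_product_kinship(M: np.ndarray, ids: list[str]) -> KinshipMatrix:
    m = M.shape[0]
    if m == 0:
        raise ValueError("no markers: cannot compute kinship")
    if np.isnan(M).any():
        raise ValueError("kinship requires a complete matrix; impute first")
    K = (M.T @ M) / m
    return KinshipMatrix(K, list(ids), m)


def compute_kinship(G: GenotypeMatrix, center: bool = False) -> KinshipMatrix:
    """Additive kinship K = (1/m) sum_k Z_k Z_k^T over raw marker codes.

    No centering or allele-frequency scaling is applied by default, matching
    the cross-product definition used for hybrid prediction.  ``center=True``
    subtracts 2p-1 per marker first (a VanRaden-style variant).
    """
    M = G.codes
    if center:
        p = allele_frequency(M)
        M = M - (2.0 * p - 1.0)[:, None]
    return _cross_product_kinship(M, G.individual_ids)


def dominance_codes(codes: np.ndarray) -> np.ndarray:
    """Heterozygosity coding W = 1 - |Z|: heterozygote 1, homozygote 0,
    half-codes (one residually heterozygous parent) 0.5 = expected
    heterozygosity of the cross."""
    return 1.0 - np.abs(codes)


def compute_dominance_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """Dominance kinship K_D = (1/m) sum_k W_k W_k^T on heterozygosity codes."""
    W = dominance_codes(G.codes)
    return _cross_product_kinship(W, G.individual_ids)
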