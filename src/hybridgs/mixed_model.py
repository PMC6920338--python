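"""GBLUP mixed model: REML estimation and BLUP prediction of hybrids.

Model
-----
The phenotype vector of n training hybrids follows

    y = X beta + xi + eps,    xi ~ N(0, K phi^2),    eps ~ N(0, I sigma^2),

where K = (1/m) sum_k Z_k Z_k^T is the marker-inferred kinship and the
polygenic effect xi marginalizes m marker effects gamma_k ~ N(0, phi^2/m).
With lambda = phi^2 / sigma^2 the covariance is V = (K lambda + I) sigma^2.
After eigendecomposing K = U diag(d) U^T, rotating by U^T makes V diagonal,
so each restricted-likelihood evaluation is O(n q^2) instead of O(n^3).

beta and sigma^2 are profiled out analytically; the restricted log
likelihood is maximized over lambda >= 0 by Newton iteration on ln(lambda)
with analytic first and second derivatives, with a bounded scalar search as
fallback.  Untested hybrids are predicted from the partitioned kinship:

    yhat_2 = X2 beta + lambda K21 (K11 lambda + I)^{-1} (y1 - X1 beta).

All additive constants independent of lambda, including -(n-q)/2 (1 + ln 2pi)
and ((n-q)/2) ln(n-q), are dropped from reported log likelihoods; comparisons
are only ever made within this convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .genotypes import KinshipMatrix

__all__ = [
    "MixedModelData",
    "REMLFit",
    "TwoKernelFit",
    "GxEFit",
    "PredictionResult",
    "EigenK",
    "eigendecompose",
    "restricted_loglik",
    "fit_reml",
    "blup_predict",
    "fit_ad_model",
    "fit_gxe_model",
]

LAMBDA_MIN = 1e-8
LAMBDA_MAX = 1e8


@dataclass
class EigenK:
    """Eigen pair of a kinship matrix: K = U diag(d) U^T, d >= 0."""

    U: np.ndarray
    d: np.ndarray


@dataclass
class MixedModelData:
    """Aligned phenotypes, fixed-effect design and kinship for one trait.

    Rows of ``y`` with missing phenotype are dropped (with a warning),
    together with the matching rows of X and rows/columns of K.
    """

    y: np.ndarray
    K: KinshipMatrix
    X: np.ndarray | None = None
    individual_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.y.size
        if self.individual_ids is None:
            self.individual_ids = list(self.K.individual_ids)
        if len(self.individual_ids) != n:
            raise ValueError("phenotype length does not match individual ids")
        if self.X is None:
            self.X = np.ones((n, 1))
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != n:
            raise ValueError("X row count does not match y")
        keep = ~np.isnan(self.y)
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} individuals with missing phenotype",
                          stacklevel=2)
            self.y = self.y[keep]
            self.X = self.X[keep]
            self.individual_ids = [g for g, k in zip(self.individual_ids, keep) if k]
        self.K = self.K.submatrix(self.individual_ids)
        q = np.linalg.matrix_rank(self.X)
        if q < self.X.shape[1]:
            raise ValueError("fixed-effect design matrix X is rank deficient")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def q(self) -> int:
        return self.X.shape[1]


@dataclass
class REMLFit:
    """REML estimates for the additive model of one trait."""

    lambda_hat: float
    beta_hat: np.ndarray
    sigma2_hat: float
    restricted_loglik: float
    n_iter: int
    converged: bool

    @property
    def phi2_hat(self) -> float:
        return self.lambda_hat * self.sigma2_hat


@dataclass
class TwoKernelFit:
    """REML estimates for a model with two genetic kernels (e.g. A-D)."""

    lambda_a: float
    lambda_d: float
    beta_hat: np.ndarray
    sigma2_hat: float
    restricted_loglik: float
    n_iter: int
    converged: bool


@dataclass
class GxEFit:
    """Genotype-by-environment GBLUP fit over E environments.

    The stacked model has environment-specific fixed means, a genomic main
    effect shared across environments (covariance J_E (x) K phi2_main) and an
    independent genomic deviation per environment (covariance
    I_E (x) K phi2_gxe).
    """

    lambda_main: float
    lambda_gxe: float
    beta_by_env: np.ndarray
    sigma2_hat: float
    restricted_loglik: float
    environments: list[str]
    n_iter: int
    converged: bool


@dataclass
class PredictionResult:
    """BLUP predictions for a set of untested hybrids, one column per trait."""

    hybrid_ids: list[str]
    y_hat: np.ndarray
    trait_names: list[str]

    def __post_init__(self) -> None:
        self.y_hat = np.atleast_2d(np.asarray(self.y_hat, dtype=float))
        if self.y_hat.shape[0] != len(self.hybrid_ids):
            self.y_hat = self.y_hat.T
        if self.y_hat.shape != (len(self.hybrid_ids), len(self.trait_names)):
            raise ValueError("prediction shape does not match ids/traits")
        if not np.isfinite(self.y_hat).all():
            raise ValueError("non-finite predictions")


def eigendecompose(K: KinshipMatrix | np.ndarray, rtol: float = 1e-8) -> EigenK:
    """Eigendecomposition of a symmetric PSD kinship matrix.

    Eigenvalues more negative than ``-rtol * max(d)`` raise; small negative
    values from round-off are clipped to 0.
    """
    A = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    if not np.allclose(A, A.T, atol=1e-8 * max(1.0, np.abs(A).max())):
        raise ValueError("kinship matrix is not symmetric")
    d, U = linalg.eigh(0.5 * (A + A.T))
    top = max(d[-1], 0.0)
    if d[0] < -max(rtol * top, 1e-10):
        raise ValueError(f"kinship matrix is not PSD (min eigenvalue {d[0]:.3e})")
    return EigenK(U=U, d=np.clip(d, 0.0, None))


def _rotated(data: MixedModelData, eigen: EigenK) -> tuple[np.ndarray, np.ndarray]:
    return eigen.U.T @ data.y, eigen.U.T @ data.X


def _profile(lam: float, ys: np.ndarray, Xs: np.ndarray, d: np.ndarray):
    """Profiled quantities at fixed lambda in the rotated basis.

    Returns (loglik, beta, sigma2, C, w, resid) where w = 1/(d lam + 1).
    """
    n, q = Xs.shape
    h = d * lam + 1.0
    if (h <= 0).any():
        raise ValueError("non-positive variance weight (lambda or eigenvalues invalid)")
    w = 1.0 / h
    Xw = Xs * w[:, None]
    C = Xs.T @ Xw
    cty = Xw.T @ ys
    try:
        beta = linalg.solve(C, cty, assume_a="pos")
    except linalg.LinAlgError:
        warnings.warn("ill-conditioned X' V^-1 X; using pseudo-inverse", stacklevel=3)
        beta = np.linalg.pinv(C) @ cty
    r = ys - Xs @ beta
    rss = float(np.sum(r * r * w))
    sigma2 = rss / (n - q)
    sign, logdetC = np.linalg.slogdet(C)
    if sign <= 0:
        raise ValueError("X' V^-1 X is singular")
    if sigma2 <= 0:
        return -np.inf, beta, sigma2, C, w, r
    ll = -0.5 * float(np.sum(np.log(h))) - 0.5 * logdetC - 0.5 * (n - q) * np.log(sigma2)
    return ll, beta, sigma2, C, w, r


def restricted_loglik(
    lam: float, data: MixedModelData, eigen: EigenK | None = None
) -> float:
    """Profiled restricted log likelihood of the variance ratio lambda.

    Equals the dense-matrix expression
    -1/2 ln|V0| - 1/2 ln|X' V0^-1 X| - (n-q)/2 ln sigma2(lambda), with
    V0 = K lambda + I, up to an additive constant (see module docstring).
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if eigen is None:
        eigen = eigendecompose(data.K)
    ys, Xs = _rotated(data, eigen)
    return _profile(lam, ys, Xs, eigen.d)[0]


def _derivatives(lam, ys, Xs, d):
    """Analytic dL/dlambda and d2L/dlambda2 of the profiled restricted
    log likelihood, using the projection-matrix identities in the rotated
    basis (everything is O(n q^2))."""
    n, q = Xs.shape
    h = d * lam + 1.0
    w = 1.0 / h
    Xw = Xs * w[:, None]
    C = Xs.T @ Xw
    Cinv = np.linalg.pinv(C)
    # P y and powers of (P D) applied to y
    cty = Xw.T @ ys
    Py = w * ys - Xw @ (Cinv @ cty)

    def P_apply(v):
        # P = W - W X (X' W X)^-1 X' W  with W = H^-1 (diagonal)
        return w * v - Xw @ (Cinv @ (Xw.T @ v))

    DPy = d * Py
    PDPy = P_apply(DPy)
    yPy = float(ys @ Py)
    yPDPy = float(Py @ DPy)
    yPDPDPy = float(DPy @ PDPy)
    # traces
    G = Xs.T @ (Xs * (d * w**2)[:, None])          # X*' H^-1 D H^-1 X*
    F = Xs.T @ (Xs * (d**2 * w**3)[:, None])       # X*' W D W D W X*  (W=H^-1)
    trPD = float(np.sum(d * w)) - float(np.trace(Cinv @ G))
    CG = Cinv @ G
    trPDPD = (float(np.sum(d**2 * w**2))
              - 2.0 * float(np.trace(Cinv @ F))
              + float(np.trace(CG @ CG)))
    nq = n - q
    dL = -0.5 * trPD + 0.5 * nq * yPDPy / yPy
    d2L = 0.5 * trPDPD + 0.5 * nq * (-2.0 * yPDPDPy * yPy + yPDPy**2) / yPy**2
    return dL, d2L


def fit_reml(
    data: MixedModelData,
    eigen: EigenK | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> REMLFit:
    """Maximize the restricted likelihood over lambda >= 0.

    Newton iteration on theta = ln(lambda) (positivity by construction),
    started from the best point of a coarse log-spaced grid; if Newton fails
    to converge, a bounded golden-section/Brent search over theta is used.
    """
    if eigen is None:
        eigen = eigendecompose(data.K)
    if data.n <= data.q:
        raise ValueError("need more observations than fixed effects")
    ys, Xs = _rotated(data, eigen)
    d = eigen.d

    def ll(lam: float) -> float:
        return _profile(lam, ys, Xs, d)[0]

    ll0 = ll(0.0)
    if not np.isfinite(ll0):
        raise ValueError("restricted likelihood is not finite at lambda = 0; "
                         "check for constant phenotypes or degenerate X")

    # coarse bracket on a log grid, then Newton from the best point
    grid = np.geomspace(LAMBDA_MIN, LAMBDA_MAX, 17)
    grid_ll = np.array([ll(g) for g in grid])
    best = int(np.argmax(grid_ll))
    converged = False
    n_iter = 0
    if grid_ll[best] <= ll0 + 1e-12 and best == 0:
        # likelihood decreases in lambda everywhere sampled: boundary optimum
        lam_hat = 0.0
        converged = True
    else:
        theta = float(np.log(grid[best]))
        lo, hi = np.log(LAMBDA_MIN), np.log(LAMBDA_MAX)
        for n_iter in range(1, max_iter + 1):
            lam = float(np.exp(theta))
            g1, g2 = _derivatives(lam, ys, Xs, d)
            gt = lam * g1                      # dL/dtheta
            ht = lam * g1 + lam * lam * g2     # d2L/dtheta2
            if not np.isfinite(gt) or not np.isfinite(ht) or ht >= 0:
                break
            step = -gt / ht
            step = float(np.clip(step, -5.0, 5.0))
            theta = float(np.clip(theta + step, lo, hi))
            if abs(step) < tol:
                converged = True
                break
        lam_hat = float(np.exp(theta))
        if not converged:
            res = optimize.minimize_scalar(
                lambda t: -ll(float(np.exp(t))),
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-10},
            )
            lam_hat = float(np.exp(res.x))
            n_iter += int(res.nfev)
            converged = bool(res.success)
        # boundary comparison: lambda = 0 may still dominate
        if ll0 >= ll(lam_hat):
            lam_hat = 0.0
            converged = True

    llhat, beta, sigma2, *_ = _profile(lam_hat, ys, Xs, d)
    if sigma2 <= 0 or not np.isfinite(sigma2):
        warnings.warn("degenerate residual variance (sigma2 <= 0); data may be constant",
                      stacklevel=2)
    return REMLFit(lambda_hat=lam_hat, beta_hat=beta, sigma2_hat=sigma2,
                   restricted_loglik=llhat, n_iter=n_iter, converged=converged)


def blup_predict(
    fit: REMLFit,
    train: MixedModelData,
    K21: np.ndarray,
    X2: np.ndarray | None = None,
    hybrid_ids: list[str] | None = None,
    trait_name: str = "trait",
    eigen: EigenK | None = None,
) -> PredictionResult:
    """BLUP of untested hybrids from the partitioned kinship:

    yhat2 = X2 beta + lambda K21 (K11 lambda + I)^{-1} (y1 - X1 beta),

    with the inverse evaluated through the training eigendecomposition as
    U diag(1/(d lambda + 1)) U^T.
    """
    K21 = np.atleast_2d(np.asarray(K21, dtype=float))
    n2 = K21.shape[0]
    if K21.shape[1] != train.n:
        raise ValueError(f"K21 has {K21.shape[1]} training columns, expected {train.n}")
    if X2 is None:
        X2 = np.ones((n2, train.q))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X2.shape != (n2, train.q):
        raise ValueError("X2 shape does not match K21 rows / training design")
    if eigen is None:
        eigen = eigendecompose(train.K)
    lam = fit.lambda_hat
    resid = train.y - train.X @ fit.beta_hat
    w = 1.0 / (eigen.d * lam + 1.0)
    vinv_resid = eigen.U @ (w * (eigen.U.T @ resid))
    yhat = X2 @ fit.beta_hat + lam * (K21 @ vinv_resid)
    if hybrid_ids is None:
        hybrid_ids = [f"test_{i}" for i in range(n2)]
    return PredictionResult(hybrid_ids=list(hybrid_ids), y_hat=yhat[:, None],
                            trait_names=[trait_name])


# ---------------------------------------------------------------------------
# Two-kernel REML (shared by the A-D and GxE models)
# ---------------------------------------------------------------------------

def _dense_profile(lam1, lam2, y, X, K1, K2):
    """Profiled restricted log likelihood for V0 = K1 lam1 + K2 lam2 + I."""
    n, q = X.shape
    V0 = lam1 * K1 + lam2 * K2 + np.eye(n)
    cho = linalg.cho_factor(V0, lower=True)
    logdetV0 = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    Vinv_X = linalg.cho_solve(cho, X)
    Vinv_y = linalg.cho_solve(cho, y)
    C = X.T @ Vinv_X
    try:
        beta = linalg.solve(C, X.T @ Vinv_y, assume_a="pos")
    except linalg.LinAlgError:
        beta = np.linalg.pinv(C) @ (X.T @ Vinv_y)
    r = y - X @ beta
    sigma2 = float(r @ linalg.cho_solve(cho, r)) / (n - q)
    sign, logdetC = np.linalg.slogdet(C)
    ll = -0.5 * logdetV0 - 0.5 * logdetC - 0.5 * (n - q) * np.log(sigma2)
    return ll, beta, sigma2, cho


def _fit_two_kernel(y, X, K1, K2, start=None, max_iter=400):
    """Maximize the two-ratio restricted likelihood over (ln lam1, ln lam2)."""
    lo, hi = np.log(LAMBDA_MIN), np.log(LAMBDA_MAX)

    def negll(theta):
        t = np.clip(theta, lo, hi)
        return -_dense_profile(float(np.exp(t[0])), float(np.exp(t[1])), y, X, K1, K2)[0]

    if start is None:
        start = (1.0, 0.1)
    x0 = np.log(np.clip(start, LAMBDA_MIN, LAMBDA_MAX))
    res = optimize.minimize(
        negll, x0, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": max_iter, "maxfev": 2 * max_iter},
    )
    theta = np.clip(res.x, lo, hi)
    lam1, lam2 = float(np.exp(theta[0])), float(np.exp(theta[1]))
    # allow exact boundary at zero for either ratio
    candidates = [(lam1, lam2), (0.0, lam2), (lam1, 0.0), (0.0, 0.0)]
    lls = [_dense_profile(a, b, y, X, K1, K2)[0] for a, b in candidates]
    best = int(np.argmax(lls))
    lam1, lam2 = candidates[best]
    ll, beta, sigma2, _ = _dense_profile(lam1, lam2, y, X, K1, K2)
    return lam1, lam2, beta, sigma2, ll, int(res.nit), bool(res.success)


def fit_ad_model(data: MixedModelData, K_D: KinshipMatrix) -> TwoKernelFit:
    """Additive + dominance REML: V = (K lam_A + K_D lam_D + I) sigma^2.

    Warm-started at the additive-only optimum (the nested one-kernel model),
    so an all-zero dominance kernel reproduces the additive fit exactly.
    """
    KD = K_D.values if isinstance(K_D, KinshipMatrix) else np.asarray(K_D, dtype=float)
    if KD.shape != (data.n, data.n):
        raise ValueError("dominance kinship dimension does not match data")
    add = fit_reml(data)
    if not KD.any():
        return TwoKernelFit(lambda_a=add.lambda_hat, lambda_d=0.0,
                            beta_hat=add.beta_hat, sigma2_hat=add.sigma2_hat,
                            restricted_loglik=add.restricted_loglik,
                            n_iter=add.n_iter, converged=add.converged)
    start = (max(add.lambda_hat, LAMBDA_MIN), max(0.1 * add.lambda_hat, LAMBDA_MIN))
    lam_a, lam_d, beta, sigma2, ll, nit, ok = _fit_two_kernel(
        data.y, data.X, data.K.values, KD, start=start)
    # the two-kernel model nests the additive model; never report a worse optimum
    if ll < add.restricted_loglik:
        lam_a, lam_d = add.lambda_hat, 0.0
        beta, sigma2, ll = add.beta_hat, add.sigma2_hat, add.restricted_loglik
    return TwoKernelFit(lambda_a=lam_a, lambda_d=lam_d, beta_hat=beta,
                        sigma2_hat=sigma2, restricted_loglik=ll,
                        n_iter=nit, converged=ok)


def predict_ad(
    fit: TwoKernelFit,
    data: MixedModelData,
    K_D: KinshipMatrix,
    K21_A: np.ndarray,
    K21_D: np.ndarray,
    X2: np.ndarray | None = None,
    hybrid_ids: list[str] | None = None,
    trait_name: str = "trait",
) -> PredictionResult:
    """BLUP under the A-D model:
    yhat2 = X2 beta + (lamA K21 + lamD K21_D)(K11 lamA + KD11 lamD + I)^-1 (y1 - X1 beta)."""
    KD = K_D.values if isinstance(K_D, KinshipMatrix) else np.asarray(K_D, dtype=float)
    n = data.n
    V0 = fit.lambda_a * data.K.values + fit.lambda_d * KD + np.eye(n)
    resid = data.y - data.X @ fit.beta_hat
    vinv_resid = linalg.solve(V0, resid, assume_a="pos")
    K21_A = np.atleast_2d(np.asarray(K21_A, dtype=float))
    K21_D = np.atleast_2d(np.asarray(K21_D, dtype=float))
    n2 = K21_A.shape[0]
    if X2 is None:
        X2 = np.ones((n2, data.q))
    yhat = X2 @ fit.beta_hat + (fit.lambda_a * K21_A + fit.lambda_d * K21_D) @ vinv_resid
    if hybrid_ids is None:
        hybrid_ids = [f"test_{i}" for i in range(n2)]
    return PredictionResult(list(hybrid_ids), yhat[:, None], [trait_name])


def fit_gxe_model(
    y_by_env: np.ndarray,
    K: KinshipMatrix,
    environments: list[str] | None = None,
) -> GxEFit:
    """REML for the multi-environment GBLUP with a shared genomic main effect
    and independent genomic-by-environment deviations (linear kernel).

    ``y_by_env`` is n x E with the same hybrids (rows, in kinship order)
    across environments.  With a single environment only the sum of the two
    variance ratios is identified, so the model collapses to the additive
    fit with lambda_gxe = 0.
    """
    Y = np.atleast_2d(np.asarray(y_by_env, dtype=float))
    if Y.ndim != 2:
        raise ValueError("y_by_env must be n x E")
    n, E = Y.shape
    if n != K.n:
        raise ValueError("phenotype rows do not match kinship dimension")
    if np.isnan(Y).any():
        raise ValueError("missing phenotypes: the GxE model needs the same "
                         "hybrids observed in every environment")
    if environments is None:
        environments = [f"env{e + 1}" for e in range(E)]
    if E == 1:
        add = fit_reml(MixedModelData(y=Y[:, 0], K=K))
        return GxEFit(lambda_main=add.lambda_hat, lambda_gxe=0.0,
                      beta_by_env=add.beta_hat, sigma2_hat=add.sigma2_hat,
                      restricted_loglik=add.restricted_loglik,
                      environments=list(environments),
                      n_iter=add.n_iter, converged=add.converged)
    # stacked model over nE observations, environment-major
    y = Y.T.ravel()
    X = np.kron(np.eye(E), np.ones((n, 1)))          # environment-specific means
    K_main = np.kron(np.ones((E, E)), K.values)      # J_E (x) K
    K_gxe = np.kron(np.eye(E), K.values)             # I_E (x) K
    # warm start from the additive fit on environment means
    add = fit_reml(MixedModelData(y=Y.mean(axis=1), K=K))
    start = (max(add.lambda_hat / E, LAMBDA_MIN), max(0.1 * add.lambda_hat, LAMBDA_MIN))
    lam_m, lam_g, beta, sigma2, ll, nit, ok = _fit_two_kernel(
        y, X, K_main, K_gxe, start=start)
    return GxEFit(lambda_main=lam_m, lambda_gxe=lam_g, beta_by_env=beta,
                  sigma2_hat=sigma2, restricted_loglik=ll,
                  environments=list(environments), n_iter=nit, converged=ok)


def predict_gxe(
    fit: GxEFit,
    y_by_env: np.ndarray,
    K: KinshipMatrix,
    K21: np.ndarray,
    hybrid_ids: list[str] | None = None,
) -> PredictionResult:
    """Per-environment BLUP of test hybrids under the GxE model.

    cov(y2_{i,e}, y1_{j,f}) = (lam_main + lam_gxe delta_ef) K21_ij sigma^2.
    Returns one column per environment.
    """
    Y = np.atleast_2d(np.asarray(y_by_env, dtype=float))
    n, E = Y.shape
    if E != len(fit.environments):
        raise ValueError("environment count does not match fit")
    K21 = np.atleast_2d(np.asarray(K21, dtype=float))
    n2 = K21.shape[0]
    y = Y.T.ravel()
    X = np.kron(np.eye(E), np.ones((n, 1)))
    V0 = (fit.lambda_main * np.kron(np.ones((E, E)), K.values)
          + fit.lambda_gxe * np.kron(np.eye(E), K.values)
          + np.eye(n * E))
    resid = y - X @ fit.beta_by_env
    vr = linalg.solve(V0, resid, assume_a="pos")
    vr_by_env = vr.reshape(E, n)
    yhat = np.empty((n2, E))
    main_part = fit.lambda_main * (K21 @ vr_by_env.sum(axis=0))
    for e in range(E):
        yhat[:, e] = (fit.beta_by_env[e] + main_part
                      + fit.lambda_gxe * (K21 @ vr_by_env[e]))
    if hybrid_ids is None:
        hybrid_ids = [f"test_{i}" for i in range(n2)]
    return PredictionResult(list(hybrid_ids), yhat, list(fit.environments))
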