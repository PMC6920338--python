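"""Shared fixtures and independent oracle implementations.

The dense-matrix oracles here deliberately avoid the package's eigen-rotated
code path: they build V0 = K lambda + I explicitly and use generic inverses,
so agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from hybridgs import GenotypeMatrix, compute_kinship

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_genotypes(rng, m=20, n=10, codes=(-1.0, 1.0), ids_prefix="h"):
    """Random complete genotype matrix on the given code set."""
    M = rng.choice(codes, size=(m, n))
    return GenotypeMatrix(M, [f"m{k}" for k in range(m)],
                          [f"{ids_prefix}{i}" for i in range(n)])


def random_kinship(rng, n, m=None):
    """PSD kinship from a random marker panel (the generic construction)."""
    m = m or 3 * n
    G = random_genotypes(rng, m=m, n=n)
    return compute_kinship(G)


def dense_restricted_loglik(lam, y, X, K):
    """Profiled restricted log likelihood evaluated with dense matrices:
    -1/2 ln|V0| - 1/2 ln|X' V0^-1 X| - (n-q)/2 ln sigma2(lam),
    V0 = K lam + I, sigma2 = (y-Xb)' V0^-1 (y-Xb) / (n-q)."""
    n, q = X.shape
    V0 = lam * K + np.eye(n)
    Vinv = np.linalg.inv(V0)
    C = X.T @ Vinv @ X
    beta = np.linalg.solve(C, X.T @ Vinv @ y)
    r = y - X @ beta
    sigma2 = float(r @ Vinv @ r) / (n - q)
    return (-0.5 * np.linalg.slogdet(V0)[1]
            - 0.5 * np.linalg.slogdet(C)[1]
            - 0.5 * (n - q) * np.log(sigma2))


def dense_blup(lam, y1, X1, beta, K11, K21, X2):
    """Partitioned-kinship BLUP by a direct dense solve."""
    n1 = y1.size
    return X2 @ beta + lam * K21 @ np.linalg.solve(lam * K11 + np.eye(n1), y1 - X1 @ beta)


def golden_section_argmax(f, lo, hi, tol=1e-10, coarse=200):
    """Grid + golden-section maximizer on [lo, hi]; independent of any
    Newton machinery."""
    xs = np.linspace(lo, hi, coarse)
    vals = [f(x) for x in xs]
    i = int(np.argmax(vals))
    a = xs[max(i - 1, 0)]
    b = xs[min(i + 1, coarse - 1)]
    invphi = (np.sqrt(5) - 1) / 2
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2
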