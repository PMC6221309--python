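"""Densities for the Student-t mixed model: likelihood and priors.

Scale matrices are decomposed as Σ = D Ω D with D diagonal (per-parameter
scales) and Ω a correlation matrix.  Priors follow the model specification:
independent N(0, 5²) on fixed effects, half-Cauchy(2.5) on the elements of
D, LKJ(1.5) on Ω, and a Gamma(shape 2, rate 0.1) prior truncated on the left
at 2 for the Student-t degrees of freedom.

Correlation matrices are parameterised for sampling by canonical partial
correlations (C-vine): under LKJ(η) in dimension d, the partial correlation
at tree level k is Beta-distributed on (−1, 1) with shape η + (d − 1 − k)/2
(both parameters equal), independently across edges.  This gives an exact
unconstrained parametrisation through atanh.
"""

from __future__ import annotations

import numpy as np
from scipy import special

HALF_CAUCHY_SCALE = 2.5
LKJ_ETA = 1.5
NU_SHAPE = 2.0
NU_RATE = 0.1
NU_LOWER = 2.0
B_PRIOR_SD = 5.0

#: C-vine edge order for d = 4: (i, j) pairs with tree level = i + 1
VINE_EDGES_4 = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


# ---------------------------------------------------------------------------
# Multivariate Student-t log-density
# ---------------------------------------------------------------------------

def mvt_logpdf(resid: np.ndarray, scale: np.ndarray, df: float) -> np.ndarray:
    """Log-density of multivariate Student-t rows with scale matrix Σ.

    ``resid`` is (n, p) or (p,); returns per-row log-densities.  ``scale`` is
    the p x p positive-definite scale matrix (not the covariance; the
    covariance is Σ·ν/(ν−2) for ν > 2).
    """
    r = np.atleast_2d(np.asarray(resid, dtype=float))
    p = r.shape[1]
    if df <= 0:
        raise ValueError("df must be positive")
    L = np.linalg.cholesky(scale)
    sol = np.linalg.solve(L, r.T)  # (p, n)
    q = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    out = (
        special.gammaln((df + p) / 2.0)
        - special.gammaln(df / 2.0)
        - 0.5 * p * np.log(df * np.pi)
        - 0.5 * logdet
        - 0.5 * (df + p) * np.log1p(q / df)
    )
    return out if np.asarray(resid).ndim > 1 else float(out[0])


# ---------------------------------------------------------------------------
# Correlation matrices via canonical partial correlations
# ---------------------------------------------------------------------------

def corr_from_partials(partials: np.ndarray, d: int = 4) -> np.ndarray:
    """Correlation matrix from C-vine canonical partial correlations.

    ``partials`` holds p_{ij} in the order of :data:`VINE_EDGES_4` (for
    d = 4); the recursion of the vine construction converts them to plain
    correlations.  Any vector in (−1, 1)^m yields a positive-definite Ω.
    """
    P = np.zeros((d, d))
    edges = VINE_EDGES_4 if d == 4 else [(i, j) for i in range(d) for j in range(i + 1, d)]
    for val, (i, j) in zip(partials, edges):
        P[i, j] = val
    R = np.eye(d)
    for i in range(d - 1):
        for j in range(i + 1, d):
            rho = P[i, j]
            for k in range(i - 1, -1, -1):
                rho = (
                    rho * np.sqrt((1.0 - P[k, i] ** 2) * (1.0 - P[k, j] ** 2))
                    + P[k, i] * P[k, j]
                )
            R[i, j] = R[j, i] = rho
    return R


def vine_beta_shapes(d: int = 4, eta: float = LKJ_ETA) -> np.ndarray:
    """Beta shape for each C-vine edge under LKJ(eta): η + (d − 1 − k)/2."""
    edges = VINE_EDGES_4 if d == 4 else [(i, j) for i in range(d) for j in range(i + 1, d)]
    return np.array([eta + (d - 1.0 - (i + 1)) / 2.0 for (i, j) in edges])


def partials_logprior(partials: np.ndarray, d: int = 4, eta: float = LKJ_ETA) -> float:
    """Log-density (up to a constant) of vine partials implied by LKJ(eta)."""
    b = vine_beta_shapes(d, eta)
    p2 = np.asarray(partials) ** 2
    if np.any(p2 >= 1.0):
        return -np.inf
    return float(np.sum((b - 1.0) * np.log1p(-p2)))


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

def half_cauchy_logpdf(x: np.ndarray, scale: float = HALF_CAUCHY_SCALE) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.where(
        x > 0,
        np.log(2.0 / (np.pi * scale)) - np.log1p((x / scale) ** 2),
        -np.inf,
    )
    return out


def lkj_logpdf(omega: np.ndarray, eta: float = LKJ_ETA) -> float:
    """LKJ log-density of a correlation matrix, up to its normalising constant.

    log p(Ω) = (η − 1)·log det Ω + const; for η > 1 the identity matrix is
    the unique mode.
    """
    omega = np.asarray(omega, dtype=float)
    if not np.allclose(np.diag(omega), 1.0):
        return -np.inf
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return -np.inf
    return float((eta - 1.0) * logdet)


def nu_logprior(nu: float, shape: float = NU_SHAPE, rate: float = NU_RATE,
                lower: float = NU_LOWER) -> float:
    """Truncated Gamma prior for the Student-t degrees of freedom."""
    if nu <= lower:
        return -np.inf
    return float((shape - 1.0) * np.log(nu) - rate * nu)


def gaussian_logpdf(x: np.ndarray, sd: float = B_PRIOR_SD) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return -0.5 * np.log(2.0 * np.pi * sd**2) - 0.5 * (x / sd) ** 2


def log_prior(
    B: np.ndarray,
    d_spec: np.ndarray,
    omega_spec: np.ndarray,
    d_lot: np.ndarray,
    omega_lot: np.ndarray,
    d_err: np.ndarray,
    omega_err: np.ndarray,
    nu: float,
) -> float:
    """Joint log prior density of the model parameters (up to constants).

    Sums the stated prior terms; out-of-support values give −inf.  Random
    intercepts U are not included here — their Gaussian density given
    (D, Ω) belongs to the hierarchical likelihood.
    """
    total = float(np.sum(gaussian_logpdf(B)))
    for dvec in (d_spec, d_lot, d_err):
        hc = half_cauchy_logpdf(np.asarray(dvec))
        if np.any(~np.isfinite(hc)):
            return -np.inf
        total += float(np.sum(hc))
    for om in (omega_spec, omega_lot, omega_err):
        lk = lkj_logpdf(om)
        if not np.isfinite(lk):
            return -np.inf
        total += lk
    nv = nu_logprior(nu)
    if not np.isfinite(nv):
        return -np.inf
    return total + nv
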