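"""MCMC for the multivariate Student-t mixed model.

The sampler exploits the scale-mixture representation of the Student-t: each
observation row carries a latent precision weight w_i ~ Gamma(ν/2, ν/2), and
conditional on the weights the model is a Gaussian linear mixed model.  The
resulting scheme is a blocked Gibbs sampler:

* w_i — conjugate Gamma update;
* vec(B) — conjugate Gaussian update (4k-dimensional solve);
* specimen and lot intercept rows of U — conjugate 4-dimensional Gaussians;
* an extra exact "ridge" move trading a constant shift between the intercept
  row of B and all rows of a random-effect block (the likelihood is flat
  along this direction; the move is Metropolis with the prior ratio, and
  dramatically improves mixing of the intercept);
* the three D/Ω scale-correlation blocks — adaptive random-walk Metropolis on
  (log D, atanh partial correlations), using the exact C-vine form of the
  LKJ prior;
* ν — adaptive random-walk Metropolis on log(ν − 2).

All conditionals leave the exact posterior invariant, so the chain is
asymptotically exact.  Draws, diagnostics (split-R̂, Metropolis acceptance
rates) and convergence flags are collected in :class:`PosteriorDraws`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .distributions import (
    B_PRIOR_SD,
    corr_from_partials,
    half_cauchy_logpdf,
    nu_logprior,
    partials_logprior,
)

P_DIM = 4  # number of texture parameters
N_SCALE_SWEEPS = 2  # centered componentwise Metropolis sweeps per scale block


@dataclass(frozen=True)
class SamplerConfig:
    """Chains, iteration counts and seed of the Gibbs sampler."""

    chains: int = 2
    warmup: int = 500
    draws: int = 500
    seed: int = 0
    rhat_threshold: float = 1.05


@dataclass
class PosteriorDraws:
    """Stacked posterior draws (S = chains x draws) and diagnostics."""

    B: np.ndarray  # (S, k, 4)
    U: np.ndarray  # (S, q, 4) specimens first, then lots
    d_spec: np.ndarray  # (S, 4)
    omega_spec: np.ndarray  # (S, 4, 4)
    d_lot: np.ndarray
    omega_lot: np.ndarray
    d_err: np.ndarray
    omega_err: np.ndarray
    nu: np.ndarray  # (S,)
    n_specimens: int
    n_lots: int
    chains: int
    x_names: list[str] = field(default_factory=list)
    rhat: dict[str, np.ndarray] = field(default_factory=dict)
    accept_rates: dict[str, float] = field(default_factory=dict)
    divergences: int = 0
    converged: bool = True

    @property
    def n_draws(self) -> int:
        return self.B.shape[0]

    def error_scale_matrix(self, s: int) -> np.ndarray:
        d = self.d_err[s]
        return d[:, None] * self.omega_err[s] * d[None, :]

    def rhat_max(self) -> float:
        return float(max(np.nanmax(v) for v in self.rhat.values()))


# ---------------------------------------------------------------------------
# split-R-hat
# ---------------------------------------------------------------------------

def split_rhat(x: np.ndarray) -> np.ndarray:
    """Split-R̂ over the leading (chain, draw) axes of ``x``.

    ``x`` has shape (chains, draws, ...); each chain is split in half, and
    the classic between/within variance ratio is returned per remaining
    index.  Constant quantities give R̂ = 1.
    """
    c, n = x.shape[0], x.shape[1]
    half = n // 2
    parts = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m = parts.shape[0]
    mean_c = parts.mean(axis=1)
    var_c = parts.var(axis=1, ddof=1)
    W = var_c.mean(axis=0)
    Bvar = half * mean_c.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vhat = (half - 1) / half * W + Bvar / half
        r = np.sqrt(vhat / W)
    return np.where(W > 0, r, 1.0)


# ---------------------------------------------------------------------------
# Gibbs machinery
# ---------------------------------------------------------------------------

def _scale_matrix(log_d: np.ndarray, t_partials: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Σ, D diag, Ω) from unconstrained (log scales, atanh partials)."""
    d = np.exp(log_d)
    omega = corr_from_partials(np.tanh(t_partials), P_DIM)
    sigma = d[:, None] * omega * d[None, :]
    return sigma, d, omega


def _block_logdensity_gaussian(theta: np.ndarray, scatter: np.ndarray, m_eff: float) -> float:
    """Gaussian log-likelihood of zero-mean rows with Σ(θ) plus its priors.

    ``scatter`` = Σ rows rᵀr (weighted for the error block); ``m_eff`` = the
    number of rows (sum of weights enters through the scatter only).  The
    prior is half-Cauchy on scales (with log-Jacobian of log d) and the
    C-vine form of LKJ(1.5) on the correlation (with tanh Jacobian).
    """
    log_d, t = theta[:P_DIM], theta[P_DIM:]
    sigma, d, _ = _scale_matrix(log_d, t)
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    inv_scatter = np.linalg.solve(sigma, scatter)
    ll = -0.5 * m_eff * logdet - 0.5 * np.trace(inv_scatter)
    p = np.tanh(t)
    prior = (
        float(np.sum(half_cauchy_logpdf(d))) + float(np.sum(log_d))  # Jacobian
        + partials_logprior(p)
        + float(np.sum(np.log1p(-(p**2))))  # d p / d t
    )
    return ll + prior


class _AdaptiveRW:
    """Random-walk Metropolis step-size state with warmup adaptation.

    ``dim`` > 1 keeps one step size per coordinate (componentwise updates
    target ~0.44 acceptance; joint updates ~0.3).
    """

    def __init__(self, dim: int, step: float = 0.1, target: float = 0.44):
        self.step = np.full(dim, step)
        self.dim = dim
        self.target = target
        self.accepted = np.zeros(dim)
        self.proposed = np.zeros(dim)

    def record(self, j: int, accepted: bool) -> None:
        self.proposed[j] += 1
        self.accepted[j] += int(accepted)

    def adapt(self) -> None:
        live = self.proposed > 0
        rate = np.divide(self.accepted, np.maximum(self.proposed, 1))
        self.step[live] *= np.exp(1.2 * (rate[live] - self.target))
        self.step = np.clip(self.step, 1e-4, 3.0)
        self.accepted[:] = 0
        self.proposed[:] = 0

    @property
    def rate(self) -> float:
        return float(np.sum(self.accepted) / max(np.sum(self.proposed), 1))


def _run_chain(
    Y: np.ndarray,
    X: np.ndarray,
    spec_idx: np.ndarray,
    lot_idx: np.ndarray,
    n_spec: int,
    n_lot: int,
    warmup: int,
    draws: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    n, k = X.shape
    p = P_DIM

    # --- initial state ----------------------------------------------------
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid0 = Y - X @ B
    s0 = np.maximum(resid0.std(axis=0), 1e-3)
    state = {
        "B": B,
        "U_spec": np.zeros((n_spec, p)),
        "U_lot": np.zeros((n_lot, p)),
        "th_spec": np.concatenate([np.log(np.full(p, 0.3)), np.zeros(6)]),
        "th_lot": np.concatenate([np.log(np.full(p, 0.2)), np.zeros(6)]),
        "th_err": np.concatenate([np.log(s0), np.zeros(6)]),
        "nu": 10.0,
        "w": np.ones(n),
    }
    rw = {
        "spec": _AdaptiveRW(2 * p + 2, 0.3),
        "lot": _AdaptiveRW(2 * p + 2, 0.5),
        "err": _AdaptiveRW(2 * p + 2, 0.1),
        "nc_spec": _AdaptiveRW(2 * p + 2, 0.2),
        "nc_lot": _AdaptiveRW(2 * p + 2, 0.4),
        "nu": _AdaptiveRW(1, 0.3),
    }
    prior_prec_b = 1.0 / B_PRIOR_SD**2

    keep = {
        name: np.empty((draws,) + shape)
        for name, shape in [
            ("B", (k, p)), ("U", (n_spec + n_lot, p)),
            ("d_spec", (p,)), ("omega_spec", (p, p)),
            ("d_lot", (p,)), ("omega_lot", (p, p)),
            ("d_err", (p,)), ("omega_err", (p, p)),
            ("nu", ()),
        ]
    }
    total_rates = {}

    spec_counts = np.bincount(spec_idx, minlength=n_spec).astype(float)
    lot_counts = np.bincount(lot_idx, minlength=n_lot).astype(float)

    for it in range(warmup + draws):
        sigma_err, d_err, omega_err = _scale_matrix(state["th_err"][:p], state["th_err"][p:])
        P_err = np.linalg.inv(sigma_err)
        sigma_spec, d_spec, omega_spec = _scale_matrix(state["th_spec"][:p], state["th_spec"][p:])
        sigma_lot, d_lot, omega_lot = _scale_matrix(state["th_lot"][:p], state["th_lot"][p:])

        # --- latent Student-t weights ------------------------------------
        resid = Y - X @ state["B"] - state["U_spec"][spec_idx] - state["U_lot"][lot_idx]
        q = np.einsum("ij,jk,ik->i", resid, P_err, resid)
        nu = state["nu"]
        state["w"] = rng.gamma((nu + p) / 2.0, 2.0 / (nu + q))
        w = state["w"]

        # --- fixed effects B ----------------------------------------------
        Yb = Y - state["U_spec"][spec_idx] - state["U_lot"][lot_idx]
        Xw = X * w[:, None]
        S_w = X.T @ Xw  # (k, k)
        A = np.kron(P_err, S_w)
        A[np.diag_indices_from(A)] += prior_prec_b
        M = X.T @ (Yb * w[:, None])  # (k, p)
        rhs = (M @ P_err).ravel(order="F")
        La = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, rhs)
        zdraw = np.linalg.solve(La.T, rng.standard_normal(k * p))
        state["B"] = (mean + zdraw).reshape(k, p, order="F")

        # --- specimen intercepts ------------------------------------------
        fixed = X @ state["B"]
        P_spec = np.linalg.inv(sigma_spec)
        r = Y - fixed - state["U_lot"][lot_idx]
        wsum = np.zeros((n_spec, p))
        np.add.at(wsum, spec_idx, r * w[:, None])
        wtot = np.bincount(spec_idx, weights=w, minlength=n_spec)
        prec = P_spec[None, :, :] + wtot[:, None, None] * P_err[None, :, :]
        mean_s = np.linalg.solve(prec, (wsum @ P_err.T)[..., None])[..., 0]
        Lp = np.linalg.cholesky(prec)
        eps = rng.standard_normal((n_spec, p))
        state["U_spec"] = mean_s + np.linalg.solve(
            np.transpose(Lp, (0, 2, 1)), eps[..., None]
        )[..., 0]

        # --- lot intercepts -----------------------------------------------
        P_lot = np.linalg.inv(sigma_lot)
        r = Y - fixed - state["U_spec"][spec_idx]
        wsum = np.zeros((n_lot, p))
        np.add.at(wsum, lot_idx, r * w[:, None])
        wtot = np.bincount(lot_idx, weights=w, minlength=n_lot)
        prec = P_lot[None, :, :] + wtot[:, None, None] * P_err[None, :, :]
        mean_l = np.linalg.solve(prec, (wsum @ P_err.T)[..., None])[..., 0]
        Lp = np.linalg.cholesky(prec)
        eps = rng.standard_normal((n_lot, p))
        state["U_lot"] = mean_l + np.linalg.solve(
            np.transpose(Lp, (0, 2, 1)), eps[..., None]
        )[..., 0]

        # --- ridge moves: shift between intercept and random-effect means -
        for block, P_blk, m_blk, d_blk in (
            ("U_spec", P_spec, n_spec, d_spec),
            ("U_lot", P_lot, n_lot, d_lot),
        ):
            delta = rng.standard_normal(p) * d_blk / np.sqrt(m_blk)
            b0_new = state["B"][0] + delta
            u_new = state[block] - delta[None, :]
            logr = (
                -0.5 * prior_prec_b * (np.sum(b0_new**2) - np.sum(state["B"][0] ** 2))
                - 0.5 * np.einsum("ij,jk,ik->", u_new, P_blk, u_new)
                + 0.5 * np.einsum("ij,jk,ik->", state[block], P_blk, state[block])
            )
            if np.log(rng.uniform()) < logr:
                state["B"] = state["B"].copy()
                state["B"][0] = b0_new
                state[block] = u_new

        # --- scale/correlation blocks (Metropolis) -------------------------
        us = state["U_spec"]
        scatter_spec = us.T @ us
        ul = state["U_lot"]
        scatter_lot = ul.T @ ul
        resid = Y - X @ state["B"] - state["U_spec"][spec_idx] - state["U_lot"][lot_idx]
        rw_resid = resid * np.sqrt(w)[:, None]
        scatter_err = rw_resid.T @ rw_resid

        for name, scat, m_eff in (
            ("spec", scatter_spec, n_spec),
            ("lot", scatter_lot, n_lot),
            ("err", scatter_err, n),
        ):
            key = f"th_{name}"
            cur = state[key].copy()
            cur_lp = _block_logdensity_gaussian(cur, scat, m_eff)
            mover = rw[name]
            for _sweep in range(N_SCALE_SWEEPS):
                for j in range(len(cur)):
                    prop = cur.copy()
                    prop[j] += mover.step[j] * rng.standard_normal()
                    prop_lp = _block_logdensity_gaussian(prop, scat, m_eff)
                    acc = np.log(rng.uniform()) < prop_lp - cur_lp
                    if acc:
                        cur, cur_lp = prop, prop_lp
                    mover.record(j, bool(acc))
            state[key] = cur

        # --- interweaved (non-centered) update of the random-effect scales -
        # In the non-centered parametrisation U = η L(θ)ᵀ with η ~ N(0, I),
        # θ is informed directly by the data likelihood, which breaks the
        # funnel coupling between scales and intercepts (ASIS interweaving).
        for name, ublock, idx in (("spec", "U_spec", spec_idx), ("lot", "U_lot", lot_idx)):
            key = f"th_{name}"
            cur = state[key].copy()
            sigma_b, _, _ = _scale_matrix(cur[:p], cur[p:])
            Lb = np.linalg.cholesky(sigma_b)
            eta = np.linalg.solve(Lb, state[ublock].T).T  # U = η Lᵀ
            other = "U_lot" if ublock == "U_spec" else "U_spec"
            other_idx = lot_idx if ublock == "U_spec" else spec_idx
            r0 = Y - X @ state["B"] - state[other][other_idx]

            def nc_logdens(theta: np.ndarray) -> float:
                sig, d_, _ = _scale_matrix(theta[:p], theta[p:])
                try:
                    Lt = np.linalg.cholesky(sig)
                except np.linalg.LinAlgError:
                    return -np.inf
                u = eta @ Lt.T
                rr = r0 - u[idx]
                ll = -0.5 * float(np.einsum("ij,jk,ik,i->", rr, P_err, rr, w))
                pc = np.tanh(theta[p:])
                prior = (
                    float(np.sum(half_cauchy_logpdf(d_)))
                    + float(np.sum(theta[:p]))
                    + partials_logprior(pc)
                    + float(np.sum(np.log1p(-(pc**2))))
                )
                return ll + prior

            cur_lp = nc_logdens(cur)
            mover = rw[f"nc_{name}"]
            for j in range(len(cur)):
                prop = cur.copy()
                prop[j] += mover.step[j] * rng.standard_normal()
                prop_lp = nc_logdens(prop)
                acc = np.log(rng.uniform()) < prop_lp - cur_lp
                if acc:
                    cur, cur_lp = prop, prop_lp
                mover.record(j, bool(acc))
            state[key] = cur
            sigma_b, _, _ = _scale_matrix(cur[:p], cur[p:])
            state[ublock] = eta @ np.linalg.cholesky(sigma_b).T

        # --- degrees of freedom -------------------------------------------
        logw_sum = float(np.sum(np.log(w)))
        w_sum = float(np.sum(w))

        def nu_logpost(nu_val: float) -> float:
            h = nu_val / 2.0
            return (
                n * (h * np.log(h) - special.gammaln(h))
                + (h - 1.0) * logw_sum
                - h * w_sum
                + nu_logprior(nu_val)
            )

        phi = np.log(state["nu"] - 2.0)
        phi_new = phi + rw["nu"].step[0] * rng.standard_normal()
        nu_new = 2.0 + np.exp(phi_new)
        logr = nu_logpost(nu_new) - nu_logpost(state["nu"]) + phi_new - phi
        acc = np.log(rng.uniform()) < logr
        if acc:
            state["nu"] = nu_new
        rw["nu"].record(0, bool(acc))

        # --- adaptation / storage ------------------------------------------
        if it < warmup:
            if (it + 1) % 50 == 0:
                for r_ in rw.values():
                    r_.adapt()
            if it == warmup - 1:
                for r_ in rw.values():
                    r_.accepted[:] = 0
                    r_.proposed[:] = 0
        else:
            s = it - warmup
            keep["B"][s] = state["B"]
            keep["U"][s] = np.vstack([state["U_spec"], state["U_lot"]])
            _, d_s, om_s = _scale_matrix(state["th_spec"][:p], state["th_spec"][p:])
            _, d_l, om_l = _scale_matrix(state["th_lot"][:p], state["th_lot"][p:])
            _, d_e, om_e = _scale_matrix(state["th_err"][:p], state["th_err"][p:])
            keep["d_spec"][s], keep["omega_spec"][s] = d_s, om_s
            keep["d_lot"][s], keep["omega_lot"][s] = d_l, om_l
            keep["d_err"][s], keep["omega_err"][s] = d_e, om_e
            keep["nu"][s] = state["nu"]

    for nm, r_ in rw.items():
        total_rates[nm] = r_.rate
    keep["accept_rates"] = total_rates
    return keep


def fit_mcmc(
    Y: np.ndarray,
    X: np.ndarray,
    spec_idx: np.ndarray,
    lot_idx: np.ndarray,
    n_specimens: int,
    n_lots: int,
    config: SamplerConfig = SamplerConfig(),
    x_names: list[str] | None = None,
) -> PosteriorDraws:
    """Sample the posterior of the Student-t mixed model.

    ``Y`` is the n x 4 log observation matrix, ``X`` the fixed design, and
    ``spec_idx``/``lot_idx`` the per-row group positions (the incidence
    matrix Z factorises into these).  Runs ``config.chains`` independent
    chains and stacks their post-warmup draws; split-R̂ is computed for every
    scalar parameter and the result is flagged (not rejected) when the
    maximum exceeds the threshold.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != P_DIM:
        raise ValueError(f"Y must be n x {P_DIM}")
    if len(X) != len(Y):
        raise ValueError("X and Y row counts differ")
    ss = np.random.SeedSequence(config.seed)
    chains = []
    for child in ss.spawn(config.chains):
        rng = np.random.default_rng(child)
        chains.append(
            _run_chain(
                Y, X, spec_idx, lot_idx, n_specimens, n_lots,
                config.warmup, config.draws, rng,
            )
        )

    def stack(name: str) -> np.ndarray:
        return np.concatenate([c[name] for c in chains], axis=0)

    def per_chain(name: str) -> np.ndarray:
        return np.stack([c[name] for c in chains], axis=0)

    rhat = {
        name: split_rhat(per_chain(name))
        for name in ("B", "U", "d_spec", "d_lot", "d_err", "nu")
    }
    accept = {
        nm: float(np.mean([c["accept_rates"][nm] for c in chains]))
        for nm in chains[0]["accept_rates"]
    }
    draws = PosteriorDraws(
        B=stack("B"), U=stack("U"),
        d_spec=stack("d_spec"), omega_spec=stack("omega_spec"),
        d_lot=stack("d_lot"), omega_lot=stack("omega_lot"),
        d_err=stack("d_err"), omega_err=stack("omega_err"),
        nu=stack("nu"),
        n_specimens=n_specimens, n_lots=n_lots, chains=config.chains,
        x_names=list(x_names or []),
        rhat=rhat, accept_rates=accept,
    )
    draws.converged = bool(draws.rhat_max() <= config.rhat_threshold)
    return draws
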