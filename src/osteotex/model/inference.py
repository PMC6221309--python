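"""Posterior summaries: WAIC, ICC, goodness of fit, predictions.

One "point" for WAIC is one observation row (one 4-vector), matching the
multivariate likelihood.  ICC uses the Student-t error variance
scale²·ν/(ν−2) so the three variance components are on a common footing.
The scaled squared Mahalanobis distance of a multivariate-t residual follows
an F(p, ν) distribution, which supplies the goodness-of-fit reference.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

from .design import build_fixed_design
from .distributions import mvt_logpdf
from .sampler import P_DIM, PosteriorDraws


# ---------------------------------------------------------------------------
# Pointwise log-likelihood and WAIC
# ---------------------------------------------------------------------------

def loglik_matrix(
    draws: PosteriorDraws,
    Y: np.ndarray,
    X: np.ndarray,
    spec_idx: np.ndarray,
    lot_idx: np.ndarray,
) -> np.ndarray:
    """Pointwise posterior log-likelihood, shape (S draws, n rows)."""
    Y = np.asarray(Y, dtype=float)
    S = draws.n_draws
    n = len(Y)
    out = np.empty((S, n))
    lot_off = draws.n_specimens
    for s in range(S):
        mean = X @ draws.B[s]
        mean += draws.U[s][spec_idx]
        mean += draws.U[s][lot_off + lot_idx]
        out[s] = mvt_logpdf(Y - mean, draws.error_scale_matrix(s), float(draws.nu[s]))
    return out


def compute_waic(loglik: np.ndarray) -> dict[str, float]:
    """WAIC from a pointwise log-likelihood matrix (S draws x n points).

    WAIC = −2·(lppd − p_waic) with lppd = Σ_i log mean_s exp(ll_si) and
    p_waic = Σ_i var_s(ll_si).
    """
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2 or loglik.shape[0] < 2:
        raise ValueError("need a (S >= 2) x n log-likelihood matrix")
    S = loglik.shape[0]
    lppd = float(np.sum(special.logsumexp(loglik, axis=0) - np.log(S)))
    p_waic = float(np.sum(np.var(loglik, axis=0, ddof=1)))
    return {"waic": -2.0 * (lppd - p_waic), "lppd": lppd, "p_waic": p_waic}


def waic_table(scores: dict[str, float]) -> pd.DataFrame:
    """Δ-WAIC table relative to the best (lowest-WAIC) model."""
    best = min(scores.values())
    rows = [
        {"model": m, "waic": w, "delta_waic": w - best}
        for m, w in sorted(scores.items())
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Intraclass correlations
# ---------------------------------------------------------------------------

def compute_icc(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior ICC of lot and specimen per texture parameter.

    Per draw and parameter j the unstructured variance decomposes into
    lot d²_lot,j, specimen d²_spec,j and error d²_err,j·ν/(ν−2); the ICC of a
    grouping factor is its share.  Returns posterior means and central 95%
    intervals.
    """
    v_lot = draws.d_lot**2
    v_spec = draws.d_spec**2
    v_err = draws.d_err**2 * (draws.nu / (draws.nu - 2.0))[:, None]
    total = v_lot + v_spec + v_err
    rows = []
    from .design import LOG_NAMES

    for factor, v in (("lot", v_lot), ("specimen", v_spec)):
        icc = v / total
        for j, name in enumerate(LOG_NAMES):
            lo, hi = np.quantile(icc[:, j], [0.025, 0.975])
            rows.append(
                {
                    "factor": factor,
                    "parameter": name,
                    "icc_mean": float(icc[:, j].mean()),
                    "icc_lo": float(lo),
                    "icc_hi": float(hi),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mahalanobis goodness of fit
# ---------------------------------------------------------------------------

def mahalanobis_gof(
    draws: PosteriorDraws,
    Y: np.ndarray,
    X: np.ndarray,
    spec_idx: np.ndarray,
    lot_idx: np.ndarray,
) -> pd.DataFrame:
    """Scaled squared Mahalanobis distances vs F-distribution quantiles.

    Residuals from the posterior-mean parameters give d²_i = r_iᵀ Σ̂⁻¹ r_i;
    d²/p for a p-variate Student-t residual follows F(p, ν̂).  Returns sorted
    (observed, theoretical) pairs for a quantile-quantile plot.
    """
    B_hat = draws.B.mean(axis=0)
    U_hat = draws.U.mean(axis=0)
    d_hat = draws.d_err.mean(axis=0)
    om_hat = draws.omega_err.mean(axis=0)
    nu_hat = float(draws.nu.mean())
    sigma = d_hat[:, None] * om_hat * d_hat[None, :]
    mean = X @ B_hat + U_hat[spec_idx] + U_hat[draws.n_specimens + lot_idx]
    r = np.asarray(Y, dtype=float) - mean
    sol = np.linalg.solve(sigma, r.T)
    d2 = np.einsum("ij,ji->i", r, sol)
    p = P_DIM
    scaled = np.sort(d2 / p)
    n = len(scaled)
    probs = (np.arange(1, n + 1) - 0.5) / n
    theo = stats.f.ppf(probs, p, nu_hat)
    return pd.DataFrame({"observed": scaled, "theoretical": theo})


# ---------------------------------------------------------------------------
# Posterior predictions
# ---------------------------------------------------------------------------

def posterior_trajectories(
    draws: PosteriorDraws,
    times: np.ndarray,
    states: tuple[str, ...] = ("UW", "GS", "SF"),
    materials: tuple[str, ...] = ("FS", "PL", "DB"),
    model_id: str = "M3",
    max_observed_time: float | None = None,
    back_transform: bool = False,
) -> pd.DataFrame:
    """Posterior fixed-effect mean trajectories over a time grid.

    Controls are held at baseline (bone, non-rescan, location C).  With
    ``back_transform`` the log-scale means are exponentiated — then they are
    geometric means in original units (flagged in the ``scale`` column).
    Times beyond ``max_observed_time`` trigger an extrapolation warning.
    """
    times = np.asarray(times, dtype=float)
    if max_observed_time is not None and times.max() > max_observed_time:
        warnings.warn(
            f"predicting beyond the last observed time "
            f"({times.max():.0f} > {max_observed_time:.0f} min)",
            UserWarning,
            stacklevel=2,
        )
    rows = []
    for st in states:
        for mat in materials:
            for t in times:
                rows.append(
                    dict(specimen="-", lot="-", state=st, material=mat,
                         time_min=t, location="C", is_mold=False,
                         is_rescan=False)
                )
    grid = pd.DataFrame(rows)
    Xg, _ = build_fixed_design(grid, model_id)
    # (S, cells, p)
    means = np.einsum("ck,skp->scp", Xg, draws.B)
    from .design import LOG_NAMES

    out = []
    for c in range(len(grid)):
        cell = means[:, c, :]
        lo, hi = np.quantile(cell, [0.025, 0.975], axis=0)
        for j, name in enumerate(LOG_NAMES):
            m, l, h = cell[:, j].mean(), lo[j], hi[j]
            if back_transform:
                m, l, h = np.exp(m), np.exp(l), np.exp(h)
            out.append(
                dict(
                    state=grid.loc[c, "state"], material=grid.loc[c, "material"],
                    time_min=grid.loc[c, "time_min"], parameter=name,
                    mean=m, lo=l, hi=h,
                    scale="geometric-original" if back_transform else "log",
                )
            )
    return pd.DataFrame(out)


def posterior_ellipses(
    draws: PosteriorDraws,
    condition: pd.DataFrame,
    pairs: list[tuple[int, int]] | None = None,
    model_id: str = "M3",
    level: float = 0.95,
) -> pd.DataFrame:
    """95% posterior contours of pairwise mean clouds for one condition.

    ``condition`` is a single-row metadata frame (state, material, time, and
    control levels); for each parameter pair the posterior draws of the
    fixed-effect mean form a 2D cloud whose Gaussian ``level`` contour is
    summarised by centre, semi-axes and orientation angle.
    """
    if draws.n_draws < 10:
        raise ValueError("need at least 10 posterior draws for a contour")
    if pairs is None:
        pairs = [(i, j) for i in range(P_DIM) for j in range(i + 1, P_DIM)]
    Xg, _ = build_fixed_design(condition, model_id)
    cloud = np.einsum("ck,skp->scp", Xg, draws.B)[:, 0, :]  # (S, p)
    from .design import LOG_NAMES

    chi2 = stats.chi2.ppf(level, 2)
    rows = []
    for (i, j) in pairs:
        pts = cloud[:, [i, j]]
        centre = pts.mean(axis=0)
        cov = np.cov(pts.T)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
        rows.append(
            dict(
                x=LOG_NAMES[i], y=LOG_NAMES[j],
                center_x=float(centre[0]), center_y=float(centre[1]),
                semi_major=float(np.sqrt(evals[0] * chi2)),
                semi_minor=float(np.sqrt(evals[1] * chi2)),
                angle_rad=angle, level=level,
            )
        )
    return pd.DataFrame(rows)
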