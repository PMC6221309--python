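"""Scikit-learn style estimator wrapping the Student-t mixed model."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .design import build_fixed_design, build_random_design, log_transform_table
from .inference import compute_icc, compute_waic, loglik_matrix, mahalanobis_gof
from .sampler import PosteriorDraws, SamplerConfig, fit_mcmc


class TextureMixedModel(BaseEstimator):
    """Multilevel multivariate Bayesian Student-t mixed model.

    Fits Y = XB + ZU + E to an observation table of raw texture parameters
    (columns ``Sa_um``, ``Sal_um``, ``Spc_inv_um``, ``Smr1_pct`` plus the
    design metadata), where Y is the natural-log 4-vector per scan, U holds
    crossed specimen and lot random intercepts and E rows are multivariate
    Student-t.

    Parameters
    ----------
    model_id : which design of the nested ladder (M0-M3) to fit.
    chains, warmup, draws : sampler schedule; the default stores
        chains x draws = 1000 posterior samples.
    seed : seed for the sampler's random stream.

    Attributes (after fit)
    ----------------------
    draws_ : :class:`PosteriorDraws` archive.
    waic_ : dict with ``waic``, ``lppd``, ``p_waic``.
    icc_ : DataFrame of posterior ICCs per factor and parameter.
    rhat_max_ : worst split-R̂ over all scalar parameters.
    converged_ : whether rhat_max_ is below the threshold (a flag, not a
        hard failure; non-converged fits are still returned).
    """

    def __init__(
        self,
        model_id: str = "M3",
        chains: int = 2,
        warmup: int = 500,
        draws: int = 500,
        seed: int = 0,
        rhat_threshold: float = 1.05,
        compute_waic_on_fit: bool = True,
    ):
        self.model_id = model_id
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.seed = seed
        self.rhat_threshold = rhat_threshold
        self.compute_waic_on_fit = compute_waic_on_fit

    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "TextureMixedModel":
        """Fit the model to an observation table (DataFrame)."""
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected the observation table as a DataFrame")
        table = X
        Y, frame = log_transform_table(table)
        Xd, x_names = build_fixed_design(frame, self.model_id)
        _, z_names, spec_idx, lot_idx = build_random_design(frame)
        n_spec = int(spec_idx.max()) + 1
        n_lot = int(lot_idx.max()) + 1
        cfg = SamplerConfig(
            chains=self.chains, warmup=self.warmup, draws=self.draws,
            seed=self.seed, rhat_threshold=self.rhat_threshold,
        )
        self.draws_: PosteriorDraws = fit_mcmc(
            Y, Xd, spec_idx, lot_idx, n_spec, n_lot, cfg, x_names=x_names
        )
        self.Y_ = Y
        self.X_design_ = Xd
        self.x_names_ = x_names
        self.z_names_ = z_names
        self.spec_idx_ = spec_idx
        self.lot_idx_ = lot_idx
        self.rhat_max_ = self.draws_.rhat_max()
        self.converged_ = self.draws_.converged
        if self.compute_waic_on_fit:
            self.loglik_ = loglik_matrix(self.draws_, Y, Xd, spec_idx, lot_idx)
            self.waic_ = compute_waic(self.loglik_)
        self.icc_ = compute_icc(self.draws_)
        return self

    # ------------------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "draws_"):
            raise RuntimeError("model is not fitted; call fit() first")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior-mean log-scale prediction for rows of a metadata table.

        Uses the fixed effects only (population-level prediction at the
        rows' covariates); returns an (n, 4) array of log texture means.
        """
        self._check_fitted()
        frame = X.copy()
        Xd, _ = build_fixed_design(frame, self.model_id)
        return Xd @ self.draws_.B.mean(axis=0)

    def gof(self) -> pd.DataFrame:
        """Mahalanobis QQ data for the fitted table."""
        self._check_fitted()
        return mahalanobis_gof(
            self.draws_, self.Y_, self.X_design_, self.spec_idx_, self.lot_idx_
        )
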