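"""Tables and figures summarising a fitted model ladder.

Every figure is written alongside the CSV of its underlying numbers; figures
are derived artifacts only and nothing downstream reads pixel values back.
Axes of log-scale panels carry tick labels in original measurement units.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Ellipse

from .model.design import LOG_NAMES
from .model.inference import posterior_ellipses, posterior_trajectories
from .model.sampler import PosteriorDraws

UNIT_LABELS = {
    "log_Sa": "Sa (µm)",
    "log_Sal": "Sal (µm)",
    "log_Spc": "Spc (1/µm)",
    "log_Smr1": "Smr1 (%)",
}

STATE_COLORS = {"UW": "#e377c2", "GS": "#17becf", "SF": "#9467bd"}
MATERIAL_COLORS = {"FS": "#2ca02c", "PL": "#ff7f0e", "DB": "#1f77b4"}


def _log_axis_original_units(ax, axis: str) -> None:
    """Tick labels in original units on a log-scale axis."""
    ticks = ax.get_xticks() if axis == "x" else ax.get_yticks()
    labels = [f"{np.exp(t):.3g}" for t in ticks]
    if axis == "x":
        ax.set_xticks(ticks, labels)
    else:
        ax.set_yticks(ticks, labels)


def write_waic_table(table: pd.DataFrame, out_dir: Path) -> Path:
    path = Path(out_dir) / "waic_table.csv"
    table.to_csv(path, index=False)
    return path


def write_icc_table(icc: pd.DataFrame, out_dir: Path) -> Path:
    path = Path(out_dir) / "icc_table.csv"
    icc.to_csv(path, index=False)
    return path


def render_ellipse_matrix(
    draws_by_condition: dict[str, PosteriorDraws | pd.DataFrame],
    conditions: dict[str, pd.DataFrame],
    observations: pd.DataFrame | None,
    out_dir: Path,
    model_id: str = "M3",
    colors: dict[str, str] | None = None,
    stem: str = "ellipses",
) -> tuple[Path, Path]:
    """Pairwise scatter panels with 95% posterior mean contours.

    ``draws_by_condition`` maps a condition label (e.g. a manufacturing
    state) to posterior draws; ``conditions`` maps the same labels to
    single-row metadata frames.  Observations, if given, are plotted as
    points in log space.  Returns (figure path, CSV path).
    """
    out_dir = Path(out_dir)
    colors = colors or {**STATE_COLORS, **MATERIAL_COLORS}
    pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    rows = []
    fig, axes = plt.subplots(2, 3, figsize=(13, 8))
    for ax, (i, j) in zip(axes.ravel(), pairs):
        for label, draws in draws_by_condition.items():
            ell = posterior_ellipses(
                draws, conditions[label], pairs=[(i, j)], model_id=model_id
            ).iloc[0]
            rows.append(dict(condition=label, **ell.to_dict()))
            col = colors.get(label, "k")
            ax.add_patch(
                Ellipse(
                    (ell.center_x, ell.center_y),
                    2 * ell.semi_major, 2 * ell.semi_minor,
                    angle=np.degrees(ell.angle_rad),
                    fill=False, color=col, lw=2, label=label,
                )
            )
            ax.plot(ell.center_x, ell.center_y, "+", color=col)
        if observations is not None:
            obs_cols = ["Sa_um", "Sal_um", "Spc_inv_um", "Smr1_pct"]
            ax.plot(
                np.log(observations[obs_cols[i]]),
                np.log(observations[obs_cols[j]]),
                ".", ms=2, color="0.6", zorder=0,
            )
        ax.set_xlabel(UNIT_LABELS[LOG_NAMES[i]])
        ax.set_ylabel(UNIT_LABELS[LOG_NAMES[j]])
        ax.relim()
        ax.autoscale_view()
        _log_axis_original_units(ax, "x")
        _log_axis_original_units(ax, "y")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig_path = out_dir / f"{stem}.png"
    csv_path = out_dir / f"{stem}.csv"
    fig.savefig(fig_path, dpi=110)
    plt.close(fig)
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return fig_path, csv_path


def render_trajectories(
    draws: PosteriorDraws,
    times: np.ndarray,
    out_dir: Path,
    model_id: str = "M3",
    max_observed_time: float | None = None,
    stem: str = "trajectories",
) -> tuple[Path, Path]:
    """Posterior mean trajectories by state and material, one panel per
    parameter x material, lines per manufacturing state."""
    out_dir = Path(out_dir)
    traj = posterior_trajectories(
        draws, times, model_id=model_id, max_observed_time=max_observed_time
    )
    materials = sorted(traj["material"].unique())
    fig, axes = plt.subplots(4, len(materials), figsize=(11, 12), sharex=True)
    axes = np.atleast_2d(axes)
    for r, pname in enumerate(LOG_NAMES):
        for c, mat in enumerate(materials):
            ax = axes[r, c]
            sub = traj[(traj.parameter == pname) & (traj.material == mat)]
            for state, g in sub.groupby("state"):
                g = g.sort_values("time_min")
                col = STATE_COLORS.get(state, "k")
                ax.plot(g.time_min, g["mean"], color=col, label=state)
                ax.fill_between(g.time_min, g.lo, g.hi, color=col, alpha=0.15)
            if r == 0:
                ax.set_title(mat)
            if c == 0:
                ax.set_ylabel(UNIT_LABELS[pname])
                _log_axis_original_units(ax, "y")
            if r == 3:
                ax.set_xlabel("time (min)")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig_path = out_dir / f"{stem}.png"
    csv_path = out_dir / f"{stem}.csv"
    fig.savefig(fig_path, dpi=110)
    plt.close(fig)
    traj.to_csv(csv_path, index=False)
    return fig_path, csv_path


def render_qq(gof: pd.DataFrame, out_dir: Path, stem: str = "mahalanobis_qq") -> tuple[Path, Path]:
    """QQ plot of scaled squared Mahalanobis distances vs F quantiles."""
    out_dir = Path(out_dir)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(gof["theoretical"], gof["observed"], ".", ms=3)
    lim = max(gof["theoretical"].max(), gof["observed"].max())
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("F-distribution quantiles")
    ax.set_ylabel("scaled squared Mahalanobis distance")
    fig.tight_layout()
    fig_path = out_dir / f"{stem}.png"
    csv_path = out_dir / f"{stem}.csv"
    fig.savefig(fig_path, dpi=110)
    plt.close(fig)
    gof.to_csv(csv_path, index=False)
    return fig_path, csv_path
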