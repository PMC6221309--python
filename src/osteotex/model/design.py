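"""Transforms and design matrices for the texture mixed model.

Texture parameters enter the model on the natural-log scale; the time
covariate is log(Time + 1.0) minutes, so time-0 rows form the baseline.
Dummy coding baselines: location C, manufacturing state UW, material DB
(materials carry no main effect — they enter only through interactions with
log time, so at time 0 the three materials coincide by construction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MODEL_IDS = ("M0", "M1", "M2", "M3")

PARAM_COLUMNS = ("Sa_um", "Sal_um", "Spc_inv_um", "Smr1_pct")
LOG_NAMES = ("log_Sa", "log_Sal", "log_Spc", "log_Smr1")


def log_transform_table(table: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Natural-log observation matrix Y (n x 4) and augmented covariates.

    Returns ``(Y, frame)`` where ``frame`` is the input with a ``log_time``
    column (log(time_min + 1.0)).  Raises on nonpositive raw parameters,
    naming the offending row.
    """
    missing = [c for c in PARAM_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"observation table lacks columns {missing}")
    raw = table[list(PARAM_COLUMNS)].to_numpy(dtype=float)
    bad = np.nonzero(~(raw > 0.0))[0]
    if bad.size:
        raise ValueError(
            f"nonpositive texture parameter in row {int(bad[0])}: "
            f"{table.iloc[int(bad[0])][list(PARAM_COLUMNS)].to_dict()}"
        )
    frame = table.copy()
    frame["log_time"] = np.log(frame["time_min"].to_numpy(dtype=float) + 1.0)
    return np.log(raw), frame


def _location_group(loc: pd.Series) -> pd.Series:
    from ..synthesis import LOCATION_GROUPS

    grouped = loc.map(lambda v: LOCATION_GROUPS.get(v, v))
    unknown = set(grouped.unique()) - {"C", "LR", "DP"}
    if unknown:
        raise ValueError(f"unknown scan location level(s): {sorted(unknown)}")
    return grouped


def build_fixed_design(table: pd.DataFrame, model_id: str) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design matrix X for one model of the ladder.

    M0: intercept only.  M1 adds the control factors (grouped location,
    bone-vs-mold, rescan test) and log time.  M2 adds the manufacturing-state
    main effects and the state x log-time and material x log-time pairwise
    interactions.  M3 adds the state x material x log-time three-way terms
    (k = 16 columns on the full coding).  Column names are deterministic.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}; expected one of {MODEL_IDS}")
    n = len(table)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    if model_id == "M0":
        return np.ones((n, 1)), names

    if "log_time" in table.columns:
        logt = table["log_time"].to_numpy(dtype=float)
    else:
        logt = np.log(table["time_min"].to_numpy(dtype=float) + 1.0)
    grp = _location_group(table["location"])
    state = table["state"].astype(str)
    material = table["material"].astype(str)
    bad_state = set(state.unique()) - {"UW", "GS", "SF"}
    bad_mat = set(material.unique()) - {"FS", "PL", "DB"}
    if bad_state or bad_mat:
        raise ValueError(
            f"unknown factor level(s): state={sorted(bad_state)}, "
            f"material={sorted(bad_mat)}"
        )

    cols += [
        (grp == "LR").to_numpy(float),
        (grp == "DP").to_numpy(float),
        table["is_mold"].to_numpy(float),
        table["is_rescan"].to_numpy(float),
        logt,
    ]
    names += ["loc_LR", "loc_DP", "is_mold", "is_rescan", "log_time"]

    if model_id in ("M2", "M3"):
        gs = (state == "GS").to_numpy(float)
        sf = (state == "SF").to_numpy(float)
        fs = (material == "FS").to_numpy(float)
        pl = (material == "PL").to_numpy(float)
        cols += [gs, sf, gs * logt, sf * logt, fs * logt, pl * logt]
        names += ["man_GS", "man_SF", "GS:log_time", "SF:log_time",
                  "FS:log_time", "PL:log_time"]
    if model_id == "M3":
        cols += [gs * fs * logt, gs * pl * logt, sf * fs * logt, sf * pl * logt]
        names += ["GS:FS:log_time", "GS:PL:log_time",
                  "SF:FS:log_time", "SF:PL:log_time"]
    return np.stack(cols, axis=1), names


def build_random_design(
    table: pd.DataFrame,
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Random-effects incidence matrix Z and group index vectors.

    Z has one column per specimen followed by one per lot; each row carries a
    single 1 in its specimen column and a single 1 in its lot column.
    Returns ``(Z, column_names, spec_idx, lot_idx)`` where the index vectors
    give each row's specimen/lot position (used by the sampler, which never
    materialises Z products).
    """
    spec_levels = sorted(table["specimen"].unique())
    if table["lot"].isna().any():
        orphan = table.loc[table["lot"].isna(), "specimen"].iloc[0]
        raise ValueError(f"specimen {orphan!r} has no lot assignment")
    per_spec = table.groupby("specimen")["lot"].nunique()
    if (per_spec > 1).any():
        raise ValueError(
            f"specimen {per_spec.idxmax()!r} maps to multiple lots"
        )
    lot_levels = sorted(table["lot"].unique())
    spec_pos = {s: i for i, s in enumerate(spec_levels)}
    lot_pos = {l: i for i, l in enumerate(lot_levels)}
    n = len(table)
    spec_idx = table["specimen"].map(spec_pos).to_numpy(dtype=int)
    lot_idx = table["lot"].map(lot_pos).to_numpy(dtype=int)
    Z = np.zeros((n, len(spec_levels) + len(lot_levels)))
    Z[np.arange(n), spec_idx] = 1.0
    Z[np.arange(n), len(spec_levels) + lot_idx] = 1.0
    names = [f"specimen[{s}]" for s in spec_levels] + [f"lot[{l}]" for l in lot_levels]
    return Z, names, spec_idx, lot_idx
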