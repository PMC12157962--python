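"""Long-format CSV interchange and result serialization.

One interchange schema is used everywhere: a row per respondent × task ×
alternative with columns ``respondent, block, task, alternative,
<one column per attribute holding the level label>, left_asc, chosen``.
Respondent covariates travel in a separate profiles CSV keyed by
``respondent``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .design import AttributeSpace, ChoiceDesign
from .errors import DataError
from .mxl import MXLResult
from .simulate import ChoiceDataset

log = logging.getLogger("npidce")

__all__ = [
    "write_design",
    "write_encoded_design",
    "write_dataset",
    "read_choice_data",
    "mxl_result_to_dict",
    "mxl_result_from_dict",
]


def write_design(design: ChoiceDesign, path) -> None:
    design.to_frame().to_csv(path, index=False)


def write_encoded_design(design: ChoiceDesign, path) -> None:
    X = design.encoded()
    B, a, t, P = X.shape
    df = pd.DataFrame(X.reshape(-1, P), columns=design.space.predictor_names)
    df.insert(0, "alternative", np.tile(np.arange(t), B * a))
    df.insert(0, "task", np.tile(np.repeat(np.arange(a), t), B))
    df.insert(0, "block", np.repeat(np.arange(B), a * t))
    df.to_csv(path, index=False)


def write_dataset(dataset: ChoiceDataset, path, profiles_path=None) -> None:
    dataset.to_frame().to_csv(path, index=False)
    if profiles_path is not None and dataset.profiles is not None:
        dataset.profiles.to_csv(profiles_path, index=False)


def read_choice_data(
    path,
    space: AttributeSpace | None = None,
    profiles_path=None,
) -> ChoiceDataset:
    """Read and validate a long-format choice CSV.

    Enforced on ingest: every (respondent, task) group has exactly one
    chosen alternative (violations are errors naming the rows); respondents
    with an incomplete set of tasks are removed listwise, mirroring the
    survey's exclusion of incomplete responses — the count is logged and
    stored as ``dataset.n_excluded``.
    """
    if space is None:
        space = AttributeSpace.canonical()
    df = pd.read_csv(path)
    required = {"respondent", "task", "alternative", "chosen"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"missing columns: {sorted(missing)}")
    for a in space.attributes:
        if a.name not in df.columns:
            raise DataError(f"missing attribute column {a.name!r}")

    # one chosen alternative per task
    grp = df.groupby(["respondent", "task"])["chosen"].sum()
    bad = grp[grp != 1]
    if not bad.empty:
        r, t = bad.index[0]
        rows = df.index[(df["respondent"] == r) & (df["task"] == t)].tolist()
        raise DataError(
            f"respondent {r}, task {t} has {int(bad.iloc[0])} chosen "
            f"alternatives (rows {rows}); exactly one is required"
        )

    # listwise deletion of incomplete respondents
    tasks_per_resp = df.groupby("respondent")["task"].nunique()
    full = int(tasks_per_resp.max())
    keep = tasks_per_resp[tasks_per_resp == full].index
    n_excluded = int(tasks_per_resp.size - keep.size)
    if n_excluded:
        log.warning("excluded %d respondent(s) with incomplete tasks", n_excluded)
        df = df[df["respondent"].isin(keep)]

    df = df.sort_values(["respondent", "task", "alternative"]).reset_index(drop=True)
    n_alts = df.groupby(["respondent", "task"]).size()
    if n_alts.nunique() != 1:
        raise DataError("alternative count varies across tasks")
    J = int(n_alts.iloc[0])
    respondents = df["respondent"].unique()
    N, T = len(respondents), full

    codes = np.empty((len(df), space.n_attributes), dtype=np.int64)
    for k, attr in enumerate(space.attributes):
        cat = pd.Categorical(df[attr.name].astype(str), categories=list(attr.levels))
        if cat.isna().any():
            bad_lv = df[attr.name][np.asarray(cat.codes) == -1].iloc[0]
            rows = df.index[np.asarray(cat.codes) == -1].tolist()[:5]
            raise DataError(
                f"unknown level {bad_lv!r} for attribute {attr.name!r} (rows {rows})"
            )
        codes[:, k] = cat.codes
    pidx = np.asarray(space.profile_index(codes)).reshape(N, T, J)

    X = np.zeros((N, T, J, space.n_predictors))
    X[..., 1:] = space.profile_matrix()[pidx]
    X[..., 0, 0] = 1.0
    chosen = (
        df["chosen"].to_numpy().reshape(N, T, J).argmax(axis=2)
    )
    blocks = (
        df.groupby("respondent", sort=True)["block"].first().to_numpy()
        if "block" in df.columns
        else None
    )
    profiles = pd.read_csv(profiles_path) if profiles_path is not None else None
    if profiles is not None:
        profiles = (
            profiles.set_index("respondent").loc[np.sort(respondents)].reset_index()
        )
    ds = ChoiceDataset(
        X=X,
        chosen=chosen,
        predictor_names=space.predictor_names,
        space=space,
        respondents=np.sort(respondents),
        blocks=blocks,
        levels=codes.reshape(N, T, J, -1),
        profiles=profiles,
    )
    ds.n_excluded = n_excluded
    return ds


# ---------------------------------------------------------------------------
# result serialization (JSON-safe)


def mxl_result_to_dict(result: MXLResult) -> dict:
    def arr(x):
        return None if x is None else np.asarray(x).tolist()

    return {
        "model": "mxl",
        "predictor_names": result.predictor_names,
        "random_set": result.random_set,
        "beta": arr(result.beta),
        "sigma": arr(result.sigma),
        "se_beta": arr(result.se_beta),
        "se_sigma": arr(result.se_sigma),
        "cov": arr(result.cov),
        "loglik": result.loglik,
        "n_respondents": result.n_respondents,
        "n_observations": result.n_observations,
        "R": result.R,
        "seed": result.seed,
        "converged": result.converged,
        "grad_norm": result.grad_norm,
        "message": result.message,
    }


def mxl_result_from_dict(d: dict) -> MXLResult:
    def arr(x):
        return None if x is None else np.asarray(x, dtype=float)

    return MXLResult(
        predictor_names=list(d["predictor_names"]),
        random_set=list(d["random_set"]),
        beta=arr(d["beta"]),
        sigma=arr(d["sigma"]),
        se_beta=arr(d["se_beta"]),
        se_sigma=arr(d["se_sigma"]),
        cov=arr(d["cov"]),
        loglik=d["loglik"],
        n_respondents=d["n_respondents"],
        n_observations=d["n_observations"],
        R=d["R"],
        seed=d["seed"],
        converged=d["converged"],
        grad_norm=d["grad_norm"],
        message=d.get("message", ""),
    )
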