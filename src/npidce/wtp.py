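"""Willingness to pay and preference-direction reporting.

WTP for an attribute level is the coefficient ratio beta_k / |beta_fee|,
with beta_fee the (negative) coefficient on the one-time fee: the money a
respondent would pay to have the level implemented (positive WTP) or to
avoid it (negative WTP).  Confidence intervals come from the delta method
or from Krinsky–Robb parametric resampling of the joint coefficient
distribution.  For latent-class fits, WTP uses each class's own fee
coefficient.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import WTPError
from .mxl import MXLResult

__all__ = ["compute_wtp", "preference_summary", "classify_preferences", "plot_wtp"]

_EXCLUDED = ("asc_left",)


def _attribute_terms(result: MXLResult, fee_name: str) -> list[int]:
    return [
        i
        for i, n in enumerate(result.predictor_names)
        if n != fee_name and n not in _EXCLUDED
    ]


def compute_wtp(
    result: MXLResult,
    method: str = "delta",
    fee_name: str = "fee",
    n_draws: int = 10_000,
    seed: int | None = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """WTP table (SGD) for every attribute level of a fitted model.

    ``method`` is ``"delta"`` (first-order variance of the ratio) or
    ``"krinsky-robb"`` (percentile CI over ``n_draws`` multivariate-normal
    parameter draws, seeded).  Requires a negative estimated fee
    coefficient; otherwise the ratio has no money-metric interpretation and
    a :class:`WTPError` is raised.
    """
    if fee_name not in result.predictor_names:
        raise WTPError(f"no {fee_name!r} predictor in this fit")
    fee_idx = result.predictor_names.index(fee_name)
    beta = result.beta
    if beta[fee_idx] >= 0:
        raise WTPError("fee coefficient is non-negative; WTP is ill-posed")
    if method not in ("delta", "krinsky-robb"):
        raise WTPError(f"unknown CI method {method!r}")

    terms = _attribute_terms(result, fee_name)
    wtp = beta[terms] / np.abs(beta[fee_idx])

    ci_low = ci_high = np.full(len(terms), np.nan)
    P = len(beta)
    if result.cov is not None:
        cov_bb = result.cov[:P, :P]
        if method == "delta":
            zcrit = stats.norm.ppf(0.5 + level / 2)
            bf = beta[fee_idx]
            # w = -b_k / b_f  (b_f < 0): gradient (-1/b_f, b_k/b_f^2)
            se = np.empty(len(terms))
            for j, k in enumerate(terms):
                g = np.zeros(P)
                g[k] = -1.0 / bf
                g[fee_idx] = beta[k] / bf**2
                se[j] = np.sqrt(g @ cov_bb @ g)
            ci_low = wtp - zcrit * se
            ci_high = wtp + zcrit * se
        else:
            rng = np.random.default_rng(seed)
            draws = rng.multivariate_normal(beta, cov_bb, size=n_draws, method="svd")
            fees = draws[:, fee_idx]
            ok = fees < 0
            if ok.sum() < n_draws // 2:
                raise WTPError("fee coefficient sign unstable under resampling")
            ratios = draws[np.ix_(ok, terms)] / np.abs(fees[ok, None])
            lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
            ci_low = np.quantile(ratios, lo, axis=0)
            ci_high = np.quantile(ratios, hi, axis=0)

    return pd.DataFrame(
        {
            "term": [result.predictor_names[k] for k in terms],
            "wtp": wtp,
            "wtp_rounded": np.round(wtp).astype(int),
            "ci_low": ci_low,
            "ci_high": ci_high,
            "direction": np.where(wtp >= 0, "pay_to_implement", "pay_to_avoid"),
        }
    )


def classify_preferences(frame: pd.DataFrame) -> pd.DataFrame:
    """Label each coefficient preferred / opposed / indifferent from its CI.

    ``frame`` needs columns ``term``, ``coefficient``, ``ci_low``,
    ``ci_high``; endpoint order within a row does not matter.
    """
    lo = np.minimum(frame["ci_low"], frame["ci_high"])
    hi = np.maximum(frame["ci_low"], frame["ci_high"])
    label = np.where(lo > 0, "preferred", np.where(hi < 0, "opposed", "indifferent"))
    out = frame[["term", "coefficient"]].copy()
    out["ci_low"], out["ci_high"], out["classification"] = lo, hi, label
    return out


def preference_summary(result, fee_name: str = "fee") -> pd.DataFrame:
    """Preferred / opposed / indifferent grid per attribute level.

    Accepts an :class:`~npidce.mxl.MXLResult` or an
    :class:`~npidce.mmml.MMMLResult` (one block per class).
    """
    if hasattr(result, "class_betas"):  # latent-class fit
        blocks = []
        for c in range(result.K):
            sub = preference_summary(result.class_result(c), fee_name)
            sub.insert(0, "class", c + 1)
            blocks.append(sub)
        return pd.concat(blocks, ignore_index=True)
    frame = result.summary_frame()
    keep = frame["term"].isin(
        [result.predictor_names[k] for k in _attribute_terms(result, fee_name)]
    )
    return classify_preferences(frame[keep].reset_index(drop=True))


def plot_wtp(wtp_table: pd.DataFrame, ax=None, title: str | None = None):
    """Horizontal bar chart of WTP with CI whiskers (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.45 * len(wtp_table) + 1))
    y = np.arange(len(wtp_table))
    ax.barh(y, wtp_table["wtp"], color=np.where(wtp_table["wtp"] >= 0, "#2b7a78", "#b0413e"))
    if wtp_table["ci_low"].notna().any():
        err = np.vstack(
            [wtp_table["wtp"] - wtp_table["ci_low"], wtp_table["ci_high"] - wtp_table["wtp"]]
        )
        ax.errorbar(wtp_table["wtp"], y, xerr=np.abs(err), fmt="none", ecolor="0.3", capsize=3)
    ax.set_yticks(y, wtp_table["term"])
    ax.axvline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("willingness to pay (SGD)")
    if title:
        ax.set_title(title)
    return ax
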