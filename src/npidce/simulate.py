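"""Synthetic respondent populations and panel choice simulation.

The default population emulates the survey sample this toolkit was built
around: ~1550 Singapore residents aged 18+, with the published demographic
marginals (58.2% female, 84.7% Chinese, 92.8% with 3+ vaccine shots, ...),
age ~ Normal(48, 14) truncated at 18 and a health-risk-attitude (HRAS-13)
sum score ~ Normal(42, 8).  Covariates are drawn independently: no joint
distribution is published, so the generator reproduces marginals only.

Choices follow the random-utility model

    U_ij = beta_i' x_j + eps_ij,      beta_i = beta_c(i) + eta_i,

with eps_ij i.i.d. type-1 extreme value (Gumbel) across respondents, tasks
and alternatives, eta_i ~ Normal(0, diag(sigma_c(i)^2)) drawn once per
respondent, and — when latent classes are configured — class c(i) drawn from
a multinomial logit on respondent covariates (reference class has
coefficient vector zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import AttributeSpace, ChoiceDesign
from .errors import ConfigError, DataError

__all__ = [
    "TABLE_MARGINALS",
    "MEMBERSHIP_COVARIATES",
    "simulate_profiles",
    "membership_design",
    "assign_classes",
    "TasteClass",
    "SimulationConfig",
    "ChoiceDataset",
    "simulate_choices",
]


#: Published sample marginals used as simulation defaults.
TABLE_MARGINALS: dict = {
    "sex": {"male": 0.418, "female": 0.582},
    "ethnicity": {"chinese": 0.847, "non_chinese": 0.153},
    "education": {
        "secondary_or_below": 0.216,
        "post_secondary": 0.268,
        "university": 0.516,
    },
    "housing": {"hdb_1_3_room": 0.221, "hdb_4_5_or_private": 0.779},
    "marital": {"married": 0.647, "unmarried": 0.353},
    "parental": {"children": 0.603, "no_children": 0.397},
    "employment": {
        "full_time": 0.568,
        "self_employed": 0.086,
        "homemaker": 0.062,
        "other": 0.284,
    },
    "vaccine": {"shots_0_2": 0.072, "shots_3_plus": 0.928},
    "age": {"mean": 48.0, "sd": 14.0, "min": 18.0},
    "hras": {"mean": 42.0, "sd": 8.0},
}


def simulate_profiles(
    n: int,
    marginals: Mapping | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw ``n`` respondent profiles from independent categorical marginals.

    Age is truncated normal (18+, mirroring the eligibility criterion); the
    HRAS-13 score is normal.  Deterministic given ``seed``.
    """
    if n < 0:
        raise DataError("n must be non-negative")
    marg = dict(TABLE_MARGINALS)
    if marginals:
        marg.update(marginals)
    rng = np.random.default_rng(seed)

    cols: dict = {"respondent": np.arange(n)}
    for field_name, dist in marg.items():
        if field_name in ("age", "hras"):
            continue
        labels = list(dist)
        p = np.asarray([dist[k] for k in labels], dtype=float)
        if np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-6:
            raise DataError(f"invalid marginal proportions for {field_name!r}")
        draws = rng.choice(len(labels), size=n, p=p)
        cols[field_name] = pd.Categorical.from_codes(draws, categories=labels)

    age = marg["age"]
    a_lo = (age.get("min", 18.0) - age["mean"]) / age["sd"]
    cols["age"] = stats.truncnorm.rvs(
        a_lo, np.inf, loc=age["mean"], scale=age["sd"], size=n, random_state=rng
    )
    hras = marg["hras"]
    cols["hras"] = rng.normal(hras["mean"], hras["sd"], size=n)
    return pd.DataFrame(cols)


#: Covariates available to the class-membership model, in reporting order.
MEMBERSHIP_COVARIATES: tuple[str, ...] = (
    "male",
    "chinese",
    "married",
    "children",
    "edu_post_secondary",
    "edu_university",
    "housing_small",
    "emp_self_employed",
    "emp_homemaker",
    "emp_other",
    "vaccine_3_plus",
    "age_decades",
    "hras_10",
)

_COVARIATE_BUILDERS = {
    "male": lambda p: (p["sex"] == "male").astype(float),
    "chinese": lambda p: (p["ethnicity"] == "chinese").astype(float),
    "married": lambda p: (p["marital"] == "married").astype(float),
    "children": lambda p: (p["parental"] == "children").astype(float),
    "edu_post_secondary": lambda p: (p["education"] == "post_secondary").astype(float),
    "edu_university": lambda p: (p["education"] == "university").astype(float),
    "housing_small": lambda p: (p["housing"] == "hdb_1_3_room").astype(float),
    "emp_self_employed": lambda p: (p["employment"] == "self_employed").astype(float),
    "emp_homemaker": lambda p: (p["employment"] == "homemaker").astype(float),
    "emp_other": lambda p: (p["employment"] == "other").astype(float),
    "vaccine_3_plus": lambda p: (p["vaccine"] == "shots_3_plus").astype(float),
    # continuous covariates centred at the sample means, per-decade / per-10-points
    "age_decades": lambda p: (p["age"] - 48.0) / 10.0,
    "hras_10": lambda p: (p["hras"] - 42.0) / 10.0,
}


def membership_design(
    profiles: pd.DataFrame, covariates: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Design matrix of the class-membership logit, intercept first."""
    if covariates is None:
        covariates = MEMBERSHIP_COVARIATES
    Z = [np.ones(len(profiles))]
    names = ["intercept"]
    for c in covariates:
        if c not in _COVARIATE_BUILDERS:
            raise ConfigError(f"unknown membership covariate {c!r}")
        try:
            Z.append(np.asarray(_COVARIATE_BUILDERS[c](profiles), dtype=float))
        except KeyError as e:
            raise ConfigError(f"profile table lacks column needed for {c!r}: {e}") from None
        names.append(c)
    return np.column_stack(Z), names


def class_probabilities(Z: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Multinomial-logit membership probabilities, reference class first.

    ``gamma`` has one row per non-reference class, columns matching ``Z``.
    Returns shape (n, K) with K = gamma.shape[0] + 1.
    """
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    eta = np.column_stack([np.zeros(Z.shape[0]), Z @ gamma.T])
    eta -= eta.max(axis=1, keepdims=True)
    ex = np.exp(eta)
    return ex / ex.sum(axis=1, keepdims=True)


def assign_classes(
    profiles: pd.DataFrame,
    gamma: np.ndarray,
    covariates: Sequence[str] | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Draw one latent-class label per respondent (class 0 = reference)."""
    Z, _ = membership_design(profiles, covariates)
    pi = class_probabilities(Z, gamma)
    rng = np.random.default_rng(seed)
    u = rng.random(len(profiles))
    return (u[:, None] > np.cumsum(pi, axis=1)).sum(axis=1)


# ---------------------------------------------------------------------------
# choice simulation


@dataclass(frozen=True)
class TasteClass:
    """Taste parameters of one (latent) class: mean vector and heterogeneity
    SDs, both of encoded-predictor length (zeros for fixed coefficients)."""

    beta: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.beta, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        if b.shape != s.shape or b.ndim != 1:
            raise ConfigError("beta and sigma must be 1-D and the same length")
        if np.any(s < 0):
            raise ConfigError("sigma must be elementwise non-negative")
        object.__setattr__(self, "beta", b)
        object.__setattr__(self, "sigma", s)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth of a simulation run.

    One :class:`TasteClass` gives the plain random-coefficients model; several
    plus a ``gamma`` matrix give the latent-class variant.  ``taste_corr``
    optionally supplies a common correlation matrix for the random
    coefficients (default: independent normals).
    """

    classes: tuple[TasteClass, ...]
    gamma: np.ndarray | None = None
    membership_covariates: tuple[str, ...] | None = None
    taste_corr: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.classes:
            raise ConfigError("need at least one taste class")
        P = self.classes[0].beta.shape[0]
        if any(c.beta.shape[0] != P for c in self.classes):
            raise ConfigError("all classes must share the predictor length")
        if len(self.classes) > 1 and self.gamma is not None:
            g = np.atleast_2d(np.asarray(self.gamma, dtype=float))
            if g.shape[0] != len(self.classes) - 1:
                raise ConfigError("gamma needs one row per non-reference class")
            object.__setattr__(self, "gamma", g)

    @property
    def n_predictors(self) -> int:
        return self.classes[0].beta.shape[0]


class ChoiceDataset:
    """Long-format panel of choices in estimation-ready array form.

    ``X`` has shape (N, T, J, P) — respondents × tasks × alternatives ×
    encoded predictors — and ``chosen`` (N, T) holds the index of the chosen
    alternative.  Exactly one alternative is chosen per task by construction.
    """

    def __init__(
        self,
        X: np.ndarray,
        chosen: np.ndarray,
        predictor_names: Sequence[str],
        space: AttributeSpace | None = None,
        respondents: np.ndarray | None = None,
        blocks: np.ndarray | None = None,
        levels: np.ndarray | None = None,
        profiles: pd.DataFrame | None = None,
        true_classes: np.ndarray | None = None,
    ) -> None:
        X = np.asarray(X, dtype=float)
        chosen = np.asarray(chosen, dtype=np.int64)
        if X.ndim != 4:
            raise DataError("X must have shape (N, T, J, P)")
        N, T, J, P = X.shape
        if chosen.shape != (N, T):
            raise DataError("chosen must have shape (N, T)")
        if np.any(chosen < 0) or np.any(chosen >= J):
            raise DataError("chosen alternative index out of range")
        if len(predictor_names) != P:
            raise DataError("predictor_names length must match X")
        self.X = X
        self.chosen = chosen
        self.predictor_names = list(predictor_names)
        self.space = space
        self.respondents = (
            np.arange(N) if respondents is None else np.asarray(respondents)
        )
        self.blocks = np.zeros(N, dtype=np.int64) if blocks is None else np.asarray(blocks)
        self.levels = levels
        self.profiles = profiles
        self.true_classes = true_classes

    @property
    def n_respondents(self) -> int:
        return self.X.shape[0]

    @property
    def n_tasks(self) -> int:
        return self.X.shape[1]

    @property
    def n_alternatives(self) -> int:
        return self.X.shape[2]

    @property
    def n_predictors(self) -> int:
        return self.X.shape[3]

    @property
    def n_observations(self) -> int:
        """Choice tasks answered in total."""
        return self.n_respondents * self.n_tasks

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per respondent × task × alternative."""
        N, T, J, _ = self.X.shape
        rows = {
            "respondent": np.repeat(self.respondents, T * J),
            "block": np.repeat(self.blocks, T * J),
            "task": np.tile(np.repeat(np.arange(T), J), N),
            "alternative": np.tile(np.arange(J), N * T),
        }
        df = pd.DataFrame(rows)
        if self.space is not None and self.levels is not None:
            lv = self.levels.reshape(N * T * J, -1)
            for k, attr in enumerate(self.space.attributes):
                df[attr.name] = pd.Categorical.from_codes(lv[:, k], categories=list(attr.levels))
        else:
            flat = self.X.reshape(N * T * J, -1)
            for p, name in enumerate(self.predictor_names):
                if name == "asc_left":
                    continue
                df[name] = flat[:, p]
        df["left_asc"] = (df["alternative"] == 0).astype(int)
        onehot = np.zeros((N, T, J), dtype=int)
        np.put_along_axis(onehot, self.chosen[..., None], 1, axis=2)
        df["chosen"] = onehot.reshape(-1)
        return df


def simulate_choices(
    design: ChoiceDesign,
    profiles: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> ChoiceDataset:
    """Simulate one panel: random block assignment, one taste draw per
    respondent, Gumbel noise per (respondent, task, alternative), argmax
    choice.  Fully reproducible given ``seed``."""
    n = len(profiles)
    Xd = design.encoded()  # (B,a,t,P)
    B, a, t, P = Xd.shape
    if config.n_predictors != P:
        raise ConfigError(
            f"config has {config.n_predictors} predictors, design encodes {P}"
        )

    ss = np.random.SeedSequence(seed)
    rng_block, rng_class, rng_taste, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    blocks = rng_block.integers(0, B, size=n)

    K = len(config.classes)
    if K == 1:
        labels = np.zeros(n, dtype=np.int64)
    else:
        gamma = (
            config.gamma
            if config.gamma is not None
            else np.zeros((K - 1, len(membership_design(profiles, config.membership_covariates)[1])))
        )
        labels = assign_classes(
            profiles, gamma, config.membership_covariates, seed=rng_class.integers(2**31)
        )

    beta_cls = np.stack([c.beta for c in config.classes])  # (K,P)
    sigma_cls = np.stack([c.sigma for c in config.classes])
    z = rng_taste.standard_normal((n, P))
    if config.taste_corr is not None:
        chol = np.linalg.cholesky(np.asarray(config.taste_corr, dtype=float))
        z = z @ chol.T
    beta_i = beta_cls[labels] + sigma_cls[labels] * z

    Xr = Xd[blocks]  # (n,a,t,P)
    V = np.einsum("natp,np->nat", Xr, beta_i)
    U = V + rng_noise.gumbel(size=(n, a, t))
    chosen = U.argmax(axis=2)

    lv = design.levels_array()[blocks] if design.space is not None else None
    return ChoiceDataset(
        X=Xr,
        chosen=chosen,
        predictor_names=design.space.predictor_names,
        space=design.space,
        respondents=profiles["respondent"].to_numpy(),
        blocks=blocks,
        levels=lv,
        profiles=profiles,
        true_classes=labels if K > 1 else None,
    )
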