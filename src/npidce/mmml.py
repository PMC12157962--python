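"""Mixed-mixed multinomial logit: a finite mixture of class-specific mixed
logits with covariate-driven class membership.

Each respondent belongs to one of ``K`` latent classes.  Within class ``c``
tastes follow the mixed-logit law ``beta_i = beta_c + eta_i`` with
class-specific heterogeneity SDs; across classes the mean preference
weights differ systematically.  Membership probabilities follow a
multinomial logit on respondent covariates (reference class coefficients
fixed at zero), so demographics predict which preference segment a
respondent belongs to.  The class count is selected by the Bayesian
Information Criterion, BIC = −2·LL + p·ln(respondents).

Estimation maximizes the simulated mixture likelihood directly (one code
path shared with the plain mixed logit), with several seeded random starts;
label switching is resolved post hoc by ordering classes on the
public-mask-mandate mean so class 1 is always the most pro-NPI segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError, FitError
from .mxl import (
    DEFAULT_RANDOM_SET,
    MXLResult,
    _covariance,
    _predictor_scale,
    _resolve_random_set,
    _respondent_loglik,
    fit_clogit,
    fit_mxl,
    halton_normal_draws,
)
from .simulate import ChoiceDataset, MEMBERSHIP_COVARIATES, membership_design

__all__ = [
    "MMMLResult",
    "mmml_loglik",
    "fit_mmml",
    "select_k",
    "membership_odds_ratios",
]

#: Predictor the relabeling rule sorts on (descending): the strongest
#: pro-mask class is reported first.
RELABEL_PREDICTOR = "masks:mandatory_public"


def _membership_logpi(Z: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Log membership probabilities (N, K), reference class first."""
    if gamma.size:
        eta = np.column_stack([np.zeros(Z.shape[0]), Z @ gamma.T])
    else:
        eta = np.zeros((Z.shape[0], 1))
    eta -= eta.max(axis=1, keepdims=True)
    lse = np.log(np.exp(eta).sum(axis=1, keepdims=True))
    return eta - lse


def _pack(betas: np.ndarray, ss: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    return np.concatenate([betas.ravel(), ss.ravel(), gamma.ravel()])


def _unpack(theta: np.ndarray, K: int, P: int, D: int, C: int):
    betas = theta[: K * P].reshape(K, P)
    ss = theta[K * P : K * (P + D)].reshape(K, D)
    gamma = theta[K * (P + D) :].reshape(K - 1, C) if K > 1 else np.zeros((0, C))
    return betas, ss, gamma


def _mixture_eval(
    X: np.ndarray,
    chosen: np.ndarray,
    Z: np.ndarray,
    theta: np.ndarray,
    K: int,
    random_idx: np.ndarray,
    draws: np.ndarray | None,
    grad: bool = True,
):
    """Simulated mixture log-likelihood, gradient and posteriors.

    The same draw block serves every class, which keeps the likelihood
    surface smooth in the class parameters and makes K-nesting comparisons
    use common randomness.
    """
    N, T, J, P = X.shape
    D = len(random_idx)
    C = Z.shape[1]
    betas, ss, gamma = _unpack(theta, K, P, D, C)

    l = np.empty((N, K))
    Gs = []
    for c in range(K):
        l[:, c], G = _respondent_loglik(
            X, chosen, betas[c], ss[c], random_idx, draws, grad=grad
        )
        Gs.append(G)
    logpi = _membership_logpi(Z, gamma)  # (N,K)
    A = logpi + l
    mx = A.max(axis=1)
    L_n = mx + np.log(np.exp(A - mx[:, None]).sum(axis=1))
    ll = float(L_n.sum())
    post = np.exp(A - L_n[:, None])  # (N,K) posteriors

    if not grad:
        return ll, None, post
    g_taste_b = np.empty((K, P))
    g_taste_s = np.empty((K, D))
    for c in range(K):
        g_taste_b[c] = post[:, c] @ Gs[c][:, :P]
        g_taste_s[c] = post[:, c] @ Gs[c][:, P:]
    if K > 1:
        pi = np.exp(logpi)
        g_gamma = (post[:, 1:] - pi[:, 1:]).T @ Z  # (K-1,C)
    else:
        g_gamma = np.zeros((0, C))
    return ll, _pack(g_taste_b, g_taste_s, g_gamma), post


def mmml_loglik(
    dataset: ChoiceDataset,
    class_betas,
    class_sigmas,
    gamma=None,
    covariates: Sequence[str] | None = None,
    random_set: Sequence[str] = DEFAULT_RANDOM_SET,
    R: int = 500,
    seed: int | None = None,
    antithetic: bool = True,
) -> float:
    """Simulated log-likelihood of the class mixture at fixed parameters.

    With ``K = 1`` (a single class) this equals the mixed-logit simulated
    log-likelihood for the same draws; with identical class parameters it is
    independent of ``gamma``.
    """
    betas = np.atleast_2d(np.asarray(class_betas, dtype=float))
    K, P = betas.shape
    if K < 1:
        raise ConfigError("need at least one class")
    if P != dataset.n_predictors:
        raise ConfigError("class means must match the encoded predictor width")
    random_idx = _resolve_random_set(dataset.predictor_names, random_set)
    D = len(random_idx)
    ss = np.atleast_2d(np.asarray(class_sigmas, dtype=float))
    if ss.shape != (K, D):
        raise ConfigError("class sigmas must have shape (K, len(random_set))")

    if K > 1:
        if dataset.profiles is None:
            raise ConfigError("latent classes need respondent profiles")
        Z, _ = membership_design(dataset.profiles, covariates)
        gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
        if gamma.shape != (K - 1, Z.shape[1]):
            raise ConfigError("gamma must have shape (K-1, n_covariates+1)")
    else:
        Z = np.ones((dataset.n_respondents, 1))
        gamma = np.zeros((0, 1))

    draws = halton_normal_draws(dataset.n_respondents, R, D, seed, antithetic) if D else None
    theta = _pack(betas, ss, gamma)
    ll, _, _ = _mixture_eval(
        dataset.X, dataset.chosen, Z, theta, K, random_idx, draws, grad=False
    )
    return ll


@dataclass
class MMMLResult:
    """Latent-class mixed-logit fit, canonically labeled (class 0 = most
    pro-mask, i.e. the "prefer NPI" segment when two classes exist)."""

    K: int
    predictor_names: list[str]
    random_set: list[str]
    covariate_names: list[str]
    class_betas: np.ndarray  # (K,P)
    class_sigmas: np.ndarray  # (K,D), absolute values
    gamma: np.ndarray  # (K-1,C)
    se_class_betas: np.ndarray | None
    se_class_sigmas: np.ndarray | None
    se_gamma: np.ndarray | None
    cov: np.ndarray | None
    loglik: float
    shares: np.ndarray  # mean posterior per class
    prior_shares: np.ndarray  # mean membership probability per class
    posteriors: np.ndarray  # (N,K)
    respondents: np.ndarray
    n_respondents: int
    R: int
    seed: int | None
    converged: bool
    grad_norm: float
    message: str = ""

    @property
    def n_params(self) -> int:
        K, P = self.class_betas.shape
        D = self.class_sigmas.shape[1]
        return K * (P + D) + self.gamma.size

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_respondents)

    def class_result(self, c: int) -> MXLResult:
        """View one class as an MXLResult (for WTP and summaries)."""
        P = self.class_betas.shape[1]
        D = self.class_sigmas.shape[1]
        cov = None
        if self.cov is not None:
            ib = np.arange(c * P, (c + 1) * P)
            is_ = np.arange(self.K * P + c * D, self.K * P + (c + 1) * D)
            idx = np.concatenate([ib, is_])
            cov = self.cov[np.ix_(idx, idx)]
        return MXLResult(
            predictor_names=self.predictor_names,
            random_set=self.random_set,
            beta=self.class_betas[c],
            sigma=self.class_sigmas[c],
            se_beta=None if self.se_class_betas is None else self.se_class_betas[c],
            se_sigma=None if self.se_class_sigmas is None else self.se_class_sigmas[c],
            cov=cov,
            loglik=self.loglik,
            n_respondents=self.n_respondents,
            n_observations=self.n_respondents,
            R=self.R,
            seed=self.seed,
            converged=self.converged,
            grad_norm=self.grad_norm,
        )

    def summary_frame(self, level: float = 0.95) -> pd.DataFrame:
        """Per-class coefficient table (one column group per class)."""
        zcrit = stats.norm.ppf(0.5 + level / 2)
        frames = []
        for c in range(self.K):
            est = np.concatenate([self.class_betas[c], self.class_sigmas[c]])
            names = list(self.predictor_names) + [f"sd:{n}" for n in self.random_set]
            if self.se_class_betas is not None:
                se = np.concatenate([self.se_class_betas[c], self.se_class_sigmas[c]])
            else:
                se = np.full_like(est, np.nan)
            z = np.divide(est, se, out=np.full_like(est, np.nan), where=se > 0)
            frames.append(
                pd.DataFrame(
                    {
                        "class": c + 1,
                        "share": self.shares[c],
                        "term": names,
                        "coefficient": est,
                        "se": se,
                        "ci_low": est - zcrit * se,
                        "ci_high": est + zcrit * se,
                        "p_value": 2 * stats.norm.sf(np.abs(z)),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def posterior_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.posteriors, columns=[f"class_{c + 1}" for c in range(self.K)]
        )
        df.insert(0, "respondent", self.respondents)
        return df


def _relabel(betas, ss, gamma, predictor_names) -> tuple:
    """Sort classes by descending mean on the relabeling predictor and
    re-reference gamma accordingly (label-switching resolution)."""
    if RELABEL_PREDICTOR in predictor_names:
        col = predictor_names.index(RELABEL_PREDICTOR)
    else:
        col = 1 if betas.shape[1] > 1 else 0
    order = np.argsort(-betas[:, col], kind="stable")
    K, C = betas.shape[0], gamma.shape[1] if gamma.size else 1
    eta = np.vstack([np.zeros((1, gamma.shape[1])), gamma]) if K > 1 else np.zeros((1, C))
    new_gamma = (
        np.stack([eta[order[c]] - eta[order[0]] for c in range(1, K)])
        if K > 1
        else gamma
    )
    return betas[order], ss[order], new_gamma, order


def _split_start(
    dataset: ChoiceDataset,
    K: int,
    random_idx: np.ndarray,
    sigma_start: float,
    C: int,
    scale: np.ndarray,
) -> np.ndarray | None:
    """Quantile-split initialization: rank respondents by the stringency of
    their chosen alternatives (count of active NPI dummies) and fit a
    conditional logit per stratum — a cheap landing spot near the mixture
    optimum."""
    X, chosen = dataset.X, dataset.chosen
    N, T, J, P = X.shape
    binary = [p for p in range(P) if set(np.unique(X[..., p])) <= {0.0, 1.0}]
    if "asc_left" in dataset.predictor_names:
        binary = [p for p in binary if p != dataset.predictor_names.index("asc_left")]
    if not binary or N < 4 * K:
        return None
    Xch = np.take_along_axis(X, chosen[:, :, None, None], axis=2)[:, :, 0, :]
    score = Xch[:, :, binary].sum(axis=(1, 2))
    order = np.argsort(score, kind="stable")
    betas = []
    for g in np.array_split(order, K)[::-1]:  # most stringency-seeking first
        sub = ChoiceDataset(
            X=X[g], chosen=chosen[g], predictor_names=dataset.predictor_names
        )
        betas.append(
            fit_clogit(sub, gtol=1e-5, maxiter=150, compute_se=False).beta * scale
        )
    D = len(random_idx)
    ss0 = np.full((K, D), sigma_start) * scale[random_idx]
    return _pack(np.stack(betas), ss0, np.zeros((K - 1, C)))


def fit_mmml(
    dataset: ChoiceDataset,
    K: int,
    random_set: Sequence[str] = DEFAULT_RANDOM_SET,
    R: int = 500,
    seed: int | None = 0,
    covariates: Sequence[str] | None = None,
    n_starts: int = 5,
    start: np.ndarray | None = None,
    sigma_start: float = 0.5,
    gtol: float = 1e-4,
    maxiter: int = 400,
    antithetic: bool = True,
    ftol: float = 1e-10,
    compute_se: bool = True,
) -> MMMLResult:
    """Fit the K-class mixture by direct maximum simulated likelihood.

    Starts from the conditional-logit solution perturbed independently per
    class (``n_starts`` seeded restarts); the best converged run wins.  An
    estimated class share below 1e-3 triggers a degenerate-solution warning.
    ``K = 1`` runs through the same code path and reproduces the plain mixed
    logit up to optimizer tolerance.
    """
    if K < 1:
        raise ConfigError("K must be >= 1")
    X, chosen = dataset.X, dataset.chosen
    N, T, J, P = X.shape
    if K > 1 and dataset.profiles is None:
        raise ConfigError("latent classes need respondent profiles")
    random_idx = _resolve_random_set(dataset.predictor_names, random_set)
    D = len(random_idx)
    if K > 1:
        Z, cov_names = membership_design(dataset.profiles, covariates)
    else:
        Z, cov_names = np.ones((N, 1)), ["intercept"]
    C = Z.shape[1]
    if N <= K * (P + D) + (K - 1) * C:
        raise ConfigError("more parameters than respondents")

    draws = halton_normal_draws(N, R, D, seed, antithetic) if D else None
    scale = _predictor_scale(X)
    Xs = X / scale
    s_full = np.concatenate(
        [np.tile(scale, K), np.tile(scale[random_idx], K), np.ones((K - 1) * C)]
    )

    def negll_grad(theta):
        # theta lives in the unit-scaled predictor space (gamma unscaled)
        ll, g, _ = _mixture_eval(Xs, chosen, Z, theta, K, random_idx, draws)
        return -ll, -g

    rng = np.random.default_rng(seed)
    base = fit_clogit(dataset, gtol=1e-6, compute_se=False).beta * scale

    starts: list[np.ndarray] = []
    n_target = n_starts
    if start is not None:
        starts.append(np.asarray(start, dtype=float) * s_full)
        n_target += 1
    if K > 1 and len(starts) < n_target:
        split = _split_start(dataset, K, random_idx, sigma_start, C, scale)
        if split is not None:
            starts.append(split)
    j = 0
    while len(starts) < n_target:
        jitter = 0.25 if j == 0 else 0.6
        betas0 = base[None, :] + jitter * rng.standard_normal((K, P))
        ss0 = np.full((K, D), sigma_start) * scale[random_idx]
        gamma0 = np.zeros((K - 1, C))
        starts.append(_pack(betas0, ss0, gamma0))
        j += 1

    best = None
    for theta0 in starts:
        res = optimize.minimize(
            negll_grad,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "ftol": ftol},
        )
        if best is None or (-res.fun) > (-best.fun) + 1e-9:
            best = res
    res = best
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"mixture optimizer did not converge: {res.message}")

    betas, ss, gamma = _unpack(res.x, K, P, D, C)
    betas, ss, gamma, order = _relabel(betas, np.abs(ss), gamma, dataset.predictor_names)
    theta = _pack(betas, ss, gamma)  # still unit-scaled
    ll, _, post = _mixture_eval(Xs, chosen, Z, theta, K, random_idx, draws, grad=False)
    shares = post.mean(axis=0)
    logpi = _membership_logpi(Z, gamma)
    prior_shares = np.exp(logpi).mean(axis=0)
    if np.any(shares < 1e-3):
        warnings.warn("degenerate solution: a class share fell below 1e-3")

    se_b = se_s = se_g = covm = None
    if compute_se:
        covm = _covariance(lambda t: negll_grad(t)[1], theta)
        if covm is not None:
            covm = covm / np.outer(s_full, s_full)  # back to the original scale
            se = np.sqrt(np.diag(covm))
            se_b = se[: K * P].reshape(K, P)
            se_s = se[K * P : K * (P + D)].reshape(K, D)
            se_g = se[K * (P + D) :].reshape(K - 1, C) if K > 1 else None
        else:
            warnings.warn("singular Hessian: standard errors unavailable")
    betas = betas / scale
    ss = ss / scale[random_idx]

    return MMMLResult(
        K=K,
        predictor_names=list(dataset.predictor_names),
        random_set=[dataset.predictor_names[i] for i in random_idx],
        covariate_names=cov_names,
        class_betas=betas,
        class_sigmas=ss,
        gamma=gamma,
        se_class_betas=se_b,
        se_class_sigmas=se_s,
        se_gamma=se_g,
        cov=covm,
        loglik=ll,
        shares=shares,
        prior_shares=prior_shares,
        posteriors=post,
        respondents=dataset.respondents,
        n_respondents=N,
        R=R if D else 0,
        seed=seed,
        converged=converged,
        grad_norm=float(np.max(np.abs(res.jac))),
        message=str(res.message),
    )


def select_k(
    dataset: ChoiceDataset,
    k_range: Sequence[int] = (1, 2, 3),
    return_fits: bool = False,
    **fit_kwargs,
):
    """Fit every K in ``k_range`` and pick the BIC minimizer.

    Non-converged fits are excluded (with a warning), never silently chosen.
    Returns ``(best_k, table)`` — and the fits keyed by K when
    ``return_fits`` is set.
    """
    if len(k_range) == 0:
        raise ConfigError("k_range must be nonempty")
    fit_kwargs.setdefault("compute_se", False)
    rows = []
    fits: dict[int, MMMLResult] = {}
    for K in k_range:
        try:
            r = fit_mmml(dataset, K=K, **fit_kwargs)
        except (FitError, ConfigError) as e:
            warnings.warn(f"K={K} failed: {e}")
            continue
        fits[K] = r
        rows.append(
            {
                "K": K,
                "loglik": r.loglik,
                "n_params": r.n_params,
                "bic": r.bic,
                "converged": r.converged,
            }
        )
        if not r.converged:
            warnings.warn(f"K={K} did not converge; excluded from selection")
    table = pd.DataFrame(rows)
    usable = table[table["converged"]]
    if usable.empty:
        raise FitError("no class count converged")
    best_k = int(usable.loc[usable["bic"].idxmin(), "K"])
    if return_fits:
        return best_k, table, fits
    return best_k, table


def membership_odds_ratios(result: MMMLResult, level: float = 0.95) -> pd.DataFrame:
    """Odds ratios exp(gamma) of belonging to each non-reference class.

    Direction: for an indicator covariate, OR > 1 means the group coded 1
    (e.g. male) has higher odds of membership in that class than the group
    coded 0, relative to class 1.  CIs are delta-method (log scale).
    """
    if not result.converged:
        raise FitError("odds ratios require a converged fit")
    if result.se_gamma is None:
        raise FitError("standard errors unavailable; cannot form OR CIs")
    zcrit = stats.norm.ppf(0.5 + level / 2)
    rows = []
    for c in range(1, result.K):
        g = result.gamma[c - 1]
        se = result.se_gamma[c - 1]
        for name, gi, si in zip(result.covariate_names, g, se):
            rows.append(
                {
                    "class": c + 1,
                    "covariate": name,
                    "odds_ratio": np.exp(gi),
                    "ci_low": np.exp(gi - zcrit * si),
                    "ci_high": np.exp(gi + zcrit * si),
                    "p_value": 2 * stats.norm.sf(abs(gi / si)) if si > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
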