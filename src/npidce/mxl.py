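"""Conditional-logit and mixed-logit estimation by maximum simulated likelihood.

The mixed logit (random-coefficients logit) treats each respondent's taste
vector as ``beta_i = beta + eta_i`` with ``eta_i ~ Normal(0, diag(sigma^2))``
on a configurable subset of predictors.  The panel likelihood of respondent
``i`` integrates the product of conditional-logit task probabilities over
``eta_i``; the integral is simulated with scrambled-Halton normal draws
(antithetic by default), one fixed block of draws per respondent held
constant throughout optimization so the simulated likelihood is a smooth,
deterministic function of the parameters.

The heterogeneity scales enter the likelihood through their absolute value,
so the simulated log-likelihood is exactly invariant to the sign of any
sigma entry and estimates are reported as |sigma|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc

from .errors import ConfigError
from .simulate import ChoiceDataset

__all__ = [
    "DEFAULT_RANDOM_SET",
    "halton_normal_draws",
    "clogit_loglik",
    "mxl_loglik",
    "fit_clogit",
    "fit_mxl",
    "MXLResult",
]

#: Predictors carrying individual-level heterogeneity by default: the five
#: NPI levels with clear taste dispersion in the motivating survey.
DEFAULT_RANDOM_SET: tuple[str, ...] = (
    "masks:mandatory_public",
    "masks:mandatory_indoors",
    "dining:not_allowed",
    "quarantine:government_facility",
    "booster:compulsory",
)


def halton_normal_draws(
    n_respondents: int,
    n_draws: int,
    n_dims: int,
    seed: int | None = None,
    antithetic: bool = True,
) -> np.ndarray:
    """Standard-normal quasi-random draws, shape (N, R, D).

    Scrambled Halton points mapped through the normal quantile function.
    With ``antithetic=True`` the second half of each respondent's block is
    the negation of the first, and an odd ``n_draws`` is rounded up to even.
    """
    if n_draws < 1:
        raise ConfigError("need at least one draw")
    if n_dims == 0:
        return np.zeros((n_respondents, n_draws, 0))
    rng = np.random.default_rng(seed)
    if antithetic:
        half = (n_draws + 1) // 2
        pts = qmc.Halton(d=n_dims, scramble=True, seed=rng).random(n_respondents * half)
        z = stats.norm.ppf(np.clip(pts, 1e-12, 1 - 1e-12))
        z = z.reshape(n_respondents, half, n_dims)
        return np.concatenate([z, -z], axis=1)
    pts = qmc.Halton(d=n_dims, scramble=True, seed=rng).random(n_respondents * n_draws)
    z = stats.norm.ppf(np.clip(pts, 1e-12, 1 - 1e-12))
    return z.reshape(n_respondents, n_draws, n_dims)


def _respondent_loglik(
    X: np.ndarray,
    chosen: np.ndarray,
    beta: np.ndarray,
    s: np.ndarray,
    random_idx: np.ndarray,
    draws: np.ndarray | None,
    grad: bool = False,
    target_chunk: float = 4e6,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-respondent simulated panel log-likelihood and its gradient.

    Returns ``l_n`` (N,) — log of the draw-averaged product of task choice
    probabilities — and, if requested, ``G`` (N, P+D) with the gradient of
    ``l_n`` with respect to (beta, s).  Heterogeneity scales are folded
    through |s|; the chain rule supplies sign(s) on the way out.
    """
    N, T, J, P = X.shape
    D = len(random_idx)
    sabs = np.abs(s)
    R = draws.shape[1] if D else 1
    l_n = np.empty(N)
    G = np.empty((N, P + D)) if grad else None

    if J == 2:
        # binary tasks: work with utility differences and the logistic CDF
        Xd = X[:, :, 0, :] - X[:, :, 1, :]  # (N,T,P)
        sgn = 1.0 - 2.0 * chosen  # +1 if first alternative chosen
        step = max(1, int(target_chunk // max(R * T, 1)))
        for i0 in range(0, N, step):
            sl = slice(i0, min(i0 + step, N))
            Xc = Xd[sl]
            sg = sgn[sl]
            dV = Xc @ beta  # (n,T)
            if D:
                Xr = np.ascontiguousarray(Xc[..., random_idx])
                eta = draws[sl] * sabs
                # batched BLAS: (n,R,D) @ (n,D,T) -> (n,R,T)
                a = sg[:, None, :] * (dV[:, None, :] + eta @ Xr.transpose(0, 2, 1))
            else:
                a = (sg * dV)[:, None, :]
            logp = -np.logaddexp(0.0, -a)  # log prob of the chosen alternative
            l_nr = logp.sum(axis=2)  # (n,R)
            mx = l_nr.max(axis=1)
            l_n[sl] = mx + np.log(np.exp(l_nr - mx[:, None]).mean(axis=1))
            if grad:
                w = np.exp(l_nr - l_n[sl][:, None]) / l_nr.shape[1]
                coef = w[:, :, None] * (-np.expm1(logp)) * sg[:, None, :]  # (n,R,T)
                # X does not depend on the draw: sum coef over draws first
                G[sl, :P] = np.einsum("ntp,nt->np", Xc, coef.sum(axis=1))
                if D:
                    Cd = draws[sl].transpose(0, 2, 1) @ coef  # (n,D,T)
                    G[sl, P:] = np.einsum("ntd,ndt->nd", Xr, Cd)
        if grad and D:
            G[:, P:] *= np.sign(s)
        return l_n, G

    step = max(1, int(target_chunk // max(R * T * J, 1)))
    for i0 in range(0, N, step):
        sl = slice(i0, min(i0 + step, N))
        Xc = X[sl]
        ch = chosen[sl]
        n = Xc.shape[0]
        V = Xc @ beta  # (n,T,J)
        if D:
            Xr = np.ascontiguousarray(Xc[..., random_idx])
            eta = draws[sl] * sabs  # (n,R,D)
            U = V[:, None] + np.einsum("ntjd,nrd->nrtj", Xr, eta)
        else:
            U = V[:, None]
        m = U.max(axis=3, keepdims=True)
        ex = np.exp(U - m)
        den = ex.sum(axis=3)
        Uch = np.take_along_axis(
            U, np.broadcast_to(ch[:, None, :, None], (n, U.shape[1], T, 1)), axis=3
        )[..., 0]
        logp = Uch - m[..., 0] - np.log(den)  # (n,R,T)
        l_nr = logp.sum(axis=2)  # (n,R)
        mx = l_nr.max(axis=1)
        l_n[sl] = mx + np.log(np.exp(l_nr - mx[:, None]).mean(axis=1))
        if grad:
            w = np.exp(l_nr - l_n[sl][:, None]) / l_nr.shape[1]  # (n,R)
            prob = ex / den[..., None]
            oh = np.zeros((n, 1, T, J))
            np.put_along_axis(oh, ch[:, None, :, None], 1.0, axis=3)
            A = (oh - prob) * w[:, :, None, None]  # (n,R,T,J)
            G[sl, :P] = np.einsum("ntjp,nrtj->np", Xc, A)
            if D:
                Bm = np.einsum("ntjd,nrtj->nrd", Xr, A)
                G[sl, P:] = (Bm * draws[sl]).sum(axis=1)
    if grad and D:
        G[:, P:] *= np.sign(s)
    return l_n, G


def _check_beta(dataset: ChoiceDataset, beta) -> np.ndarray:
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (dataset.n_predictors,):
        raise ConfigError(
            f"beta must have length {dataset.n_predictors}, got {beta.shape}"
        )
    return beta


def clogit_loglik(dataset: ChoiceDataset, beta) -> float:
    """Conditional-logit log-likelihood: sum over chosen alternatives of the
    within-task log softmax utility."""
    beta = _check_beta(dataset, beta)
    l_n, _ = _respondent_loglik(
        dataset.X, dataset.chosen, beta, np.empty(0), np.empty(0, dtype=int), None
    )
    return float(l_n.sum())


def _resolve_random_set(
    predictor_names: Sequence[str], random_set: Sequence[str]
) -> np.ndarray:
    idx = []
    for name in random_set:
        if name not in predictor_names:
            raise ConfigError(f"random-set predictor {name!r} not in the design")
        idx.append(predictor_names.index(name))
    return np.asarray(sorted(idx), dtype=int)


def mxl_loglik(
    dataset: ChoiceDataset,
    beta,
    sigma,
    random_set: Sequence[str] = DEFAULT_RANDOM_SET,
    R: int = 500,
    seed: int | None = None,
    antithetic: bool = True,
    draws: np.ndarray | None = None,
) -> float:
    """Simulated mixed-logit log-likelihood at fixed parameters.

    ``sigma`` lists heterogeneity SDs in the (predictor-order sorted)
    ``random_set`` order.  Deterministic given ``(R, seed, antithetic)``;
    with ``sigma = 0`` it equals :func:`clogit_loglik` exactly.
    """
    beta = _check_beta(dataset, beta)
    random_idx = _resolve_random_set(dataset.predictor_names, random_set)
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (len(random_idx),):
        raise ConfigError("sigma must match the random set length")
    if draws is None:
        draws = halton_normal_draws(
            dataset.n_respondents, R, len(random_idx), seed, antithetic
        )
    l_n, _ = _respondent_loglik(
        dataset.X, dataset.chosen, beta, sigma, random_idx, draws
    )
    return float(l_n.sum())


# ---------------------------------------------------------------------------
# results container


@dataclass
class MXLResult:
    """Mixed-logit (or conditional-logit, when ``random_set`` is empty) fit."""

    predictor_names: list[str]
    random_set: list[str]
    beta: np.ndarray
    sigma: np.ndarray  # |sigma|, random-set order
    se_beta: np.ndarray | None
    se_sigma: np.ndarray | None
    cov: np.ndarray | None  # joint covariance of (beta, sigma)
    loglik: float
    n_respondents: int
    n_observations: int
    R: int
    seed: int | None
    converged: bool
    grad_norm: float
    trace: list[float] = field(default_factory=list)
    message: str = ""

    @property
    def n_params(self) -> int:
        return len(self.beta) + len(self.sigma)

    @property
    def bic(self) -> float:
        """−2·LL + p·ln(respondents)."""
        return -2.0 * self.loglik + self.n_params * np.log(self.n_respondents)

    def _stack(self) -> tuple[np.ndarray, np.ndarray | None, list[str]]:
        est = np.concatenate([self.beta, self.sigma])
        se = (
            np.concatenate([self.se_beta, self.se_sigma])
            if self.se_beta is not None
            else None
        )
        names = list(self.predictor_names) + [f"sd:{n}" for n in self.random_names]
        return est, se, names

    @property
    def random_names(self) -> list[str]:
        idx = _resolve_random_set(self.predictor_names, self.random_set)
        return [self.predictor_names[i] for i in idx]

    def summary_frame(self, level: float = 0.95) -> pd.DataFrame:
        """Coefficients, Wald CIs and p-values, means first then SD terms."""
        est, se, names = self._stack()
        zcrit = stats.norm.ppf(0.5 + level / 2)
        if se is None:
            se = np.full_like(est, np.nan)
        z = np.divide(est, se, out=np.full_like(est, np.nan), where=se > 0)
        return pd.DataFrame(
            {
                "term": names,
                "coefficient": est,
                "se": se,
                "ci_low": est - zcrit * se,
                "ci_high": est + zcrit * se,
                "p_value": 2 * stats.norm.sf(np.abs(z)),
            }
        )


# ---------------------------------------------------------------------------
# fitting


def _predictor_scale(X: np.ndarray) -> np.ndarray:
    """Per-predictor scale (max |value|) used to condition the optimizer.

    Dummy predictors stay at 1; a money predictor in tens of SGD is shrunk
    to unit range.  Estimates and covariances are mapped back afterwards, so
    scaling is invisible to callers.
    """
    s = np.abs(X).max(axis=(0, 1, 2))
    s[s == 0] = 1.0
    return s


def _numerical_hessian(gfun, theta: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite differences of an analytic gradient."""
    k = len(theta)
    H = np.empty((k, k))
    for i in range(k):
        h = rel_step * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tp[i] += h
        tm = theta.copy()
        tm[i] -= h
        H[:, i] = (gfun(tp) - gfun(tm)) / (2 * h)
    return 0.5 * (H + H.T)


def _covariance(neg_grad_fun, theta: np.ndarray) -> np.ndarray | None:
    H = _numerical_hessian(neg_grad_fun, theta)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    d = np.diag(cov)
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        return None
    return cov


def fit_clogit(
    dataset: ChoiceDataset,
    start: np.ndarray | None = None,
    gtol: float = 1e-7,
    maxiter: int = 300,
    compute_se: bool = True,
) -> MXLResult:
    """Maximum-likelihood conditional logit (the sigma = 0 special case)."""
    return fit_mxl(
        dataset,
        random_set=(),
        R=1,
        seed=0,
        start=start,
        gtol=gtol,
        maxiter=maxiter,
        compute_se=compute_se,
    )


def fit_mxl(
    dataset: ChoiceDataset,
    random_set: Sequence[str] = DEFAULT_RANDOM_SET,
    R: int = 500,
    seed: int | None = 0,
    start: np.ndarray | None = None,
    sigma_start: float = 0.5,
    gtol: float = 1e-5,
    maxiter: int = 500,
    antithetic: bool = True,
    ftol: float = 1e-10,
    compute_se: bool = True,
) -> MXLResult:
    """Maximum simulated likelihood mixed logit from a conditional-logit
    warm start.

    One scrambled-Halton draw block per respondent is generated once and
    held fixed; the optimizer is L-BFGS with the analytic gradient of the
    simulated likelihood.  Standard errors come from the inverse numerical
    Hessian at the optimum; a singular Hessian is flagged (``se_beta`` is
    ``None``) rather than silently dropped.
    """
    X, chosen = dataset.X, dataset.chosen
    N, T, J, P = X.shape
    random_idx = _resolve_random_set(dataset.predictor_names, random_set)
    D = len(random_idx)
    scale = _predictor_scale(X)
    s_full = np.concatenate([scale, scale[random_idx]])
    Xs = X / scale
    draws = halton_normal_draws(N, R, D, seed, antithetic) if D else None

    def negll_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        # theta lives in the unit-scaled predictor space
        l_n, G = _respondent_loglik(
            Xs, chosen, theta[:P], theta[P:], random_idx, draws, grad=True
        )
        return -float(l_n.sum()), -G.sum(axis=0)

    if start is None:
        if D:
            warm = fit_mxl(
                dataset, random_set=(), R=1, seed=0, gtol=1e-6,
                maxiter=maxiter, compute_se=False,
            )
            theta0 = np.concatenate(
                [warm.beta * scale, np.full(D, sigma_start) * scale[random_idx]]
            )
        else:
            theta0 = np.zeros(P)
    else:
        theta0 = np.asarray(start, dtype=float)
        if theta0.shape != (P + D,):
            raise ConfigError(f"start must have length {P + D}")
        theta0 = theta0 * s_full

    trace: list[float] = []

    def cb(intermediate_result) -> None:
        trace.append(-float(intermediate_result.fun))

    res = optimize.minimize(
        negll_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        callback=cb,
        options={"maxiter": maxiter, "gtol": gtol, "ftol": ftol},
    )
    theta = res.x
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"mixed-logit optimizer did not converge: {res.message}")

    se_beta = se_sigma = cov = None
    if compute_se:
        cov = _covariance(lambda t: negll_grad(t)[1], theta)
        if cov is not None:
            cov = cov / np.outer(s_full, s_full)  # back to the original scale
            se = np.sqrt(np.diag(cov))
            se_beta, se_sigma = se[:P], se[P:]
        else:
            warnings.warn("singular Hessian: standard errors unavailable")

    return MXLResult(
        predictor_names=list(dataset.predictor_names),
        random_set=[dataset.predictor_names[i] for i in random_idx],
        beta=theta[:P] / scale,
        sigma=np.abs(theta[P:]) / scale[random_idx],
        se_beta=se_beta,
        se_sigma=se_sigma,
        cov=cov,
        loglik=-res.fun,
        n_respondents=N,
        n_observations=N * T,
        R=R if D else 0,
        seed=seed,
        converged=converged,
        grad_norm=grad_norm,
        trace=trace,
        message=str(res.message),
    )
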