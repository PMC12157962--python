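import numpy as np
import pytest
from scipy.special import roots_hermitenorm

import npidce as n
from conftest import TABLE3_BETA, sigma_vector
from npidce.mxl import halton_normal_draws


def brute_force_clogit(dataset, beta):
    """Independent oracle: explicit product of softmax terms."""
    total = 0.0
    for i in range(dataset.n_respondents):
        for t in range(dataset.n_tasks):
            u = dataset.X[i, t] @ beta
            p = np.exp(u - u.max())
            p /= p.sum()
            total += np.log(p[dataset.chosen[i, t]])
    return total


def gauss_hermite_loglik(dataset, beta, sigma, random_index, n_nodes=80):
    """Quadrature oracle for a single random coefficient: integrates the
    panel probability against the standard normal weight exactly."""
    nodes, wts = roots_hermitenorm(n_nodes)
    wts = wts / np.sqrt(2 * np.pi)
    total = 0.0
    for i in range(dataset.n_respondents):
        vals = np.empty(len(nodes))
        for k, z in enumerate(nodes):
            b = beta.copy()
            b[random_index] += sigma * z
            lp = 0.0
            for t in range(dataset.n_tasks):
                u = dataset.X[i, t] @ b
                p = np.exp(u - u.max())
                p /= p.sum()
                lp += np.log(p[dataset.chosen[i, t]])
            vals[k] = np.exp(lp)
        total += np.log(np.dot(wts, vals))
    return total


class TestClogitLoglik:
    def test_zero_beta_binary_tasks(self, homogeneous_dataset):
        N = homogeneous_dataset.n_observations
        ll = n.clogit_loglik(homogeneous_dataset, np.zeros(12))
        assert ll == pytest.approx(-N * np.log(2), abs=1e-9)

    def test_matches_brute_force_product(self, homogeneous_dataset):
        rng = np.random.default_rng(0)
        tiny = n.ChoiceDataset(
            X=homogeneous_dataset.X[:1, :3],
            chosen=homogeneous_dataset.chosen[:1, :3],
            predictor_names=homogeneous_dataset.predictor_names,
        )
        for _ in range(5):
            beta = rng.normal(scale=0.7, size=12)
            assert n.clogit_loglik(tiny, beta) == pytest.approx(
                brute_force_clogit(tiny, beta), abs=1e-12
            )

    def test_perfect_separation_limit(self, space):
        """A huge coefficient on a dummy present only in chosen alternatives
        drives the log-likelihood to zero from below."""
        p_ref = int(space.profile_index(np.zeros(7, dtype=int)))
        p_alt = int(space.profile_index(np.array([1, 0, 0, 0, 0, 0, 0])))
        design = n.ChoiceDesign(space=space, profiles=np.array([[[p_alt, p_ref]]]))
        X = design.encoded()[None, 0]
        ds = n.ChoiceDataset(
            X=X, chosen=np.zeros((1, 1), dtype=int), predictor_names=space.predictor_names
        )
        beta = np.zeros(12)
        beta[1] = 50.0
        ll = n.clogit_loglik(ds, beta)
        assert -1e-3 < ll < 0


class TestMxlLoglik:
    def test_sigma_zero_equals_clogit(self, heterogeneous_dataset):
        beta = TABLE3_BETA
        for R in (1, 7, 40):
            sim = n.mxl_loglik(
                heterogeneous_dataset, beta, np.zeros(5), R=R, seed=3
            )
            assert sim == pytest.approx(
                n.clogit_loglik(heterogeneous_dataset, beta), abs=1e-9
            )

    def test_matches_gauss_hermite(self, heterogeneous_dataset):
        """One random coefficient on a small panel: simulated value agrees
        with deterministic quadrature."""
        ds = n.ChoiceDataset(
            X=heterogeneous_dataset.X[:4],
            chosen=heterogeneous_dataset.chosen[:4],
            predictor_names=heterogeneous_dataset.predictor_names,
        )
        beta = TABLE3_BETA
        idx = ds.predictor_names.index("masks:mandatory_public")
        oracle = gauss_hermite_loglik(ds, beta, 0.8, idx)
        sim = n.mxl_loglik(
            ds, beta, np.array([0.8]), random_set=("masks:mandatory_public",),
            R=2000, seed=4,
        )
        assert sim == pytest.approx(oracle, abs=1e-3)

    def test_sign_invariance_exact(self, heterogeneous_dataset):
        beta = TABLE3_BETA
        s = np.array([0.5, -0.3, 0.7, -0.2, 0.4])
        a = n.mxl_loglik(heterogeneous_dataset, beta, s, R=30, seed=5)
        b = n.mxl_loglik(heterogeneous_dataset, beta, np.abs(s), R=30, seed=5)
        assert a == b

    def test_deterministic_given_seed(self, heterogeneous_dataset):
        args = (TABLE3_BETA, 0.8 * np.ones(5))
        a = n.mxl_loglik(heterogeneous_dataset, *args, R=50, seed=6)
        b = n.mxl_loglik(heterogeneous_dataset, *args, R=50, seed=6)
        assert a == b

    def test_draw_count_convergence(self, heterogeneous_dataset):
        """Simulated value approaches a large-R reference as R grows."""
        ds = n.ChoiceDataset(
            X=heterogeneous_dataset.X[:30],
            chosen=heterogeneous_dataset.chosen[:30],
            predictor_names=heterogeneous_dataset.predictor_names,
        )
        args = (TABLE3_BETA, 0.8 * np.ones(5))
        ref = n.mxl_loglik(ds, *args, R=20_000, seed=7)
        errs = [
            abs(n.mxl_loglik(ds, *args, R=R, seed=7) - ref) for R in (50, 500, 5000)
        ]
        assert errs[2] < errs[0] and errs[2] < 0.01

    def test_location_invariance(self, homogeneous_dataset):
        """Adding any constant vector to every alternative of each task
        leaves the choice likelihood unchanged."""
        ds = homogeneous_dataset
        shift = np.linspace(-1, 1, 12)
        X2 = ds.X + shift  # same shift for both alternatives of every task
        ds2 = n.ChoiceDataset(X=X2, chosen=ds.chosen, predictor_names=ds.predictor_names)
        beta = TABLE3_BETA
        assert n.clogit_loglik(ds2, beta) == pytest.approx(
            n.clogit_loglik(ds, beta), abs=1e-8
        )

    def test_invalid_draw_count(self, heterogeneous_dataset):
        with pytest.raises(n.ConfigError):
            halton_normal_draws(5, 0, 2)


class TestFitMxl:
    def test_clogit_recovers_homogeneous_truth(self, homogeneous_dataset):
        res = n.fit_clogit(homogeneous_dataset)
        assert res.converged
        # 750 binary tasks: loose sampling bound on the mean absolute error
        assert np.abs(res.beta - TABLE3_BETA).mean() < 0.2

    def test_sigma_constrained_mxl_equals_clogit(self, homogeneous_dataset):
        a = n.fit_clogit(homogeneous_dataset, compute_se=False)
        b = n.fit_mxl(homogeneous_dataset, random_set=(), compute_se=False)
        assert b.loglik == pytest.approx(a.loglik, abs=1e-6)
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-5)

    def test_optimizer_trace_monotone(self, heterogeneous_dataset):
        res = n.fit_mxl(
            heterogeneous_dataset, R=50, seed=8, maxiter=60, compute_se=False
        )
        assert np.all(np.diff(res.trace) >= -1e-6)

    def test_fee_rescaling_equivariance(self, homogeneous_dataset):
        """Multiplying the fee predictor by k divides its coefficient by k
        and leaves WTP unchanged."""
        ds = homogeneous_dataset
        k = 10.0
        X2 = ds.X.copy()
        X2[..., -1] *= k
        ds2 = n.ChoiceDataset(X=X2, chosen=ds.chosen, predictor_names=ds.predictor_names)
        r1 = n.fit_clogit(ds, compute_se=False)
        r2 = n.fit_clogit(ds2, compute_se=False)
        assert r2.beta[-1] == pytest.approx(r1.beta[-1] / k, rel=1e-3)
        # WTP in original SGD: the rescaled fit quotes fee per 1/k SGD
        wtp1 = r1.beta[1] / abs(r1.beta[-1])
        wtp2 = r2.beta[1] / abs(r2.beta[-1]) / k
        assert wtp2 == pytest.approx(wtp1, rel=1e-3)

    def test_summary_frame_layout(self, homogeneous_dataset):
        res = n.fit_clogit(homogeneous_dataset)
        frame = res.summary_frame()
        assert list(frame["term"]) == homogeneous_dataset.predictor_names
        np.testing.assert_allclose(
            frame["ci_high"] - frame["ci_low"], 2 * 1.959964 * frame["se"], rtol=1e-6
        )

    def test_mismatched_start_rejected(self, homogeneous_dataset):
        with pytest.raises(n.ConfigError):
            n.fit_mxl(homogeneous_dataset, random_set=(), start=np.zeros(3))
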