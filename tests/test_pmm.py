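"""Gibbs sampler, heritability, DIC and model enumeration."""

import numpy as np
import pandas as pd
import pytest

from harelink import phylo, pmm, simulate
from harelink.errors import TransformError, ValidationError

SMALL = dict(iterations=6000, burn_in=1000, thin=5)


@pytest.fixture(scope="module")
def small_problem():
    rng = np.random.default_rng(0)
    n = 50
    X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
    beta = np.array([1.0, 0.5, -0.5])
    y = X @ beta + rng.standard_normal(n)
    return y, X


class TestDesignMatrix:
    def test_log_transforms(self):
        table = pd.DataFrame(
            {"species": ["a", "b"], "sgs": [0.0, np.e - 1],
             "density": [1.0, 1.0], "ei": [2.0, 2.0], "area": [3.0, 3.0]}
        )
        spec = pmm.ModelSpec(predictors=("density", "ei", "area"))
        y, X, names = pmm.design_matrix(table, spec)
        assert y[0] == pytest.approx(0.0) and y[1] == pytest.approx(1.0)
        assert np.allclose(X[:, 1], 0.0)  # log(1)
        assert names == ["intercept", "density", "ei", "area"]

    def test_nonpositive_predictor_names_species(self):
        table = pd.DataFrame(
            {"species": ["ok", "bad"], "sgs": [1.0, 1.0], "density": [1.0, -2.0]}
        )
        with pytest.raises(TransformError, match="bad"):
            pmm.design_matrix(table, pmm.ModelSpec(predictors=("density",)))

    def test_missing_values_rejected(self):
        table = pd.DataFrame(
            {"species": ["a", "b"], "sgs": [1.0, np.nan], "density": [1.0, 1.0]}
        )
        with pytest.raises(ValidationError, match="b"):
            pmm.design_matrix(table, pmm.ModelSpec(predictors=("density",)))


class TestGibbsSampler:
    def test_conjugate_oracle_fixed_variance(self, small_problem):
        """With fixed residual variance and no random effect the posterior is
        the closed-form Bayesian regression posterior."""
        y, X = small_problem
        spec = pmm.ModelSpec(predictors=("x1", "x2"), include_phylogeny=False,
                             seed=3, fixed_variances=(0.0, 1.0), **SMALL)
        post = pmm.gibbs_sample(y, X, None, spec)
        bhat = np.linalg.solve(X.T @ X, X.T @ y)
        cov = np.linalg.inv(X.T @ X)
        mc_se = post.beta.std(axis=0) / np.sqrt(post.n_draws)
        assert np.all(np.abs(post.beta.mean(axis=0) - bhat) < 3 * mc_se)
        assert np.allclose(post.beta.std(axis=0), np.sqrt(np.diag(cov)), rtol=0.1)

    def test_deterministic_given_seed(self, small_problem):
        y, X = small_problem
        spec = pmm.ModelSpec(predictors=("x1", "x2"), include_phylogeny=False,
                             seed=9, iterations=2000, burn_in=200, thin=2)
        p1 = pmm.gibbs_sample(y, X, None, spec)
        p2 = pmm.gibbs_sample(y, X, None, spec)
        assert np.array_equal(p1.beta, p2.beta)
        assert np.array_equal(p1.sigma2_e, p2.sigma2_e)

    def test_retained_draw_count(self, small_problem):
        y, X = small_problem
        spec = pmm.ModelSpec(predictors=("x1", "x2"), include_phylogeny=False,
                             seed=1, iterations=5000, burn_in=1000, thin=10)
        post = pmm.gibbs_sample(y, X, None, spec)
        assert post.n_draws == 400

    def test_joint_permutation_invariance(self):
        """Permuting rows of (y, X, R) jointly leaves summaries unchanged
        within Monte-Carlo error (exchangeability of the likelihood)."""
        tree = simulate.simulate_yule_tree(40, 1.0, 5)
        R = phylo.vcv_to_correlation(phylo.phylo_vcv(tree)).matrix
        rng = np.random.default_rng(5)
        n = 40
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        L = np.linalg.cholesky(R + 1e-10 * np.eye(n))
        y = X @ [1.0, 0.5] + 0.5 * (L @ rng.standard_normal(n)) + 0.5 * rng.standard_normal(n)
        spec = pmm.ModelSpec(predictors=("x",), seed=2, **SMALL)
        post = pmm.gibbs_sample(y, X, R, spec)
        perm = rng.permutation(n)
        post_p = pmm.gibbs_sample(y[perm], X[perm], R[np.ix_(perm, perm)],
                                  pmm.ModelSpec(predictors=("x",), seed=22, **SMALL))
        se = post.beta.std(axis=0) / 8  # generous MC tolerance
        assert np.all(np.abs(post.beta.mean(0) - post_p.beta.mean(0)) < 6 * se)

    def test_non_pd_matrix_rejected(self, small_problem):
        y, X = small_problem
        R = np.ones((len(y), len(y)))  # rank 1
        with pytest.raises(ValidationError, match="positive definite"):
            pmm.gibbs_sample(y, X, R, pmm.ModelSpec(predictors=("x1", "x2"), seed=0, **SMALL))

    def test_null_phylogenetic_signal_h2_near_zero(self):
        tree = simulate.simulate_yule_tree(100, 1.0, 8)
        R = phylo.vcv_to_correlation(phylo.phylo_vcv(tree)).matrix
        rng = np.random.default_rng(8)
        n = 100
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)  # beta = 0, s2p = 0
        spec = pmm.ModelSpec(predictors=("x",), seed=88, **SMALL)
        post = pmm.gibbs_sample(y, X, R, spec)
        assert post.h2.mean() < 0.15

    def test_no_phylogeny_h2_is_zero(self, small_problem):
        y, X = small_problem
        spec = pmm.ModelSpec(predictors=("x1", "x2"), include_phylogeny=False,
                             seed=4, **SMALL)
        post = pmm.gibbs_sample(y, X, None, spec)
        assert np.all(post.h2 == 0.0)
        assert np.all(post.sigma2_e > 0)


class TestHeritability:
    def test_equal_variances_give_half(self):
        post = pmm.PmmPosterior(
            beta=np.zeros((200, 1)), sigma2_p=np.ones(200), sigma2_e=np.ones(200),
            h2=np.full(200, 0.5), predictor_names=["b0"],
            spec=pmm.ModelSpec(),
        )
        mean, (lo, hi) = pmm.heritability(post)
        assert mean == 0.5 and lo == 0.5 and hi == 0.5

    def test_few_draws_warn(self):
        post = pmm.PmmPosterior(
            beta=np.zeros((10, 1)), sigma2_p=np.ones(10), sigma2_e=np.ones(10),
            h2=np.full(10, 0.5), predictor_names=["b0"], spec=pmm.ModelSpec(),
        )
        with pytest.warns(UserWarning, match="retained draws"):
            pmm.heritability(post)

    def test_hpd_narrowest_interval(self):
        rng = np.random.default_rng(1)
        draws = np.concatenate([rng.normal(0, 0.1, 950), rng.normal(8, 0.1, 50)])
        lo, hi = pmm.hpd_interval(draws, 0.95)
        assert hi < 1.0  # excludes the remote 5% cluster

    def test_hpd_narrower_than_central_interval(self):
        rng = np.random.default_rng(2)
        draws = rng.gamma(2.0, 1.0, 5000)  # skewed
        lo, hi = pmm.hpd_interval(draws, 0.9)
        qlo, qhi = np.quantile(draws, [0.05, 0.95])
        assert (hi - lo) <= (qhi - qlo) + 1e-9


class TestDic:
    def test_identical_draws_zero_pd(self, small_problem):
        y, X = small_problem
        m = 50
        post = pmm.PmmPosterior(
            beta=np.tile([1.0, 0.5, -0.5], (m, 1)), sigma2_p=np.zeros(m),
            sigma2_e=np.ones(m), h2=np.zeros(m),
            predictor_names=["b0", "b1", "b2"], spec=pmm.ModelSpec(),
        )
        d, pd_eff, skipped = pmm.dic(post, y, X, None)
        assert pd_eff == pytest.approx(0.0, abs=1e-8)
        assert skipped == 0

    def test_intercept_only_preferred_on_null_data(self):
        """On pure-noise data the simpler model should usually win DIC."""
        wins = 0
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            n = 60
            table = pd.DataFrame(
                {
                    "species": [f"s{i}" for i in range(n)],
                    "sgs": np.abs(rng.standard_normal(n)),
                    "density": np.exp(rng.standard_normal(n)),
                    "ei": np.exp(rng.standard_normal(n)),
                    "area": np.exp(rng.standard_normal(n)),
                }
            )
            spec = pmm.ModelSpec(seed=seed, include_phylogeny=False,
                                 iterations=4000, burn_in=500, thin=5)
            y0, X0, _ = pmm.design_matrix(table, pmm.ModelSpec(predictors=(), seed=seed))
            p0 = pmm.gibbs_sample(y0, X0, None,
                                  pmm.ModelSpec(predictors=(), include_phylogeny=False,
                                                seed=seed, iterations=4000, burn_in=500, thin=5))
            y3, X3, _ = pmm.design_matrix(table, spec)
            p3 = pmm.gibbs_sample(y3, X3, None, spec)
            wins += p0.dic <= p3.dic
        assert wins >= 4


class TestEnumerateModels:
    def test_enumeration_count_and_ranking(self):
        rng = np.random.default_rng(0)
        n = 40
        table = pd.DataFrame(
            {
                "species": [f"s{i}" for i in range(n)],
                "sgs": np.abs(rng.standard_normal(n)),
                "density": np.exp(rng.standard_normal(n)),
                "ei": np.exp(rng.standard_normal(n)),
                "area": np.exp(rng.standard_normal(n)),
            }
        )
        spec = pmm.ModelSpec(seed=1, include_phylogeny=False,
                             iterations=3000, burn_in=500, thin=5)
        rank = pmm.enumerate_models(table, ["density", "ei", "area"], None, spec)
        assert len(rank.table) == 8
        assert rank.table["delta_dic"].iloc[0] == pytest.approx(0.0)
        assert rank.table["competing"].iloc[0]
        assert (rank.table["dic"].diff().dropna() >= -1e-9).all()

    def test_duplicate_predictor_tie_broken_by_size(self):
        rng = np.random.default_rng(3)
        n = 40
        x = np.exp(rng.standard_normal(n))
        table = pd.DataFrame(
            {
                "species": [f"s{i}" for i in range(n)],
                "sgs": np.abs(rng.standard_normal(n)),
                "p1": x, "p2": x,  # identical columns
            }
        )
        spec = pmm.ModelSpec(seed=2, include_phylogeny=False,
                             iterations=3000, burn_in=500, thin=5)
        rank = pmm.enumerate_models(table, ["p1", "p2"], None, spec)
        # among near-tied models the smaller wins on equal DIC; table stays complete
        assert len(rank.table) == 4
        assert set(rank.table["model"]) == {"intercept", "p1", "p2", "p1+p2"}
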