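"""Nested-model fitting and testing against hand derivations and oracles."""

import numpy as np
import pytest
from scipy import stats

from idas.datatypes import ObservationDesign
from idas.models import (
    THREE_WAY_SPECS,
    TWO_WAY_SPECS,
    ModelSpec,
    design_matrix,
    f_statistic_nested,
    f_test_nested,
    fit_fixed,
    fit_mixed,
    lrt_nested,
    spec,
)

from conftest import random_design


def oracle_ols(X, y):
    """Independent least-squares oracle: explicit pseudo-inverse + direct RSS."""
    beta = np.linalg.pinv(X) @ y
    r = y - X @ beta
    return float(r @ r), int(np.linalg.matrix_rank(X))


class TestModelSpec:
    def test_interaction_requires_marginals(self):
        with pytest.raises(ValueError, match="marginal"):
            ModelSpec(frozenset({"f1:f2"}))

    def test_three_way_requires_all_lower_terms(self):
        with pytest.raises(ValueError, match="marginal"):
            spec("f1", "f2", "f3", "f1:f2", "f1:f2:f3")

    def test_nesting_relation(self):
        assert TWO_WAY_SPECS["null"].is_nested_in(TWO_WAY_SPECS["full"])
        assert not TWO_WAY_SPECS["f1_only"].is_nested_in(TWO_WAY_SPECS["f2_only"])
        assert not TWO_WAY_SPECS["full"].is_nested_in(THREE_WAY_SPECS["full"])


class TestFixedFits:
    def test_hand_2x2_full(self, y_2x2, design_2x2):
        fit = fit_fixed(y_2x2, design_2x2, TWO_WAY_SPECS["full"])
        assert fit.rss == pytest.approx(8.0, abs=1e-10)
        assert fit.df_resid == 4

    def test_hand_2x2_additive_interaction_ss_zero(self, y_2x2, design_2x2):
        fit = fit_fixed(y_2x2, design_2x2, TWO_WAY_SPECS["additive"])
        assert fit.rss == pytest.approx(8.0, abs=1e-10)
        assert fit.df_resid == 5

    def test_hand_2x2_f1_only(self, y_2x2, design_2x2):
        fit = fit_fixed(y_2x2, design_2x2, TWO_WAY_SPECS["f1_only"])
        assert fit.rss == pytest.approx(10.0, abs=1e-10)
        assert fit.df_resid == 6

    def test_constant_response_zero_rss(self, design_2x2):
        y = np.full(8, 3.5)
        for s in TWO_WAY_SPECS.values():
            assert fit_fixed(y, design_2x2, s).rss == pytest.approx(0.0, abs=1e-20)

    def test_rank_deficient_missing_cell(self):
        # (a2, b2) never observed: full model loses one estimable column
        d = ObservationDesign(obs_ids=list("pqrstu"),
                              f1=np.array(["a1"] * 4 + ["a2"] * 2),
                              f2=np.array(["b1", "b1", "b2", "b2", "b1", "b1"]))
        fit = fit_fixed(np.arange(6.0), d, TWO_WAY_SPECS["full"])
        assert fit.n_fixed_params == 3  # intercept, a2, b2; interaction column dropped
        assert fit.df_resid == 3


class TestFTest:
    def test_equal_rss_gives_p_one(self, y_2x2, design_2x2):
        full = fit_fixed(y_2x2, design_2x2, TWO_WAY_SPECS["full"])
        add = fit_fixed(y_2x2, design_2x2, TWO_WAY_SPECS["additive"])
        assert f_test_nested(full, add) == 1.0

    def test_hand_f_statistic(self, y_2x2, design_2x2):
        add = fit_fixed(y_2x2, design_2x2, TWO_WAY_SPECS["additive"])
        f1o = fit_fixed(y_2x2, design_2x2, TWO_WAY_SPECS["f1_only"])
        F, dfn, dfd = f_statistic_nested(add, f1o)
        assert (F, dfn, dfd) == (pytest.approx(1.25), 1, 5)
        assert f_test_nested(add, f1o) == pytest.approx(stats.f.sf(1.25, 1, 5))

    def test_non_nested_rejected(self, y_2x2, design_2x2):
        f1o = fit_fixed(y_2x2, design_2x2, TWO_WAY_SPECS["f1_only"])
        f2o = fit_fixed(y_2x2, design_2x2, TWO_WAY_SPECS["f2_only"])
        with pytest.raises(ValueError, match="not nested"):
            f_test_nested(f1o, f2o)

    def test_saturated_full_zero_rss_p_zero(self, design_2x2):
        # piecewise-constant on cells with nonzero interaction: full fits exactly
        y = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 7.0, 7.0])
        full = fit_fixed(y, design_2x2, TWO_WAY_SPECS["full"])
        add = fit_fixed(y, design_2x2, TWO_WAY_SPECS["additive"])
        assert full.rss == pytest.approx(0.0, abs=1e-18)
        assert f_test_nested(full, add) == 0.0

    def test_matches_brute_force_oracle_on_random_designs(self):
        """F and p agree with the explicit pseudo-inverse oracle to 1e-8."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            I, J = rng.integers(2, 5, size=2)
            n = int(rng.integers(I * J + 4, 40))
            d = random_design(rng, I, J, n)
            y = rng.normal(size=n)
            full = fit_fixed(y, d, TWO_WAY_SPECS["full"])
            red = fit_fixed(y, d, TWO_WAY_SPECS["additive"])
            Xf = design_matrix(d, TWO_WAY_SPECS["full"])
            Xr = design_matrix(d, TWO_WAY_SPECS["additive"])
            rss_f, rank_f = oracle_ols(Xf, y)
            rss_r, rank_r = oracle_ols(Xr, y)
            assert full.rss == pytest.approx(rss_f, abs=1e-8)
            assert red.rss == pytest.approx(rss_r, abs=1e-8)
            df_f, df_r = n - rank_f, n - rank_r
            if df_f > 0 and df_r > df_f and rss_f > 1e-12:
                F = ((rss_r - rss_f) / (df_r - df_f)) / (rss_f / df_f)
                p = stats.f.sf(F, df_r - df_f, df_f)
                assert f_test_nested(full, red) == pytest.approx(p, abs=1e-8)

    def test_invariant_to_relabeling_and_permutation(self, design_2x2, y_2x2):
        p0 = f_test_nested(fit_fixed(y_2x2, design_2x2, TWO_WAY_SPECS["additive"]),
                           fit_fixed(y_2x2, design_2x2, TWO_WAY_SPECS["f1_only"]))
        rng = np.random.default_rng(3)
        perm = rng.permutation(8)
        relabel = {"a1": "zz", "a2": "aa"}
        d2 = ObservationDesign(
            obs_ids=[design_2x2.obs_ids[i] for i in perm],
            f1=np.array([relabel[v] for v in design_2x2.f1[perm]]),
            f2=design_2x2.f2[perm],
        )
        p1 = f_test_nested(fit_fixed(y_2x2[perm], d2, TWO_WAY_SPECS["additive"]),
                           fit_fixed(y_2x2[perm], d2, TWO_WAY_SPECS["f1_only"]))
        assert p1 == pytest.approx(p0, abs=1e-12)

    def test_monotone_nesting_rss(self):
        rng = np.random.default_rng(7)
        d = random_design(rng, 3, 2, 24)
        y = rng.normal(size=24)
        order = ["null", "f1_only", "additive", "full"]
        rss = [fit_fixed(y, d, TWO_WAY_SPECS[s]).rss for s in order]
        assert all(a >= b - 1e-9 for a, b in zip(rss, rss[1:]))


def three_way_design(n_subjects=6, I=2, J=2, K=2, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for s in range(n_subjects):
        for i in range(I):
            for j in range(J):
                for k in range(K):
                    recs.append((f"a{i}", f"b{j}", f"c{k}", f"s{s}"))
    f1, f2, f3, subj = map(np.array, zip(*recs))
    return ObservationDesign(obs_ids=[f"o{i}" for i in range(len(f1))],
                             f1=f1, f2=f2, f3=f3, subject=subj), rng


class TestMixedFits:
    def test_zero_subject_variance_matches_fixed_gaussian_loglik(self):
        """With sigma_u = 0 the ML mixed loglik equals the closed-form
        Gaussian likelihood of the same fixed-effect model."""
        d, rng = three_way_design(seed=1)
        y = rng.normal(size=d.n_obs)  # no subject effect at all
        mixed = fit_mixed(y, d, THREE_WAY_SPECS["additive"])
        fixed = fit_fixed(y, d, spec("f1", "f2", "f3"))
        n = fixed.n_obs
        ll_closed = -0.5 * n * (np.log(2 * np.pi * fixed.rss / n) + 1.0)
        assert mixed.loglik >= ll_closed - 1e-6
        assert mixed.loglik == pytest.approx(ll_closed, abs=1e-4)

    def test_large_subject_variance_beats_fixed_likelihood(self):
        d, rng = three_way_design(seed=2)
        u = rng.normal(0, 3.0, size=6)
        subj_idx = np.array([int(s[1:]) for s in d.subject])
        y = rng.normal(size=d.n_obs, scale=0.3) + u[subj_idx]
        mixed = fit_mixed(y, d, THREE_WAY_SPECS["null"])
        fixed = fit_fixed(y, d, spec())
        n = fixed.n_obs
        ll_fixed = -0.5 * n * (np.log(2 * np.pi * fixed.rss / n) + 1.0)
        assert mixed.loglik > ll_fixed + 5.0
        assert mixed.sigma_u2 > 1.0

    def test_loglik_nesting_monotone(self):
        d, rng = three_way_design(seed=3)
        subj_idx = np.array([int(s[1:]) for s in d.subject])
        y = rng.normal(size=d.n_obs) + rng.normal(0, 0.7, size=6)[subj_idx]
        order = ["null", "f1_only", "additive", "all_two_way", "full"]
        lls = [fit_mixed(y, d, THREE_WAY_SPECS[s]).loglik for s in order]
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))

    def test_agrees_with_statsmodels_mixedlm(self):
        """Cross-check the profiled ML against the established implementation
        away from the variance boundary."""
        import warnings

        from statsmodels.regression.mixed_linear_model import MixedLM

        d, rng = three_way_design(n_subjects=8, seed=4)
        subj_idx = np.array([int(s[1:]) for s in d.subject])
        y = rng.normal(size=d.n_obs, scale=0.5) + rng.normal(0, 1.0, size=8)[subj_idx]
        ours = fit_mixed(y, d, THREE_WAY_SPECS["additive"])
        X = design_matrix(d, THREE_WAY_SPECS["additive"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = MixedLM(y, X, groups=d.subject.astype(str)).fit(reml=False)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-5)

    def test_single_subject_rejected(self):
        d = ObservationDesign(obs_ids=list("abcd"),
                              f1=np.array(["x", "x", "y", "y"]),
                              f2=np.array(["u", "v", "u", "v"]),
                              f3=np.array(["p", "q", "p", "q"]),
                              subject=np.array(["s0"] * 4))
        with pytest.raises(ValueError, match="2 subjects"):
            fit_mixed(np.arange(4.0), d, THREE_WAY_SPECS["null"])


class TestLRT:
    def test_identical_fits_p_one(self):
        d, rng = three_way_design(seed=5)
        y = rng.normal(size=d.n_obs)
        full = fit_mixed(y, d, THREE_WAY_SPECS["additive"])
        red = fit_mixed(y, d, THREE_WAY_SPECS["f1_only"])
        same = fit_mixed(y, d, THREE_WAY_SPECS["additive"])
        assert lrt_nested(full, red) <= 1.0
        with pytest.raises(ValueError, match="degrees of freedom"):
            lrt_nested(full, same)

    def test_chi2_upper_tail_value(self):
        """Deviance 3.84 on 1 df sits at the canonical p ~ 0.050."""
        assert stats.chi2.sf(3.84, 1) == pytest.approx(0.0500, abs=5e-4)
        d, rng = three_way_design(seed=6)
        y = rng.normal(size=d.n_obs)
        full = fit_mixed(y, d, THREE_WAY_SPECS["additive"])
        red = fit_mixed(y, d, THREE_WAY_SPECS["f1_only"])
        D = max(2 * (full.loglik - red.loglik), 0.0)
        df = full.n_fixed_params - red.n_fixed_params
        assert lrt_nested(full, red) == pytest.approx(stats.chi2.sf(D, df), abs=1e-12)

    def test_planted_three_way_interaction_detected(self):
        """A strong three-way interaction rejects the no-three-way model
        in nearly every seeded replicate."""
        from idas.simulate import simulate_three_way

        hits = 0
        for s in range(20):
            pb, _ = simulate_three_way(n_per_category=1, effect_sd=1.5,
                                       noise_sd=0.5, seed=100 + s,
                                       categories=("F1xF2xF3",))
            y = pb.values[0]
            full = fit_mixed(y, pb.design, THREE_WAY_SPECS["full"])
            red = fit_mixed(y, pb.design, THREE_WAY_SPECS["all_two_way"])
            hits += lrt_nested(full, red) < 0.01
        assert hits >= 19
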