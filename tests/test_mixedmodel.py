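"""Crossed random-intercepts LMM: agreement with independent fitters
(statsmodels MixedLM, lme4, OLS/GLS closed forms) and LRT/permutation-p
contracts."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from megprime.mixedmodel import (
    CrossedLMM,
    GroupStructure,
    batched_term_t,
    build_design,
    fit_lmm,
    lrt_nested,
    mc_pvalue_fixed_effect,
    within_group_permutations,
    _whiten_factor,
)

from conftest import crossed_table


@pytest.fixture(scope="module")
def fixture_table():
    rng = np.random.default_rng(42)
    return crossed_table(8, 12, rng, subject_sd=1.0, item_sd=0.5,
                         residual_sd=0.8, effect=0.5)


def _fit(df, method):
    X, names = build_design(df, terms=("prime_type",))
    est = CrossedLMM(method=method)
    est.fit(X, df["y"], subjects=df["subject_id"], items=df["item_id"],
            term_names=names)
    return est


class TestAgainstStatsmodels:
    @pytest.mark.parametrize("method,reml", [("REML", True), ("ML", False)])
    def test_estimates_match(self, fixture_table, method, reml):
        import statsmodels.api as sm

        est = _fit(fixture_table, method)
        df = fixture_table.assign(
            x=(fixture_table.prime_type == "unrelated").astype(float), g=1
        )
        mf = sm.MixedLM.from_formula(
            "y ~ x", groups="g",
            vc_formula={"subj": "0+C(subject_id)", "item": "0+C(item_id)"},
            data=df,
        ).fit(reml=reml)
        np.testing.assert_allclose(est.coef_, mf.fe_params.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(
            [est.vc_item_, est.vc_subject_], mf.vcomp, atol=5e-3
        )
        assert est.vc_residual_ == pytest.approx(mf.scale, abs=5e-3)
        if not reml:
            assert est.loglik_ == pytest.approx(mf.llf, abs=1e-5)

    def test_t_is_coef_over_se(self, fixture_table):
        est = _fit(fixture_table, "REML")
        np.testing.assert_allclose(est.tvalues_, est.coef_ / est.bse_)


class TestAgainstLme4:
    def test_ml_fit_matches_lmer(self, fixture_table, tmp_path):
        rscript = shutil.which("Rscript")
        assert rscript, "Rscript not on PATH"
        df = fixture_table.assign(
            x=(fixture_table.prime_type == "unrelated").astype(float)
        )
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        code = (
            f"suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            "m <- lmer(y ~ x + (1|subject_id) + (1|item_id), data=d, REML=FALSE);"
            "cat(fixef(m), as.numeric(logLik(m)), sep='\\n')"
        )
        out = subprocess.run([rscript, "-e", code], capture_output=True,
                             text=True, check=True)
        intercept, slope, ll = (float(v) for v in out.stdout.strip().splitlines())
        est = _fit(fixture_table, "ML")
        assert est.coef_[0] == pytest.approx(intercept, abs=1e-4)
        assert est.coef_[1] == pytest.approx(slope, abs=1e-4)
        assert est.loglik_ == pytest.approx(ll, abs=1e-4)


class TestClosedFormOracles:
    def test_balanced_design_matches_ols(self):
        # in a fully balanced crossed design the GLS fixed-effect estimate
        # is invariant to the variance ratios, hence equals OLS exactly
        rng = np.random.default_rng(1)
        df = crossed_table(6, 10, rng, subject_sd=2.0, item_sd=1.0,
                           residual_sd=1.0, effect=0.3)
        est = _fit(df, "REML")
        X, _ = build_design(df, terms=("prime_type",))
        beta_ols = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(est.coef_, beta_ols, atol=1e-8)

    def test_fixed_ratios_match_dense_gls(self):
        rng = np.random.default_rng(2)
        df = crossed_table(5, 8, rng, subject_sd=1.0, item_sd=0.7,
                           residual_sd=0.9, effect=0.4)
        # unbalance the factor so GLS and OLS genuinely differ
        df = df.drop(index=df.index[[0, 1, 2, 11, 17]]).reset_index(drop=True)
        lam = (1.3, 0.6)
        X, names = build_design(df, terms=("prime_type",))
        est = CrossedLMM(fixed_ratios=lam)
        est.fit(X, df["y"], subjects=df["subject_id"], items=df["item_id"],
                term_names=names)
        # dense-matrix GLS oracle
        s = pd.factorize(df["subject_id"])[0]
        i = pd.factorize(df["item_id"])[0]
        n = len(df)
        V = np.eye(n)
        V += lam[0] * (s[:, None] == s[None, :])
        V += lam[1] * (i[:, None] == i[None, :])
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ df["y"].to_numpy())
        np.testing.assert_allclose(est.coef_, beta, atol=1e-8)

    def test_ols_equivalence_when_components_shrink(self):
        # generative variance components are zero; on fixtures where the
        # fitted components shrink to ~0 the fit must equal OLS
        matched = 0
        for seed in range(6):
            rng = np.random.default_rng(seed)
            df = crossed_table(8, 20, rng, residual_sd=1.0, effect=0.2)
            est = _fit(df, "ML")
            if est.vc_subject_ < 1e-6 and est.vc_item_ < 1e-6:
                X, _ = build_design(df, terms=("prime_type",))
                beta = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
                np.testing.assert_allclose(est.coef_, beta, atol=1e-6)
                matched += 1
        assert matched >= 1


class TestEdgeCases:
    def test_constant_response(self, fixture_table):
        df = fixture_table.assign(y=3.25)
        est = _fit(df, "REML")
        assert est.coef_[0] == pytest.approx(3.25)
        assert est.coef_[1] == 0.0 and est.tvalues_[1] == 0.0
        assert est.vc_residual_ == 0.0
        assert np.isfinite(est.loglik_)

    def test_rank_deficient_design_names_terms(self, fixture_table):
        X, names = build_design(fixture_table, terms=("prime_type",))
        X = np.column_stack([X, X[:, 1]])
        names = names + ["dup"]
        with pytest.raises(ValueError, match="dup"):
            CrossedLMM().fit(X, fixture_table["y"],
                             subjects=fixture_table["subject_id"],
                             items=fixture_table["item_id"], term_names=names)

    def test_requires_two_levels_of_each_grouping(self, fixture_table):
        df = fixture_table[fixture_table.subject_id == "S00"]
        with pytest.raises(ValueError, match="2 subjects"):
            _fit(df, "REML")


class TestLrt:
    def test_zero_interaction_column_gives_zero_chisq(self, fixture_table):
        df = fixture_table
        Xr, nr = build_design(df, terms=("prime_type",))
        Xf = np.column_stack([Xr, np.zeros(len(df))])
        nf = nr + ["null_interaction"]
        chi2, dof, p = lrt_nested(df["y"], Xr, Xf, df["subject_id"],
                                  df["item_id"], names_reduced=nr, names_full=nf)
        assert chi2 < 1e-6 and dof == 1 and p == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_chisq_nonnegative_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        df = crossed_table(5, 8, rng, subject_sd=0.8, item_sd=0.5,
                           residual_sd=1.0)
        df["z"] = rng.normal(size=len(df))
        Xr, nr = build_design(df, terms=("prime_type",))
        Xf, nf = build_design(df, terms=("prime_type", "z"))
        chi2, dof, p = lrt_nested(df["y"], Xr, Xf, df["subject_id"],
                                  df["item_id"], names_reduced=nr, names_full=nf)
        assert chi2 >= 0.0 and 0.0 <= p <= 1.0

    def test_strong_interaction_detected(self):
        rng = np.random.default_rng(7)
        df = crossed_table(10, 40, rng, residual_sd=1.0)
        df["z"] = rng.normal(size=len(df))
        x = (df.prime_type == "unrelated").to_numpy(float)
        df["y"] = df["y"] + 5.0 * x * df["z"]  # interaction 5x residual SD
        Xr, nr = build_design(df, terms=("prime_type", "z"))
        Xf, nf = build_design(df, terms=("prime_type", "z"),
                              interactions=(("prime_type", "z"),))
        chi2, dof, p = lrt_nested(df["y"], Xr, Xf, df["subject_id"],
                                  df["item_id"], names_reduced=nr, names_full=nf)
        assert p < 0.001

    def test_non_nested_terms_rejected(self, fixture_table):
        df = fixture_table
        Xr, nr = build_design(df, terms=("prime_type",))
        with pytest.raises(ValueError, match="subset"):
            lrt_nested(df["y"], Xr, Xr[:, :1], df["subject_id"], df["item_id"],
                       names_reduced=nr, names_full=["Intercept"])


class TestMcPvalue:
    def test_p_in_unit_interval_and_deterministic(self, fixture_table):
        df = fixture_table.rename(columns={"y": "rt_ms"})
        p1 = mc_pvalue_fixed_effect(df, n_iter=300, seed=5)
        p2 = mc_pvalue_fixed_effect(df, n_iter=300, seed=5)
        assert p1 == p2 and 0.0 < p1 <= 1.0

    def test_constant_term_rejected(self, fixture_table):
        df = fixture_table.assign(prime_type="related").rename(columns={"y": "rt_ms"})
        with pytest.raises(ValueError, match="constant"):
            mc_pvalue_fixed_effect(df, n_iter=10, seed=0)

    def test_score_approximation_matches_refit_ts(self):
        # the batched fixed-ratio t equals a full GLS refit at those ratios
        rng = np.random.default_rng(3)
        df = crossed_table(4, 6, rng, subject_sd=0.6, item_sd=0.4,
                           residual_sd=1.0, effect=0.5)
        struct = GroupStructure(df["subject_id"], df["item_id"])
        col = (df.prime_type == "unrelated").to_numpy(float)
        y = df["y"].to_numpy()
        lam = (0.4, 0.2)
        idx = within_group_permutations(struct.si, 20, rng)
        P = col[idx].T
        t_batch = batched_term_t(struct, lam, np.ones((len(df), 1)), P, y,
                                 whiten=_whiten_factor(struct, *lam))
        for j in range(5):
            Xp = np.column_stack([np.ones(len(df)), P[:, j]])
            est = CrossedLMM(method="REML", fixed_ratios=lam)
            est.fit(Xp, y, subjects=df["subject_id"], items=df["item_id"])
            assert t_batch[j] == pytest.approx(est.tvalues_[1], abs=1e-8)

    def test_within_subject_permutations_preserve_counts(self):
        rng = np.random.default_rng(0)
        groups = np.repeat(np.arange(5), 8)
        col = np.tile(np.array([1.0] * 3 + [0.0] * 5), 5)
        idx = within_group_permutations(groups, 50, rng)
        for row in idx:
            permuted = col[row]
            for g in range(5):
                assert permuted[groups == g].sum() == 3.0
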