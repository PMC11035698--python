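import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from stressmeta.effect_sizes import compute_effect_table
from stressmeta.multilevel_meta import (
    ConvergenceError,
    RandomStructure,
    _neg_loglik,
    build_vmatrix,
    fit_meta,
    latitude_metaregression,
    pooled_by_level,
    select_random_structure,
)
from stressmeta.synthetic_data import SimulationConfig, simulate_dataset

from conftest import simulate_effect_rows


def frame(values, variances, clusters=None, **extra):
    k = len(values)
    df = pd.DataFrame(
        {
            "value": values,
            "variance": variances,
            "cluster_id": clusters if clusters is not None else np.arange(k),
            "effect_size_id": np.arange(k),
        }
    )
    for name, col in extra.items():
        df[name] = col
    return df


class TestVMatrix:
    def test_cross_cluster_independence(self):
        V = build_vmatrix(frame([0.1, 0.2], [0.01, 0.04], clusters=["a", "b"]), r=0.5)
        assert V.matrix[0, 1] == 0.0
        assert np.allclose(np.diag(V.matrix), [0.01, 0.04])

    def test_within_cluster_covariance(self):
        V = build_vmatrix(frame([0.1, 0.2], [0.01, 0.04], clusters=["a", "a"]), r=0.5)
        assert V.matrix[0, 1] == pytest.approx(0.5 * np.sqrt(0.01 * 0.04))
        assert V.matrix[0, 1] == pytest.approx(0.01)

    def test_r_zero_is_diagonal(self):
        V = build_vmatrix(frame([0.1, 0.2], [0.01, 0.04], clusters=["a", "a"]), r=0.0)
        assert V.matrix[0, 1] == 0.0

    @pytest.mark.parametrize("r", [-0.1, 1.0, 1.5])
    def test_invalid_r_rejected(self, r):
        with pytest.raises(ValueError):
            build_vmatrix(frame([0.1], [0.01]), r=r)

    def test_psd(self):
        rng = np.random.default_rng(0)
        df = frame(rng.normal(size=8), rng.uniform(0.01, 0.2, 8),
                   clusters=["a", "a", "a", "b", "b", "c", "c", "c"])
        V = build_vmatrix(df, r=0.9)
        assert np.all(np.linalg.eigvalsh(V.matrix) > 0)


class TestFitMeta:
    def test_single_effect_with_fixed_zero_residual(self):
        df = frame([0.25], [0.04])
        V = build_vmatrix(df, r=0.5)
        fit = fit_meta(df, V, fixed_components={"effect_size_id": 0.0})
        assert fit.beta["intercept"] == pytest.approx(0.25, abs=1e-10)
        assert fit.se["intercept"] == pytest.approx(0.2, abs=1e-10)

    def test_symmetric_weights_give_plain_mean(self):
        df = frame([0.1, 0.2, 0.3], [0.01, 0.01, 0.01])
        V = build_vmatrix(df, r=0.5)
        fit = fit_meta(df, V)
        assert fit.beta["intercept"] == pytest.approx(0.2, abs=1e-8)

    def test_reml_matches_grid_search_oracle(self):
        # brute-force likelihood maximization over a (sigma2_study,
        # sigma2_resid) grid must not beat the optimizer
        rng = np.random.default_rng(21)
        df = simulate_effect_rows(rng, k=30, n_studies=10, mu=0.1,
                                  sigma_study=np.sqrt(0.05), sigma_resid=0.05, v=0.01)
        V = build_vmatrix(df, r=0.0)
        random = RandomStructure(("study_id",))
        fit = fit_meta(df, V, random=random, method="REML")
        y = df["value"].to_numpy()
        X = np.ones((30, 1))
        g = df["study_id"].to_numpy()
        ZZ = [(g[:, None] == g[None, :]).astype(float), np.eye(30)]
        grid = np.log(np.geomspace(1e-6, 1.0, 60))
        best_grid = min(
            _neg_loglik(np.array([a, b]), y, X, V.matrix, ZZ, True)
            for a, b in itertools.product(grid, grid)
        )
        assert -fit.loglik <= best_grid + 1e-6
        # and the grid argmax is inside the optimizer's neighbourhood
        s2 = fit.variance_components["study_id"]
        assert 0.0 <= s2 < 1.0

    def test_estimates_invariant_to_row_order_and_cluster_labels(self):
        rng = np.random.default_rng(3)
        df = simulate_effect_rows(rng, k=24, n_studies=8, mu=0.05,
                                  sigma_study=0.2, sigma_resid=0.1, v=0.02)
        perm = rng.permutation(24)
        shuffled = df.iloc[perm].reset_index(drop=True)
        shuffled["study_id"] = "st_" + shuffled["study_id"].astype(str)
        f1 = fit_meta(df, build_vmatrix(df, 0.0), random=RandomStructure(("study_id",)))
        f2 = fit_meta(shuffled, build_vmatrix(shuffled, 0.0),
                      random=RandomStructure(("study_id",)))
        assert f1.beta["intercept"] == pytest.approx(f2.beta["intercept"], abs=1e-6)
        assert f1.se["intercept"] == pytest.approx(f2.se["intercept"], abs=1e-6)

    def test_rank_deficiency_names_aliased_columns(self):
        rng = np.random.default_rng(4)
        df = simulate_effect_rows(rng, k=20, n_studies=5, v=0.01)
        df["dup"] = df["value"] * 0 + 1.0  # constant, aliased with intercept
        V = build_vmatrix(df, 0.0)
        with pytest.raises(ValueError, match="dup"):
            fit_meta(df, V, moderators=["dup"])

    def test_classical_random_effects_equivalence(self):
        # r = 0, one residual component, equal v: the REML intercept-only
        # fit is a textbook univariate random-effects meta-analysis; compare
        # against a DerSimonian-Laird moment estimate computed from scratch
        rng = np.random.default_rng(11)
        k, v, tau2 = 60, 0.02, 0.05
        y = 0.1 + rng.normal(0, np.sqrt(tau2), k) + rng.normal(0, np.sqrt(v), k)
        df = frame(y, np.full(k, v))
        fit = fit_meta(df, build_vmatrix(df, 0.0))
        w = 1.0 / v
        q = np.sum(w * (y - y.mean()) ** 2)
        tau2_dl = max(0.0, (q - (k - 1)) / ((k - 1) * w))
        mu_dl = y.mean()  # equal weights regardless of tau2
        assert fit.beta["intercept"] == pytest.approx(mu_dl, abs=0.01)
        assert fit.variance_components["effect_size_id"] == pytest.approx(tau2_dl, abs=0.03)

    def test_metafor_cross_check(self, tmp_path):
        # independent oracle: R metafor rma.mv on the identical model
        rscript = shutil.which("Rscript")
        assert rscript is not None, "Rscript expected on PATH"
        rng = np.random.default_rng(7)
        cfg = SimulationConfig(n_studies=8, experiments_per_species=2,
                               responses_per_experiment=2, seed=7)
        experiments, _ = simulate_dataset(cfg)
        eff = compute_effect_table(experiments, es_types=["main_oa", "main_ow"])
        V = build_vmatrix(eff, r=0.5)
        fit = fit_meta(eff, V, moderators=["stressor"],
                       random=RandomStructure(("study_id",)), method="ML")
        csv = tmp_path / "eff.csv"
        eff[["effect_size_id", "cluster_id", "study_id", "stressor",
             "value", "variance"]].to_csv(csv, index=False)
        script = f"""
        suppressMessages(library(metafor))
        d <- read.csv('{csv}')
        s <- sqrt(d$variance)
        V <- outer(s, s) * 0.5 * outer(d$cluster_id, d$cluster_id, "==")
        diag(V) <- d$variance
        f <- rma.mv(value, V, mods = ~ stressor,
                    random = list(~1|study_id, ~1|effect_size_id),
                    data = d, method = "ML")
        cat(coef(f), f$se, f$sigma2, logLik(f), f$QM, sep='\\n')
        """
        out = subprocess.run([rscript, "-e", script], capture_output=True, text=True,
                             check=True)
        vals = [float(x) for x in out.stdout.split()]
        b0, b1, se0, se1, s2_study, s2_res, ll, qm = vals
        assert fit.beta.iloc[0] == pytest.approx(b0, abs=1e-5)
        assert fit.beta.iloc[1] == pytest.approx(b1, abs=1e-5)
        assert fit.se.iloc[0] == pytest.approx(se0, rel=1e-4)
        assert fit.se.iloc[1] == pytest.approx(se1, rel=1e-4)
        assert fit.variance_components["study_id"] == pytest.approx(s2_study, abs=1e-5)
        assert fit.variance_components["effect_size_id"] == pytest.approx(s2_res, abs=1e-5)
        assert fit.loglik == pytest.approx(ll, abs=1e-4)
        assert fit.qm == pytest.approx(qm, rel=1e-4)


class TestRandomStructureSelection:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(2)
        df = simulate_effect_rows(rng, k=20, n_studies=5, v=0.01)
        V = build_vmatrix(df, 0.0)
        only = RandomStructure(("study_id",))
        best, table = select_random_structure(df, V, [only])
        assert best == only and len(table) == 1

    def test_strong_study_heterogeneity_selects_study_term(self):
        rng = np.random.default_rng(12)
        df = simulate_effect_rows(rng, k=160, n_studies=40, mu=0.0,
                                  sigma_study=0.4, sigma_resid=0.05, v=0.01)
        V = build_vmatrix(df, 0.0)
        best, _ = select_random_structure(
            df, V, [RandomStructure(()), RandomStructure(("study_id",))]
        )
        assert "study_id" in best.terms

    def test_aic_penalty_breaks_likelihood_ties(self):
        # no heterogeneity at any level: adding a term cannot raise the
        # likelihood enough to pay its AIC cost
        rng = np.random.default_rng(13)
        df = simulate_effect_rows(rng, k=60, n_studies=12, v=0.02)
        V = build_vmatrix(df, 0.0)
        best, table = select_random_structure(
            df, V, [RandomStructure(()), RandomStructure(("study_id",))]
        )
        assert best.terms == ()


class TestPooledByLevel:
    def test_one_level_grouping_equals_intercept_fit(self):
        rng = np.random.default_rng(6)
        df = simulate_effect_rows(rng, k=30, n_studies=10, mu=0.2,
                                  sigma_study=0.1, v=0.01)
        df["grp"] = "only"
        V = build_vmatrix(df, 0.0)
        random = RandomStructure(("study_id",))
        table, _ = pooled_by_level(df, V, random=random, grouping=["grp"])
        ref = fit_meta(df, V, random=random)
        assert table.loc[0, "estimate"] == pytest.approx(ref.beta["intercept"], abs=1e-6)
        assert table.loc[0, "se"] == pytest.approx(ref.se["intercept"], abs=1e-6)

    def test_identical_effects_recovered_exactly(self):
        df = frame([0.3] * 4 + [-0.1] * 4, [0.01] * 8)
        df["grp"] = ["a"] * 4 + ["b"] * 4
        V = build_vmatrix(df, 0.0)
        table, fit = pooled_by_level(df, V, grouping=["grp"])
        est = table.set_index("level")["estimate"]
        assert est["a"] == pytest.approx(0.3, abs=1e-6)
        assert est["b"] == pytest.approx(-0.1, abs=1e-6)
        assert table["k"].tolist() == [4, 4]

    def test_low_k_levels_flagged(self):
        df = frame([0.1, 0.2, 0.3, 0.4, 0.5], [0.01] * 5)
        df["grp"] = ["a", "a", "a", "a", "b"]
        table, _ = pooled_by_level(df, build_vmatrix(df, 0.0), grouping=["grp"])
        assert bool(table.set_index("level").loc["b", "flagged_low_k"])


class TestLatitudeMetaRegression:
    def test_flat_effects_give_null_slope(self):
        rng = np.random.default_rng(8)
        df = simulate_effect_rows(rng, k=80, n_studies=20, mu=0.1,
                                  sigma_study=0.05, v=0.01)
        df["abs_latitude"] = rng.uniform(0, 70, 80)
        fit = latitude_metaregression(df, build_vmatrix(df, 0.0),
                                      random=RandomStructure(("study_id",)))
        assert fit.ci_low["abs_latitude"] < 0 < fit.ci_high["abs_latitude"]

    def test_injected_slope_recovered(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(40):
            df = simulate_effect_rows(rng, k=100, n_studies=25, mu=0.0,
                                      sigma_study=0.05, v=0.01)
            lat = rng.uniform(0, 70, 100)
            df["abs_latitude"] = lat
            df["value"] = df["value"] + 0.005 * lat
            fit = latitude_metaregression(df, build_vmatrix(df, 0.0),
                                          random=RandomStructure(("study_id",)))
            hits += fit.ci_low["abs_latitude"] <= 0.005 <= fit.ci_high["abs_latitude"]
        assert hits / 40 >= 0.9

    def test_zero_latitude_variance_rejected(self):
        df = frame([0.1, 0.2, 0.3], [0.01] * 3)
        df["abs_latitude"] = 45.0
        with pytest.raises(ValueError, match="latitude"):
            latitude_metaregression(df, build_vmatrix(df, 0.0))
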