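"""Mixed-model statistics: closed forms, oracles, and Monte-Carlo behavior."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ctgrain import stats
from ctgrain.stats import (
    correlation_matrix,
    fit_fixed_model,
    fit_random_model,
    repeatability,
    simulate_trait_table,
    tukey_hsd,
)


def _one_way_table(k=8, r=4, sigma_g=2.0, sigma_e=1.0, seed=7):
    rng = np.random.default_rng(seed)
    rows = []
    for gi in range(k):
        ge = rng.normal(0, sigma_g)
        for rep in range(1, r + 1):
            rows.append(
                {"genotype": f"G{gi:02d}", "rep": rep, "row": 1, "col": 1,
                 "y": 10 + ge + rng.normal(0, sigma_e)}
            )
    return pd.DataFrame(rows)


class TestRepeatability:
    @pytest.mark.parametrize(
        "sg, se, r, expect",
        [(1.0, 1.0, 3, 0.75), (5.0, 0.0, 2, 1.0), (0.0, 3.0, 4, 0.0)],
    )
    def test_closed_forms(self, sg, se, r, expect):
        assert repeatability(sg, se, r) == pytest.approx(expect)

    def test_monotone_in_genetic_variance_and_replication(self):
        assert repeatability(2, 1, 3) > repeatability(1, 1, 3)
        assert repeatability(1, 1, 6) > repeatability(1, 1, 3)

    def test_degenerate_flagged(self):
        assert np.isnan(repeatability(0.0, 0.0, 3))
        with pytest.raises(ValueError):
            repeatability(-1.0, 1.0, 3)


class TestRandomModel:
    def test_balanced_one_way_matches_anova_ems(self):
        tab = _one_way_table()
        fit = fit_random_model(tab, "y", effects=("genotype",), check_normality=False)
        k, r = 8, 4
        ybar = tab.groupby("genotype")["y"].mean()
        grand = tab["y"].mean()
        msb = r * ((ybar - grand) ** 2).sum() / (k - 1)
        msw = ((tab["y"] - ybar.reindex(tab["genotype"]).to_numpy()) ** 2).sum() / (
            k * (r - 1)
        )
        assert fit.components["genotype"] == pytest.approx((msb - msw) / r, rel=1e-3)
        assert fit.sigma2_e == pytest.approx(msw, rel=1e-3)
        # self-consistency: reported R equals the closed form on the components
        assert fit.repeatability == pytest.approx(
            repeatability(fit.components["genotype"], fit.sigma2_e, 4)
        )

    def test_matches_lme4_reml_components(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the lme4 cross-check")
        tab, _ = simulate_trait_table(
            sigma2_g=4.0, sigma2_e=1.0, sigma2_rep=1.0, sigma2_row=0.8,
            sigma2_col=0.8, seed=2,
        )
        csv = tmp_path / "tab.csv"
        tab.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(lme4))\n'
            f'd <- read.csv("{csv}")\n'
            'm <- lmer(y ~ 1 + (1|genotype) + (1|rep) + (1|row) + (1|col), data=d, REML=TRUE)\n'
            'vc <- as.data.frame(VarCorr(m))\n'
            'write.csv(vc[, c("grp", "vcov")], stdout(), row.names=FALSE)\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        ).stdout
        ref = {
            row.split(",")[0].strip('"'): float(row.split(",")[1])
            for row in out.strip().splitlines()[1:]
        }
        fit = fit_random_model(tab, "y", check_normality=False)
        assert fit.components["genotype"] == pytest.approx(ref["genotype"], rel=0.02)
        assert fit.sigma2_e == pytest.approx(ref["Residual"], rel=0.02)

    def test_pure_noise_prunes_genotype_and_zero_repeatability(self):
        # seeded null draw whose between-group mean square falls below the
        # within-group mean square, i.e. a boundary REML solution
        tab = _one_way_table(sigma_g=0.0, sigma_e=1.0, seed=4)
        fit = fit_random_model(tab, "y", effects=("genotype",), check_normality=False)
        assert "genotype" in fit.dropped
        assert fit.components.get("genotype", 0.0) == 0.0
        assert fit.repeatability == 0.0
        assert (fit.eblups == 0).all()

    def test_prune_trace_records_dropped_effects(self):
        # row/col simulated absent: their boundary estimates must be pruned
        tab, _ = simulate_trait_table(
            sigma2_g=4.0, sigma2_e=1.0, sigma2_row=0.0, sigma2_col=0.0,
            sigma2_rep=0.0, seed=8,
        )
        fit = fit_random_model(tab, "y", check_normality=False)
        assert set(fit.dropped) <= {"rep", "row", "col"}
        assert len(fit.prune_trace) == len(fit.dropped)
        assert "genotype" in fit.components and fit.components["genotype"] > 1.0


class TestNormalityGate:
    def test_normal_residuals_keep_identity_scale(self):
        tab, _ = simulate_trait_table(seed=6)
        fit = fit_random_model(tab, "y")
        assert fit.transform == "none" and fit.ad_normal

    def test_lognormal_response_triggers_log10(self):
        tab, _ = simulate_trait_table(
            sigma2_g=0.2, sigma2_e=0.05, mean=2.0, seed=5
        )
        tab["y"] = 10.0 ** tab["y"]
        fit = fit_random_model(tab, "y")
        assert fit.transform == "log10" and fit.ad_normal

    def test_nonpositive_values_cannot_transform(self):
        tab, _ = simulate_trait_table(sigma2_g=0.2, sigma2_e=0.05, mean=2.0, seed=5)
        tab["y"] = 10.0 ** tab["y"]
        tab.loc[0, "y"] = -1.0
        with pytest.raises(ValueError, match="log10"):
            fit_random_model(tab, "y")


class TestFixedModel:
    def test_balanced_blues_equal_genotype_means(self):
        tab = _one_way_table()
        fit = fit_fixed_model(tab, "y", effects=("genotype", "rep"),
                              check_normality=False)
        means = tab.groupby("genotype")["y"].mean().sort_index()
        assert np.allclose(fit.blues.to_numpy(), means.to_numpy(), atol=1e-6)

    def test_all_equal_responses_give_equal_blues(self):
        tab = _one_way_table()
        tab["y"] = 5.5
        fit = fit_fixed_model(tab, "y", effects=("genotype",), check_normality=False)
        assert np.allclose(fit.blues.to_numpy(), 5.5)

    def test_unbalanced_blues_match_gls_normal_equations(self):
        # delete one observation, then solve the mixed-model GLS directly
        tab = _one_way_table(k=5, r=3, seed=3).drop(index=0).reset_index(drop=True)
        fit = fit_fixed_model(tab, "y", effects=("genotype", "rep"),
                              check_normality=False)
        genos = sorted(tab["genotype"].unique())
        X = pd.get_dummies(tab["genotype"]).to_numpy(dtype=float)
        Z = pd.get_dummies(tab["rep"]).to_numpy(dtype=float)
        s2_rep = fit.components.get("rep", 0.0)
        V = fit.sigma2_e * np.eye(len(tab)) + s2_rep * Z @ Z.T
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ tab["y"].to_numpy())
        assert np.allclose(fit.blues.reindex(genos).to_numpy(), beta, atol=1e-4)


class TestTukeyHSD:
    def test_identical_genotypes_not_significant(self):
        rng = np.random.default_rng(0)
        rows = [
            {"genotype": g, "rep": r, "row": 1, "col": 1, "y": rng.normal()}
            for g in ("A", "B") for r in range(1, 7)
        ]
        tab = pd.DataFrame(rows)
        tab.loc[tab.genotype == "B", "y"] = tab.loc[tab.genotype == "A", "y"].to_numpy()
        fit = fit_fixed_model(tab, "y", effects=("genotype",), check_normality=False)
        _, signif, letters = tukey_hsd(fit)
        assert not signif.loc["A", "B"]
        assert letters["A"] == letters["B"]

    @pytest.mark.parametrize("delta", [0.3, 1.5, 2.5])
    def test_two_groups_match_two_sample_t(self, delta):
        rng = np.random.default_rng(int(delta * 10))
        rows = [
            {"genotype": g, "rep": r, "row": 1, "col": 1,
             "y": rng.normal(0 if g == "A" else delta)}
            for g in ("A", "B") for r in range(1, 9)
        ]
        tab = pd.DataFrame(rows)
        fit = fit_fixed_model(tab, "y", effects=("genotype",), check_normality=False)
        _, signif, _ = tukey_hsd(fit, alpha=0.05)
        t = sps.ttest_ind(
            tab.loc[tab.genotype == "A", "y"], tab.loc[tab.genotype == "B", "y"]
        )
        assert bool(signif.loc["A", "B"]) == bool(t.pvalue < 0.05)

    def test_null_familywise_error_near_alpha(self):
        # balanced one-way null: direct means/MSE and the studentized range
        rng = np.random.default_rng(1)
        k, r, sims = 5, 4, 800
        q = sps.studentized_range.ppf(0.95, k, k * (r - 1))
        hits = 0
        for _ in range(sims):
            y = rng.normal(size=(k, r))
            means = y.mean(axis=1)
            mse = y.var(axis=1, ddof=1).mean()
            hsd = q * np.sqrt(mse / r)
            hits += (np.abs(means[:, None] - means[None, :]) > hsd).any()
        assert 0.03 < hits / sims < 0.08

    def test_letter_groups_follow_mean_ordering(self):
        rng = np.random.default_rng(4)
        rows = [
            {"genotype": g, "rep": r, "row": 1, "col": 1, "y": mu + rng.normal(0, 0.3)}
            for g, mu in (("A", 0.0), ("B", 0.1), ("C", 5.0))
            for r in range(1, 6)
        ]
        fit = fit_fixed_model(pd.DataFrame(rows), "y", effects=("genotype",),
                              check_normality=False)
        _, _, letters = tukey_hsd(fit)
        assert letters["C"] == "a"
        assert letters["A"] == letters["B"] == "b"


class TestCorrelations:
    def test_self_and_exact_linear_correlation(self):
        df = pd.DataFrame(
            {"genotype": list("abcde"), "x": [1.0, 2, 3, 4, 5]}
        )
        df["y"] = 2 * df["x"] + 3
        r, p, flags = correlation_matrix(df)
        assert r.loc["x", "x"] == pytest.approx(1.0)
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert flags.loc["x", "y"]

    def test_matches_textbook_formula_on_toy_pairs(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 3.0, 3.0, 6.0, 7.0])
        df = pd.DataFrame({"genotype": list("abcde"), "x": x, "y": y})
        r, _, _ = correlation_matrix(df)
        hand = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r.loc["x", "y"] == pytest.approx(hand)

    def test_zero_variance_column_flagged_nan(self):
        df = pd.DataFrame(
            {"genotype": list("abcd"), "x": [1.0, 2, 3, 4], "z": [5.0, 5, 5, 5]}
        )
        r, p, _ = correlation_matrix(df)
        assert np.isnan(r.loc["x", "z"]) and np.isnan(p.loc["x", "z"])

    def test_eblups_track_true_genotype_values(self):
        tab, g_eff = simulate_trait_table(sigma2_g=4.0, sigma2_e=1.0, seed=42)
        fit = fit_random_model(tab, "y", check_normality=False)
        rho = np.corrcoef(fit.eblups.reindex(g_eff.index), g_eff)[0, 1]
        assert rho > 0.9
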