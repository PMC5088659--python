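"""Differential expression, permutation FDR, and trait-correlation contracts."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from regionrank import association as asc
from regionrank import synthdata as sd


# ---------------------------------------------------------------------------
# independent oracle for the moderated t (separate code path: brentq-based
# trigamma inversion, explicit loops)
# ---------------------------------------------------------------------------
def oracle_moderated_t(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    n1, n2 = xa.shape[1], xb.shape[1]
    df = n1 + n2 - 2
    s2 = np.array(
        [
            (np.sum((xa[g] - xa[g].mean()) ** 2) + np.sum((xb[g] - xb[g].mean()) ** 2)) / df
            for g in range(xa.shape[0])
        ]
    )
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2)
    if evar > 0:
        half_d0 = optimize.brentq(
            lambda x: special.polygamma(1, x) - evar, 1e-8, 1e8, xtol=1e-14
        )
        d0 = 2 * half_d0
        s0_sq = np.exp(np.mean(e) + special.digamma(half_d0) - np.log(half_d0))
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    else:
        s2_post = np.full_like(s2, np.exp(np.mean(e)))
    delta = xb.mean(axis=1) - xa.mean(axis=1)
    return delta / np.sqrt(s2_post * (1 / n1 + 1 / n2))


class TestSeverityGroups:
    @pytest.mark.parametrize(
        "trait,value,expected",
        [
            ("Braak", 0, "normal"),
            ("Braak", 2, "normal"),
            ("Braak", 3, "low"),
            ("Braak", 4, "low"),
            ("Braak", 5, "high"),
            ("CDR", 0.0, "normal"),
            ("CDR", 0.5, "low"),
            ("CDR", 2.0, "low"),
            ("CDR", 3.0, "high"),
            ("CERAD", 0, "normal"),
            ("CERAD", 1, "low"),
            ("CERAD", 2, "low"),
            ("CERAD", 3, "high"),
        ],
    )
    def test_ordinal_binning_rules(self, trait, value, expected):
        traits = pd.DataFrame({trait: [value]}, index=["s1"])
        assert asc.assign_severity_groups(traits, trait).loc["s1"] == expected

    def test_quantitative_zero_normal_median_split(self):
        traits = pd.DataFrame({"PLQ_Mn": [0, 0, 1, 2, 3, 4]}, index=list("abcdef"))
        g = asc.assign_severity_groups(traits, "PLQ_Mn")
        assert list(g[list("ab")]) == ["normal", "normal"]
        assert list(g[list("cd")]) == ["low", "low"]  # median 2.5; <= goes low
        assert list(g[list("ef")]) == ["high", "high"]

    def test_unknown_trait_errors(self):
        with pytest.raises(KeyError):
            asc.assign_severity_groups(pd.DataFrame({"CDR": [0]}), "nosuch")


class TestModeratedT:
    def test_identical_group_means_give_null_statistics(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(50, 1))
        m = pd.DataFrame(
            np.repeat(base, 12, axis=1) + 0.0, columns=[f"s{i}" for i in range(12)]
        )
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=m.columns)
        res = asc.moderated_t_test(m, groups, ("A", "B"))
        assert np.abs(res.table["t"]).max() < 1e-10
        assert (res.table["p"] > 0.999).all()

    def test_zero_prior_df_equals_ordinary_t(self):
        m, groups, _ = sd.simulate_two_group(80, 8, seed=1)
        res = asc.moderated_t_test(m, groups, ("A", "B"), prior_df=0)
        xa = m[groups.index[groups == "A"]].to_numpy()
        xb = m[groups.index[groups == "B"]].to_numpy()
        t_ref = stats.ttest_ind(xb, xa, axis=1, equal_var=True).statistic
        np.testing.assert_allclose(res.table["t"].to_numpy(), t_ref, atol=1e-10)

    def test_matches_independent_shrinkage_oracle(self):
        # heterogeneous true variances exercise the generic prior fit
        rng = np.random.default_rng(2)
        sig2 = 5 * 0.8 / rng.chisquare(5, 100)
        x = rng.normal(0, np.sqrt(sig2)[:, None], size=(100, 20))
        m = pd.DataFrame(x, columns=[f"s{i}" for i in range(20)])
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=m.columns)
        res = asc.moderated_t_test(m, groups, ("A", "B"))
        xa = x[:, :10]
        xb = x[:, 10:]
        np.testing.assert_allclose(
            res.table["t"].to_numpy(), oracle_moderated_t(xa, xb), atol=1e-8
        )

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_limma_reference(self, tmp_path):
        rng = np.random.default_rng(3)
        sig2 = 4 * 0.5 / rng.chisquare(4, 80)
        x = rng.normal(7, np.sqrt(sig2)[:, None], size=(80, 16))
        m = pd.DataFrame(
            x, index=[f"p{i}" for i in range(80)], columns=[f"s{i}" for i in range(16)]
        )
        groups = pd.Series(["A"] * 8 + ["B"] * 8, index=m.columns, name="group")
        m.to_csv(tmp_path / "expr.tsv", sep="\t")
        groups.to_csv(tmp_path / "groups.tsv", sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'm <- as.matrix(read.delim("{tmp_path}/expr.tsv", row.names=1))\n'
            f'g <- read.delim("{tmp_path}/groups.tsv", row.names=1)\n'
            'design <- model.matrix(~ factor(g$group, levels=c("A","B")))\n'
            "fit <- eBayes(lmFit(m, design))\n"
            f'write.table(data.frame(t=fit$t[,2]), "{tmp_path}/limma_t.tsv", sep="\\t", quote=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma_t.tsv", sep="\t", index_col=0)
        res = asc.moderated_t_test(m, groups, ("A", "B"))
        np.testing.assert_allclose(res.table["t"].to_numpy(), ref["t"].to_numpy(), atol=1e-6)

    def test_small_group_errors(self):
        m = pd.DataFrame(np.ones((3, 3)), columns=["a", "b", "c"])
        groups = pd.Series(["A", "A", "B"], index=m.columns)
        with pytest.raises(ValueError, match=">=2 samples"):
            asc.moderated_t_test(m, groups, ("A", "B"))


class TestEmpiricalFdr:
    def test_printed_formula_hand_example(self):
        # n=1000, P=50, N=5000, FP=25 -> 1000 * (25/5000) / 50 = 0.1
        obs = np.concatenate([np.full(50, 5.0), np.zeros(950)])
        perm = np.concatenate([np.full(25, 6.0), np.zeros(4975)])
        assert asc.empirical_fdr(obs, perm, cutoff=5.0) == pytest.approx(0.1)

    def test_no_false_positives_gives_zero(self):
        obs = np.array([3.0, 4.0, 0.1])
        perm = np.zeros(100)
        assert asc.empirical_fdr(obs, perm, cutoff=2.0) == 0.0

    def test_nothing_significant_gives_one(self):
        assert asc.empirical_fdr(np.array([0.1, 0.2]), np.array([5.0]), cutoff=3.0) == 1.0

    def test_empty_observed_errors(self):
        with pytest.raises(ValueError):
            asc.empirical_fdr(np.array([]), np.array([1.0]), 0.5)

    def test_equals_bh_on_empirical_pvalues(self):
        rng = np.random.default_rng(4)
        obs = rng.standard_normal(400)
        perm = rng.standard_normal(4000)
        fdr = asc.empirical_fdr_curve(obs, perm)
        emp_p = np.array([(np.abs(perm) >= abs(s)).mean() for s in obs])
        bh = multipletests(emp_p, method="fdr_bh")[1]
        np.testing.assert_allclose(fdr, bh, atol=1e-10)

    def test_curve_monotone_in_statistic(self):
        rng = np.random.default_rng(5)
        obs = rng.standard_normal(200)
        perm = rng.standard_normal(1000)
        fdr = asc.empirical_fdr_curve(obs, perm)
        order = np.argsort(-np.abs(obs))
        assert (np.diff(fdr[order]) >= -1e-15).all()

    def test_global_null_fdr_near_one_at_lax_cutoff(self):
        rng = np.random.default_rng(6)
        obs = rng.standard_normal(2000)
        perm = rng.standard_normal(10000)
        assert asc.empirical_fdr(obs, perm, cutoff=0.5) > 0.8


class TestCallDegs:
    @staticmethod
    def _table(fc, fdr):
        return pd.DataFrame({"log2_fc": fc, "t": fc, "p": fdr, "fdr": fdr},
                            index=[f"p{i}" for i in range(len(fc))])

    def test_fold_change_filter_excludes_small_effects(self):
        de = self._table([0.5], [0.001])  # FC ~1.41 < 1.5
        out = asc.call_degs(de)
        assert out == {"up": [], "down": []}

    def test_direction_split(self):
        de = self._table([1.0, -1.0, 2.0], [0.04, 0.01, 0.5])
        out = asc.call_degs(de)
        assert out["up"] == ["p0"] and out["down"] == ["p1"]

    def test_invariant_to_probeset_order_and_group_relabeling(self):
        m, groups, _ = sd.simulate_two_group(300, 10, de_fraction=0.2, seed=7)
        null = asc.permuted_moderated_t(m, groups, ("A", "B"), n_perm=10, rng=1)
        t1 = asc.moderated_t_test(m, groups, ("A", "B")).table
        t1["fdr"] = asc.empirical_fdr_curve(t1["t"].to_numpy(), null)
        out1 = asc.call_degs(t1)
        perm = np.random.default_rng(8).permutation(len(m))
        m2 = m.iloc[perm]
        t2 = asc.moderated_t_test(m2, groups, ("A", "B")).table
        t2["fdr"] = asc.empirical_fdr_curve(t2["t"].to_numpy(), null)
        out2 = asc.call_degs(t2)
        assert out1 == out2
        # relabeling samples within groups changes nothing
        cols = list(m.columns)
        shuffled = cols[:5][::-1] + cols[5:10] + cols[10:][::-1]
        t3 = asc.moderated_t_test(m[shuffled], groups, ("A", "B")).table
        t3["fdr"] = asc.empirical_fdr_curve(t3["t"].to_numpy(), null)
        assert asc.call_degs(t3) == out1


class TestSpearman:
    def test_monotone_transform_gives_rho_one(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(1, 20))
        trait = pd.Series(np.exp(x[0]), index=[f"s{i}" for i in range(20)])
        m = pd.DataFrame(x, columns=trait.index)
        out = asc.spearman_trait_correlation(m, trait, n_perm=3, seed=0)
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_brute_force_rank_formula(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        y = pd.Series([5.0, 6.0, 7.0, 8.0, 7.0], index=[f"s{i}" for i in range(5)])
        m = pd.DataFrame(x, columns=y.index)
        out = asc.spearman_trait_correlation(m, y, n_perm=3, seed=0)
        rx = stats.rankdata(x[0])
        ry = stats.rankdata(y.to_numpy())
        expected = np.corrcoef(rx, ry)[0, 1]
        assert out["rho"].iloc[0] == pytest.approx(expected, abs=1e-12)
        assert out["rho"].iloc[0] == pytest.approx(stats.spearmanr(x[0], y).statistic)

    def test_null_trait_yields_no_calls(self):
        rng = np.random.default_rng(10)
        m = pd.DataFrame(rng.normal(size=(500, 40)), columns=[f"s{i}" for i in range(40)])
        trait = pd.Series(rng.normal(size=40), index=m.columns)
        out = asc.spearman_trait_correlation(m, trait, n_perm=20, seed=11)
        assert (out["fdr"] < 0.05).sum() <= 5
        assert np.abs(out["rho"]).mean() < 0.2

    def test_constant_trait_errors(self):
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 6)),
                         columns=[f"s{i}" for i in range(6)])
        with pytest.raises(ValueError, match="constant"):
            asc.spearman_trait_correlation(m, pd.Series(1.0, index=m.columns), seed=0)

    @pytest.mark.parametrize("transform", [np.exp, np.tanh, lambda v: v**3])
    def test_rho_invariant_under_monotone_transforms(self, transform):
        rng = np.random.default_rng(12)
        m = pd.DataFrame(rng.normal(size=(20, 15)), columns=[f"s{i}" for i in range(15)])
        trait = pd.Series(rng.normal(size=15), index=m.columns)
        a = asc.spearman_trait_correlation(m, trait, n_perm=2, seed=0)["rho"]
        b = asc.spearman_trait_correlation(m, trait.map(transform), n_perm=2, seed=0)["rho"]
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)
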