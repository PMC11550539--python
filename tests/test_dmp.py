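"""Differential methylation: linear model, moderated t, selection,
annotation, ORA and Venn partitions."""

import subprocess
import textwrap
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st
from scipy.special import comb

import methylcascade as mc
from methylcascade.dmp import ModerationPrior, read_gmt


def _beta(X):
    return pd.DataFrame(X, index=[f"cg{i:06d}" for i in range(X.shape[0])])


class TestFitProbeModels:
    def test_identical_groups_zero_logfc(self):
        X = np.tile(np.linspace(0.2, 0.8, 10)[:, None], (1, 8))
        tab = mc.fit_probe_models(_beta(X), ["A"] * 4 + ["B"] * 4, ("A", "B"))
        np.testing.assert_allclose(tab.logFC, 0.0, atol=1e-12)

    def test_constant_offset_recovered_noise_free(self):
        X = np.full((5, 8), 0.4)
        X[:, :4] += 0.3
        tab = mc.fit_probe_models(_beta(X), ["A"] * 4 + ["B"] * 4, ("A", "B"))
        np.testing.assert_allclose(tab.logFC, 0.3, atol=1e-12)
        np.testing.assert_allclose(tab.s2, 0.0, atol=1e-12)
        assert (tab.df == 6).all()

    def test_pooled_variance_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0.5, 0.1, size=(50, 12))
        tab = mc.fit_probe_models(_beta(X), ["A"] * 5 + ["B"] * 7, ("A", "B"))
        a, b = X[:, :5], X[:, 5:]
        pooled = ((a.var(axis=1, ddof=1) * 4) + (b.var(axis=1, ddof=1) * 6)) / 10
        np.testing.assert_allclose(tab.s2, pooled, atol=1e-12)

    def test_small_group_rejected(self):
        X = np.zeros((5, 3))
        with pytest.raises(ValueError, match=">= 2 samples"):
            mc.fit_probe_models(_beta(X), ["A", "A", "B"], ("A", "B"))


class TestModeratedT:
    def _stats(self, seed=0, n_probes=1000, n=8, het=True):
        rng = np.random.default_rng(seed)
        sds = 0.05 * np.exp(rng.normal(0, 0.6, n_probes)) if het else np.full(n_probes, 0.05)
        X = rng.normal(0.5, sds[:, None], size=(n_probes, 2 * n))
        return mc.fit_probe_models(_beta(X), ["A"] * n + ["B"] * n, ("A", "B")), X, n

    def test_d0_zero_equals_ordinary_t(self):
        tab, X, n = self._stats(seed=1)
        _, out = mc.moderate_and_test(tab, prior=ModerationPrior(0.0, 1.0))
        tt = st.ttest_ind(X[:, :n], X[:, n:], axis=1)
        np.testing.assert_allclose(out.t, tt.statistic, atol=1e-8)
        np.testing.assert_allclose(out.p, tt.pvalue, atol=1e-8)

    def test_d0_infinite_fixes_posterior_variance(self):
        tab, _, _ = self._stats(seed=2)
        s0sq = 0.004
        _, out = mc.moderate_and_test(tab, prior=ModerationPrior(np.inf, s0sq))
        se = np.sqrt(s0sq * (1 / 8 + 1 / 8))
        np.testing.assert_allclose(out.t, tab.logFC / se, atol=1e-10)

    def test_null_type_i_error_calibrated(self):
        rng = np.random.default_rng(42)
        X = rng.normal(0.5, 0.05, size=(5000, 20))
        tab = mc.fit_probe_models(_beta(X), ["A"] * 10 + ["B"] * 10, ("A", "B"))
        _, out = mc.moderate_and_test(tab)
        rate = (out.p < 0.01).mean()
        assert abs(rate - 0.01) <= 0.004

    def test_all_zero_variance_rejected(self):
        X = np.tile(np.linspace(0, 1, 20)[:, None], (1, 8))
        tab = mc.fit_probe_models(_beta(X), ["A"] * 4 + ["B"] * 4, ("A", "B"))
        with pytest.raises(ValueError, match="noise-free"):
            mc.moderate_and_test(tab)

    def test_spike_in_sensitivity_and_fdr(self):
        rng = np.random.default_rng(7)
        n_probes, n_spike = 5000, 200
        X = rng.normal(0.5, 0.05, size=(n_probes, 20))
        idx = rng.choice(n_probes, n_spike, replace=False)
        X[idx, :10] += 0.3
        tab = mc.fit_probe_models(_beta(X), ["A"] * 10 + ["B"] * 10, ("A", "B"))
        _, out = mc.moderate_and_test(tab)
        sel = mc.select_dmps(out)
        spiked = set(out.index[np.isin(np.arange(n_probes), idx)])
        tp = len(set(sel) & spiked)
        assert tp / n_spike >= 0.9
        assert (len(sel) - tp) / max(len(sel), 1) <= 0.05

    def test_bh_adjustment_is_monotone_and_above_raw(self):
        tab, _, _ = self._stats(seed=3, n_probes=500)
        _, out = mc.moderate_and_test(tab)
        assert (out.adj_p >= out.p - 1e-12).all()
        o = out.sort_values("p")
        assert (np.diff(o.adj_p) >= -1e-12).all()

    def test_matches_limma_ebayes(self, tmp_path):
        """Dual-route check: trigamma-matching prior and moderated t must
        reproduce limma's eBayes on the same matrix."""
        rng = np.random.default_rng(9)
        sds = 0.05 * np.exp(rng.normal(0, 0.6, 400))
        X = rng.normal(0.5, sds[:, None], size=(400, 10))
        tab = mc.fit_probe_models(_beta(X), ["A"] * 5 + ["B"] * 5, ("A", "B"))
        prior, out = mc.moderate_and_test(tab)
        np.savetxt(tmp_path / "X.txt", X)
        out[["t"]].to_csv(tmp_path / "py.csv")
        script = textwrap.dedent("""
            suppressMessages(library(limma))
            X <- as.matrix(read.table("X.txt"))
            design <- model.matrix(~0 + factor(rep(c("A","B"), each=5)))
            colnames(design) <- c("A","B")
            fit <- eBayes(contrasts.fit(lmFit(X, design),
                                        makeContrasts(A-B, levels=design)))
            py <- read.csv("py.csv")
            cat(fit$df.prior, fit$s2.prior, max(abs(fit$t[,1] - py$t)), "\\n")
        """)
        (tmp_path / "check.R").write_text(script)
        res = subprocess.run(["Rscript", "check.R"], cwd=tmp_path,
                             capture_output=True, text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        d0_r, s0sq_r, tdiff = map(float, res.stdout.split())
        assert prior.d0 == pytest.approx(d0_r, rel=1e-4)
        assert prior.s0sq == pytest.approx(s0sq_r, rel=1e-4)
        assert tdiff < 1e-6


class TestSelection:
    def _table(self, adj_p, logfc):
        return pd.DataFrame({"adj_p": adj_p, "logFC": logfc},
                            index=[f"p{i}" for i in range(len(adj_p))])

    @pytest.mark.parametrize(
        "adj_p,logfc,selected",
        [
            (0.005, 0.25, True),
            (0.02, 0.5, False),
            (0.005, 0.2, False),   # |logFC| exactly 0.2: "exceeding" is strict
            (0.01, 0.5, False),    # adj p exactly 0.01: "below" is strict
            (0.005, -0.25, True),
        ],
    )
    def test_threshold_strictness(self, adj_p, logfc, selected):
        sel = mc.select_dmps(self._table([adj_p], [logfc]))
        assert ("p0" in sel) == selected


class TestAnnotation:
    def _manifest(self):
        return pd.DataFrame(
            {
                "gene": ["G1", "G1", "G2", "", "G3"],
                "enhancer_flag": [True, False, True, True, True],
                "promoter_flag": [False, True, True, False, True],
            },
            index=pd.Index([f"p{i}" for i in range(5)], name="probe_id"),
        )

    def test_direction_split_and_flags(self):
        table = pd.DataFrame({"logFC": [-0.3, 0.4, 0.5, -0.6, 0.3]},
                             index=[f"p{i}" for i in range(5)])
        sets = mc.annotate_regulatory(table, table.index, self._manifest())
        assert sets["enhancer_hypo"] == {"G1"}
        assert sets["promoter_hyper"] == {"G1", "G2", "G3"}
        assert sets["enhancer_hyper"] == {"G2", "G3"}
        # p3 has empty gene: dropped despite enhancer flag
        assert "G" not in set().union(*sets.values())

    def test_gene_deduplicated_across_probes(self):
        man = self._manifest()
        table = pd.DataFrame({"logFC": [0.3, 0.3]}, index=["p0", "p1"])
        man2 = man.loc[["p0", "p1"]].copy()
        man2["enhancer_flag"] = True
        sets = mc.annotate_regulatory(table, table.index, man2)
        assert sets["enhancer_hyper"] == {"G1"}

    def test_set_sizes_match_brute_force_join(self):
        rng = np.random.default_rng(3)
        n = 200
        man = pd.DataFrame(
            {
                "gene": [f"G{rng.integers(0, 40)}" if rng.random() > 0.1 else ""
                         for _ in range(n)],
                "enhancer_flag": rng.random(n) < 0.3,
                "promoter_flag": rng.random(n) < 0.4,
            },
            index=pd.Index([f"p{i}" for i in range(n)], name="probe_id"),
        )
        table = pd.DataFrame({"logFC": rng.normal(0, 0.3, n)}, index=man.index)
        subset = table.index[rng.random(n) < 0.4]
        sets = mc.annotate_regulatory(table, subset, man)
        oracle = {
            g for p in subset
            if (g := man.at[p, "gene"]) and man.at[p, "enhancer_flag"]
            and table.at[p, "logFC"] > 0
        }
        assert sets["enhancer_hyper"] == oracle


class TestOra:
    def test_exact_hypergeometric_example(self):
        universe = [f"g{i}" for i in range(20)]
        gene_sets = {"S": {"g0", "g1", "g2", "g18", "g19"}}
        res = mc.fisher_ora(["g0", "g1", "g2", "g10"], gene_sets, universe)
        # overlap 3 of list 4, set 5, universe 20: p = 155/4845
        assert res.iloc[0].p == pytest.approx(155 / 4845, abs=1e-12)
        assert res.iloc[0].overlap == 3

    def test_zero_overlap_small_set_gives_p_one(self):
        universe = [f"g{i}" for i in range(100)]
        res = mc.fisher_ora(["g0"], {"S": {"g99"}}, universe)
        assert res.iloc[0].p == pytest.approx(1.0)

    def test_matches_enumeration_on_small_universes(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            N = int(rng.integers(5, 50))
            universe = [f"g{i}" for i in range(N)]
            gene_set = set(rng.choice(universe, rng.integers(1, N), replace=False))
            glist = list(rng.choice(universe, rng.integers(1, N), replace=False))
            res = mc.fisher_ora(glist, {"S": gene_set}, universe)
            K, n = len(gene_set), len(glist)
            k_obs = len(gene_set & set(glist))
            p_oracle = sum(
                comb(K, k, exact=True) * comb(N - K, n - k, exact=True)
                for k in range(k_obs, min(K, n) + 1)
            ) / comb(N, n, exact=True)
            assert res.iloc[0].p == pytest.approx(p_oracle, abs=1e-12)

    def test_bh_example(self):
        universe = [f"g{i}" for i in range(30)]
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def test_gene_list_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            mc.fisher_ora(["gX"], {"S": {"g0"}}, ["g0", "g1"])

    def test_gmt_roundtrip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("SET1\tdesc\tg1\tg2\nSET2\tdesc\tg3\n")
        sets = read_gmt(path)
        assert sets == {"SET1": {"g1", "g2"}, "SET2": {"g3"}}


class TestVenn:
    def test_identical_sets_all_in_full_intersection(self):
        s = {"a", "b", "c"}
        counts = mc.venn_counts({"X": set(s), "Y": set(s), "Z": set(s)})
        assert counts["X&Y&Z"] == 3
        assert counts["X"] == counts["Y"] == counts["X&Y"] == 0

    def test_disjoint_sets(self):
        counts = mc.venn_counts({"X": {1, 2}, "Y": {3}})
        assert counts == {"X": 2, "Y": 1, "X&Y": 0}

    def test_random_sets_match_set_algebra(self):
        rng = np.random.default_rng(5)
        pool = [f"e{i}" for i in range(40)]
        sets = {n: set(rng.choice(pool, rng.integers(5, 30), replace=False))
                for n in "ABC"}
        counts = mc.venn_counts(sets)
        for r in (1, 2, 3):
            for combo in combinations("ABC", r):
                inside = set.intersection(*(sets[c] for c in combo))
                outside = set().union(*(sets[c] for c in "ABC" if c not in combo))
                assert counts["&".join(combo)] == len(inside - outside)

    def test_more_than_three_sets_rejected(self):
        with pytest.raises(ValueError, match="2 or 3"):
            mc.venn_counts({str(i): {i} for i in range(4)})
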