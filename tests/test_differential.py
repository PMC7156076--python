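"""Moderated-t contrast, prior estimation, BH adjustment."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import detectome as dt
from detectome.differential import fit_variance_prior, trigamma_inverse
from detectome.model import DetectionLevelMatrix, DetectomeError, SampleAnnotation


def _dataset(rng, m=100, n1=6, n2=6, shift=0.0, heteroscedastic=True):
    sd = rng.uniform(0.5, 2.0, (m, 1)) if heteroscedastic else np.ones((m, 1))
    base = rng.uniform(3, 11, (m, 1))
    x = base + sd * rng.standard_normal((m, n1 + n2))
    x[:, :n1] += shift
    ids = [f"m{i:03d}" for i in range(m)]
    cols = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    anns = [
        SampleAnnotation(c, "case" if c.startswith("a") else "control", "plasma")
        for c in cols
    ]
    return DetectionLevelMatrix(pd.DataFrame(x, index=ids, columns=cols)), anns


class TestTwoGroupStats:
    def test_constructed_means(self):
        levels = DetectionLevelMatrix(
            pd.DataFrame(
                [[9.0, 9.0, 7.0, 7.0]],
                index=["m1"],
                columns=["a1", "a2", "b1", "b2"],
            )
        )
        anns = [
            SampleAnnotation("a1", "case", "plasma"),
            SampleAnnotation("a2", "case", "plasma"),
            SampleAnnotation("b1", "control", "plasma"),
            SampleAnnotation("b2", "control", "plasma"),
        ]
        out = dt.two_group_stats(levels, anns)
        assert out.at["m1", "logFC"] == 2.0
        assert out.at["m1", "AveExpr"] == 8.0

    def test_identical_groups_zero_logfc(self, rng):
        levels, anns = _dataset(rng, m=20)
        levels.levels.iloc[:, 6:] = levels.levels.iloc[:, :6].to_numpy()
        out = dt.two_group_stats(levels, anns)
        assert np.allclose(out["logFC"], 0)

    def test_small_group_errors(self, rng):
        levels, anns = _dataset(rng, m=5, n1=1, n2=6)
        with pytest.raises(DetectomeError, match=">= 2"):
            dt.two_group_stats(levels, anns)


class TestModeratedT:
    def test_zero_prior_df_equals_pooled_t(self, rng):
        levels, anns = _dataset(rng, m=200, n1=12, n2=11)
        table = dt.moderated_t(levels, anns, prior_df=0)
        x = levels.levels.to_numpy()
        ref = stats.ttest_ind(x[:, :12].T, x[:, 12:].T, equal_var=True)
        got = table.loc[levels.mirna_ids]
        np.testing.assert_allclose(got["t"], ref.statistic, rtol=1e-9)
        np.testing.assert_allclose(got["p_value"], ref.pvalue, rtol=1e-9)

    def test_infinite_prior_df_orders_by_logfc(self, rng):
        levels, anns = _dataset(rng, m=50)
        table = dt.moderated_t(levels, anns, prior_df=np.inf, prior_var=1.0)
        by_t = list(table.index)
        by_fc = list(
            table["logFC"].abs().sort_values(ascending=False, kind="stable").index
        )
        assert by_t == by_fc

    def test_label_swap_negates_t_preserves_p(self, rng):
        levels, anns = _dataset(rng, m=60)
        swapped = [
            SampleAnnotation(
                a.sample_id,
                "control" if a.group == "case" else "case",
                a.compartment,
            )
            for a in anns
        ]
        t1 = dt.moderated_t(levels, anns).sort_index()
        t2 = dt.moderated_t(levels, swapped).sort_index()
        np.testing.assert_allclose(t1["t"], -t2["t"], rtol=1e-9)
        np.testing.assert_allclose(t1["logFC"], -t2["logFC"], rtol=1e-9)
        np.testing.assert_allclose(t1["p_value"], t2["p_value"], rtol=1e-9)

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for x in (0.1, 0.7, 2.0, 15.0, 200.0):
            y = float(polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)

    def test_prior_recovers_known_f_distribution(self, rng):
        """Variances simulated as s0^2 * F(d, d0) give back (d0, s0^2)."""
        d, d0, s0 = 21, 8.0, 1.5
        s2 = s0 * rng.f(d, d0, size=20000)
        prior = fit_variance_prior(s2, d)
        assert not prior.fallback
        assert prior.prior_df == pytest.approx(d0, rel=0.15)
        assert prior.prior_var == pytest.approx(s0, rel=0.1)

    def test_homoscedastic_ensemble_falls_back(self, rng):
        """Equal true variances leave no excess log-variance spread at large
        d, so the moment fit can hit the fallback prior; the statistic must
        still be finite and calibrated."""
        levels, anns = _dataset(rng, m=300, n1=40, n2=40, heteroscedastic=False)
        table = dt.moderated_t(levels, anns)
        assert np.isfinite(table["t"]).all()

    def test_matches_limma_reference(self, rng, tmp_path):
        """Independent oracle: the Bioconductor limma implementation on the
        same matrix agrees on moderated t and p."""
        levels, anns = _dataset(rng, m=300, n1=6, n2=6)
        data_path = tmp_path / "x.tsv"
        levels.levels.to_csv(data_path, sep="\t")
        script = tmp_path / "ref.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            x <- as.matrix(read.delim(args[1], row.names=1))
            design <- cbind(Intercept=1, Case=c(rep(1,6), rep(0,6)))
            fit <- eBayes(lmFit(x, design))
            out <- topTable(fit, coef="Case", number=Inf, sort.by="none")
            write.table(out, args[2], sep="\\t", quote=FALSE)
            """
        )
        out_path = tmp_path / "limma.tsv"
        subprocess.run(
            ["Rscript", str(script), str(data_path), str(out_path)],
            check=True,
            capture_output=True,
        )
        ref = pd.read_csv(out_path, sep="\t")
        table = dt.moderated_t(levels, anns).loc[ref.index]
        np.testing.assert_allclose(table["logFC"], ref["logFC"], rtol=1e-6)
        np.testing.assert_allclose(table["t"], ref["t"], rtol=1e-3)
        np.testing.assert_allclose(table["p_value"], ref["P.Value"], rtol=1e-2)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            dt.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert dt.bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_all_ones_stay_one(self):
        assert (dt.bh_adjust([1.0] * 5) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(DetectomeError):
            dt.bh_adjust([0.5, 1.2])

    @settings(max_examples=200, derandomize=True)
    @given(
        ps=st.lists(
            st.floats(0, 1, allow_nan=False), min_size=1, max_size=20
        )
    )
    def test_matches_brute_force_definition(self, ps):
        """adj(i) = min over j with p(j) >= p(i) of min(1, m*p(j)/rank(j))."""
        adj = dt.bh_adjust(ps)
        m = len(ps)
        order = np.argsort(ps, kind="stable")
        expect = np.empty(m)
        running = 1.0
        for rank_from_top in range(m - 1, -1, -1):
            idx = order[rank_from_top]
            running = min(running, m * ps[idx] / (rank_from_top + 1))
            expect[idx] = running
        np.testing.assert_allclose(adj, expect, rtol=1e-12, atol=1e-12)
        assert (adj >= np.asarray(ps) - 1e-12).all()


class TestSelectAndReport:
    def test_threshold_one_selects_everything(self, rng):
        levels, anns = _dataset(rng, m=40)
        table = dt.moderated_t(levels, anns)
        sel = dt.select_and_report(table, 1.0)
        assert sel.n_selected == 40

    def test_counts_consistent_with_table(self, rng):
        levels, anns = _dataset(rng, m=150)
        table = dt.moderated_t(levels, anns)
        sel = dt.select_and_report(table, 0.05)
        assert sel.n_selected == int((table["p_value"] < 0.05).sum())
        assert sel.n_adjusted_significant == int(
            (table["adj_p_value"] < 0.05).sum()
        )
        assert set(sel.volcano.columns) == {"logFC", "neg_log10_p"}
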