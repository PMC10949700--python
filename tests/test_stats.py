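"""NB fold-change test behaviour, masked-decay clauses, shift tests."""

import numpy as np
import pandas as pd
import pytest

from slam_mzt.stats import (
    bh_adjust,
    group_shift,
    lna_derepression,
    masked_decay_genes,
    nb_fold_change_test,
)


def _nb_counts(rng, mu, phi, n_samples):
    r = 1 / phi
    return np.stack(
        [rng.negative_binomial(r, r / (r + mu)) for _ in range(n_samples)], axis=1
    )


def _frame(arr, genes=None):
    genes = genes if genes is not None else [f"g{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=genes)


class TestNbFoldChangeTest:
    def test_identical_groups_are_null(self):
        counts = _frame(np.full((5, 3), 200))
        libs = np.full(3, 1e6)
        de = nb_fold_change_test(counts, counts.copy(), libs, libs)
        assert np.allclose(de["log2fc"], 0.0)
        assert (de["pvalue"] > 0.9).all()

    def test_swapping_groups_negates_log2fc_and_keeps_p(self):
        rng = np.random.default_rng(3)
        a = _frame(_nb_counts(rng, rng.uniform(50, 500, 40), 0.05, 3))
        b = _frame(_nb_counts(rng, rng.uniform(50, 500, 40), 0.05, 3), genes=a.index)
        libs = np.full(3, 1e6)
        fwd = nb_fold_change_test(a, b, libs, libs)
        rev = nb_fold_change_test(b, a, libs, libs)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["pvalue"], rev["pvalue"], rtol=1e-9)

    def test_two_fold_change_recovered(self):
        rng = np.random.default_rng(5)
        mu = rng.lognormal(np.log(1000), 0.3, 300)
        a = _frame(_nb_counts(rng, 2 * mu, 0.05, 3))
        b = _frame(_nb_counts(rng, mu, 0.05, 3), genes=a.index)
        libs = np.full(3, 1e6)
        de = nb_fold_change_test(a, b, libs, libs)
        assert de["log2fc"].mean() == pytest.approx(1.0, abs=0.1)
        assert (de["padj"] < 0.05).mean() > 0.9

    def test_zero_library_group_refused(self):
        counts = _frame(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            nb_fold_change_test(counts, counts, [0, 0], [1e6, 1e6])

    def test_padj_bounds(self):
        rng = np.random.default_rng(8)
        a = _frame(_nb_counts(rng, np.full(100, 100.0), 0.05, 3))
        b = _frame(_nb_counts(rng, np.full(100, 100.0), 0.05, 3), genes=a.index)
        de = nb_fold_change_test(a, b, np.full(3, 1e6), np.full(3, 1e6))
        assert ((de["padj"] >= de["pvalue"] - 1e-12) & (de["padj"] <= 1.0)).all()


class TestMultipleTesting:
    def test_bh_monotone_in_p_rank(self):
        p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p).all()

    def test_bonferroni_via_group_shift(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 50), rng.normal(2, 1, 50)
        raw = group_shift(a, b, test="wilcoxon", alternative="greater")
        corr = group_shift(
            a, b, test="wilcoxon", alternative="greater", correction="bonferroni", n_comparisons=10
        )
        assert corr.pvalue == pytest.approx(min(1.0, raw.pvalue * 10))


class TestGroupShift:
    def test_identical_samples_wilcoxon(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        res = group_shift(x, x.copy(), test="wilcoxon", alternative="greater")
        assert res.pvalue >= 0.5

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        res = group_shift(x + 10, x, test="wilcoxon", alternative="greater")
        assert res.pvalue < 1e-6

    def test_ks_one_sided_direction(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=200)
        up = group_shift(base + 1, base, test="ks", alternative="greater")
        down = group_shift(base - 1, base, test="ks", alternative="greater")
        assert up.pvalue < 1e-6 and down.pvalue > 0.5

    def test_chisq_identical_proportions(self):
        res = group_shift([30, 60, 90], [10, 20, 30], test="chisq")
        assert res.pvalue == pytest.approx(1.0)

    def test_degenerate_inputs_warn_and_return_one(self):
        with pytest.warns(UserWarning):
            res = group_shift([1.0, 1.0], [1.0, 1.0], test="ks")
        assert res.pvalue == 1.0


class TestMaskedDecay:
    def _de(self, rows, cols=("log2fc", "padj")):
        return pd.DataFrame(rows, columns=list(cols)).set_index(
            pd.Index([f"g{i}" for i in range(len(rows))], name="gene_id")
        )

    def test_clause_conjunction(self):
        # g0: strong total decay -> excluded; g1: all clauses met -> flagged;
        # g2: tvu not significant -> excluded; g3: known target -> excluded
        de_total = self._de([(-3.0, 0.9), (-0.2, 0.9), (-0.2, 0.9), (-0.2, 0.9)])
        de_tvu = self._de([(-1.0, 0.001), (-1.0, 0.001), (-1.0, 0.4), (-1.0, 0.001)])
        classes = pd.Series("maternal_zygotic", index=de_total.index)
        has_site = pd.Series([True, True, True, True], index=de_total.index)
        out = masked_decay_genes(de_total, de_tvu, classes, has_site, known_targets={"g3"})
        assert list(out["masked_decay"]) == [False, True, False, False]
        assert out.loc["g1", "group"] == "masked_decay_target"

    def test_positive_tvu_fold_change_not_flagged(self):
        de_total = self._de([(-0.2, 0.9)])
        de_tvu = self._de([(0.5, 0.001)])
        classes = pd.Series("maternal_zygotic", index=de_total.index)
        out = masked_decay_genes(
            de_total, de_tvu, classes, pd.Series(False, index=de_total.index)
        )
        assert not out["masked_decay"].any()

    def test_non_mz_class_never_flagged(self):
        de_total = self._de([(-0.2, 0.9)])
        de_tvu = self._de([(-1.0, 0.001)])
        classes = pd.Series("pure_maternal", index=de_total.index)
        out = masked_decay_genes(
            de_total, de_tvu, classes, pd.Series(True, index=de_total.index)
        )
        assert not out["masked_decay"].any()

    def test_missing_input_refused(self):
        de = self._de([(-0.2, 0.9)])
        with pytest.raises(ValueError):
            masked_decay_genes(de, de.iloc[:0], pd.Series(dtype=str), pd.Series(dtype=bool))


class TestLnaDerepression:
    def test_shifted_targets_detected_and_cpm_filter_applied(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(400)]
        fc = rng.normal(0, 0.3, 400)
        fc[:100] += 1.0  # de-repressed targets
        de = pd.DataFrame({"log2fc": fc}, index=pd.Index(genes, name="gene_id"))
        targets = set(genes[:100])
        controls = set(genes[200:])
        cpm = pd.Series(10.0, index=genes)
        cpm[genes[:50]] = 0.5  # half the targets fail the >2 labeled CPM filter
        res = lna_derepression({"labeled": de}, targets, controls, cpm)
        assert res["labeled"].pvalue < 0.01
        assert res["labeled"].n_a == 50

    def test_empty_target_set_skipped_with_warning(self):
        de = pd.DataFrame(
            {"log2fc": [0.1]}, index=pd.Index(["g0"], name="gene_id")
        )
        with pytest.warns(UserWarning):
            res = lna_derepression({"labeled": de}, set(), {"g0"})
        assert res == {}
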