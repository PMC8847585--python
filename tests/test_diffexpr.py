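"""Normalization, NB Wald testing, BH correction, FPKM and ddCt."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from prc2sig import diffexpr
from prc2sig.diffexpr import (
    bh_adjust,
    call_degs,
    ddct_fold_change,
    fpkm,
    nb_wald_test,
    size_factors,
)

CONDS = ["control"] * 3 + ["treated"] * 3


def nb_counts(seed, n=2000, mean=200.0, disp=0.05, lfc=0.0, spike_frac=0.0, reps=3):
    """NB count matrix; the first ``spike_frac`` of genes get +-lfc (balanced)."""
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(np.log(mean) - 0.18, 0.6, n)
    size = 1.0 / disp
    fold = np.ones(n)
    k = int(n * spike_frac)
    fold[: k // 2] = 2.0 ** lfc
    fold[k // 2 : k] = 2.0 ** -lfc

    def draw(m):
        return rng.negative_binomial(size, size / (size + m[:, None]), (len(m), reps))

    cols = [f"c{i}" for i in range(reps)] + [f"t{i}" for i in range(reps)]
    counts = pd.DataFrame(np.hstack([draw(mu), draw(mu * fold)]), columns=cols)
    return counts, k


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_sample_worked_example(self):
        counts = pd.DataFrame({"a": [10, 100, 4], "b": [20, 200, 8]})
        assert np.allclose(size_factors(counts), [0.70710678, 1.41421356])

    def test_invariant_to_gene_order(self):
        counts, _ = nb_counts(0, n=100)
        shuffled = counts.sample(frac=1.0, random_state=1)
        assert np.allclose(size_factors(counts), size_factors(shuffled))

    def test_no_reference_gene_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="all-positive"):
            size_factors(counts)


class TestBH:
    def test_single_pvalue_unchanged(self):
        assert np.isclose(bh_adjust([0.03])[0], 0.03)

    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_step_up_definition(self, pvals):
        """padj_i = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j), capped."""
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        ranked = p[order]
        oracle_sorted = np.minimum.accumulate(
            (ranked * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(oracle_sorted, 1.0)
        assert np.allclose(bh_adjust(p), oracle)

    def test_monotone_and_dominating(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=200)
        padj = bh_adjust(p)
        assert (padj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestNBWald:
    def test_identical_arms_are_null(self):
        base = pd.DataFrame(
            {"g": [100, 50, 400, 10, 77, 250, 31, 5, 999, 123]}
        ).to_numpy()
        counts = pd.DataFrame(
            np.repeat(base, 6, axis=1), columns=[f"s{i}" for i in range(6)]
        )
        res = nb_wald_test(counts, CONDS)
        assert np.allclose(res.log2fc, 0.0)
        assert (res.p > 0.99).all()

    def test_null_type_one_error_calibrated(self):
        """Raw p < 0.05 fraction stays near nominal over 3 replicate nulls."""
        fracs = [
            (nb_wald_test(nb_counts(seed)[0], CONDS).p < 0.05).mean()
            for seed in (1, 2, 3)
        ]
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_null_pvalues_approximately_uniform(self):
        res = nb_wald_test(nb_counts(7)[0], CONDS)
        assert kstest(res.p, "uniform").statistic < 0.05

    def test_strong_spike_detected(self):
        counts, _ = nb_counts(3, n=500)
        mu = 500.0
        rng = np.random.default_rng(9)
        size = 1 / 0.05
        spiked = np.concatenate(
            [
                rng.negative_binomial(size, size / (size + mu), 3),
                rng.negative_binomial(size, size / (size + 8 * mu), 3),
            ]
        )
        counts.loc[len(counts)] = spiked
        res = nb_wald_test(counts, CONDS)
        assert res.p.iloc[-1] < 1e-4

    def test_power_monotone_in_effect_size(self):
        rates = []
        for lfc in (1.0, 2.0):
            counts, k = nb_counts(11, n=1000, lfc=lfc, spike_frac=0.1)
            res = nb_wald_test(counts, CONDS)
            detected = (res.padj.to_numpy()[:k] <= 0.05).mean()
            rates.append(detected)
        assert rates[1] >= rates[0]

    def test_single_replicate_arm_rejected(self):
        counts, _ = nb_counts(0, n=20)
        with pytest.raises(ValueError, match="replicates"):
            nb_wald_test(counts, ["control"] * 5 + ["treated"])

    def test_log2fc_agrees_with_established_nb_glm(self):
        """Independent cross-check against the DESeq2-style reference fit."""
        pytest.importorskip("pydeseq2")
        import contextlib
        import io as stdio

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        counts, _ = nb_counts(5, n=150, lfc=2.0, spike_frac=0.2)
        res = nb_wald_test(counts, CONDS)
        meta = pd.DataFrame({"condition": CONDS}, index=counts.columns)
        with contextlib.redirect_stdout(stdio.StringIO()):
            dds = DeseqDataSet(
                counts=counts.T, metadata=meta, design="~condition", quiet=True
            )
            dds.deseq2()
            st_ = DeseqStats(dds, contrast=["condition", "treated", "control"], quiet=True)
            st_.summary()
        ref = st_.results_df["log2FoldChange"].to_numpy()
        r = np.corrcoef(res.log2fc.to_numpy(), ref)[0, 1]
        assert r > 0.95


class TestCallDegs:
    def make_result(self, rows):
        table = pd.DataFrame(rows, columns=["log2fc", "p", "padj"])
        table.index = [f"g{i}" for i in range(len(rows))]
        return diffexpr.DEResult(table)

    def test_boundary_is_inclusive(self):
        res = self.make_result([(1.0, 0.01, 0.05)])
        up, down = call_degs(res)
        assert up == ["g0"] and down == []

    def test_all_insignificant_empty(self):
        res = self.make_result([(3.0, 1.0, 1.0), (-3.0, 1.0, 1.0)])
        assert call_degs(res) == ([], [])

    def test_toy_table_membership(self):
        res = self.make_result(
            [
                (1.5, 0.001, 0.01),   # up
                (0.9, 0.001, 0.01),   # |lfc| below threshold
                (-2.0, 0.002, 0.04),  # down
                (2.5, 0.2, 0.51),     # padj above alpha
                (-1.0, 0.01, 0.05),   # down, both boundaries
            ]
        )
        up, down = call_degs(res)
        assert up == ["g0"] and down == ["g2", "g4"]

    def test_up_down_disjoint(self):
        counts, _ = nb_counts(13, n=300, lfc=1.5, spike_frac=0.3)
        res = nb_wald_test(counts, CONDS)
        up, down = call_degs(res)
        assert not set(up) & set(down)


class TestFpkmAndDdct:
    def test_fpkm_unit_plug_in(self):
        counts = pd.DataFrame({"s": [10, 0]})
        out = fpkm(counts, [1000, 500], [1_000_000])
        assert np.isclose(out.iloc[0, 0], 10.0)
        assert out.iloc[1, 0] == 0.0

    def test_fpkm_halves_when_library_doubles(self):
        counts = pd.DataFrame({"s1": [10], "s2": [10]})
        out = fpkm(counts, [1000], [1_000_000, 2_000_000])
        assert np.isclose(out.iloc[0, 0], 2 * out.iloc[0, 1])

    def test_fpkm_zero_length_rejected(self):
        with pytest.raises(ValueError):
            fpkm(pd.DataFrame({"s": [1]}), [0], [100])

    @pytest.mark.parametrize(
        "cts,expected",
        [((20, 15, 20, 15), 1.0), ((20, 15, 18, 15), 0.25), ((19, 15, 20, 15), 2.0)],
    )
    def test_ddct_fold_changes(self, cts, expected):
        assert np.isclose(ddct_fold_change(*cts), expected)
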