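"""A/B compartment calling, switch classification, expression association."""

import numpy as np
import pandas as pd
import pytest

from diffarch.compartments import (
    CompartmentError, CompartmentTrack, classify_switches, compartment_pc1,
    expression_by_category, genes_by_switch_category, switch_fractions,
)
from diffarch.genome import BinTable, SignalTrack
from diffarch.matrix import ContactMatrix


def plaid_matrix(block_vector, scale=100.0, strength=0.3, alpha=1.0, seed=None):
    """Checkerboard contact matrix from a planted ±1 block vector."""
    e = np.asarray(block_vector, dtype=float)
    n = len(e)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    same = np.outer(e, e) > 0
    mu = scale * (d + 1.0) ** (-alpha) * np.where(same, 1 + strength, 1 - strength)
    if seed is not None:
        rng = np.random.default_rng(seed)
        c = rng.poisson(np.triu(mu)).astype(float)
        mu = np.triu(c) + np.triu(c, 1).T
    return ContactMatrix(BinTable("chr1", n * 100_000, 100_000), mu)


def track_from_vector(e, binsize=100_000, high=2.0, low=0.5):
    """Reference signal higher on +1 blocks (open chromatin proxy)."""
    vals = np.where(np.asarray(e) > 0, high, low)
    t = SignalTrack()
    n = len(vals)
    starts = np.arange(n) * binsize
    t.add_chrom("chr1", starts, starts + binsize, vals)
    return t


def planted_vector(n=60, block=6, seed=0):
    rng = np.random.default_rng(seed)
    e = []
    lab = 1
    while len(e) < n:
        e.extend([lab] * block)
        lab = -lab
    return np.asarray(e[:n])


class TestCompartmentPC1:
    def test_recovers_planted_blocks(self):
        e = planted_vector()
        m = plaid_matrix(e, seed=1)
        t = compartment_pc1(m, track_from_vector(e))
        labels = t.labels
        expect = np.where(e > 0, "A", "B")
        agreement = np.mean(labels == expect)
        assert agreement >= 0.95

    def test_negated_planting_flips_all_labels(self):
        # the checkerboard itself is sign-symmetric: the flip is carried by
        # the orientation reference, which tracks the open compartment
        e = planted_vector()
        t1 = compartment_pc1(plaid_matrix(e), track_from_vector(e))
        t2 = compartment_pc1(plaid_matrix(-e), track_from_vector(-e))
        ok = (t1.labels != "NA") & (t2.labels != "NA")
        assert np.all(t1.labels[ok] != t2.labels[ok])

    def test_reference_rescaling_preserves_labels(self):
        # scaling the reference keeps quartile membership, hence orientation
        e = planted_vector()
        m = plaid_matrix(e, seed=3)
        t1 = compartment_pc1(m, track_from_vector(e))
        t2 = compartment_pc1(m, track_from_vector(e).scale(10.0))
        np.testing.assert_array_equal(t1.labels, t2.labels)

    def test_scale_invariance(self):
        e = planted_vector()
        ref = track_from_vector(e)
        m = plaid_matrix(e, seed=2)
        t1 = compartment_pc1(m, ref)
        t2 = compartment_pc1(m.scaled(13.7), ref)
        np.testing.assert_array_equal(t1.labels, t2.labels)

    def test_uniform_matrix_is_degenerate(self):
        n = 30
        m = ContactMatrix(BinTable("chr1", n * 100_000, 100_000), np.full((n, n), 5.0))
        with pytest.raises(CompartmentError, match="no compartment signal"):
            compartment_pc1(m, track_from_vector(np.ones(n)))

    def test_too_few_bins_is_error(self):
        e = planted_vector(n=6)
        with pytest.raises(CompartmentError, match="insufficient bins"):
            compartment_pc1(plaid_matrix(e), track_from_vector(e))


class TestClassifySwitches:
    def _track(self, pc1):
        pc1 = np.asarray(pc1, dtype=float)
        return CompartmentTrack(BinTable("chr1", len(pc1) * 100_000, 100_000), pc1)

    def test_category_mapping(self):
        t1 = self._track([1, 1, -1, -1, np.nan])
        t2 = self._track([1, -1, 1, -1, 1])
        sw = classify_switches(t1, t2)
        assert sw["category"].tolist() == ["A->A", "A->B", "B->A", "B->B", "NA"]

    def test_identity_gives_all_stable(self):
        t = self._track([1, -1, 1, -1])
        sw = classify_switches(t, t)
        fr = switch_fractions(sw)
        stable = fr[fr["category"].isin(["A->A", "B->B"])]["pct_of_informative"].sum()
        assert stable == pytest.approx(100.0)
        assert fr[fr["category"].isin(["A->B", "B->A"])]["n_bins"].sum() == 0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        a = self._track(rng.normal(size=50))
        b = self._track(rng.normal(size=50))
        f1 = switch_fractions(classify_switches(a, b)).set_index("category")
        f2 = switch_fractions(classify_switches(b, a)).set_index("category")
        assert f1.loc["A->B", "n_bins"] == f2.loc["B->A", "n_bins"]
        assert f1.loc["B->A", "n_bins"] == f2.loc["A->B", "n_bins"]

    def test_planted_flip_fractions_exact(self):
        base = np.ones(100)
        base[:50] = -1
        flipped = base.copy()
        flipped[:10] = 1    # 10 planted B->A
        flipped[50:60] = -1  # 10 planted A->B
        sw = classify_switches(self._track(base), self._track(flipped))
        fr = switch_fractions(sw).set_index("category")
        assert fr.loc["A->B", "pct_of_informative"] == pytest.approx(10.0)
        assert fr.loc["B->A", "pct_of_informative"] == pytest.approx(10.0)

    def test_fractions_sum_to_100(self):
        rng = np.random.default_rng(1)
        sw = classify_switches(self._track(rng.normal(size=40)),
                               self._track(rng.normal(size=40)))
        fr = switch_fractions(sw)
        assert fr["pct_of_informative"].sum() == pytest.approx(100.0)

    def test_mismatched_bins_rejected(self):
        with pytest.raises(CompartmentError):
            classify_switches(self._track([1, -1]), self._track([1, -1, 1]))


class TestGenesByCategory:
    def _switch_table(self):
        t1 = CompartmentTrack(BinTable("chr1", 400_000, 100_000),
                              np.array([1.0, 1.0, -1.0, np.nan]))
        t2 = CompartmentTrack(BinTable("chr1", 400_000, 100_000),
                              np.array([1.0, -1.0, 1.0, np.nan]))
        return classify_switches(t1, t2)

    def _expr(self):
        return pd.DataFrame({
            "gene": ["gA", "gAB", "gBA", "gNA", "gNonDE"],
            "chrom": "chr1",
            "start": [50_000, 150_000, 250_000, 350_000, 50_000],
            "end": [60_000, 160_000, 260_000, 360_000, 60_000],
            "strand": "+",
            "fpkm1": 1.0, "fpkm2": 2.0, "log2fc": 1.0,
            "is_de": [True, True, True, True, False],
        })

    def test_tss_bin_assignment_and_drops(self):
        groups, dropped = genes_by_switch_category(self._switch_table(), self._expr())
        assert list(groups["A->A"]["gene"]) == ["gA"]
        assert list(groups["A->B"]["gene"]) == ["gAB"]
        assert list(groups["B->A"]["gene"]) == ["gBA"]
        assert dropped == 1          # gNA sits in the masked bin
        total = sum(len(g) for g in groups.values())
        assert total == 3            # partition of retained DEGs

    def test_minus_strand_gene_uses_its_tss(self):
        expr = self._expr()
        # minus-strand gene spanning bins 1-2; TSS at end-1 = bin 2 (B->A)
        expr.loc[1, ["start", "end", "strand"]] = [150_000, 250_001, "-"]
        groups, _ = genes_by_switch_category(self._switch_table(), expr)
        assert "gAB" in set(groups["B->A"]["gene"])


class TestExpressionByCategory:
    def _groups(self, seed=0, n=50):
        rng = np.random.default_rng(seed)

        def frame(fcs):
            fcs = np.asarray(fcs)
            return pd.DataFrame({
                "gene": [f"g{i}" for i in range(len(fcs))],
                "fpkm1": np.full(len(fcs), 4.0),
                "fpkm2": 4.0 * 2.0 ** fcs,
                "log2fc": fcs,
            })

        return {
            "B->A": frame(rng.normal(1.5, 0.5, n)),
            "A->B": frame(rng.normal(-1.5, 0.5, n)),
        }

    def test_planted_direction_and_significance(self):
        stats = expression_by_category(self._groups()).set_index("category")
        assert stats.loc["B->A", "median_log2fc"] > 0 > stats.loc["A->B", "median_log2fc"]
        assert stats.loc["B->A", "p_vs_A->B"] < 1e-6

    def test_identical_groups_are_null(self):
        g = self._groups()
        g["A->B"] = g["B->A"].copy()
        stats = expression_by_category(g).set_index("category")
        assert stats.loc["B->A", "median_log2fc"] == stats.loc["A->B", "median_log2fc"]
        assert stats.loc["B->A", "p_vs_A->B"] > 0.9

    def test_small_category_reports_nan_p(self):
        g = self._groups()
        g["A->B"] = g["A->B"].iloc[:2]
        stats = expression_by_category(g).set_index("category")
        assert np.isnan(stats.loc["B->A", "p_vs_A->B"])
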