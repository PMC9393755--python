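"""Loop detection, significant interactions, classification, APA."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_null_matrix
from diffarch.genome import BinTable
from diffarch.loops import (
    LoopError, _nb_tail_p, apa, classify_loops, detect_loops, loops_to_bedpe,
    read_bedpe, significant_interactions,
)
from diffarch.matrix import ContactMatrix


def decay_matrix_with_peaks(peaks, n=1200, scale=1200.0, enrichment=5.0,
                            resolution=10_000, seed=0):
    """Distance decay + Poisson noise with planted focal peaks."""
    rng = np.random.default_rng(seed)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    mu = scale * (d + 1.0) ** -1.0
    for i, j in peaks:
        mu[i, j] *= enrichment
        mu[j, i] = mu[i, j]
    c = rng.poisson(np.triu(mu)).astype(float)
    c = np.triu(c) + np.triu(c, 1).T
    return ContactMatrix(BinTable("chr1", n * resolution, resolution), c)


def plant_peaks(rng, n=1200, count=20, dmin=10, dmax=100, margin=15, sep=15):
    peaks = []
    while len(peaks) < count:
        d = int(rng.integers(dmin, dmax + 1))
        i = int(rng.integers(margin, n - margin - d))
        j = i + d
        if all(max(abs(i - a), abs(j - b)) > sep for a, b in peaks):
            peaks.append((i, j))
    return peaks


class TestDetectLoops:
    def test_planted_peaks_recovered(self):
        rng = np.random.default_rng(11)
        peaks = plant_peaks(rng)
        m = decay_matrix_with_peaks(peaks, seed=11)
        calls = detect_loops(m)
        hits = sum(
            any(max(abs(r.bin1 - i), abs(r.bin2 - j)) <= 1 for r in calls.itertuples())
            for i, j in peaks)
        assert hits / len(peaks) >= 0.8
        assert (calls["distance"] <= 1_000_000).all()

    def test_no_calls_beyond_max_distance(self):
        # peak planted at 1.2 Mb is outside the search range
        far = [(100, 220)]  # 120 bins * 10 kb = 1.2 Mb
        m = decay_matrix_with_peaks(far, seed=3, enrichment=50.0)
        calls = detect_loops(m)
        assert not ((calls["bin1"] == 100) & (calls["bin2"] == 220)).any()

    def test_null_matrix_rarely_calls(self):
        calls = detect_loops(make_null_matrix(0, n=1000))
        assert len(calls) <= 2

    def test_empty_matrix_gives_empty_loopset(self):
        m = ContactMatrix(BinTable("chr1", 500_000, 10_000), np.zeros((50, 50)))
        assert len(detect_loops(m)) == 0

    def test_poisson_fallback_under_dispersed(self):
        # variance <= mean: NB fit impossible, Poisson tail used
        assert _nb_tail_p(10, 2.0, 1.5) == pytest.approx(
            _nb_tail_p(10, 2.0, 2.0))


class TestSignificantInteractions:
    def test_uniform_matrix_gives_no_calls(self):
        n = 300
        m = ContactMatrix(BinTable("chr1", n * 5_000, 5_000), np.full((n, n), 9.0))
        assert len(significant_interactions(m)) == 0

    def test_single_inflated_pixel_called(self):
        n = 400
        rng = np.random.default_rng(5)
        base = rng.poisson(20.0, (n, n)).astype(float)
        base = np.triu(base) + np.triu(base, 1).T
        i, j = 100, 110  # distance 10 bins * 5 kb = 50 kb
        base[i, j] = base[j, i] = 20.0 + 10 * np.sqrt(20.0) * 3
        m = ContactMatrix(BinTable("chr1", n * 5_000, 5_000), base)
        calls = significant_interactions(m)
        assert ((calls["bin1"] == i) & (calls["bin2"] == j)).any()
        top = calls.sort_values("z").iloc[-1]
        assert (top["bin1"], top["bin2"]) == (i, j)

    def test_min_distance_excludes_short_range(self):
        n = 400
        rng = np.random.default_rng(6)
        base = rng.poisson(20.0, (n, n)).astype(float)
        base = np.triu(base) + np.triu(base, 1).T
        base[100, 103] = base[103, 100] = 500.0   # 15 kb apart
        m = ContactMatrix(BinTable("chr1", n * 5_000, 5_000), base)
        calls = significant_interactions(m)
        assert not ((calls["bin1"] == 100) & (calls["bin2"] == 103)).any()


class TestClassifyLoops:
    def _loops(self, anchors):
        return pd.DataFrame({"chrom": "chr1",
                             "bin1": [a for a, _ in anchors],
                             "bin2": [b for _, b in anchors]})

    def test_identity_all_stable(self):
        l = self._loops([(10, 60), (100, 150)])
        out = classify_loops(l, l)
        assert out["cls"].tolist() == ["stable", "stable"]

    def test_condition2_only_is_gained(self):
        out = classify_loops(self._loops([]), self._loops([(100, 200)]))
        assert out["cls"].tolist() == ["gained"]

    def test_partition_arithmetic(self):
        l1 = self._loops([(10, 60), (100, 150), (300, 360)])
        l2 = self._loops([(10, 60), (200, 260)])
        out = classify_loops(l1, l2)
        n = out["cls"].value_counts()
        assert n.get("stable", 0) + n.get("gained", 0) == len(l2)
        assert n.get("stable", 0) + n.get("lost", 0) == len(l1)

    def test_swap_symmetry(self):
        l1 = self._loops([(10, 60), (100, 150)])
        l2 = self._loops([(10, 60), (200, 260), (300, 330)])
        a = classify_loops(l1, l2)["cls"].value_counts()
        b = classify_loops(l2, l1)["cls"].value_counts()
        assert a.get("gained", 0) == b.get("lost", 0)
        assert a.get("lost", 0) == b.get("gained", 0)

    def test_tolerance_matching(self):
        l1 = self._loops([(10, 60)])
        l2 = self._loops([(11, 60)])
        assert sorted(classify_loops(l1, l2, match_tol_bins=0)["cls"]) == \
            ["gained", "lost"]
        assert classify_loops(l1, l2, match_tol_bins=1)["cls"].tolist() == \
            ["stable"]


class TestApa:
    def test_flat_matrix_scores_one(self):
        n = 200
        m = ContactMatrix(BinTable("chr1", n * 10_000, 10_000), np.full((n, n), 4.0))
        loops = pd.DataFrame({"chrom": "chr1", "bin1": [50], "bin2": [120]})
        res = apa(m, loops)
        assert res.score == pytest.approx(1.0)
        assert res.n_loops == 1

    def test_planted_enrichment_scores_high(self):
        rng = np.random.default_rng(21)
        peaks = plant_peaks(rng, count=15, dmin=30)
        m = decay_matrix_with_peaks(peaks, seed=21)
        loops = pd.DataFrame({"chrom": "chr1",
                              "bin1": [i for i, _ in peaks],
                              "bin2": [j for _, j in peaks]})
        assert apa(m, loops).score > 1.5

    def test_loops_near_diagonal_or_edge_skipped(self):
        n = 100
        m = ContactMatrix(BinTable("chr1", n * 10_000, 10_000), np.full((n, n), 4.0))
        loops = pd.DataFrame({"chrom": "chr1",
                              "bin1": [5, 40, 30], "bin2": [95, 55, 80]})
        res = apa(m, loops)   # first: edge; second: too close to diagonal
        assert res.n_loops == 1 and res.n_skipped == 2

    def test_all_skipped_is_error(self):
        n = 50
        m = ContactMatrix(BinTable("chr1", n * 10_000, 10_000), np.full((n, n), 4.0))
        loops = pd.DataFrame({"chrom": "chr1", "bin1": [1], "bin2": [49]})
        with pytest.raises(LoopError):
            apa(m, loops)


class TestBedpeIO:
    def test_round_trip_and_anchor_normalization(self, tmp_path):
        loops = pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "bin1": [50, 120], "bin2": [10, 160],   # first pair reversed
            "p_nb": [0.001, 0.02], "q_nb": [0.01, 0.04],
            "cls": ["gained", "stable"],
        })
        p = tmp_path / "loops.bedpe"
        loops_to_bedpe(loops, 5_000, p)
        back = read_bedpe(p, 5_000)
        assert back[["bin1", "bin2"]].values.tolist() == [[10, 50], [120, 160]]
        assert back["cls"].tolist() == ["gained", "stable"]

    def test_empty_loopset_writes_header_only(self, tmp_path):
        p = tmp_path / "empty.bedpe"
        loops_to_bedpe(pd.DataFrame(columns=["chrom", "bin1", "bin2"]), 5_000, p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#")
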