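"""TAD-separation score, boundary calling, and two-condition classification.

The separation (insulation) score at bin *i* measures how well contacts are
blocked across *i*: for each window size *w*, take the mean of the "diamond"
submatrix between (i-w, i] and (i, i+w], z-score those diamond means per
window across the chromosome, and average the z across windows. Lower score
means stronger insulation; boundaries are significant local minima.

Differential classes follow the standard two-condition logic: boundaries
found in both conditions are *stable*; a boundary found only in condition 2
whose condition-2 score is lower than the condition-1 score at that bin is
*gained*; a boundary found only in condition 1 whose condition-2 score is
higher is *lost*; condition-specific boundaries failing their score
comparison are reported as *unclassified*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ContactMatrix, expected_by_distance
from .stats import bh_adjust, rank_sum_test

__all__ = [
    "SeparationTrack",
    "separation_score",
    "call_boundaries",
    "classify_boundaries",
    "tad_size_stats",
    "window_sizes_in_bins",
]


class TadError(ValueError):
    pass


@dataclass
class SeparationTrack:
    """Multi-window TAD-separation score for one chromosome."""

    chrom: str
    resolution: int
    windows: list[int]          # window sizes in bins
    diamonds: np.ndarray        # (n_windows, n_bins) raw diamond means, NaN undefined
    zscores: np.ndarray         # (n_windows, n_bins) per-window z-scores
    score: np.ndarray           # (n_bins,) mean z across windows, NaN undefined
    matrix: "ContactMatrix | None" = None   # source matrix, for boundary tests
    expected: "np.ndarray | None" = None    # per-distance mean, for O/E pixels

    @property
    def n_bins(self) -> int:
        return self.score.shape[0]

    def diamond_pixels(self, i: int) -> np.ndarray:
        """O/E pixel values of the largest-window diamond at bin ``i``.

        Pixels are divided by the per-distance expectation so the boundary
        test compares homogeneous values; raw pixels would span the whole
        distance-decay range and drown the insulation signal.
        """
        if self.matrix is None or self.expected is None:
            raise TadError("separation track does not carry its source matrix")
        w = max(self.windows)
        valid = self.matrix.valid
        rows = np.arange(i - w + 1, i + 1)
        cols = np.arange(i + 1, i + w + 1)
        rows = rows[(rows >= 0) & valid[np.clip(rows, 0, self.n_bins - 1)]]
        cols = cols[(cols < self.n_bins) & valid[np.clip(cols, 0, self.n_bins - 1)]]
        vals = self.matrix.counts[np.ix_(rows, cols)]
        dist = np.abs(np.subtract.outer(rows, cols))
        exp = self.expected[dist]
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(exp > 0, vals / exp, np.nan)
        return oe[np.isfinite(oe)].ravel()


def window_sizes_in_bins(min_depth: int, max_depth: int, step: int, resolution: int) -> list[int]:
    """Window sizes floor(bp/resolution), duplicates removed, >= 1 bin."""
    if max_depth < min_depth:
        raise TadError("max_depth must be >= min_depth")
    if step <= 0:
        raise TadError("step must be positive")
    out = []
    for bp in range(min_depth, max_depth + 1, step):
        w = bp // resolution
        if w >= 1 and w not in out:
            out.append(w)
    return out


def separation_score(
    m: ContactMatrix,
    min_depth: int = 15000,
    max_depth: int = 75000,
    step: int = 7500,
) -> SeparationTrack:
    """Multi-window diamond insulation score (z-score units)."""
    res = m.resolution
    if min_depth < 2 * res:
        raise TadError(f"min_depth ({min_depth}) must be >= 2x resolution ({res})")
    windows = window_sizes_in_bins(min_depth, max_depth, step, res)
    n = m.n_bins
    wmax = max(windows)
    diamonds = np.full((len(windows), n), np.nan)
    if n < 2 * wmax + 1:
        # chromosome too short for the largest window: empty track
        return SeparationTrack(m.chrom, res, windows, diamonds,
                               diamonds.copy(), np.full(n, np.nan))
    # 2D prefix sums for O(1) diamond block sums
    c = np.zeros((n + 1, n + 1))
    c[1:, 1:] = np.cumsum(np.cumsum(m.counts, axis=0), axis=1)
    nval = np.zeros(n + 1)
    nval[1:] = np.cumsum(m.valid)
    # score defined only where every window fits: i in [wmax-1, n-1-wmax]
    idx = np.arange(wmax - 1, n - wmax)
    for k, w in enumerate(windows):
        r0, r1 = idx - w + 1, idx + 1        # rows [i-w+1, i]
        c0, c1 = idx + 1, idx + w + 1        # cols [i+1, i+w]
        block = c[r1, c1] - c[r0, c1] - c[r1, c0] + c[r0, c0]
        # masked bins have zero rows/cols: average over valid cells only,
        # requiring at least half the diamond to be informative
        ncell = (nval[r1] - nval[r0]) * (nval[c1] - nval[c0])
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(ncell >= 0.5 * w * w, block / ncell, np.nan)
        diamonds[k, idx] = vals
    zscores = np.full_like(diamonds, np.nan)
    for k in range(len(windows)):
        row = diamonds[k]
        ok = np.isfinite(row)
        if ok.sum() > 1 and np.nanstd(row) > 0:
            mu, sd = np.nanmean(row), np.nanstd(row)
            zscores[k, ok] = (row[ok] - mu) / sd
        elif ok.sum() > 0:
            zscores[k, ok] = 0.0
    defined = np.isfinite(diamonds).all(axis=0)
    score = np.full(n, np.nan)
    if defined.any():
        score[defined] = zscores[:, defined].mean(axis=0)
    return SeparationTrack(m.chrom, res, windows, diamonds, zscores, score,
                           matrix=m, expected=expected_by_distance(m).values)


def _local_extrema(score: np.ndarray):
    """Indices of local minima and maxima (flat runs resolve leftmost)."""
    minima, maxima = [], []
    ok = np.isfinite(score)
    for i in range(1, len(score) - 1):
        if not (ok[i - 1] and ok[i] and ok[i + 1]):
            continue
        if score[i] < score[i - 1] and score[i] <= score[i + 1]:
            minima.append(i)
        if score[i] > score[i - 1] and score[i] >= score[i + 1]:
            maxima.append(i)
    return np.asarray(minima, dtype=int), np.asarray(maxima, dtype=int)


def call_boundaries(
    t: SeparationTrack,
    delta: float = 0.01,
    threshold_comparisons: float = 0.01,
) -> pd.DataFrame:
    """Call TAD boundaries as significant local minima of the separation score.

    A candidate minimum is retained if (a) its score lies at least ``delta``
    below the lesser of the flanking local maxima, and (b) a one-sided
    rank-sum test of the diamond pixel values at the minimum against those
    pooled at the flanking maxima gives BH-adjusted q <
    ``threshold_comparisons``. Pixel values (not the per-window means) carry
    the test: neighboring window means are strongly correlated, so they
    would separate at every noise minimum.

    Returns a table with columns chrom/bin/start/end/score/p/q.
    """
    score = t.score
    if np.isfinite(score).sum() < 3:
        return pd.DataFrame(columns=["chrom", "bin", "start", "end", "score", "p", "q"])
    minima, maxima = _local_extrema(score)
    cands = []
    for i in minima:
        left = maxima[maxima < i]
        right = maxima[maxima > i]
        finite = np.flatnonzero(np.isfinite(score))
        lmax = score[left[-1]] if len(left) else np.nanmax(score[finite[0]: i]) if i > finite[0] else np.nan
        rmax = score[right[0]] if len(right) else np.nanmax(score[i + 1: finite[-1] + 1]) if i < finite[-1] else np.nan
        if not (np.isfinite(lmax) and np.isfinite(rmax)):
            continue
        if score[i] > min(lmax, rmax) - delta:
            continue
        li = left[-1] if len(left) else int(finite[0] + np.nanargmax(score[finite[0]: i]))
        ri = right[0] if len(right) else int(i + 1 + np.nanargmax(score[i + 1: finite[-1] + 1]))
        at_min = t.diamond_pixels(i)
        at_max = np.concatenate([t.diamond_pixels(li), t.diamond_pixels(ri)])
        _, p = rank_sum_test(at_min, at_max, alternative="less")
        cands.append({"bin": int(i), "score": float(score[i]), "p": p})
    if not cands:
        return pd.DataFrame(columns=["chrom", "bin", "start", "end", "score", "p", "q"])
    df = pd.DataFrame(cands)
    df["q"] = bh_adjust(df["p"].to_numpy())
    df = df[df["q"] < threshold_comparisons].reset_index(drop=True)
    df.insert(0, "chrom", t.chrom)
    df.insert(2, "start", df["bin"] * t.resolution)
    df.insert(3, "end", (df["bin"] + 1) * t.resolution)
    return df


def _smoothed_score(t: SeparationTrack, i: int, half: int = 1) -> float:
    lo, hi = max(0, i - half), min(t.n_bins, i + half + 1)
    vals = t.score[lo:hi]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if len(vals) else np.nan


def classify_boundaries(
    b1: pd.DataFrame,
    b2: pd.DataFrame,
    t1: SeparationTrack,
    t2: SeparationTrack,
    match_tol_bins: int = 1,
) -> pd.DataFrame:
    """Stable / gained / lost / unclassified classes for the boundary union.

    Boundaries matched across conditions within ``match_tol_bins`` are
    stable. Condition-2-only boundaries with a lower (±1-bin-averaged)
    condition-2 score than condition 1 at that bin are gained; condition-1
    -only boundaries with a higher condition-2 score are lost; remaining
    condition-specific boundaries are unclassified.
    """
    if (t1.chrom, t1.resolution) != (t2.chrom, t2.resolution) or t1.n_bins != t2.n_bins:
        raise TadError("separation tracks do not share a bin table")
    bins1 = b1["bin"].to_numpy(dtype=int) if len(b1) else np.array([], dtype=int)
    bins2 = b2["bin"].to_numpy(dtype=int) if len(b2) else np.array([], dtype=int)
    # greedy nearest matching, each boundary used once
    pairs = sorted(
        ((abs(int(x) - int(y)), i, j) for i, x in enumerate(bins1)
         for j, y in enumerate(bins2) if abs(int(x) - int(y)) <= match_tol_bins),
    )
    used1, used2, matched = set(), set(), []
    for _, i, j in pairs:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        matched.append((i, j))
    rows = []
    for i, j in matched:
        b = int(bins1[i])
        rows.append({"bin": b, "bin_cond2": int(bins2[j]), "cls": "stable",
                     "score1": _smoothed_score(t1, b), "score2": _smoothed_score(t2, b)})
    for j, b in enumerate(bins2):
        if j in used2:
            continue
        s1, s2 = _smoothed_score(t1, int(b)), _smoothed_score(t2, int(b))
        cls = "gained" if np.isfinite(s1) and np.isfinite(s2) and s2 < s1 else "unclassified"
        rows.append({"bin": int(b), "bin_cond2": int(b), "cls": cls,
                     "score1": s1, "score2": s2})
    for i, b in enumerate(bins1):
        if i in used1:
            continue
        s1, s2 = _smoothed_score(t1, int(b)), _smoothed_score(t2, int(b))
        cls = "lost" if np.isfinite(s1) and np.isfinite(s2) and s2 > s1 else "unclassified"
        rows.append({"bin": int(b), "bin_cond2": int(b), "cls": cls,
                     "score1": s1, "score2": s2})
    df = pd.DataFrame(rows, columns=["bin", "bin_cond2", "cls", "score1", "score2"])
    df.insert(0, "chrom", t1.chrom)
    df["start"] = df["bin"] * t1.resolution
    df["end"] = (df["bin"] + 1) * t1.resolution
    return df.sort_values("bin").reset_index(drop=True)


def tad_size_stats(
    boundaries1: dict[str, pd.DataFrame],
    boundaries2: dict[str, pd.DataFrame],
    resolution: int,
) -> dict:
    """TAD counts and size distributions per condition, with a rank-sum test.

    TADs are the intervals between consecutive boundaries on a chromosome;
    the regions before the first and after the last boundary are not counted.
    """
    def sizes(per_chrom):
        out = []
        for df in per_chrom.values():
            b = np.sort(df["bin"].to_numpy(dtype=int))
            if len(b) >= 2:
                out.extend((np.diff(b) * resolution).tolist())
        return np.asarray(out, dtype=float)

    s1, s2 = sizes(boundaries1), sizes(boundaries2)
    if len(s1) >= 2 and len(s2) >= 2:
        _, p = rank_sum_test(s1, s2, alternative="two-sided")
    else:
        p = np.nan
    return {
        "n_tads": (len(s1), len(s2)),
        "sizes": (s1, s2),
        "median_size": (float(np.median(s1)) if len(s1) else np.nan,
                        float(np.median(s2)) if len(s2) else np.nan),
        "p_size": p,
    }
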