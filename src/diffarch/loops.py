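"""Chromatin loop detection, differential classification, and APA scoring.

Loop detection follows a three-stage scheme: (1) strict candidate selection
— pixels enriched over the distance-decay expectation and above a high
per-distance quantile; (2) a negative-binomial tail test against the pixel's
distance stratum (method-of-moments fit; Poisson fallback when the stratum
is under-dispersed); (3) a one-sided rank-sum test of the peak against its
surrounding neighborhood on the observed/expected scale. The NB p-values
are BH-adjusted within the chromosome; adjacent significant pixels are
merged (8-connected) into one loop at the local maximum.

A HOMER-style significant-interaction caller (per-distance z-score) and
aggregate peak analysis (APA) are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import ContactMatrix, expected_by_distance
from .stats import bh_adjust, rank_sum_test

__all__ = [
    "detect_loops",
    "significant_interactions",
    "classify_loops",
    "apa",
    "ApaResult",
    "loops_to_bedpe",
    "read_bedpe",
]

LOOP_COLUMNS = [
    "chrom", "bin1", "bin2", "distance", "observed", "expected",
    "p_nb", "q_nb", "p_rank", "cls",
]


class LoopError(ValueError):
    pass


def _empty_loopset() -> pd.DataFrame:
    return pd.DataFrame(columns=LOOP_COLUMNS)


def _pooled_dispersion(stratum_ratios, stratum_invmu, min_pixels: int = 20):
    """Per-distance extra-Poisson dispersion alpha, sparse strata pooled.

    For raw counts Y with per-pixel expectation m under the null,
    Var(Y) = m + alpha*m^2, so Var(Y/m) ~ mean(1/m) + alpha; alpha is
    estimated by method of moments per distance stratum. alpha = 0 (the
    under-dispersed case) falls back to a Poisson tail.
    """
    ds = sorted(stratum_ratios)
    alphas = {}
    group_r, group_i, group_ds = [], [], []
    for d in ds + [None]:
        if d is not None:
            group_r.append(stratum_ratios[d])
            group_i.append(stratum_invmu[d])
            group_ds.append(d)
        enough = sum(len(g) for g in group_r) >= min_pixels
        if group_ds and (enough or d is None):
            r = np.concatenate(group_r)
            inv = np.concatenate(group_i)
            v = float(r.var(ddof=1)) if len(r) > 1 else 0.0
            alpha = max(v - float(inv.mean()), 0.0)
            for gd in group_ds:
                alphas[gd] = alpha
            group_r, group_i, group_ds = [], [], []
    return alphas


def _nb_tail_p(x: float, mu: float, var: float) -> float:
    """P(X >= x) under a method-of-moments NB (Poisson fallback if var<=mu)."""
    if mu <= 0:
        return 1.0
    k = max(int(np.round(x)), 0)
    if var > mu:
        r = mu * mu / (var - mu)
        p = r / (r + mu)
        return float(sps.nbinom.sf(k - 1, r, p))
    return float(sps.poisson.sf(k - 1, mu))


def _ring_oe(counts, expected, n, i, j, peak_width, neighborhood_width, valid):
    """O/E values in the square ring around (i, j), excluding the peak block."""
    vals = []
    for di in range(-neighborhood_width, neighborhood_width + 1):
        for dj in range(-neighborhood_width, neighborhood_width + 1):
            if abs(di) <= peak_width and abs(dj) <= peak_width:
                continue
            a, b = i + di, j + dj
            if a < 0 or b < 0 or a >= n or b >= n:
                continue
            if a > b:
                a, b = b, a
            d = b - a
            if d < 1 or not (valid[a] and valid[b]):
                continue
            e = expected[d]
            if e > 0:
                vals.append(counts[a, b] / e)
    return np.asarray(vals)


def detect_loops(
    m: ContactMatrix,
    max_distance: int = 1_000_000,
    p_threshold: float = 0.05,
    peak_width: int = 1,
    neighborhood_width: int = 5,
    min_enrichment: float = 2.0,
    candidate_quantile: float = 0.95,
) -> pd.DataFrame:
    """Call focal chromatin loops on a corrected intra-chromosomal matrix."""
    n = m.n_bins
    if m.total == 0:
        return _empty_loopset()
    valid = m.valid
    expected = expected_by_distance(m).values
    res = m.resolution
    d_min = neighborhood_width + 1          # keep the ring off the diagonal
    d_max = min(max_distance // res, n - 1)
    counts = m.counts
    # per-bin biases: the NB test runs on the raw-count scale, where the
    # null expectation of pixel (i,j) is expected[d] * w_i * w_j; testing
    # corrected counts directly would inflate tails at low-coverage bins
    if m.weights is not None:
        w = m.weights
    else:
        w = np.where(valid, 1.0, np.nan)

    # local (donut) background: ring mean of the O/E matrix around each
    # pixel, via prefix sums; this is what distinguishes a focal peak from
    # shared structural (TAD/compartment) elevation
    dist = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((expected[dist] > 0) & valid[:, None] & valid[None, :],
                      counts / np.where(expected[dist] > 0, expected[dist], 1.0),
                      0.0)
    vmask = (valid[:, None] & valid[None, :]).astype(float)

    def _boxsum(a, h):
        s = np.zeros((n + 1, n + 1))
        s[1:, 1:] = np.cumsum(np.cumsum(a, axis=0), axis=1)
        r0 = np.clip(np.arange(n) - h, 0, n)
        r1 = np.clip(np.arange(n) + h + 1, 0, n)
        return s[np.ix_(r1, r1)] - s[np.ix_(r0, r1)] - s[np.ix_(r1, r0)] + s[np.ix_(r0, r0)]

    ring_sum = _boxsum(oe, neighborhood_width) - _boxsum(oe, peak_width)
    ring_cnt = _boxsum(vmask, neighborhood_width) - _boxsum(vmask, peak_width)
    with np.errstate(invalid="ignore", divide="ignore"):
        local_bg = np.where(ring_cnt > 0, ring_sum / ring_cnt, np.nan)
    local_bg = np.maximum(local_bg, 0.5)   # floor: depleted neighborhoods

    stratum_ratios: dict[int, np.ndarray] = {}
    stratum_invmu: dict[int, np.ndarray] = {}
    stratum_idx: dict[int, np.ndarray] = {}
    candidates = []
    for d in range(d_min, d_max + 1):
        diag = np.diagonal(counts, offset=d)
        ok = valid[: n - d] & valid[d:]
        vals = diag[ok]
        if len(vals) == 0 or expected[d] <= 0:
            continue
        wprod = (w[: n - d] * w[d:])[ok]
        bg_diag = np.diagonal(local_bg, offset=d)
        mu_raw = bg_diag[ok] * expected[d] * wprod
        stratum_ratios[d] = vals * wprod / mu_raw       # raw / null expectation
        stratum_invmu[d] = 1.0 / mu_raw
        stratum_idx[d] = np.flatnonzero(ok)
        # enrichment is judged against the pixel's own null (local background
        # x distance expectation), plus a per-distance high-quantile cut
        q_cut = float(np.quantile(vals, candidate_quantile))
        hits = np.flatnonzero(
            ok & (diag >= min_enrichment * bg_diag[: n - d] * expected[d])
            & (diag >= q_cut) & (diag > 0)
        )
        for i in hits:
            candidates.append((int(i), int(i + d)))
    if not candidates:
        return _empty_loopset()

    # NB tail p for EVERY tested pixel; BH must run over the whole tested
    # family — correcting only pre-selected candidates would void FDR control
    alphas = _pooled_dispersion(stratum_ratios, stratum_invmu)
    pix_p: dict[tuple[int, int], float] = {}
    all_p = []
    for d, idx in stratum_idx.items():
        mu_vec = 1.0 / stratum_invmu[d]                # raw-scale expectation
        k = np.maximum(np.round(stratum_ratios[d] * mu_vec), 0.0)  # raw counts
        alpha = alphas[d]
        if alpha > 0:
            r = 1.0 / alpha
            pp = r / (r + mu_vec)
            pvec = sps.nbinom.sf(k - 1, r, pp)
        else:
            pvec = sps.poisson.sf(k - 1, mu_vec)
        for i, p in zip(idx, pvec):
            pix_p[(int(i), int(i + d))] = float(p)
        all_p.append(pvec)
    q_all = bh_adjust(np.concatenate(all_p))
    pix_q: dict[tuple[int, int], float] = {}
    pos = 0
    for d, idx in stratum_idx.items():
        for i in idx:
            pix_q[(int(i), int(i + d))] = float(q_all[pos])
            pos += 1

    rows = []
    for i, j in candidates:
        d = j - i
        obs = counts[i, j]
        p_nb = pix_p[(i, j)]
        ring = _ring_oe(counts, expected, n, i, j, peak_width, neighborhood_width, valid)
        if len(ring) >= 10 and expected[d] > 0:
            _, p_rank = rank_sum_test([obs / expected[d]], ring, alternative="greater")
        else:
            p_rank = np.nan
        rows.append({"bin1": i, "bin2": j, "distance": d * res,
                     "observed": float(obs), "expected": float(expected[d]),
                     "p_nb": p_nb, "q_nb": pix_q[(i, j)], "p_rank": p_rank})
    if not rows:
        return _empty_loopset()
    df = pd.DataFrame(rows)
    sig = df[(df["q_nb"] < p_threshold) & (df["p_rank"] < p_threshold)]
    if len(sig) == 0:
        return _empty_loopset()

    # merge 8-connected significant pixels; keep the maximum-observed pixel
    pixels = {(int(r.bin1), int(r.bin2)): r for r in sig.itertuples()}
    seen, merged = set(), []
    for px in pixels:
        if px in seen:
            continue
        stack, comp = [px], []
        seen.add(px)
        while stack:
            cur = stack.pop()
            comp.append(cur)
            ci, cj = cur
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    nb = (ci + di, cj + dj)
                    if nb in pixels and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
        best = max(comp, key=lambda px_: pixels[px_].observed)
        merged.append(pixels[best])
    out = pd.DataFrame(merged)[["bin1", "bin2", "distance", "observed",
                                "expected", "p_nb", "q_nb", "p_rank"]]
    out.insert(0, "chrom", m.chrom)
    out["cls"] = "NA"
    return out.sort_values(["bin1", "bin2"]).reset_index(drop=True)


def significant_interactions(
    m: ContactMatrix,
    min_dist: int = 20_000,
    max_dist: int = 1_000_000,
    z_min: float = 1.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Long-range interaction calls by per-distance z-score of observed counts.

    Pairs with distance strictly greater than ``min_dist`` and at most
    ``max_dist`` are tested; calls require z >= ``z_min`` and a normal
    right-tail p < ``p_threshold``; BH-adjusted q is reported.
    """
    n = m.n_bins
    valid = m.valid
    res = m.resolution
    counts = m.counts
    rows = []
    for d in range(1, min(max_dist // res, n - 1) + 1):
        if d * res <= min_dist:
            continue
        diag = np.diagonal(counts, offset=d)
        ok = valid[: n - d] & valid[d:]
        vals = diag[ok]
        if len(vals) < 3:
            continue
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0:
            continue
        z = (diag - mu) / sd
        p = sps.norm.sf(z)
        hits = np.flatnonzero(ok & (z >= z_min) & (p < p_threshold))
        for i in hits:
            rows.append({"bin1": int(i), "bin2": int(i + d), "distance": d * res,
                         "observed": float(diag[i]), "expected": float(mu),
                         "z": float(z[i]), "p": float(p[i])})
    if not rows:
        return pd.DataFrame(columns=["chrom", "bin1", "bin2", "distance",
                                     "observed", "expected", "z", "p", "q"])
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    df.insert(0, "chrom", m.chrom)
    return df.sort_values(["bin1", "bin2"]).reset_index(drop=True)


def classify_loops(l1: pd.DataFrame, l2: pd.DataFrame, match_tol_bins: int = 0) -> pd.DataFrame:
    """Stable/gained/lost partition of the loop union across two conditions.

    Loops whose both anchors match within ``match_tol_bins`` are stable;
    condition-2-only loops are gained; condition-1-only loops are lost.
    """
    a1 = list(zip(l1["bin1"].astype(int), l1["bin2"].astype(int))) if len(l1) else []
    a2 = list(zip(l2["bin1"].astype(int), l2["bin2"].astype(int))) if len(l2) else []
    pairs = sorted(
        (max(abs(x1 - y1), abs(x2 - y2)), i, j)
        for i, (x1, x2) in enumerate(a1)
        for j, (y1, y2) in enumerate(a2)
        if max(abs(x1 - y1), abs(x2 - y2)) <= match_tol_bins
    )
    used1, used2, rows = set(), set(), []
    chrom = l1["chrom"].iloc[0] if len(l1) else (l2["chrom"].iloc[0] if len(l2) else "")
    for _, i, j in pairs:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        rows.append({"chrom": chrom, "bin1": a1[i][0], "bin2": a1[i][1],
                     "cls": "stable"})
    for j, (b1, b2) in enumerate(a2):
        if j not in used2:
            rows.append({"chrom": chrom, "bin1": b1, "bin2": b2, "cls": "gained"})
    for i, (b1, b2) in enumerate(a1):
        if i not in used1:
            rows.append({"chrom": chrom, "bin1": b1, "bin2": b2, "cls": "lost"})
    df = pd.DataFrame(rows, columns=["chrom", "bin1", "bin2", "cls"])
    return df.sort_values(["bin1", "bin2"]).reset_index(drop=True)


@dataclass
class ApaResult:
    """Aggregate peak analysis over a loop set."""

    matrix: np.ndarray    # (2k+1, 2k+1) mean O/E submatrix
    score: float          # center pixel over mean of the larger-distance corner
    n_loops: int
    n_skipped: int


def apa(m: ContactMatrix, loops: pd.DataFrame, flank_bins: int = 10) -> ApaResult:
    """APA score: stacked O/E submatrices around loop pixels.

    Loops closer than (2k+1) bins to the diagonal or to a chromosome edge
    are skipped. Score = center pixel of the mean stack divided by the mean
    of the k x k corner block at larger genomic distance.
    """
    k = flank_bins
    n = m.n_bins
    expected = expected_by_distance(m).values
    dist = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(expected[dist] > 0, m.counts / expected[dist], np.nan)
    stack = np.zeros((2 * k + 1, 2 * k + 1))
    used = skipped = 0
    for r in loops.itertuples():
        i, j = int(r.bin1), int(r.bin2)
        if i > j:
            i, j = j, i
        if i - k < 0 or j + k >= n or (j - i) <= 2 * k:
            skipped += 1
            continue
        sub = oe[i - k: i + k + 1, j - k: j + k + 1]
        if not np.all(np.isfinite(sub)):
            skipped += 1
            continue
        stack += sub
        used += 1
    if used == 0:
        raise LoopError("no usable loops for APA (all skipped)")
    agg = stack / used
    corner = agg[0:k, k + 1: 2 * k + 1]   # larger-distance corner block
    score = float(agg[k, k] / corner.mean())
    return ApaResult(matrix=agg, score=score, n_loops=used, n_skipped=skipped)


# ---------------------------------------------------------------------------
# BEDPE interchange
# ---------------------------------------------------------------------------

def loops_to_bedpe(loops: pd.DataFrame, resolution: int, path) -> None:
    """Write loops as BEDPE with p-value and class columns; anchors ordered."""
    with open(path, "w") as fh:
        fh.write("#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tp_nb\tq_nb\tcls\n")
        for r in loops.itertuples():
            b1, b2 = sorted((int(r.bin1), int(r.bin2)))
            p_nb = getattr(r, "p_nb", np.nan)
            q_nb = getattr(r, "q_nb", np.nan)
            cls = getattr(r, "cls", "NA")
            fh.write(
                f"{r.chrom}\t{b1 * resolution}\t{(b1 + 1) * resolution}"
                f"\t{r.chrom}\t{b2 * resolution}\t{(b2 + 1) * resolution}"
                f"\t.\t{p_nb:.6g}\t{q_nb:.6g}\t{cls}\n"
            )


def read_bedpe(path, resolution: int) -> pd.DataFrame:
    """Read a BEDPE written by :func:`loops_to_bedpe`."""
    df = pd.read_csv(path, sep="\t", comment=None, header=0)
    df.columns = [c.lstrip("#") for c in df.columns]
    out = pd.DataFrame({
        "chrom": df["chrom1"],
        "bin1": df["start1"] // resolution,
        "bin2": df["start2"] // resolution,
    })
    out["distance"] = (out["bin2"] - out["bin1"]) * resolution
    for col in ("p_nb", "q_nb", "cls"):
        if col in df.columns:
            out[col] = df[col]
    return out
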