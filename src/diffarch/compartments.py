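"""A/B compartment assignment and two-condition switch analysis.

Compartments are called per chromosome at coarse (100-kb) resolution from the
first principal component of the Pearson correlation matrix of the
observed/expected contact map. Positive PC1 = compartment A (open), negative
= B (closed). Because an eigenvector's sign is arbitrary, PC1 is oriented
against an external reference track (ATAC coverage by default): bins in the
top quartile of reference signal must have positive mean PC1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinTable, SignalTrack, tss_position
from .matrix import ContactMatrix, expected_by_distance
from .stats import rank_sum_test

__all__ = [
    "CompartmentTrack",
    "compartment_pc1",
    "classify_switches",
    "genes_by_switch_category",
    "expression_by_category",
]

SWITCH_CATEGORIES = ["A->A", "B->B", "A->B", "B->A"]


class CompartmentError(ValueError):
    pass


@dataclass
class CompartmentTrack:
    """PC1 values and A/B labels per coarse bin of one chromosome."""

    bins: BinTable
    pc1: np.ndarray  # NaN on masked bins

    @property
    def labels(self) -> np.ndarray:
        """'A' where PC1 > 0, 'B' where PC1 < 0, 'NA' where masked or 0."""
        lab = np.full(self.bins.n_bins, "NA", dtype=object)
        lab[np.nan_to_num(self.pc1) > 0] = "A"
        lab[np.nan_to_num(self.pc1) < 0] = "B"
        return lab


def compartment_pc1(
    m: ContactMatrix,
    reference: SignalTrack,
    min_valid_bins: int = 10,
) -> CompartmentTrack:
    """First principal component of the O/E correlation matrix, sign-oriented.

    ``reference`` supplies the orientation rule: the quartile of valid bins
    with the highest reference signal must have positive mean PC1.
    """
    valid = m.valid
    if valid.sum() < min_valid_bins:
        raise CompartmentError(
            f"{m.chrom}: insufficient bins ({int(valid.sum())} valid, "
            f"need >= {min_valid_bins})"
        )
    expected = expected_by_distance(m)
    sub = m.counts[np.ix_(valid, valid)]
    idx = np.flatnonzero(valid)
    dist = np.abs(idx[:, None] - idx[None, :])
    exp = expected.values[dist]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp > 0, sub / exp, 0.0)
    if np.std(oe) < 1e-12:
        raise CompartmentError(f"{m.chrom}: no compartment signal (constant O/E map)")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(oe)
    corr = np.nan_to_num(corr)
    if np.std(corr) < 1e-12:
        raise CompartmentError(f"{m.chrom}: no compartment signal (degenerate correlation)")
    eigvals, eigvecs = np.linalg.eigh(corr)
    v = eigvecs[:, -1]  # leading eigenvector (eigh sorts ascending)

    ref_vals = reference.bin_values(m.bins)[valid]
    top = ref_vals >= np.quantile(ref_vals, 0.75)
    if v[top].mean() < 0:
        v = -v

    pc1 = np.full(m.n_bins, np.nan)
    pc1[valid] = v
    return CompartmentTrack(m.bins, pc1)


def classify_switches(t1: CompartmentTrack, t2: CompartmentTrack) -> pd.DataFrame:
    """Per-bin switch category between two conditions.

    Returns a per-bin table with columns chrom/start/end/pc1_1/pc1_2/
    label1/label2/category; category is 'NA' if either label is NA.
    Use :func:`switch_fractions` for the genome-fraction summary.
    """
    if t1.bins != t2.bins:
        raise CompartmentError("compartment tracks on different bin tables")
    l1, l2 = t1.labels, t2.labels
    category = np.where(
        (l1 == "NA") | (l2 == "NA"),
        "NA",
        np.char.add(np.char.add(l1.astype(str), "->"), l2.astype(str)),
    )
    bins = t1.bins
    i = np.arange(bins.n_bins)
    return pd.DataFrame(
        {
            "chrom": bins.chrom,
            "start": bins.bin_start(i),
            "end": bins.bin_end(i),
            "bin": i,
            "pc1_1": t1.pc1,
            "pc1_2": t2.pc1,
            "label1": l1,
            "label2": l2,
            "category": category,
        }
    )


def switch_fractions(switches: pd.DataFrame) -> pd.DataFrame:
    """Percent of bins per category, both over non-NA bins and over all bins."""
    counts = switches["category"].value_counts()
    total = len(switches)
    non_na = int((switches["category"] != "NA").sum())
    rows = []
    for cat in SWITCH_CATEGORIES:
        n = int(counts.get(cat, 0))
        rows.append(
            {
                "category": cat,
                "n_bins": n,
                "pct_of_informative": 100.0 * n / non_na if non_na else np.nan,
                "pct_of_all": 100.0 * n / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)


def genes_by_switch_category(
    switches: dict[str, pd.DataFrame] | pd.DataFrame,
    expr: pd.DataFrame,
) -> tuple[dict[str, pd.DataFrame], int]:
    """Assign DE-flagged genes to the switch category of their TSS bin.

    ``switches`` maps chromosome -> per-bin switch table (or a single table).
    Returns (category -> gene sub-table, number of DEGs dropped because the
    TSS fell in a masked/NA bin or on an absent chromosome).
    """
    if isinstance(switches, pd.DataFrame):
        switches = {c: g for c, g in switches.groupby("chrom")}
    groups: dict[str, list] = {c: [] for c in SWITCH_CATEGORIES}
    dropped = 0
    degs = expr[expr["is_de"]]
    for _, row in degs.iterrows():
        table = switches.get(row["chrom"])
        if table is None:
            dropped += 1
            continue
        tss = tss_position(row)
        width = int(table["end"].iloc[0] - table["start"].iloc[0])
        idx = tss // width
        if idx >= len(table):
            dropped += 1
            continue
        cat = table["category"].iloc[idx]
        if cat == "NA":
            dropped += 1
            continue
        groups[cat].append(row)
    out = {
        cat: pd.DataFrame(rows) if rows else expr.iloc[0:0]
        for cat, rows in groups.items()
    }
    return out, dropped


def expression_by_category(groups: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-category expression summary and pairwise Wilcoxon rank-sum tests.

    For each category: n, median/mean log2FC, mean log2(FPKM+1) per
    condition, the within-category between-condition rank-sum p, and the
    rank-sum p against every other non-empty category (on log2FC).
    Categories with n < 3 get NaN p-values.
    """
    cats = [c for c in groups if len(groups[c]) > 0]
    rows = []
    for cat in cats:
        g = groups[cat]
        fc = g["log2fc"].to_numpy(dtype=float)
        e1 = np.log2(g["fpkm1"].to_numpy(dtype=float) + 1)
        e2 = np.log2(g["fpkm2"].to_numpy(dtype=float) + 1)
        if len(g) >= 3:
            _, p_cond = rank_sum_test(e2, e1, alternative="two-sided")
        else:
            p_cond = np.nan
        row = {
            "category": cat,
            "n": len(g),
            "median_log2fc": float(np.median(fc)),
            "mean_log2fc": float(np.mean(fc)),
            "mean_log2_fpkm1": float(np.mean(e1)),
            "mean_log2_fpkm2": float(np.mean(e2)),
            "p_between_conditions": p_cond,
        }
        for other in cats:
            if other == cat:
                continue
            if len(g) >= 3 and len(groups[other]) >= 3:
                _, p = rank_sum_test(
                    fc, groups[other]["log2fc"].to_numpy(dtype=float),
                    alternative="two-sided",
                )
            else:
                p = np.nan
            row[f"p_vs_{other}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
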