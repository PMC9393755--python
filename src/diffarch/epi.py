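"""Enhancer-promoter interaction (EPI) calling from classified loops.

An EPI is a loop with one anchor overlapping a gene's TSS and the other
anchor overlapping at least one enhancer, requiring a minimum 1-bp overlap
under half-open coordinates. Both anchor-role assignments are tested; the
two roles must sit on different anchors (no self-EPIs). EPIs inherit the
gain/loss/stable class of their loop, and differential EPI tallies
deduplicate genes (a gene linked by several EPIs counts once).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import GenomicInterval
from .stats import rank_sum_test

__all__ = ["identify_epis", "differential_epis", "epi_expression_stats"]

EPI_COLUMNS = [
    "chrom", "bin1", "bin2", "promoter_anchor", "gene", "enhancers",
    "cls", "ambiguous",
]


def _trees(intervals: list[GenomicInterval]) -> dict[str, IntervalTree]:
    out: dict[str, IntervalTree] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return out


def identify_epis(
    loops: pd.DataFrame,
    tss: list[GenomicInterval],
    enhancers: list[GenomicInterval],
    resolution: int,
) -> pd.DataFrame:
    """Emit one EPI call per loop, role assignment, and gene.

    ``tss`` intervals carry the gene id in ``name``. Loops ambiguous in role
    orientation (both assignments valid) yield calls for both orientations,
    flagged ``ambiguous``.
    """
    if not tss or not enhancers:
        warnings.warn("empty TSS or enhancer annotation: no EPIs can be called")
        return pd.DataFrame(columns=EPI_COLUMNS)
    tss_trees = _trees(tss)
    enh_trees = _trees(enhancers)
    rows = []
    for r in loops.itertuples():
        chrom = r.chrom
        anchors = []
        for b in (int(r.bin1), int(r.bin2)):
            anchors.append((b * resolution, (b + 1) * resolution))
        tt = tss_trees.get(chrom, IntervalTree())
        et = enh_trees.get(chrom, IntervalTree())
        hits = []
        for prom_idx in (0, 1):
            enh_idx = 1 - prom_idx
            genes = sorted({h.data.name for h in tt.overlap(*anchors[prom_idx])})
            enh_hit = sorted(
                f"{h.begin}-{h.end}" for h in et.overlap(*anchors[enh_idx])
            )
            if genes and enh_hit:
                hits.append((prom_idx, genes, enh_hit))
        ambiguous = len(hits) == 2
        for prom_idx, genes, enh_hit in hits:
            for gene in genes:
                rows.append({
                    "chrom": chrom,
                    "bin1": int(r.bin1),
                    "bin2": int(r.bin2),
                    "promoter_anchor": prom_idx + 1,
                    "gene": gene,
                    "enhancers": ",".join(enh_hit),
                    "cls": getattr(r, "cls", "NA"),
                    "ambiguous": ambiguous,
                })
    return pd.DataFrame(rows, columns=EPI_COLUMNS)


def differential_epis(epis: pd.DataFrame, expr: pd.DataFrame):
    """Split EPI calls by loop class and tally unique DE genes per side.

    Returns (gained EPI table, lost EPI table, summary dict). DEG tallies
    deduplicate gene ids and count DE-flagged genes only.
    """
    de_genes = set(expr.loc[expr["is_de"], "gene"]) if len(expr) else set()
    gained = epis[epis["cls"] == "gained"].reset_index(drop=True)
    lost = epis[epis["cls"] == "lost"].reset_index(drop=True)
    summary = {
        "n_gained_epis": len(gained),
        "n_lost_epis": len(lost),
        "gained_degs": sorted(set(gained["gene"]) & de_genes),
        "lost_degs": sorted(set(lost["gene"]) & de_genes),
    }
    summary["n_gained_degs"] = len(summary["gained_degs"])
    summary["n_lost_degs"] = len(summary["lost_degs"])
    return gained, lost, summary


def epi_expression_stats(
    gained_genes: list[str],
    lost_genes: list[str],
    expr: pd.DataFrame,
) -> dict:
    """Expression direction of gained- vs lost-EPI DEGs.

    Mean and median log2FC per side, plus a two-sided rank-sum p between the
    two sides (NaN if either side has fewer than 2 genes).
    """
    indexed = expr.set_index("gene")

    def side(genes):
        fc = indexed.loc[[g for g in genes if g in indexed.index], "log2fc"]
        fc = fc.to_numpy(dtype=float)
        return {
            "n": len(fc),
            "mean_log2fc": float(np.mean(fc)) if len(fc) else np.nan,
            "median_log2fc": float(np.median(fc)) if len(fc) else np.nan,
            "_values": fc,
        }

    g, l = side(gained_genes), side(lost_genes)
    if g["n"] >= 2 and l["n"] >= 2:
        _, p = rank_sum_test(g["_values"], l["_values"], alternative="two-sided")
    else:
        p = np.nan
    out = {
        "gained": {k: v for k, v in g.items() if not k.startswith("_")},
        "lost": {k: v for k, v in l.items() if not k.startswith("_")},
        "p_gained_vs_lost": p,
    }
    return out
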