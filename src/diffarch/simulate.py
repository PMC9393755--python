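"""Two-condition synthetic genome generator with planted, exported truth.

The generator emulates the statistical structure a differential Hi-C
analysis assumes: power-law distance decay, plaid A/B compartments,
insulated TADs, focal loops, per-bin multiplicative biases, and matched
ATAC/RNA tracks. Condition 2 is rebuilt with planted changes — compartment
switches, TAD splits (gained boundaries) and merges (lost boundaries), loop
gains/losses, enhancer-promoter interaction gains/losses — and expression
effects drawn from category-specific normal distributions, so every pipeline
stage can be scored against ground truth.

Counts are Poisson around the structured expectation. ATAC tracks carry
higher signal in A than B compartments (this also drives PC1 sign
orientation), Gaussian peaks at TAD boundaries and loop anchors, and
condensed flanking regions: fixed-width dips on both sides of every TAD
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .genome import (
    BinTable, GenomicInterval, SignalTrack,
    write_bed, write_bedgraph, write_expression_table,
)
from .matrix import ContactMatrix, write_triplet_matrix

__all__ = ["GeneratorConfig", "SyntheticTruth", "generate", "truth_compare"]


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic two-condition genome."""

    seed: int = 1
    chrom_sizes: dict = field(default_factory=lambda: {
        "chr1": 20_000_000, "chr2": 20_000_000,
    })
    hic_resolution: int = 10_000
    compartment_resolution: int = 100_000

    # contact model
    decay_exponent: float = 1.0
    # Sequencing depth, as the expected count between adjacent bins. Chosen
    # by power analysis: a 5x focal enrichment at the maximum loop distance
    # (1 Mb; background ~ contact_scale/100 per pixel) must clear a
    # genome-wide FDR-corrected Poisson tail with >= 95% probability, which
    # needs a background of ~8-10 counts per far pixel. This emulates a
    # deeply sequenced (merged-replicate) in situ Hi-C library, ~17M
    # intra-chromosomal contacts per 20-Mb chromosome at 10-kb bins.
    contact_scale: float = 1200.0
    plaid_strength: float = 0.3        # +/- modulation for same/cross compartment
    compartment_block_range: tuple = (5, 10)   # block size in compartment bins
    tad_size_range: tuple = (20, 60)           # TAD size in Hi-C bins
    insulation_depth: float = 0.5      # cross-TAD contact reduction (50%)
    bias_sd: float = 0.3               # log-normal per-bin bias

    # loops (per genome)
    n_loops_stable: int = 40
    n_loops_gained: int = 25
    n_loops_lost: int = 25
    loop_enrichment: float = 5.0
    loop_dist_range_bins: tuple = (10, 100)

    # planted condition-2 changes (per genome)
    n_switch_ab: int = 10
    n_switch_ba: int = 10
    n_tad_splits: int = 8      # -1 = split every eligible TAD
    n_tad_merges: int = 8
    # a split TAD's halves must stay resolvable by multi-window insulation
    # scoring (largest window 150 kb = 15 bins at the 10-kb default)
    min_split_half_bins: int = 15
    n_epi_gained: int = 20
    n_epi_lost: int = 20

    # genes / expression
    n_comp_genes_per_direction: int = 50
    n_stable_de_genes: int = 100
    n_background_genes: int = 200
    comp_effect_mean: float = 1.5
    comp_effect_sd: float = 0.5
    epi_effect_mean: float = 1.0
    epi_effect_sd: float = 0.4

    # ATAC / RNA tracks
    track_binsize: int = 1_000
    atac_level_a: float = 1.4
    atac_level_b: float = 0.6
    atac_boundary_peak: float = 2.0
    atac_boundary_peak_sd: int = 5_000
    atac_anchor_peak: float = 1.0
    atac_anchor_peak_sd: int = 3_000
    dip_width: int = 20_000
    dip_offset: int = 25_000
    dip_depth: float = 0.4
    atac_noise_sd: float = 0.05
    n_background_enhancers: int = 50   # per chromosome

    def validate(self) -> None:
        if self.hic_resolution <= 0 or self.compartment_resolution % self.hic_resolution:
            raise ConfigError("compartment resolution must be a multiple of Hi-C resolution")
        for chrom, size in self.chrom_sizes.items():
            n = size // self.hic_resolution
            if n < 4 * self.tad_size_range[1]:
                raise ConfigError(f"{chrom} too short for the requested TAD sizes")
            if self.loop_dist_range_bins[1] >= n:
                raise ConfigError(f"{chrom} too short for the requested loop distances")
        if not (0 < self.insulation_depth < 1):
            raise ConfigError("insulation_depth must be in (0, 1)")
        if not (0 < self.plaid_strength < 1):
            raise ConfigError("plaid_strength must be in (0, 1)")


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside the synthetic file bundle."""

    compartments: pd.DataFrame   # chrom, bin, label1, label2, category
    boundaries: pd.DataFrame     # chrom, bin, cls in {stable, gained, lost}
    loops: pd.DataFrame          # chrom, bin1, bin2, cls
    epis: pd.DataFrame           # chrom, gene, promoter_bin, enhancer_bin, cls
    genes: pd.DataFrame          # expression table + true_category


def _split(total: int, k: int) -> list[int]:
    base, rem = divmod(total, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def _add_peak(arr, x, center, amp, sd):
    lo = np.searchsorted(x, center - 4 * sd)
    hi = np.searchsorted(x, center + 4 * sd)
    arr[lo:hi] += amp * np.exp(-((x[lo:hi] - center) ** 2) / (2 * sd * sd))


def generate(config: GeneratorConfig, outdir=None):
    """Build the two-condition synthetic bundle.

    Returns ``(bundle, truth)``. ``bundle`` holds in-memory objects
    (matrices per condition and chromosome, ATAC/RNA SignalTracks,
    expression table, annotations); when ``outdir`` is given the full text
    file bundle is also written there. Same config (incl. seed) gives
    byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = sorted(config.chrom_sizes)
    nc = len(chroms)
    res = config.hic_resolution
    cres = config.compartment_resolution
    factor = cres // res

    shares = {
        key: _split(getattr(config, key), nc)
        for key in ("n_switch_ab", "n_switch_ba", "n_tad_splits", "n_tad_merges",
                    "n_loops_stable", "n_loops_gained", "n_loops_lost",
                    "n_epi_gained", "n_epi_lost", "n_comp_genes_per_direction",
                    "n_stable_de_genes", "n_background_genes")
    }

    matrices = {"cond1": {}, "cond2": {}}
    atac_tracks = {"cond1": SignalTrack(), "cond2": SignalTrack()}
    rna_tracks = {"cond1": SignalTrack(), "cond2": SignalTrack()}
    enhancers, tss_list = [], []
    dars = {"hyper": [], "hypo": []}
    truth_comp, truth_bnd, truth_loops, truth_epis = [], [], [], []
    gene_rows = []

    for ci, chrom in enumerate(chroms):
        crng = np.random.default_rng(rng.integers(0, 2**31))
        size = config.chrom_sizes[chrom]
        n = size // res
        n_comp = size // cres

        # --- compartment blocks ---------------------------------------
        blocks = []
        pos = 0
        label = "A" if crng.integers(0, 2) else "B"
        while pos < n_comp:
            blen = int(crng.integers(*config.compartment_block_range, endpoint=True))
            end = min(pos + blen, n_comp)
            blocks.append([pos, end, label])
            label = "B" if label == "A" else "A"
            pos = end
        labels1 = np.empty(n_comp, dtype=object)
        for b0, b1, lab in blocks:
            labels1[b0:b1] = lab
        labels2 = labels1.copy()
        a_blocks = [k for k, b in enumerate(blocks) if b[2] == "A"]
        b_blocks = [k for k, b in enumerate(blocks) if b[2] == "B"]
        n_ab, n_ba = shares["n_switch_ab"][ci], shares["n_switch_ba"][ci]
        if n_ab > len(a_blocks) or n_ba > len(b_blocks):
            raise ConfigError(f"{chrom}: not enough compartment blocks to plant switches")
        ab_sel = sorted(crng.choice(a_blocks, size=n_ab, replace=False).tolist())
        ba_sel = sorted(crng.choice(b_blocks, size=n_ba, replace=False).tolist())
        for k in ab_sel:
            labels2[blocks[k][0]: blocks[k][1]] = "B"
        for k in ba_sel:
            labels2[blocks[k][0]: blocks[k][1]] = "A"
        for k in range(n_comp):
            truth_comp.append({"chrom": chrom, "bin": k,
                               "label1": labels1[k], "label2": labels2[k],
                               "category": f"{labels1[k]}->{labels2[k]}"})

        # --- TADs -------------------------------------------------------
        # compartment transitions coincide with TAD boundaries (TADs nest
        # within compartments): every block edge is forced into the boundary
        # set, replacing any independently drawn boundary nearby
        bounds = []
        pos = 0
        while True:
            pos += int(crng.integers(*config.tad_size_range, endpoint=True))
            if pos >= n - config.tad_size_range[0]:
                break
            bounds.append(pos)
        edges = [b0 * factor for b0, _, _ in blocks[1:]]
        bounds1 = sorted(set(p for p in bounds if all(abs(p - e) > 3 for e in edges))
                         | set(edges))
        tads1 = list(zip([0] + bounds1, bounds1 + [n]))
        inner = [(a, b) for a, b in tads1
                 if b - a >= 2 * config.min_split_half_bins]
        n_split = len(inner) if config.n_tad_splits < 0 else shares["n_tad_splits"][ci]
        n_merge = shares["n_tad_merges"][ci]
        mergeable = [p for p in bounds1 if p not in edges]
        if n_split > len(inner) or n_merge > len(mergeable):
            raise ConfigError(f"{chrom}: not enough TADs to plant splits/merges")
        split_idx = crng.choice(len(inner), size=n_split, replace=False)
        split_pos = sorted(int((inner[k][0] + inner[k][1]) // 2) for k in split_idx)
        mergeable = [p for p in mergeable if p not in split_pos]
        merge_pos = sorted(crng.choice(mergeable, size=n_merge, replace=False).tolist())
        bounds2 = sorted((set(bounds1) - set(merge_pos)) | set(split_pos))
        for p in bounds1:
            if p in merge_pos:
                truth_bnd.append({"chrom": chrom, "bin": p - 1, "cls": "lost"})
            else:
                truth_bnd.append({"chrom": chrom, "bin": p - 1, "cls": "stable"})
        for p in split_pos:
            truth_bnd.append({"chrom": chrom, "bin": p - 1, "cls": "gained"})

        # --- loops ------------------------------------------------------
        margin = 12
        placed = []

        def sample_loops(count):
            out = []
            tries = 0
            while len(out) < count:
                tries += 1
                if tries > 100000:
                    raise ConfigError(f"{chrom}: cannot place {count} loops")
                d = int(crng.integers(*config.loop_dist_range_bins, endpoint=True))
                i = int(crng.integers(margin, n - margin - d))
                j = i + d
                if all(max(abs(i - a), abs(j - b)) > margin for a, b in placed):
                    placed.append((i, j))
                    out.append((i, j))
            return out

        loops_stable = sample_loops(shares["n_loops_stable"][ci])
        loops_gained = sample_loops(shares["n_loops_gained"][ci])
        loops_lost = sample_loops(shares["n_loops_lost"][ci])
        for (i, j), cls in (
            [(l, "stable") for l in loops_stable]
            + [(l, "gained") for l in loops_gained]
            + [(l, "lost") for l in loops_lost]
        ):
            truth_loops.append({"chrom": chrom, "bin1": i, "bin2": j, "cls": cls})

        # --- contact matrices ------------------------------------------
        bias = np.exp(crng.normal(0.0, config.bias_sd, size=n))
        bias /= np.exp(np.mean(np.log(bias)))
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        base = config.contact_scale * (d + 1.0) ** (-config.decay_exponent)
        bb = np.outer(bias, bias)

        def build(labels_comp, bound_list, loop_list, cond_rng):
            lab_hic = np.repeat(labels_comp, factor)[:n]
            same = lab_hic[:, None] == lab_hic[None, :]
            plaid = np.where(same, 1 + config.plaid_strength, 1 - config.plaid_strength)
            tad_id = np.searchsorted(bound_list, np.arange(n), side="right")
            cross = tad_id[:, None] != tad_id[None, :]
            tadf = np.where(cross, 1 - config.insulation_depth, 1.0)
            mu = base * plaid * tadf * bb
            for (i, j) in loop_list:
                mu[i, j] *= config.loop_enrichment
                mu[j, i] = mu[i, j]
            counts = cond_rng.poisson(np.triu(mu)).astype(float)
            counts = np.triu(counts) + np.triu(counts, 1).T
            return ContactMatrix(BinTable(chrom, size, res), counts)

        matrices["cond1"][chrom] = build(labels1, bounds1,
                                         loops_stable + loops_lost,
                                         np.random.default_rng(crng.integers(0, 2**31)))
        matrices["cond2"][chrom] = build(labels2, bounds2,
                                         loops_stable + loops_gained,
                                         np.random.default_rng(crng.integers(0, 2**31)))

        # --- genes & expression ----------------------------------------
        anchor_bins = {b for l in placed for b in l}

        def tss_clear_of_anchors(tpos):
            b = tpos // res
            return all(abs(b - a) > 2 for a in anchor_bins)

        def make_gene(tpos, log2fc, is_de, tag):
            glen = int(crng.integers(5_000, 30_000, endpoint=True))
            strand = "+" if crng.integers(0, 2) else "-"
            if strand == "+":
                start, end = tpos, min(tpos + glen, size)
            else:
                start, end = max(tpos + 1 - glen, 0), tpos + 1
            fpkm1 = float(np.exp(crng.normal(2.0, 1.0)))
            fpkm2 = fpkm1 * 2.0 ** log2fc
            gene_rows.append({
                "gene": f"{chrom}_g{len(gene_rows)}",
                "chrom": chrom, "start": start, "end": end, "strand": strand,
                "fpkm1": fpkm1, "fpkm2": fpkm2, "log2fc": float(log2fc),
                "is_de": bool(is_de), "true_category": tag,
            })
            return gene_rows[-1]

        def random_tss_in_blocks(block_ids, count):
            out = []
            tries = 0
            while len(out) < count:
                tries += 1
                if tries > 100000:
                    raise ConfigError(f"{chrom}: cannot place genes in blocks")
                k = int(crng.choice(block_ids))
                b0, b1, _ = blocks[k]
                lo, hi = b0 * cres + 5_000, b1 * cres - 35_000
                if hi <= lo:
                    continue
                tpos = int(crng.integers(lo, hi))
                if tss_clear_of_anchors(tpos):
                    out.append(tpos)
            return out

        n_dir = shares["n_comp_genes_per_direction"][ci]
        for tpos in random_tss_in_blocks(ab_sel, n_dir):
            make_gene(tpos, crng.normal(-config.comp_effect_mean, config.comp_effect_sd),
                      True, "A->B")
        for tpos in random_tss_in_blocks(ba_sel, n_dir):
            make_gene(tpos, crng.normal(config.comp_effect_mean, config.comp_effect_sd),
                      True, "B->A")
        stable_ids = [k for k in range(len(blocks))
                      if k not in set(ab_sel) | set(ba_sel)]
        for tpos in random_tss_in_blocks(stable_ids, shares["n_stable_de_genes"][ci]):
            make_gene(tpos, crng.normal(0.0, 1.0), True, "stable")
        for tpos in random_tss_in_blocks(stable_ids, shares["n_background_genes"][ci]):
            make_gene(tpos, crng.normal(0.0, 0.3), False, "background")

        # --- EPIs -------------------------------------------------------
        def plant_epis(loop_list, count, sign, cls):
            for (i, j) in loop_list[:count]:
                tpos = i * res + res // 2
                g = make_gene(tpos, crng.normal(sign * config.epi_effect_mean,
                                                config.epi_effect_sd),
                              True, f"epi_{cls}")
                tss_list.append(GenomicInterval(chrom, tpos, tpos + 1,
                                                name=g["gene"], strand=g["strand"]))
                e0 = j * res + 2_000
                enhancers.append(GenomicInterval(chrom, e0, e0 + 500,
                                                 name=f"{chrom}_e{len(enhancers)}"))
                truth_epis.append({"chrom": chrom, "gene": g["gene"],
                                   "promoter_bin": i, "enhancer_bin": j, "cls": cls})

        plant_epis(loops_gained, shares["n_epi_gained"][ci], +1, "gained")
        plant_epis(loops_lost, shares["n_epi_lost"][ci], -1, "lost")

        # background enhancers, kept away from loop anchors
        n_bg_enh = 0
        tries = 0
        while n_bg_enh < config.n_background_enhancers and tries < 100000:
            tries += 1
            p = int(crng.integers(10_000, size - 10_000))
            if tss_clear_of_anchors(p):
                enhancers.append(GenomicInterval(chrom, p, p + 500,
                                                 name=f"{chrom}_e{len(enhancers)}"))
                n_bg_enh += 1

        # --- ATAC / RNA tracks -----------------------------------------
        tb = config.track_binsize
        n_track = size // tb
        starts = np.arange(n_track) * tb
        x = starts + tb / 2

        def atac(labels_comp, bound_list, loop_list, noise_rng):
            comp_of_bin = np.minimum(starts // cres, n_comp - 1)
            lab = labels_comp[comp_of_bin]
            arr = np.where(lab == "A", config.atac_level_a, config.atac_level_b).astype(float)
            for p in bound_list:
                _add_peak(arr, x, p * res, config.atac_boundary_peak,
                          config.atac_boundary_peak_sd)
            for (i, j) in loop_list:
                for b in (i, j):
                    _add_peak(arr, x, int((b + 0.5) * res), config.atac_anchor_peak,
                              config.atac_anchor_peak_sd)
            dipf = np.ones(n_track)
            half = config.dip_width // 2
            for p in bound_list:
                c = p * res
                for s in (-1, 1):
                    lo, hi = c + s * config.dip_offset - half, c + s * config.dip_offset + half
                    sel = (x >= lo) & (x < hi)
                    dipf[sel] = np.minimum(dipf[sel], 1 - config.dip_depth)
            arr = arr * dipf * np.exp(noise_rng.normal(0, config.atac_noise_sd, n_track))
            track = SignalTrack()
            track.add_chrom(chrom, starts, starts + tb, arr)
            return track

        t1 = atac(labels1, bounds1, loops_stable + loops_lost,
                  np.random.default_rng(crng.integers(0, 2**31)))
        t2 = atac(labels2, bounds2, loops_stable + loops_gained,
                  np.random.default_rng(crng.integers(0, 2**31)))
        for cond, t in (("cond1", t1), ("cond2", t2)):
            s, e, v = t.arrays(chrom)
            atac_tracks[cond].add_chrom(chrom, s, e, v)

        def rna(fpkm_col):
            arr = np.full(n_track, 0.05)
            for g in gene_rows:
                if g["chrom"] != chrom:
                    continue
                lo, hi = g["start"] // tb, -(-g["end"] // tb)
                arr[lo:hi] += 0.2 * np.log2(g[fpkm_col] + 1)
            track = SignalTrack()
            track.add_chrom(chrom, starts, starts + tb, arr)
            return track

        for cond, col in (("cond1", "fpkm1"), ("cond2", "fpkm2")):
            s, e, v = rna(col).arrays(chrom)
            rna_tracks[cond].add_chrom(chrom, s, e, v)

        # --- DARs -------------------------------------------------------
        for p in split_pos:
            dars["hyper"].append(GenomicInterval(chrom, p * res - 1_000, p * res + 1_000))
        for p in merge_pos:
            dars["hypo"].append(GenomicInterval(chrom, p * res - 1_000, p * res + 1_000))

    genes_df = pd.DataFrame(gene_rows)
    expr = genes_df.drop(columns=["true_category"])
    # non-EPI genes still need TSS annotations for EPI calling realism
    for _, g in genes_df[~genes_df["true_category"].str.startswith("epi_")].iterrows():
        tpos = int(g["start"]) if g["strand"] != "-" else int(g["end"]) - 1
        tss_list.append(GenomicInterval(g["chrom"], tpos, tpos + 1,
                                        name=g["gene"], strand=g["strand"]))

    truth = SyntheticTruth(
        compartments=pd.DataFrame(truth_comp),
        boundaries=pd.DataFrame(truth_bnd).sort_values(["chrom", "bin"]).reset_index(drop=True),
        loops=pd.DataFrame(truth_loops).sort_values(["chrom", "bin1", "bin2"]).reset_index(drop=True),
        epis=pd.DataFrame(truth_epis),
        genes=genes_df,
    )
    bundle = {
        "config": config,
        "matrices": matrices,
        "atac": atac_tracks,
        "rna": rna_tracks,
        "expression": expr,
        "enhancers": sorted(enhancers, key=lambda e: (e.chrom, e.start)),
        "tss": sorted(tss_list, key=lambda t: (t.chrom, t.start)),
        "dars": dars,
    }
    if outdir is not None:
        _write_bundle(bundle, truth, Path(outdir))
    return bundle, truth


def _write_bundle(bundle, truth: SyntheticTruth, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for cond in ("cond1", "cond2"):
        write_triplet_matrix(bundle["matrices"][cond], outdir / f"{cond}.matrix.tsv")
        write_bedgraph(bundle["atac"][cond], outdir / f"atac_{cond}.bedgraph")
        write_bedgraph(bundle["rna"][cond], outdir / f"rna_{cond}.bedgraph")
    write_bed(bundle["enhancers"], outdir / "enhancers.bed")
    write_bed(bundle["tss"], outdir / "tss.bed")
    write_bed(bundle["dars"]["hyper"], outdir / "dars_hyper.bed")
    write_bed(bundle["dars"]["hypo"], outdir / "dars_hypo.bed")
    write_expression_table(bundle["expression"], outdir / "expression.tsv")
    truth.compartments.to_csv(outdir / "truth_compartments.tsv", sep="\t", index=False)
    truth.boundaries.to_csv(outdir / "truth_boundaries.tsv", sep="\t", index=False)
    truth.loops.to_csv(outdir / "truth_loops.tsv", sep="\t", index=False)
    truth.epis.to_csv(outdir / "truth_epis.tsv", sep="\t", index=False)
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False,
                       float_format="%.6g")
    cfg = asdict(bundle["config"])
    cfg["compartment_block_range"] = list(cfg["compartment_block_range"])
    cfg["tad_size_range"] = list(cfg["tad_size_range"])
    cfg["loop_dist_range_bins"] = list(cfg["loop_dist_range_bins"])
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def _match_1d(truth_bins, called_bins, tol):
    """Greedy nearest matching of 1-D positions within tolerance."""
    pairs = sorted(
        (abs(t - c), i, j)
        for i, t in enumerate(truth_bins)
        for j, c in enumerate(called_bins)
        if abs(t - c) <= tol
    )
    used_t, used_c = set(), set()
    for _, i, j in pairs:
        if i not in used_t and j not in used_c:
            used_t.add(i)
            used_c.add(j)
    return used_t, used_c


def _prf(n_truth, n_called, n_matched):
    precision = n_matched / n_called if n_called else np.nan
    recall = n_matched / n_truth if n_truth else np.nan
    if n_truth and n_called and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = np.nan
    return {"n_truth": n_truth, "n_called": n_called, "n_matched": n_matched,
            "precision": precision, "recall": recall, "f1": f1}


def truth_compare(
    truth: SyntheticTruth,
    called_boundaries: Optional[pd.DataFrame] = None,
    called_loops: Optional[pd.DataFrame] = None,
    called_switches: Optional[pd.DataFrame] = None,
    boundary_tol: int = 1,
    loop_tol: int = 0,
) -> dict:
    """Precision/recall/F1 of called features against the planted truth.

    Classified tables (``cls`` column) are scored per class; the switch
    table is scored as per-bin category agreement plus a confusion matrix.
    """
    report: dict = {}
    if called_boundaries is not None:
        report["boundaries"] = {}
        for cls in ("stable", "gained", "lost", "all"):
            t = truth.boundaries if cls == "all" else truth.boundaries[truth.boundaries["cls"] == cls]
            c = called_boundaries if cls == "all" else called_boundaries[called_boundaries["cls"] == cls]
            matched = 0
            for chrom in sorted(set(t["chrom"]) | set(c["chrom"])):
                tb = t.loc[t["chrom"] == chrom, "bin"].to_numpy()
                cb = c.loc[c["chrom"] == chrom, "bin"].to_numpy()
                used_t, _ = _match_1d(tb, cb, boundary_tol)
                matched += len(used_t)
            report["boundaries"][cls] = _prf(len(t), len(c), matched)
    if called_loops is not None:
        report["loops"] = {}
        for cls in ("stable", "gained", "lost", "all"):
            t = truth.loops if cls == "all" else truth.loops[truth.loops["cls"] == cls]
            c = called_loops if cls == "all" else called_loops[called_loops["cls"] == cls]
            tset = {}
            for r in t.itertuples():
                tset.setdefault(r.chrom, []).append((int(r.bin1), int(r.bin2)))
            matched = 0
            for r in c.itertuples():
                anchors = tset.get(r.chrom, [])
                hit = next(
                    (a for a in anchors
                     if max(abs(a[0] - int(r.bin1)), abs(a[1] - int(r.bin2))) <= loop_tol),
                    None,
                )
                if hit is not None:
                    anchors.remove(hit)
                    matched += 1
            report["loops"][cls] = _prf(len(t), len(c), matched)
    if called_switches is not None:
        t = truth.compartments.set_index(["chrom", "bin"])["category"]
        merged = called_switches.copy()
        merged["truth"] = [
            t.get((r.chrom, int(r.bin)), "NA") for r in merged.itertuples()
        ]
        informative = merged[merged["category"] != "NA"]
        agree = (informative["category"] == informative["truth"]).mean() if len(informative) else np.nan
        confusion = pd.crosstab(merged["truth"], merged["category"])
        report["switches"] = {
            "bin_agreement": float(agree),
            "n_informative": int(len(informative)),
            "confusion": confusion,
        }
    return report
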