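"""End-to-end two-condition pipeline: matrices -> compartments -> TADs ->
loops -> EPIs -> profiles, with provenance logging and a synthetic demo.

Each stage writes its outputs under the run directory with stable filenames
and never mutates another stage's outputs. Default parameters follow the
standard tool settings at 5-kb working resolution (boundary windows
15/75/7.5 kb, loop search <= 1 Mb at p < 0.05, compartments at 100 kb) and
scale with the working resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import compartments as comp_mod
from . import epi as epi_mod
from . import loops as loop_mod
from . import profiles as prof_mod
from . import tads as tad_mod
from .genome import GenomicInterval, write_bedgraph, SignalTrack
from .matrix import ContactMatrix, ice_correct, normalize_to_common_depth
from .simulate import GeneratorConfig, generate, truth_compare

__all__ = ["RunConfig", "run_pipeline", "run_demo"]


@dataclass
class RunConfig:
    """Effective parameters for one pipeline run."""

    seed: int = 1
    outdir: str = "diffarch_run"
    # matrix stage
    ice_max_iter: int = 200
    ice_tol: float = 1e-5
    ice_mad_filter: float = 3.0
    # compartments
    compartment_resolution: int = 100_000
    # TADs (None -> scaled from working resolution: 3x / 15x / 1.5x res)
    tad_min_depth: Optional[int] = None
    tad_max_depth: Optional[int] = None
    tad_step: Optional[int] = None
    tad_delta: float = 0.01
    tad_threshold_comparisons: float = 0.01
    boundary_match_tol_bins: int = 1
    # loops
    loop_max_distance: int = 1_000_000
    loop_p_threshold: float = 0.05
    loop_match_tol_bins: int = 0
    apa_flank_bins: int = 10
    # profiles
    profile_window: int = 50_000
    profile_binsize: int = 1_000
    dip_search_window: int = 30_000
    dip_min_width: int = 10_000
    dip_min_depth_frac: float = 0.25

    def tad_params(self, resolution: int) -> tuple[int, int, int]:
        scale = resolution / 5_000
        return (
            self.tad_min_depth or int(15_000 * scale),
            self.tad_max_depth or int(75_000 * scale),
            self.tad_step or int(7_500 * scale),
        )


def _boundary_intervals(df: pd.DataFrame, resolution: int) -> list[GenomicInterval]:
    # a boundary at bin b insulates at the edge between bins b and b+1;
    # profiles are centered on that edge, not on the bin midpoint
    return [
        GenomicInterval(r.chrom, (int(r.bin) + 1) * resolution - 1,
                        (int(r.bin) + 1) * resolution + 1)
        for r in df.itertuples()
    ]


def run_pipeline(
    bundle: dict,
    config: RunConfig,
    truth=None,
    outdir: Optional[Path] = None,
) -> dict:
    """Run every stage on an input bundle (see :func:`diffarch.simulate.generate`).

    Returns a results dict; when ``outdir`` is given, all stage outputs and a
    provenance log are written there.
    """
    res = {}
    log = {"parameters": asdict(config), "stages": {}}
    chroms = sorted(bundle["matrices"]["cond1"])
    work_res = next(iter(bundle["matrices"]["cond1"].values())).resolution
    chrom_sizes = {c: bundle["matrices"]["cond1"][c].bins.size for c in chroms}

    # ---- matrix stage: balance and depth-normalize --------------------
    corrected = {"cond1": {}, "cond2": {}}
    for chrom in chroms:
        m1 = ice_correct(bundle["matrices"]["cond1"][chrom], config.ice_max_iter,
                         config.ice_tol, config.ice_mad_filter)
        m2 = ice_correct(bundle["matrices"]["cond2"][chrom], config.ice_max_iter,
                         config.ice_tol, config.ice_mad_filter)
        m1, m2 = normalize_to_common_depth(m1, m2)
        corrected["cond1"][chrom] = m1
        corrected["cond2"][chrom] = m2
    log["stages"]["matrix"] = {"chromosomes": chroms, "resolution": work_res}

    # ---- compartments --------------------------------------------------
    factor = config.compartment_resolution // work_res
    switch_tables = {}
    for chrom in chroms:
        c1 = ice_correct(bundle["matrices"]["cond1"][chrom].coarsen(factor),
                         config.ice_max_iter, config.ice_tol, config.ice_mad_filter)
        c2 = ice_correct(bundle["matrices"]["cond2"][chrom].coarsen(factor),
                         config.ice_max_iter, config.ice_tol, config.ice_mad_filter)
        t1 = comp_mod.compartment_pc1(c1, bundle["atac"]["cond1"])
        t2 = comp_mod.compartment_pc1(c2, bundle["atac"]["cond2"])
        switch_tables[chrom] = comp_mod.classify_switches(t1, t2)
    switches = pd.concat(switch_tables.values(), ignore_index=True)
    fractions = comp_mod.switch_fractions(switches)
    groups, dropped = comp_mod.genes_by_switch_category(switch_tables, bundle["expression"])
    expr_stats = comp_mod.expression_by_category(groups)
    res["switches"] = switches
    res["switch_fractions"] = fractions
    res["switch_gene_groups"] = groups
    res["expression_by_category"] = expr_stats
    log["stages"]["compartments"] = {
        "n_bins": int(len(switches)),
        "degs_dropped_na_bins": int(dropped),
        "fractions_pct_informative": {
            r.category: round(r.pct_of_informative, 2) for r in fractions.itertuples()
        },
    }

    # ---- TADs -----------------------------------------------------------
    min_d, max_d, step = config.tad_params(work_res)
    sep = {"cond1": {}, "cond2": {}}
    bounds = {"cond1": {}, "cond2": {}}
    classified_bnd = {}
    for chrom in chroms:
        for cond in ("cond1", "cond2"):
            t = tad_mod.separation_score(corrected[cond][chrom], min_d, max_d, step)
            sep[cond][chrom] = t
            bounds[cond][chrom] = tad_mod.call_boundaries(
                t, config.tad_delta, config.tad_threshold_comparisons)
        classified_bnd[chrom] = tad_mod.classify_boundaries(
            bounds["cond1"][chrom], bounds["cond2"][chrom],
            sep["cond1"][chrom], sep["cond2"][chrom],
            config.boundary_match_tol_bins)
    boundaries = pd.concat(classified_bnd.values(), ignore_index=True)
    tad_stats = tad_mod.tad_size_stats(bounds["cond1"], bounds["cond2"], work_res)
    res["separation"] = sep
    res["boundaries_per_condition"] = bounds
    res["boundaries"] = boundaries
    res["tad_stats"] = tad_stats
    log["stages"]["tads"] = {
        "windows_bins": sep["cond1"][chroms[0]].windows,
        "n_boundaries": {c: int(sum(len(b) for b in bounds[c].values()))
                         for c in ("cond1", "cond2")},
        "classes": boundaries["cls"].value_counts().to_dict(),
        "n_tads": list(tad_stats["n_tads"]),
        "median_tad_size": list(tad_stats["median_size"]),
    }

    # ---- loops ----------------------------------------------------------
    loop_calls = {"cond1": {}, "cond2": {}}
    classified_loops = {}
    for chrom in chroms:
        for cond in ("cond1", "cond2"):
            loop_calls[cond][chrom] = loop_mod.detect_loops(
                corrected[cond][chrom],
                max_distance=config.loop_max_distance,
                p_threshold=config.loop_p_threshold)
        classified_loops[chrom] = loop_mod.classify_loops(
            loop_calls["cond1"][chrom], loop_calls["cond2"][chrom],
            config.loop_match_tol_bins)
    loops = pd.concat(classified_loops.values(), ignore_index=True)
    apa_scores = {}
    for cls, cond in (("stable", "cond2"), ("gained", "cond2"), ("lost", "cond1")):
        scores = []
        for chrom in chroms:
            sub = classified_loops[chrom][classified_loops[chrom]["cls"] == cls]
            if len(sub):
                try:
                    scores.append(loop_mod.apa(corrected[cond][chrom], sub,
                                               config.apa_flank_bins).score)
                except loop_mod.LoopError:
                    pass
        apa_scores[cls] = float(np.mean(scores)) if scores else np.nan
    res["loops_per_condition"] = loop_calls
    res["loops"] = loops
    res["apa_scores"] = apa_scores
    log["stages"]["loops"] = {
        "n_loops": {c: int(sum(len(l) for l in loop_calls[c].values()))
                    for c in ("cond1", "cond2")},
        "classes": loops["cls"].value_counts().to_dict(),
        "apa_scores": {k: (round(v, 3) if np.isfinite(v) else None)
                       for k, v in apa_scores.items()},
    }

    # ---- EPIs -----------------------------------------------------------
    epis = epi_mod.identify_epis(loops, bundle["tss"], bundle["enhancers"], work_res)
    gained_epis, lost_epis, epi_summary = epi_mod.differential_epis(
        epis, bundle["expression"])
    epi_stats = epi_mod.epi_expression_stats(
        epi_summary["gained_degs"], epi_summary["lost_degs"], bundle["expression"])
    res["epis"] = epis
    res["epi_summary"] = epi_summary
    res["epi_expression"] = epi_stats
    log["stages"]["epi"] = {
        "n_epis": int(len(epis)),
        "n_gained_epis": epi_summary["n_gained_epis"],
        "n_lost_epis": epi_summary["n_lost_epis"],
        "n_gained_degs": epi_summary["n_gained_degs"],
        "n_lost_degs": epi_summary["n_lost_degs"],
    }

    # ---- profiles -------------------------------------------------------
    profiles = {}
    for cls in ("stable", "gained", "lost"):
        centers = _boundary_intervals(boundaries[boundaries["cls"] == cls], work_res)
        if not centers:
            continue
        profiles[cls] = {
            cond: prof_mod.metaprofile(bundle["atac"][cond], centers,
                                       config.profile_window, config.profile_binsize,
                                       chrom_sizes)
            for cond in ("cond1", "cond2")
        }
    dips = {}
    for cls, per_cond in profiles.items():
        # probe the condition in which the boundary actually exists
        cond = "cond2" if cls == "gained" else "cond1"
        dips[cls] = prof_mod.detect_flank_dips(
            per_cond[cond], config.dip_search_window,
            config.dip_min_width, config.dip_min_depth_frac)
    res["boundary_profiles"] = profiles
    res["flank_dips"] = dips
    log["stages"]["profiles"] = {
        cls: {
            "dip_left_width": (round(d.left.width) if d.left.detected else None),
            "dip_right_width": (round(d.right.width) if d.right.detected else None),
        }
        for cls, d in dips.items()
    }

    # ---- recovery vs truth ---------------------------------------------
    if truth is not None:
        recovery = truth_compare(truth, called_boundaries=boundaries,
                                 called_loops=loops, called_switches=switches)
        res["recovery"] = recovery
        log["stages"]["recovery"] = {
            "boundary_f1_all": round(recovery["boundaries"]["all"]["f1"], 4),
            "loop_recall_all": round(recovery["loops"]["all"]["recall"], 4),
            "switch_bin_agreement": round(recovery["switches"]["bin_agreement"], 4),
        }

    res["log"] = log
    if outdir is not None:
        _write_outputs(res, bundle, config, Path(outdir), work_res)
    return res


def _write_outputs(res, bundle, config, outdir: Path, work_res: int) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    res["switches"].to_csv(outdir / "compartment_switches.tsv", sep="\t",
                           index=False, float_format="%.6g")
    res["switch_fractions"].to_csv(outdir / "switch_fractions.tsv", sep="\t",
                                   index=False, float_format="%.6g")
    res["expression_by_category"].to_csv(outdir / "expression_by_category.tsv",
                                         sep="\t", index=False, float_format="%.6g")
    res["boundaries"].to_csv(outdir / "boundaries_classified.tsv", sep="\t",
                             index=False, float_format="%.6g")
    for cond in ("cond1", "cond2"):
        track = SignalTrack()
        for chrom, t in res["separation"][cond].items():
            ok = np.isfinite(t.score)
            idx = np.flatnonzero(ok)
            track.add_chrom(chrom, idx * t.resolution, (idx + 1) * t.resolution,
                            np.round(t.score[ok], 6))
        write_bedgraph(track, outdir / f"separation_{cond}.bedgraph")
    loop_mod.loops_to_bedpe(res["loops"], work_res, outdir / "loops_classified.bedpe")
    res["epis"].to_csv(outdir / "epis.tsv", sep="\t", index=False)
    with open(outdir / "apa_scores.tsv", "w") as fh:
        fh.write("class\tapa_score\n")
        for cls, score in res["apa_scores"].items():
            fh.write(f"{cls}\t{score:.6g}\n")
    for cls, per_cond in res["boundary_profiles"].items():
        for cond, prof in per_cond.items():
            df = pd.DataFrame({"position": prof.positions,
                               "mean_signal": np.round(prof.mean, 6)})
            df.to_csv(outdir / f"profile_atac_{cls}_{cond}.tsv", sep="\t", index=False)
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(res["log"], fh, indent=2, sort_keys=True, default=str)


def run_demo(outdir, seed: int = 1, generator_config: Optional[GeneratorConfig] = None,
             run_config: Optional[RunConfig] = None) -> dict:
    """Full synthetic demo: generate a two-condition genome, run every stage,
    and write outputs plus a recovery report."""
    outdir = Path(outdir)
    gcfg = generator_config or GeneratorConfig(seed=seed)
    rcfg = run_config or RunConfig(seed=seed)
    bundle, truth = generate(gcfg, outdir=outdir / "inputs")
    res = run_pipeline(bundle, rcfg, truth=truth, outdir=outdir / "results")
    rec = res["recovery"]
    with open(outdir / "results" / "recovery_report.tsv", "w") as fh:
        fh.write("feature\tclass\tn_truth\tn_called\tprecision\trecall\tf1\n")
        for feat in ("boundaries", "loops"):
            for cls, d in rec[feat].items():
                fh.write(f"{feat}\t{cls}\t{d['n_truth']}\t{d['n_called']}\t"
                         f"{d['precision']:.4f}\t{d['recall']:.4f}\t{d['f1']:.4f}\n")
        fh.write(f"switches\tall\t{rec['switches']['n_informative']}\t"
                 f"{rec['switches']['n_informative']}\t-\t-\t"
                 f"{rec['switches']['bin_agreement']:.4f}\n")
    return res
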