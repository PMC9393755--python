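"""Metaprofiles around genomic features and the boundary-flanking dip detector.

A metaprofile averages a signal track in fixed windows around feature
centers (e.g. ATAC coverage around TAD boundaries). Gene-body profiles
rescale each gene body to a fixed number of bins, with strand-aware flanks.
The flank-dip detector looks for condensed (low-accessibility) regions on
either side of a profile center: contiguous runs below a fraction of the
side's outer baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genome import GenomicInterval, SignalTrack, tss_position

__all__ = [
    "MetaProfile",
    "metaprofile",
    "genebody_profile",
    "FlankDipReport",
    "DipSide",
    "detect_flank_dips",
]


class ProfileError(ValueError):
    pass


@dataclass
class MetaProfile:
    """Average signal in position bins spanning [-window, +window]."""

    window: int
    binsize: int
    positions: np.ndarray      # bin-center offsets from the feature center
    matrix: np.ndarray         # (n_features_used, n_bins) per-feature values
    n_features: int
    n_excluded: int            # features truncated by chromosome ends

    @property
    def mean(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


def metaprofile(
    track: SignalTrack,
    centers: list[GenomicInterval],
    window: int,
    binsize: int,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> MetaProfile:
    """Mean signal around feature centers.

    Features whose window would extend past a chromosome end (when sizes are
    given) or below 0 are excluded from the average.
    """
    if not centers:
        raise ProfileError("no feature centers given")
    if window % binsize != 0:
        raise ProfileError("window must be a multiple of binsize")
    nbins = 2 * window // binsize
    offsets = np.arange(nbins + 1) * binsize - window
    rows, excluded = [], 0
    for iv in centers:
        c = iv.center
        lo, hi = c - window, c + window
        size = (chrom_sizes or {}).get(iv.chrom)
        if lo < 0 or (size is not None and hi > size):
            excluded += 1
            continue
        rows.append(track.binned_means(iv.chrom, c + offsets))
    if not rows:
        raise ProfileError("all features truncated by chromosome ends")
    matrix = np.vstack(rows)
    positions = (offsets[:-1] + offsets[1:]) // 2
    return MetaProfile(window=window, binsize=binsize, positions=positions,
                       matrix=matrix, n_features=len(rows), n_excluded=excluded)


def genebody_profile(
    track: SignalTrack,
    genes: pd.DataFrame,
    flank: int = 10_000,
    n_body_bins: int = 50,
    flank_binsize: Optional[int] = None,
) -> dict:
    """Average signal across scaled gene bodies with fixed flanks.

    Each gene body is rescaled to ``n_body_bins``; the ``flank`` bp upstream
    of the TSS and downstream of the TES are sampled at ``flank_binsize``
    (default flank/10). Minus-strand genes are flipped so upstream is left.
    Genes shorter than one body bin or truncated at the chromosome start are
    skipped and tallied.
    """
    if flank_binsize is None:
        flank_binsize = max(flank // 10, 1)
    n_flank = flank // flank_binsize
    rows, skipped = [], 0
    for _, g in genes.iterrows():
        start, end = int(g["start"]), int(g["end"])
        if end - start < n_body_bins:
            skipped += 1
            continue
        if start - flank < 0:
            skipped += 1
            continue
        chrom = g["chrom"]
        up_edges = np.arange(n_flank + 1) * flank_binsize + (start - flank)
        body_edges = np.linspace(start, end, n_body_bins + 1).astype(np.int64)
        down_edges = np.arange(n_flank + 1) * flank_binsize + end
        vals = np.concatenate([
            track.binned_means(chrom, up_edges),
            track.binned_means(chrom, body_edges),
            track.binned_means(chrom, down_edges),
        ])
        if g["strand"] == "-":
            vals = vals[::-1]
        rows.append(vals)
    if not rows:
        raise ProfileError("no usable genes for gene-body profile")
    matrix = np.vstack(rows)
    return {
        "mean": matrix.mean(axis=0),
        "matrix": matrix,
        "n_flank_bins": n_flank,
        "n_body_bins": n_body_bins,
        "n_genes": len(rows),
        "n_skipped": skipped,
    }


@dataclass
class DipSide:
    detected: bool
    center_offset: float = np.nan   # bp from the profile center (signed)
    width: float = np.nan           # bp
    depth: float = np.nan           # fraction below the side baseline


@dataclass
class FlankDipReport:
    left: DipSide
    right: DipSide


def _side_dip(positions, values, search_window, min_width, min_depth_frac, binsize):
    """Deepest qualifying low run on one side (positions all same sign)."""
    if len(values) == 0:
        return DipSide(False)
    # baseline from the outer third of the side (farthest from the center)
    order = np.argsort(np.abs(positions))
    outer = order[len(order) - max(len(order) // 3, 1):]
    baseline = float(np.median(values[outer]))
    if baseline <= 0:
        return DipSide(False)
    below = values < (1.0 - min_depth_frac) * baseline
    best = None
    i = 0
    while i < len(below):
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(below) and below[j + 1]:
            j += 1
        run_pos = positions[i: j + 1]
        center = float(np.mean(run_pos))
        width = float((j - i + 1) * binsize)
        # a dip qualifies if its center lies inside the search window
        if abs(center) <= search_window and width >= min_width:
            depth = 1.0 - float(np.mean(values[i: j + 1])) / baseline
            if best is None or width > best.width:
                best = DipSide(True, center_offset=center, width=width, depth=depth)
        i = j + 1
    return best if best is not None else DipSide(False)


def detect_flank_dips(
    p: MetaProfile,
    search_window: int = 30_000,
    min_width: int = 10_000,
    min_depth_frac: float = 0.25,
) -> FlankDipReport:
    """Detect condensed (low-signal) regions flanking a profile center.

    Per side, the maximal contiguous run below (1 - min_depth_frac) x the
    side's outer-third median baseline whose center falls within
    ``search_window`` of the profile center; detected iff its width is at
    least ``min_width``. Absence of dips is a valid (negative) report.
    """
    if p.window < search_window:
        raise ProfileError("profile window smaller than the dip search window")
    mean = p.mean
    left_mask = p.positions < 0
    right_mask = p.positions > 0
    left = _side_dip(p.positions[left_mask], mean[left_mask], search_window,
                     min_width, min_depth_frac, p.binsize)
    right = _side_dip(p.positions[right_mask], mean[right_mask], search_window,
                      min_width, min_depth_frac, p.binsize)
    return FlankDipReport(left=left, right=right)
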