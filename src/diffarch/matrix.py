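"""Binned Hi-C contact matrices: building, balancing, and comparison.

A :class:`ContactMatrix` is a symmetric per-chromosome matrix of interaction
counts at a fixed resolution. Intra-bin pairs are counted once on the
diagonal; the matrix "total mass" is the sum of the upper triangle including
the diagonal, so binning conserves the number of input pairs.

Balancing is iterative correction (ICE): per-bin multiplicative biases are
removed by alternately dividing by the (normalized) marginals until the
coefficient of variation of the retained-bin marginals falls below ``tol``.
Low-coverage bins (zero marginal, or marginal deviating from the median by
more than ``mad_filter`` median-absolute-deviations) are masked first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genome import BinTable

__all__ = [
    "ContactMatrix",
    "ExpectedProfile",
    "bin_pairs",
    "sum_matrices",
    "normalize_to_common_depth",
    "ice_correct",
    "expected_by_distance",
    "log2_ratio_matrix",
    "read_triplet_matrix",
    "write_triplet_matrix",
]


class MatrixError(ValueError):
    pass


@dataclass
class ContactMatrix:
    """Symmetric nonnegative contact matrix for one chromosome."""

    bins: BinTable
    counts: np.ndarray
    weights: Optional[np.ndarray] = None  # per-bin bias; NaN = masked

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.bins.n_bins
        if self.counts.shape != (n, n):
            raise MatrixError(
                f"counts shape {self.counts.shape} does not match {n} bins"
            )
        if not np.allclose(self.counts, self.counts.T, atol=1e-8, rtol=1e-8):
            raise MatrixError("contact matrix must be symmetric")
        if np.any(self.counts < 0):
            raise MatrixError("contact matrix must be nonnegative")

    @property
    def chrom(self) -> str:
        return self.bins.chrom

    @property
    def resolution(self) -> int:
        return self.bins.bin_width

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    @property
    def total(self) -> float:
        """Total contact mass: upper triangle plus diagonal."""
        return float(np.triu(self.counts).sum())

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of usable bins."""
        if self.weights is not None:
            return np.isfinite(self.weights)
        return self.counts.sum(axis=1) > 0

    def scaled(self, factor: float) -> "ContactMatrix":
        return ContactMatrix(self.bins, self.counts * factor, weights=self.weights)

    def coarsen(self, factor: int) -> "ContactMatrix":
        """Aggregate to a ``factor``-times coarser resolution (counts summed)."""
        if factor < 1:
            raise MatrixError("coarsen factor must be >= 1")
        coarse_bins = BinTable(self.bins.chrom, self.bins.size,
                               self.bins.bin_width * factor)
        m = coarse_bins.n_bins
        out = np.zeros((m, m))
        idx = np.arange(self.n_bins) // factor
        np.add.at(out, (idx[:, None], idx[None, :]),
                  self.counts)
        return ContactMatrix(coarse_bins, out)


@dataclass
class ExpectedProfile:
    """Per-distance (in bins) mean contact value for one chromosome."""

    values: np.ndarray  # length n_bins, index = distance in bins

    def __getitem__(self, d: int) -> float:
        return float(self.values[d])


def bin_pairs(pairs, bins: BinTable) -> ContactMatrix:
    """Bin a list of (pos1, pos2) contacts into a symmetric matrix.

    Each pair adds one count: off-diagonal pairs appear at both [i,j] and
    [j,i]; intra-bin pairs add once on the diagonal, so the upper-triangle
    mass equals the number of pairs.
    """
    n = bins.n_bins
    m = np.zeros((n, n))
    for pos1, pos2 in pairs:
        try:
            i, j = bins.bin_index(int(pos1)), bins.bin_index(int(pos2))
        except ValueError as exc:
            raise MatrixError(f"pair ({pos1}, {pos2}): {exc}") from exc
        if i == j:
            m[i, i] += 1
        else:
            m[i, j] += 1
            m[j, i] += 1
    return ContactMatrix(bins, m)


def sum_matrices(a: ContactMatrix, b: ContactMatrix) -> ContactMatrix:
    """Element-wise sum (replicate merging)."""
    if a.bins != b.bins:
        raise MatrixError("cannot sum matrices on different bin tables")
    return ContactMatrix(a.bins, a.counts + b.counts)


def normalize_to_common_depth(a: ContactMatrix, b: ContactMatrix):
    """Scale both matrices to the smaller of the two total masses."""
    ta, tb = a.total, b.total
    if ta <= 0 or tb <= 0:
        raise MatrixError("cannot depth-normalize a zero-mass matrix")
    target = min(ta, tb)
    return a.scaled(target / ta), b.scaled(target / tb)


def _coverage_mask(counts: np.ndarray, mad_filter: Optional[float]) -> np.ndarray:
    # low-coverage removal: zero marginals, plus marginals more than
    # mad_filter MADs BELOW the median; high marginals are multiplicative
    # bias, which is exactly what the correction itself removes
    marg = counts.sum(axis=1)
    valid = marg > 0
    if mad_filter is not None and valid.sum() > 2:
        med = np.median(marg[valid])
        mad = np.median(np.abs(marg[valid] - med))
        if mad > 0:
            valid &= marg >= med - mad_filter * mad
    return valid


def ice_correct(
    m: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    mad_filter: Optional[float] = 3.0,
) -> ContactMatrix:
    """Iterative correction of per-bin biases.

    Masks low-coverage bins, then balances the retained submatrix so all its
    marginals are equal (total mass preserved). Returns a new matrix with
    masked rows/columns zeroed and per-bin weights (NaN on masked bins).
    """
    valid = _coverage_mask(m.counts, mad_filter)
    if valid.sum() < 2:
        raise MatrixError("matrix too sparse: all bins masked by coverage filter")
    w = m.counts[np.ix_(valid, valid)].copy()
    orig_mass = w.sum()
    bias = np.ones(w.shape[0])
    for _ in range(max_iter):
        s = w.sum(axis=1)
        if np.any(s <= 0):
            raise MatrixError("matrix too sparse: zero marginal during correction")
        cv = s.std() / s.mean()
        if cv < tol:
            break
        s = s / s.mean()
        w /= s[:, None]
        w /= s[None, :]
        bias *= s
    scale = w.sum() / orig_mass
    w /= scale
    n = m.n_bins
    out = np.zeros((n, n))
    out[np.ix_(valid, valid)] = w
    weights = np.full(n, np.nan)
    # fold the final rescale into the reported bias so corrected == raw/(w_i*w_j)
    weights[valid] = bias * np.sqrt(scale)
    return ContactMatrix(m.bins, out, weights=weights)


def expected_by_distance(m: ContactMatrix) -> ExpectedProfile:
    """Mean contact value at each bin distance, over valid bin pairs."""
    n = m.n_bins
    valid = m.valid
    values = np.zeros(n)
    for d in range(n):
        diag = np.diagonal(m.counts, offset=d)
        ok = valid[: n - d] & valid[d:]
        if ok.any():
            values[d] = diag[ok].mean()
    return ExpectedProfile(values)


def log2_ratio_matrix(a: ContactMatrix, b: ContactMatrix, pseudocount: float = 1.0) -> np.ndarray:
    """log2((b+pc)/(a+pc)); inputs should be depth-normalized to common mass."""
    if a.bins != b.bins:
        raise MatrixError("cannot compare matrices on different bin tables")
    return np.log2(b.counts + pseudocount) - np.log2(a.counts + pseudocount)


# ---------------------------------------------------------------------------
# Sparse triplet text I/O (the interchange contract for matrices)
# ---------------------------------------------------------------------------

def write_triplet_matrix(matrices: dict[str, ContactMatrix], path) -> None:
    """Write matrices as 'chrom bin1_start bin2_start count' triplet text.

    Only the upper triangle (including diagonal) is stored. A header line
    records the resolution and chromosome sizes.
    """
    chroms = sorted(matrices)
    res = {matrices[c].resolution for c in chroms}
    if len(res) != 1:
        raise MatrixError("all matrices in one file must share a resolution")
    with open(path, "w") as fh:
        sizes = ",".join(f"{c}:{matrices[c].bins.size}" for c in chroms)
        fh.write(f"#resolution={res.pop()}\tsizes={sizes}\n")
        fh.write("chrom\tbin1_start\tbin2_start\tcount\n")
        for chrom in chroms:
            m = matrices[chrom]
            iu, ju = np.triu_indices(m.n_bins)
            vals = m.counts[iu, ju]
            nz = vals != 0
            df = pd.DataFrame({
                "chrom": chrom,
                "bin1_start": iu[nz] * m.resolution,
                "bin2_start": ju[nz] * m.resolution,
                "count": vals[nz],
            })
            df.to_csv(fh, sep="\t", index=False, header=False, float_format="%.6g")


def read_triplet_matrix(path) -> dict[str, ContactMatrix]:
    """Read a triplet text file written by :func:`write_triplet_matrix`."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#resolution="):
            raise MatrixError(f"{path}: missing '#resolution=' header")
        fields = dict(kv.split("=", 1) for kv in header[1:].split("\t"))
        res = int(fields["resolution"])
        sizes = {}
        for entry in fields["sizes"].split(","):
            chrom, size = entry.split(":")
            sizes[chrom] = int(size)
        df = pd.read_csv(fh, sep="\t")
    out = {}
    for chrom, size in sizes.items():
        bins = BinTable(chrom, size, res)
        n = bins.n_bins
        counts = np.zeros((n, n))
        sub = df[df["chrom"] == chrom]
        i = (sub["bin1_start"] // res).to_numpy()
        j = (sub["bin2_start"] // res).to_numpy()
        v = sub["count"].to_numpy(dtype=float)
        if np.any((i < 0) | (i >= n) | (j < 0) | (j >= n)):
            raise MatrixError(f"{path}: bin start outside chromosome {chrom}")
        counts[i, j] = v
        counts[j, i] = v
        out[chrom] = ContactMatrix(bins, counts)
    return out
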