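"""Anchored and length-rescaled signal matrices and composite (metagene) profiles.

Every figure-style analysis reduces to one of two matrix constructions:

* ``anchored_matrix`` — rows are fixed-width windows around anchors (TSS/TES),
  reoriented so transcription runs left to right;
* ``scaled_region_matrix`` — rows are variable-length regions resampled onto a
  fixed number of body columns by mean-preserving, coverage-weighted
  averaging (never interpolation or summing), so a constant signal keeps its
  amplitude exactly; unscaled flanks are appended on both sides.

Column statistics (mean, SEM, n) ignore missing entries.
"""
from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotation import Gene
from .tracks import GenomicTrack

logger = logging.getLogger("torsionmap")

DEFAULT_FLANK_BP = 1000
DEFAULT_N_BODY_BINS = 100


@dataclass
class CompositeMatrix:
    """Rows (genes/pairs/loops) x columns (positions) with NaN as missing.

    ``positions`` holds, per column, the bp offset of the bin start relative
    to the anchor (anchored mode) or, for scaled mode, negative/positive bp
    offsets for the flanks and the fractional body coordinate in [0, 1)
    scaled by 1000 (i.e. "per-mille through the body") for body columns.
    """

    values: np.ndarray
    row_labels: list[str]
    positions: np.ndarray
    mode: str  # "anchored" | "scaled"
    n_flank_cols: int = 0

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Anchored matrices
# ---------------------------------------------------------------------------

def anchors_from_genes(genes: Sequence[Gene], at: str = "tss",
                       ) -> tuple[list[tuple[str, int, str]], list[tuple[int, int]], list[str]]:
    """Build (chrom, position, strand) anchors plus ORF bounds and labels."""
    if at not in ("tss", "tes"):
        raise ValueError("anchor kind must be 'tss' or 'tes'")
    anchors = [(g.chrom, g.tss if at == "tss" else g.tes, g.strand) for g in genes]
    bounds = [(g.start, g.end) for g in genes]
    labels = [g.name for g in genes]
    return anchors, bounds, labels


def anchored_matrix(track: GenomicTrack,
                    anchors: Sequence[tuple[str, int, str]],
                    flank_bp: int = DEFAULT_FLANK_BP,
                    exclusion: str = "none",
                    gene_bounds: Sequence[tuple[int, int]] | None = None,
                    row_labels: Sequence[str] | None = None) -> CompositeMatrix:
    """Stack track windows ``[anchor - flank, anchor + flank)`` around anchors.

    Minus-strand rows are reversed so transcription runs left to right.
    ``exclusion='beyond_TES'`` masks, per row, oriented offsets at or past the
    row's own TES (for TSS-anchored views); ``'beyond_TSS'`` masks offsets
    upstream of the TSS (for TES-anchored views). Off-chromosome columns are
    missing; anchors that fall off their chromosome are skipped with a log.
    """
    w = track.genome.bin_width
    if flank_bp % w != 0 or flank_bp <= 0:
        raise ValueError("flank_bp must be a positive multiple of the bin width")
    if exclusion not in ("none", "beyond_TES", "beyond_TSS"):
        raise ValueError(f"unknown exclusion mode {exclusion!r}")
    if exclusion != "none" and gene_bounds is None:
        raise ValueError("exclusion requires gene_bounds")
    nf = flank_bp // w
    offsets = (np.arange(2 * nf) - nf) * w  # oriented bin-start offsets
    rows, labels = [], []
    n_skipped = 0
    for i, (chrom, pos, strand) in enumerate(anchors):
        n = track.genome.n_bins(chrom)
        if not (0 <= pos < track.genome.length(chrom)):
            n_skipped += 1
            continue
        abin = pos // w
        lo, hi = abin - nf, abin + nf
        row = np.full(2 * nf, np.nan)
        src_lo, src_hi = max(lo, 0), min(hi, n)
        row[src_lo - lo: src_hi - lo] = track.data[chrom][src_lo:src_hi]
        if strand == "-":
            row = row[::-1].copy()
        if exclusion != "none":
            start, end = gene_bounds[i]
            if exclusion == "beyond_TES":
                dist = (end - pos) if strand == "+" else (pos - start)
                row[offsets >= dist] = np.nan
            else:  # beyond_TSS
                dist = (pos - start) if strand == "+" else (end - pos)
                row[offsets < -dist] = np.nan
        rows.append(row)
        labels.append(row_labels[i] if row_labels is not None else str(i))
    if n_skipped:
        logger.info("anchored_matrix: skipped %d off-chromosome anchors", n_skipped)
    if not rows:
        raise ValueError("no valid anchors")
    return CompositeMatrix(np.array(rows), labels, offsets, "anchored")


# ---------------------------------------------------------------------------
# Scaled-region matrices
# ---------------------------------------------------------------------------

def _rebin_mean(src_edges: np.ndarray, src_vals: np.ndarray,
                tgt_edges: np.ndarray) -> np.ndarray:
    """Rebin a piecewise-constant signal by coverage-weighted averaging.

    NaN source stretches carry no weight; target cells covered only by NaN
    are NaN. Exact (no interpolation error) and mean-preserving.
    """
    finite = ~np.isnan(src_vals)
    widths = np.diff(src_edges)
    cum_val = np.concatenate([[0.0], np.cumsum(np.where(finite, src_vals, 0.0) * widths)])
    cum_cov = np.concatenate([[0.0], np.cumsum(finite * widths)])
    v = np.interp(tgt_edges, src_edges, cum_val)
    c = np.interp(tgt_edges, src_edges, cum_cov)
    dv, dc = np.diff(v), np.diff(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = dv / dc
    out[dc <= 0] = np.nan
    return out


def scaled_region_matrix(track: GenomicTrack,
                         regions: Sequence[tuple],
                         flank_bp: int = DEFAULT_FLANK_BP,
                         n_body_bins: int = DEFAULT_N_BODY_BINS,
                         row_labels: Sequence[str] | None = None) -> CompositeMatrix:
    """Resample variable-length regions onto a common axis, amplitude-preserving.

    ``regions`` holds ``(chrom, start, end, strand)`` tuples. The body signal
    is rebinned into ``n_body_bins`` equal-width cells by coverage-weighted
    averaging of the source bins, which preserves the per-row body mean (and
    maps a constant region to a constant row). Flank bins are appended
    unscaled; minus-strand rows are reversed whole. Regions shorter than one
    bin are skipped with a log.
    """
    w = track.genome.bin_width
    if flank_bp % w != 0 or flank_bp < 0:
        raise ValueError("flank_bp must be a non-negative multiple of the bin width")
    if n_body_bins < 1:
        raise ValueError("n_body_bins must be >= 1")
    nf = flank_bp // w
    positions = np.concatenate([
        (np.arange(nf) - nf) * w,
        np.floor(1000.0 * np.arange(n_body_bins) / n_body_bins),
        np.arange(nf) * w,  # downstream flank, offsets from region end
    ])
    rows, labels = [], []
    n_skipped = 0
    for i, region in enumerate(regions):
        chrom, start, end, strand = region[:4]
        if end - start < w:
            n_skipped += 1
            continue
        n = track.genome.n_bins(chrom)
        vals = track.data[chrom]
        k0, k1 = start // w, (end - 1) // w  # source bins overlapping the body
        src_edges = np.concatenate([[start], (np.arange(k0, k1 + 1) + 1) * w])
        src_edges[-1] = end
        src_edges = np.clip(src_edges, start, end).astype(float)
        body = _rebin_mean(src_edges, vals[k0:k1 + 1],
                           start + (end - start) * np.arange(n_body_bins + 1) / n_body_bins)
        left = np.full(nf, np.nan)
        lo = k0 - nf
        src_lo = max(lo, 0)
        left[src_lo - lo:] = vals[src_lo:k0] if k0 > 0 else []
        right = np.full(nf, np.nan)
        r0 = k1 + 1
        r1 = min(r0 + nf, n)
        right[: r1 - r0] = vals[r0:r1]
        row = np.concatenate([left, body, right])
        if strand == "-":
            row = row[::-1].copy()
        rows.append(row)
        labels.append(row_labels[i] if row_labels is not None else str(i))
    if n_skipped:
        logger.info("scaled_region_matrix: skipped %d too-short regions", n_skipped)
    if not rows:
        raise ValueError("no valid regions")
    return CompositeMatrix(np.array(rows), labels, positions, "scaled", n_flank_cols=nf)


# ---------------------------------------------------------------------------
# Column statistics and row ops
# ---------------------------------------------------------------------------

def composite_profile(matrix: CompositeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column (mean, SEM, n) over non-missing entries.

    SEM uses the sample SD (ddof=1) divided by sqrt(n); single-entry columns
    get SEM 0 by convention, empty columns are NaN.
    """
    if matrix.n_rows < 1:
        raise ValueError("matrix has no rows")
    vals = matrix.values
    finite = ~np.isnan(vals)
    n = finite.sum(axis=0)
    sums = np.where(finite, vals, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / n
    mean[n == 0] = np.nan
    sem = np.zeros(matrix.n_cols)
    multi = n > 1
    if multi.any():
        with np.errstate(invalid="ignore"):
            sd = np.nanstd(vals[:, multi], axis=0, ddof=1)
        sem[multi] = sd / np.sqrt(n[multi])
    sem[n == 0] = np.nan
    return mean, sem, n


def sort_rows(matrix: CompositeMatrix, keys: Sequence[float],
              descending: bool = False) -> CompositeMatrix:
    """Stable sort of rows by key (e.g. ORF size for heatmap displays)."""
    keys = np.asarray(keys, dtype=float)
    if len(keys) != matrix.n_rows:
        raise ValueError("one key per row is required")
    order = np.argsort(-keys if descending else keys, kind="stable")
    return CompositeMatrix(matrix.values[order],
                           [matrix.row_labels[i] for i in order],
                           matrix.positions, matrix.mode, matrix.n_flank_cols)


def autocorrelation_period_bp(profile: np.ndarray, bin_width: int) -> int | None:
    """Dominant spatial period of a composite profile, in bp.

    Computed as the lag of the first non-zero-lag local maximum of the
    autocorrelation of the mean-subtracted profile (missing values carry no
    weight). Returns None when the autocorrelation has no interior maximum.
    """
    from scipy.signal import find_peaks
    x = np.asarray(profile, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        return None
    x = x - x.mean()
    ac = np.correlate(x, x, mode="full")[x.size - 1:]
    peaks, _ = find_peaks(ac)
    if peaks.size == 0:
        return None
    return int(peaks[0] * bin_width)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def matrix_to_tsv(matrix: CompositeMatrix, path: str) -> None:
    """Row label + values per line; gzip if the path ends in .gz."""
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("label\t" + "\t".join(f"{p:g}" for p in matrix.positions) + "\n")
        for label, row in zip(matrix.row_labels, matrix.values):
            fh.write(label + "\t" + "\t".join(
                "nan" if np.isnan(v) else f"{v:.6g}" for v in row) + "\n")


def profile_to_tsv(matrix: CompositeMatrix, path: str) -> None:
    mean, sem, n = composite_profile(matrix)
    with open(path, "w") as fh:
        fh.write("position\tmean\tsem\tn\n")
        for p, m, s, k in zip(matrix.positions, mean, sem, n):
            fh.write(f"{p:g}\t{m:.6g}\t{s:.6g}\t{k}\n")
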