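"""The signed torsion signal: zero-torsion baseline subtraction and quantification.

The core quantity is the per-bin difference between the mean-normalized
crosslink signal measured in living cells (with torsion) and the signal
measured after fixing chromatin and relaxing torsion by restriction digestion
(the zero-torsion baseline). Because psoralen intercalation is favoured by
underwound DNA, a positive difference indicates net (-) torsion (underwound),
a negative difference net (+) torsion (overwound). Purified-DNA sequence
normalization is an accessibility-view step only and is never part of the
torsion computation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import Gene
from .composites import anchored_matrix, anchors_from_genes, composite_profile
from .tracks import (GenomicTrack, IntervalSet, average_tracks, divide_tracks,
                     mask_blacklist, normalize_mean, subtract_tracks)

logger = logging.getLogger("torsionmap")

SIGN_CONVENTION = "positive = (-) torsion (underwound); negative = (+) torsion (overwound)"

MEAN_ONE_TOLERANCE = 1e-3


@dataclass(eq=False)
class TorsionTrack(GenomicTrack):
    """A GenomicTrack of baseline-subtracted torsion values plus provenance."""

    provenance: dict = field(default_factory=dict)
    sign_convention: str = SIGN_CONVENTION


@dataclass(frozen=True)
class PeakValleyStat:
    """Group-level torsion summary at the composite TSS peak / TES valley."""

    group: str
    anchor: str  # "tss_peak" | "tes_valley"
    mean: float
    sem: float
    n: int
    window_bp: int
    extremum_offset_bp: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("PeakValleyStat needs n >= 1")
        if self.sem < 0:
            raise ValueError("SEM must be >= 0")


# ---------------------------------------------------------------------------
# Sequence normalization (accessibility views only)
# ---------------------------------------------------------------------------

def sequence_normalize(sample_track: GenomicTrack, purified_track: GenomicTrack,
                       mode: str = "ratio", pseudocount: float = 0.0) -> GenomicTrack:
    """Normalize a crosslink track against purified (deproteinized) DNA.

    Removes the intercalator's DNA-sequence preference; used only for
    accessibility-style views, never inside the torsion computation. Both
    inputs should already be mean-normalized (warned otherwise).
    """
    if mode not in ("ratio", "difference"):
        raise ValueError("mode must be 'ratio' or 'difference'")
    for name, t in (("sample", sample_track), ("purified", purified_track)):
        m = t.mean()
        if abs(m - 1.0) > MEAN_ONE_TOLERANCE:
            logger.warning("sequence_normalize: %s track mean %.4g != 1 "
                           "(expected mean-normalized input)", name, m)
    if mode == "ratio":
        return divide_tracks(sample_track, purified_track, pseudocount)
    return subtract_tracks(sample_track, purified_track)


# ---------------------------------------------------------------------------
# Torsion computation
# ---------------------------------------------------------------------------

def compute_torsion(with_torsion_reps: Sequence[GenomicTrack],
                    without_torsion_reps: Sequence[GenomicTrack],
                    blacklist: IntervalSet | None = None,
                    normalize_before_average: bool = True) -> TorsionTrack:
    """Baseline-subtracted torsion track from replicate crosslink coverages.

    Pipeline per condition: blacklist-mask each replicate, mean-normalize,
    average; then subtract (with - without). ``normalize_before_average=False``
    swaps the normalize/average order. Mean normalization makes the result
    invariant to per-replicate sequencing depth.
    """
    if not with_torsion_reps or not without_torsion_reps:
        raise ValueError("need at least one replicate per condition")

    def condition_mean(reps: Sequence[GenomicTrack]) -> GenomicTrack:
        if blacklist is not None:
            reps = [mask_blacklist(t, blacklist) for t in reps]
        if normalize_before_average:
            return average_tracks([normalize_mean(t) for t in reps])
        return normalize_mean(average_tracks(reps))

    with_mean = condition_mean(with_torsion_reps)
    without_mean = condition_mean(without_torsion_reps)
    diff = subtract_tracks(with_mean, without_mean)
    provenance = {
        "n_with_replicates": len(with_torsion_reps),
        "n_without_replicates": len(without_torsion_reps),
        "n_masked_bins": diff.n_missing(),
        "normalize_before_average": normalize_before_average,
    }
    return TorsionTrack(diff.genome, diff.data, provenance=provenance)


# ---------------------------------------------------------------------------
# Peak/valley quantification
# ---------------------------------------------------------------------------

def _locate_extremum(torsion: GenomicTrack, genes: Sequence[Gene],
                     anchor_kind: str, search_bp: int, flank_bp: int,
                     context: str) -> int:
    """Bp offset (bin start, oriented) of the composite extremum near the anchor."""
    at = "tss" if anchor_kind == "tss_peak" else "tes"
    anchors, _, labels = anchors_from_genes(genes, at=at)
    mat = anchored_matrix(torsion, anchors, flank_bp=flank_bp, row_labels=labels)
    mean, _, _ = composite_profile(mat)
    in_search = np.abs(mat.positions) <= search_bp
    candidates = np.where(in_search & ~np.isnan(mean))[0]
    if candidates.size == 0:
        raise ValueError(f"{context}: no finite composite values in search window")
    if anchor_kind == "tss_peak":
        ext_col = candidates[np.argmax(mean[candidates])]
    else:
        ext_col = candidates[np.argmin(mean[candidates])]
    search_cols = np.where(in_search)[0]
    if ext_col in (search_cols[0], search_cols[-1]):
        logger.warning("peak_valley_stats: %s %s extremum on search-window edge",
                       context, anchor_kind)
    return int(mat.positions[ext_col])


def _group_stat(torsion: GenomicTrack, genes: Sequence[Gene], group: str,
                anchor_kind: str, window_bp: int, flank_bp: int,
                ext_pos: int) -> PeakValleyStat:
    at = "tss" if anchor_kind == "tss_peak" else "tes"
    anchors, bounds, labels = anchors_from_genes(genes, at=at)
    mat = anchored_matrix(torsion, anchors, flank_bp=flank_bp, row_labels=labels)
    # Extremum position = bin-start offset of the extremum column; average the
    # bins whose centers lie within +/- window_bp of it (4 bins at w=10, bp=20).
    w = torsion.genome.bin_width
    centers = mat.positions + w / 2.0
    sel = np.abs(centers - ext_pos) <= window_bp
    win = mat.values[:, sel]
    finite = ~np.isnan(win)
    counts = finite.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_gene = np.where(finite, win, 0.0).sum(axis=1) / counts
    per_gene = per_gene[counts > 0]
    n = per_gene.size
    if n == 0:
        raise ValueError(f"group {group!r}: no genes with data in the window")
    sem = float(np.std(per_gene, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return PeakValleyStat(group, anchor_kind, float(per_gene.mean()), sem, n,
                          window_bp, int(ext_pos))


def peak_valley_stats(torsion: GenomicTrack,
                      groups: Mapping[str, Sequence[Gene]],
                      window_bp: int = 20,
                      search_bp: int = 500,
                      flank_bp: int = 1000,
                      extremum_scope: str = "global") -> list[PeakValleyStat]:
    """Per-group mean +/- SEM of torsion at the composite TSS peak and TES valley.

    The composite profile is built (TSS- and TES-anchored), its extremum
    located within ``+/- search_bp`` of the anchor, and each gene's torsion
    averaged over the bins within ``+/- window_bp`` of that extremum; the
    statistic is the across-gene mean with its standard error.

    With ``extremum_scope="global"`` (the default) the extremum is located
    once on the pooled composite of all groups and the same position is used
    for every group; this avoids the selection bias of locating a maximum on
    a noise-dominated group and then averaging the same data at it.
    ``"per_group"`` locates it independently per group.
    """
    if extremum_scope not in ("global", "per_group"):
        raise ValueError("extremum_scope must be 'global' or 'per_group'")
    stats: list[PeakValleyStat] = []
    ext_global: dict[str, int] = {}
    if extremum_scope == "global":
        pooled = [g for genes in groups.values() for g in genes]
        if not pooled:
            raise ValueError("no genes in any group")
        for kind in ("tss_peak", "tes_valley"):
            ext_global[kind] = _locate_extremum(torsion, pooled, kind,
                                                search_bp, flank_bp, "pooled")
    for group, genes in groups.items():
        if len(genes) == 0:
            raise ValueError(f"group {group!r} has no genes")
        for kind in ("tss_peak", "tes_valley"):
            if extremum_scope == "global":
                ext = ext_global[kind]
            else:
                ext = _locate_extremum(torsion, genes, kind, search_bp,
                                       flank_bp, f"group {group!r}")
            stats.append(_group_stat(torsion, genes, group, kind,
                                     window_bp, flank_bp, ext))
    return stats


def peak_valley_table(stats: Sequence[PeakValleyStat]) -> pd.DataFrame:
    return pd.DataFrame({
        "group": [s.group for s in stats],
        "anchor": [s.anchor for s in stats],
        "mean": [s.mean for s in stats],
        "sem": [s.sem for s in stats],
        "n": [s.n for s in stats],
        "window_bp": [s.window_bp for s in stats],
        "extremum_offset_bp": [s.extremum_offset_bp for s in stats],
    })
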