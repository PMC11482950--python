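"""Cohesin-loop boundary analyses: nested refinement, peak snapping, composites.

Loops are intrachromosomal boundary pairs (L, R) with a contact-strength
score. Refinement keeps only the smallest loop in nested configurations so
each genomic region is represented once; boundaries can be snapped to the
nearest cohesin ChIP peak within 500 bp, mirroring how loop calls are
reconciled with cohesin occupancy.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .annotation import percentile_groups
from .composites import CompositeMatrix, scaled_region_matrix
from .tracks import GenomicTrack

logger = logging.getLogger("torsionmap")

DEFAULT_MAX_SNAP_DIST_BP = 500
DEFAULT_PEAK_MIN_SEPARATION_BP = 250


@dataclass(frozen=True)
class Loop:
    chrom: str
    left: int
    right: int
    score: float
    name: str = "."
    adjusted: bool = False

    def __post_init__(self) -> None:
        if self.left >= self.right:
            raise ValueError(f"loop {self.name}: left boundary must be < right")

    @property
    def span(self) -> int:
        return self.right - self.left


@dataclass
class PeakSet:
    """Per-chromosome sorted peak positions (bp) with heights."""

    peaks: dict[str, tuple[np.ndarray, np.ndarray]]

    def positions(self, chrom: str) -> np.ndarray:
        return self.peaks.get(chrom, (np.array([]), np.array([])))[0]

    def __len__(self) -> int:
        return sum(len(p[0]) for p in self.peaks.values())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_loops_tsv(path: str) -> list[Loop]:
    """5-column TSV: chrom, L, R, score, name (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns[:4]) != ["chrom", "L", "R", "score"]:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "L", "R", "score", "name"])
    if "name" not in df.columns:
        df["name"] = "."
    return [Loop(r.chrom, int(r.L), int(r.R), float(r.score), str(r.name))
            for r in df.itertuples()]


def read_loops_bedpe(path: str) -> list[Loop]:
    """BEDPE adapter: boundaries are the midpoints of the two anchor intervals."""
    loops = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            c1, s1, e1, c2, s2, e2 = f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])
            if c1 != c2:
                logger.info("read_loops_bedpe: skipping interchromosomal record %d", i)
                continue
            name = f[6] if len(f) > 6 else "."
            score = float(f[7]) if len(f) > 7 else 0.0
            loops.append(Loop(c1, (s1 + e1) // 2, (s2 + e2) // 2, score, name))
    return loops


def loops_to_table(loops: Sequence[Loop]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [l.chrom for l in loops],
        "L": [l.left for l in loops],
        "R": [l.right for l in loops],
        "score": [l.score for l in loops],
        "name": [l.name for l in loops],
        "adjusted": [l.adjusted for l in loops],
    })


def peakset_to_bed(peaks: PeakSet, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, (pos, height) in peaks.peaks.items():
            for p, h in zip(pos, height):
                fh.write(f"{chrom}\t{int(p)}\t{int(p) + 1}\tpeak\t{h:g}\t.\n")


# ---------------------------------------------------------------------------
# Nested-loop refinement
# ---------------------------------------------------------------------------

def refine_nested_loops(loops: Sequence[Loop]) -> list[Loop]:
    """Drop loops that strictly contain another loop (keep the smallest).

    A loop strictly contains another iff the other's [L, R] lies within its
    own and is shorter — loops sharing one boundary count as nested when the
    other boundary is strictly inside. The retained set is containment-free.
    """
    by_chrom: dict[str, list[Loop]] = {}
    for lp in loops:
        by_chrom.setdefault(lp.chrom, []).append(lp)
    kept: list[Loop] = []
    for chrom_loops in by_chrom.values():
        L = np.array([l.left for l in chrom_loops])
        R = np.array([l.right for l in chrom_loops])
        span = R - L
        for i, lp in enumerate(chrom_loops):
            contains = (L >= L[i]) & (R <= R[i]) & (span < span[i])
            if not contains.any():
                kept.append(lp)
    order = {id(l): i for i, l in enumerate(loops)}
    kept.sort(key=lambda l: order[id(l)])
    return kept


# ---------------------------------------------------------------------------
# Simple peak calling
# ---------------------------------------------------------------------------

def call_peaks_simple(track: GenomicTrack, min_height: float | None = None,
                      min_separation_bp: int = DEFAULT_PEAK_MIN_SEPARATION_BP,
                      ) -> PeakSet:
    """Greedy local-maximum peak caller at bin-center resolution.

    Candidates are local maxima with value >= ``min_height`` (default: the
    90th percentile of the track); peaks are accepted in descending height
    (leftmost wins ties) with an exclusion radius of ``min_separation_bp``.
    """
    w = track.genome.bin_width
    if min_height is None:
        min_height = float(np.nanpercentile(track.values(), 90))
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ci, chrom in enumerate(track.genome.names):
        vals = np.where(np.isnan(track.data[chrom]), -np.inf, track.data[chrom])
        idx, _ = find_peaks(np.concatenate([[-np.inf], vals, [-np.inf]]),
                            height=min_height, plateau_size=1)
        idx = idx - 1  # undo padding
        if idx.size == 0:
            out[chrom] = (np.array([]), np.array([]))
            continue
        heights = vals[idx]
        order = np.lexsort((idx, -heights))  # descending height, leftmost ties
        accepted: list[int] = []
        for k in order:
            pos = idx[k] * w + w // 2
            if all(abs(pos - (idx[a] * w + w // 2)) >= min_separation_bp
                   for a in accepted):
                accepted.append(k)
        accepted_idx = np.sort(idx[np.array(accepted)])
        out[chrom] = (accepted_idx * w + w // 2, vals[accepted_idx])
    peaks = PeakSet(out)
    if len(peaks) == 0:
        logger.warning("call_peaks_simple: no peaks found (min_height=%g)", min_height)
    return peaks


# ---------------------------------------------------------------------------
# Boundary snapping
# ---------------------------------------------------------------------------

def _nearest_peak(pos: int, peak_pos: np.ndarray, max_dist: int) -> int | None:
    """Nearest peak strictly within ``max_dist``; leftmost on exact ties."""
    if peak_pos.size == 0:
        return None
    i = np.searchsorted(peak_pos, pos)
    best, best_d = None, max_dist
    if i > 0:  # left neighbour first so it wins distance ties
        d = abs(pos - peak_pos[i - 1])
        if d < best_d:
            best, best_d = int(peak_pos[i - 1]), d
    if i < peak_pos.size:
        d = abs(peak_pos[i] - pos)
        if d < best_d:
            best, best_d = int(peak_pos[i]), d
    return best


def adjust_boundaries(loops: Sequence[Loop], peaks: PeakSet,
                      max_dist_bp: int = DEFAULT_MAX_SNAP_DIST_BP,
                      require_both: bool = False) -> list[Loop]:
    """Snap each boundary to the nearest ChIP peak strictly within ``max_dist_bp``.

    Boundaries move independently by default (``require_both=True`` demands
    both snap or neither moves). Loops whose boundaries would invert are
    dropped with a log.
    """
    out: list[Loop] = []
    n_dropped = 0
    for lp in loops:
        pos = peaks.positions(lp.chrom)
        new_l = _nearest_peak(lp.left, pos, max_dist_bp)
        new_r = _nearest_peak(lp.right, pos, max_dist_bp)
        if require_both and (new_l is None or new_r is None):
            new_l = new_r = None
        left = new_l if new_l is not None else lp.left
        right = new_r if new_r is not None else lp.right
        moved = (left != lp.left) or (right != lp.right)
        if left >= right:
            n_dropped += 1
            continue
        out.append(replace(lp, left=left, right=right, adjusted=moved))
    if n_dropped:
        logger.info("adjust_boundaries: dropped %d loops with inverted boundaries",
                    n_dropped)
    return out


# ---------------------------------------------------------------------------
# Grouping and composites
# ---------------------------------------------------------------------------

def loop_score_percentile_groups(loops: Sequence[Loop],
                                 boundaries: Sequence[float] = (20, 40, 60, 80),
                                 ) -> np.ndarray:
    """Percentile grouping on loop scores (same contract as gene grouping)."""
    return percentile_groups(loops, key=[l.score for l in loops],
                             boundaries=boundaries)


def loop_composites(track: GenomicTrack, loops: Sequence[Loop],
                    flank_bp: int = 1000, n_body_bins: int = 100) -> CompositeMatrix:
    """Boundary-to-boundary rescaled composite (delegates to scaled regions)."""
    regions = [(l.chrom, l.left, l.right, "+") for l in loops]
    labels = [l.name if l.name != "." else f"loop{i}" for i, l in enumerate(loops)]
    return scaled_region_matrix(track, regions, flank_bp=flank_bp,
                                n_body_bins=n_body_bins, row_labels=labels)
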