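"""Binned genomic signal tracks: data model, bedGraph I/O, ICL coverage, arithmetic.

All coordinates are 0-based half-open (BED/bedGraph convention). Signals live on
a fixed grid of ``bin_width``-bp bins (default 10 bp): bin *k* of a chromosome
covers ``[k*w, (k+1)*w)``, with the last bin truncated at the chromosome end.
Missing data is represented as NaN; uncovered bedGraph positions are 0, not
missing — masking (blacklists, composite exclusions) is what produces missing
values, and missingness propagates through arithmetic and is excluded from
means.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

logger = logging.getLogger("torsionmap")

DEFAULT_BIN_WIDTH = 10


# ---------------------------------------------------------------------------
# Genome index and intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome names/lengths plus the common bin width."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    bin_width: int = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(L <= 0 for L in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")

    @classmethod
    def from_dict(cls, sizes: dict[str, int], bin_width: int = DEFAULT_BIN_WIDTH) -> "GenomeIndex":
        return cls(tuple(sizes), tuple(sizes.values()), bin_width)

    @classmethod
    def from_chrom_sizes(cls, path: str, bin_width: int = DEFAULT_BIN_WIDTH) -> "GenomeIndex":
        """Read a two-column ``chrom<TAB>length`` file."""
        names: list[str] = []
        lengths: list[int] = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                names.append(parts[0])
                lengths.append(int(parts[1]))
        return cls(tuple(names), tuple(lengths), bin_width)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[self.names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome: {chrom!r}") from None

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.length(chrom) / self.bin_width)

    def bin_widths(self, chrom: str) -> np.ndarray:
        """Per-bin genomic width (last bin may be truncated)."""
        w, L, n = self.bin_width, self.length(chrom), self.n_bins(chrom)
        widths = np.full(n, w, dtype=float)
        widths[-1] = L - (n - 1) * w
        return widths

    def write_chrom_sizes(self, path: str) -> None:
        with open(path, "w") as fh:
            for name, L in zip(self.names, self.lengths):
                fh.write(f"{name}\t{L}\n")


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval start must be < end: {self}")


@dataclass
class IntervalSet:
    """A plain list of genomic intervals, optionally bound to a genome."""

    records: list[Interval] = field(default_factory=list)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_bed(cls, path: str) -> "IntervalSet":
        recs: list[Interval] = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "browser", "#")):
                    continue
                f = line.split()
                name = f[3] if len(f) > 3 else None
                score = float(f[4]) if len(f) > 4 else None
                strand = f[5] if len(f) > 5 else None
                recs.append(Interval(f[0], int(f[1]), int(f[2]), name, score, strand))
        return cls(recs)

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fields = [r.chrom, str(r.start), str(r.end)]
                if r.name is not None or r.score is not None or r.strand is not None:
                    fields += [r.name or ".",
                               "0" if r.score is None else f"{r.score:g}",
                               r.strand or "."]
                fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# GenomicTrack
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class GenomicTrack:
    """Per-chromosome binned signal vectors on a shared :class:`GenomeIndex`.

    Two tracks are arithmetic-compatible iff their genome indices are equal.
    """

    genome: GenomeIndex
    data: dict[str, np.ndarray]

    @classmethod
    def zeros(cls, genome: GenomeIndex) -> "GenomicTrack":
        return cls(genome, {c: np.zeros(genome.n_bins(c)) for c in genome.names})

    @classmethod
    def from_arrays(cls, genome: GenomeIndex, data: dict[str, np.ndarray]) -> "GenomicTrack":
        track = cls(genome, {c: np.asarray(v, dtype=float) for c, v in data.items()})
        track.validate()
        return track

    def validate(self) -> None:
        for chrom in self.genome.names:
            if chrom not in self.data:
                raise ValueError(f"track missing chromosome {chrom!r}")
            n = self.genome.n_bins(chrom)
            if len(self.data[chrom]) != n:
                raise ValueError(
                    f"{chrom}: expected {n} bins, got {len(self.data[chrom])}")
            vals = self.data[chrom]
            if np.isinf(vals).any():
                raise ValueError(f"{chrom}: non-missing values must be finite")

    def copy(self) -> "GenomicTrack":
        return GenomicTrack(self.genome, {c: v.copy() for c, v in self.data.items()})

    def compatible(self, other: "GenomicTrack") -> bool:
        return self.genome == other.genome

    def values(self) -> np.ndarray:
        """All bins concatenated in chromosome order."""
        return np.concatenate([self.data[c] for c in self.genome.names])

    def mean(self) -> float:
        """Mean over non-missing bins."""
        return float(np.nanmean(self.values()))

    def n_missing(self) -> int:
        return int(np.isnan(self.values()).sum())

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]


def _require_compatible(*tracks: GenomicTrack) -> None:
    first = tracks[0]
    for t in tracks[1:]:
        if not first.compatible(t):
            raise ValueError("tracks have incompatible genome indices")


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------

def read_bedgraph(path: str, genome: GenomeIndex) -> GenomicTrack:
    """Read a 4-column bedGraph into a binned track.

    Interval values are distributed into bins by coverage-weighted averaging:
    each bin's value is the integral of the (piecewise-constant) bedGraph
    signal over the bin divided by the bin's genomic width. Positions not
    covered by any interval contribute 0. Overlapping intervals are an error
    (the dialect would be ambiguous).
    """
    w = genome.bin_width
    num = {c: np.zeros(genome.n_bins(c)) for c in genome.names}
    seen: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.names}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.split()
            chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            if chrom not in num:
                raise ValueError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end")
            if end > genome.length(chrom):
                raise ValueError(f"{path}:{ln}: interval past end of {chrom}")
            seen[chrom].append((start, end))
            k0, k1 = start // w, (end - 1) // w
            ks = np.arange(k0, k1 + 1)
            overlap = np.minimum(end, (ks + 1) * w) - np.maximum(start, ks * w)
            np.add.at(num[chrom], ks, value * overlap)
    for chrom, ivals in seen.items():
        ivals.sort()
        for (s0, e0), (s1, _) in zip(ivals, ivals[1:]):
            if s1 < e0:
                raise ValueError(
                    f"{path}: overlapping bedGraph intervals on {chrom} near {s1}")
    data = {c: num[c] / genome.bin_widths(c) for c in genome.names}
    return GenomicTrack(genome, data)


def write_bedgraph(track: GenomicTrack, path: str) -> None:
    """Write a track as bedGraph, merging runs of equal-valued adjacent bins.

    Missing bins are omitted; chromosome order follows the genome index.
    """
    w = track.genome.bin_width
    with open(path, "w") as fh:
        for chrom in track.genome.names:
            vals = track.data[chrom]
            L = track.genome.length(chrom)
            n = len(vals)
            k = 0
            while k < n:
                if np.isnan(vals[k]):
                    k += 1
                    continue
                j = k + 1
                while j < n and not np.isnan(vals[j]) and vals[j] == vals[k]:
                    j += 1
                fh.write(f"{chrom}\t{k * w}\t{min(j * w, L)}\t{vals[k]:.10g}\n")
                k = j


# ---------------------------------------------------------------------------
# ICL coverage from alignments
# ---------------------------------------------------------------------------

def icl_coverage_from_alignments(alignments, genome: GenomeIndex) -> GenomicTrack:
    """Count per-bin 5' ends of first-in-pair alignments (the crosslink sites).

    ``alignments`` is a path to a SAM/BAM file or an open
    :class:`pysam.AlignmentFile`. Each mapped, primary, non-duplicate,
    first-in-pair record contributes one count at the bin holding the 5'-most
    genomic base of the read (leftmost base for forward reads, rightmost for
    reverse reads). Duplicate *removal* is assumed done upstream; here only
    the duplicate flag is honoured. Single-end data is rejected.
    """
    own = isinstance(alignments, str)
    af = pysam.AlignmentFile(alignments) if own else alignments
    w = genome.bin_width
    counts = {c: np.zeros(genome.n_bins(c)) for c in genome.names}
    try:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            if not read.is_paired:
                raise ValueError(
                    "unpaired alignment encountered; single-end data is not "
                    "supported (ICL position is defined by the 5' end of Read 1)")
            if (not read.is_read1 or read.is_secondary
                    or read.is_supplementary or read.is_duplicate):
                continue
            chrom = read.reference_name
            if chrom not in counts:
                raise ValueError(f"alignment to unknown chromosome {chrom!r}")
            pos5 = read.reference_end - 1 if read.is_reverse else read.reference_start
            counts[chrom][pos5 // w] += 1
    finally:
        if own:
            af.close()
    return GenomicTrack(genome, counts)


# ---------------------------------------------------------------------------
# Track arithmetic and normalization
# ---------------------------------------------------------------------------

def _mask_bins(genome: GenomeIndex, intervals: IntervalSet) -> dict[str, np.ndarray]:
    """Boolean per-chromosome arrays: True where a bin overlaps an interval."""
    w = genome.bin_width
    mask = {c: np.zeros(genome.n_bins(c), dtype=bool) for c in genome.names}
    for iv in intervals:
        if iv.chrom not in mask:
            raise ValueError(f"blacklist chromosome {iv.chrom!r} not in genome")
        k0 = iv.start // w
        k1 = min((iv.end - 1) // w, genome.n_bins(iv.chrom) - 1)
        mask[iv.chrom][k0:k1 + 1] = True
    return mask


def normalize_mean(track: GenomicTrack, mask: IntervalSet | None = None) -> GenomicTrack:
    """Divide every bin by the genome-wide mean over non-missing bins.

    If ``mask`` is given, bins overlapping it are excluded from the mean
    computation (but still divided). The output mean over the normalization
    domain is exactly 1.
    """
    excluded = _mask_bins(track.genome, mask) if mask is not None else None
    total, count = 0.0, 0
    for chrom in track.genome.names:
        vals = track.data[chrom]
        keep = ~np.isnan(vals)
        if excluded is not None:
            keep &= ~excluded[chrom]
        total += float(vals[keep].sum())
        count += int(keep.sum())
    if count == 0:
        raise ValueError("no bins available to compute the normalization mean")
    mean = total / count
    if mean == 0:
        raise ValueError("cannot normalize a track with zero mean")
    return GenomicTrack(track.genome, {c: v / mean for c, v in track.data.items()})


def average_tracks(tracks: Sequence[GenomicTrack]) -> GenomicTrack:
    """Per-bin arithmetic mean; a bin missing in any input is missing."""
    if not tracks:
        raise ValueError("need at least one track to average")
    _require_compatible(*tracks)
    genome = tracks[0].genome
    data = {}
    for chrom in genome.names:
        stack = np.stack([t.data[chrom] for t in tracks])
        data[chrom] = stack.mean(axis=0)  # NaN anywhere -> NaN, as required
    return GenomicTrack(genome, data)


def subtract_tracks(a: GenomicTrack, b: GenomicTrack) -> GenomicTrack:
    _require_compatible(a, b)
    return GenomicTrack(a.genome, {c: a.data[c] - b.data[c] for c in a.genome.names})


def divide_tracks(a: GenomicTrack, b: GenomicTrack, pseudocount: float = 0.0) -> GenomicTrack:
    """Per-bin ``(a + eps) / (b + eps)``.

    With ``pseudocount=0``, zero-denominator bins become missing and their
    count is logged (not raised): these are uninformative, not fatal.
    """
    _require_compatible(a, b)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    data = {}
    n_zero = 0
    for chrom in a.genome.names:
        numer = a.data[chrom] + pseudocount
        denom = b.data[chrom] + pseudocount
        with np.errstate(divide="ignore", invalid="ignore"):
            out = numer / denom
        bad = (denom == 0) & ~np.isnan(numer)
        n_zero += int(bad.sum())
        out[denom == 0] = np.nan
        data[chrom] = out
    if n_zero:
        logger.warning("divide_tracks: %d zero-denominator bins set to missing", n_zero)
    return GenomicTrack(a.genome, data)


def mask_blacklist(track: GenomicTrack, blacklist: IntervalSet) -> GenomicTrack:
    """Set bins overlapping any blacklist interval by >= 1 bp to missing."""
    out = track.copy()
    if len(blacklist) == 0:
        return out
    for chrom, m in _mask_bins(track.genome, blacklist).items():
        out.data[chrom][m] = np.nan
    return out


def moving_average(track: GenomicTrack, n_bins: int) -> GenomicTrack:
    """Centered moving average over an odd number of bins (visual smoothing).

    NaN-aware: each output bin averages the non-missing inputs in its window;
    all-missing windows stay missing.
    """
    if n_bins % 2 != 1 or n_bins < 1:
        raise ValueError("smoothing window must be a positive odd bin count")
    if n_bins == 1:
        return track.copy()
    kernel = np.ones(n_bins)
    data = {}
    for chrom, vals in track.data.items():
        finite = ~np.isnan(vals)
        num = np.convolve(np.where(finite, vals, 0.0), kernel, mode="same")
        den = np.convolve(finite.astype(float), kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            out = num / den
        out[den == 0] = np.nan
        data[chrom] = out
    return GenomicTrack(track.genome, data)
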