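"""Gene model, expression from stranded mRNA tracks, percentile grouping, gene pairs.

Genes are stranded ORF intervals; the TSS/TES anchors are the stranded ORF
bounds (no UTR model — the annotation inputs are ORF BED files). Gene pairs
are nearest neighbours in per-chromosome coordinate order, classified by
strand configuration, with the shared intergenic gap optionally "purified"
(no third annotation overlaps it).
"""
from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .tracks import GenomicTrack, Interval, IntervalSet

logger = logging.getLogger("torsionmap")

PROMOTER_CLASSES = ("UNB", "TFO", "STM", "RP")

DEFAULT_PERCENTILE_BREAKS = (20.0, 40.0, 60.0, 80.0)  # quintiles


@dataclass(frozen=True)
class Gene:
    chrom: str
    start: int
    end: int
    strand: str
    name: str
    expression: float | None = None
    promoter_class: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.name}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenePair:
    """Adjacent gene pair; ``left.start < right.start`` on one chromosome."""

    left: Gene
    right: Gene
    configuration: str  # divergent | convergent | codirectional
    gap_start: int
    gap_end: int
    purified: bool

    @property
    def chrom(self) -> str:
        return self.left.chrom


def read_genes(bed_path: str) -> list[Gene]:
    """Read BED6 ORF annotations into :class:`Gene` records (input order kept)."""
    genes: list[Gene] = []
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.split()
            if len(f) < 6:
                raise ValueError(
                    f"{bed_path}:{ln}: BED6 with a strand column is required")
            genes.append(Gene(f[0], int(f[1]), int(f[2]), f[5], f[3]))
    return genes


def write_genes(genes: Sequence[Gene], bed_path: str) -> None:
    with open(bed_path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")


def genes_by_chrom(genes: Iterable[Gene]) -> dict[str, list[Gene]]:
    """Per-chromosome lists sorted by start (stable)."""
    out: dict[str, list[Gene]] = {}
    for g in genes:
        out.setdefault(g.chrom, []).append(g)
    for chrom in out:
        out[chrom].sort(key=lambda g: g.start)
    return out


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def expression_from_mrna(plus_track: GenomicTrack, minus_track: GenomicTrack,
                         genes: Sequence[Gene]) -> list[Gene]:
    """Quantify expression as mean |plus - minus| mRNA signal over ORF bins.

    The strand subtraction makes the measure strand-agnostic (the absolute
    value recovers minus-strand genes with the same formula). Returns new
    Gene records with ``expression`` set.
    """
    if not plus_track.compatible(minus_track):
        raise ValueError("mRNA strand tracks have incompatible genomes")
    w = plus_track.genome.bin_width
    out = []
    for g in genes:
        diff = plus_track.data[g.chrom] - minus_track.data[g.chrom]
        k0, k1 = g.start // w, (g.end - 1) // w
        if g.size < w:
            raise ValueError(f"gene {g.name}: ORF shorter than one bin")
        expr = float(np.nanmean(np.abs(diff[k0:k1 + 1])))
        out.append(replace(g, expression=expr))
    return out


# ---------------------------------------------------------------------------
# Percentile grouping
# ---------------------------------------------------------------------------

def percentile_groups(items: Sequence, key: Callable | str | Sequence[float],
                      boundaries: Sequence[float] = DEFAULT_PERCENTILE_BREAKS,
                      ) -> np.ndarray:
    """Partition items by empirical percentile rank of a key.

    ``key`` is a callable, an attribute name (e.g. ``"expression"``/``"size"``),
    or a precomputed value sequence. The percentile rank of an item is
    ``100 * (# items with strictly smaller key) / n`` — ties share the rank of
    their first occurrence, so an all-equal key puts every item in the first
    group. Returns a group index per item (0-based, ``len(boundaries)+1``
    groups); every item lands in exactly one group.
    """
    if len(items) == 0:
        raise ValueError("cannot group an empty list")
    bounds = list(boundaries)
    if bounds != sorted(bounds) or len(set(bounds)) != len(bounds):
        raise ValueError("percentile boundaries must be strictly increasing")
    if bounds and not (0 < bounds[0] and bounds[-1] < 100):
        raise ValueError("percentile boundaries must lie within (0, 100)")
    if callable(key):
        vals = np.asarray([key(x) for x in items], dtype=float)
    elif isinstance(key, str):
        vals = np.asarray([getattr(x, key) for x in items], dtype=float)
    else:
        vals = np.asarray(key, dtype=float)
        if len(vals) != len(items):
            raise ValueError("key values and items differ in length")
    if np.isnan(vals).any():
        raise ValueError("key values contain NaN")
    n = len(vals)
    order = np.sort(vals)
    n_smaller = np.searchsorted(order, vals, side="left")
    pct = 100.0 * n_smaller / n
    return np.array([bisect_right(bounds, p) for p in pct], dtype=int)


def group_members(items: Sequence, assignment: np.ndarray, n_groups: int | None = None) -> list[list]:
    """Materialize percentile-group assignments as lists (input order kept)."""
    k = int(assignment.max()) + 1 if n_groups is None else n_groups
    groups: list[list] = [[] for _ in range(k)]
    for item, g in zip(items, assignment):
        groups[g].append(item)
    return groups


# ---------------------------------------------------------------------------
# Gene pairs
# ---------------------------------------------------------------------------

def _configuration(left: Gene, right: Gene) -> str:
    if left.strand == "-" and right.strand == "+":
        return "divergent"
    if left.strand == "+" and right.strand == "-":
        return "convergent"
    return "codirectional"


def classify_gene_pairs(genes: Sequence[Gene],
                        all_annotations: IntervalSet | None = None,
                        ) -> list[GenePair]:
    """Emit nearest-neighbour gene pairs with strand configuration.

    Pairs are adjacent genes in per-chromosome coordinate order; pairs whose
    ORFs overlap are skipped (count logged). The ``purified`` flag is True iff
    no ``all_annotations`` interval other than the two members themselves
    overlaps the intergenic gap — membership is judged by matching name or
    exact ORF coordinates.
    """
    pairs: list[GenePair] = []
    n_skipped = 0
    ann_by_chrom: dict[str, list[Interval]] = {}
    if all_annotations is not None:
        for iv in all_annotations:
            ann_by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, chrom_genes in genes_by_chrom(genes).items():
        for left, right in zip(chrom_genes, chrom_genes[1:]):
            if left.end > right.start:
                n_skipped += 1
                continue
            gap_start, gap_end = left.end, right.start
            purified = True
            if all_annotations is not None and gap_end > gap_start:
                for iv in ann_by_chrom.get(chrom, []):
                    if iv.start < gap_end and iv.end > gap_start:
                        is_member = any(
                            iv.name == g.name or (iv.start == g.start and iv.end == g.end)
                            for g in (left, right))
                        if not is_member:
                            purified = False
                            break
            pairs.append(GenePair(left, right, _configuration(left, right),
                                  gap_start, gap_end, purified))
    if n_skipped:
        logger.info("classify_gene_pairs: skipped %d overlapping-ORF pairs", n_skipped)
    return pairs


def filter_pairs_by_class(pairs: Sequence[GenePair], classes: Iterable[str]) -> list[GenePair]:
    """Keep pairs where BOTH members' promoter class is in ``classes``."""
    wanted = set(classes)
    return [p for p in pairs
            if p.left.promoter_class in wanted and p.right.promoter_class in wanted]


# ---------------------------------------------------------------------------
# Promoter classes and table I/O
# ---------------------------------------------------------------------------

def read_class_table(path: str) -> dict[str, str]:
    """Two-column TSV ``gene<TAB>class``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "cls"],
                     dtype=str, comment="#")
    return dict(zip(df["gene"], df["cls"]))

def assign_promoter_classes(genes: Sequence[Gene], classes: dict[str, str]) -> list[Gene]:
    return [replace(g, promoter_class=classes.get(g.name)) for g in genes]

def pairs_to_table(pairs: Sequence[GenePair]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [p.chrom for p in pairs],
        "leftGene": [p.left.name for p in pairs],
        "rightGene": [p.right.name for p in pairs],
        "config": [p.configuration for p in pairs],
        "gapStart": [p.gap_start for p in pairs],
        "gapEnd": [p.gap_end for p in pairs],
        "purified": [p.purified for p in pairs],
    })
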