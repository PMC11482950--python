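"""Synthetic genomes, chromatin fields, and crosslink count tracks.

The generator implements the twin-supercoiled-domain picture of transcription
on a desk-scale genome so that every pipeline stage can be exercised against
known ground truth:

* an annotation layer (non-overlapping ORFs with sampled lengths, gaps,
  strands, log-normal expression, promoter classes);
* an accessibility field with an NFR bump upstream of each TSS and a damped
  ~160-bp nucleosome-repeat modulation through gene bodies;
* a torsion field with (-) torsion tails behind promoters and (+) torsion
  tails past terminators, exponentially confined (default decay 750 bp, i.e.
  within 1-2 kb), promoter amplitude scaling with expression and terminator
  amplitude additionally with gene length; divergent promoter pairs bound by
  an insulator have their inward tails truncated at the insulator;
* a multiplicative smooth sequence-preference field;
* Poisson count sampling with an approximately linear torsion->crosslinking
  response, ``rate = depth * seq * access * max(0, 1 + kappa * torsion)``;
* companion mRNA, cohesin and loop fixtures.

All randomness flows from one seed through named substreams, so each stage is
independently reproducible.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .annotation import Gene, GenePair, classify_gene_pairs, write_genes
from .loops import Loop, loops_to_table
from .tracks import GenomeIndex, GenomicTrack, write_bedgraph

logger = logging.getLogger("torsionmap")

# named substreams: every stage derives its rng as default_rng([seed, STREAM])
_STREAM_ANNOTATION = 1
_STREAM_FIELDS = 2
_STREAM_SAMPLING = 3
_STREAM_FIXTURES = 4

_TAIL_CUTOFF_DECAY_LENGTHS = 8.0


@dataclass(frozen=True)
class SimulationParams:
    """All generator knobs; defaults define the standard study conditions."""

    # genome
    n_chromosomes: int = 4
    chromosome_length: int = 300_000
    bin_width: int = 10
    # gene layout
    gene_length_log_mean: float = 7.0    # ln bp; mean length ~1.3 kb
    gene_length_log_sd: float = 0.55
    gene_length_min: int = 150
    gene_length_max: int = 15_000
    intergenic_gap_mean: float = 400.0   # bp, gamma-distributed gaps
    intergenic_gap_shape: float = 2.0
    intergenic_gap_min: int = 60
    strand_plus_probability: float = 0.5
    # expression (arbitrary units, log-normal)
    expression_log_mean: float = 0.0
    expression_log_sd: float = 1.0
    # promoter classes
    class_proportions: tuple[tuple[str, float], ...] = (
        ("UNB", 0.45), ("TFO", 0.35), ("STM", 0.20))
    # accessibility field (unitless, clipped to [a_min, 1])
    accessibility_baseline: float = 0.5
    nfr_amplitude: float = 0.4
    nfr_offset_bp: float = 80.0          # NFR bump center upstream of the TSS
    nfr_width_bp: float = 60.0           # Gaussian sigma
    nucleosome_amplitude: float = 0.25
    nucleosome_repeat_bp: float = 160.0
    phasing_decay_bp: float = 800.0
    accessibility_min: float = 0.05
    # torsion field (t > 0 means (-) torsion; kappa*t is the fractional
    # change of the crosslinking rate)
    tss_amplitude: float = 0.2
    tes_amplitude: float = 0.05
    tes_length_coeff: float = 1e-4       # per bp of ORF length
    torsion_decay_bp: float = 750.0      # confines torsion to within 1-2 kb
    kappa: float = 0.5                   # linear torsion->crosslinking response
    insulator_leakage: float = 0.0       # 0 = hard truncation at insulators
    insulator_bound_prob: tuple[tuple[str, float], ...] = (
        ("UNB", 0.0), ("TFO", 1.0), ("STM", 1.0))
    # sequence preference (multiplicative log-normal smooth field)
    sequence_log_sd: float = 0.25
    sequence_corr_bp: float = 200.0
    # sequencing depth: physical crosslink density times the sequencing
    # oversampling of each crosslink event; expected counts per bin per
    # replicate = icl_per_kb * depth_scale * bin_width / 1000
    depth_icl_per_kb: float = 0.2
    depth_scale: float = 30_000.0
    n_with_replicates: int = 2
    n_without_replicates: int = 3
    # companion fixtures
    mrna_noise_sd: float = 0.05          # relative, per bin
    cohesin_background: float = 0.1
    cohesin_peak_height: float = 2.0     # per unit loop score
    cohesin_peak_width_bp: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.accessibility_baseline <= 1):
            raise ValueError("accessibility baseline must be in (0, 1]")
        for name in ("nfr_amplitude", "nucleosome_amplitude", "tss_amplitude",
                     "tes_amplitude", "tes_length_coeff", "kappa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("torsion_decay_bp", "phasing_decay_bp", "depth_scale",
                     "depth_icl_per_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def expected_counts_per_bin(self) -> float:
        return self.depth_icl_per_kb * self.depth_scale * self.bin_width / 1000.0


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests: annotation, fields, planted features."""

    params: SimulationParams
    genome: GenomeIndex
    genes: list[Gene]
    divergent_pairs: list[GenePair] = field(default_factory=list)
    insulators: list[tuple[str, int]] = field(default_factory=list)
    # per-gene upstream truncation distance (bp from TSS), for insulated genes
    upstream_truncation: dict[str, int] = field(default_factory=dict)
    accessibility: GenomicTrack | None = None
    torsion: GenomicTrack | None = None
    sequence: GenomicTrack | None = None
    loops: list[Loop] = field(default_factory=list)


def _rng(params: SimulationParams, stream: int, seed: int | None = None) -> np.random.Generator:
    return np.random.default_rng([seed if seed is not None else params.seed, stream])


def _bin_centers(genome: GenomeIndex, chrom: str) -> np.ndarray:
    w = genome.bin_width
    return np.arange(genome.n_bins(chrom)) * w + w / 2.0


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def make_genome_and_genes(params: SimulationParams, seed: int | None = None) -> SyntheticTruth:
    """Lay out non-overlapping ORFs with sampled lengths, gaps, strands,
    expression and promoter classes; place insulators at bound divergent gaps."""
    rng = _rng(params, _STREAM_ANNOTATION, seed)
    names = tuple(f"chr{i + 1}" for i in range(params.n_chromosomes))
    genome = GenomeIndex(names, (params.chromosome_length,) * params.n_chromosomes,
                         params.bin_width)
    class_names = [c for c, _ in params.class_proportions]
    class_probs = np.array([p for _, p in params.class_proportions])
    class_probs = class_probs / class_probs.sum()
    genes: list[Gene] = []
    for chrom in names:
        L = params.chromosome_length
        cursor = int(rng.gamma(params.intergenic_gap_shape,
                               params.intergenic_gap_mean / params.intergenic_gap_shape))
        placed = 0
        while True:
            length = int(round(rng.lognormal(params.gene_length_log_mean,
                                             params.gene_length_log_sd)))
            length = min(max(length, params.gene_length_min), params.gene_length_max)
            if cursor + length > L - 200:
                break
            strand = "+" if rng.random() < params.strand_plus_probability else "-"
            expr = float(rng.lognormal(params.expression_log_mean,
                                       params.expression_log_sd))
            cls = class_names[rng.choice(len(class_names), p=class_probs)]
            genes.append(Gene(chrom, cursor, cursor + length, strand,
                              f"g{chrom[3:]}_{placed:04d}", expression=expr,
                              promoter_class=cls))
            placed += 1
            gap = max(params.intergenic_gap_min,
                      int(rng.gamma(params.intergenic_gap_shape,
                                    params.intergenic_gap_mean / params.intergenic_gap_shape)))
            cursor += length + gap
        if placed == 0:
            raise ValueError(f"chromosome {chrom} too short for a single gene")
    truth = SyntheticTruth(params, genome, genes)

    ins_prob = dict(params.insulator_bound_prob)
    pairs = classify_gene_pairs(genes)
    for pair in pairs:
        if pair.configuration != "divergent":
            continue
        truth.divergent_pairs.append(pair)
        p = max(ins_prob.get(pair.left.promoter_class, 0.0),
                ins_prob.get(pair.right.promoter_class, 0.0))
        if rng.random() < p:
            pos = (pair.gap_start + pair.gap_end) // 2
            truth.insulators.append((pair.chrom, pos))
            # distance from each member's TSS to the insulator
            truth.upstream_truncation[pair.left.name] = abs(pos - pair.left.tss)
            truth.upstream_truncation[pair.right.name] = abs(pos - pair.right.tss)
    return truth


# ---------------------------------------------------------------------------
# Fields
# ---------------------------------------------------------------------------

def accessibility_field(truth: SyntheticTruth, params: SimulationParams | None = None,
                        ) -> GenomicTrack:
    """a(x) = baseline + NFR Gaussian upstream of each TSS
    + A_nuc * exp(-d/lambda_phase) * cos(2 pi d / repeat) through gene bodies,
    clipped to [a_min, 1]. Orientation follows the gene strand."""
    p = params or truth.params
    genome = truth.genome
    data = {c: np.full(genome.n_bins(c), p.accessibility_baseline) for c in genome.names}
    for g in truth.genes:
        centers = _bin_centers(genome, g.chrom)
        a = data[g.chrom]
        sign = 1 if g.strand == "+" else -1
        # NFR bump upstream of the TSS
        x0 = g.tss - sign * p.nfr_offset_bp
        half = 5 * p.nfr_width_bp
        k0 = max(int((x0 - half) // genome.bin_width), 0)
        k1 = min(int((x0 + half) // genome.bin_width) + 1, len(a))
        d = centers[k0:k1] - x0
        a[k0:k1] += p.nfr_amplitude * np.exp(-0.5 * (d / p.nfr_width_bp) ** 2)
        # damped nucleosome-repeat modulation within the ORF
        k0 = max(g.start // genome.bin_width, 0)
        k1 = min((g.end - 1) // genome.bin_width + 1, len(a))
        d_in = (centers[k0:k1] - g.tss) * sign
        d_in = np.clip(d_in, 0, None)
        a[k0:k1] += (p.nucleosome_amplitude * np.exp(-d_in / p.phasing_decay_bp)
                     * np.cos(2 * np.pi * d_in / p.nucleosome_repeat_bp))
    for c in data:
        np.clip(data[c], p.accessibility_min, 1.0, out=data[c])
    track = GenomicTrack(genome, data)
    truth.accessibility = track
    return track


def torsion_field(truth: SyntheticTruth, params: SimulationParams | None = None,
                  ) -> GenomicTrack:
    """Twin-supercoiled-domain torsion field, summed over genes.

    Each gene contributes ``+T_tss * E * exp(-d/lambda)`` upstream of its TSS
    ((-) torsion behind the promoter) and ``-(T_tes + c_len * size) * E *
    exp(-d/lambda)`` downstream of its TES ((+) torsion past the terminator).
    Insulated divergent promoters have their inward tails truncated at the
    insulator coordinate (scaled by the leakage fraction beyond it).
    """
    p = params or truth.params
    genome = truth.genome
    data = {c: np.zeros(genome.n_bins(c)) for c in genome.names}
    cutoff = _TAIL_CUTOFF_DECAY_LENGTHS * p.torsion_decay_bp
    w = genome.bin_width
    for g in truth.genes:
        E = g.expression if g.expression is not None else 0.0
        if E == 0.0:
            continue
        centers = _bin_centers(genome, g.chrom)
        t = data[g.chrom]
        sign = 1 if g.strand == "+" else -1
        # (-) torsion tail upstream of the TSS
        if sign > 0:
            k0 = max(int((g.tss - cutoff) // w), 0)
            k1 = max(g.tss // w, 0)
        else:
            k0 = min(int(g.tss // w) + 1, len(t))
            k1 = min(int((g.tss + cutoff) // w) + 1, len(t))
        d = (g.tss - centers[k0:k1]) * sign
        contrib = p.tss_amplitude * E * np.exp(d / -p.torsion_decay_bp)
        contrib[d < 0] = 0.0
        d_ins = truth.upstream_truncation.get(g.name)
        if d_ins is not None:
            contrib[d > d_ins] *= p.insulator_leakage
        t[k0:k1] += contrib
        # (+) torsion tail downstream of the TES
        amp = (p.tes_amplitude + p.tes_length_coeff * g.size) * E
        if sign > 0:
            k0 = min(int(g.tes // w) + 1, len(t))
            k1 = min(int((g.tes + cutoff) // w) + 1, len(t))
        else:
            k0 = max(int((g.tes - cutoff) // w), 0)
            k1 = max(g.tes // w, 0)
        d = (centers[k0:k1] - g.tes) * sign
        contrib = amp * np.exp(d / -p.torsion_decay_bp)
        contrib[d < 0] = 0.0
        t[k0:k1] -= contrib
    track = GenomicTrack(genome, data)
    truth.torsion = track
    return track


def sequence_field(truth: SyntheticTruth, params: SimulationParams | None = None,
                   seed: int | None = None) -> GenomicTrack:
    """Smooth multiplicative sequence-preference field, exp(N(0, log_sd))."""
    p = params or truth.params
    rng = _rng(p, _STREAM_FIELDS, seed)
    genome = truth.genome
    sigma_bins = p.sequence_corr_bp / genome.bin_width
    data = {}
    for chrom in genome.names:
        z = rng.standard_normal(genome.n_bins(chrom))
        z = gaussian_filter1d(z, sigma_bins, mode="wrap")
        sd = z.std()
        if sd > 0:
            z = z / sd
        data[chrom] = np.exp(p.sequence_log_sd * z)
    track = GenomicTrack(genome, data)
    truth.sequence = track
    return track


# ---------------------------------------------------------------------------
# Count sampling
# ---------------------------------------------------------------------------

def expected_rates(truth: SyntheticTruth, params: SimulationParams | None = None,
                   ) -> dict[str, GenomicTrack]:
    """Noise-free per-bin expected counts for the three conditions."""
    p = params or truth.params
    if truth.accessibility is None or truth.torsion is None or truth.sequence is None:
        raise ValueError("fields must be computed before sampling")
    D = p.expected_counts_per_bin
    genome = truth.genome
    out = {"with": {}, "without": {}, "purified": {}}
    n_clipped = 0
    for chrom in genome.names:
        s = truth.sequence.data[chrom]
        a = truth.accessibility.data[chrom]
        t = truth.torsion.data[chrom]
        response = 1.0 + p.kappa * t
        n_clipped += int((response < 0).sum())
        out["purified"][chrom] = D * s
        out["without"][chrom] = D * s * a
        out["with"][chrom] = D * s * a * np.clip(response, 0.0, None)
    if n_clipped:
        logger.info("expected_rates: %d bins clipped at zero rate (kappa*t < -1)",
                    n_clipped)
    return {k: GenomicTrack(genome, v) for k, v in out.items()}


def sample_icl_tracks(truth: SyntheticTruth, params: SimulationParams | None = None,
                      seed: int | None = None,
                      ) -> tuple[list[GenomicTrack], list[GenomicTrack], GenomicTrack]:
    """Poisson-sample crosslink count tracks for the three conditions.

    Returns (with-torsion replicates, zero-torsion replicates, purified track);
    counts are independent across bins, replicates and conditions.
    """
    p = params or truth.params
    rng = _rng(p, _STREAM_SAMPLING, seed)
    rates = expected_rates(truth, p)
    genome = truth.genome

    def draw(rate: GenomicTrack) -> GenomicTrack:
        return GenomicTrack(genome, {
            c: rng.poisson(rate.data[c]).astype(float) for c in genome.names})

    with_reps = [draw(rates["with"]) for _ in range(p.n_with_replicates)]
    without_reps = [draw(rates["without"]) for _ in range(p.n_without_replicates)]
    purified = draw(rates["purified"])
    return with_reps, without_reps, purified


# ---------------------------------------------------------------------------
# Companion fixtures: mRNA, cohesin, loops
# ---------------------------------------------------------------------------

def synthetic_mrna_and_chip(truth: SyntheticTruth, params: SimulationParams | None = None,
                            seed: int | None = None,
                            ) -> tuple[GenomicTrack, GenomicTrack, GenomicTrack, list[Loop]]:
    """Strand-specific mRNA tracks, a cohesin ChIP-like track, and planted loops.

    mRNA: each ORF carries its gene's true expression (plus relative noise) on
    the strand-appropriate track, so ``expression_from_mrna`` recovers it.
    Loops connect consecutive convergent-gap midpoints per chromosome, scored
    by the local (+)-torsion magnitude at their boundaries; cohesin is a
    background plus Gaussian bumps at loop boundaries, height ~ loop score.
    """
    p = params or truth.params
    if truth.torsion is None:
        raise ValueError("torsion field must be computed before planting loops")
    rng = _rng(p, _STREAM_FIXTURES, seed)
    genome = truth.genome
    w = genome.bin_width
    plus = GenomicTrack.zeros(genome)
    minus = GenomicTrack.zeros(genome)
    for g in truth.genes:
        E = g.expression or 0.0
        k0, k1 = g.start // w, (g.end - 1) // w + 1
        signal = E * (1.0 + p.mrna_noise_sd * rng.standard_normal(k1 - k0)) \
            if p.mrna_noise_sd > 0 else np.full(k1 - k0, E)
        (plus if g.strand == "+" else minus).data[g.chrom][k0:k1] += signal

    # plant loops at convergent-gap midpoints (snapped to bin centers)
    midpoints: dict[str, list[int]] = {}
    pairs = classify_gene_pairs(truth.genes)
    for pair in pairs:
        if pair.configuration != "convergent" or pair.gap_end <= pair.gap_start:
            continue
        mid = (pair.gap_start + pair.gap_end) // 2
        midpoints.setdefault(pair.chrom, []).append((mid // w) * w + w // 2)
    loops: list[Loop] = []
    for chrom, mids in midpoints.items():
        mids.sort()
        t = truth.torsion.data[chrom]
        for i, (lb, rb) in enumerate(zip(mids, mids[1:])):
            pos_torsion = [max(0.0, -t[b // w]) for b in (lb, rb)]
            score = float(np.mean(pos_torsion))
            loops.append(Loop(chrom, lb, rb, score, f"loop_{chrom[3:]}_{i:03d}"))
    if not loops:
        logger.warning("synthetic_mrna_and_chip: no convergent pairs, no loops planted")
    truth.loops = loops

    cohesin = GenomicTrack(genome, {
        c: np.full(genome.n_bins(c), p.cohesin_background) for c in genome.names})
    sigma = p.cohesin_peak_width_bp
    boundary_heights: dict[tuple[str, int], float] = {}
    for lp in loops:
        for b in (lp.left, lp.right):
            key = (lp.chrom, b)
            h = p.cohesin_peak_height * lp.score
            boundary_heights[key] = max(boundary_heights.get(key, 0.0), h)
    for (chrom, b), h in boundary_heights.items():
        centers = _bin_centers(genome, chrom)
        k0 = max(int((b - 5 * sigma) // w), 0)
        k1 = min(int((b + 5 * sigma) // w) + 1, len(centers))
        d = centers[k0:k1] - b
        cohesin.data[chrom][k0:k1] += h * np.exp(-0.5 * (d / sigma) ** 2)
    return plus, minus, cohesin, loops


def recovery_correlation(recovered: GenomicTrack, truth: SyntheticTruth,
                         min_abs: float = 0.1, smooth_bins: int = 5) -> float:
    """Pearson r between a recovered torsion track and the injected field.

    The recovered track is lightly smoothed (moving average over
    ``smooth_bins`` bins) and compared over bins where the injected field
    exceeds the generator's noise floor (``|t| >= min_abs``).
    """
    from .tracks import moving_average
    if truth.torsion is None:
        raise ValueError("truth has no torsion field")
    sm = moving_average(recovered, smooth_bins)
    rec, inj = [], []
    for chrom in truth.genome.names:
        t = truth.torsion.data[chrom]
        r = sm.data[chrom]
        sel = (np.abs(t) >= min_abs) & ~np.isnan(r)
        rec.append(r[sel])
        inj.append(t[sel])
    rec = np.concatenate(rec)
    inj = np.concatenate(inj)
    if rec.size < 2:
        raise ValueError("too few bins above the noise floor")
    return float(np.corrcoef(rec, inj)[0, 1])


# ---------------------------------------------------------------------------
# One-call simulation and fixture export
# ---------------------------------------------------------------------------

def simulate(params: SimulationParams | None = None, seed: int | None = None,
             ) -> tuple[SyntheticTruth, dict]:
    """Run the full generator; returns the truth object and all emitted tracks."""
    p = params or SimulationParams()
    if seed is not None:
        p = replace(p, seed=seed)
    truth = make_genome_and_genes(p)
    accessibility_field(truth, p)
    torsion_field(truth, p)
    sequence_field(truth, p)
    with_reps, without_reps, purified = sample_icl_tracks(truth, p)
    mrna_plus, mrna_minus, cohesin, _ = synthetic_mrna_and_chip(truth, p)
    tracks = {
        "with": with_reps,
        "without": without_reps,
        "purified": purified,
        "mrna_plus": mrna_plus,
        "mrna_minus": mrna_minus,
        "cohesin": cohesin,
    }
    return truth, tracks


def write_fixture_dir(truth: SyntheticTruth, tracks: dict, outdir: str) -> dict:
    """Emit bedGraphs, BED6 genes, class/loop/truth TSVs and a JSON manifest."""
    os.makedirs(outdir, exist_ok=True)
    p = truth.params
    files: dict[str, str] = {}

    def path(name: str) -> str:
        files[name] = name
        return os.path.join(outdir, name)

    truth.genome.write_chrom_sizes(path("genome.chrom.sizes"))
    write_genes(truth.genes, path("genes.bed"))
    with open(path("classes.tsv"), "w") as fh:
        for g in truth.genes:
            fh.write(f"{g.name}\t{g.promoter_class}\n")
    for i, t in enumerate(tracks["with"]):
        write_bedgraph(t, path(f"icl_with_torsion_rep{i + 1}.bedgraph"))
    for i, t in enumerate(tracks["without"]):
        write_bedgraph(t, path(f"icl_without_torsion_rep{i + 1}.bedgraph"))
    write_bedgraph(tracks["purified"], path("icl_purified.bedgraph"))
    write_bedgraph(tracks["mrna_plus"], path("mrna_plus.bedgraph"))
    write_bedgraph(tracks["mrna_minus"], path("mrna_minus.bedgraph"))
    write_bedgraph(tracks["cohesin"], path("cohesin.bedgraph"))
    if truth.accessibility is not None:
        write_bedgraph(truth.accessibility, path("truth_accessibility.bedgraph"))
    if truth.torsion is not None:
        write_bedgraph(truth.torsion, path("truth_torsion.bedgraph"))
    loops_to_table(truth.loops).to_csv(path("loops.tsv"), sep="\t", index=False)
    with open(path("truth_genes.tsv"), "w") as fh:
        fh.write("name\tchrom\tstart\tend\tstrand\texpression\tclass\n")
        for g in truth.genes:
            fh.write(f"{g.name}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}"
                     f"\t{g.expression:.8g}\t{g.promoter_class}\n")
    with open(path("insulators.tsv"), "w") as fh:
        fh.write("chrom\tposition\n")
        for chrom, pos in truth.insulators:
            fh.write(f"{chrom}\t{pos}\n")
    manifest = {
        "seed": p.seed,
        "params": dataclasses.asdict(p),
        "n_genes": len(truth.genes),
        "n_loops": len(truth.loops),
        "n_insulators": len(truth.insulators),
        "files": sorted(files),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
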