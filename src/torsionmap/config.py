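"""Pipeline configuration: a single YAML-serializable record with validation."""
from __future__ import annotations

import dataclasses
import logging
import os
import sys
from dataclasses import dataclass, field

import yaml

logger = logging.getLogger("torsionmap")


@dataclass
class PipelineConfig:
    """Paths and parameters for an end-to-end run.

    Path fields may be None when the corresponding analysis is not requested;
    ``validate()`` checks numeric ranges, ``validate_paths()`` additionally
    checks that every referenced input exists.
    """

    # inputs
    chrom_sizes: str | None = None
    with_tracks: list[str] = field(default_factory=list)
    without_tracks: list[str] = field(default_factory=list)
    purified_track: str | None = None
    blacklist: str | None = None
    genes_bed: str | None = None
    annotations_bed: str | None = None
    class_table: str | None = None
    mrna_plus: str | None = None
    mrna_minus: str | None = None
    cohesin_track: str | None = None
    loops_table: str | None = None
    # parameters
    bin_width: int = 10
    normalize_before_average: bool = True
    division_pseudocount: float = 0.0
    purified_mode: str = "ratio"               # ratio | difference
    flank_bp: int = 1000
    n_body_bins: int = 100
    exclusion: str = "none"                    # none | beyond_TES | beyond_TSS
    percentile_breaks: list[float] = field(default_factory=lambda: [20, 40, 60, 80])
    peak_window_bp: int = 20
    peak_search_bp: int = 500
    loop_max_snap_dist_bp: int = 500
    peak_min_separation_bp: int = 250
    peak_min_height: float | None = None
    seed: int = 0
    output_dir: str = "torsionmap_out"

    def validate(self) -> list[str]:
        """Return a list of violations (empty = valid)."""
        problems: list[str] = []
        if self.bin_width <= 0:
            problems.append("bin_width must be positive")
        if self.purified_mode not in ("ratio", "difference"):
            problems.append("purified_mode must be 'ratio' or 'difference'")
        if self.exclusion not in ("none", "beyond_TES", "beyond_TSS"):
            problems.append("exclusion must be none|beyond_TES|beyond_TSS")
        if self.flank_bp % self.bin_width != 0 or self.flank_bp <= 0:
            problems.append("flank_bp must be a positive multiple of bin_width")
        if self.n_body_bins < 1:
            problems.append("n_body_bins must be >= 1")
        if sorted(self.percentile_breaks) != list(self.percentile_breaks) or any(
                not (0 < b < 100) for b in self.percentile_breaks):
            problems.append("percentile_breaks must be increasing within (0,100)")
        if self.division_pseudocount < 0:
            problems.append("division_pseudocount must be >= 0")
        for name in ("peak_window_bp", "peak_search_bp", "loop_max_snap_dist_bp",
                     "peak_min_separation_bp"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive")
        return problems

    def validate_paths(self) -> list[str]:
        missing: list[str] = []
        single = [self.chrom_sizes, self.purified_track, self.blacklist,
                  self.genes_bed, self.annotations_bed, self.class_table,
                  self.mrna_plus, self.mrna_minus, self.cohesin_track,
                  self.loops_table]
        for p in single + list(self.with_tracks) + list(self.without_tracks):
            if p is not None and not os.path.exists(p):
                missing.append(p)
        return missing

    def to_yaml(self, path: str | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True,
                              default_flow_style=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def setup_logging(log_file: str | None = None, level: int = logging.INFO) -> None:
    """Log to stderr (and optionally a file) at INFO by default."""
    root = logging.getLogger("torsionmap")
    root.setLevel(level)
    root.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    root.addHandler(sh)
    if log_file is not None:
        fh = logging.FileHandler(log_file)
        fh.setFormatter(fmt)
        root.addHandler(fh)
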