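"""Configuration objects for every pipeline stage.

All stage configs are plain dataclasses validated eagerly in
``__post_init__`` so that invalid settings fail at construction time, not
mid-pipeline. Every source of randomness flows from a single integer seed
through named substreams (see :func:`gscresist.config.stage_rng`).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "ConfigError",
    "CohortConfig",
    "DssParams",
    "ClassificationConfig",
    "SsgseaConfig",
    "MethylationConfig",
    "stage_rng",
]


class ConfigError(ValueError):
    """Raised when a configuration violates its documented invariants."""


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random generator.

    A single global ``seed`` is combined with a stable hash of the stage
    name so that no stage consumes another stage's stream and adding a new
    stage never perturbs existing ones.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class CohortConfig:
    """Settings of the synthetic multi-modal cohort generator.

    Defaults emulate the design of a patient-derived glioblastoma stem-cell
    (GSC) screening study: 4 drug-sensitive and 5 drug-resistant cultures, a
    common panel of 329 drugs each tested in a 5-point 10-fold dose
    escalation against DMSO / benzethonium-chloride-like controls, bulk
    RNA-seq counts, and a nanopore-style CpG-island methylome with a planted
    MGMT-like promoter of 98 CpG sites.
    """

    n_sensitive: int = 4
    n_resistant: int = 5
    n_drugs: int = 329
    doses_per_drug: int = 5
    dose_step_log10: float = 1.0
    n_genes: int = 2000
    n_islands: int = 500
    seed: int = 0

    # effect sizes
    frac_active_drugs_sensitive: float = 0.35
    frac_active_drugs_resistant: float = 0.10
    stemness_log2fc: float = 1.0
    dm_island_fraction: float = 0.10
    dm_delta: float = 30.0  # methylation-percentage group difference

    # noise levels
    viability_cv: float = 0.08  # CV of multiplicative luminescence noise
    nb_dispersion: float = 0.1  # negative-binomial dispersion of counts
    meth_beta_precision: float = 50.0  # Beta precision of per-site 5mC
    dss_noise_sd: float = 2.0  # DSS-scale jitter used by gen_dss_matrix

    # plate layout / controls
    neg_ctrl_mean: float = 10_000.0  # DMSO luminescence
    pos_ctrl_mean: float = 500.0  # positive control (full kill)
    n_ctrl_wells: int = 16

    # methylome geometry
    chrom_length: int = 10_000_000
    mean_island_methylation: float = 35.0  # cohort-level island mean, %
    coverage_mean: float = 20.0
    coverage_floor: int = 1
    mgmt_mean_methylated: float = 30.0
    mgmt_mean_unmethylated: float = 10.0

    # incomplete-screening emulation
    missing_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_sensitive", "n_resistant", "n_drugs",
                     "doses_per_drug", "n_genes", "n_islands"):
            _check(int(getattr(self, name)) >= 1, f"{name} must be >= 1")
        for name in ("frac_active_drugs_sensitive",
                     "frac_active_drugs_resistant", "dm_island_fraction",
                     "missing_fraction"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must lie in [0, 1]")
        _check(self.frac_active_drugs_resistant
               <= self.frac_active_drugs_sensitive,
               "resistant samples must not respond to more drugs than "
               "sensitive ones (frac_active_drugs_resistant > "
               "frac_active_drugs_sensitive)")
        _check(0.0 <= self.dm_delta <= 100.0, "dm_delta must lie in [0, 100]")
        _check(self.viability_cv >= 0.0, "viability_cv must be >= 0")
        _check(self.nb_dispersion >= 0.0, "nb_dispersion must be >= 0")
        _check(self.meth_beta_precision > 0.0,
               "meth_beta_precision must be > 0")
        _check(self.pos_ctrl_mean < self.neg_ctrl_mean,
               "positive-control mean must lie below the negative-control "
               "mean (no control separation)")
        _check(self.n_ctrl_wells >= 2, "n_ctrl_wells must be >= 2")
        _check(0.0 < self.mean_island_methylation < 100.0,
               "mean_island_methylation must lie in (0, 100)")
        _check(self.coverage_floor >= 1, "coverage_floor must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.n_sensitive + self.n_resistant


@dataclass
class DssParams:
    """Drug Sensitivity Score settings.

    ``activity_threshold`` is the inhibition floor t of the activity window
    (default 10%, i.e. the 10-100% window); DSS integrates the fitted
    inhibition curve above t across the tested concentration range and
    normalizes by the full window area.
    """

    activity_threshold: float = 10.0
    ceiling: float = 100.0
    dss_variant: str = "dss1"

    def __post_init__(self) -> None:
        _check(0.0 <= self.activity_threshold < 100.0,
               "activity_threshold must lie in [0, 100)")
        _check(self.dss_variant in ("dss1", "dss2"),
               "dss_variant must be 'dss1' or 'dss2'")


@dataclass
class ClassificationConfig:
    """Responder counting, clustering and multiscale-bootstrap settings."""

    responder_threshold: float = 10.0
    n_clusters: int = 2
    bootstrap_b: int = 10_000
    scales: tuple = tuple(np.round(np.arange(0.5, 1.41, 0.1), 10))
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.responder_threshold > 0,
               "responder_threshold must be > 0")
        _check(self.n_clusters >= 2, "n_clusters must be >= 2")
        _check(self.bootstrap_b >= 1, "bootstrap_b must be >= 1")
        _check(all(r > 0 for r in self.scales),
               "bootstrap scales must be positive")


@dataclass
class SsgseaConfig:
    """Single-sample GSEA settings (rank weight exponent alpha)."""

    alpha: float = 0.75
    normalize: bool = True  # divide ES by (n_genes - n_set_genes)

    def __post_init__(self) -> None:
        _check(self.alpha >= 0, "alpha must be >= 0")


@dataclass
class MethylationConfig:
    """CpG-island aggregation, MGMT and differential-methylation settings.

    ``mgmt_region`` is given in 1-based inclusive coordinates (hg38), the
    convention the region is usually printed in; it is converted internally
    to the 0-based half-open convention of BED/bedMethyl.
    """

    min_site_coverage: int = 5
    dm_alpha: float = 0.05
    mgmt_region: tuple = ("chr10", 129_466_685, 129_467_446)
    mgmt_cutoff: float = 22.0
    test: str = "student"  # or "welch"
    combine_strands: bool = False

    def __post_init__(self) -> None:
        _check(self.min_site_coverage >= 0,
               "min_site_coverage must be >= 0")
        _check(0.0 < self.dm_alpha < 1.0, "dm_alpha must lie in (0, 1)")
        _check(0.0 < self.mgmt_cutoff < 100.0,
               "mgmt_cutoff must lie in (0, 100)")
        _check(self.test in ("student", "welch"),
               "test must be 'student' or 'welch'")
        chrom, s, e = self.mgmt_region
        _check(isinstance(chrom, str) and s <= e,
               "mgmt_region must be (chrom, start, end) 1-based inclusive")

    @property
    def mgmt_region_bed(self) -> tuple:
        """MGMT region as (chrom, start, end), 0-based half-open."""
        chrom, s1, e1 = self.mgmt_region
        return (chrom, s1 - 1, e1)


def config_to_dict(cfg) -> dict:
    """Flatten a dataclass config to a plain JSON-serializable dict."""
    out = {}
    for f in fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out
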