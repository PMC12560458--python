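"""Synthetic multi-modal cohort generator with planted group structure.

Every downstream stage of the pipeline (dose-response scoring, resistance
clustering, expression scoring, methylation analysis) is testable against
this module: it plants a known resistant/sensitive split and returns a
:class:`TruthTable` recording every planted signal.

Noise models (the standard minimal model per modality):

* luminescence wells — multiplicative lognormal noise with a given CV;
* RNA-seq counts — negative binomial via the gamma-Poisson mixture;
* per-CpG-site 5mC fractions — Beta around the island mean with a given
  precision (Beta ``a + b``).

Group structure: a fraction of drugs is active in every culture, a further
fraction only in sensitive cultures, the rest inert; stemness-panel genes
are upregulated (and MES-panel genes shifted up, PN-panel genes down) in
resistant cultures; a fraction of CpG islands receives a planted
between-group methylation difference; an MGMT-like promoter of 98 CpG
sites carries a planted per-sample methylation status.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .config import CohortConfig, ConfigError, stage_rng
from .dose_response import ViabilityScreen, dss_from_curve, logistic4

__all__ = [
    "TruthTable",
    "gen_viability_screen",
    "gen_dss_matrix",
    "gen_expression_matrix",
    "gen_methylome",
    "sample_names",
]

STEMNESS_SET_SIZE = 34  # size of the stemness gene panel
PN_SET_SIZE = 30
MES_SET_SIZE = 30
MGMT_REGION = ("chr10", 129_466_684, 129_467_446)  # 0-based half-open
MGMT_N_SITES = 98


@dataclass
class TruthTable:
    """Planted ground truth of a synthetic cohort.

    ``curves`` maps (sample, drug) to the true 4PL parameters (dict with
    bottom/top/log10_ec50/slope/x1/x2/active); ``dm_islands`` maps island id
    to the signed methylation delta (resistant mean minus sensitive mean, in
    percentage points).
    """

    group_labels: Dict[str, str] = field(default_factory=dict)
    curves: Dict[Tuple[str, str], dict] = field(default_factory=dict)
    drug_category: Dict[str, str] = field(default_factory=dict)
    stemness_genes: List[str] = field(default_factory=list)
    pn_genes: List[str] = field(default_factory=list)
    mes_genes: List[str] = field(default_factory=list)
    dm_islands: Dict[str, float] = field(default_factory=dict)
    island_means: Dict[str, Dict[str, float]] = field(default_factory=dict)
    mgmt_means: Dict[str, float] = field(default_factory=dict)

    def true_dss(self, sample: str, drug: str, t: float = 10.0) -> float:
        """DSS implied by the planted 4PL parameters of one series."""
        c = self.curves[(sample, drug)]
        return dss_from_curve(c["bottom"], c["top"], c["log10_ec50"],
                              c["slope"], c["x1"], c["x2"], t=t)

    def to_json(self, path) -> None:
        payload = {
            "group_labels": self.group_labels,
            "curves": {f"{s}|{d}": v for (s, d), v in self.curves.items()},
            "drug_category": self.drug_category,
            "stemness_genes": self.stemness_genes,
            "pn_genes": self.pn_genes,
            "mes_genes": self.mes_genes,
            "dm_islands": self.dm_islands,
            "island_means": self.island_means,
            "mgmt_means": self.mgmt_means,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def sample_names(config: CohortConfig) -> Tuple[List[str], Dict[str, str]]:
    """Deterministic sample ids and their planted group labels."""
    sens = [f"GSC-S{i + 1:02d}" for i in range(config.n_sensitive)]
    res = [f"GSC-R{i + 1:02d}" for i in range(config.n_resistant)]
    labels = {s: "sensitive" for s in sens}
    labels.update({s: "resistant" for s in res})
    return sens + res, labels


def _plant_drug_truth(config: CohortConfig, rng: np.random.Generator,
                      truth: TruthTable) -> Tuple[List[str], np.ndarray]:
    """Plant per-drug dose grids, activity categories and 4PL curves."""
    samples, labels = sample_names(config)
    truth.group_labels = labels
    n_drugs = config.n_drugs
    drugs = [f"D{i + 1:04d}" for i in range(n_drugs)]

    log_cmin = rng.uniform(-3.0, 0.0, size=n_drugs)
    span = config.dose_step_log10 * (config.doses_per_drug - 1)
    fr = config.frac_active_drugs_resistant
    fs = config.frac_active_drugs_sensitive
    u = rng.uniform(size=n_drugs)
    cats = np.where(u < fr, "active_all",
                    np.where(u < fs, "active_sensitive_only", "inactive"))
    truth.drug_category = dict(zip(drugs, cats))

    for sample in samples:
        for j, drug in enumerate(drugs):
            x1 = float(log_cmin[j])
            x2 = x1 + span
            cat = cats[j]
            active = (cat == "active_all"
                      or (cat == "active_sensitive_only"
                          and labels[sample] == "sensitive"))
            if active:
                top = float(rng.uniform(60.0, 100.0))
                slope = float(rng.uniform(0.7, 2.0))
                # keep the transition inside the tested window so the
                # curve is identifiable from the 5-point series
                m = float(rng.uniform(x1 + 0.25 * span, x2 - 0.25 * span))
            else:
                # consume the same number of draws to keep per-series
                # streams aligned across activity patterns
                _ = rng.uniform(size=3)
                top, slope, m = 0.0, 1.0, 0.5 * (x1 + x2)
            truth.curves[(sample, drug)] = {
                "bottom": 0.0, "top": top, "log10_ec50": m,
                "slope": slope, "x1": x1, "x2": x2, "active": bool(active),
            }
    return drugs, log_cmin


def _noise_factors(rng: np.random.Generator, cv: float,
                   size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise; exact ones at cv = 0."""
    if cv == 0.0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def gen_viability_screen(
        config: CohortConfig) -> Tuple[List[ViabilityScreen], TruthTable]:
    """Generate per-sample raw drug screens with planted 4PL truth.

    Each sample gets one well per (drug, dose) plus shared negative (DMSO)
    and positive control wells; the raw signal interpolates between the
    control means according to the planted inhibition curve, times
    lognormal noise with CV ``viability_cv``.
    """
    rng = stage_rng(config.seed, "viability")
    truth = TruthTable()
    drugs, _ = _plant_drug_truth(config, rng, truth)
    samples = list(truth.group_labels)
    neg, pos = config.neg_ctrl_mean, config.pos_ctrl_mean

    screens = []
    for sample in samples:
        rows = []
        for kind, mean in (("neg_ctrl", neg), ("pos_ctrl", pos)):
            f = _noise_factors(rng, config.viability_cv,
                               config.n_ctrl_wells)
            for w in range(config.n_ctrl_wells):
                rows.append((None, w, np.nan, mean * f[w], kind))
        for drug in drugs:
            if (config.missing_fraction > 0.0
                    and rng.uniform() < config.missing_fraction):
                continue
            c = truth.curves[(sample, drug)]
            x = c["x1"] + config.dose_step_log10 * np.arange(
                config.doses_per_drug)
            y = logistic4(x, c["bottom"], c["top"], c["log10_ec50"],
                          c["slope"])
            signal = (neg - (neg - pos) * y / 100.0) * _noise_factors(
                rng, config.viability_cv, config.doses_per_drug)
            for k in range(config.doses_per_drug):
                rows.append((drug, k, 10.0 ** x[k], signal[k], "drug"))
        wells = pd.DataFrame(
            rows, columns=["drug", "dose_index", "concentration",
                           "signal", "well_type"])
        screens.append(ViabilityScreen(sample=sample, wells=wells))
    return screens, truth


def gen_dss_matrix(config: CohortConfig,
                   t: float = 10.0) -> Tuple[pd.DataFrame, TruthTable]:
    """DSS matrix computed from planted 4PL truth plus DSS-scale jitter.

    A fast alternative to generating raw wells and re-fitting every curve:
    the true-curve DSS is perturbed with Gaussian noise of sd
    ``config.dss_noise_sd`` (clipped to [0, 100]). Missing entries are
    injected at rate ``config.missing_fraction``.
    """
    rng = stage_rng(config.seed, "dss-matrix")
    truth = TruthTable()
    drugs, _ = _plant_drug_truth(config, rng, truth)
    samples = list(truth.group_labels)
    mat = pd.DataFrame(index=pd.Index(drugs, name="drug"),
                       columns=samples, dtype=float)
    for sample in samples:
        for drug in drugs:
            if (config.missing_fraction > 0.0
                    and rng.uniform() < config.missing_fraction):
                continue
            val = truth.true_dss(sample, drug, t=t)
            if config.dss_noise_sd > 0:
                val += rng.normal(0.0, config.dss_noise_sd)
            mat.loc[drug, sample] = min(max(val, 0.0), 100.0)
    return mat, truth


def gen_expression_matrix(
        config: CohortConfig
) -> Tuple[pd.DataFrame, Dict[str, List[str]], TruthTable]:
    """Negative-binomial RNA-seq counts with planted group shifts.

    Stemness-panel genes are shifted by ``stemness_log2fc`` in resistant
    samples; MES-panel genes likewise up in resistant, PN-panel genes up in
    sensitive samples. Returns (counts genes x samples, gene sets, truth).
    """
    need = STEMNESS_SET_SIZE + PN_SET_SIZE + MES_SET_SIZE
    if config.n_genes < need:
        raise ConfigError(
            f"n_genes must be >= {need} to host the planted gene panels")
    rng = stage_rng(config.seed, "expression")
    truth = TruthTable()
    _, labels = sample_names(config)
    truth.group_labels = labels
    samples = list(labels)

    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    stem = genes[:STEMNESS_SET_SIZE]
    pn = genes[STEMNESS_SET_SIZE:STEMNESS_SET_SIZE + PN_SET_SIZE]
    mes = genes[STEMNESS_SET_SIZE + PN_SET_SIZE:need]
    truth.stemness_genes, truth.pn_genes, truth.mes_genes = stem, pn, mes

    base = rng.lognormal(mean=3.0, sigma=1.2, size=config.n_genes)
    fc = 2.0 ** config.stemness_log2fc
    mu = np.tile(base[:, None], (1, len(samples)))
    is_res = np.array([labels[s] == "resistant" for s in samples])
    stem_idx = np.arange(STEMNESS_SET_SIZE)
    pn_idx = np.arange(STEMNESS_SET_SIZE, STEMNESS_SET_SIZE + PN_SET_SIZE)
    mes_idx = np.arange(STEMNESS_SET_SIZE + PN_SET_SIZE, need)
    mu[np.ix_(stem_idx, np.where(is_res)[0])] *= fc
    mu[np.ix_(mes_idx, np.where(is_res)[0])] *= fc
    mu[np.ix_(pn_idx, np.where(~is_res)[0])] *= fc

    if config.nb_dispersion == 0.0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape=shape, scale=mu / shape)
        counts = rng.poisson(lam)
    expr = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                        columns=samples)
    gene_sets = {"STEMNESS": stem, "PN": pn, "MES": mes}
    return expr, gene_sets, truth


def gen_methylome(
        config: CohortConfig
) -> Tuple[pd.DataFrame, Dict[str, pd.DataFrame], TruthTable]:
    """Synthetic CpG-island reference and per-sample site-level methylomes.

    Islands are placed without overlap on a synthetic chromosome ``chrS``
    (5-100 CpG sites each, one site per dinucleotide position); an
    MGMT-like promoter of 98 sites is emitted on ``chr10`` at the hg38 MGMT
    coordinates so the MGMT classifier runs unchanged on synthetic data.

    Returns (islands BED-like frame, {sample: site records}, truth). Site
    record columns: chrom, start, end, strand, coverage, percent.
    """
    rng = stage_rng(config.seed, "methylome")
    truth = TruthTable()
    _, labels = sample_names(config)
    truth.group_labels = labels
    samples = list(labels)

    n_isl = config.n_islands
    n_sites = rng.integers(5, 101, size=n_isl)
    gap = 200
    lengths = 2 * n_sites
    if int(np.sum(lengths + gap)) > config.chrom_length:
        raise ConfigError(
            "island count incompatible with chromosome length "
            f"({n_isl} islands need > {config.chrom_length} bp)")
    starts = np.concatenate([[1000], 1000 + np.cumsum(lengths + gap)[:-1]])
    ends = starts + lengths
    ids = [f"CGI{i + 1:05d}" for i in range(n_isl)]
    islands = pd.DataFrame({
        "chrom": "chrS", "start": starts.astype(int),
        "end": ends.astype(int), "island_id": ids})

    # island-level group means (%)
    sd = 15.0
    base = np.clip(rng.normal(config.mean_island_methylation, sd, n_isl),
                   2.0, 98.0)
    n_dm = int(round(config.dm_island_fraction * n_isl))
    dm_idx = rng.choice(n_isl, size=n_dm, replace=False) if n_dm else []
    signs = rng.choice([-1.0, 1.0], size=n_dm)
    mean_res = base.copy()
    mean_sen = base.copy()
    for k, i in enumerate(np.atleast_1d(dm_idx)):
        b = float(np.clip(base[i], 20.0, 60.0))
        mean_res[i] = b + signs[k] * config.dm_delta / 2.0
        mean_sen[i] = b - signs[k] * config.dm_delta / 2.0
        truth.dm_islands[ids[i]] = float(mean_res[i] - mean_sen[i])
    for i in range(n_isl):
        truth.island_means[ids[i]] = {
            "resistant": float(mean_res[i]), "sensitive": float(mean_sen[i])}

    # MGMT-like promoter: 98 evenly spaced sites at the hg38 coordinates
    chrom_m, s0, e0 = MGMT_REGION
    mgmt_pos = np.unique(
        np.linspace(s0, e0 - 1, MGMT_N_SITES).round().astype(int))
    mgmt_state = rng.uniform(size=len(samples)) < 0.5
    for s, methylated in zip(samples, mgmt_state):
        truth.mgmt_means[s] = (config.mgmt_mean_methylated if methylated
                               else config.mgmt_mean_unmethylated)

    prec = config.meth_beta_precision
    records: Dict[str, pd.DataFrame] = {}
    for sample in samples:
        grp = labels[sample]
        positions, percents = [], []
        chroms = []
        for i in range(n_isl):
            mean = (mean_res[i] if grp == "resistant" else mean_sen[i])
            pos = starts[i] + 2 * np.arange(n_sites[i])
            pct = _beta_percent(rng, mean, prec, n_sites[i])
            positions.append(pos)
            percents.append(pct)
            chroms.append(np.full(n_sites[i], "chrS", dtype=object))
        # MGMT-like region
        pct_m = _beta_percent(rng, truth.mgmt_means[sample], prec,
                              len(mgmt_pos))
        positions.append(mgmt_pos)
        percents.append(pct_m)
        chroms.append(np.full(len(mgmt_pos), chrom_m, dtype=object))

        pos_all = np.concatenate(positions)
        pct_all = np.concatenate(percents)
        chrom_all = np.concatenate(chroms)
        cov = np.maximum(config.coverage_floor,
                         rng.poisson(config.coverage_mean,
                                     size=pos_all.size))
        records[sample] = pd.DataFrame({
            "chrom": chrom_all,
            "start": pos_all.astype(int),
            "end": pos_all.astype(int) + 1,
            "strand": "+",
            "coverage": cov.astype(int),
            "percent": pct_all,
        })
    return islands, records, truth


def _beta_percent(rng: np.random.Generator, mean_pct: float,
                  precision: float, n: int) -> np.ndarray:
    """Per-site 5mC percentages: Beta(mean*prec, (1-mean)*prec) * 100.

    An infinite precision degenerates to every site equalling the island
    mean exactly.
    """
    p = min(max(mean_pct / 100.0, 0.0), 1.0)
    if not np.isfinite(precision):
        return np.full(n, 100.0 * p)
    if p == 0.0 or p == 1.0:
        return np.full(n, 100.0 * p)
    return 100.0 * rng.beta(p * precision, (1.0 - p) * precision, size=n)
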