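"""CpG-island methylation analysis from bedMethyl site records.

Per-CpG-site 5mC calls (the tabular output of nanopore modified-base
pipelines) are depth-filtered, aggregated into CpG-island mean methylation
(unweighted mean over sites falling in each island, both strands pooled),
classified for MGMT promoter status (mean over the 98-CpG hg38 promoter
window, methylated when strictly above 22%), tested per island for
differential methylation between resistant and sensitive groups
(two-sample t-test at raw p < alpha, no multiplicity correction — a BH
column is emitted for information only), and linked to inversely changed
expression of the associated genes.

Coordinate conventions: islands follow BED (0-based half-open); the MGMT
region is configured in the 1-based inclusive coordinates it is printed in
and converted internally.
"""

from __future__ import annotations

import warnings
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr, ttest_ind

from .config import MethylationConfig

__all__ = [
    "read_bedmethyl",
    "filter_depth",
    "island_methylation",
    "mgmt_status",
    "differential_islands",
    "link_expression",
    "derive_island_gene_map",
    "combine_strands",
]

SITE_COLUMNS = ["chrom", "start", "end", "strand", "coverage", "percent"]


class BedMethylError(ValueError):
    """Unparseable bedMethyl input."""


def read_bedmethyl(path, mod_code: str = "m") -> pd.DataFrame:
    """Parse a bedMethyl file into site records.

    Expects >= 11 tab-separated columns (modkit dialect): column 4 the
    modification code, column 10 the valid coverage, column 11 the percent
    modified. Only records with the requested modification code (default
    5mC, "m") are kept. Malformed lines are counted (reported in
    ``result.attrs["n_malformed"]``); more than 10% malformed lines raise.
    """
    rows = []
    n_bad = 0
    n_total = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            n_total += 1
            parts = line.split("\t")
            if len(parts) < 11:
                n_bad += 1
                continue
            try:
                chrom = parts[0]
                start = int(parts[1])
                strand = parts[5]
                cov = int(parts[9])
                pct = float(parts[10])
            except ValueError:
                n_bad += 1
                continue
            if parts[3] != mod_code:
                continue
            rows.append((chrom, start, start + 1, strand, cov, pct))
    if n_total and n_bad / n_total > 0.10:
        raise BedMethylError(
            f"{path}: {n_bad}/{n_total} malformed lines (> 10%)")
    out = pd.DataFrame(rows, columns=SITE_COLUMNS)
    out.attrs["n_malformed"] = n_bad
    return out


def filter_depth(records: pd.DataFrame,
                 cfg: MethylationConfig | None = None) -> pd.DataFrame:
    """Keep sites with valid coverage >= the configured floor (inclusive)."""
    cfg = cfg or MethylationConfig()
    keep = records["coverage"] >= cfg.min_site_coverage
    out = records.loc[keep].reset_index(drop=True)
    out.attrs["n_dropped"] = int((~keep).sum())
    return out


def combine_strands(records: pd.DataFrame) -> pd.DataFrame:
    """Merge +/- records of the same CpG dinucleotide.

    The minus-strand cytosine of a CpG sits one base downstream of the
    plus-strand one; records are pooled by the plus-strand position with a
    coverage-weighted mean percentage.
    """
    rec = records.copy()
    pos = np.where(rec["strand"] == "-", rec["start"] - 1, rec["start"])
    rec["_pos"] = pos
    grp = rec.groupby(["chrom", "_pos"], sort=True)
    cov = grp["coverage"].sum()
    pct = grp.apply(
        lambda g: float(np.average(g["percent"], weights=g["coverage"]))
        if g["coverage"].sum() > 0 else float(g["percent"].mean()),
        include_groups=False)
    out = pd.DataFrame({
        "chrom": [c for c, _ in cov.index],
        "start": [p for _, p in cov.index],
        "strand": "+",
        "coverage": cov.to_numpy(),
        "percent": pct.to_numpy(),
    })
    out["end"] = out["start"] + 1
    return out[SITE_COLUMNS].reset_index(drop=True)


def _island_means_one(records: pd.DataFrame,
                      islands: pd.DataFrame) -> pd.DataFrame:
    """(mean percent, n sites) per island for one sample's records."""
    means = np.full(len(islands), np.nan)
    counts = np.zeros(len(islands), dtype=int)
    for chrom, isl in islands.groupby("chrom", sort=False):
        sub = records[records["chrom"] == chrom]
        if sub.empty:
            continue
        starts = isl["start"].to_numpy()
        ends = isl["end"].to_numpy()
        order = np.argsort(starts, kind="mergesort")
        starts_s, ends_s = starts[order], ends[order]
        pos = sub["start"].to_numpy()
        pct = sub["percent"].to_numpy(dtype=float)
        idx = np.searchsorted(starts_s, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends_s[np.clip(idx, 0, None)])
        if not ok.any():
            continue
        tgt = isl.index.to_numpy()[order][idx[ok]]
        df = pd.DataFrame({"i": tgt, "p": pct[ok]})
        agg = df.groupby("i")["p"].agg(["mean", "count"])
        means[agg.index.to_numpy()] = agg["mean"].to_numpy()
        counts[agg.index.to_numpy()] = agg["count"].to_numpy()
    return pd.DataFrame({"mean": means, "n_sites": counts},
                        index=islands["island_id"].to_numpy())


def island_methylation(records: Mapping[str, pd.DataFrame],
                       islands: pd.DataFrame,
                       cfg: MethylationConfig | None = None):
    """Islands x samples matrix of mean methylation percentages.

    ``records`` maps sample id to site records (apply
    :func:`filter_depth` beforehand if depth filtering is wanted). Site
    membership is by half-open interval overlap on the same chromosome,
    both strands pooled; each island value is the unweighted mean of its
    sites' percentages. Islands with zero covered sites in a sample are
    missing. Returns (matrix, contributing-site-count matrix).
    """
    _validate_islands(islands)
    cols_mean = {}
    cols_n = {}
    for sample, rec in records.items():
        res = _island_means_one(rec, islands.reset_index(drop=True))
        cols_mean[sample] = res["mean"]
        cols_n[sample] = res["n_sites"]
    mat = pd.DataFrame(cols_mean)
    nmat = pd.DataFrame(cols_n)
    mat.index.name = "island_id"
    nmat.index.name = "island_id"
    n_empty = int(mat.isna().sum().sum())
    if n_empty:
        warnings.warn(
            f"{n_empty} island x sample entr(ies) have no covered sites",
            stacklevel=2)
    return mat, nmat


def _validate_islands(islands: pd.DataFrame) -> None:
    if (islands["start"] >= islands["end"]).any():
        raise ValueError("island with start >= end")
    for _, isl in islands.groupby("chrom"):
        s = isl.sort_values("start")
        if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
            warnings.warn("overlapping islands in the reference",
                          stacklevel=3)


def mgmt_status(records: pd.DataFrame,
                cfg: MethylationConfig | None = None) -> dict:
    """MGMT promoter methylation call for one sample.

    Mean percent over the CpG sites inside the configured promoter window
    (1-based inclusive bounds, converted to 0-based half-open); methylated
    when the mean is strictly above the cutoff (default 22%). Zero sites
    in the window yield status "undetermined".
    """
    cfg = cfg or MethylationConfig()
    chrom, s0, e0 = cfg.mgmt_region_bed
    sel = records[(records["chrom"] == chrom)
                  & (records["start"] >= s0)
                  & (records["start"] < e0)]
    if sel.empty:
        return {"mean_percent": float("nan"), "n_sites": 0,
                "status": "undetermined"}
    mean = float(sel["percent"].mean())
    status = "methylated" if mean > cfg.mgmt_cutoff else "unmethylated"
    return {"mean_percent": mean, "n_sites": int(len(sel)),
            "status": status}


def differential_islands(matrix: pd.DataFrame, labels: pd.DataFrame,
                         cfg: MethylationConfig | None = None
                         ) -> pd.DataFrame:
    """Per-island two-sample t-test between resistant and sensitive groups.

    Student's equal-variance test by default (Welch selectable via
    ``cfg.test``). Islands lacking >= 2 non-missing values per group are
    skipped with a warning. Raw p-values are compared against
    ``cfg.dm_alpha`` (no multiplicity correction, the convention for this
    analysis); a BH column is appended for information only. Direction is
    reported relative to the resistant group.
    """
    cfg = cfg or MethylationConfig()
    groups = labels["group"].reindex(matrix.columns)
    res_cols = groups[groups == "resistant"].index
    sen_cols = groups[groups == "sensitive"].index
    if len(res_cols) < 2 or len(sen_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    A = matrix[res_cols].to_numpy(dtype=float)
    B = matrix[sen_cols].to_numpy(dtype=float)
    ok = (np.isfinite(A).sum(axis=1) >= 2) & (np.isfinite(B).sum(axis=1) >= 2)
    if (~ok).any():
        warnings.warn(
            f"skipping {int((~ok).sum())} island(s) with < 2 values per "
            "group", stacklevel=2)
    A, B = A[ok], B[ok]
    idx = matrix.index[ok]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = ttest_ind(A, B, axis=1, equal_var=(cfg.test == "student"),
                         nan_policy="omit")
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    mean_r = np.nanmean(A, axis=1)
    mean_s = np.nanmean(B, axis=1)
    # zero variance in both groups: p = 1 on equal means, else certain
    var0 = (np.nanvar(A, axis=1) == 0.0) & (np.nanvar(B, axis=1) == 0.0)
    eq = var0 & (mean_r == mean_s)
    ne = var0 & (mean_r != mean_s)
    t[eq], p[eq] = 0.0, 1.0
    t[ne], p[ne] = np.inf * np.sign(mean_r - mean_s)[ne], 0.0
    out = pd.DataFrame({
        "mean_resistant": mean_r,
        "mean_sensitive": mean_s,
        "t": t,
        "pvalue": p,
        "direction": np.where(mean_r < mean_s, "hypo", "hyper"),
        "significant": p < cfg.dm_alpha,
    }, index=idx)
    out.index.name = "island_id"
    if len(out):
        from statsmodels.stats.multitest import multipletests
        out["p_adj_bh"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def link_expression(dm: pd.DataFrame,
                    island_gene_map: Mapping[str, str],
                    norm_expr: pd.DataFrame,
                    labels: pd.DataFrame,
                    matrix: pd.DataFrame | None = None,
                    significant_only: bool = True) -> pd.DataFrame:
    """Link differentially methylated islands to inverse expression change.

    An island is linked when the sign of its between-group methylation
    difference (resistant minus sensitive) is opposite to the sign of its
    associated gene's expression difference; a regulatory relationship in
    the classical promoter-methylation sense. When the island methylation
    ``matrix`` is passed, the per-island Spearman correlation of
    methylation vs expression across samples is reported alongside.
    Unmapped islands are skipped, with the count in ``result.attrs``.
    """
    groups = labels["group"].reindex(norm_expr.columns)
    res_cols = groups[groups == "resistant"].index
    sen_cols = groups[groups == "sensitive"].index
    sub = dm[dm["significant"]] if significant_only else dm
    rows = []
    n_unmapped = 0
    for island, rec in sub.iterrows():
        gene = island_gene_map.get(island)
        if gene is None or gene not in norm_expr.index:
            n_unmapped += 1
            continue
        d_meth = rec["mean_resistant"] - rec["mean_sensitive"]
        d_expr = (norm_expr.loc[gene, res_cols].mean()
                  - norm_expr.loc[gene, sen_cols].mean())
        linked = bool(np.sign(d_meth) * np.sign(d_expr) < 0)
        rho = np.nan
        if matrix is not None and island in matrix.index:
            shared = [c for c in matrix.columns if c in norm_expr.columns]
            rho, _ = spearmanr(matrix.loc[island, shared],
                               norm_expr.loc[gene, shared])
        rows.append((island, gene, d_meth, d_expr, linked, rho))
    out = pd.DataFrame(
        rows, columns=["island_id", "gene", "delta_methylation",
                       "delta_expression", "linked",
                       "spearman_rho"]).set_index("island_id")
    out.attrs["n_unmapped"] = n_unmapped
    if n_unmapped:
        warnings.warn(f"{n_unmapped} island(s) without a mapped gene "
                      "skipped", stacklevel=2)
    return out


def derive_island_gene_map(islands: pd.DataFrame, tss: pd.DataFrame,
                           window: int = 2000) -> Dict[str, str]:
    """Map each island to a gene whose TSS falls in it or within ``window``.

    ``tss`` columns: gene, chrom, pos (0-based). When several genes
    qualify, the one with the TSS closest to the island midpoint wins; the
    2 kb default window is a pragmatic convention, not a biological claim.
    """
    out: Dict[str, str] = {}
    for _, isl in islands.iterrows():
        cand = tss[(tss["chrom"] == isl["chrom"])
                   & (tss["pos"] >= isl["start"] - window)
                   & (tss["pos"] < isl["end"] + window)]
        if cand.empty:
            continue
        mid = 0.5 * (isl["start"] + isl["end"])
        out[isl["island_id"]] = cand.iloc[
            (cand["pos"] - mid).abs().argmin()]["gene"]
    return out
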