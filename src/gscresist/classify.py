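"""Resistance classification from DSS matrices.

Cultures are ranked by responder counts (number of drugs with DSS above a
threshold, default 10), the DSS matrix is restricted to drugs screened in
every culture and centered per drug against the cohort mean, cultures are
clustered by Ward.D2 agglomeration on Euclidean distances, and cluster
stability is quantified with the multiscale bootstrap (approximately
unbiased AU p-values alongside naive bootstrap probabilities BP).

The cluster with the lower mean responder count is labeled "resistant" —
a deterministic stand-in for labeling by inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import norm

from .config import ClassificationConfig, stage_rng

__all__ = [
    "WelchResult",
    "ClusterStability",
    "count_responders",
    "normalize_dss",
    "restrict_common",
    "cluster_cultures",
    "multiscale_bootstrap",
    "fit_au_from_bp",
    "compare_counts",
    "linkage_to_newick",
]


@dataclass
class WelchResult:
    statistic: float
    df: float
    pvalue: float


@dataclass
class ClusterStability:
    """Per-cluster multiscale-bootstrap stability.

    ``clusters`` entries carry: members (tuple of sample ids), bp (naive
    bootstrap probability at scale 1), au (approximately unbiased
    p-value), bp_per_scale (dict scale -> bootstrap probability).
    """

    b: int
    scales: tuple
    clusters: List[dict] = field(default_factory=list)


def count_responders(dss: pd.DataFrame,
                     threshold: float = 10.0) -> pd.DataFrame:
    """Per-sample count of drugs with DSS >= threshold, ranked descending.

    Missing entries never count. Ties in the ranking are broken by
    lexicographic sample id (stable, documented).
    """
    if dss.empty:
        raise ValueError("empty DSS matrix")
    counts = (dss >= threshold).sum(axis=0).astype(int)
    out = pd.DataFrame({"responder_count": counts})
    out = out.sort_values(["responder_count"],
                          ascending=False, kind="mergesort")
    # secondary lexicographic tie-break
    out = (out.reset_index().rename(columns={"index": "sample"})
           .sort_values(["responder_count", "sample"],
                        ascending=[False, True], kind="mergesort")
           .set_index("sample"))
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def restrict_common(dss: pd.DataFrame,
                    samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Keep only drugs with a non-missing DSS in every listed sample."""
    cols = list(samples) if samples is not None else list(dss.columns)
    if not cols:
        raise ValueError("empty sample subset")
    sub = dss[cols]
    keep = sub.notna().all(axis=1)
    if not keep.any():
        raise ValueError("no drug was screened in every listed sample")
    return sub.loc[keep]


def normalize_dss(dss: pd.DataFrame) -> pd.DataFrame:
    """Center each drug (row) on its cohort mean.

    The conventional pre-clustering transform of "normalizing to the
    average DSS per drug": subtraction of the per-drug mean across
    samples. Rows that are entirely missing are dropped with a warning.
    """
    all_missing = dss.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} drug(s) with no DSS values",
            stacklevel=2)
        dss = dss.loc[~all_missing]
    return dss.sub(dss.mean(axis=1, skipna=True), axis=0)


def cluster_cultures(centered: pd.DataFrame,
                     responder_counts: pd.DataFrame,
                     n_clusters: int = 2):
    """Ward.D2 clustering of sample columns; labels resistant/sensitive.

    Returns (scipy linkage matrix, labels frame with columns group,
    cluster, responder_count). The cluster with the lower mean responder
    count is "resistant". Requires a complete matrix (use
    :func:`restrict_common` first).
    """
    if centered.isna().any().any():
        raise ValueError("missing values present; run restrict_common first")
    samples = list(centered.columns)
    if len(samples) < n_clusters:
        raise ValueError(
            f"need >= {n_clusters} samples, got {len(samples)}")
    X = centered.to_numpy(dtype=float).T  # samples x drugs
    Z = linkage(X, method="ward", metric="euclidean")
    assign = fcluster(Z, t=n_clusters, criterion="maxclust")
    labels = pd.DataFrame(index=pd.Index(samples, name="sample"))
    labels["cluster"] = assign
    counts = responder_counts["responder_count"].reindex(samples)
    mean_counts = counts.groupby(labels["cluster"]).mean()
    order = mean_counts.sort_values(kind="mergesort").index
    name_of = {order[0]: "resistant"}
    for c in order[1:]:
        name_of[c] = "sensitive"
    labels["group"] = labels["cluster"].map(name_of)
    labels["responder_count"] = counts
    labels["provenance"] = "clustered"
    return Z, labels


def _clades(Z: np.ndarray, n: int) -> set:
    """All clades (as frozensets of leaf indices) of a linkage matrix."""
    sets: Dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = set()
    for k in range(Z.shape[0]):
        a, b = int(Z[k, 0]), int(Z[k, 1])
        merged = sets[a] | sets[b]
        sets[n + k] = merged
        out.add(merged)
    return out


def fit_au_from_bp(scales: Sequence[float], bps: Sequence[float],
                   b: int) -> dict:
    """Fit the multiscale-bootstrap model and return AU.

    Transforms bootstrap probabilities at each scale r to normal quantiles
    z_r = Phi^-1(1 - BP_r) and fits psi(r) = v*sqrt(r) + c/sqrt(r) by
    weighted least squares (binomial weights); AU = 1 - Phi(v - c).

    Degenerate cases: BP constant across scales corresponds to the c = 0
    model, under which AU and BP coincide, so the constant value is
    returned directly; all-zero BP yields AU = 0 with a warning; scales
    with saturated BP (exactly 0 or 1, where the normal quantile is
    infinite) are excluded from the fit, and when fewer than three
    informative scales remain the BP at (or nearest) scale 1 is returned.
    """
    r = np.asarray(scales, dtype=float)
    bp = np.asarray(bps, dtype=float)
    if np.all(bp <= 0.0):
        warnings.warn("cluster never reproduced at any scale; AU = 0",
                      stacklevel=2)
        return {"au": 0.0, "v": np.inf, "c": 0.0}
    if np.ptp(bp) < 1e-12:
        # constant BP: no curvature term (c = 0), AU == BP identically
        return {"au": float(bp[0]), "v": np.nan, "c": 0.0}
    usable = (bp > 0.0) & (bp < 1.0)
    if usable.sum() < 3:
        near1 = int(np.argmin(np.abs(r - 1.0)))
        return {"au": float(bp[near1]), "v": np.nan, "c": 0.0}
    r, bpc = r[usable], bp[usable]
    z = norm.ppf(1.0 - bpc)
    w = b * norm.pdf(z) ** 2 / (bpc * (1.0 - bpc))
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    WX = X * w[:, None]
    beta, *_ = np.linalg.lstsq(X.T @ WX, X.T @ (w * z), rcond=None)
    v, c = float(beta[0]), float(beta[1])
    au = float(1.0 - norm.cdf(v - c))
    return {"au": au, "v": v, "c": c}


def multiscale_bootstrap(centered: pd.DataFrame,
                         cfg: ClassificationConfig) -> ClusterStability:
    """AU/BP stability of the reference clusters by multiscale bootstrap.

    For each scale r, drugs (rows) are resampled with replacement to size
    round(r * n_drugs), the cultures are re-clustered, and the fraction of
    replicates in which each reference cluster reappears as a clade is
    recorded (BP_r); the AU p-value is obtained from the scale trend (see
    :func:`fit_au_from_bp`). Fully seeded and reproducible.
    """
    counts = count_responders(centered.fillna(-np.inf),
                              threshold=cfg.responder_threshold)
    Z_ref, labels = cluster_cultures(centered, counts, cfg.n_clusters)
    samples = list(centered.columns)
    idx_of = {s: i for i, s in enumerate(samples)}
    refs = []
    for _, grp in labels.groupby("cluster"):
        refs.append(frozenset(idx_of[s] for s in grp.index))
    rng = stage_rng(cfg.seed, "multiscale-bootstrap")
    X = centered.to_numpy(dtype=float)
    n_drugs = X.shape[0]
    hits = np.zeros((len(refs), len(cfg.scales)), dtype=np.int64)
    for si, r in enumerate(cfg.scales):
        m = max(1, int(round(r * n_drugs)))
        for _ in range(cfg.bootstrap_b):
            rows = rng.integers(0, n_drugs, size=m)
            Xb = X[rows].T  # samples x resampled drugs
            Zb = linkage(Xb, method="ward", metric="euclidean")
            clades = _clades(Zb, len(samples))
            for ci, ref in enumerate(refs):
                if len(ref) == 1 or len(ref) == len(samples) or ref in clades:
                    hits[ci, si] += 1
    stab = ClusterStability(b=cfg.bootstrap_b, scales=tuple(cfg.scales))
    scale1 = (list(cfg.scales).index(1.0)
              if 1.0 in cfg.scales else len(cfg.scales) // 2)
    for ci, ref in enumerate(refs):
        bps = hits[ci] / cfg.bootstrap_b
        fit = fit_au_from_bp(cfg.scales, bps, cfg.bootstrap_b)
        stab.clusters.append({
            "members": tuple(sorted(samples[i] for i in ref)),
            "bp": float(bps[scale1]),
            "au": fit["au"],
            "bp_per_scale": {float(r): float(p)
                             for r, p in zip(cfg.scales, bps)},
        })
    return stab


def compare_counts(counts: pd.DataFrame,
                   labels: pd.DataFrame) -> WelchResult:
    """Welch two-sample t-test of responder counts between the groups."""
    merged = counts.join(labels[["group"]], how="inner")
    groups = [g["responder_count"].to_numpy(dtype=float)
              for _, g in merged.groupby("group")]
    if len(groups) != 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need two groups with >= 2 samples each")
    a, b = groups
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(na + nb - 2), 1.0)
        return WelchResult(np.inf, float(na + nb - 2), 0.0)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    from scipy.stats import t as tdist
    p = 2.0 * tdist.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


def linkage_to_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(leaf_names)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: leaf_names[i] for i in range(n)}
    for k in range(Z.shape[0]):
        a, b, h = int(Z[k, 0]), int(Z[k, 1]), float(Z[k, 2])
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h
    return nodes[n + Z.shape[0] - 1] + ";"
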