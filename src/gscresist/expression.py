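"""Expression scoring: stemness set scores, ssGSEA subtyping, ORA.

The stemness set score summarizes a gene panel per group as the sum over
panel genes of the group-mean rank-normalized z-score (genes are ranked
across samples, ranks standardized to mean 0 / sd 1). Proneural (PN) vs
mesenchymal (MES) subtype calls come from paired single-sample GSEA
enrichment scores; over-representation of differentially expressed gene
lists is tested with the hypergeometric upper tail and Benjamini-Hochberg
adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata
from statsmodels.stats.multitest import multipletests

from .config import SsgseaConfig
from .classify import WelchResult, compare_counts

__all__ = [
    "SetScoreResult",
    "normalize_expression",
    "gene_zscores",
    "set_score",
    "ssgsea_score",
    "classify_subtype",
    "ora_hypergeometric",
]


@dataclass
class SetScoreResult:
    """Group-level gene-set score with its Welch contrast.

    ``per_sample`` holds each sample's mean z over the set genes;
    ``group_scores`` maps group -> sum over set genes of the group-mean z.
    """

    genes_used: list
    per_sample: pd.Series
    group_scores: Dict[str, float]
    welch: WelchResult


def normalize_expression(expr: pd.DataFrame,
                         mode: str = "log2cpm") -> pd.DataFrame:
    """Normalize a counts matrix; default log2(CPM + 1).

    A simple variance stabilizer adequate for the rank-based scores
    downstream. The chosen mode is recorded in ``result.attrs``. A
    ``mode="none"`` passthrough flags pre-normalized input.
    """
    if mode == "none":
        out = expr.astype(float).copy()
        out.attrs["normalization"] = "none"
        return out
    if mode != "log2cpm":
        raise ValueError(f"unknown normalization mode {mode!r}")
    if (expr.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    lib = expr.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(
            f"zero library size in sample(s): {list(zero.index)}")
    cpm = expr.div(lib, axis=1) * 1e6
    out = np.log2(cpm + 1.0)
    out.attrs["normalization"] = "log2cpm"
    return out


def gene_zscores(norm_expr: pd.DataFrame) -> pd.DataFrame:
    """Rank-normalized z-scores per gene across samples.

    Each gene's values are replaced by their ranks across samples (average
    ranks on ties) and the ranks standardized to mean 0, sd 1 (sample sd).
    Constant genes yield an all-zero row with a warning.
    """
    if norm_expr.shape[1] < 2:
        raise ValueError("need >= 2 samples for rank z-scores")
    vals = norm_expr.to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 1, vals)
    mean = ranks.mean(axis=1, keepdims=True)
    sd = ranks.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0.0)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s) assigned all-zero "
            "z-scores", stacklevel=2)
    sd[sd == 0.0] = 1.0
    z = (ranks - mean) / sd
    z[constant, :] = 0.0
    return pd.DataFrame(z, index=norm_expr.index,
                        columns=norm_expr.columns)


def set_score(z: pd.DataFrame, geneset: Sequence[str],
              labels: pd.DataFrame) -> SetScoreResult:
    """Group stemness-style set score over a gene panel.

    Per group: sum over panel genes of the group-mean z-score. The group
    contrast is a Welch t-test on the per-sample mean z over panel genes.
    Panel genes absent from the matrix are dropped with a warning.
    """
    present = [g for g in geneset if g in z.index]
    missing = len(list(geneset)) - len(present)
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    if missing:
        warnings.warn(f"{missing} set gene(s) absent from the matrix; "
                      "dropped", stacklevel=2)
    zs = z.loc[present]
    per_sample = zs.mean(axis=0)
    groups = labels["group"].reindex(z.columns)
    group_scores = {}
    for grp, cols in groups.groupby(groups):
        group_scores[grp] = float(
            zs[cols.index].mean(axis=1).sum())
    counts = pd.DataFrame({"responder_count": per_sample})
    welch = compare_counts(counts, labels)
    return SetScoreResult(genes_used=present, per_sample=per_sample,
                          group_scores=group_scores, welch=welch)


def _ssgsea_one(values: np.ndarray, in_set: np.ndarray,
                alpha: float) -> float:
    """ES of one sample: running difference of the weighted in-set ECDF
    and the uniform out-of-set ECDF over the descending expression rank.

    ``values`` must already be ordered descending; ``in_set`` is the
    aligned membership mask. Weights are |rank value|^alpha with rank
    value N..1 down the ordering.
    """
    n = values.size
    k = int(in_set.sum())
    rank_values = np.arange(n, 0, -1, dtype=float)
    w = np.where(in_set, rank_values ** alpha, 0.0)
    denom_in = w.sum()
    p_in = np.cumsum(w) / denom_in
    p_out = np.cumsum(~in_set) / (n - k)
    return float(np.sum(p_in - p_out))


def ssgsea_score(norm_expr: pd.DataFrame, geneset: Sequence[str],
                 cfg: SsgseaConfig | None = None) -> pd.Series:
    """Single-sample GSEA enrichment score per sample.

    Genes are ordered by expression descending within each sample (ties
    broken deterministically by gene symbol); the ES is the summed
    difference between the weighted ECDF of in-set genes (weights = rank
    value ^ alpha) and the ECDF of out-of-set genes, normalized by
    (n_genes - n_set_genes) when ``cfg.normalize``.
    """
    cfg = cfg or SsgseaConfig()
    genes = norm_expr.index
    members = set(geneset) & set(genes)
    if not members:
        raise ValueError("gene set does not intersect the matrix")
    if len(members) >= len(genes):
        raise ValueError("gene set covers the whole universe")
    # deterministic tie handling: pre-sort genes by symbol, stable sort on
    # values keeps symbol order within ties
    sym_order = np.argsort(genes.to_numpy().astype(str), kind="mergesort")
    in_set_base = np.isin(genes.to_numpy(), list(members))[sym_order]
    vals_base = norm_expr.to_numpy(dtype=float)[sym_order]
    out = {}
    for j, sample in enumerate(norm_expr.columns):
        v = vals_base[:, j]
        order = np.argsort(-v, kind="mergesort")
        es = _ssgsea_one(v[order], in_set_base[order], cfg.alpha)
        if cfg.normalize:
            es /= (len(genes) - len(members))
        out[sample] = es
    return pd.Series(out, name="es")


def classify_subtype(es_pn: pd.Series, es_mes: pd.Series) -> pd.DataFrame:
    """Per-sample PN/MES call as the argmax of the two enrichment scores.

    Exact ties are labeled "ambiguous" with a warning. The margin
    (es_pn - es_mes) is reported alongside.
    """
    df = pd.DataFrame({"es_pn": es_pn, "es_mes": es_mes})
    if df.isna().any().any():
        raise ValueError("both enrichment scores required for every sample")
    margin = df["es_pn"] - df["es_mes"]
    label = np.where(margin > 0, "PN",
                     np.where(margin < 0, "MES", "ambiguous"))
    if (label == "ambiguous").any():
        warnings.warn("exact PN/MES score tie(s) labeled 'ambiguous'",
                      stacklevel=2)
    df["margin"] = margin
    df["subtype"] = label
    return df


def ora_hypergeometric(de_genes: Sequence[str], universe: Sequence[str],
                       genesets: Mapping[str, Sequence[str]]
                       ) -> pd.DataFrame:
    """Over-representation of a DE gene list in each gene set.

    For each set: overlap k, upper-tail hypergeometric
    p = P(X >= k), X ~ Hypergeom(N=|universe|, K=|set ∩ universe|,
    n=|de_genes|); Benjamini-Hochberg adjustment across sets.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    de = set(de_genes)
    stray = de - uni
    if stray:
        raise ValueError(
            f"DE genes outside the universe: {sorted(stray)[:5]}")
    n_u, n_de = len(uni), len(de)
    rows = []
    for name, members in genesets.items():
        in_u = set(members) & uni
        k = len(in_u & de)
        K = len(in_u)
        p = float(hypergeom.sf(k - 1, n_u, K, n_de)) if K else 1.0
        rows.append((name, k, K, n_de, n_u, p))
    tab = pd.DataFrame(
        rows, columns=["geneset", "overlap", "set_size", "n_de",
                       "n_universe", "pvalue"]).set_index("geneset")
    if len(tab):
        tab["p_adj"] = multipletests(tab["pvalue"], method="fdr_bh")[1]
    return tab
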