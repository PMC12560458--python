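"""Stemness set scores, ssGSEA subtype calls and over-representation.

Generates synthetic RNA-seq counts with a planted 1 log2-unit stemness
upregulation in resistant cultures, scores the stemness panel from
rank-normalized z-scores, calls proneural (PN) vs mesenchymal (MES)
subtypes from paired ssGSEA scores, and runs a hypergeometric
over-representation test on a toy DE gene list.
"""

import pandas as pd

import gscresist as g
from gscresist.config import CohortConfig

cfg = CohortConfig(n_drugs=5, n_genes=2000, n_islands=5, seed=7,
                   stemness_log2fc=1.0)
expr, gene_sets, truth = g.gen_expression_matrix(cfg)
labels = pd.DataFrame({"group": truth.group_labels})

norm = g.normalize_expression(expr)          # log2(CPM + 1)
z = g.gene_zscores(norm)                     # rank z-scores per gene
stem = g.set_score(z, gene_sets["STEMNESS"], labels)

print("stemness set score (sum over panel genes of group-mean z):")
for grp, score in stem.group_scores.items():
    print(f"  {grp:>9s}: {score:+7.2f}")
print(f"  Welch p = {stem.welch.pvalue:.2e}")
print()

es_pn = g.ssgsea_score(norm, gene_sets["PN"])
es_mes = g.ssgsea_score(norm, gene_sets["MES"])
subtypes = g.classify_subtype(es_pn, es_mes)
print("ssGSEA subtype calls (argmax of PN vs MES enrichment):")
print(subtypes.round(4).to_string())
print()

universe = list(expr.index)
de_genes = gene_sets["STEMNESS"][:20] + universe[-10:]
ora = g.ora_hypergeometric(de_genes, universe, gene_sets)
print("over-representation of the DE list in each panel:")
print(ora.to_string(float_format=lambda v: f"{v:.3g}"))
print()
print("A positive stemness score in the resistant group recovers the "
      "planted shift;\nlow hypergeometric p flags panels enriched in the "
      "DE list.")
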