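"""Classify synthetic GSC cultures into resistant and sensitive groups.

Generates a DSS matrix with planted group structure (4 sensitive, 5
resistant cultures), ranks the cultures by responder counts (drugs with
DSS >= 10), clusters the per-drug-centered matrix with Ward.D2 and
reports multiscale-bootstrap stability (AU/BP) of the two clusters.
"""

import gscresist as g
from gscresist.config import ClassificationConfig, CohortConfig

cfg = CohortConfig(n_drugs=120, n_genes=100, n_islands=5, seed=2024)
dss, truth = g.gen_dss_matrix(cfg)

common = g.restrict_common(dss)
counts = g.count_responders(common)
centered = g.normalize_dss(common)
Z, labels = g.cluster_cultures(centered, counts)
welch = g.compare_counts(counts, labels)
stability = g.multiscale_bootstrap(
    centered, ClassificationConfig(bootstrap_b=1000, seed=2024))

print("responder counts (drugs with DSS >= 10), ranked:")
print(counts.to_string())
print()
print("cluster assignment vs planted truth:")
for s in labels.index:
    print(f"  {s}: called {labels.loc[s, 'group']:>9s}, "
          f"planted {truth.group_labels[s]}")
print()
print(f"Welch t-test of responder counts between groups: "
      f"p = {welch.pvalue:.2e}")
for c in stability.clusters:
    print(f"cluster {c['members']}: BP = {c['bp']:.3f}, AU = {c['au']:.3f}")
print()
print("AU (approximately unbiased) near 1 means the cluster reappears in "
      "virtually\nevery feature-resampled replicate at every scale, i.e. "
      "the split is robust.")
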