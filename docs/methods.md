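# Methods

This note documents the models, defaults and numerical choices behind
`gscresist`, and what the synthetic-data tests do and do not demonstrate
about real screening data.

## Dose-response model and DSS

Percent inhibition is computed per well as
`100 * (neg_mean - signal) / (neg_mean - pos_mean)` from the plate's
DMSO (negative) and full-kill (positive) control means, then clipped to
[-25, 100]: mild growth stimulation is informative for the fit, but
unbounded negative values would dominate the least-squares objective.

The four-parameter logistic is fitted on the log10-concentration axis by
bounded trust-region least squares (`scipy.optimize.least_squares`) with
bottom in [-25, 25], top in [-25, 120], slope in (0, 10] and midpoint m
in [x1 - 2, x2 + 2]. Four deterministic starts (combinations of data-
driven bottom/top, the median x and the half-maximal x, shallow and
steep slopes) guard against local minima; the best residual sum of
squares wins. Convergence is accepted either on scipy's step tolerances
(1e-10) or when the projected gradient is small relative to the
residual scale: flat or step-like series have unidentifiable (m, s) and
crawl along a bound without ever meeting step tolerances, although the
fit itself is stationary. Non-convergent series score DSS = 0 with a
warning rather than a missing value, so responder counts stay
conservative. Series with fewer than two distinct doses are rejected;
replicate wells are averaged before fitting.

DSS integrates the fitted curve, clipped to [0, 100], above the
activity floor t = 10% across the tested window only (no
extrapolation), normalized by the full window area (100 - t)(x2 - x1)
and scaled to [0, 100]. Because the logistic is monotone, its crossings
with t and 100 are solved in closed form and the logistic antiderivative
`b*x + (t-b)/(s ln10) * log1p(10^{s(x-m)})` is applied piecewise; the
result agrees with a 1e5-point trapezoid rule to < 1e-6 (tested). The
`dss2` compatibility variant additionally divides by log10(top); it is
off by default.

## Resistance classification

Responder count is the number of drugs with DSS at or above 10 (the
threshold is inclusive); ranking ties break lexicographically by sample
id. Before clustering, the matrix is restricted to drugs with a value in
every culture (no imputation), and each drug is centered on its cohort
mean. Centering was chosen over division for "normalizing to the
per-drug average": division is unstable for drugs with near-zero mean
DSS, and centering is the conventional pre-clustering transform; the
alternative reading is noted as an interpretation.

Clustering is agglomerative Ward (equivalent to R's Ward.D2 on
Euclidean distances) over sample columns, cut at two clusters. The
cluster with the lower mean responder count is labeled "resistant" — a
deterministic replacement for labeling by inspection.

### Multiscale bootstrap

For each scale r in {0.5, ..., 1.4}, drugs (rows) are resampled with
replacement to round(r * n_drugs) rows — features are the replicated
units, the convention for expression-like matrices — and the cultures
re-clustered; BP_r is the fraction of replicates in which a reference
cluster reappears as a clade. The AU p-value comes from weighted least
squares of z_r = Phi^-1(1 - BP_r) on (sqrt(r), 1/sqrt(r)) with binomial
weights, AU = 1 - Phi(v - c). Two degeneracies are handled explicitly:
(i) constant BP across scales is the c = 0 model, under which AU and BP
coincide, so the constant is returned directly (also covering BP = 1
everywhere); (ii) scales with saturated BP (exactly 0 or 1, infinite
normal quantile) are excluded from the fit, and with fewer than three
informative scales the BP nearest scale 1 is returned — extrapolating
from clipped quantiles would otherwise produce arbitrary AU values for
clusters that are in fact maximally stable. The default 10,000
replicates per scale match standard practice; tests use 2,000 and check
seed-to-seed agreement within Monte-Carlo error.

Group contrasts on responder counts use Welch's t-test
(Welch-Satterthwaite degrees of freedom); two groups with zero variance
and equal means report t = 0, p = 1.

## Expression scores

Counts are normalized as log2(CPM + 1). A model-based variance
stabilizer would require an external dispersion fit; the downstream
scores are rank-based and depend only weakly on the stabilizer, so the
simple transform is used and recorded in the output's metadata.

Rank z-scores: per gene, values are ranked across samples (average
ranks on ties) and the ranks standardized to mean 0, sd 1 (sample sd,
so three samples give z = -1, 0, 1). Constant genes become all-zero
rows with a warning. The group set score is the **sum** over panel
genes of the group-mean z; for a ~34-gene panel this reproduces the
familiar magnitude of ±10-25 that a mean would compress to below 1. The
group contrast is Welch's t on per-sample mean z.

ssGSEA: genes are ordered by expression descending within each sample
(ties broken by gene symbol, deterministically); the enrichment score is
the summed difference between the weighted ECDF of in-set genes
(weights = rank value ^ alpha, alpha = 0.75 by convention of the
original single-sample formulation) and the unweighted ECDF of
out-of-set genes, optionally normalized by (n_genes − n_set_genes). At
alpha = 0 the score depends on ranks only (tested as an invariance).
Subtype calls are the argmax of the PN and MES enrichment scores; exact
ties are labeled "ambiguous".

ORA uses the hypergeometric upper tail P(X >= k) with BH adjustment
across gene sets. Differential expression itself is out of scope: DE
gene lists are inputs.

## Methylation

bedMethyl records (tab-separated, >= 11 columns; modification code in
column 4, valid coverage in column 10, percent modified in column 11)
are parsed for the 5mC code "m"; files with more than 10% malformed
lines are rejected. The depth floor of 5 reads is applied per site
(valid coverage >= 5, inclusive); the floor can equally be read as a
genome-wide QC criterion, so it is configurable.

Island methylation is the unweighted mean of site percentages over
sites with start in [island_start, island_end) on the same chromosome,
both strands pooled; `combine_strands` optionally merges the two
cytosines of a CpG dinucleotide by coverage-weighted average. Islands
with no covered sites are missing, not zero. The MGMT promoter is
configured in printed 1-based inclusive hg38 coordinates
(chr10:129,466,685-129,467,446) and converted internally to the 0-based
half-open convention; both end points are unit-tested. The classifier
is the plain mean over sites in the window with a strict > 22% cutoff.

Differential methylation uses the classical equal-variance two-sample
t-test by default (Welch selectable) at raw p < 0.05 without
multiplicity correction — the convention for this analysis; a BH column
is emitted for information only. An island is "linked" to its gene when
the sign of the between-group methylation difference is opposite to the
sign of the gene's expression difference; the per-island Spearman
correlation across samples is reported alongside. Island-to-gene
mapping is an input table; the bundled helper maps an island to the
gene whose TSS falls inside it or within 2 kb (an explicitly pragmatic
default).

## Synthetic cohorts

The generator emulates the design of a 9-culture screening study: 4
sensitive and 5 resistant cultures, up to 329 drugs in a 5-point
10-fold dose escalation, 16 DMSO and 16 positive-control wells per
plate, bulk counts for 2,000 genes and a methylome of CpG islands on a
synthetic chromosome plus an MGMT-like 98-site promoter at the true
hg38 coordinates.

Noise models are the standard minimal choices per modality: unit-mean
lognormal multiplicative noise for luminescence (CV 8%, typical of
CellTiter-Glo-style assays), negative-binomial counts via the
gamma-Poisson mixture (dispersion 0.1), and Beta-distributed per-site
5mC fractions (precision 50) around island means centered at 35% — the
level reported for global CpG-island methylation in GSC cohorts.
Group structure: each drug is active everywhere, active only in
sensitive cultures, or inert, with sensitive cultures responding to 35%
of drugs and resistant ones to 10%; stemness-panel genes are shifted by
1 log2 unit in resistant cultures (MES-panel likewise, PN-panel in
sensitive); 10% of islands carry a 30-percentage-point group
difference; each sample's MGMT-like promoter is planted at 10% or 30%
mean methylation. Per-drug anchor concentrations and dose ranges are
randomized because real panels' ranges are compound-specific and not
modeled. Determinism: every stage draws from
`SeedSequence(seed, spawn_key=crc32(stage))`, so identical config and
seed give byte-identical files and no stage perturbs another.

`gen_dss_matrix` produces DSS values directly from the planted 4PL
parameters plus Gaussian jitter (sd 2 DSS units): it exists so that
cluster-level properties can be exercised at the full 300-drug design
size without refitting thousands of curves; curve fitting itself is
validated separately on noiseless and noisy screens.

What the synthetic cohort does **not** emulate: plate/batch effects,
drug-drug mechanism correlations, compositional library-size artifacts,
bisulfite-style measurement error or read-level methylation calls, copy
number or mutation structure. Passing tests therefore demonstrate
correctness of the computations and recoverability of planted effects
under idealized noise — not performance on any particular patient
cohort.

## Problem sizes in the test and acceptance runs

Tests run the clustering recovery at the study design size (9 samples x
300 drugs, 50 seeds), the bootstrap at B = 2,000, the null calibration
on 2,000 islands and the power check on 100 planted islands out of 500;
raw-well fitting is exercised on 40-60-drug screens. These sizes were
chosen as the smallest that pin each property tightly; all quantities
are recomputed at the same sizes by `scripts/acceptance.py`.

## Known limitations

- The DSS variant implemented is the unnormalized-asymptote area score;
  published DSS definitions differ in asymptote handling, so absolute
  values are comparable only within a variant.
- AU p-values are asymptotic in the number of bootstrap replicates and
  scales; with saturated BP profiles the implementation reports BP
  itself rather than an extrapolated AU.
- The log2(CPM + 1) stand-in is not a variance-stabilizing
  transformation; score magnitudes (not ranks) may shift slightly under
  a different normalizer.
- Bell-shaped (non-monotone) dose-response series are outside the 4PL
  family; they fit as shallow or boundary curves and are flagged only
  through their residuals.
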