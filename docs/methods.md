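# Methods

## Model and procedure

`mirdep` analyses a probes × samples matrix of log2 expression intensities
(the output of an upstream normalisation such as RMA; normalisation itself is
out of scope) annotated with a genotype ∈ {WT, KO} and condition ∈ {M0, M1,
M2} per sample. Probes are the unit of analysis; gene symbols are
annotations, matched case-insensitively, and never collapsed, because one
transcript is commonly covered by several probes.

**Contrasts.** For groups A and B, per probe: FC = 2^(x̄_A − x̄_B),
MEV = (x̄_A + x̄_B)/2, p from the two-tailed pooled-variance ("equal SD")
two-sample t-test with df = n_A + n_B − 2, and BH step-up adjusted p across
all probes of the contrast (never across contrasts). Unbalanced groups are
supported; each group needs ≥ 2 samples. A probe with zero pooled variance
gets p = 1 if the means coincide and p = 0 otherwise, with a logged flag.

**Signature.** Up = {FC ≥ 2, p_adj < 0.05}, Down = {FC ≤ 0.5, p_adj < 0.05}
on the WT M1-vs-M0 contrast. Threshold comparisons are inclusive, and the
p-filter uses adjusted p; both are flags (`inclusive=`, `use_adjusted=`)
because reasonable labs do either.

**Dependency partition.** A signature gene is *dependent* when its KO fold
change lies strictly inside (0.5, 2) — the complement of the inclusive
signature boundary, so a gene sitting exactly on 2.0 still counts as
responding. It is *attenuated* when it is beyond the threshold but its
response is smaller than in WT (FC_KO/FC_WT < 1 for up genes, > 1 for down
genes), and *independent* otherwise. The labels partition the signature
exactly. The overall dependency percentage is the unweighted pooled fraction
over up ∪ down; per-direction percentages are always reported alongside.

**Affected-gene list.** Union of two criteria, each applied symmetrically in
both directions: (1) responds in WT (FC ≥ 2 or ≤ 0.5) but not in KO (KO FC
inside the band); (2) FC ≥ 2 or ≤ 0.5 directly between the activated
genotypes. Each member carries a provenance tag (criterion1 / criterion2 /
both).

**Fold-change trend.** OLS of log2(FC_KO) on log2(FC_WT); a = 2^intercept,
b = slope, R² from the log-log residuals. The parameters are log-base
invariant, and the fit is scale-equivariant (rescaling all FC_WT by c leaves
b alone and rescales a by c^−b). By default the fit uses all probes (the
whole-population scatter); since null genes contribute uncorrelated noise on
both axes, they pull the population slope toward zero — the planted exponent
is recovered by fitting on the genes the partition labels attenuated, which
is what the acceptance script does.

**Target screen.** The universe comes from a canonical seed-site scan of
3'UTR FASTA (record id = gene/probe id) or from a user list. Site types use
the standard definitions against seed = miRNA nucleotides 2–8, on the UTR
sense strand 5'→3': a 6mer complements nucleotides 2–7; 7mer-m8 extends
pairing to nucleotide 8 (one base 5' on the UTR); 7mer-A1 instead has an
adenine opposite nucleotide 1 (one base 3' on the UTR); an 8mer has both.
Each locus is reported once with its most specific type, 0-based half-open
coordinates, U/T equivalent, case-insensitive. No conservation or context
scoring is attempted: the scanner is deliberately a minimal, fully specified
sequence filter. Downstream: repression filter (FC ≤ 0.5 in WT M1-vs-M0),
re-induction filter (FC > 1 in KO-M1 vs WT-M1; top set at ≥ 2 — the
KO-M1-vs-WT-M1 axis, not KO-M1-vs-KO-M0, is the defining contrast for the
top set), then per-gene Pearson R against the miRNA's per-sample expression
over all samples, with two-tailed p from t = R√(n−2)/√(1−R²), df = n − 2.
The miRNA vector may be a matrix probe or an external per-sample file, since
small-RNA expression is often measured on a separate assay. The final report
is sorted by ascending R with a significance count at α = 0.05.

**Clustering.** Samples are clustered on a panel (typically dependent up
genes plus top targets) with per-gene z-scoring (flag-controlled, default
on), correlation distance 1 − Pearson R between sample profiles, and average
linkage — heatmap convention; metric and linkage are configurable.
`nearest_major_cluster` cuts at k clusters and reports each query sample's
co-members, operationalising "KO activated samples cluster with resting
samples".

**qPCR.** Comparative Ct: ΔCt = Ct_target − Ct_reference per sample,
ΔΔCt against the mean ΔCt of an explicit calibrator sample or group (always
an argument — studies calibrate variously to time zero or to the resting
condition), RQ = 2^−ΔΔCt. Standard curve: per-gene Ct = slope·log10(q) +
intercept fitted on ≥ 3 dilution points, quantity ratios target/reference
normalised to the calibrator; with equal (100%) efficiencies this reduces
analytically to the ΔΔCt result, which the tests assert to 1e-9.
Efficiencies are "comparable" when they differ by < 5 percentage points
(configurable; no published criterion exists). Replicate RQs are summarised
by geometric mean (RQ is ratio-scaled); bar-chart-style reporting scales group
means and SEMs so a chosen reference condition reads 100%.

## Synthetic generator

The generator emulates the study design the pipeline expects: group sizes
default to 3/3/3/2 (WT-M0/WT-M1/KO-M0/KO-M1 — the unbalanced design arises
in practice when a replicate fails QC), baseline per probe ~ N(7, 2) log2
units, i.i.d. Gaussian noise sd 0.25 log2 per measurement. Probe classes are
assigned deterministically by index (truth counts exact): 5% induced and 5%
repressed in WT-M1, a fraction f (default 0.5) of each fully dependent (zero
KO effect), the remainder attenuated with KO log2 effect = b × WT effect
(default b = 0.6); 30 target genes repressed 3-fold in WT-M1 only and fully
de-repressed in KO-M1; everything else null. Per-gene effect magnitudes are
drawn Uniform(2, 6) log2 (4- to 64-fold): activation responses span that
range in real M1 data, and the spread on the log-FC axis is what makes the
attenuation exponent identifiable by OLS — with a degenerate effect size the
x-variance would be pure measurement noise and any slope estimate would
collapse. The miRNA vector is 2^4 baseline with a 2^7.5 (~180-fold) boost in
WT-M1 only, mirroring the M1-restricted induction of inflammation-associated
miRNAs; its inverse coupling to target genes arises purely from the shared
group structure. UTRs are uniform random RNA (default 300 nt): target genes
get one planted site of the requested type with guard flanks pinning the
classification, non-targets are rejection-sampled until the scanner finds no
canonical site. Ct tables plant per-group RQs with a per-sample loading
offset on both genes (so reference normalisation must cancel it).

What the generator does **not** emulate: intensity-dependent
(heteroscedastic) noise, probe-level cross-hybridisation, correlated genes,
composition effects, or realistic UTR base composition. Passing recovery
tests therefore shows the pipeline's arithmetic and filters are correct under
the assumed model, not that the model captures every property of microarray
data.

## Numerical choices and degenerate inputs

- Fold changes are computed and thresholded on the linear scale; all
  statistics on log2.
- BH adjustment delegates to statsmodels (`fdr_bh`) and is checked against a
  direct step-up enumeration. BH is not idempotent (re-adjusting adjusted
  p-values inflates them); only oracle equivalence and monotonicity are
  asserted.
- TSV round trips are bit-exact: values are parsed with correctly rounded
  float conversion (`astype(float)`), not pandas' fast lossy `to_numeric`.
- Correlations are clipped to [−1, 1] before the t transform; |R| = 1 maps
  to p = 0; zero-variance vectors yield NaN with a `degenerate` flag.
- Dendrogram merge heights are scipy's; ties are broken by scipy's internal
  order, and tests compare sorted height multisets.
- Duplicate probe ids, non-numeric cells, missing sample-sheet rows, unknown
  genotype/condition labels, groups of size 1, empty gene sets, invalid UTR
  characters and non-positive fold changes all raise with the offending
  item named; a sample sheet that is a superset of the matrix only warns.

## Problem sizes used in tests

Unit tests run on toys (≤ 1,000 probes). Recovery checks use 10,000 probes ×
10 seeds per condition and the null calibration 10,000 probes × 5 seeds —
the smallest sizes at which the ±5-point / ±0.05 recovery bands are
comfortably inside the estimator's sampling error. The whole suite runs in
well under a minute.

## Known limitations

- Probe-to-gene mapping is annotation only; no summarisation strategies.
- No moderated-variance (shrinkage) t statistics; with n = 2–3 per group the
  pooled t is exactly what it claims, but real studies may prefer limma-style
  moderation.
- The seed scanner finds canonical sites only — no bulged, offset or
  3'-supplementary sites, no conservation, no context scores — so its
  universe is a coarse stand-in for curated target databases.
- The published 18-gene table bundled in `mirdep.datasets` reports printed
  (R, p) pairs whose sample size is not stated; the package counts
  significance on the printed values and does not attempt to re-derive those
  p-values.
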