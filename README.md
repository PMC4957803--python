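# mirdep

Quantifying how much of an activation-induced gene-expression signature
depends on a single microRNA, by contrasting wild-type (WT) and knockout (KO)
genotypes.

The motivating system is the inflammatory (M1, LPS + IFN-γ-stimulated)
macrophage: miR-155 is induced >100-fold on M1 activation, and macrophages
from miR-155 knockout mice fail to mount much of the M1 transcriptional
programme. `mirdep` turns that comparison into a reusable pipeline for any
genotype-by-condition expression study:

- **Contrasts** — per-probe linear fold changes FC = 2^(x̄_A − x̄_B) on log2
  expression, pooled-variance two-tailed t-tests, Benjamini–Hochberg FDR
  adjustment, and ≥2FC / ≤0.5FC signature calling.
- **Dependency partitioning** — each WT signature gene is labelled by its KO
  behaviour: *dependent* (KO fold change collapses inside the (0.5, 2) band),
  *attenuated* (still beyond 2FC but smaller than in WT), or *independent*;
  summary percentages are reported per direction and pooled.
- **Fold-change dampening trend** — OLS of log₂FC_KO on log₂FC_WT gives the
  power law FC_KO = a·FC_WT^b; b = 1 means the knockout responds like the
  wild type, b < 1 means a genome-wide dampening of the activation response.
- **Candidate-target screen** — canonical seed-site scanning of 3'UTRs
  (6mer / 7mer-A1 / 7mer-m8 / 8mer against miRNA nucleotides 2–8), a
  repression filter (FC ≤ 0.5 in WT activation), a re-induction filter
  (FC > 1, top set ≥ 2, in KO-M1 vs WT-M1), and an inverse Pearson
  correlation ranking against the miRNA's own expression.
- **Clustering** — average-linkage/correlation-distance clustering of samples
  on a gene panel, e.g. to ask whether KO activated samples look more like
  resting than like WT activated samples.
- **qPCR quantification** — comparative-Ct (2^−ΔΔCt) and standard-curve
  methods with reference-gene normalisation and percent-of-condition
  reporting, for validating individual genes.
- **Synthetic data** — a generator that plants all of the above structure
  (dependency fractions, attenuation exponent, inversely correlated targets,
  seeded UTRs, Ct tables) with exact truth labels, so every stage is testable
  without any download.

## Worked example

Generate a synthetic study (5,000 probes; 3 WT-M0, 3 WT-M1, 3 KO-M0 and
2 KO-M1 samples; half of the planted signature fully miRNA-dependent, the
rest dampened with exponent b = 0.6) and partition its signature:

```sh
mirdep generate --seed 1 --n-probes 5000 --out-dir data
mirdep dependency data/expression.tsv data/sample_sheet.csv --out-dir results
```

prints

```json
{
  "pct_up_dependent": 49.799196787148595,
  "pct_down_dependent": 55.072463768115945,
  "pct_overall_dependent": 52.57142857142857,
  "trend": {
    "a": 1.0029241381954312,
    "b": 0.29892901094346136,
    "r_squared": 0.43455319606606535
  }
}
```

Half of the called signature (52.6%) lost its response in the knockout,
matching the planted 50% (the slight excess comes from planted miRNA targets,
which are de-repressed in the KO and therefore also land in the dependent
band). The trend line here is fitted over *all* probes, where the mass of
null genes dilutes the slope (b ≈ 0.30, R² ≈ 0.43); restricted to the genes
the partition labels attenuated (`--signature-only` on a signature subset),
the fit recovers the planted exponent b ≈ 0.6.

The full pipeline — contrasts, signature, dependency, UTR seed scan, target
screen, clustering, manifest — runs from a YAML config:

```sh
mirdep run --config config.yaml --out-dir results
```

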