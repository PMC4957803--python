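"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a two-genotype (WT / miRNA-knockout), two-condition
(resting M0 / activated M1) expression study on the log2 scale: log-normal
baseline per probe, planted activation effects in WT-M1, a planted fraction of
those effects fully lost (dependent) or dampened by a power-law exponent
(attenuated) in the knockout, planted miRNA target genes repressed in WT-M1
and de-repressed in KO-M1, a miRNA expression vector high in WT-M1 only, 3'UTR
sequences carrying (or guaranteed free of) canonical seed sites, and qPCR Ct
tables consistent with planted relative quantities.

Class assignment is deterministic by probe index before any noise is drawn, so
truth counts are exact rather than binomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, join_sample_sheet
from .qpcr import CtTable
from .target_screen import MatureMiRNA, scan_seed_sites, _RNA_COMPLEMENT, _revcomp

LABEL_NULL = "null"
LABEL_IND_DEP = "induced-dependent"
LABEL_IND_ATT = "induced-attenuated"
LABEL_REP_DEP = "repressed-dependent"
LABEL_REP_ATT = "repressed-attenuated"
LABEL_TARGET = "target"

DEFAULT_GROUP_SIZES = {("WT", "M0"): 3, ("WT", "M1"): 3, ("KO", "M0"): 3, ("KO", "M1"): 2}


@dataclass
class GeneratorParams:
    """Knobs of the expression generator.

    Per-gene activation effects (log2 fold change in WT-M1 vs WT-M0) are drawn
    uniformly from [effect_size, effect_spread * effect_size], i.e. 4- to
    64-fold at the defaults — activation signatures span that range in practice, and the spread
    is what makes the fold-change trend identifiable.  Attenuated genes respond
    in the knockout with the WT log2 effect scaled by ``attenuation_exponent``
    (FC_KO = FC_WT ** b); dependent genes do not respond at all.
    """

    n_probes: int = 10_000
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    fraction_induced: float = 0.05
    fraction_repressed: float = 0.05
    fraction_dependent: float = 0.5
    attenuation_exponent: float = 0.6
    n_targets: int = 30
    target_repression_fc: float = 3.0
    effect_size: float = 2.0  # minimum planted |log2 FC|
    effect_spread: float = 3.0  # upper bound multiplier; 1.0 = fixed effects
    noise_sd: float = 0.25  # log2 scale
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    mir_baseline: float = 4.0  # log2 miRNA expression outside WT-M1
    mir_induction: float = 7.5  # log2 boost in WT-M1 (~180-fold)
    seed: int | None = None

    def validate(self) -> None:
        for name in ("fraction_induced", "fraction_repressed", "fraction_dependent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.fraction_induced + self.fraction_repressed > 1.0:
            raise ValueError("induced + repressed fractions exceed 1")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every genotype x condition group needs >=2 samples")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-probe class labels and true effects.

    ``effect_wt`` / ``effect_ko`` are the true log2 M1-vs-M0 effects per
    genotype; true fold changes follow as 2**effect.  ``mir_vector`` is the
    per-sample log2 miRNA expression (noise-free part plus noise, as emitted).
    """

    labels: pd.Series
    effect_wt: pd.Series
    effect_ko: pd.Series
    mir_vector: pd.Series
    params: GeneratorParams

    @property
    def target_probes(self) -> list[str]:
        return self.labels.index[self.labels == LABEL_TARGET].tolist()

    def probes_with_label(self, label: str) -> list[str]:
        return self.labels.index[self.labels == label].tolist()

    def true_fc_wt(self) -> pd.Series:
        return np.exp2(self.effect_wt)

    def true_fc_ko(self) -> pd.Series:
        return np.exp2(self.effect_ko)


def _assign_labels(params: GeneratorParams) -> np.ndarray:
    n = params.n_probes
    n_ind = round(params.fraction_induced * n)
    n_rep = round(params.fraction_repressed * n)
    n_ind_dep = round(params.fraction_dependent * n_ind)
    n_rep_dep = round(params.fraction_dependent * n_rep)
    if n_ind + n_rep + params.n_targets > n:
        raise ValueError("planted classes exceed n_probes")
    labels = np.full(n, LABEL_NULL, dtype=object)
    i = 0
    for label, count in (
        (LABEL_IND_DEP, n_ind_dep),
        (LABEL_IND_ATT, n_ind - n_ind_dep),
        (LABEL_REP_DEP, n_rep_dep),
        (LABEL_REP_ATT, n_rep - n_rep_dep),
        (LABEL_TARGET, params.n_targets),
    ):
        labels[i : i + count] = label
        i += count
    return labels


def generate_expression(
    params: GeneratorParams,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate (annotated ExpressionMatrix, sample sheet, SyntheticTruth).

    log2 value = per-probe baseline + class-specific group effect + N(0, sd)
    noise.  The miRNA vector is emitted in the truth object (and is also
    appended to nothing — it is a separate measurement, as in a small-RNA
    assay).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    sample_ids, genotypes, conditions = [], [], []
    for (gt, cond), size in params.group_sizes.items():
        for r in range(1, size + 1):
            sample_ids.append(f"{gt}_{cond}_{r}")
            genotypes.append(gt)
            conditions.append(cond)
    sheet = pd.DataFrame(
        {
            "genotype": genotypes,
            "condition": conditions,
            "replicate": [int(s.rsplit("_", 1)[1]) for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    n = params.n_probes
    probes = pd.Index([f"probe_{i:05d}" for i in range(n)], name="probe_id")
    labels = _assign_labels(params)

    if params.effect_spread < 1.0:
        raise ValueError("effect_spread must be >= 1")
    magnitudes = rng.uniform(
        params.effect_size, params.effect_spread * params.effect_size, size=n
    )
    effect_wt = np.zeros(n)
    effect_ko = np.zeros(n)
    b = params.attenuation_exponent
    for idx in range(n):
        lab = labels[idx]
        if lab in (LABEL_IND_DEP, LABEL_IND_ATT):
            effect_wt[idx] = magnitudes[idx]
            effect_ko[idx] = 0.0 if lab == LABEL_IND_DEP else b * magnitudes[idx]
        elif lab in (LABEL_REP_DEP, LABEL_REP_ATT):
            effect_wt[idx] = -magnitudes[idx]
            effect_ko[idx] = 0.0 if lab == LABEL_REP_DEP else -b * magnitudes[idx]
        elif lab == LABEL_TARGET:
            effect_wt[idx] = -np.log2(params.target_repression_fc)
            effect_ko[idx] = 0.0  # fully de-repressed in the knockout

    baseline = rng.normal(params.baseline_mean, params.baseline_sd, size=n)
    is_m1 = np.array([c == "M1" for c in conditions])
    is_wt = np.array([g == "WT" for g in genotypes])
    effect_per_sample = np.where(
        is_m1[None, :], np.where(is_wt[None, :], effect_wt[:, None], effect_ko[:, None]), 0.0
    )
    values = (
        baseline[:, None]
        + effect_per_sample
        + rng.normal(0.0, params.noise_sd, size=(n, len(sample_ids)))
    )

    mir = (
        params.mir_baseline
        + np.where(is_m1 & is_wt, params.mir_induction, 0.0)
        + rng.normal(0.0, params.noise_sd, size=len(sample_ids))
    )

    symbols = pd.Series([f"G{i:05d}" for i in range(n)], index=probes, name="gene_symbol")
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=sample_ids),
        gene_symbols=symbols,
    )
    matrix = join_sample_sheet(matrix, sheet)
    truth = SyntheticTruth(
        labels=pd.Series(labels, index=probes, name="label"),
        effect_wt=pd.Series(effect_wt, index=probes, name="effect_wt"),
        effect_ko=pd.Series(effect_ko, index=probes, name="effect_ko"),
        mir_vector=pd.Series(mir, index=pd.Index(sample_ids, name="sample_id"), name="mir"),
        params=params,
    )
    return matrix, sheet, truth


# -- UTR generation ----------------------------------------------------------

_RNA_ALPHABET = "ACGU"


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_RNA_ALPHABET), size=length))


def _site_string(mir: MatureMiRNA, site_type: str, rng: np.random.Generator) -> str:
    """A planted site plus guard flanks that pin its classification."""
    core6 = _revcomp(mir.sequence[1:7])
    m8 = _RNA_COMPLEMENT[mir.sequence[7]]
    not_m8 = rng.choice([c for c in _RNA_ALPHABET if c != m8])
    not_a = rng.choice([c for c in _RNA_ALPHABET if c != "A"])
    if site_type == "8mer":
        return m8 + core6 + "A"
    if site_type == "7mer-m8":
        return m8 + core6 + not_a
    if site_type == "7mer-A1":
        return not_m8 + core6 + "A"
    if site_type == "6mer":
        return not_m8 + core6 + not_a
    raise ValueError(f"unknown site type {site_type!r}")


def generate_utrs(
    truth: SyntheticTruth,
    mir: MatureMiRNA,
    site_type: str = "8mer",
    utr_length: int = 300,
    genes: list[str] | None = None,
    max_attempts: int = 1000,
) -> str:
    """Generate 3'UTR FASTA text: seed sites planted in targets, none elsewhere.

    Target-gene UTRs carry at least one canonical site of ``site_type``
    (guaranteed by construction and verified by the scanner); non-target UTRs
    are rejection-sampled until the scanner finds no canonical site at all.
    Record ids are probe ids.
    """
    rng = np.random.default_rng((truth.params.seed or 0) + 7)
    targets = set(truth.target_probes)
    if genes is None:
        genes = list(truth.labels.index)
    records = []
    for gene in genes:
        for _ in range(max_attempts):
            if gene in targets:
                body = _random_rna(rng, utr_length)
                insert_at = int(rng.integers(1, max(2, utr_length - 10)))
                seq = body[:insert_at] + _site_string(mir, site_type, rng) + body[insert_at:]
                sites = scan_seed_sites(seq, mir, utr_id=gene)
                if sites and any(s.site_type == site_type for s in sites):
                    break
            else:
                seq = _random_rna(rng, utr_length)
                if not scan_seed_sites(seq, mir, utr_id=gene):
                    break
        else:
            raise RuntimeError(f"could not generate a conforming UTR for {gene}")
        records.append(f">{gene}\n{seq}")
    return "\n".join(records) + "\n"


# -- qPCR generation ---------------------------------------------------------

def generate_ct_table(
    rq_by_group: dict[str, float],
    target_gene: str = "Nos2",
    reference_gene: str = "Hprt",
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    loading_sd: float = 0.5,
    seed: int = 0,
) -> CtTable:
    """Ct table whose comparative-Ct quantification recovers the planted RQs.

    Per sample, a loading offset ~ N(0, loading_sd) shifts both genes (the
    reference normalisation must cancel it); the target Ct additionally drops
    by log2(RQ) of the sample's group.  With ``noise_sd`` = 0 the recovery is
    exact (relative to the calibrator group's planted RQ).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, rq in rq_by_group.items():
        if rq <= 0:
            raise ValueError(f"planted RQ must be positive, got {rq} for {group}")
        for r in range(1, n_replicates + 1):
            sample = f"{group}_{r}"
            loading = rng.normal(0.0, loading_sd)
            ref_ct = 20.0 + loading + rng.normal(0.0, noise_sd)
            target_ct = 24.0 - np.log2(rq) + loading + rng.normal(0.0, noise_sd)
            rows.append((sample, reference_gene, ref_ct))
            rows.append((sample, target_gene, target_ct))
    data = pd.DataFrame(rows, columns=["sample_id", "gene", "ct"])
    return CtTable(data=data, reference_gene=reference_gene)
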