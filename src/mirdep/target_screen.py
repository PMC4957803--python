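"""Candidate miRNA-target discovery.

The screen chains four pure filters: (1) a canonical seed-site scan of 3'UTR
sequences (or a user-supplied candidate list) defines the target universe;
(2) genes repressed on activation in the wild type (FC <= 0.5, WT-M1 vs WT-M0)
are candidate targets; (3) genes de-repressed in the knockout (KO-M1 vs WT-M1
FC > 1, "re-induced"; >= 2 defines the top set); (4) inverse Pearson correlation
of each gene's expression with the miRNA's across all samples ranks the result.

Seed-site types follow the canonical nomenclature: the seed is miRNA nucleotides
2-8; a 6mer site complements nucleotides 2-7, 7mer-m8 extends the pairing to
nucleotide 8, 7mer-A1 adds an adenine opposite nucleotide 1, and an 8mer has
both.  No conservation or context scoring is applied — the scanner is a
deliberately minimal sequence filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, GeneSet
from .differential import ContrastResult

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")


def _normalize_rna(seq: str, what: str) -> str:
    """Uppercase, DNA->RNA (T->U); reject anything outside {A,C,G,U}."""
    out = seq.upper().replace("T", "U")
    for pos, ch in enumerate(out):
        if ch not in _RNA_COMPLEMENT:
            raise ValueError(f"invalid character {ch!r} at position {pos} in {what}")
    return out


def _revcomp(seq: str) -> str:
    return "".join(_RNA_COMPLEMENT[c] for c in reversed(seq))


@dataclass
class MatureMiRNA:
    """A mature miRNA sequence, 5'->3'; the seed is nucleotides 2-8."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = _normalize_rna(self.sequence, f"miRNA {self.name}")
        if len(self.sequence) < 8:
            raise ValueError(f"miRNA {self.name}: need >=8 nt, got {len(self.sequence)}")

    @property
    def seed(self) -> str:
        return self.sequence[1:8]


@dataclass
class SeedSite:
    """A canonical seed-match locus on a UTR (0-based, half-open)."""

    utr_id: str
    start: int
    end: int
    site_type: str
    match: str


def scan_seed_sites(utr_seq: str, mir: MatureMiRNA, utr_id: str = "") -> list[SeedSite]:
    """Find all canonical seed sites of ``mir`` in a UTR sequence.

    The UTR is taken as the mRNA sense strand 5'->3' (DNA or RNA, any case).
    Each seed-match locus is reported once with its most specific type
    (8mer > 7mer-m8 / 7mer-A1 > 6mer).
    """
    utr = _normalize_rna(utr_seq, f"UTR {utr_id or '<anonymous>'}")
    core6 = _revcomp(mir.sequence[1:7])  # complements miRNA nt 2-7
    m8_base = _RNA_COMPLEMENT[mir.sequence[7]]  # pairs miRNA nt 8, 5' of the core on the UTR
    sites: list[SeedSite] = []
    pos = utr.find(core6)
    while pos != -1:
        has_m8 = pos >= 1 and utr[pos - 1] == m8_base
        has_a1 = pos + 6 < len(utr) and utr[pos + 6] == "A"
        if has_m8 and has_a1:
            start, end, site_type = pos - 1, pos + 7, "8mer"
        elif has_m8:
            start, end, site_type = pos - 1, pos + 6, "7mer-m8"
        elif has_a1:
            start, end, site_type = pos, pos + 7, "7mer-A1"
        else:
            start, end, site_type = pos, pos + 6, "6mer"
        sites.append(SeedSite(utr_id=utr_id, start=start, end=end, site_type=site_type,
                              match=utr[start:end]))
        pos = utr.find(core6, pos + 1)
    return sites


def scan_utr_fasta(records, mir: MatureMiRNA) -> dict[str, list[SeedSite]]:
    """Scan an iterable of Bio.SeqRecord (or (id, seq) pairs) for seed sites."""
    out: dict[str, list[SeedSite]] = {}
    for rec in records:
        if hasattr(rec, "seq"):
            utr_id, seq = rec.id, str(rec.seq)
        else:
            utr_id, seq = rec
        out[utr_id] = scan_seed_sites(seq, mir, utr_id=utr_id)
    return out


def candidate_targets(
    fc_wt: ContrastResult,
    universe: GeneSet,
    repression_threshold: float = 0.5,
    alpha: float | None = None,
) -> GeneSet:
    """Repression filter: universe members down-regulated on WT activation.

    Keeps universe members with FC <= ``repression_threshold`` in the WT
    activated-vs-resting contrast; an optional adjusted-p filter is applied
    when ``alpha`` is given.  An empty intersection is a warning, not an error.
    """
    if len(universe) == 0:
        raise ValueError("candidate universe is empty")
    probes = universe.match(fc_wt.table.index)
    fc = fc_wt.fc.loc[probes]
    mask = fc <= repression_threshold
    if alpha is not None:
        mask &= fc_wt.p_adj.loc[probes] < alpha
    members = fc.index[mask].tolist()
    return GeneSet(name="candidate-targets", members=members, direction="down")


def reinduction_filter(
    candidates: GeneSet,
    fc_cross: ContrastResult,
    top_threshold: float = 2.0,
) -> tuple[GeneSet, GeneSet, float]:
    """De-repression filter on the KO-M1 vs WT-M1 contrast.

    Returns (reinduced: FC > 1, top: FC >= top_threshold, fraction_reinduced).
    """
    probes = candidates.match(fc_cross.table.index)
    fc = fc_cross.fc.loc[probes]
    reinduced = GeneSet(name="re-induced", members=fc.index[fc > 1.0].tolist())
    top = GeneSet(name=f"top (FC>={top_threshold})", members=fc.index[fc >= top_threshold].tolist())
    fraction = len(reinduced) / len(probes) if probes else float("nan")
    return reinduced, top, fraction


def correlate_with_mir(
    matrix: ExpressionMatrix,
    mir_vector,
    genes: GeneSet | list[str],
) -> pd.DataFrame:
    """Pearson correlation of each gene's expression with the miRNA, plus p.

    The two-tailed p comes from t = R*sqrt(n-2)/sqrt(1-R^2) with df = n-2.
    Genes with zero expression variance get NaN and a ``degenerate`` flag.
    """
    mir = np.asarray(mir_vector, dtype=float)
    if mir.size != matrix.shape[1]:
        raise ValueError(
            f"miRNA vector length {mir.size} does not match {matrix.shape[1]} samples"
        )
    n = mir.size
    if n < 3:
        raise ValueError("need >=3 samples for a correlation p-value")
    members = genes.members if isinstance(genes, GeneSet) else list(genes)
    probes = [g for g in members if g in matrix.probe_ids]
    expr = matrix.values.loc[probes].to_numpy(dtype=float)

    mir_c = mir - mir.mean()
    expr_c = expr - expr.mean(axis=1, keepdims=True)
    denom = np.sqrt((expr_c**2).sum(axis=1) * (mir_c**2).sum())
    degenerate = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (expr_c @ mir_c) / denom
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(t) & ~degenerate] = 0.0  # |R| == 1 exactly
    r[degenerate] = np.nan
    p[degenerate] = np.nan
    return pd.DataFrame(
        {"r": r, "p": p, "degenerate": degenerate}, index=pd.Index(probes, name="probe_id")
    )


def build_target_report(
    top: GeneSet,
    correlations: pd.DataFrame,
    fc_wt: ContrastResult,
    fc_cross: ContrastResult,
    fc_ko: ContrastResult,
    symbols: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assemble the final per-target report, sorted by ascending correlation R.

    One row per top-set gene: symbol, Pearson R and p against the miRNA, then
    FC and p for WT-M1 vs WT-M0, KO-M1 vs WT-M1 and KO-M1 vs KO-M0.  The number
    of rows significantly inversely correlated at ``alpha`` is attached as
    ``report.attrs['n_significant']``.
    """
    rows = []
    for gene in top:
        rows.append(
            {
                "probe_id": gene,
                "gene_symbol": symbols.get(gene, gene) if symbols is not None else gene,
                "r": correlations["r"].get(gene, np.nan),
                "r_p": correlations["p"].get(gene, np.nan),
                "fc_wt_m1_vs_wt_m0": fc_wt.fc.get(gene, np.nan),
                "p_wt_m1_vs_wt_m0": fc_wt.p_raw.get(gene, np.nan),
                "fc_ko_m1_vs_wt_m1": fc_cross.fc.get(gene, np.nan),
                "p_ko_m1_vs_wt_m1": fc_cross.p_raw.get(gene, np.nan),
                "fc_ko_m1_vs_ko_m0": fc_ko.fc.get(gene, np.nan),
                "p_ko_m1_vs_ko_m0": fc_ko.p_raw.get(gene, np.nan),
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "probe_id", "gene_symbol", "r", "r_p",
            "fc_wt_m1_vs_wt_m0", "p_wt_m1_vs_wt_m0",
            "fc_ko_m1_vs_wt_m1", "p_ko_m1_vs_wt_m1",
            "fc_ko_m1_vs_ko_m0", "p_ko_m1_vs_ko_m0",
        ],
    ).set_index("probe_id")
    report = report.sort_values("r", ascending=True)
    report.attrs["n_significant"] = int(((report["r"] < 0) & (report["r_p"] < alpha)).sum())
    return report


def count_significant_inverse(r, p, alpha: float = 0.05) -> int:
    """How many (R, p) pairs are significantly inversely correlated at alpha."""
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    return int(((r < 0) & (p < alpha)).sum())
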