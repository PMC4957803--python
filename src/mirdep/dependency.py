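"""Partition an activation signature by its behaviour in the knockout.

The central question: which part of the wild-type activation signature still
changes when the miRNA is absent?  A signature gene whose knockout fold change
collapses into the 2FC band is *dependent* on the miRNA; one that still crosses
the threshold but moves less than in the wild type is *attenuated*; the rest are
*independent*.  A power-law trend y = a * x**b fitted to the KO-vs-WT fold-change
scatter summarises the genome-wide dampening (b = 1 means no dampening, b = 0
means complete loss of the response).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneSet
from .differential import ContrastResult, Signature

DEPENDENT = "dependent"
ATTENUATED = "attenuated"
INDEPENDENT = "independent"


@dataclass
class DependencyPartition:
    """Per-gene dependency labels plus the summary percentages.

    ``table`` columns: direction (up/down), fc_wt, fc_ko, ratio (fc_ko/fc_wt),
    label (dependent/attenuated/independent).
    """

    table: pd.DataFrame
    pct_up_dependent: float
    pct_down_dependent: float
    pct_overall_dependent: float
    up_threshold: float
    down_threshold: float

    def members(self, label: str, direction: str | None = None) -> list[str]:
        mask = self.table["label"] == label
        if direction is not None:
            mask &= self.table["direction"] == direction
        return self.table.index[mask].tolist()

    def counts(self) -> pd.Series:
        return self.table["label"].value_counts()

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t")


def classify_dependency(
    signature: Signature,
    fc_wt: ContrastResult,
    fc_ko: ContrastResult,
    up_threshold: float = 2.0,
    down_threshold: float = 0.5,
) -> DependencyPartition:
    """Label every signature gene dependent / attenuated / independent.

    dependent:   KO fold change strictly inside (down_threshold, up_threshold) —
                 the gene no longer responds in the knockout.
    attenuated:  KO fold change still beyond the threshold, but smaller in
                 magnitude than the WT fold change (ratio < 1 for up genes,
                 > 1 for down genes).
    independent: the KO response is as large as (or larger than) the WT one.
    """
    rows = []
    for direction, gene_set in (("up", signature.up), ("down", signature.down)):
        for gene in gene_set:
            missing = [
                c.label for c in (fc_wt, fc_ko) if gene not in c.table.index
            ]
            if missing:
                raise KeyError(f"signature gene {gene!r} missing from contrast(s): {missing}")
            wt = float(fc_wt.fc.loc[gene])
            ko = float(fc_ko.fc.loc[gene])
            ratio = ko / wt
            if down_threshold < ko < up_threshold:
                label = DEPENDENT
            elif (direction == "up" and ratio < 1.0) or (direction == "down" and ratio > 1.0):
                label = ATTENUATED
            else:
                label = INDEPENDENT
            rows.append((gene, direction, wt, ko, ratio, label))

    table = pd.DataFrame(
        rows, columns=["probe_id", "direction", "fc_wt", "fc_ko", "ratio", "label"]
    ).set_index("probe_id")

    def _pct(direction: str | None) -> float:
        sub = table if direction is None else table[table["direction"] == direction]
        if len(sub) == 0:
            return float("nan")
        return 100.0 * (sub["label"] == DEPENDENT).sum() / len(sub)

    return DependencyPartition(
        table=table,
        pct_up_dependent=_pct("up"),
        pct_down_dependent=_pct("down"),
        pct_overall_dependent=_pct(None),
        up_threshold=up_threshold,
        down_threshold=down_threshold,
    )


def compile_affected_list(
    fc_wt: ContrastResult,
    fc_ko: ContrastResult,
    fc_cross: ContrastResult,
    up_threshold: float = 2.0,
    down_threshold: float = 0.5,
) -> GeneSet:
    """Compile the miRNA-affected gene list from three contrasts.

    Criterion 1: responds in WT (FC >= up or <= down in WT-M1 vs WT-M0) but not
    in KO (KO FC inside the band).  Criterion 2: differs directly between the
    activated genotypes (|FC| beyond threshold in WT-M1 vs KO-M1).  The result
    is the union, with a provenance tag per gene.
    """
    universe = fc_wt.table.index
    for other in (fc_ko, fc_cross):
        if not universe.equals(other.table.index):
            raise ValueError(
                f"contrasts have mismatched probe universes: {fc_wt.label} vs {other.label}"
            )
    wt = fc_wt.fc.to_numpy()
    ko = fc_ko.fc.reindex(universe).to_numpy()
    cross = fc_cross.fc.reindex(universe).to_numpy()

    responds_wt = (wt >= up_threshold) | (wt <= down_threshold)
    silent_ko = (ko < up_threshold) & (ko > down_threshold)
    crit1 = responds_wt & silent_ko
    crit2 = (cross >= up_threshold) | (cross <= down_threshold)

    members, tags = [], {}
    for probe, c1, c2 in zip(universe, crit1, crit2):
        if c1 or c2:
            members.append(probe)
            tags[probe] = "both" if (c1 and c2) else ("criterion1" if c1 else "criterion2")
    return GeneSet(name="miRNA-affected", members=members, tags=tags)


@dataclass
class PowerLawFit:
    """y = a * x**b fitted by OLS on log2-log2 axes."""

    a: float
    b: float
    r_squared: float
    n: int

    def predict(self, fc_wt) -> np.ndarray:
        return self.a * np.asarray(fc_wt, dtype=float) ** self.b


def fit_fcfc_trend(fc_wt, fc_ko) -> PowerLawFit:
    """Fit the power-law trend of KO fold changes against WT fold changes.

    OLS of log2(fc_ko) on log2(fc_wt); a = 2**intercept, b = slope.  b < 1
    indicates a genome-wide dampening of the activation response in the
    knockout; points exactly on y = x give a = b = 1.
    """
    x = np.asarray(fc_wt, dtype=float)
    y = np.asarray(fc_ko, dtype=float)
    if x.shape != y.shape:
        raise ValueError("fc_wt and fc_ko must be paired vectors of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 points for a trend fit, got {x.size}")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("fold changes must be positive")
    lx, ly = np.log2(x), np.log2(y)
    fit = stats.linregress(lx, ly)
    return PowerLawFit(
        a=float(2.0 ** fit.intercept),
        b=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        n=int(x.size),
    )


def marker_panel_report(
    panel: GeneSet,
    fc_wt: ContrastResult,
    fc_ko: ContrastResult,
    partition: DependencyPartition | None = None,
    symbols: pd.Series | None = None,
) -> pd.DataFrame:
    """Report a marker panel's WT and KO fold changes on the FC-FC plane.

    A gene above the y = x line (fc_ko > fc_wt) is less induced-suppressed in
    the knockout — for an M2 marker panel this flags markers whose silencing
    under inflammatory stimulation requires the miRNA.  Panel entries are
    matched case-insensitively against probe ids and, when provided, symbols.
    """
    index = fc_wt.table.index
    matched = set(panel.match(index))
    if symbols is not None:
        wanted = {m.lower() for m in panel.members}
        matched |= {p for p, sym in symbols.items() if str(sym).lower() in wanted and p in index}
    if not matched:
        raise KeyError(f"no gene of panel {panel.name!r} found in the contrasts")
    probes = [p for p in index if p in matched]
    wt = fc_wt.fc.loc[probes]
    ko = fc_ko.fc.reindex(probes)
    report = pd.DataFrame(
        {
            "gene_symbol": symbols.reindex(probes) if symbols is not None else probes,
            "fc_wt": wt,
            "fc_ko": ko,
            "above_line": ko.to_numpy() > wt.to_numpy(),
        },
        index=pd.Index(probes, name="probe_id"),
    )
    if partition is not None:
        report["dependency"] = partition.table["label"].reindex(probes)
    return report
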