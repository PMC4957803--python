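"""Relative quantification of qPCR Ct data.

Two routes, chosen by whether the target and reference amplification
efficiencies are comparable: the comparative-Ct (2^-ddCt) method, and the
standard-curve method (absolute quantities interpolated per gene from a
log10-dilution curve, then target/reference ratios).  Both normalise to a
reference gene (e.g. Hprt for mRNA, sno202 for small RNA) and to an explicit
calibrator sample or group.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

#: slope of a 100%-efficiency standard curve: Ct falls by log2(10) per decade
PERFECT_SLOPE = -1.0 / np.log10(2.0)


@dataclass
class CtTable:
    """Long-format Ct measurements: one row per (sample, gene)."""

    data: pd.DataFrame  # columns: sample_id, gene, ct
    reference_gene: str

    def __post_init__(self) -> None:
        required = {"sample_id", "gene", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing column(s) {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive cycle counts")
        have_ref = set(self.data.loc[self.data["gene"] == self.reference_gene, "sample_id"])
        all_samples = set(self.data["sample_id"])
        if have_ref != all_samples:
            missing_samples = sorted(all_samples - have_ref)
            raise ValueError(
                f"reference gene {self.reference_gene!r} missing for sample(s) {missing_samples}"
            )

    @classmethod
    def from_csv(cls, path: str | Path, reference_gene: str) -> "CtTable":
        return cls(data=pd.read_csv(path), reference_gene=reference_gene)

    def ct_of(self, gene: str) -> pd.Series:
        sub = self.data[self.data["gene"] == gene]
        return sub.set_index("sample_id")["ct"].astype(float)


@dataclass
class StandardCurve:
    """Fitted dilution curve: Ct = slope * log10(quantity) + intercept."""

    slope: float
    intercept: float
    log10_quantities: np.ndarray
    cts: np.ndarray

    @classmethod
    def fit(cls, log10_quantities, cts) -> "StandardCurve":
        q = np.asarray(log10_quantities, dtype=float)
        c = np.asarray(cts, dtype=float)
        if q.size < 3:
            raise ValueError("a standard curve needs >=3 dilution points")
        res = stats.linregress(q, c)
        if res.slope >= 0:
            raise ValueError("standard-curve slope must be negative (Ct falls with input)")
        return cls(slope=float(res.slope), intercept=float(res.intercept),
                   log10_quantities=q, cts=c)

    @property
    def efficiency(self) -> float:
        """Amplification efficiency; 1.0 means perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def quantity(self, ct) -> np.ndarray:
        return 10.0 ** ((np.asarray(ct, dtype=float) - self.intercept) / self.slope)


def efficiencies_comparable(curve_a: StandardCurve, curve_b: StandardCurve,
                            tolerance: float = 0.05) -> bool:
    """Whether two curves' efficiencies differ by less than ``tolerance``."""
    return abs(curve_a.efficiency - curve_b.efficiency) < tolerance


def _calibrator_samples(ct: CtTable, calibrator) -> list[str]:
    samples = [calibrator] if isinstance(calibrator, str) else list(calibrator)
    known = set(ct.data["sample_id"])
    missing = [s for s in samples if s not in known]
    if missing:
        raise KeyError(f"calibrator sample(s) not in Ct table: {missing}")
    return samples


def ddct_quantify(ct: CtTable, target_gene: str, calibrator) -> pd.Series:
    """Relative quantity per sample by the comparative-Ct method.

    dCt = Ct_target - Ct_reference per sample; ddCt = dCt - mean dCt of the
    calibrator sample(s); RQ = 2^-ddCt.  A single calibrator sample gets RQ = 1
    exactly.
    """
    target = ct.ct_of(target_gene)
    ref = ct.ct_of(ct.reference_gene)
    missing = [s for s in ref.index if s not in target.index]
    if missing:
        raise ValueError(f"target gene {target_gene!r} has no Ct for sample(s) {missing}")
    dct = target - ref.reindex(target.index)
    cal = _calibrator_samples(ct, calibrator)
    ddct = dct - dct.loc[cal].mean()
    return np.exp2(-ddct).rename("rq")


def standard_curve_quantify(
    ct: CtTable,
    target_gene: str,
    curves: dict[str, StandardCurve],
    calibrator,
    extrapolation_margin: float = 1.0,
) -> pd.Series:
    """Relative quantity per sample by the standard-curve method.

    Each gene's Ct is converted to an input quantity through its own curve;
    the target quantity is divided by the reference-gene quantity per sample
    and normalised to the calibrator mean ratio.  Cts falling outside a curve's
    fitted range by more than ``extrapolation_margin`` cycles are flagged via
    ``result.attrs['extrapolated']``.
    """
    for gene in (target_gene, ct.reference_gene):
        if gene not in curves:
            raise KeyError(f"no standard curve for gene {gene!r}")
    target = ct.ct_of(target_gene)
    ref = ct.ct_of(ct.reference_gene).reindex(target.index)

    extrapolated: list[str] = []
    for gene, series in ((target_gene, target), (ct.reference_gene, ref)):
        lo, hi = curves[gene].cts.min(), curves[gene].cts.max()
        out = (series < lo - extrapolation_margin) | (series > hi + extrapolation_margin)
        extrapolated += [f"{gene}:{s}" for s in series.index[out]]

    ratio = pd.Series(
        curves[target_gene].quantity(target) / curves[ct.reference_gene].quantity(ref),
        index=target.index,
    )
    cal = _calibrator_samples(ct, calibrator)
    result = (ratio / ratio.loc[cal].mean()).rename("rq")
    result.attrs["extrapolated"] = extrapolated
    return result


def percent_of_condition(
    rq: pd.Series,
    groups: pd.Series,
    reference_condition: str,
) -> pd.DataFrame:
    """Express group means as a percentage of a reference condition's mean.

    Returns per-group mean percentage and SEM, both scaled by the same factor
    (100 / reference mean).  The reference group itself reads 100.
    """
    groups = groups.reindex(rq.index)
    if reference_condition not in set(groups):
        raise KeyError(f"reference condition {reference_condition!r} not among groups")
    stats_ = rq.groupby(groups).agg(["mean", "sem", "count"])
    ref_mean = stats_.loc[reference_condition, "mean"]
    if ref_mean == 0:
        raise ZeroDivisionError("reference condition mean is zero")
    scale = 100.0 / ref_mean
    return pd.DataFrame(
        {
            "percent": stats_["mean"] * scale,
            "sem": stats_["sem"] * scale,
            "n": stats_["count"].astype(int),
        }
    )


def summarize_rq(rq: pd.Series, groups: pd.Series) -> pd.Series:
    """Geometric-mean RQ per group (RQ is ratio-scaled)."""
    return np.exp2(np.log2(rq).groupby(groups.reindex(rq.index)).mean()).rename("rq_geomean")
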