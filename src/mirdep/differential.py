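"""Group contrasts: fold changes, pooled-variance t-tests, BH adjustment, signature calls.

All statistics are computed probe-wise on the log2 scale; fold changes are
reported on the linear scale (FC = 2**(mean_A - mean_B)).  The t-test is the
two-tailed pooled-variance ("equal SD") two-sample test; multiple-testing
correction is Benjamini-Hochberg step-up within each contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

Group = tuple[str, str]  # (genotype, condition)


@dataclass
class ContrastResult:
    """Per-probe statistics of one group contrast (A vs B).

    ``table`` columns: mean_log2_a, mean_log2_b, mev, log2_fc, fc, p_raw, p_adj.
    MEV (mean expression value) is (mean_A + mean_B)/2 in log2 units — the x axis
    of an FC-vs-MEV plot.
    """

    label: str
    table: pd.DataFrame
    n_a: int
    n_b: int

    @property
    def fc(self) -> pd.Series:
        return self.table["fc"]

    @property
    def p_raw(self) -> pd.Series:
        return self.table["p_raw"]

    @property
    def p_adj(self) -> pd.Series:
        return self.table["p_adj"]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t")


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    Sorted ascending, each p_(i) is scaled by m/i, then a cumulative minimum is
    taken from the largest rank down and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def contrast(
    matrix: ExpressionMatrix,
    group_a: Group,
    group_b: Group,
    label: str | None = None,
) -> ContrastResult:
    """Contrast two genotype x condition groups probe-wise.

    FC = 2**(mean_log2_A - mean_log2_B); p from the pooled-variance two-sample
    t-test with df = n_A + n_B - 2; p_adj by BH across all probes of this
    contrast.  Probes with zero pooled variance get p_raw = 1 when the group
    means coincide and p_raw = 0 otherwise, and are flagged in the log.
    """
    samples_a = matrix.group_samples(*group_a)
    samples_b = matrix.group_samples(*group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"each group needs >=2 samples for a p-value; got "
            f"{group_a}={len(samples_a)}, {group_b}={len(samples_b)}"
        )
    if set(samples_a) & set(samples_b):
        raise ValueError("contrast groups must be disjoint")

    a = matrix.values[samples_a].to_numpy(dtype=float)
    b = matrix.values[samples_b].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    diff = mean_a - mean_b

    t_res = stats.ttest_ind(a, b, axis=1, equal_var=True)
    p_raw = np.asarray(t_res.pvalue, dtype=float)

    # degenerate probes: zero pooled variance makes t undefined
    pooled_ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    degenerate = pooled_ss == 0
    if degenerate.any():
        logger.warning("%d probe(s) with zero pooled variance in %s", degenerate.sum(), label)
        p_raw[degenerate] = np.where(diff[degenerate] == 0, 1.0, 0.0)

    table = pd.DataFrame(
        {
            "mean_log2_a": mean_a,
            "mean_log2_b": mean_b,
            "mev": (mean_a + mean_b) / 2.0,
            "log2_fc": diff,
            "fc": np.exp2(diff),
            "p_raw": p_raw,
            "p_adj": adjust_bh(p_raw),
        },
        index=matrix.probe_ids,
    )
    if label is None:
        label = f"{group_a[0]}-{group_a[1]} vs {group_b[0]}-{group_b[1]}"
    return ContrastResult(label=label, table=table, n_a=len(samples_a), n_b=len(samples_b))


@dataclass
class Signature:
    """Up/down gene sets called from one contrast, with the thresholds used."""

    up: GeneSet
    down: GeneSet
    up_threshold: float
    down_threshold: float
    alpha: float
    use_adjusted: bool = True

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)

    def __len__(self) -> int:
        return self.n_up + self.n_down


def call_signature(
    result: ContrastResult,
    up_threshold: float = 2.0,
    down_threshold: float = 0.5,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    inclusive: bool = True,
) -> Signature:
    """Call an up/down signature: FC beyond threshold and p below alpha.

    Threshold comparisons are inclusive by default (FC >= up, FC <= down); the
    p filter uses the BH-adjusted p unless ``use_adjusted=False``.
    """
    if not (up_threshold > 1.0 > down_threshold > 0.0):
        raise ValueError("thresholds must satisfy up > 1 > down > 0")
    fc = result.fc
    p = result.p_adj if use_adjusted else result.p_raw
    if inclusive:
        up_mask = (fc >= up_threshold) & (p < alpha)
        down_mask = (fc <= down_threshold) & (p < alpha)
    else:
        up_mask = (fc > up_threshold) & (p < alpha)
        down_mask = (fc < down_threshold) & (p < alpha)
    up = GeneSet(name=f"{result.label} up", members=fc.index[up_mask].tolist(), direction="up")
    down = GeneSet(name=f"{result.label} down", members=fc.index[down_mask].tolist(), direction="down")
    return Signature(
        up=up,
        down=down,
        up_threshold=up_threshold,
        down_threshold=down_threshold,
        alpha=alpha,
        use_adjusted=use_adjusted,
    )
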