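"""Config-driven end-to-end run: contrasts -> signature -> dependency ->
target screen -> clustering, with a reproducibility manifest.

Every threshold the analysis uses (2FC, 0.5FC, alpha, re-induction cut) is a
named config key; nothing is hard-coded downstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .core_io import (
    ExpressionMatrix,
    GeneSet,
    join_sample_sheet,
    read_expression,
    read_gene_set,
    read_sample_sheet,
)
from .differential import contrast, call_signature
from .dependency import classify_dependency, compile_affected_list, fit_fcfc_trend
from .clustering import cluster_samples
from .target_screen import (
    MatureMiRNA,
    build_target_report,
    candidate_targets,
    correlate_with_mir,
    reinduction_filter,
    scan_utr_fasta,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and thresholds of one pipeline run."""

    expression: list[str]  # one matrix, or several to column-join
    sample_sheet: str
    utr_fasta: str | None = None
    target_list: str | None = None
    mir_name: str = "miRNA"
    mir_sequence: str | None = None
    mir_probe: str | None = None  # probe id carrying the miRNA's expression
    mir_expression: str | None = None  # CSV sample_id,value
    up_fc: float = 2.0
    down_fc: float = 0.5
    alpha: float = 0.05
    top_threshold: float = 2.0
    use_adjusted_p: bool = True
    cluster_metric: str = "correlation"
    cluster_linkage: str = "average"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        expr = raw.get("expression")
        if isinstance(expr, str):
            raw["expression"] = [expr]
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _load_matrix(config: RunConfig) -> ExpressionMatrix:
    matrices = [read_expression(p) for p in config.expression]
    if len(matrices) == 1:
        matrix = matrices[0]
    else:
        # column-join matrices sharing a probe universe (e.g. per-genotype series)
        common = matrices[0].values.index
        for m in matrices[1:]:
            common = common.intersection(m.values.index)
        values = pd.concat([m.values.loc[common] for m in matrices], axis=1)
        symbols = matrices[0].gene_symbols
        matrix = ExpressionMatrix(
            values=values, gene_symbols=symbols.loc[common] if symbols is not None else None
        )
    sheet = read_sample_sheet(config.sample_sheet)
    return join_sample_sheet(matrix, sheet)


def _mir_vector(config: RunConfig, matrix: ExpressionMatrix):
    if config.mir_probe is not None:
        if config.mir_probe not in matrix.probe_ids:
            raise KeyError(f"mir_probe {config.mir_probe!r} not in the matrix")
        return matrix.values.loc[config.mir_probe]
    if config.mir_expression is not None:
        vec = pd.read_csv(config.mir_expression, index_col=0).iloc[:, 0]
        return vec.reindex(matrix.sample_ids)
    return None


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full analysis; writes outputs under ``out_dir``, returns summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    current_stage = "setup"

    def _stage(name):
        nonlocal current_stage
        current_stage = name
        logger.info("[%7.2fs] stage: %s", time.time() - t0, name)

    summary: dict = {}
    try:
        _stage("load")
        matrix = _load_matrix(config)
        summary["n_probes"], summary["n_samples"] = matrix.shape
        summary["sources"] = "column-joined" if len(config.expression) > 1 else "single-matrix"

        _stage("contrasts")
        fc_wt = contrast(matrix, ("WT", "M1"), ("WT", "M0"))
        fc_ko = contrast(matrix, ("KO", "M1"), ("KO", "M0"))
        fc_cross_ko = contrast(matrix, ("KO", "M1"), ("WT", "M1"))  # re-induction axis
        fc_cross_wt = contrast(matrix, ("WT", "M1"), ("KO", "M1"))
        for res, stem in (
            (fc_wt, "contrast_wt_m1_vs_wt_m0"),
            (fc_ko, "contrast_ko_m1_vs_ko_m0"),
            (fc_cross_ko, "contrast_ko_m1_vs_wt_m1"),
        ):
            res.to_tsv(out / f"{stem}.tsv")

        _stage("signature")
        signature = call_signature(
            fc_wt,
            up_threshold=config.up_fc,
            down_threshold=config.down_fc,
            alpha=config.alpha,
            use_adjusted=config.use_adjusted_p,
        )
        summary["signature"] = {"n_up": signature.n_up, "n_down": signature.n_down}
        (out / "signature_up.txt").write_text("\n".join(signature.up.members) + "\n")
        (out / "signature_down.txt").write_text("\n".join(signature.down.members) + "\n")

        _stage("dependency")
        partition = classify_dependency(
            signature, fc_wt, fc_ko, up_threshold=config.up_fc, down_threshold=config.down_fc
        )
        partition.to_tsv(out / "dependency_partition.tsv")
        trend = fit_fcfc_trend(fc_wt.fc, fc_ko.fc)
        affected = compile_affected_list(
            fc_wt, fc_ko, fc_cross_wt, up_threshold=config.up_fc, down_threshold=config.down_fc
        )
        (out / "affected_genes.txt").write_text(
            "".join(f"{g}\t{affected.tags[g]}\n" for g in affected.members)
        )
        summary["dependency"] = {
            "pct_up_dependent": partition.pct_up_dependent,
            "pct_down_dependent": partition.pct_down_dependent,
            "pct_overall_dependent": partition.pct_overall_dependent,
            "n_affected": len(affected),
        }
        summary["trend"] = {"a": trend.a, "b": trend.b, "r_squared": trend.r_squared}

        _stage("target screen")
        universe = None
        if config.utr_fasta is not None:
            from Bio import SeqIO

            mir = MatureMiRNA(name=config.mir_name, sequence=config.mir_sequence)
            hits = scan_utr_fasta(SeqIO.parse(config.utr_fasta, "fasta"), mir)
            universe = GeneSet(
                name="seed-site universe", members=[g for g, s in hits.items() if s]
            )
            summary["screen_mode"] = "seed-scan"
        elif config.target_list is not None:
            universe = read_gene_set(config.target_list, name="user target list")
            summary["screen_mode"] = "user-list"

        if universe is not None:
            candidates = candidate_targets(fc_wt, universe, repression_threshold=config.down_fc)
            reinduced, top, frac = reinduction_filter(
                candidates, fc_cross_ko, top_threshold=config.top_threshold
            )
            mir_vec = _mir_vector(config, matrix)
            if mir_vec is not None:
                correlations = correlate_with_mir(matrix, mir_vec, top)
            else:
                correlations = pd.DataFrame(
                    {"r": float("nan"), "p": float("nan")}, index=pd.Index(top.members)
                )
            report = build_target_report(
                top, correlations, fc_wt, fc_cross_ko, fc_ko,
                symbols=matrix.gene_symbols, alpha=config.alpha,
            )
            report.to_csv(out / "target_report.tsv", sep="\t")
            summary["targets"] = {
                "n_universe": len(universe),
                "n_candidates": len(candidates),
                "fraction_reinduced": frac,
                "n_top": len(top),
                "n_significant_inverse": report.attrs["n_significant"],
            }
            panel = list(dict.fromkeys(partition.members(label="dependent", direction="up") + top.members))
        else:
            panel = partition.members(label="dependent", direction="up")
            summary["targets"] = None

        _stage("clustering")
        if len(panel) >= 2:
            dendro = cluster_samples(
                matrix, panel, metric=config.cluster_metric, method=config.cluster_linkage
            )
            dendro.to_tsv(out / "linkage.tsv")
            (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
            summary["clustering"] = {"n_panel": len(panel), "leaf_order": dendro.leaf_order()}
        else:
            summary["clustering"] = None

        manifest = {
            "mirdep_version": __version__,
            "config": asdict(config),
            "config_hash": config.digest(),
            "seed": config.seed,
            "elapsed_s": round(time.time() - t0, 3),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    except Exception as exc:  # annotate failures with the stage that raised
        raise RuntimeError(f"pipeline failed at stage {current_stage!r}: {exc}") from exc
    return summary
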