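"""End-to-end orchestration: QC -> signals -> omnibus -> selection -> calls.

``call_cohort`` is the library entry point shared by the CLI and the
benchmark; ``run_pipeline`` adds file I/O around it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allelic as ai
from . import combine, embryo, expression
from . import io as mio

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All caller thresholds with their defaults.

    fdr_level is the nominal FDR controlled at each level of the
    embryo/cell/chromosome tree; effect_threshold gates the expression
    p-value on |1 - s|; the remaining knobs are QC and coverage floors
    documented in their owning modules.
    """

    fdr_level: float = 0.01
    effect_threshold: float = 0.2
    cell_depth_quantile: float = 0.10
    depth_filter_strict: bool = True
    min_median_cpm: float = 50.0
    min_genes: int = 2000
    min_genes_per_chrom: int = 25
    min_reads: int = 20
    min_snps: int = 5
    meiotic_cutoff: float = 0.75
    meiotic_criterion: str = "fraction_75"
    expression_center: float | str = "stratum-median"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")
        if self.effect_threshold < 0:
            raise ValueError("effect_threshold must be >= 0")
        if not 0 < self.cell_depth_quantile <= 0.5:
            raise ValueError("cell_depth_quantile must be in (0, 0.5]")
        if self.meiotic_criterion not in ("fraction_75", "lt2_normal"):
            raise ValueError(f"unknown meiotic_criterion {self.meiotic_criterion!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class CohortResult:
    """Signals, hierarchical selection state and final calls."""

    signals: pd.DataFrame            # one row per tested cell-chromosome
    tree: combine.TreeBHResult
    calls: pd.DataFrame              # rejected leaves with monosomy/trisomy labels
    strata: list = field(default_factory=list)
    qc: dict = field(default_factory=dict)
    config: PipelineConfig = None
    mode: str = "combined"


def build_leaf_ledger(cells: pd.Series | list[str],
                      embryo_of: pd.Series,
                      chromosomes=mio.AUTOSOMES) -> pd.DataFrame:
    """The full hypothesis ledger: every retained cell x every autosome.

    Cell-chromosomes without any usable signal stay in the ledger with
    p = 1 so that the multiplicity burden reflects all tests performed.
    """
    cells = list(cells)
    return pd.DataFrame({
        "cell_id": np.repeat(cells, len(chromosomes)),
        "embryo_id": np.repeat(embryo_of.loc[cells].to_numpy(), len(chromosomes)),
        "chromosome": np.tile(chromosomes, len(cells)),
    })


def call_cohort(counts: pd.DataFrame,
                gene_map: pd.DataFrame,
                meta: pd.DataFrame,
                allelic: pd.DataFrame | None = None,
                *,
                config: PipelineConfig | None = None,
                apply_depth_filter: bool = True,
                mode: str = "combined") -> CohortResult:
    """Run the full caller on an in-memory cohort.

    ``mode`` is "combined" (default), "expression_only" (the leaf
    p-value is then the gated expression p; the allelic table, if given,
    is ignored) or "ai_only" (the leaf p-value is the allelic-imbalance
    p; expression enters only the dosage score columns).
    """
    config = config or PipelineConfig()
    if mode not in ("combined", "expression_only", "ai_only"):
        raise ValueError(f"unknown mode {mode!r}")
    qc: dict = {}

    # --- cell QC and stratification
    if apply_depth_filter:
        retained, removed = mio.filter_cells_by_depth(
            meta, config.cell_depth_quantile, strict=config.depth_filter_strict)
    else:
        retained, removed = list(meta.index), []
    qc["n_cells_in"] = len(meta)
    qc["n_cells_depth_removed"] = len(removed)

    counts = counts[retained]
    cpm = mio.compute_cpm(counts)
    strata = mio.build_strata(meta, retained)
    strata = mio.qc_strata(strata, cpm, config.min_median_cpm, config.min_genes)
    analysis_cells = [c for st in strata if st.passed for c in st.cells]
    qc["n_strata"] = len(strata)
    qc["n_strata_passed"] = sum(s.passed for s in strata)
    qc["n_cells_retained"] = len(analysis_cells)
    if not analysis_cells:
        raise ValueError("no cells retained: every stratum failed QC")

    # --- expression signal
    scores = expression.dosage_scores(cpm, strata, gene_map,
                                      config.min_genes_per_chrom)
    scores = expression.expression_pvalues(scores, center=config.expression_center)
    scores["p_expr_gated"] = combine.gate_expression_p(
        scores["s"], scores["p_expr"], config.effect_threshold)

    # --- allelic signal
    if mode in ("combined", "ai_only") and allelic is not None and len(allelic):
        allelic = allelic[allelic["cell_id"].isin(analysis_cells)]
        ai_obs, null_model = ai.allelic_signal(
            allelic, min_reads=config.min_reads, min_snps=config.min_snps)
        qc["ai_null"] = {"mu": null_model.mu_null, "sigma": null_model.sigma_null,
                         "slope": null_model.slope}
    else:
        ai_obs = pd.DataFrame(columns=["cell_id", "chromosome", "n_snps",
                                       "total_reads", "ai_ratio", "residual",
                                       "z_ai", "p_ai"])

    # --- merge onto the full hypothesis ledger
    ledger = build_leaf_ledger(analysis_cells, meta["embryo_id"])
    signals = (ledger
               .merge(scores, on=["cell_id", "chromosome"], how="left")
               .merge(ai_obs, on=["cell_id", "chromosome"], how="left"))

    if mode == "expression_only":
        signals["p"] = signals["p_expr_gated"].fillna(1.0)
        signals["chi2"] = np.nan
        signals["df"] = np.nan
    elif mode == "ai_only":
        signals["p"] = signals["p_ai"].fillna(1.0)
        signals["chi2"] = np.nan
        signals["df"] = np.nan
    else:
        chi2, p = combine.fisher_combine(signals["p_expr_gated"].to_numpy(),
                                         signals["p_ai"].to_numpy())
        signals["chi2"] = chi2
        signals["df"] = np.where(
            signals["p_expr_gated"].notna() & signals["p_ai"].notna(), 4,
            np.where(signals["p_expr_gated"].notna() | signals["p_ai"].notna(), 2, 0))
        signals["p"] = p
    signals.rename(columns={"p": "p_combined"}, inplace=True)

    # --- hierarchical selection and type assignment
    tree = combine.treebh_select(
        signals[["embryo_id", "cell_id", "chromosome", "p_combined"]]
        .rename(columns={"p_combined": "p"}),
        q=config.fdr_level)
    signals["rejected"] = tree.leaf_table["rejected"].to_numpy()
    rejected = signals[signals["rejected"]].copy()
    if "z_expr" not in rejected.columns:
        rejected["z_expr"] = np.nan
    if "z_ai" not in rejected.columns:
        rejected["z_ai"] = np.nan
    calls = combine.assign_ploidy_type(rejected)
    logger.info("rejected %d embryos / %d cells / %d cell-chromosomes at q=%g",
                *tree.n_rejected, config.fdr_level)
    return CohortResult(signals=signals, tree=tree, calls=calls, strata=strata,
                        qc=qc, config=config, mode=mode)


def run_pipeline(counts_path, gene_map_path, meta_path, allele_path,
                 outdir, config: PipelineConfig | None = None,
                 mode: str = "combined") -> CohortResult:
    """File-based pipeline: read inputs, call, classify, write outputs.

    Writes calls.tsv, signals.tsv, classifications.tsv,
    embryo_summary.tsv, selection_report.json and a config echo.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_file_log(outdir / "pipeline.log")

    data = mio.read_counts(counts_path, gene_map_path, meta_path)
    allelic = mio.read_allele_counts(allele_path) if allele_path else None
    result = call_cohort(data.counts, data.gene_map, data.meta, allelic,
                         config=config, mode=mode)

    meta = data.meta
    analysis_cells = result.signals["cell_id"].unique()
    cells_per_embryo = {e: list(g.index) for e, g in
                        meta.loc[analysis_cells].groupby("embryo_id")}
    calls = result.calls
    classes = embryo.classify_embryo_errors(
        calls, cells_per_embryo, cutoff=config.meiotic_cutoff,
        criterion=config.meiotic_criterion)

    result.signals.to_csv(outdir / "signals.tsv", sep="\t", index=False)
    calls_cols = ["embryo_id", "cell_id", "chromosome", "s", "z_expr", "p_expr",
                  "ai_ratio", "z_ai", "p_ai", "p_combined", "call"]
    calls[[c for c in calls_cols if c in calls.columns]].to_csv(
        outdir / "calls.tsv", sep="\t", index=False)
    embryo.classifications_table(classes).to_csv(
        outdir / "classifications.tsv", sep="\t", index=False)
    embryo.summarize_embryos(calls, cells_per_embryo).to_csv(
        outdir / "embryo_summary.tsv", sep="\t", index=False)

    report = {
        "q": config.fdr_level,
        "levels": {"embryo": result.tree.levels["embryo"],
                   "cell": result.tree.levels["cell"],
                   "leaf": result.tree.levels["leaf"]},
        "n_rejected": dict(zip(("embryos", "cells", "leaves"),
                               result.tree.n_rejected)),
        "n_tests": {"embryos": int(result.tree.embryo_table.shape[0]),
                    "cells": int(result.tree.cell_table.shape[0]),
                    "leaves": int(result.tree.leaf_table.shape[0])},
        "qc": _jsonable(result.qc),
        "mode": mode,
    }
    with open(outdir / "selection_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    config.to_yaml(outdir / "config.yaml")
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _setup_file_log(path) -> None:
    handler = logging.FileHandler(path)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s\t%(name)s\t%(levelname)s\t%(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S%z"))
    root = logging.getLogger("mosaiscan")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
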