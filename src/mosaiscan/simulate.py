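"""Synthetic cohorts with known ploidy truth, and caller benchmarking.

The generator plants whole-chromosome errors of two origins in each
embryo: meiotic errors (a gain or loss present in every cell, planted
with a per-embryo probability) and mitotic errors (planted with a
per-division probability while a binary lineage tree grows to the
requested cell count, inherited by all descendants of the affected
daughter; with some probability the sister lineage receives the
reciprocal event, mimicking mitotic nondisjunction). Stacked events that
would push a chromosome below one or above three copies are skipped.

Conditional on the planted copy numbers the generator emulates both
caller inputs:

* expression counts — negative binomial per gene and cell, with
  log-normal baseline gene means, a log-normal cell size factor, mean
  scaled by copy_number/2, and dispersion scaled by an overdispersion
  factor (0.3 / 1 / 5 span reduced, baseline and inflated variance);
* allele counts — a target min-allele ratio drawn per cell-chromosome
  from a ploidy-state-specific beta distribution (variance scaled by the
  same factor), realized as binomial per-SNP allele counts at Poisson
  SNP depths.

``run_benchmark`` replays the full caller on many replicates, in
combined and expression-only modes, and scores leaf-level calls against
the planted truth.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import AUTOSOMES

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study-design and noise parameters of the synthetic cohort.

    Defaults describe a reduced blastocyst-like cohort: 20 embryos of 8
    cells, a 20% chance of a meiotic error per embryo and a 5% chance of
    a mitotic error per cell division, 140 genes per autosome (about
    3000 sufficiently expressed genes total, matching the scale of a
    passing stratum), and beta allelic-ratio parameters per ploidy state
    (disomy centered near 0.38 rather than the ideal 0.5 because of
    technical reference bias and bursty allele sampling; monosomy near 0,
    trisomy intermediate, reflecting its 2:1 allele dosage).
    """

    n_embryos: int = 20
    cells_per_embryo: int = 8
    meiotic_prob: float = 0.2
    mitotic_prob: float = 0.05
    reciprocal_prob: float = 0.5
    n_chromosomes: int = 22
    genes_per_chromosome: int = 140
    snps_per_chromosome: int = 25
    mean_snp_depth: float = 30.0
    log_mean_expression: float = math.log(100.0)
    log_sd_expression: float = 1.0
    size_factor_sd: float = 0.15
    base_dispersion: float = 0.1
    # (mean, sd) of the min-allele ratio per ploidy state
    disomy_ai: tuple[float, float] = (0.38, 0.06)
    trisomy_ai: tuple[float, float] = (0.28, 0.07)
    monosomy_ai: tuple[float, float] = (0.02, 0.02)
    overdispersion_factors: tuple[float, ...] = (0.3, 1.0, 5.0)
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self):
        for name in ("disomy_ai", "trisomy_ai", "monosomy_ai"):
            m, sd = getattr(self, name)
            if not 0 < m < 0.5:
                raise ValueError(f"{name} mean must be in (0, 0.5)")
            if sd ** 2 >= m * (1 - m):
                raise ValueError(f"{name} variance infeasible for a beta")
        if any(f <= 0 for f in self.overdispersion_factors):
            raise ValueError("overdispersion factors must be > 0")
        if self.genes_per_chromosome <= 0:
            raise ValueError("genes_per_chromosome must be positive")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return AUTOSOMES[: self.n_chromosomes]

    def rng(self, *stream: int) -> np.random.Generator:
        """Derive an independent generator from the config seed and a
        stream path (e.g. replicate index, component id)."""
        return np.random.default_rng([self.seed, *stream])


@dataclass
class SimData:
    """One simulated cohort: caller inputs plus the planted truth."""

    counts: pd.DataFrame        # genes x cells
    gene_map: pd.DataFrame      # gene_id -> chromosome, is_protein_coding
    meta: pd.DataFrame          # cell metadata (single stratum)
    allelic: pd.DataFrame       # per-SNP allele counts
    truth: pd.DataFrame         # embryo_id, cell_id, chromosome, copy_number, origin
    config: SimConfig = None
    overdispersion: float = 1.0


# ---------------------------------------------------------------------------
# ploidy truth


def simulate_ploidy_states(config: SimConfig,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Plant meiotic and lineage-structured mitotic errors.

    Returns one row per (embryo, cell, chromosome) with copy_number in
    {1, 2, 3}, origin in {none, meiotic, mitotic} and, for mitotic
    events, the division at which the error arose.
    """
    chroms = config.chromosomes
    n_chrom = len(chroms)
    records = []
    n_skipped = 0
    for e in range(config.n_embryos):
        embryo_id = f"emb{e:03d}"
        cn0 = np.full(n_chrom, 2, dtype=int)
        origin0 = np.array(["none"] * n_chrom, dtype=object)
        division0 = np.full(n_chrom, -1, dtype=int)
        if rng.random() < config.meiotic_prob:
            c = int(rng.integers(n_chrom))
            delta = 1 if rng.random() < 0.5 else -1
            cn0[c] += delta
            origin0[c] = "meiotic"
        # grow a binary lineage tree to the requested cell count
        cells = [(cn0, origin0, division0)]
        division = 0
        while len(cells) < config.cells_per_embryo:
            cn, origin, div = cells.pop(0)
            child1 = (cn.copy(), origin.copy(), div.copy())
            child2 = (cn.copy(), origin.copy(), div.copy())
            if rng.random() < config.mitotic_prob:
                c = int(rng.integers(n_chrom))
                delta = 1 if rng.random() < 0.5 else -1
                reciprocal = rng.random() < config.reciprocal_prob
                if 1 <= child1[0][c] + delta <= 3:
                    child1[0][c] += delta
                    child1[1][c] = "mitotic"
                    child1[2][c] = division
                else:
                    n_skipped += 1
                if reciprocal:
                    if 1 <= child2[0][c] - delta <= 3:
                        child2[0][c] -= delta
                        child2[1][c] = "mitotic"
                        child2[2][c] = division
                    else:
                        n_skipped += 1
            cells.extend([child1, child2])
            division += 1
        for i, (cn, origin, div) in enumerate(cells):
            cell_id = f"{embryo_id}_c{i:02d}"
            for j, chrom in enumerate(chroms):
                records.append((embryo_id, cell_id, chrom,
                                int(cn[j]), origin[j], int(div[j])))
    if n_skipped:
        logger.info("skipped %d stacked events outside copy numbers 1..3", n_skipped)
    return pd.DataFrame(records, columns=["embryo_id", "cell_id", "chromosome",
                                          "copy_number", "origin", "division"])


# ---------------------------------------------------------------------------
# expression counts


def simulate_expression(truth: pd.DataFrame,
                        config: SimConfig,
                        overdispersion: float,
                        rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts given planted copy numbers.

    Per gene g and cell i the mean is lambda_g * (copy_number/2) * sf_i
    with variance mu + phi * mu^2 and dispersion phi = base_dispersion *
    overdispersion. Returns (counts genes x cells, gene map).
    """
    if config.genes_per_chromosome <= 0:
        raise ValueError("zero genes configured")
    chroms = config.chromosomes
    gene_ids, gene_chrom = [], []
    for chrom in chroms:
        for g in range(config.genes_per_chromosome):
            gene_ids.append(f"g_{chrom}_{g:04d}")
            gene_chrom.append(chrom)
    n_genes = len(gene_ids)

    cn = truth.pivot_table(index="cell_id", columns="chromosome",
                           values="copy_number", sort=False)
    cells = list(cn.index)
    cn = cn[list(chroms)].to_numpy(float)              # cells x chroms
    lam = rng.lognormal(config.log_mean_expression,
                        config.log_sd_expression, size=n_genes)
    sf = rng.lognormal(0.0, config.size_factor_sd, size=len(cells))
    chrom_idx = np.array([chroms.index(c) for c in gene_chrom])
    mu = lam[:, None] * (cn.T[chrom_idx] / 2.0) * sf[None, :]

    phi = config.base_dispersion * overdispersion
    if phi < 1e-8:
        counts = rng.poisson(mu)
    else:
        n_param = 1.0 / phi
        p_param = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p_param)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=cells)
    gene_map = pd.DataFrame({"chromosome": gene_chrom,
                             "is_protein_coding": True},
                            index=pd.Index(gene_ids, name="gene_id"))
    return counts_df, gene_map


# ---------------------------------------------------------------------------
# allele counts


def beta_shapes(mean: float, var: float) -> tuple[float, float]:
    """Moment-matched beta shape parameters for a target mean/variance."""
    if var <= 0 or var >= mean * (1 - mean):
        raise ValueError(f"infeasible beta variance {var} for mean {mean}")
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


def _state_params(config: SimConfig) -> dict[int, tuple[float, float]]:
    return {1: config.monosomy_ai, 2: config.disomy_ai, 3: config.trisomy_ai}


def simulate_allelic(truth: pd.DataFrame,
                     config: SimConfig,
                     overdispersion: float,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Per-SNP allele counts whose chromosome-level min-ratio matches, in
    expectation, a beta draw conditioned on the planted ploidy state.

    The beta describes the distribution of *observed* chromosome-level
    ratios (its parameters are meant to be fitted to real ratios, whose
    dispersion already includes per-SNP sampling noise), so the drawn
    target is realized directly: minor-haplotype reads are allocated to
    each SNP by stochastic rounding of target x depth, which makes the
    expected chromosome min-ratio exactly the target without
    double-counting sampling noise. Beta variances are scaled by the
    overdispersion factor and capped just below the feasibility bound
    m(1-m); draws at or above 0.5 are rejected and redrawn. Per SNP,
    depth is Poisson and the minor haplotype is assigned to ref or alt
    at random.
    """
    params = _state_params(config)
    n = len(truth)
    target = np.empty(n)
    for state, (m, sd) in params.items():
        mask = (truth["copy_number"] == state).to_numpy()
        if not mask.any():
            continue
        var = sd ** 2 * overdispersion
        bound = 0.95 * m * (1 - m)
        if var > bound:
            warnings.warn(f"beta variance for copy number {state} capped at "
                          f"feasibility bound ({var:.4g} -> {bound:.4g})")
            var = bound
        a, b = beta_shapes(m, var)
        k = int(mask.sum())
        draws = rng.beta(a, b, size=k)
        for _ in range(100):  # redraw the rare mass at/above perfect balance
            bad = draws >= 0.5
            if not bad.any():
                break
            draws[bad] = rng.beta(a, b, size=int(bad.sum()))
        target[mask] = np.minimum(draws, 0.4999)

    S = config.snps_per_chromosome
    depth = rng.poisson(config.mean_snp_depth, size=(n, S))
    ideal = target[:, None] * depth
    minor = np.floor(ideal).astype(np.int64)
    minor += (rng.random(size=(n, S)) < ideal - np.floor(ideal)).astype(np.int64)
    minor = np.minimum(minor, depth // 2)  # min(ref, alt) must be the minor side
    minor_is_ref = rng.random(size=(n, S)) < 0.5
    ref = np.where(minor_is_ref, minor, depth - minor)
    alt = depth - ref

    cell = np.repeat(truth["cell_id"].to_numpy(), S)
    chrom = np.repeat(truth["chromosome"].to_numpy(), S)
    pos = np.tile((np.arange(S) + 1) * 1000, n)  # 1-based placeholder coordinates
    out = pd.DataFrame({"cell_id": cell, "chromosome": chrom, "position": pos,
                        "refCount": ref.ravel(), "altCount": alt.ravel()})
    return out[out["refCount"] + out["altCount"] >= 1].reset_index(drop=True)


# ---------------------------------------------------------------------------
# cohort assembly


def simulate_cohort(config: SimConfig,
                    overdispersion: float = 1.0,
                    replicate: int = 0) -> SimData:
    """One full synthetic cohort (deterministic given config + replicate)."""
    truth = simulate_ploidy_states(config, config.rng(replicate, 0))
    counts, gene_map = simulate_expression(truth, config, overdispersion,
                                           config.rng(replicate, 1))
    allelic = simulate_allelic(truth, config, overdispersion,
                               config.rng(replicate, 2))
    meta_rng = config.rng(replicate, 3)
    cells = truth[["embryo_id", "cell_id"]].drop_duplicates()
    meta = pd.DataFrame({
        "embryo_id": cells["embryo_id"].to_numpy(),
        "stage": 5,
        "cell_type": "blastomere",
        "mapped_reads": counts[cells["cell_id"]].sum(axis=0).to_numpy(),
        "pct_mapped": meta_rng.uniform(0.7, 0.9, size=len(cells)),
    }, index=pd.Index(cells["cell_id"], name="cell_id"))
    return SimData(counts=counts, gene_map=gene_map, meta=meta,
                   allelic=allelic, truth=truth, config=config,
                   overdispersion=overdispersion)


def write_cohort(data: SimData, outdir) -> None:
    """Write a cohort to disk (MTX counts + TSV sidecars, allele counts,
    metadata, truth, config echo)."""
    from pathlib import Path

    import scipy.io
    import scipy.sparse
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "counts.mtx",
                     scipy.sparse.csr_matrix(data.counts.to_numpy()))
    data.counts.index.to_series().to_csv(outdir / "genes.tsv", sep="\t",
                                         header=False, index=False)
    pd.Series(data.counts.columns).to_csv(outdir / "cells.tsv", sep="\t",
                                          header=False, index=False)
    data.gene_map.reset_index().to_csv(outdir / "gene_map.tsv", sep="\t", index=False)
    data.meta.reset_index().to_csv(outdir / "cell_meta.tsv", sep="\t", index=False)
    al = data.allelic.rename(columns={"chromosome": "contig"})
    al.to_csv(outdir / "allele_counts.tsv", sep="\t", index=False)
    data.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(data.config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# parameter estimation from called data


DEFAULT_AI_PARAMS = {1: (0.02, 0.02), 2: (0.38, 0.06), 3: (0.28, 0.07)}


def estimate_sim_params(ai_obs: pd.DataFrame,
                        states: pd.Series,
                        min_n: int = 30,
                        out_path=None) -> dict[int, tuple[float, float]]:
    """Method-of-moments beta (mean, sd) of the min-allele ratio per
    ploidy state, for re-parameterizing the generator from called data.

    ``states`` maps the rows of ``ai_obs`` to copy numbers. States with
    fewer than ``min_n`` observations fall back to defaults (logged);
    zero variance within a state is an error. With ``out_path`` the
    estimates are also written to a reusable YAML parameter file.
    """
    out: dict[int, tuple[float, float]] = {}
    ratios = ai_obs["ai_ratio"].to_numpy(float)
    for state in (1, 2, 3):
        vals = ratios[states.to_numpy() == state]
        if len(vals) < min_n:
            logger.warning("ploidy state %d has %d < %d observations; "
                           "using defaults", state, len(vals), min_n)
            out[state] = DEFAULT_AI_PARAMS[state]
            continue
        var = float(np.var(vals, ddof=1))
        if var == 0:
            raise ValueError(f"degenerate (constant) ratios for state {state}")
        out[state] = (float(np.mean(vals)), math.sqrt(var))
    if out_path is not None:
        import yaml
        payload = {f"copy_number_{state}": {"mean": m, "sd": sd}
                   for state, (m, sd) in out.items()}
        with open(out_path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# benchmarking


@dataclass
class BenchmarkResult:
    """Leaf-level performance per (overdispersion, mode), aggregated over
    replicates (per-replicate values retained)."""

    per_replicate: pd.DataFrame
    summary: pd.DataFrame


def score_calls(leaf_table: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Confusion counts of rejected leaves against planted copy numbers."""
    merged = leaf_table.merge(
        truth[["cell_id", "chromosome", "copy_number"]],
        on=["cell_id", "chromosome"], how="left")
    pos = merged["copy_number"].to_numpy() != 2
    rej = merged["rejected"].to_numpy(bool)
    tp = int(np.sum(rej & pos))
    fp = int(np.sum(rej & ~pos))
    fn = int(np.sum(~rej & pos))
    tn = int(np.sum(~rej & ~pos))
    return {
        "TP": tp, "FP": fp, "FN": fn, "TN": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "precision": tp / (tp + fp) if tp + fp else np.nan,
    }


def false_discovery_proportions(tree, truth: pd.DataFrame) -> dict[str, float]:
    """Realized false discovery proportion at each tree level.

    A selected embryo/cell is a false discovery when the truth table has
    no aneuploid chromosome anywhere in it; a selected leaf when its own
    copy number is 2. The proportion is 0 when nothing is selected.
    """
    tl = tree.leaf_table.merge(truth[["cell_id", "chromosome", "copy_number"]],
                               on=["cell_id", "chromosome"], how="left")
    tl["pos"] = tl["copy_number"].to_numpy() != 2
    rej = tl[tl["rejected"]]
    fdp_leaf = 0.0 if rej.empty else float((~rej["pos"]).mean())

    cell_pos = tl.groupby(["embryo_id", "cell_id"])["pos"].any()
    sel_cells = tree.cell_table[tree.cell_table["rejected"]]
    fdp_cell = 0.0 if sel_cells.empty else float(np.mean(
        [not cell_pos.loc[(e, c)]
         for e, c in sel_cells[["embryo_id", "cell_id"]].to_numpy()]))

    emb_pos = tl.groupby("embryo_id")["pos"].any()
    sel_emb = tree.embryo_table[tree.embryo_table["rejected"]]
    fdp_embryo = 0.0 if sel_emb.empty else float(np.mean(
        [not emb_pos.loc[e] for e in sel_emb["embryo_id"]]))
    return {"embryo": fdp_embryo, "cell": fdp_cell, "leaf": fdp_leaf}


def run_benchmark(config: SimConfig,
                  q: float = 0.01,
                  modes: tuple[str, ...] = ("expression_only", "combined"),
                  overdispersion_factors: tuple[float, ...] | None = None,
                  n_replicates: int | None = None) -> BenchmarkResult:
    """Simulate, call (both modes at matched nominal FDR) and score.

    Signals are computed once per replicate and the hierarchical
    selection re-run per mode on the appropriate leaf p-values.
    """
    from .pipeline import call_cohort, PipelineConfig

    factors = overdispersion_factors or config.overdispersion_factors
    n_rep = n_replicates or config.n_replicates
    pconf = PipelineConfig(fdr_level=q, min_genes=0)
    rows = []
    for od in factors:
        for rep in range(n_rep):
            data = simulate_cohort(config, overdispersion=od, replicate=rep)
            for mode in modes:
                res = call_cohort(data.counts, data.gene_map, data.meta,
                                  data.allelic, config=pconf,
                                  apply_depth_filter=False, mode=mode)
                rows.append({"overdispersion": od, "mode": mode, "replicate": rep,
                             **score_calls(res.tree.leaf_table, data.truth)})
    per_rep = pd.DataFrame(rows)
    summary = (per_rep.groupby(["overdispersion", "mode"])
               [["sensitivity", "specificity", "precision", "TP", "FP", "FN", "TN"]]
               .mean().reset_index())
    return BenchmarkResult(per_replicate=per_rep, summary=summary)
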