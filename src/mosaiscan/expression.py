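"""Chromosome-wide expression dosage signal.

For each cell i and autosome j within a stratum we compute a dosage
score s_ij with null expectation 1 (about 0.5 under monosomy and 1.5
under trisomy): each gene's CPM in cell i is divided by its
leave-one-out mean over the other cells of the stratum, and s_ij is the
median of these ratios over the genes on chromosome j. The score is
converted to a robust Z-statistic using a per-stratum, per-chromosome
MAD scale, and to a two-sided normal p-value.

The null center of the Z-statistic defaults to the stratum-wide median
of s pooled over all chromosomes, which absorbs the small downward bias
of a median of right-skewed count ratios while remaining robust to
strata in which many cells share a single-chromosome (meiotic)
aneuploidy; pass ``center=1.0`` for the fixed theoretical center.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import AUTOSOMES, Stratum

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # keeps log p finite for Fisher combination
MAD_TO_SD = 1.4826  # consistency constant for normal data


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each cell's counts to sum to one million.

    Raises if any cell has zero total counts (naming the cell).
    """
    totals = counts.sum(axis=0)
    zero = totals.index[totals.to_numpy() == 0]
    if len(zero):
        raise ValueError(f"cell {zero[0]!r} has zero total counts")
    return counts.div(totals, axis=1) * 1e6


def dosage_scores(cpm: pd.DataFrame,
                  strata: list[Stratum],
                  gene_map: pd.DataFrame,
                  min_genes_per_chrom: int = 25) -> pd.DataFrame:
    """Per-cell, per-chromosome dosage scores within each passing stratum.

    Returns a long table (cell_id, chromosome, stratum_id, s, n_genes).
    Chromosomes with fewer than ``min_genes_per_chrom`` usable genes in a
    stratum are marked missing (no row emitted).
    """
    records: list[pd.DataFrame] = []
    chrom_of = gene_map["chromosome"]
    for st in strata:
        if not st.passed:
            continue
        cells = st.cells
        genes = [g for g in st.genes if g in chrom_of.index]
        if len(cells) < 2 or not genes:
            continue
        X = cpm.loc[genes, cells].to_numpy(float)
        n = len(cells)
        # leave-one-out mean of each gene over the stratum's other cells
        loo = (X.sum(axis=1, keepdims=True) - X) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(loo > 0, X / loo, np.nan)
        chroms = chrom_of.loc[genes].to_numpy()
        for chrom in AUTOSOMES:
            rows = np.flatnonzero(chroms == chrom)
            if rows.size == 0:
                continue
            r = ratio[rows]
            n_valid = np.sum(~np.isnan(r), axis=0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                s = np.nanmedian(r, axis=0)
            ok = n_valid >= min_genes_per_chrom
            if not ok.any():
                logger.debug("stratum %s: chromosome %s has < %d usable genes",
                             st.stratum_id, chrom, min_genes_per_chrom)
                continue
            records.append(pd.DataFrame({
                "cell_id": np.asarray(cells)[ok],
                "chromosome": chrom,
                "stratum_id": st.stratum_id,
                "s": s[ok],
                "n_genes": n_valid[ok],
            }))
    if not records:
        return pd.DataFrame(columns=["cell_id", "chromosome", "stratum_id",
                                     "s", "n_genes"])
    return pd.concat(records, ignore_index=True)


def expression_pvalues(scores: pd.DataFrame,
                       center: float | str = "stratum-median",
                       min_cells: int = 5) -> pd.DataFrame:
    """Add robust Z-statistics and two-sided p-values to a dosage table.

    The scale for chromosome j is 1.4826 x MAD of {s_ij} over the
    stratum's cells. ``center`` is either a fixed null value (e.g. 1.0)
    or ``"stratum-median"`` (default, see module docstring). Degenerate
    chromosomes (zero MAD or < ``min_cells`` cells) get p = 1.
    """
    scores = scores.copy()
    z = np.full(len(scores), np.nan)
    p = np.ones(len(scores))
    for sid, stratum_rows in scores.groupby("stratum_id").groups.items():
        s_all = scores.loc[stratum_rows, "s"].to_numpy(float)
        if center == "stratum-median":
            c = float(np.median(s_all))
        else:
            c = float(center)
        sub = scores.loc[stratum_rows]
        for chrom, rows in sub.groupby("chromosome").groups.items():
            vals = scores.loc[rows, "s"].to_numpy(float)
            idx = scores.index.get_indexer(rows)
            if len(vals) < min_cells:
                warnings.warn(f"stratum {sid} chromosome {chrom}: "
                              f"{len(vals)} < {min_cells} cells; p set to 1")
                continue
            mad = np.median(np.abs(vals - np.median(vals)))
            sigma = MAD_TO_SD * mad
            if sigma == 0:
                warnings.warn(f"stratum {sid} chromosome {chrom}: zero MAD "
                              "(degenerate); p set to 1")
                z[idx] = 0.0
                continue
            zj = (vals - c) / sigma
            z[idx] = zj
            p[idx] = np.clip(2.0 * stats.norm.sf(np.abs(zj)), P_FLOOR, 1.0)
    scores["z_expr"] = z
    scores["p_expr"] = p
    return scores
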