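"""Embryo-level interpretation of chromosome calls.

Meiotic errors arise in the gametes and affect every embryonic cell,
while mitotic errors arise post-zygotically and affect a clonal subset;
an aneuploidy (a particular chromosome gain or loss) is therefore
classified meiotic when it is carried by at least 75% of the embryo's
cells (or, under the alternative criterion, when fewer than two of the
embryo's cells are normal for that chromosome), and mitotic otherwise.

This module also summarizes the cohort across a grid of FDR levels,
clusters cells within an embryo by their aneuploidy signature
(approximating clonal ancestry), and correlates per-chromosome
aneuploidy rates with protein-coding gene counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .combine import treebh_select

logger = logging.getLogger(__name__)

CATEGORIES = ("euploid", "meiotic_only", "mitotic_only", "both", "indeterminate")


@dataclass
class ErrorClassification:
    embryo_id: str
    category: str
    criterion: str
    # one row per called (chromosome, monosomy|trisomy): origin + support
    events: pd.DataFrame = field(default_factory=pd.DataFrame)


def classify_embryo_errors(calls: pd.DataFrame,
                           cells_per_embryo: dict[str, list[str]],
                           cutoff: float = 0.75,
                           criterion: str = "fraction_75",
                           denominator: str = "all_cells") -> list[ErrorClassification]:
    """Classify each called aneuploidy as meiotic or mitotic per embryo.

    ``calls`` needs columns embryo_id, cell_id, chromosome, call.
    ``cells_per_embryo`` maps each embryo to its retained cells (the
    denominator of the fraction rule). ``criterion`` is ``fraction_75``
    (meiotic iff the fraction of cells carrying that exact aneuploidy is
    >= cutoff) or ``lt2_normal`` (meiotic iff fewer than two cells are
    normal for that chromosome). ``denominator`` is ``all_cells`` or
    ``called_cells`` (only cells with a non-missing test on that
    chromosome; requires a ``tested`` table merged upstream — falls back
    to all cells when unavailable).

    Embryos with fewer than two retained cells are ``indeterminate``.
    A chromosome carrying reciprocal monosomy and trisomy in different
    cells counts as two events.
    """
    if criterion not in ("fraction_75", "lt2_normal"):
        raise ValueError(f"unknown criterion {criterion!r}")
    results = []
    for embryo_id, cells in cells_per_embryo.items():
        n_cells = len(cells)
        emb_calls = calls[calls["embryo_id"] == embryo_id]
        if n_cells < 2:
            results.append(ErrorClassification(embryo_id, "indeterminate", criterion))
            continue
        if emb_calls.empty:
            results.append(ErrorClassification(embryo_id, "euploid", criterion))
            continue
        rows = []
        for (chrom, call), grp in emb_calls.groupby(["chromosome", "call"]):
            carriers = grp["cell_id"].nunique()
            frac = carriers / n_cells
            n_affected_chrom = emb_calls.loc[emb_calls["chromosome"] == chrom,
                                             "cell_id"].nunique()
            n_normal = n_cells - n_affected_chrom
            if criterion == "fraction_75":
                origin = "meiotic" if frac >= cutoff else "mitotic"
            else:
                origin = "meiotic" if n_normal < 2 else "mitotic"
            rows.append({"chromosome": chrom, "call": call, "n_carriers": carriers,
                         "fraction": frac, "n_normal_cells": n_normal,
                         "origin": origin})
        events = pd.DataFrame(rows)
        has_mei = (events["origin"] == "meiotic").any()
        has_mit = (events["origin"] == "mitotic").any()
        category = ("both" if has_mei and has_mit
                    else "meiotic_only" if has_mei
                    else "mitotic_only")
        results.append(ErrorClassification(embryo_id, category, criterion, events))
    return results


def classifications_table(classifications: list[ErrorClassification]) -> pd.DataFrame:
    """Flatten classifications to one row per (embryo, chromosome, call)."""
    rows = []
    for cl in classifications:
        if cl.events.empty:
            rows.append({"embryo_id": cl.embryo_id, "category": cl.category,
                         "criterion": cl.criterion})
        else:
            for rec in cl.events.to_dict("records"):
                rows.append({"embryo_id": cl.embryo_id, "category": cl.category,
                             "criterion": cl.criterion, **rec})
    return pd.DataFrame(rows)


def summarize_embryos(calls: pd.DataFrame,
                      cells_per_embryo: dict[str, list[str]]) -> pd.DataFrame:
    """Per-embryo aneuploid cell counts and fractions."""
    rows = []
    for embryo_id, cells in cells_per_embryo.items():
        emb = calls[calls["embryo_id"] == embryo_id]
        n_aneu = emb["cell_id"].nunique()
        rows.append({"embryo_id": embryo_id, "n_cells": len(cells),
                     "n_aneuploid_cells": n_aneu,
                     "fraction_aneuploid": n_aneu / len(cells) if cells else np.nan,
                     "n_aneuploid_leaves": len(emb)})
    return pd.DataFrame(rows)


def summarize_cohort(leaves: pd.DataFrame,
                     q_grid: list[float]) -> pd.DataFrame:
    """Proportions of aneuploid chromosomes, cells and embryos per FDR level.

    Re-runs the hierarchical selection at each level of the grid; the
    three proportion curves are non-decreasing in q.
    """
    n_embryos = leaves["embryo_id"].nunique()
    n_cells = leaves[["embryo_id", "cell_id"]].drop_duplicates().shape[0]
    n_leaves = len(leaves)
    rows = []
    for q in sorted(q_grid):
        res = treebh_select(leaves, q=q)
        re_, rc, rl = res.n_rejected
        rows.append({"q": q,
                     "n_embryos": n_embryos, "n_cells": n_cells, "n_leaves": n_leaves,
                     "aneuploid_embryos": re_, "aneuploid_cells": rc,
                     "aneuploid_leaves": rl,
                     "prop_embryos": re_ / n_embryos,
                     "prop_cells": rc / n_cells,
                     "prop_leaves": rl / n_leaves})
    return pd.DataFrame(rows)


def cohort_proportions(n_flagged: dict[str, int], n_total: dict[str, int]) -> dict[str, float]:
    """Proportions from flagged/total counts at the three tree levels."""
    return {level: n_flagged[level] / n_total[level] for level in n_flagged}


def cluster_cells_hierarchical(signatures: pd.DataFrame,
                               null_value: float = 0.0):
    """Cluster an embryo's cells by aneuploidy signature.

    ``signatures`` is cells x chromosomes (Z-scores or dosage scores);
    missing entries are imputed to ``null_value`` (0 for Z, 1 for s).
    Returns (linkage matrix, ordered signature matrix) using Euclidean
    distance with average linkage, or None for embryos with < 2 usable
    cells.
    """
    if signatures.shape[0] < 2:
        logger.info("skipping clustering: fewer than 2 cells")
        return None
    X = signatures.fillna(null_value).to_numpy(float)
    Z = linkage(X, method="average", metric="euclidean")
    order = leaves_list(Z)
    return Z, signatures.iloc[order]


def chromosome_rate_gene_correlation(leaf_table: pd.DataFrame,
                                     gene_counts: pd.Series) -> tuple[float, float]:
    """Pearson correlation of per-chromosome aneuploidy rates with
    protein-coding gene counts.

    Rate = rejected leaves / tested leaves per chromosome. Raises on zero
    variance in either vector.
    """
    grp = leaf_table.groupby("chromosome")["rejected"]
    rates = grp.mean()
    common = rates.index.intersection(gene_counts.index)
    x = rates.loc[common].to_numpy(float)
    y = gene_counts.loc[common].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in rates or gene counts")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
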