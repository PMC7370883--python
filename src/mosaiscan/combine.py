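"""Omnibus combination and hierarchical FDR selection.

The expression p-value is first gated by the dosage effect size: if
|1 - s| < 0.2 the expression test is considered uninformative and its
p-value is set to 1. The gated expression p and the allelic-imbalance p
are then combined with Fisher's method (chi-square with 4 df; 2 df when
only one signal is available for a cell-chromosome).

Multiplicity is handled on the hypothesis tree chromosomes-within-cells-
within-embryos: parent p-values are Simes-aggregated from their
children, Benjamini-Hochberg selection is run at the embryo level at the
nominal level q, and within each selected family at levels shrunk by the
product of ancestor selection fractions (the tree-structured BH recipe).
Selected leaves are finally labeled monosomy or trisomy by 2-means
clustering of their (z_expr, z_ai) pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


def gate_expression_p(s, p_expr, threshold: float = 0.2):
    """Set expression p to 1 where the dosage effect |1 - s| < threshold.

    The inequality is inclusive: |1 - s| == threshold passes the gate.
    Accepts scalars or arrays.
    """
    s = np.asarray(s, float)
    p = np.asarray(p_expr, float)
    # small tolerance keeps the boundary inclusive under float rounding
    gated = np.where(np.abs(1.0 - s) >= threshold - 1e-12, p, 1.0)
    return float(gated) if gated.ndim == 0 else gated


def fisher_combine(p1, p2):
    """Fisher's method for two p-values.

    Returns (chi2, p_combined) with chi2 = -2(ln p1 + ln p2) referred to
    the upper tail of a chi-square with 4 degrees of freedom. Inputs are
    expected in (0, 1] (clip beforehand). NaN in one argument falls back
    to the single-signal 2-df path.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    both = ~(np.isnan(p1) | np.isnan(p2))
    lp1 = np.where(np.isnan(p1), 0.0, np.log(np.clip(p1, P_FLOOR, 1.0)))
    lp2 = np.where(np.isnan(p2), 0.0, np.log(np.clip(p2, P_FLOOR, 1.0)))
    chi2 = -2.0 * (lp1 + lp2)
    df = np.where(both, 4, 2)
    none = np.isnan(p1) & np.isnan(p2)
    p = np.clip(stats.chi2.sf(chi2, df), P_FLOOR, 1.0)
    p = np.where(none, 1.0, p)
    chi2 = np.where(none, 0.0, chi2)
    if p.ndim == 0:
        return float(chi2), float(p)
    return chi2, p


def simes(p_children) -> float:
    """Simes combined p-value: min over i of m * p_(i) / i, capped at 1."""
    p = np.sort(np.asarray(p_children, float))
    m = len(p)
    if m == 0:
        raise ValueError("simes requires a non-empty p-value list")
    return float(min(1.0, np.min(m * p / np.arange(1, m + 1))))


def _bh_reject(pvals: np.ndarray, alpha: float) -> np.ndarray:
    if len(pvals) == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(pvals, alpha=alpha, method="fdr_bh")[0]


@dataclass
class TreeBHResult:
    """Selection state at every level of the embryo -> cell -> chromosome tree."""

    q: float
    embryo_table: pd.DataFrame   # embryo_id, p, rejected
    cell_table: pd.DataFrame     # embryo_id, cell_id, p, rejected
    leaf_table: pd.DataFrame     # embryo_id, cell_id, chromosome, p, rejected
    levels: dict = field(default_factory=dict)  # adjusted BH levels per family

    @property
    def n_rejected(self) -> tuple[int, int, int]:
        return (int(self.embryo_table["rejected"].sum()),
                int(self.cell_table["rejected"].sum()),
                int(self.leaf_table["rejected"].sum()))


def treebh_select(leaves: pd.DataFrame, q: float = 0.01) -> TreeBHResult:
    """Hierarchical BH selection over embryos, cells and chromosomes.

    ``leaves`` needs columns embryo_id, cell_id, chromosome, p. Level 1
    runs BH at level q on Simes-aggregated embryo p-values; level 2,
    within each selected embryo, at q * (R1/m1); level 3, within each
    selected cell, at q * (R1/m1) * (R2e/m2e), where R/m are the selected
    fractions of the ancestor families. A leaf can only be rejected if
    its cell and embryo are.
    """
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    required = {"embryo_id", "cell_id", "chromosome", "p"}
    missing = required - set(leaves.columns)
    if missing:
        raise ValueError(f"leaf table is missing columns: {sorted(missing)}")
    leaves = leaves.reset_index(drop=True)

    cell_p = (leaves.groupby(["embryo_id", "cell_id"], sort=True)["p"]
              .apply(lambda p: simes(p.to_numpy())).reset_index())
    embryo_p = (cell_p.groupby("embryo_id", sort=True)["p"]
                .apply(lambda p: simes(p.to_numpy())).reset_index())

    # level 1: embryos
    embryo_p["rejected"] = _bh_reject(embryo_p["p"].to_numpy(), q)
    m1 = len(embryo_p)
    r1 = int(embryo_p["rejected"].sum())
    q2 = q * r1 / m1 if m1 else 0.0
    levels = {"embryo": q, "cell": q2, "leaf": {}}

    # level 2: cells within each selected embryo
    cell_p["rejected"] = False
    selected_embryos = set(embryo_p.loc[embryo_p["rejected"], "embryo_id"])
    for emb in selected_embryos:
        fam = cell_p["embryo_id"] == emb
        rej = _bh_reject(cell_p.loc[fam, "p"].to_numpy(), q2)
        cell_p.loc[fam, "rejected"] = rej
        m2 = int(fam.sum())
        r2 = int(rej.sum())
        levels["leaf"][emb] = q2 * r2 / m2 if m2 else 0.0

    # level 3: leaves within each selected cell
    leaves = leaves.copy()
    leaves["rejected"] = False
    sel_cells = cell_p.loc[cell_p["rejected"], ["embryo_id", "cell_id"]]
    for emb, cell in sel_cells.itertuples(index=False):
        q3 = levels["leaf"][emb]
        fam = (leaves["embryo_id"] == emb) & (leaves["cell_id"] == cell)
        leaves.loc[fam, "rejected"] = _bh_reject(leaves.loc[fam, "p"].to_numpy(), q3)

    result = TreeBHResult(q=q, embryo_table=embryo_p, cell_table=cell_p,
                          leaf_table=leaves, levels=levels)
    _assert_hierarchy(result)
    return result


def _assert_hierarchy(res: TreeBHResult) -> None:
    """No rejected node without a rejected ancestor (checked on every run)."""
    ok_cells = set(map(tuple, res.cell_table.loc[res.cell_table["rejected"],
                                                 ["embryo_id", "cell_id"]].to_numpy()))
    ok_embryos = set(res.embryo_table.loc[res.embryo_table["rejected"], "embryo_id"])
    rej = res.leaf_table[res.leaf_table["rejected"]]
    for emb, cell in rej[["embryo_id", "cell_id"]].drop_duplicates().itertuples(index=False):
        assert emb in ok_embryos, "rejected leaf in a non-rejected embryo"
        assert (emb, cell) in ok_cells, "rejected leaf in a non-rejected cell"


def assign_ploidy_type(rejected: pd.DataFrame) -> pd.DataFrame:
    """Label rejected leaves monosomy or trisomy.

    2-means on the (z_expr, z_ai) pairs with deterministic initialization
    (componentwise min and max); the cluster with the lower mean Z is
    monosomy. Leaves with a missing Z, or degenerate inputs (< 2 usable
    points, identical points), fall back to the sign of the available
    Z-score (negative -> monosomy).
    """
    rejected = rejected.copy()
    if len(rejected) == 0:
        rejected["call"] = pd.Series(dtype=object)
        return rejected

    z = rejected[["z_expr", "z_ai"]].to_numpy(float)
    call = np.array([None] * len(rejected), dtype=object)
    complete = ~np.isnan(z).any(axis=1)
    pts = z[complete]

    clustered = False
    if len(pts) >= 2 and not np.allclose(pts, pts[0]):
        init = np.vstack([pts.min(axis=0), pts.max(axis=0)])
        if not np.allclose(init[0], init[1]):
            km = KMeans(n_clusters=2, init=init, n_init=1, max_iter=300).fit(pts)
            means = np.array([pts[km.labels_ == k].mean() if np.any(km.labels_ == k)
                              else np.inf for k in (0, 1)])
            mono_cluster = int(np.argmin(means))  # ties resolve to cluster 0
            labels = np.where(km.labels_ == mono_cluster, "monosomy", "trisomy")
            call[complete] = labels
            clustered = True
    if not clustered and complete.any():
        call[complete] = _sign_call(z[complete])
    if (~complete).any():
        call[~complete] = _sign_call(z[~complete])
    rejected["call"] = call
    return rejected


def _sign_call(z: np.ndarray) -> np.ndarray:
    """Sign fallback: z_expr < 0 -> monosomy; use z_ai when z_expr is missing.

    With both missing (no informative signal) the label defaults to
    monosomy, the more detectable state.
    """
    zx, za = z[:, 0], z[:, 1]
    primary = np.where(np.isnan(zx), za, zx)
    primary = np.where(np.isnan(primary), -1.0, primary)
    return np.where(primary < 0, "monosomy", "trisomy").astype(object)
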