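"""Input parsing, quality control and stratification.

The caller consumes three tables:

* a raw gene-by-cell count matrix (wide TSV or MatrixMarket with
  ``genes.tsv`` / ``cells.tsv`` sidecars),
* a gene map assigning each gene to a chromosome (analysis is restricted
  to the 22 autosomes),
* per-cell metadata (embryo, embryonic day, cell type, mapped reads and
  percent mapped reads) used for depth-based QC and stratification,

plus, optionally, an ASEReadCounter-style per-cell allele count table.

Cells are grouped into (embryonic stage x cell type) strata within which
expression baselines are comparable; strata that retain too few
sufficiently expressed genes fail QC and contribute no calls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

#: Fixed autosome set; everything else (sex chromosomes, scaffolds) is dropped.
AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))

_AUTOSOME_SET = frozenset(AUTOSOMES)


def normalize_chromosome(label: object) -> str | None:
    """Map a chromosome label ('7', 'chr7') to canonical 'chr7' form.

    Returns None for anything that is not an autosome.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    canon = f"chr{s}"
    return canon if canon in _AUTOSOME_SET else None


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountData:
    """Validated gene-by-cell count matrix with aligned annotations."""

    counts: pd.DataFrame          # genes x cells, non-negative integers
    gene_map: pd.DataFrame        # index gene_id; chromosome, is_protein_coding
    meta: pd.DataFrame            # index cell_id; embryo_id, stage, cell_type, ...
    n_genes_dropped: int = 0

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class Stratum:
    """One (stage, cell type) group of cells plus its retained gene list."""

    stratum_id: str
    stage: object
    cell_type: str
    cells: list[str]
    genes: list[str] = field(default_factory=list)
    passed: bool = True
    fail_reason: str | None = None

    @property
    def n_genes(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# readers


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dup = index[index.duplicated()][0]
        raise ValueError(f"duplicate {what} ID: {dup!r}")


def read_gene_map(path: str | Path) -> pd.DataFrame:
    """Read a gene map TSV (gene_id, chromosome[, is_protein_coding]).

    Non-autosomal genes are dropped; chromosome labels are normalized to
    'chr1'..'chr22'.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "chromosome"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene map is missing columns: {sorted(missing)}")
    df = df.set_index("gene_id")
    _check_unique(df.index, "gene")
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    df = df[df["chromosome"].notna()]
    if "is_protein_coding" not in df.columns:
        df["is_protein_coding"] = True
    df["is_protein_coding"] = df["is_protein_coding"].astype(bool)
    return df


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    """Read per-cell metadata (cell_id, embryo_id, stage, cell_type,
    mapped_reads, pct_mapped)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "embryo_id": str})
    required = {"cell_id", "embryo_id", "stage", "cell_type",
                "mapped_reads", "pct_mapped"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cell metadata is missing columns: {sorted(missing)}")
    df = df.set_index("cell_id")
    _check_unique(df.index, "cell")
    if df[["stage", "cell_type"]].isna().any().any():
        bad = df.index[df[["stage", "cell_type"]].isna().any(axis=1)][0]
        raise ValueError(f"cell {bad!r} has missing stage or cell_type")
    pct = df["pct_mapped"].to_numpy(float)
    if np.any((pct < 0) | (pct > 1)):
        raise ValueError("pct_mapped must be a fraction in [0, 1]")
    return df


def _read_matrix(matrix_path: Path) -> pd.DataFrame:
    if matrix_path.suffix == ".mtx":
        mat = scipy.io.mmread(matrix_path)
        genes = pd.read_csv(matrix_path.with_name("genes.tsv"),
                            sep="\t", header=None)[0].astype(str)
        cells = pd.read_csv(matrix_path.with_name("cells.tsv"),
                            sep="\t", header=None)[0].astype(str)
        dense = np.asarray(scipy.sparse.coo_matrix(mat).todense())
        counts = pd.DataFrame(dense, index=genes, columns=cells)
    else:
        counts = pd.read_csv(matrix_path, sep="\t", index_col=0)
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
    return counts


def read_counts(matrix_path: str | Path,
                gene_map_path: str | Path,
                cell_meta_path: str | Path) -> CountData:
    """Read and validate the count matrix against gene map and cell metadata.

    Genes absent from the map or not on an autosome are dropped (logged);
    duplicated IDs or non-integer/negative counts are hard errors.
    """
    matrix_path = Path(matrix_path)
    counts = _read_matrix(matrix_path)
    _check_unique(counts.index, "gene")
    _check_unique(counts.columns, "cell")

    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("count matrix contains non-numeric entries")
    if np.any(values != np.floor(values)):
        raise ValueError("count matrix contains non-integer entries")
    if np.any(values < 0):
        raise ValueError("count matrix contains negative entries")
    counts = counts.astype(np.int64)

    gene_map = read_gene_map(gene_map_path)
    meta = read_cell_meta(cell_meta_path)

    keep = counts.index.intersection(gene_map.index)
    n_dropped = counts.shape[0] - len(keep)
    if n_dropped:
        logger.info("dropped %d genes not mapped to an autosome", n_dropped)
    counts = counts.loc[keep]
    if counts.shape[0] == 0:
        raise ValueError("no genes retained after autosome/gene-map filtering")

    missing_cells = counts.columns.difference(meta.index)
    if len(missing_cells):
        raise ValueError(f"cells absent from metadata: {list(missing_cells)[:5]}")
    meta = meta.loc[counts.columns]
    return CountData(counts=counts, gene_map=gene_map.loc[keep], meta=meta,
                     n_genes_dropped=n_dropped)


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Read a per-cell ASEReadCounter-style allele count TSV.

    Expected columns: cell_id, contig, position, refCount, altCount (extra
    ASEReadCounter columns such as variantID / totalCount are ignored).
    Positions are 1-based; non-autosomal contigs and zero-coverage rows
    are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    required = {"cell_id", "contig", "position", "refCount", "altCount"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"allele count table is missing columns: {sorted(missing)}")
    df["chromosome"] = df["contig"].map(normalize_chromosome)
    df = df[df["chromosome"].notna()].copy()
    ref = df["refCount"].to_numpy()
    alt = df["altCount"].to_numpy()
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("allele counts must be non-negative")
    df = df[(df["refCount"] + df["altCount"]) >= 1]
    return df[["cell_id", "chromosome", "position", "refCount", "altCount"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# quality control


def filter_cells_by_depth(meta: pd.DataFrame,
                          quantile: float = 0.10,
                          strict: bool = True) -> tuple[list[str], list[str]]:
    """Remove low-depth cells: the union of cells below the given quantile
    of mapped reads and of percent mapped reads.

    Uses the linear-interpolation (type-7) quantile. With ``strict`` (the
    default) cells strictly below the cutoff are removed; otherwise cells
    at or below it.

    Returns (retained cell IDs, removed cell IDs), preserving input order.
    """
    if not 0 < quantile <= 0.5:
        raise ValueError(f"quantile must be in (0, 0.5], got {quantile}")
    reads = meta["mapped_reads"].to_numpy(float)
    pct = meta["pct_mapped"].to_numpy(float)
    cut_reads = np.quantile(reads, quantile, method="linear")
    cut_pct = np.quantile(pct, quantile, method="linear")
    if strict:
        low = (reads < cut_reads) | (pct < cut_pct)
    else:
        low = (reads <= cut_reads) | (pct <= cut_pct)
    removed = list(meta.index[low])
    retained = list(meta.index[~low])
    logger.info("depth filter removed %d of %d cells", len(removed), len(meta))
    return retained, removed


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million over the full retained (autosomal) gene set.

    Library-size normalization is deliberately independent of stratum
    membership and of downstream per-stratum gene filtering.
    """
    totals = counts.sum(axis=0)
    zero = totals.index[totals.to_numpy() == 0]
    if len(zero):
        raise ValueError(f"cell {zero[0]!r} has zero total counts")
    return counts.div(totals, axis=1) * 1e6


def filter_genes_in_stratum(cpm: pd.DataFrame,
                            stratum_cells: list[str],
                            min_median_cpm: float = 50.0) -> list[str]:
    """Genes whose median CPM across the stratum's cells is >= threshold."""
    if len(stratum_cells) < 2:
        raise ValueError("stratum has fewer than 2 cells")
    med = cpm[stratum_cells].median(axis=1)
    return list(med.index[med.to_numpy() >= min_median_cpm])


def build_strata(meta: pd.DataFrame, cells: list[str] | None = None) -> list[Stratum]:
    """Partition retained cells into (stage, cell type) strata."""
    sub = meta if cells is None else meta.loc[cells]
    strata = []
    for (stage, cell_type), grp in sub.groupby(["stage", "cell_type"], sort=True):
        sid = f"E{stage}.{cell_type}"
        strata.append(Stratum(stratum_id=sid, stage=stage, cell_type=str(cell_type),
                              cells=list(grp.index)))
    return strata


def qc_strata(strata: list[Stratum],
              cpm: pd.DataFrame,
              min_median_cpm: float = 50.0,
              min_genes: int = 2000) -> list[Stratum]:
    """Apply per-stratum gene filtering and flag failing strata.

    A stratum fails if it has fewer than two cells or retains fewer than
    ``min_genes`` sufficiently expressed genes.
    """
    for st in strata:
        if len(st.cells) < 2:
            st.passed = False
            st.fail_reason = "fewer than 2 cells"
            st.genes = []
            continue
        st.genes = filter_genes_in_stratum(cpm, st.cells, min_median_cpm)
        if st.n_genes < min_genes:
            st.passed = False
            st.fail_reason = f"only {st.n_genes} genes >= {min_median_cpm} median CPM"
            logger.info("stratum %s failed QC: %s", st.stratum_id, st.fail_reason)
        else:
            st.passed = True
    n_pass = sum(s.passed for s in strata)
    logger.info("strata QC: %d of %d strata passed", n_pass, len(strata))
    return strata


def flag_small_embryos(meta: pd.DataFrame, cells: list[str],
                       min_cells: int = 2) -> set[str]:
    """Embryos with fewer retained cells than needed for origin
    classification; their cells still receive chromosome-level calls."""
    sizes = meta.loc[cells].groupby("embryo_id").size()
    small = set(sizes.index[sizes < min_cells])
    if small:
        warnings.warn(f"{len(small)} embryo(s) have < {min_cells} retained cells; "
                      "origin classification will be indeterminate for them")
    return small
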