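import pandas as pd
import pytest

from mosaiscan import PipelineConfig, SimConfig, call_cohort, simulate_cohort


@pytest.fixture(scope="session")
def sim_config():
    """Small but fully featured cohort for unit tests."""
    return SimConfig(n_embryos=6, cells_per_embryo=8,
                     genes_per_chromosome=60, seed=123)


@pytest.fixture(scope="session")
def cohort(sim_config):
    return simulate_cohort(sim_config, overdispersion=1.0, replicate=0)


@pytest.fixture(scope="session")
def pcfg():
    # simulated strata have ~1300 expressed genes; disable the real-data
    # min_genes floor that is calibrated to ~3000-gene strata
    return PipelineConfig(min_genes=0)


@pytest.fixture(scope="session")
def called(cohort, pcfg):
    return call_cohort(cohort.counts, cohort.gene_map, cohort.meta,
                       cohort.allelic, config=pcfg, apply_depth_filter=False)


@pytest.fixture()
def toy_files(tmp_path):
    """Tiny wide-TSV cohort on disk (3 genes incl. one chrX, 2 cells)."""
    counts = tmp_path / "counts.tsv"
    counts.write_text("gene_id\tcellA\tcellB\n"
                      "g1\t10\t20\n"
                      "g2\t5\t0\n"
                      "gX\t7\t3\n")
    gene_map = tmp_path / "gene_map.tsv"
    gene_map.write_text("gene_id\tchromosome\tis_protein_coding\n"
                        "g1\tchr1\tTrue\n"
                        "g2\t2\tTrue\n"
                        "gX\tchrX\tTrue\n")
    meta = tmp_path / "meta.tsv"
    meta.write_text("cell_id\tembryo_id\tstage\tcell_type\tmapped_reads\tpct_mapped\n"
                    "cellA\te1\t5\tTE\t1000\t0.8\n"
                    "cellB\te1\t5\tTE\t2000\t0.9\n")
    return {"counts": counts, "gene_map": gene_map, "meta": meta,
            "dir": tmp_path}


def make_meta(n_cells, reads=None, pct=None, embryo="e1"):
    reads = reads if reads is not None else [1000 * (i + 1) for i in range(n_cells)]
    pct = pct if pct is not None else [0.8] * n_cells
    return pd.DataFrame({
        "embryo_id": embryo, "stage": 5, "cell_type": "TE",
        "mapped_reads": reads, "pct_mapped": pct,
    }, index=pd.Index([f"c{i:02d}" for i in range(n_cells)], name="cell_id"))
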