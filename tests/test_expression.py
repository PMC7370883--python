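import numpy as np
import pandas as pd
import pytest

from mosaiscan import PipelineConfig, call_cohort
from mosaiscan.expression import cpm_normalize, dosage_scores, expression_pvalues
from mosaiscan.io import Stratum


def brute_force_dosage(cpm: pd.DataFrame, cells, gene_chrom: dict) -> dict:
    """Independent oracle: naive loops over cells, chromosomes and genes."""
    out = {}
    for cell in cells:
        others = [c for c in cells if c != cell]
        by_chrom = {}
        for gene, chrom in gene_chrom.items():
            loo = np.mean([cpm.loc[gene, o] for o in others])
            if loo > 0:
                by_chrom.setdefault(chrom, []).append(cpm.loc[gene, cell] / loo)
        for chrom, ratios in by_chrom.items():
            out[(cell, chrom)] = float(np.median(ratios))
    return out


def _stratum(cells, genes):
    return [Stratum("s1", 5, "TE", list(cells), genes=list(genes))]


def _gene_map(gene_chrom):
    return pd.DataFrame({"chromosome": list(gene_chrom.values())},
                        index=pd.Index(gene_chrom.keys(), name="gene_id"))


class TestCpmNormalize:
    def test_sums_to_one_million(self):
        counts = pd.DataFrame({"c1": [50, 50], "c2": [10, 30]}, index=["g1", "g2"])
        cpm = cpm_normalize(counts)
        assert np.allclose(cpm.sum(axis=0), 1e6)
        assert np.allclose(cpm["c1"], [5e5, 5e5])

    def test_scale_invariance(self):
        counts = pd.DataFrame({"c1": [3, 9, 12]}, index=["a", "b", "c"])
        pd.testing.assert_frame_equal(cpm_normalize(counts),
                                      cpm_normalize(counts * 10))

    def test_zero_cell_named_in_error(self):
        counts = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            cpm_normalize(counts)


class TestDosageScores:
    def test_identical_cells_score_one(self):
        genes = [f"g{i}" for i in range(6)]
        cpm = pd.DataFrame(np.tile([[10.], [20], [30], [40], [50], [60]], 4),
                           index=genes, columns=list("abcd"))
        gc = {g: "chr1" for g in genes}
        scores = dosage_scores(cpm, _stratum("abcd", genes), _gene_map(gc),
                               min_genes_per_chrom=3)
        assert np.allclose(scores["s"], 1.0)

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(10)]
        gc = {g: ("chr1" if i < 5 else "chr2") for i, g in enumerate(genes)}
        cpm = pd.DataFrame(rng.integers(1, 200, (10, 4)).astype(float),
                           index=genes, columns=list("abcd"))
        scores = dosage_scores(cpm, _stratum("abcd", genes), _gene_map(gc),
                               min_genes_per_chrom=3)
        oracle = brute_force_dosage(cpm, list("abcd"), gc)
        for row in scores.itertuples():
            assert row.s == pytest.approx(oracle[(row.cell_id, row.chromosome)])

    def test_halved_chromosome_scores_half(self):
        # cell "a" expresses every chr7 gene at half the others' shared level
        chr7 = [f"s{i}" for i in range(6)]
        rest = [f"r{i}" for i in range(6)]
        gc = {**{g: "chr7" for g in chr7}, **{g: "chr1" for g in rest}}
        cpm = pd.DataFrame(100.0, index=chr7 + rest, columns=list("abcd"))
        cpm.loc[chr7, "a"] = 50.0
        scores = dosage_scores(cpm, _stratum("abcd", chr7 + rest),
                               _gene_map(gc), min_genes_per_chrom=3)
        s = scores.set_index(["cell_id", "chromosome"])["s"]
        assert s[("a", "chr7")] == pytest.approx(0.5)
        # leave-one-out reference for the other cells is (50+100+100)/3
        assert s[("b", "chr7")] == pytest.approx(1.2)
        assert s[("a", "chr1")] == pytest.approx(1.0)

    def test_off_chromosome_perturbation_leaves_score_unchanged(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(8)]
        gc = {g: ("chr1" if i < 4 else "chr2") for i, g in enumerate(genes)}
        cpm = pd.DataFrame(rng.uniform(10, 100, (8, 4)), index=genes,
                           columns=list("abcd"))
        base = dosage_scores(cpm, _stratum("abcd", genes), _gene_map(gc), 3)
        bumped = cpm.copy()
        bumped.loc["g7", "a"] *= 2  # chr2 gene, cell a
        after = dosage_scores(bumped, _stratum("abcd", genes), _gene_map(gc), 3)
        get = lambda df: df.set_index(["cell_id", "chromosome"])["s"]
        assert get(base)[("a", "chr1")] == get(after)[("a", "chr1")]

    def test_gene_label_permutation_invariance(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(7)]
        gc = {g: "chr3" for g in genes}
        cpm = pd.DataFrame(rng.uniform(5, 50, (7, 5)), index=genes,
                           columns=list("abcde"))
        perm = list(rng.permutation(genes))
        a = dosage_scores(cpm, _stratum("abcde", genes), _gene_map(gc), 3)
        b = dosage_scores(cpm.loc[perm], _stratum("abcde", perm), _gene_map(gc), 3)
        merged = a.merge(b, on=["cell_id", "chromosome"])
        assert np.allclose(merged["s_x"], merged["s_y"])


class TestExpressionPvalues:
    def _scores(self, values):
        return pd.DataFrame({"cell_id": [f"c{i}" for i in range(len(values))],
                             "chromosome": "chr1", "stratum_id": "s1",
                             "s": values, "n_genes": 30})

    def test_score_at_null_center_gives_p_one(self):
        out = expression_pvalues(self._scores([1.0, 1.01, 0.99, 1.02, 0.98]),
                                 center=1.0)
        row = out[out["s"] == 1.0].iloc[0]
        assert row.z_expr == 0
        assert row.p_expr == 1

    def test_outlier_score_mad_scale(self):
        # MAD of {0.98, 1.01, 0.99, 1.02, 0.5} about its median 0.99 is 0.02,
        # so sigma = 0.029652 and the 0.5 cell sits ~16.9 sigma below 1
        out = expression_pvalues(self._scores([0.98, 1.01, 0.99, 1.02, 0.5]),
                                 center=1.0)
        row = out[out["s"] == 0.5].iloc[0]
        assert row.z_expr == pytest.approx(-0.5 / (1.4826 * 0.02), rel=1e-6)
        assert row.p_expr < 1e-20

    def test_degenerate_stratum_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="zero MAD"):
            out = expression_pvalues(self._scores([1.0] * 5), center=1.0)
        assert (out["p_expr"] == 1).all()

    def test_too_few_cells_warns(self):
        with pytest.warns(UserWarning, match="< 5 cells"):
            out = expression_pvalues(self._scores([0.5, 1.0, 1.5]), center=1.0)
        assert (out["p_expr"] == 1).all()


@pytest.fixture(scope="module")
def euploid_signals():
    from mosaiscan import SimConfig, simulate_cohort
    cfg = SimConfig(n_embryos=12, cells_per_embryo=8, meiotic_prob=0.0,
                    mitotic_prob=0.0, genes_per_chromosome=80, seed=77)
    data = simulate_cohort(cfg, overdispersion=1.0, replicate=0)
    res = call_cohort(data.counts, data.gene_map, data.meta, data.allelic,
                      config=PipelineConfig(min_genes=0),
                      apply_depth_filter=False)
    return res.signals


class TestNullCalibration:

    def test_euploid_false_positive_rate(self, euploid_signals):
        p = euploid_signals["p_expr"].dropna()
        assert len(p) >= 2000
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.02)

    def test_euploid_z_moments(self, euploid_signals):
        z = euploid_signals["z_expr"].dropna()
        assert abs(z.mean()) < 0.1
        assert 0.85 < z.std() < 1.15


def test_monotone_dosage_response(cohort, called):
    sig = called.signals.merge(
        cohort.truth[["cell_id", "chromosome", "copy_number"]],
        on=["cell_id", "chromosome"])
    means = sig.groupby("copy_number")["s"].mean()
    assert means[1] < means[2] < means[3]
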