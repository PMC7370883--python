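import numpy as np
import pandas as pd
import pytest

from mosaiscan import io as mio
from mosaiscan.simulate import (SimConfig, beta_shapes, estimate_sim_params,
                                run_benchmark, simulate_allelic,
                                simulate_cohort, simulate_expression,
                                simulate_ploidy_states, write_cohort)


class TestPloidyStates:
    def test_meiotic_errors_cover_all_cells(self):
        cfg = SimConfig(n_embryos=10, meiotic_prob=1.0, mitotic_prob=0.0, seed=1)
        truth = simulate_ploidy_states(cfg, cfg.rng(0))
        for _, emb in truth.groupby("embryo_id"):
            affected = emb[emb["copy_number"] != 2]
            assert affected["chromosome"].nunique() == 1
            assert affected["cell_id"].nunique() == cfg.cells_per_embryo
            assert set(affected["origin"]) == {"meiotic"}

    def test_mitotic_errors_cover_binary_subtrees(self):
        cfg = SimConfig(n_embryos=30, meiotic_prob=0.0, mitotic_prob=0.2, seed=2)
        truth = simulate_ploidy_states(cfg, cfg.rng(0))
        mitotic = truth[truth["origin"] == "mitotic"]
        assert len(mitotic) > 0
        checked = 0
        for _, grp in mitotic.groupby(["embryo_id", "chromosome"]):
            if grp["division"].nunique() > 1 or grp["copy_number"].nunique() > 1:
                continue  # stacked or reciprocal events overlap subtrees
            # descendants of one daughter of a balanced 8-cell tree
            assert grp["cell_id"].nunique() in (1, 2, 4)
            checked += 1
        assert checked >= 5

    def test_zero_probabilities_all_disomic(self):
        cfg = SimConfig(n_embryos=5, meiotic_prob=0.0, mitotic_prob=0.0, seed=3)
        truth = simulate_ploidy_states(cfg, cfg.rng(0))
        assert (truth["copy_number"] == 2).all()
        assert (truth["origin"] == "none").all()

    def test_copy_numbers_bounded(self):
        cfg = SimConfig(n_embryos=10, meiotic_prob=1.0, mitotic_prob=0.9, seed=4)
        truth = simulate_ploidy_states(cfg, cfg.rng(0))
        assert truth["copy_number"].between(1, 3).all()


class TestExpression:
    def test_dosage_scales_mean_cpm(self):
        # 22 chromosomes keep the compositional effect of losing or
        # gaining one chromosome on the per-cell CPM total below 2.5%
        cfg = SimConfig(n_embryos=12, cells_per_embryo=8,
                        genes_per_chromosome=200, meiotic_prob=1.0,
                        mitotic_prob=0.0, seed=5)
        truth = simulate_ploidy_states(cfg, cfg.rng(0))
        counts, gene_map = simulate_expression(truth, cfg, 1.0, cfg.rng(1))
        cpm = mio.compute_cpm(counts)
        chrom_of = gene_map["chromosome"]
        cn = truth.set_index(["cell_id", "chromosome"])["copy_number"]
        ratios = {1: [], 2: [], 3: []}
        base = {c: cpm.loc[chrom_of[chrom_of == c].index].sum(axis=0)
                for c in cfg.chromosomes}
        for chrom in cfg.chromosomes:
            tot = base[chrom]
            disomic = [c for c in cpm.columns if cn[(c, chrom)] == 2]
            ref = tot[disomic].mean()
            for cell in cpm.columns:
                ratios[cn[(cell, chrom)]].append(tot[cell] / ref)
        assert np.mean(ratios[1]) == pytest.approx(0.5, abs=0.05)
        assert np.mean(ratios[2]) == pytest.approx(1.0, abs=0.05)
        assert np.mean(ratios[3]) == pytest.approx(1.5, abs=0.05)

    def test_overdispersion_increases_variance(self):
        cfg = SimConfig(n_embryos=4, n_chromosomes=2, genes_per_chromosome=100,
                        meiotic_prob=0.0, mitotic_prob=0.0, seed=6)
        truth = simulate_ploidy_states(cfg, cfg.rng(0))
        lo, _ = simulate_expression(truth, cfg, 0.3, cfg.rng(1))
        hi, _ = simulate_expression(truth, cfg, 5.0, cfg.rng(1))
        v_lo = lo.var(axis=1)
        v_hi = hi.var(axis=1)
        assert (v_hi > v_lo).mean() > 0.95

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(genes_per_chromosome=0)


class TestAllelic:
    def test_beta_moment_matching(self):
        a, b = beta_shapes(0.4, 0.01)
        assert (a, b) == (pytest.approx(9.2), pytest.approx(13.8))
        rng = np.random.default_rng(7)
        draws = rng.beta(a, b, 100_000)
        assert draws.mean() == pytest.approx(0.4, abs=0.005)
        assert draws.var() == pytest.approx(0.01, rel=0.05)

    def test_infeasible_variance_rejected(self):
        with pytest.raises(ValueError):
            beta_shapes(0.4, 0.3)

    def test_monosomy_nearly_monoallelic(self):
        cfg = SimConfig(n_embryos=10, meiotic_prob=1.0, mitotic_prob=0.0, seed=8)
        truth = simulate_ploidy_states(cfg, cfg.rng(0))
        allelic = simulate_allelic(truth, cfg, 1.0, cfg.rng(2))
        obs = allelic.groupby(["cell_id", "chromosome"]).apply(
            lambda g: np.minimum(g.refCount, g.altCount).sum()
            / (g.refCount + g.altCount).sum(), include_groups=False)
        cn = truth.set_index(["cell_id", "chromosome"])["copy_number"]
        mono = obs[cn.loc[obs.index] == 1]
        assert len(mono) > 0
        assert 0 <= mono.mean() <= 0.06

    def test_overdispersion_scales_ratio_variance(self):
        cfg = SimConfig(n_embryos=25, meiotic_prob=0.0, mitotic_prob=0.0,
                        n_chromosomes=8, genes_per_chromosome=5, seed=9)
        truth = simulate_ploidy_states(cfg, cfg.rng(0))
        ratio = {}
        for od in (0.3, 1.0):
            al = simulate_allelic(truth, cfg, od, cfg.rng(2))
            g = al.groupby(["cell_id", "chromosome"])
            ratio[od] = (g.apply(lambda x: np.minimum(x.refCount, x.altCount).sum()
                                 / (x.refCount + x.altCount).sum(),
                                 include_groups=False))
        assert ratio[1.0].var() / ratio[0.3].var() == pytest.approx(1 / 0.3, rel=0.35)


class TestParamEstimation:
    def test_recovery_from_known_betas(self):
        rng = np.random.default_rng(10)
        states, ratios = [], []
        true = {1: (0.02, 0.018), 2: (0.38, 0.05), 3: (0.28, 0.06)}
        for state, (m, sd) in true.items():
            a, b = beta_shapes(m, sd ** 2)
            draws = rng.beta(a, b, 2000)
            ratios += list(draws)
            states += [state] * 2000
        obs = pd.DataFrame({"ai_ratio": ratios})
        est = estimate_sim_params(obs, pd.Series(states))
        for state, (m, sd) in true.items():
            assert est[state][0] == pytest.approx(m, abs=0.02)
            assert est[state][1] ** 2 == pytest.approx(sd ** 2, rel=0.3)

    def test_small_stratum_falls_back_to_defaults(self, caplog):
        obs = pd.DataFrame({"ai_ratio": [0.4, 0.35] * 20})
        states = pd.Series([2] * 40)
        est = estimate_sim_params(obs, states)
        assert est[1] == (0.02, 0.02)  # monosomy absent: defaults

    def test_constant_ratios_degenerate(self):
        obs = pd.DataFrame({"ai_ratio": [0.4] * 40})
        with pytest.raises(ValueError, match="degenerate"):
            estimate_sim_params(obs, pd.Series([2] * 40))


class TestDeterminismAndIO:
    def test_same_seed_identical_cohorts(self):
        cfg = SimConfig(n_embryos=3, genes_per_chromosome=30, seed=99)
        a = simulate_cohort(cfg, 1.0, replicate=0)
        b = simulate_cohort(cfg, 1.0, replicate=0)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.allelic, b.allelic)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        c = simulate_cohort(cfg, 1.0, replicate=1)
        assert not a.counts.equals(c.counts)

    def test_written_cohort_round_trips_through_readers(self, tmp_path):
        cfg = SimConfig(n_embryos=2, genes_per_chromosome=26, seed=98)
        data = simulate_cohort(cfg, 1.0, replicate=0)
        write_cohort(data, tmp_path)
        back = mio.read_counts(tmp_path / "counts.mtx",
                               tmp_path / "gene_map.tsv",
                               tmp_path / "cell_meta.tsv")
        assert back.counts.shape == data.counts.shape
        assert (back.counts.to_numpy() == data.counts.to_numpy()).all()
        allelic = mio.read_allele_counts(tmp_path / "allele_counts.tsv")
        assert len(allelic) == len(data.allelic)


class TestBenchmark:
    def test_tiny_end_to_end(self):
        cfg = SimConfig(n_embryos=4, cells_per_embryo=8,
                        genes_per_chromosome=40, seed=13)
        res = run_benchmark(cfg, n_replicates=1, overdispersion_factors=(1.0,))
        assert set(res.summary["mode"]) == {"combined", "expression_only"}
        assert (res.summary["specificity"] > 0.98).all()

    def test_all_null_reports_nan_sensitivity_and_low_fp(self):
        cfg = SimConfig(n_embryos=6, meiotic_prob=0.0, mitotic_prob=0.0,
                        genes_per_chromosome=40, seed=14)
        res = run_benchmark(cfg, n_replicates=2, overdispersion_factors=(1.0,))
        assert res.per_replicate["sensitivity"].isna().all()
        assert (res.per_replicate["FP"] <= 2).all()
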