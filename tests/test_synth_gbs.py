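"""Synthetic population generator: founders, crosses, reads, datasets."""

import numpy as np
import pytest
from scipy import stats

from gbsimpute import genolik, synth_gbs
from gbsimpute.genolik import ErrorModel
from gbsimpute.synth_gbs import (
    Cross,
    CrossPlan,
    DepthModel,
    SimConfig,
    generate_dataset,
    simulate_crosses,
    simulate_founders,
    simulate_reads,
)


class TestSimulateFounders:
    def test_single_ancestral_haplotype_collapses_pool(self):
        pool = simulate_founders(10, 50, k_ancestral=1, seed=0)
        ref = pool.haplotypes[0, 0]
        assert (pool.haplotypes == ref).all()

    def test_sfs_mean_matches_beta_within_three_se(self):
        pool = simulate_founders(50, 5000, seed=1)
        freq = pool.genotypes.mean(axis=1) / 2.0
        a, b = 0.3, 1.7
        beta_mean = a / (a + b)
        beta_sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        se = beta_sd / np.sqrt(5000)
        # sample frequencies add binomial noise around the Beta draw;
        # allow that extra spread on top of the Beta sampling error
        assert abs(freq.mean() - beta_mean) < 3 * se + 0.01

    def test_same_seed_identical_pool(self):
        a = simulate_founders(8, 100, seed=42)
        b = simulate_founders(8, 100, seed=42)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_positions_strictly_increasing(self):
        pool = simulate_founders(5, 500, seed=3)
        assert (np.diff(pool.positions) > 0).all()

    def test_ld_decays_with_distance(self):
        pool = simulate_founders(100, 800, seed=4)
        g = pool.genotypes.astype(float)
        sd = g.std(axis=1)
        rng = np.random.default_rng(5)
        dist, r2 = [], []
        for _ in range(3000):
            i = rng.integers(0, 799)
            j = min(799, i + rng.integers(1, 120))
            if i == j or sd[i] == 0 or sd[j] == 0:
                continue
            dist.append(pool.positions[j] - pool.positions[i])
            r2.append(np.corrcoef(g[i], g[j])[0, 1] ** 2)
        # Spearman trend of r2 over distance deciles must be negative
        deciles = np.quantile(dist, np.linspace(0, 1, 11))
        idx = np.clip(np.searchsorted(deciles, dist) - 1, 0, 9)
        means = [np.mean([r for r, k in zip(r2, idx) if k == d])
                 for d in range(10)]
        rho = stats.spearmanr(np.arange(10), means)[0]
        assert rho < 0


class TestSimulateCrosses:
    def test_no_recombination_transmits_parental_haplotypes(self):
        pool = simulate_founders(4, 60, seed=6)
        plan = CrossPlan([Cross(0, 1, 20)])
        off = simulate_crosses(pool, plan, genetic_length=0.0, seed=7)
        parental = np.vstack([pool.haplotypes[0], pool.haplotypes[1]])
        for j in range(20):
            # each offspring genotype must be a sum of one haplotype per parent
            matches = [
                (off[:, j] == pool.haplotypes[0, a] + pool.haplotypes[1, b]).all()
                for a in (0, 1) for b in (0, 1)
            ]
            assert any(matches)
        assert parental.shape == (4, 60)

    def test_mendelian_homozygous_cross(self):
        pool = simulate_founders(3, 40, k_ancestral=2, seed=8)
        pool.haplotypes[:2] = 0  # both parents AA at every site
        off = simulate_crosses(pool, CrossPlan([Cross(0, 1, 15)]),
                               genetic_length=1.0, seed=9)
        assert (off == 0).all()

    def test_unknown_parent_rejected(self):
        pool = simulate_founders(2, 10, seed=10)
        with pytest.raises(ValueError, match="not in the founder pool"):
            simulate_crosses(pool, CrossPlan([Cross(0, 5, 1)]), seed=0)

    def test_cross_validation_of_parents(self):
        with pytest.raises(ValueError, match="distinct"):
            Cross(1, 1, 5)


class TestSimulateReads:
    def test_zero_rate_all_missing(self):
        truth = np.ones((5, 4), dtype=np.int8)
        adm = simulate_reads(truth, DepthModel(lam=0.0), seed=0)
        assert (adm.depths == 0).all()

    def test_error_rate_recovered_from_homozygous_reads(self):
        # pooled reads from BB individuals carry allele A at rate e
        truth = np.full((100, 100), 2, dtype=np.int8)
        adm = simulate_reads(truth, DepthModel(lam=10, fixed=True),
                             ErrorModel(0.01), seed=1)
        frac_a = adm.depths[..., 0].sum() / adm.depths.sum()
        assert frac_a == pytest.approx(0.01, abs=0.001)

    def test_poisson_zero_class_missingness(self):
        truth = np.zeros((200, 200), dtype=np.int8)
        adm = simulate_reads(
            truth, DepthModel(lam=1.0, ind_shape=None, site_shape=None),
            seed=2)
        missing = (adm.total_depth == 0).mean()
        assert missing == pytest.approx(np.exp(-1), abs=0.01)

    def test_heterozygote_reads_unbiased(self):
        truth = np.ones((50, 50), dtype=np.int8)
        adm = simulate_reads(truth, DepthModel(lam=20, fixed=True), seed=3)
        frac_b = adm.depths[..., 1].sum() / adm.depths.sum()
        assert frac_b == pytest.approx(0.5, abs=0.01)


class TestGenerateDataset:
    def test_same_seed_identical_outputs(self):
        cfg = SimConfig(n_founders=12, n_parents=6, n_crosses=8,
                        offspring_per_cross=2, n_sites=60, seed=21)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        np.testing.assert_array_equal(a.adm.depths, b.adm.depths)
        np.testing.assert_array_equal(a.truth, b.truth)
        assert a.adm.samples == b.adm.samples

    def test_shapes_and_sample_naming(self, small_dataset):
        ds = small_dataset
        cfg = ds.config
        n = cfg.n_founders + cfg.n_crosses * cfg.offspring_per_cross
        assert ds.truth.shape == (cfg.n_sites, n)
        assert ds.adm.n_samples == n
        assert ds.founder_samples[0].startswith("GG")
        assert ds.offspring_samples[0].startswith("C1-")

    def test_truth_consistent_with_founder_haplotypes(self, small_dataset):
        ds = small_dataset
        np.testing.assert_array_equal(
            ds.truth[:, :ds.pool.n_founders], ds.pool.genotypes)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="n_parents"):
            SimConfig(n_founders=5, n_parents=10).validate()
        with pytest.raises(ValueError, match="distinct pairs"):
            SimConfig(n_founders=5, n_parents=3, n_crosses=10).validate()

    def test_config_dict_round_trip(self):
        cfg = SimConfig(seed=9)
        assert SimConfig.from_dict(cfg.to_dict()) == cfg

    def test_write_dataset_round_trips_through_vcf(self, tmp_path,
                                                   small_dataset):
        from gbsimpute import io_vcf

        paths = synth_gbs.write_dataset(small_dataset, tmp_path)
        adm = io_vcf.read_allele_depths(paths["study_vcf"])
        np.testing.assert_array_equal(adm.depths, small_dataset.adm.depths)
        ref = io_vcf.read_allele_depths(paths["reference_vcf"])
        assert ref.n_samples == small_dataset.pool.n_founders
        assert "|" in paths["reference_vcf"].read_text()[-2000:]
        truth = io_vcf.read_dosage_tsv(paths["truth_tsv"])
        np.testing.assert_array_equal(truth.values, small_dataset.truth)


def test_posterior_dosages_converge_to_truth_at_high_depth():
    rng = np.random.default_rng(30)
    truth = rng.integers(0, 3, size=(100, 100)).astype(np.int8)
    adm = simulate_reads(truth, DepthModel(lam=50, fixed=True),
                         ErrorModel(0.01), seed=31)
    d = genolik.dosage_matrix(adm)
    close = np.abs(d.values - truth) <= 0.01
    assert close.mean() >= 0.99
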