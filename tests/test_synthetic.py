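"""Synthetic-cohort generator: spectrum, HWE, structure, trios, determinism."""
import numpy as np
import pytest
from scipy import stats

from svpopgen._util import harmonic_number
from svpopgen.synthetic import (
    SimulationConfig, simulate_cohort, simulate_gene_models, simulate_sfs,
)

from conftest import SMALL_THETA


class TestSimulateSfs:
    def test_zero_theta_yields_no_sites(self):
        assert len(simulate_sfs(0.0, 100, seed=1)) == 0

    def test_rejects_fewer_than_two_chromosomes(self):
        with pytest.raises(ValueError):
            simulate_sfs(10.0, 1, seed=1)

    def test_singleton_fraction_matches_harmonic_expectation(self):
        """At n=10 the neutral singleton fraction is 1/a_10 = 1/2.8290."""
        counts = simulate_sfs(10_000 / harmonic_number(10), 10, seed=42)
        assert len(counts) > 8_000
        frac = np.mean(counts == 1)
        expected = 1 / 2.828968
        se = np.sqrt(expected * (1 - expected) / len(counts))
        assert abs(frac - expected) < 3 * se

    def test_expected_site_count_is_theta_times_a_n(self):
        """theta=50, n=100: mean K over 200 replicates ~ 50 * a_100 = 258.9."""
        rng = np.random.default_rng(5)
        ks = [len(simulate_sfs(50.0, 100, rng=rng)) for _ in range(200)]
        expected = 50 * harmonic_number(100)
        se = np.sqrt(expected / 200)  # Poisson
        assert abs(np.mean(ks) - expected) < 4 * se

    def test_neutral_sfs_matches_one_over_i_shape(self):
        """Chi-square goodness of fit to the 1/i spectrum is not rejected."""
        n = 50
        counts = simulate_sfs(10_000 / harmonic_number(n), n, seed=3, tilt=0.0)
        observed = np.bincount(counts, minlength=n)[1:n]
        i = np.arange(1, n)
        expected = len(counts) * (1 / i) / np.sum(1 / i)
        stat, p = stats.chisquare(observed, expected)
        assert p > 0.01


class TestSimulationConfig:
    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="proportions"):
            SimulationConfig(population_proportions={"AFR": 0.5, "EUR": 0.4})

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(selection_map={"pLoF": -1.0})


class TestSimulateCohort:
    def test_same_seed_is_reproducible(self, gene_fixtures):
        genes, elements, _ = gene_fixtures
        cfg = dict(seed=123, n_samples=60, n_trios=5,
                   theta={"DEL": 80.0, "INS": 40.0})
        a = simulate_cohort(SimulationConfig(**cfg), genes=genes)
        b = simulate_cohort(SimulationConfig(**cfg), genes=genes)
        assert [r.id for r in a.cohort.records] == [r.id for r in b.cohort.records]
        np.testing.assert_array_equal(a.cohort.genotypes.dosage, b.cohort.genotypes.dosage)
        assert a.truth_sites.equals(b.truth_sites)

    def test_zero_error_rate_gives_zero_mendelian_violations(self, gene_fixtures):
        from svpopgen.popgen import mendelian_check
        genes, _, _ = gene_fixtures
        cfg = SimulationConfig(seed=9, n_samples=80, n_trios=10,
                               theta={"DEL": 150.0, "DUP": 60.0},
                               genotyping_error_rate=0.0)
        syn = simulate_cohort(cfg, genes=genes)
        res = mendelian_check(syn.cohort)
        assert res["median_violation_rate"] == 0.0
        assert res["per_trio"]["violation_rate"].max() == 0.0

    def test_selection_shifts_afs_down(self, small_cohort):
        truth = small_cohort.truth_sites
        sel = truth[truth["selection_s"] > 0]["global_af"]
        neutral = truth[(truth["selection_s"] == 0)
                        & truth["svtype"].isin(["DEL", "DUP"])]["global_af"]
        assert len(sel) > 50
        assert sel.mean() < neutral.mean()
        stat, p = stats.mannwhitneyu(sel, neutral, alternative="less")
        assert p < 0.01

    def test_realized_allele_counts_match_drawn_counts(self, gene_fixtures):
        """Copy placement preserves the sampled spectrum (no genotyping error)."""
        cfg = SimulationConfig(seed=21, n_samples=100, n_trios=0,
                               theta={"DEL": 200.0}, genotyping_error_rate=0.0,
                               selection_map={})
        syn = simulate_cohort(cfg)
        truth = syn.truth_sites.set_index("sv_id")
        mismatches = sum(
            1 for r in syn.cohort.biallelic_records
            if r.ac != truth.loc[r.id, "drawn_ac"])
        assert mismatches / max(1, len(syn.cohort.biallelic_records)) < 0.02

    def test_hwe_holds_within_populations(self, small_cohort):
        from svpopgen.popgen import hwe_fraction
        frac = hwe_fraction(small_cohort.cohort)
        assert frac > 0.85

    def test_insertion_sizes_cluster_at_mobile_element_peaks(self, small_cohort):
        sizes = np.array([r.svlen for r in small_cohort.cohort.records
                          if r.svtype == "INS"])
        assert len(sizes) > 100
        near_peak = ((np.abs(np.log(sizes / 300)) < 0.5)
                     | (np.abs(np.log(sizes / 2100)) < 0.5)
                     | (np.abs(np.log(sizes / 6000)) < 0.5))
        assert near_peak.mean() > 0.95

    def test_population_structure_recoverable_by_pca(self, gene_fixtures):
        from svpopgen.popgen import common_dosage_matrix, pca_structure
        from sklearn.metrics import silhouette_score
        cfg = SimulationConfig(
            seed=31, n_samples=150, n_trios=0,
            population_proportions={"AFR": 0.5, "EUR": 0.5},
            fst={"AFR": 0.08, "EUR": 0.08},
            theta={"DEL": 600.0}, sfs_tilt=0.0)
        syn = simulate_cohort(cfg)
        d, _ = common_dosage_matrix(syn.cohort)
        coords = pca_structure(d, n_components=3)
        pops = [syn.cohort.samples.population_of()[s]
                for s in syn.cohort.samples.unrelated_ids]
        assert silhouette_score(coords[:, :3], pops) > 0


class TestSimulateGeneModels:
    def test_single_gene_is_well_formed(self):
        genes, _, _ = simulate_gene_models(1, seed=2)
        g = genes[0]
        assert g.start < g.end and 2 <= g.n_exons <= 30
        for (s, e), (s2, e2) in zip(g.exons, g.exons[1:]):
            assert g.start <= s < e <= s2 < e2 <= g.end

    def test_constraint_rank_is_permutation(self, gene_fixtures):
        genes, _, _ = gene_fixtures
        ranks = sorted(g.constraint_rank for g in genes)
        assert ranks == list(range(1, len(genes) + 1))

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            simulate_gene_models(0, seed=1)

    def test_conservation_track_elevated_over_exons(self, gene_fixtures):
        genes, _, track = gene_fixtures
        g = genes[0]
        s, e = g.exons[0]
        exon_mean = track.score_sum(g.chrom, s, e) / (e - s)
        assert exon_mean > 0.4
        assert track.score_sum(g.chrom, g.end + 500_000, g.end + 501_000) >= 0.0
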