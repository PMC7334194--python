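"""Population-genetic statistics: HWE, Watterson, burden, trios, LD, PCA."""
import numpy as np
import pandas as pd
import pytest

from svpopgen import popgen
from svpopgen.sv_io import SVRecord
from svpopgen.synthetic import simulate_sfs

from conftest import make_cohort


class TestHweTest:
    def test_exact_hwe_proportions_give_p_one(self):
        assert popgen.hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        # p=q=0.5, expected (25,50,25), chi2 = 1+2+1 = 4 -> p = 0.0455
        assert popgen.hwe_test(30, 40, 30) == pytest.approx(0.04550026, abs=1e-6)

    def test_monomorphic_returns_one(self):
        assert popgen.hwe_test(100, 0, 0) == 1.0
        assert popgen.hwe_test(0, 0, 100) == 1.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            popgen.hwe_test(0, 0, 0)

    def test_exact_test_agrees_with_chi_square_at_large_counts(self):
        p_chi = popgen.hwe_test(300, 500, 200)
        p_ex = popgen.hwe_test_exact(300, 500, 200)
        assert (p_chi < 0.05) == (p_ex < 0.05)


class TestWatterson:
    def test_zero_segregating_sites(self):
        theta, _ = popgen.watterson_theta(0, 10)
        assert theta == 0.0

    def test_harmonic_arithmetic(self):
        theta, a_n = popgen.watterson_theta(11, 4)
        assert a_n == pytest.approx(1.833333, abs=1e-6)
        assert theta == pytest.approx(6.0, abs=1e-9)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            popgen.watterson_theta(-1, 10)

    def test_estimator_recovers_simulated_theta(self):
        rng = np.random.default_rng(17)
        estimates = []
        for _ in range(100):
            k = len(simulate_sfs(50.0, 100, rng=rng))
            estimates.append(popgen.watterson_theta(k, 100)[0])
        assert abs(np.mean(estimates) - 50.0) / 50.0 < 0.02


class TestMutationRate:
    def test_zero_theta(self):
        res = popgen.sv_mutation_rate(0.0, 10_000)
        assert res["rate_per_birth"] == 0.0 and res["ci"] == (0.0, 0.0)

    def test_algebraic_identity(self):
        res = popgen.sv_mutation_rate(4 * 10_000, 10_000)
        assert res["mu_haploid"] == pytest.approx(1.0)
        assert res["rate_per_birth"] == pytest.approx(2.0)

    def test_bad_ne_rejected(self):
        with pytest.raises(ValueError):
            popgen.sv_mutation_rate(10.0, 0)

    def test_published_rate_interval_implies_2_to_8_births(self):
        """A 0.29 (0.13-0.44) per-birth rate is one new SV every 2-8 births."""
        assert popgen.births_per_new_sv((0.13, 0.44)) == (2, 8)

    def test_bootstrap_ci_brackets_point_estimate(self):
        res = popgen.sv_mutation_rate(100.0, 10_000, n_chromosomes=200, seed=4)
        lo, hi = res["ci"]
        assert lo <= res["rate_per_birth"] <= hi


class TestSvShareOfPlof:
    def test_published_arithmetic(self):
        assert popgen.sv_share_of_plof(5.5, 1.3, 16.3, include_ied=True) == \
            pytest.approx(29.4, abs=0.05)
        assert popgen.sv_share_of_plof(5.5, 1.3, 16.3, include_ied=False) == \
            pytest.approx(25.2, abs=0.05)

    def test_no_snvs_gives_100_percent(self):
        assert popgen.sv_share_of_plof(3.0, 0.0, 0.0, include_ied=False) == 100.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            popgen.sv_share_of_plof(0.0, 0.0, 0.0)


class TestBurden:
    def _toy(self):
        # 3 samples x 4 SVs; sv3 is rare (ac=1), sv0 common
        records = [
            SVRecord("sv0", "chrA", 100, 200, "DEL", 100),
            SVRecord("sv1", "chrA", 300, 400, "DEL", 100),
            SVRecord("sv2", "chrA", 500, 600, "DUP", 100),
            SVRecord("sv3", "chrA", 700, 800, "DUP", 100),
        ]
        dosage = np.array([
            [1, 1, 0, 0],
            [2, 0, 1, 0],
            [1, 0, 0, 1],
        ])
        cohort = make_cohort(records, dosage)
        pairs = pd.DataFrame([
            {"sv_id": "sv0", "gene_id": "g1", "category": "pLoF"},
            {"sv_id": "sv1", "gene_id": "g1", "category": "pLoF"},
            {"sv_id": "sv1", "gene_id": "g2", "category": "pLoF"},
            {"sv_id": "sv2", "gene_id": "g3", "category": "copy_gain"},
            {"sv_id": "sv3", "gene_id": "g3", "category": "IED"},
        ])
        return cohort, pairs

    def test_hand_enumerated_counts(self):
        cohort, pairs = self._toy()
        # af: sv0 4/6, sv1 1/6, sv2 1/6, sv3 1/6 -> only none are <1%
        burden = popgen.per_genome_burden(cohort, pairs, rare_af=0.2)
        ps = burden.per_sample.set_index("sample_id")
        # s0 carries sv0,sv1 -> genes g1,g2 pLoF = 2; s1 carries sv0 (g1) and sv2
        assert ps.loc["s0", "pLoF_all"] == 2
        assert ps.loc["s1", "pLoF_all"] == 1
        assert ps.loc["s1", "copy_gain_all"] == 1
        assert ps.loc["s2", "IED_all"] == 1
        # rare stratum: sv1, sv2, sv3 (af=1/6 < 0.2); rare sv1 hits g1 and g2
        assert ps.loc["s0", "pLoF_rare"] == 2

    def test_sample_with_no_alt_genotypes_counts_zero(self):
        cohort, pairs = self._toy()
        cohort.genotypes.dosage[2, :] = 0
        cohort.recompute_allele_stats(warn_on_mismatch=False)
        burden = popgen.per_genome_burden(cohort, pairs)
        assert burden.per_sample.set_index("sample_id").loc["s2", "total_all"] == 0

    def test_total_equals_sum_of_categories(self):
        cohort, pairs = self._toy()
        burden = popgen.per_genome_burden(cohort, pairs)
        ps = burden.per_sample
        assert (ps["total_all"] ==
                ps["pLoF_all"] + ps["copy_gain_all"] + ps["IED_all"]).all()
        total = burden.means
        m = {(r["category"], r["stratum"]): r["mean"] for _, r in total.iterrows()}
        assert m[("total", "all")] == pytest.approx(
            m[("pLoF", "all")] + m[("copy_gain", "all")] + m[("IED", "all")])

    def test_homozygous_plof_counted(self):
        cohort, pairs = self._toy()
        burden = popgen.per_genome_burden(cohort, pairs)
        assert burden.per_sample.set_index("sample_id").loc["s1", "hom_pLoF"] == 1


class TestMendelian:
    def test_consistent_and_violating_patterns(self):
        from svpopgen.sv_io import SampleTable
        st = SampleTable(pd.DataFrame({
            "sample_id": ["dad", "mom", "kid"],
            "population": "EUR", "sex": ["M", "F", "M"],
            "father_id": ["", "", "dad"], "mother_id": ["", "", "mom"],
            "is_unrelated": [True, True, False],
        }))
        records = [SVRecord(f"sv{i}", "chrA", 100 * i + 100, 100 * i + 150, "DEL", 50)
                   for i in range(3)]
        # sv0: dad 0/1, mom 0/0, kid 0/1 -> consistent
        # sv1: both parents 0/0, kid 1/1 -> violation
        # sv2: parents 0/0, kid 0/1 -> de novo candidate (not a violation count? it is impossible too)
        dosage = np.array([
            [1, 0, 0],
            [0, 0, 0],
            [1, 2, 1],
        ])
        cohort = make_cohort(records, dosage, sample_table=st)
        res = popgen.mendelian_check(cohort)
        trio = res["per_trio"].iloc[0]
        assert trio["n_sites"] == 3
        assert trio["violation_rate"] == pytest.approx(2 / 3)
        assert trio["de_novo_rate"] == pytest.approx(1 / 3)

    def test_no_trios_rejected(self, small_cohort):
        from svpopgen.sv_io import Cohort
        cohort = small_cohort.cohort
        unrel = cohort.samples.df[cohort.samples.df["is_unrelated"]]
        from svpopgen.sv_io import SampleTable
        pruned = Cohort(cohort.records, SampleTable(unrel.copy()), cohort.genotypes,
                        cohort.contigs)
        with pytest.raises(ValueError, match="trio"):
            popgen.mendelian_check(pruned)

    def test_violation_rate_monotone_in_genotyping_error(self, gene_fixtures):
        from svpopgen.synthetic import SimulationConfig, simulate_cohort
        rates = []
        for e in (0.0, 0.01, 0.05):
            cfg = SimulationConfig(seed=13, n_samples=80, n_trios=10,
                                   theta={"DEL": 150.0}, genotyping_error_rate=e)
            syn = simulate_cohort(cfg)
            rates.append(popgen.mendelian_check(syn.cohort)["median_violation_rate"])
        assert rates[0] == 0.0
        assert rates[0] < rates[1] < rates[2]


class TestLd:
    def test_identical_vectors(self):
        assert popgen.ld_r2([0, 1, 2, 0], [0, 1, 2, 0]) == pytest.approx(1.0)

    def test_hand_computed_zero_correlation(self):
        assert popgen.ld_r2([0, 1, 2, 0, 1, 2], [0, 1, 2, 2, 1, 0]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            popgen.ld_r2([1, 1, 1, 1], [0, 1, 2, 0])

    def test_simulated_haplotype_correlation_recovers_r2(self):
        from svpopgen.synthetic import simulate_ld_pair
        a, b = simulate_ld_pair(20_000, rho=0.9, af=0.3, seed=8)
        assert popgen.ld_r2(a, b) == pytest.approx(0.81, abs=0.02)


class TestSizeAf:
    def test_flat_af_profile(self):
        sites = pd.DataFrame({
            "svlen": np.logspace(2, 6, 200), "af": 0.25})
        prof = popgen.size_af_relationship(sites, n_size_bins=5, seed=1)
        assert np.allclose(prof["mean_af"], 0.25)
        assert ((prof["ci_lo"] <= 0.25) & (prof["ci_hi"] >= 0.25)).all()

    def test_monotone_decreasing_when_large_svs_are_rare(self):
        rng = np.random.default_rng(2)
        svlen = np.logspace(2, 6, 2_000)
        af = np.clip(0.5 / np.sqrt(svlen / 100) + rng.normal(0, 0.005, 2_000), 1e-4, 1)
        prof = popgen.size_af_relationship(
            pd.DataFrame({"svlen": svlen, "af": af}), n_size_bins=8, seed=3)
        from scipy.stats import spearmanr
        rho, _ = spearmanr(prof["size_bin"], prof["mean_af"])
        assert rho < -0.9

    def test_bootstrap_ci_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(4)
        def width(n):
            sites = pd.DataFrame({
                "svlen": np.full(n, 1000.0),
                "af": rng.uniform(0, 0.5, n)})
            prof = popgen.size_af_relationship(sites, n_size_bins=1, seed=5)
            return float((prof["ci_hi"] - prof["ci_lo"]).iloc[0])
        w1, w4 = width(400), width(1600)
        assert w4 < w1  # ~1/sqrt(n) scaling
        assert w4 / w1 == pytest.approx(0.5, abs=0.25)


class TestPca:
    def test_identical_samples_share_coordinates(self):
        d = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 1.0]])
        coords = popgen.pca_structure(d, n_components=2)
        np.testing.assert_allclose(coords[0], coords[1], atol=1e-12)

    def test_fewer_sites_than_components_rejected(self):
        with pytest.raises(ValueError):
            popgen.pca_structure(np.zeros((5, 2)), n_components=3)

    def test_single_population_shows_no_structure(self):
        from sklearn.metrics import silhouette_score
        rng = np.random.default_rng(6)
        d = rng.binomial(2, 0.3, size=(100, 300)).astype(float)
        coords = popgen.pca_structure(d)
        labels = ["a"] * 50 + ["b"] * 50  # arbitrary split of one population
        assert abs(silhouette_score(coords, labels)) < 0.05
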