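"""Carrier-frequency screens and exact binomial intervals."""
import numpy as np
import pytest

from svpopgen.clinical import (
    GenomicDisorderLocus, binomial_ci, gd_carrier_frequencies,
    gene_list_carrier_rate, large_rare_carrier_rate,
)
from svpopgen.sv_io import SVRecord

from conftest import make_cohort
import pandas as pd


class TestBinomialCi:
    def test_zero_carriers_lower_bound_is_zero(self):
        p, lo, hi = binomial_ci(0, 100)
        assert p == 0.0 and lo == 0.0 and hi > 0

    def test_beta_quantile_values(self):
        # frozen from independent beta-quantile computation
        _, lo, hi = binomial_ci(5, 100)
        assert (lo, hi) == (pytest.approx(0.016432, abs=1e-5),
                            pytest.approx(0.112835, abs=1e-5))
        _, lo, hi = binomial_ci(2, 10)
        assert (lo, hi) == (pytest.approx(0.025211, abs=1e-5),
                            pytest.approx(0.556095, abs=1e-5))

    def test_all_carriers_upper_bound_is_one(self):
        _, _, hi = binomial_ci(10, 10)
        assert hi == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(1, 0)
        with pytest.raises(ValueError):
            binomial_ci(5, 4)


def ten_sample_cnv_cohort():
    """One DEL overlapping the locus, carried by samples 0 and 3."""
    records = [
        SVRecord("del_hit", "chrA", 1_000_000, 1_800_000, "DEL", 800_000),
        SVRecord("del_small", "chrA", 1_000_000, 1_200_000, "DEL", 200_000),
        SVRecord("dup_wrong_way", "chrA", 1_000_000, 1_900_000, "DUP", 900_000),
    ]
    dosage = np.zeros((10, 3), dtype=int)
    dosage[0, 0] = 1
    dosage[3, 0] = 2
    dosage[5, 1] = 1   # covers only 25% of the region
    dosage[6, 2] = 1   # wrong dosage direction
    return make_cohort(records, dosage)


LOCUS = GenomicDisorderLocus("GD1", "chrA", 1_000_000, 1_800_000, "DEL")


class TestGdCarrierFrequencies:
    def test_two_of_ten_carriers_with_exact_ci(self):
        out = gd_carrier_frequencies(ten_sample_cnv_cohort(), [LOCUS])
        row = out.iloc[0]
        assert row["n_carriers"] == 2
        assert row["carrier_freq"] == pytest.approx(0.20)
        assert row["ci_lo"] == pytest.approx(0.0252, abs=1e-4)
        assert row["ci_hi"] == pytest.approx(0.5561, abs=1e-4)

    def test_wrong_dosage_direction_never_counts(self):
        dup_locus = GenomicDisorderLocus("GD2", "chrA", 1_000_000, 1_800_000, "DUP")
        out = gd_carrier_frequencies(ten_sample_cnv_cohort(), [dup_locus])
        assert out.iloc[0]["n_carriers"] == 1  # only the DUP carrier

    def test_partial_coverage_below_threshold_excluded(self):
        out = gd_carrier_frequencies(ten_sample_cnv_cohort(), [LOCUS],
                                     min_coverage=0.5)
        assert out.iloc[0]["n_carriers"] == 2  # del_small (25%) excluded
        out2 = gd_carrier_frequencies(ten_sample_cnv_cohort(), [LOCUS],
                                      min_coverage=0.2)
        assert out2.iloc[0]["n_carriers"] == 3

    def test_absent_chromosome_warns_and_returns_zero(self, caplog):
        ghost = GenomicDisorderLocus("GD3", "chrZ", 0, 1_000, "DEL")
        out = gd_carrier_frequencies(ten_sample_cnv_cohort(), [ghost])
        assert out.iloc[0]["carrier_freq"] == 0.0


class TestGeneListCarrierRate:
    def _cohort_with_plof(self):
        records = [SVRecord(f"sv{i}", "chrA", 1000 * i, 1000 * i + 100, "DEL", 100)
                   for i in range(4)]
        dosage = np.zeros((20, 4), dtype=int)
        dosage[0, 0] = 1
        dosage[1, 0] = 1
        dosage[2, 1] = 1
        dosage[4, 2] = 1  # sv2 is annotated to an unlisted gene
        cohort = make_cohort(records, dosage)
        pairs = pd.DataFrame([
            {"sv_id": "sv0", "gene_id": "listed1", "category": "pLoF"},
            {"sv_id": "sv1", "gene_id": "listed2", "category": "pLoF"},
            {"sv_id": "sv2", "gene_id": "unlisted", "category": "pLoF"},
            {"sv_id": "sv3", "gene_id": "listed1", "category": "copy_gain"},
        ])
        return cohort, pairs

    def test_hand_enumerated_rate(self):
        cohort, pairs = self._cohort_with_plof()
        res = gene_list_carrier_rate(cohort, pairs, {"listed1", "listed2"},
                                     af_threshold=0.5)
        assert res["carrier_rate"] == pytest.approx(3 / 20)

    def test_disjoint_gene_list_gives_zero(self):
        cohort, pairs = self._cohort_with_plof()
        res = gene_list_carrier_rate(cohort, pairs, {"nowhere"}, af_threshold=0.5)
        assert res["carrier_rate"] == 0.0

    def test_monotone_in_af_threshold(self):
        cohort, pairs = self._cohort_with_plof()
        rates = [gene_list_carrier_rate(cohort, pairs, {"listed1", "listed2"},
                                        af_threshold=t)["carrier_rate"]
                 for t in (0.01, 0.1, 0.9)]
        assert rates == sorted(rates)

    def test_empty_gene_list_rejected(self):
        cohort, pairs = self._cohort_with_plof()
        with pytest.raises(ValueError, match="empty"):
            gene_list_carrier_rate(cohort, pairs, set())


class TestLargeRareCarrierRate:
    def _cohort(self):
        records = [
            SVRecord("big_del", "chrA", 0, 2_000_000, "DEL", 2_000_000),
            SVRecord("big_inv", "chrB", 0, 1_500_000, "INV", 1_500_000),
            SVRecord("small", "chrA", 5_000_000, 5_000_100, "DEL", 100),
            SVRecord("big_common", "chrB", 8_000_000, 9_500_000, "DUP", 1_500_000),
        ]
        dosage = np.zeros((50, 4), dtype=int)
        dosage[0, 0] = 1          # big_del carrier
        dosage[1, 1] = 1          # big_inv carrier
        dosage[2, 2] = 1          # small SV only
        dosage[:40, 3] = 1        # big_common is too common to qualify
        return make_cohort(records, dosage)

    def test_hand_enumerated_rate_and_balanced_fraction(self):
        res = large_rare_carrier_rate(self._cohort(), af_threshold=0.05)
        assert res["n_carriers"] == 2
        assert res["carrier_rate"] == pytest.approx(0.04)
        assert res["balanced_complex_fraction"] == pytest.approx(0.5)

    def test_no_large_svs_gives_zero(self):
        res = large_rare_carrier_rate(self._cohort(), min_size=10_000_000)
        assert res["carrier_rate"] == 0.0

    def test_rate_nonincreasing_in_min_size(self):
        cohort = self._cohort()
        rates = [large_rare_carrier_rate(cohort, min_size=s, af_threshold=0.05)["carrier_rate"]
                 for s in (100, 1_000_000, 1_800_000)]
        assert rates[0] >= rates[1] >= rates[2]
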