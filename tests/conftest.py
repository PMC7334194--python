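import numpy as np
import pandas as pd
import pytest

from svpopgen.annotation import GeneModel, NoncodingElement
from svpopgen.sv_io import Cohort, GenotypeMatrix, SampleTable, SVRecord
from svpopgen.synthetic import SimulationConfig, simulate_cohort, simulate_gene_models

SMALL_THETA = {"DEL": 300.0, "INS": 220.0, "DUP": 130.0, "MCNV": 8.0,
               "INV": 10.0, "CPX": 12.0, "CTX": 2.0, "BND": 3.0}


@pytest.fixture(scope="session")
def gene_fixtures():
    """400 synthetic genes + elements + conservation track (seeded)."""
    return simulate_gene_models(400, seed=11)


@pytest.fixture(scope="session")
def small_cohort(gene_fixtures):
    """Desk-scale synthetic cohort: 120 samples, ~4k sites, 12 trios."""
    genes, elements, _ = gene_fixtures
    cfg = SimulationConfig(seed=7, n_samples=120, n_trios=12, theta=dict(SMALL_THETA))
    return simulate_cohort(cfg, genes=genes, elements=elements)


@pytest.fixture()
def toy_gene():
    """5-exon plus-strand gene on [10_000, 20_000); all exons fully coding."""
    exons = [(10_000, 10_200), (12_000, 12_200), (14_000, 14_200),
             (16_000, 16_200), (19_800, 20_000)]
    return GeneModel(gene_id="toy", chrom="chrA", start=10_000, end=20_000,
                     strand="+", exons=exons)


def make_cohort(records, dosage, sample_table=None, mcnv=None):
    """Hand-built cohort helper for enumeration tests."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples = dosage.shape[0]
    if sample_table is None:
        sample_table = SampleTable.all_unrelated([f"s{i}" for i in range(n_samples)])
    site_ids = [r.id for r in records if r.svtype != "MCNV"]
    mcnv_ids = [r.id for r in records if r.svtype == "MCNV"]
    cn = None
    if mcnv is not None:
        cn = np.asarray(mcnv, dtype=np.int16)
    gm = GenotypeMatrix(sample_table.sample_ids, site_ids, dosage, mcnv_ids, cn)
    cohort = Cohort(records, sample_table, gm, {})
    cohort.recompute_allele_stats(warn_on_mismatch=False)
    return cohort
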