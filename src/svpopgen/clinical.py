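"""Clinical carrier-frequency screens.

Three screens over an annotated cohort: carrier frequencies at genomic
disorder loci (recurrent pathogenic CNV regions, matched by dosage
direction and fractional coverage of the critical region), carrier rates
for very rare pLoF SVs in user-supplied clinical gene lists, and the rate
of carrying at least one very large (>= 1 Mb) rare SV. All proportions get
exact Clopper–Pearson binomial confidence intervals.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sv_io import Cohort

log = logging.getLogger(__name__)

BALANCED_OR_COMPLEX = ("INV", "CTX", "CPX")


@dataclass(frozen=True)
class GenomicDisorderLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    dosage_direction: str  # DEL or DUP

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.locus_id}: empty critical region")
        if self.dosage_direction not in ("DEL", "DUP"):
            raise ValueError(f"{self.locus_id}: dosage direction must be DEL or DUP")


def read_gd_loci(path) -> list[GenomicDisorderLocus]:
    """BED4+1: chrom, start, end, locus_id, dosage_direction."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["chrom", "start", "end", "locus_id", "dosage_direction"])
    return [GenomicDisorderLocus(r.locus_id, r.chrom, int(r.start), int(r.end),
                                 r.dosage_direction) for r in df.itertuples()]


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float, float]:
    """Clopper–Pearson interval: (proportion, lower, upper)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return k / n, lo, hi


def _carrier_mask(cohort: Cohort, qualifying_ids: list[str]) -> np.ndarray:
    gm = cohort.genotypes
    unrelated = cohort.samples.unrelated_ids
    cols = [gm._site_index[s] for s in qualifying_ids if s in gm._site_index]
    if not cols:
        return np.zeros(len(unrelated), dtype=bool)
    d = gm.sample_rows(unrelated)
    return (d[:, cols] > 0).any(axis=1)


def gd_carrier_frequencies(cohort: Cohort, loci: list[GenomicDisorderLocus],
                           min_coverage: float = 0.5) -> pd.DataFrame:
    """Per-locus carrier frequency, overall and per population.

    A carrier holds >= 1 PASS CNV call of the locus's dosage direction whose
    overlap covers at least ``min_coverage`` of the critical region; calls of
    the opposite dosage direction never count.
    """
    unrelated = cohort.samples.unrelated_ids
    pops = cohort.samples.population_of()
    pop_labels = sorted(set(pops[s] for s in unrelated))
    known_chroms = {r.chrom for r in cohort.records}
    rows = []
    for locus in loci:
        if locus.chrom not in known_chroms:
            log.warning("locus %s on chromosome %s absent from callset",
                        locus.locus_id, locus.chrom)
        qualifying = []
        width = locus.end - locus.start
        for r in cohort.analysis_records:
            if r.svtype != locus.dosage_direction or r.chrom != locus.chrom:
                continue
            overlap = max(0, min(r.end, locus.end) - max(r.start, locus.start))
            if overlap / width >= min_coverage:
                qualifying.append(r.id)
        carriers = _carrier_mask(cohort, qualifying)
        freq, lo, hi = binomial_ci(int(carriers.sum()), len(unrelated))
        row = {"locus_id": locus.locus_id, "dosage_direction": locus.dosage_direction,
               "n_carriers": int(carriers.sum()), "n_samples": len(unrelated),
               "carrier_freq": freq, "ci_lo": lo, "ci_hi": hi}
        for pop in pop_labels:
            idx = np.array([pops[s] == pop for s in unrelated])
            if idx.sum():
                pf, plo, phi = binomial_ci(int(carriers[idx].sum()), int(idx.sum()))
                row[f"freq_{pop}"] = pf
        rows.append(row)
    return pd.DataFrame(rows)


def gene_list_carrier_rate(cohort: Cohort, gene_pairs: pd.DataFrame,
                           gene_list: set[str] | list[str],
                           af_threshold: float = 0.001) -> dict:
    """Fraction of samples carrying >= 1 very rare pLoF SV in listed genes."""
    gene_list = set(gene_list)
    if not gene_list:
        raise ValueError("empty gene list")
    af = {r.id: r.af for r in cohort.records}
    qual = gene_pairs[
        (gene_pairs["category"] == "pLoF")
        & gene_pairs["gene_id"].isin(gene_list)
        & (gene_pairs["sv_id"].map(af).fillna(1.0) < af_threshold)
    ]["sv_id"].unique().tolist()
    carriers = _carrier_mask(cohort, qual)
    n = len(cohort.samples.unrelated_ids)
    rate, lo, hi = binomial_ci(int(carriers.sum()), n)
    return {"carrier_rate": rate, "ci": (lo, hi), "n_carriers": int(carriers.sum()),
            "n_samples": n, "n_qualifying_svs": len(qual)}


def large_rare_carrier_rate(cohort: Cohort, min_size: int = 1_000_000,
                            af_threshold: float = 0.01) -> dict:
    """Rate of carrying >= 1 very large rare SV, with balanced/complex share.

    Qualifying sites are PASS non-BND SVs with svlen >= min_size and
    AF < af_threshold. The balanced/complex fraction is computed over
    qualifying sites observed in >= 1 carrier (INV, CTX and CPX classes).
    """
    qual = [r for r in cohort.analysis_records
            if r.svlen >= min_size and r.af < af_threshold]
    # restrict to sites genotyped as biallelic columns
    gm = cohort.genotypes
    qual = [r for r in qual if r.id in gm._site_index]
    carriers = _carrier_mask(cohort, [r.id for r in qual])
    n = len(cohort.samples.unrelated_ids)
    rate, lo, hi = binomial_ci(int(carriers.sum()), n)
    d = gm.sample_rows(cohort.samples.unrelated_ids)
    carried = [r for r in qual if (d[:, gm._site_index[r.id]] > 0).any()]
    n_bal = sum(1 for r in carried if r.svtype in BALANCED_OR_COMPLEX)
    return {
        "carrier_rate": rate, "ci": (lo, hi), "n_carriers": int(carriers.sum()),
        "n_samples": n, "n_qualifying_svs": len(qual),
        "balanced_complex_fraction": (n_bal / len(carried)) if carried else float("nan"),
    }
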