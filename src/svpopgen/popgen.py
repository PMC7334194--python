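"""Allele-frequency, equilibrium, diversity, burden, LD and structure statistics.

Conventions: "rare" means AF < 1% and "very rare" AF < 0.1%; singletons are
allele count 1 among unrelated samples; the cohort-level Hardy–Weinberg
fraction counts sites with chi-square p >= 0.05 (threshold configurable).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import harmonic_number
from .sv_io import Cohort

RARE_AF = 0.01
VERY_RARE_AF = 0.001
HWE_ALPHA = 0.05


# --- Hardy–Weinberg ----------------------------------------------------------

def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Chi-square (1 df) Hardy–Weinberg test p-value from genotype counts.

    Expected counts are n*p^2, 2npq, n*q^2 at the observed allele frequency;
    monomorphic sites return p = 1 by convention.
    """
    counts = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative genotype counts")
    n = counts.sum()
    if n == 0:
        raise ValueError("no genotyped samples")
    q = (counts[1] + 2 * counts[2]) / (2 * n)
    p = 1 - q
    if q == 0 or q == 1:
        return 1.0
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def hwe_test_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy–Weinberg test (conditional on allele counts)."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotyped samples")
    n_a = n_het + 2 * n_hom_alt
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    n_a = min(n_a, 2 * n - n_a)
    hets = np.arange(n_a % 2, n_a + 1, 2)
    logp = np.array([
        _log_hwe_prob(n, n_a, int(h)) for h in hets
    ])
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == n_het][0] if np.any(hets == n_het) else 0.0
    return float(probs[probs <= obs + 1e-12].sum())


def _log_hwe_prob(n, n_a, n_het):
    from scipy.special import gammaln
    n_b = 2 * n - n_a
    n_aa = (n_a - n_het) // 2
    n_bb = (n_b - n_het) // 2
    return (gammaln(n + 1) - gammaln(n_aa + 1) - gammaln(n_het + 1) - gammaln(n_bb + 1)
            + n_het * np.log(2) + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1))


def hwe_site_pvalues(cohort: Cohort, exact: bool = False) -> pd.DataFrame:
    """Per-site HWE p-values over unrelated samples (biallelic sites)."""
    gm = cohort.genotypes
    unrelated = cohort.samples.unrelated_ids
    d = gm.sample_rows(unrelated)
    idx = {s: i for i, s in enumerate(gm.site_ids)}
    test = hwe_test_exact if exact else hwe_test
    rows = []
    for r in cohort.biallelic_records:
        if r.id not in idx:
            continue
        col = d[:, idx[r.id]]
        obs = col[col >= 0]
        if len(obs) == 0:
            continue
        n0 = int(np.sum(obs == 0)); n1 = int(np.sum(obs == 1)); n2 = int(np.sum(obs == 2))
        rows.append({"sv_id": r.id, "hwe_p": test(n0, n1, n2)})
    return pd.DataFrame(rows, columns=["sv_id", "hwe_p"])


def hwe_fraction(cohort: Cohort, alpha: float = HWE_ALPHA) -> float:
    """Fraction of biallelic sites consistent with HWE (p >= alpha)."""
    p = hwe_site_pvalues(cohort)
    if not len(p):
        return float("nan")
    return float(np.mean(p["hwe_p"] >= alpha))


# --- diversity / mutation rate ----------------------------------------------

def watterson_theta(n_segregating_sites: int, n_chromosomes: int) -> tuple[float, float]:
    """Watterson estimator: (theta_hat, a_n) with theta_hat = K / a_n."""
    if n_segregating_sites < 0:
        raise ValueError("negative segregating-site count")
    a_n = harmonic_number(n_chromosomes)
    return n_segregating_sites / a_n, a_n


def sv_mutation_rate(theta: float, effective_population_size: float,
                     n_chromosomes: int | None = None,
                     n_bootstrap: int = 100, seed: int = 0) -> dict:
    """De novo SVs per diploid genome per generation from Watterson's theta.

    theta = 4*Ne*mu gives the per-haploid-genome rate mu = theta / (4*Ne);
    the per-birth (diploid) rate is 2*mu. When ``n_chromosomes`` is given the
    95% CI comes from a parametric bootstrap of the segregating-site count
    (K* ~ Poisson(theta * a_n), re-estimating theta and the rate each time).
    """
    if effective_population_size <= 0:
        raise ValueError("Ne must be positive")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    mu = theta / (4.0 * effective_population_size)
    rate = 2.0 * mu
    if theta == 0:
        return {"theta": 0.0, "mu_haploid": 0.0, "rate_per_birth": 0.0,
                "ci": (0.0, 0.0), "ne": effective_population_size}
    ci = (rate, rate)
    if n_chromosomes is not None:
        rng = np.random.default_rng(seed)
        a_n = harmonic_number(n_chromosomes)
        k = theta * a_n
        ks = rng.poisson(k, size=n_bootstrap)
        rates = 2.0 * (ks / a_n) / (4.0 * effective_population_size)
        ci = tuple(np.quantile(rates, [0.025, 0.975]))
    return {"theta": theta, "mu_haploid": mu, "rate_per_birth": rate,
            "ci": (float(ci[0]), float(ci[1])), "ne": effective_population_size}


def births_per_new_sv(rate_ci: tuple[float, float]) -> tuple[int, int]:
    """Invert a per-birth rate CI into a 'one new SV every X–Y births' band."""
    lo, hi = rate_ci
    if lo <= 0 or hi <= 0:
        raise ValueError("rate CI must be positive")
    return (round(1.0 / hi), round(1.0 / lo))


# --- per-genome burden -------------------------------------------------------

BURDEN_CATEGORIES = ("pLoF", "copy_gain", "IED")


@dataclass
class BurdenSummary:
    per_sample: pd.DataFrame  # sample_id x (category, stratum) gene counts
    means: pd.DataFrame       # mean/median per (category, stratum)

    def mean(self, category: str, stratum: str = "all") -> float:
        return float(self.means.loc[
            (self.means["category"] == category) & (self.means["stratum"] == stratum),
            "mean"].iloc[0])


def per_genome_burden(cohort: Cohort, gene_pairs: pd.DataFrame,
                      rare_af: float = RARE_AF) -> BurdenSummary:
    """Genes altered per genome by category and AF stratum.

    A gene counts once per sample per category if the sample carries >= 1
    alternate allele of any SV annotated with that (gene, category) pair.
    Also reports homozygous-pLoF gene counts.
    """
    gm = cohort.genotypes
    unrelated = cohort.samples.unrelated_ids
    missing = set(unrelated) - set(gm.sample_ids)
    if missing:
        raise ValueError(f"samples missing from genotype matrix: {sorted(missing)[:3]}")
    d = gm.sample_rows(unrelated)
    site_idx = {s: i for i, s in enumerate(gm.site_ids)}
    af = {r.id: r.af for r in cohort.records}

    strata = {"all": lambda sv: True, "rare": lambda sv: af.get(sv, 0.0) < rare_af}
    results = {}
    hom_plof = np.zeros(len(unrelated), dtype=int)
    for category in BURDEN_CATEGORIES:
        cat_pairs = gene_pairs[gene_pairs["category"] == category]
        for stratum, keep in strata.items():
            counts = np.zeros(len(unrelated), dtype=int)
            for gene_id, grp in cat_pairs.groupby("gene_id"):
                cols = [site_idx[s] for s in grp["sv_id"]
                        if s in site_idx and keep(s)]
                if not cols:
                    continue
                hit = (d[:, cols] > 0).any(axis=1)
                counts += hit
                if category == "pLoF" and stratum == "all":
                    hom_plof += (d[:, cols] == 2).any(axis=1)
            results[(category, stratum)] = counts

    per_sample = pd.DataFrame({"sample_id": unrelated})
    for (cat, stratum), counts in results.items():
        per_sample[f"{cat}_{stratum}"] = counts
    per_sample["total_all"] = sum(results[(c, "all")] for c in BURDEN_CATEGORIES)
    per_sample["total_rare"] = sum(results[(c, "rare")] for c in BURDEN_CATEGORIES)
    per_sample["hom_pLoF"] = hom_plof

    rows = []
    for (cat, stratum), counts in results.items():
        rows.append({"category": cat, "stratum": stratum,
                     "mean": float(np.mean(counts)), "median": float(np.median(counts))})
    for stratum in ("all", "rare"):
        tot = per_sample[f"total_{stratum}"]
        rows.append({"category": "total", "stratum": stratum,
                     "mean": float(tot.mean()), "median": float(tot.median())})
    return BurdenSummary(per_sample, pd.DataFrame(rows))


def sv_share_of_plof(rare_plof_sv_mean: float, rare_ied_sv_mean: float,
                     rare_plof_snv_mean: float, include_ied: bool = True) -> float:
    """Percentage of rare per-genome gene-inactivating events contributed by SVs."""
    for v in (rare_plof_sv_mean, rare_ied_sv_mean, rare_plof_snv_mean):
        if v < 0:
            raise ValueError("means must be >= 0")
    sv = rare_plof_sv_mean + (rare_ied_sv_mean if include_ied else 0.0)
    denom = sv + rare_plof_snv_mean
    if denom == 0:
        raise ValueError("all-zero denominator")
    return 100.0 * sv / denom


# --- trios -------------------------------------------------------------------

def mendelian_check(cohort: Cohort) -> dict:
    """Per-trio Mendelian violation and apparent de novo rates.

    A site violates transmission if the child genotype is impossible given
    the parents (e.g. hom-alt child of a hom-ref parent). An apparent de novo
    is a het child of two hom-ref parents. Cohort medians are reported over
    trios; missing genotypes in a trio skip that site.
    """
    trios = cohort.samples.trios()
    if not trios:
        raise ValueError("no complete trios in the cohort")
    gm = cohort.genotypes
    biallelic = {r.id for r in cohort.biallelic_records}
    cols = [i for i, s in enumerate(gm.site_ids) if s in biallelic]
    rows = []
    for child, father, mother in trios:
        c = gm.sample_rows([child])[0][cols]
        f = gm.sample_rows([father])[0][cols]
        m = gm.sample_rows([mother])[0][cols]
        ok = (c >= 0) & (f >= 0) & (m >= 0)
        seg = ok & ((c > 0) | (f > 0) | (m > 0))  # sites informative in this trio
        c, f, m = c[seg], f[seg], m[seg]
        min_c = np.maximum(f == 2, 0) + np.maximum(m == 2, 0)
        max_c = (f > 0).astype(int) + (m > 0).astype(int)
        violation = (c < min_c) | (c > max_c)
        de_novo = (c == 1) & (f == 0) & (m == 0)
        n = int(seg.sum())
        rows.append({
            "child": child,
            "n_sites": n,
            "violation_rate": float(violation.mean()) if n else 0.0,
            "de_novo_rate": float(de_novo.mean()) if n else 0.0,
        })
    df = pd.DataFrame(rows)
    return {
        "per_trio": df,
        "median_violation_rate": float(df["violation_rate"].median()),
        "median_de_novo_rate": float(df["de_novo_rate"].median()),
    }


# --- LD ----------------------------------------------------------------------

def ld_r2(dosage_a, dosage_b) -> float:
    """Squared Pearson correlation of two dosage vectors (missing = -1 dropped)."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    keep = (a >= 0) & (b >= 0)
    a, b = a[keep], b[keep]
    if len(a) < 2 or np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("monomorphic site: zero variance")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


# --- size vs AF --------------------------------------------------------------

def size_af_relationship(sites: pd.DataFrame, n_size_bins: int = 10,
                         n_bootstrap: int = 100, seed: int = 0) -> pd.DataFrame:
    """Mean AF per log-spaced size bin with a 95% bootstrap CI over sites."""
    df = sites[sites["svlen"] > 0].copy()
    if not len(df):
        raise ValueError("no sites with positive svlen")
    edges = np.logspace(np.log10(df["svlen"].min()),
                        np.log10(df["svlen"].max() + 1), n_size_bins + 1)
    df["size_bin"] = np.clip(np.digitize(df["svlen"], edges) - 1, 0, n_size_bins - 1)
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_size_bins):
        af = df.loc[df["size_bin"] == b, "af"].to_numpy()
        if len(af) == 0:
            rows.append({"size_bin": b, "lo_bp": edges[b], "hi_bp": edges[b + 1],
                         "n": 0, "mean_af": np.nan, "ci_lo": np.nan, "ci_hi": np.nan})
            continue
        boots = np.array([
            af[rng.integers(0, len(af), len(af))].mean() for _ in range(n_bootstrap)])
        rows.append({"size_bin": b, "lo_bp": edges[b], "hi_bp": edges[b + 1],
                     "n": len(af), "mean_af": float(af.mean()),
                     "ci_lo": float(np.quantile(boots, 0.025)),
                     "ci_hi": float(np.quantile(boots, 0.975))})
    return pd.DataFrame(rows)


# --- structure ---------------------------------------------------------------

def pca_structure(dosage: np.ndarray, n_components: int = 3) -> np.ndarray:
    """Principal-component coordinates of samples from common-site dosages.

    Columns are centered and decomposed by SVD. Deterministic up to sign;
    signs are fixed by making the largest-magnitude loading of each
    component positive.
    """
    x = np.asarray(dosage, dtype=float)
    if x.shape[1] < n_components:
        raise ValueError("fewer sites than components")
    if x.shape[0] < n_components:
        raise ValueError("fewer samples than components")
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :n_components] * s[:n_components]
    for k in range(n_components):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            coords[:, k] *= -1
    return coords


def common_dosage_matrix(cohort: Cohort, min_af: float = RARE_AF) -> tuple[np.ndarray, list[str]]:
    """(unrelated-sample dosage matrix, site ids) restricted to common sites."""
    gm = cohort.genotypes
    unrelated = cohort.samples.unrelated_ids
    keep = [r.id for r in cohort.biallelic_records if r.af > min_af]
    cols = [gm._site_index[s] for s in keep if s in gm._site_index]
    d = gm.sample_rows(unrelated)[:, cols].astype(float)
    d[d < 0] = np.nan
    col_means = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(col_means, inds[1])
    return d, keep


# --- cohort-level summaries --------------------------------------------------

def cohort_summary(cohort: Cohort) -> dict:
    """Headline cohort statistics: counts, singleton and rare proportions."""
    sites = cohort.site_frame()
    bi = sites[sites["is_biallelic"]]
    gm = cohort.genotypes
    unrelated = cohort.samples.unrelated_ids
    d = gm.sample_rows(unrelated)
    per_genome = (d > 0).sum(axis=1)
    return {
        "n_sites": int(len(sites)),
        "n_biallelic": int(len(bi)),
        "singleton_proportion": float((bi["ac"] == 1).mean()) if len(bi) else float("nan"),
        "rare_proportion": float((bi["af"] < RARE_AF).mean()) if len(bi) else float("nan"),
        "median_svs_per_genome": float(np.median(per_genome)),
        "mean_svs_per_genome": float(np.mean(per_genome)),
    }
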