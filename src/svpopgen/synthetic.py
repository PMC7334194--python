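"""Synthetic SV cohorts with the statistical structure the analyses assume.

The generator emulates, at desk scale, the features of a cohort-scale SV
callset that the downstream statistics rely on:

* per-class site counts and allele counts drawn from the neutral
  infinite-sites spectrum (K ~ Poisson(theta * a_n), P(count=i) ∝ 1/i),
  optionally tilted by a growth-like exponent and by per-category selection
  shifts (resampling weight ∝ i^-s);
* Hardy–Weinberg genotypes with Balding–Nichols population differentiation,
  realized by allocating each site's drawn allele copies among populations
  (weights ∝ n_pop * p_pop with p_pop ~ Beta around the global frequency)
  and then uniformly among chromosomes within a population — this keeps the
  realized allele count equal to the drawn one, so the simulated spectrum is
  exactly the sampled spectrum;
* per-class size models: log-normal for CNVs/inversions and a 3-component
  log-normal mixture for insertions with modes near 300 bp, 2.1 kb and 6 kb
  (the Alu / SVA / LINE-1 mobile-element peaks);
* positional placement on a synthetic multi-arm genome with optional
  telomeric/centromeric enrichment per class;
* trios by Mendelian transmission, perturbed by a genotyping error rate;
* truth tables recording each site's intended functional category, selection
  strength and generative frequencies, for parameter-recovery tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._util import harmonic_number
from .annotation import GeneModel, NoncodingElement
from .cpx import AlleleStructure, Segment
from .sv_io import Cohort, GenotypeMatrix, SampleTable, SVRecord

# --- synthetic genome --------------------------------------------------------

#: (chrom, p-arm end, centromere end, chromosome end), bp
_GENOME = (
    ("chrA", 40_000_000, 44_000_000, 100_000_000),
    ("chrB", 30_000_000, 33_000_000, 80_000_000),
    ("chrC", 25_000_000, 28_000_000, 65_000_000),
    ("chrD", 15_000_000, 17_000_000, 50_000_000),
)


def synthetic_arm_map() -> pd.DataFrame:
    """Arm table (chrom, arm, start, end) for the synthetic genome."""
    rows = []
    for chrom, p_end, cen_end, q_end in _GENOME:
        rows.append({"chrom": chrom, "arm": "p", "start": 0, "end": p_end})
        rows.append({"chrom": chrom, "arm": "q", "start": cen_end, "end": q_end})
    return pd.DataFrame(rows)


def synthetic_contigs() -> dict[str, int]:
    return {chrom: end for chrom, _, _, end in _GENOME}


# --- configuration -----------------------------------------------------------

#: log-normal size models per class: (median bp, sigma of log size)
DEFAULT_SIZE_MODELS = {
    "DEL": (1_500.0, 1.4),
    "DUP": (5_000.0, 1.3),
    "INV": (3_000.0, 1.4),
    "CPX": (5_000.0, 1.1),
    "MCNV": (8_000.0, 0.9),
}
#: insertion mixture: (weight, median bp, sigma) — Alu / SVA / LINE-1 peaks
INS_MIXTURE = ((0.60, 300.0, 0.10), (0.25, 2_100.0, 0.15), (0.15, 6_000.0, 0.12))

#: per-class theta; proportions loosely follow a WGS SV callset (DEL- and
#: INS-dominated, inversions rare). At 500 samples these give ~20k sites.
DEFAULT_THETA = {
    "DEL": 1050.0, "INS": 800.0, "DUP": 420.0,
    "MCNV": 25.0, "INV": 30.0, "CPX": 40.0, "CTX": 5.0, "BND": 8.0,
}

#: telomeric / centromeric density multipliers (1 = uniform along the arm)
DEFAULT_POSITION_BIAS = {
    "DEL": {"tel": 1.6, "cen": 1.0},
    "DUP": {"tel": 1.2, "cen": 1.4},
    "MCNV": {"tel": 1.0, "cen": 1.8},
    "INS": {"tel": 1.0, "cen": 1.0},
    "INV": {"tel": 1.0, "cen": 1.0},
    "CPX": {"tel": 1.3, "cen": 1.0},
    "CTX": {"tel": 1.0, "cen": 1.0},
    "BND": {"tel": 1.0, "cen": 1.0},
}

#: AF down-shift (spectrum tilt exponent) per intended functional category
DEFAULT_SELECTION = {"pLoF": 0.35, "copy_gain": 0.15, "IED": 0.10}

#: probability a DEL/DUP site is deliberately placed to realize a category
DEFAULT_TARGETING = {
    "DEL": {"pLoF": 0.10, "intronic": 0.05, "promoter": 0.03, "intergenic": 0.82},
    "DUP": {"copy_gain": 0.06, "IED": 0.06, "intronic": 0.05, "intergenic": 0.83},
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a desk-scale cohort: 500 unrelated diploid samples in
    five continental populations with Balding–Nichols differentiation, 50
    trios, ~20,000 sites, a growth-like spectrum tilt that puts roughly half
    of all sites at allele count 1, and purifying selection injected on
    coding-overlap categories.
    """

    n_samples: int = 500
    population_proportions: dict = field(default_factory=lambda: {
        "AFR": 0.35, "AMR": 0.15, "EAS": 0.15, "EUR": 0.30, "OTH": 0.05})
    fst: dict = field(default_factory=lambda: {
        "AFR": 0.10, "AMR": 0.03, "EAS": 0.08, "EUR": 0.06, "OTH": 0.02})
    n_trios: int = 50
    theta: dict = field(default_factory=lambda: dict(DEFAULT_THETA))
    size_models: dict = field(default_factory=lambda: dict(DEFAULT_SIZE_MODELS))
    ins_mixture: tuple = INS_MIXTURE
    selection_map: dict = field(default_factory=lambda: dict(DEFAULT_SELECTION))
    targeting: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TARGETING.items()})
    position_bias: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_POSITION_BIAS.items()})
    sfs_tilt: float = 0.8
    genotyping_error_rate: float = 2e-4
    seed: int = 0

    def __post_init__(self):
        total = sum(self.population_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population proportions sum to {total}, not 1")
        for name, value in [("theta", self.theta), ("selection_map", self.selection_map)]:
            for k, v in value.items():
                if v < 0:
                    raise ValueError(f"{name}[{k}] = {v} < 0")
        if self.genotyping_error_rate < 0 or self.genotyping_error_rate > 1:
            raise ValueError("genotyping error rate outside [0,1]")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.seed is None:
            raise ValueError("seed is mandatory")


# --- spectrum ----------------------------------------------------------------

def simulate_sfs(theta: float, n_chromosomes: int, seed=None, tilt: float = 0.0,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw site allele counts from the (optionally tilted) neutral spectrum.

    The number of segregating sites is K ~ Poisson(theta * a_n); each site's
    count i in 1..n-1 has probability ∝ i^-(1+tilt). With tilt = 0 this is
    the standard infinite-sites neutral spectrum, with expected singleton
    fraction 1/a_n.
    """
    if n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    a_n = harmonic_number(n_chromosomes)
    k = rng.poisson(theta * a_n)
    if k == 0:
        return np.array([], dtype=int)
    i = np.arange(1, n_chromosomes)
    w = i.astype(float) ** (-(1.0 + tilt))
    return rng.choice(i, size=k, p=w / w.sum())


def _tilted_counts(rng, n_chromosomes, size, tilt):
    i = np.arange(1, n_chromosomes)
    w = i.astype(float) ** (-(1.0 + tilt))
    return rng.choice(i, size=size, p=w / w.sum())


# --- gene models -------------------------------------------------------------

def simulate_gene_models(n_genes: int, seed: int, n_elements: int = 300,
                         n_element_classes: int = 14):
    """Synthetic gene models, noncoding elements and a conservation track.

    Genes have 2–30 exons on random strands with UTR-trimmed first/last
    exons; a constraint rank (a permutation of 1..n_genes) stands in for an
    SNV-constraint ordering. Elements fall into ``n_element_classes``
    classes. The conservation track is elevated over exons and over half of
    the element classes, with low background elsewhere.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    arms = synthetic_arm_map()
    genes: list[GeneModel] = []
    occupied: dict[str, IntervalTree] = {c: IntervalTree() for c in synthetic_contigs()}
    i = 0
    attempts = 0
    while i < n_genes and attempts < 50 * n_genes:
        attempts += 1
        arm = arms.iloc[rng.integers(len(arms))]
        n_exons = int(rng.integers(2, 31))
        exon_sizes = np.maximum(60, rng.lognormal(np.log(150), 0.5, n_exons)).astype(int)
        intron_sizes = np.maximum(200, rng.lognormal(np.log(2_000), 0.8, n_exons - 1)).astype(int)
        span = int(exon_sizes.sum() + intron_sizes.sum())
        lo, hi = int(arm["start"]) + 10_000, int(arm["end"]) - span - 10_000
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        if occupied[arm["chrom"]].overlap(start - 5_000, start + span + 5_000):
            continue
        exons = []
        pos = start
        for j in range(n_exons):
            exons.append((pos, pos + int(exon_sizes[j])))
            pos += int(exon_sizes[j])
            if j < n_exons - 1:
                pos += int(intron_sizes[j])
        end = exons[-1][1]
        utr5 = min(int(rng.integers(0, max(1, exon_sizes[0] // 2))), exon_sizes[0] - 10)
        utr3 = min(int(rng.integers(0, max(1, exon_sizes[-1] // 2))), exon_sizes[-1] - 10)
        genes.append(GeneModel(
            gene_id=f"gene{i:05d}", chrom=str(arm["chrom"]), start=start, end=end,
            strand="+" if rng.random() < 0.5 else "-", exons=exons,
            cds_start=start + max(0, utr5), cds_end=end - max(0, utr3),
        ))
        occupied[arm["chrom"]].addi(start, end)
        i += 1
    if len(genes) < n_genes:
        raise RuntimeError("could not place all genes on the synthetic genome")
    ranks = rng.permutation(n_genes) + 1
    for g, r in zip(genes, ranks):
        g.constraint_rank = int(r)

    elements: list[NoncodingElement] = []
    for j in range(n_elements):
        arm = arms.iloc[rng.integers(len(arms))]
        size = int(np.clip(rng.lognormal(np.log(800), 0.6), 100, 20_000))
        lo, hi = int(arm["start"]), int(arm["end"]) - size
        start = int(rng.integers(lo, hi))
        cls = f"class{int(j % n_element_classes):02d}"
        elements.append(NoncodingElement(f"el{j:05d}", str(arm["chrom"]), start, start + size, cls))

    conserved_classes = {f"class{c:02d}" for c in range(0, n_element_classes, 2)}
    track = ConservationTrack.build(genes, elements, conserved_classes, rng)
    return genes, elements, track


class ConservationTrack:
    """Sparse per-base conservation scores; unlisted positions score 0."""

    def __init__(self, intervals: pd.DataFrame):
        # columns: chrom, start, end, score
        self.intervals = intervals.reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}
        for _, row in self.intervals.iterrows():
            self._trees.setdefault(row["chrom"], IntervalTree()).addi(
                int(row["start"]), int(row["end"]), float(row["score"]))

    @classmethod
    def build(cls, genes, elements, conserved_classes, rng) -> "ConservationTrack":
        rows = []
        for g in genes:
            for s, e in g.exons:
                rows.append({"chrom": g.chrom, "start": s, "end": e,
                             "score": float(np.clip(rng.normal(0.8, 0.1), 0, 1))})
        for el in elements:
            base = 0.7 if el.element_class in conserved_classes else 0.1
            rows.append({"chrom": el.chrom, "start": el.start, "end": el.end,
                         "score": float(np.clip(rng.normal(base, 0.08), 0, 1))})
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "score"]))

    def score_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base scores over [start, end); gaps contribute 0."""
        total = 0.0
        for iv in self._trees.get(chrom, IntervalTree()).overlap(start, end):
            total += iv.data * max(0, min(end, iv.end) - max(start, iv.begin))
        return total

    def to_bedgraph(self, path):
        self.intervals.sort_values(["chrom", "start"]).to_csv(
            path, sep="\t", index=False, header=False)

    @classmethod
    def from_bedgraph(cls, path) -> "ConservationTrack":
        df = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "score"])
        return cls(df)


# --- placement helpers -------------------------------------------------------

def _sample_position(rng, arms, bias, size) -> tuple[str, int]:
    """Place an interval of ``size`` bp on a random arm with edge bias.

    Arms are chosen proportionally to length; within an arm the position is
    drawn uniformly and accepted with a weight that multiplies density by
    ``tel`` within 10% of the telomeric end and by ``cen`` within 10% of the
    centromeric end.
    """
    lengths = (arms["end"] - arms["start"]).to_numpy(float)
    w_tel = bias.get("tel", 1.0)
    w_cen = bias.get("cen", 1.0)
    wmax = max(1.0, w_tel, w_cen)
    while True:
        arm = arms.iloc[rng.choice(len(arms), p=lengths / lengths.sum())]
        lo, hi = int(arm["start"]), int(arm["end"])
        if hi - lo <= size + 2:
            continue
        pos = int(rng.integers(lo, hi - size))
        frac = (pos - lo) / (hi - lo)
        tel_frac = frac if arm["arm"] == "p" else 1.0 - frac
        w = 1.0
        if tel_frac < 0.10:
            w = w_tel
        elif tel_frac > 0.90:
            w = w_cen
        if rng.random() * wmax <= w:
            return str(arm["chrom"]), pos


def _targeted_interval(rng, category, svtype, genes) -> tuple[str, int, int] | None:
    """Coordinates that unambiguously realize ``category`` for ``svtype``."""
    for _ in range(40):
        g = genes[rng.integers(len(genes))]
        coding = g.coding_exons()
        if category == "pLoF" and svtype == "DEL" and coding:
            s, e = coding[rng.integers(len(coding))]
            pad = int(rng.integers(10, 200))
            return g.chrom, max(0, s - pad), e + pad
        if category == "copy_gain" and svtype == "DUP":
            pad = int(rng.integers(1_000, 10_000))
            return g.chrom, max(0, g.start - pad), g.end + pad
        if category == "IED" and svtype == "DUP" and len(coding) >= 3:
            k = rng.integers(1, len(coding) - 1)
            s, e = coding[k]
            prev_end = coding[k - 1][1]
            next_start = coding[k + 1][0]
            if s - prev_end > 20 and next_start - e > 20:
                return g.chrom, int(prev_end + (s - prev_end) // 2), int(e + (next_start - e) // 2)
        if category == "intronic" and len(g.exons) >= 2:
            k = rng.integers(len(g.exons) - 1)
            s, e = g.exons[k][1], g.exons[k + 1][0]
            if e - s > 400:
                return g.chrom, s + 100, e - 100
        if category == "promoter":
            ps, pe = g.promoter()
            if pe - ps > 400:
                return g.chrom, ps + 100, pe - 100
    return None


def _random_cpx_structure(rng, chrom, start, size) -> tuple[AlleleStructure, str]:
    """A random complex allele at (chrom, start) with footprint ~size bp."""
    kind = rng.choice(["delINV", "INVdel", "dupINV", "INVdup",
                       "delINVdel", "dupINVdup", "delINVdup", "dupINVdel",
                       "dDUP", "dDUP_iDEL", "INS_iDEL"])
    third = max(50, size // 3)
    a, b, c = start, start + third, start + 2 * third
    d = start + 3 * third
    def flank(tok, s, e):
        return Segment(chrom, s, e, "+", 0 if tok == "del" else 2)
    inv = lambda s, e: Segment(chrom, s, e, "-", 1)
    if kind in ("delINV", "INVdel", "dupINV", "INVdup"):
        f = flank("del" if "del" in kind else "dup", a, b)
        segs = [f, inv(b, c)] if kind.startswith(("del", "dup")) else [inv(a, b), flank("del" if "del" in kind else "dup", b, c)]
    elif kind in ("delINVdel", "dupINVdup", "delINVdup", "dupINVdel"):
        left = "del" if kind.startswith("del") else "dup"
        right = "del" if kind.endswith("del") else "dup"
        segs = [flank(left, a, b), inv(b, c), flank(right, c, d)]
    elif kind in ("dDUP", "dDUP_iDEL"):
        sink = start + 10 * third
        segs = [Segment(chrom, a, b, "+" if rng.random() < 0.5 else "-", 2,
                        inserted_at=(chrom, sink))]
        if kind == "dDUP_iDEL":
            segs.append(Segment(chrom, sink - 200, sink + 200, "+", 0))
    else:  # INS_iDEL
        sink = start + third
        segs = [Segment("*", 0, max(60, third), "+", 2, inserted_at=(chrom, sink)),
                Segment(chrom, sink - 150, sink + 150, "+", 0)]
    return AlleleStructure(segs), str(kind)


# --- the cohort generator ----------------------------------------------------

@dataclass
class SyntheticCohort:
    cohort: Cohort
    truth_sites: pd.DataFrame
    genes: list[GeneModel] | None = None
    elements: list[NoncodingElement] | None = None
    conservation: ConservationTrack | None = None


def _build_samples(config: SimulationConfig, rng) -> SampleTable:
    pops = list(config.population_proportions)
    probs = np.array([config.population_proportions[p] for p in pops])
    counts = rng.multinomial(config.n_samples, probs)
    rows = []
    k = 0
    for pop, c in zip(pops, counts):
        for _ in range(c):
            rows.append({"sample_id": f"s{k:05d}", "population": pop,
                         "sex": "F" if rng.random() < 0.5 else "M",
                         "father_id": "", "mother_id": "", "is_unrelated": True})
            k += 1
    df = pd.DataFrame(rows)
    # trios: pick disjoint parent couples among unrelated samples; the child
    # is an extra, related sample
    n_trios = min(config.n_trios, len(df) // 2)
    parents = rng.choice(len(df), size=2 * n_trios, replace=False)
    for t in range(n_trios):
        f, m = df.iloc[parents[2 * t]]["sample_id"], df.iloc[parents[2 * t + 1]]["sample_id"]
        rows.append({"sample_id": f"fam{t:03d}_child", "population":
                     df.iloc[parents[2 * t]]["population"],
                     "sex": "F" if rng.random() < 0.5 else "M",
                     "father_id": f, "mother_id": m, "is_unrelated": False})
    return SampleTable(pd.DataFrame(rows))


def _place_alleles(rng, ac, pop_of_sample, pop_index, fst, n_unrelated) -> np.ndarray:
    """Distribute ``ac`` allele copies over 2*n_unrelated chromosomes.

    Population shares follow Balding–Nichols frequencies around the global
    frequency; copies land uniformly on chromosomes within a population, so
    within-population genotypes satisfy HWE by exchangeability and the
    realized total count equals ``ac`` exactly.
    """
    n_chrom = 2 * n_unrelated
    p_global = ac / n_chrom
    weights = np.zeros(len(pop_index))
    for pop, (idx, f) in pop_index.items():
        if f > 0 and 0 < p_global < 1:
            a = p_global * (1 - f) / f
            b = (1 - p_global) * (1 - f) / f
            p_pop = rng.beta(a, b)
        else:
            p_pop = p_global
        weights[idx] = len(pop_of_sample[pop]) * 2 * p_pop
    dosage = np.zeros(n_unrelated, dtype=np.int8)
    if weights.sum() == 0:
        weights[:] = 1.0
    shares = rng.multinomial(ac, weights / weights.sum())
    for pop, (idx, _) in pop_index.items():
        share = shares[idx]
        members = pop_of_sample[pop]
        n_ch = 2 * len(members)
        if share > n_ch:
            share = n_ch
        if share == 0:
            continue
        chroms = rng.choice(n_ch, size=share, replace=False)
        for ch in chroms:
            dosage[members[ch // 2]] += 1
    return dosage


def simulate_cohort(config: SimulationConfig,
                    genes: list[GeneModel] | None = None,
                    elements: list[NoncodingElement] | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config``.

    Reproducible given the seed. When gene models are supplied (or generated
    via :func:`simulate_gene_models`), a configured fraction of DEL/DUP sites
    is deliberately placed to realize known functional categories, and
    selection-map categories have their allele counts redrawn from the tilted
    spectrum; the truth table records both.
    """
    root = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(6)]
    r_samples, r_sites, r_place, r_geno, r_trio, r_err = rngs

    samples = _build_samples(config, r_samples)
    unrelated = samples.unrelated_ids
    n_unrel = len(unrelated)
    n_chrom = 2 * n_unrel
    arms = synthetic_arm_map()

    pop_map = samples.population_of()
    pop_of_sample: dict[str, list[int]] = {}
    for i, s in enumerate(unrelated):
        pop_of_sample.setdefault(pop_map[s], []).append(i)
    pop_index = {pop: (k, config.fst.get(pop, 0.0))
                 for k, pop in enumerate(sorted(pop_of_sample))}

    records: list[SVRecord] = []
    truth_rows: list[dict] = []
    dosage_cols: list[np.ndarray] = []
    site_ids: list[str] = []
    mcnv_ids: list[str] = []
    cn_cols: list[np.ndarray] = []

    site_no = 0
    for svtype in sorted(config.theta):
        theta = config.theta[svtype]
        if theta <= 0:
            continue
        counts = simulate_sfs(theta, n_chrom, tilt=config.sfs_tilt, rng=r_sites)
        for ac in counts:
            site_no += 1
            sv_id = f"{svtype}_{site_no:06d}"
            # size
            if svtype == "INS":
                w = np.array([m[0] for m in config.ins_mixture])
                comp = config.ins_mixture[r_place.choice(len(w), p=w / w.sum())]
                size = int(max(50, r_place.lognormal(np.log(comp[1]), comp[2])))
            elif svtype in ("CTX", "BND"):
                size = 1
            else:
                med, sig = config.size_models[svtype]
                size = int(np.clip(r_place.lognormal(np.log(med), sig), 50, 5_000_000))
            # intended category and placement
            category = "unplaced"
            placed = None
            if genes is not None and svtype in config.targeting:
                targets = config.targeting[svtype]
                cats = list(targets)
                probs = np.array([targets[c] for c in cats], dtype=float)
                probs = probs / probs.sum()
                intended = str(cats[r_place.choice(len(cats), p=probs)])
                if intended != "intergenic":
                    placed = _targeted_interval(r_place, intended, svtype, genes)
                    if placed is not None:
                        category = intended
            if placed is not None:
                chrom, start, end = placed
                size = max(end - start, 1)
            else:
                chrom, start = _sample_position(
                    r_place, arms, config.position_bias.get(svtype, {}), size)
                end = start + (0 if svtype == "INS" else size)
            if svtype == "INS":
                end = start
            # selection: redraw allele count from the selected spectrum
            s_shift = config.selection_map.get(category, 0.0)
            if s_shift > 0:
                ac = int(_tilted_counts(r_sites, n_chrom, 1, config.sfs_tilt + s_shift)[0])

            structure = cpx_type = None
            chrom2 = pos2 = None
            if svtype == "CPX":
                structure, cpx_type = _random_cpx_structure(r_place, chrom, start, size)
                _, s0, e0 = structure.span()
                start, end = s0, max(e0, s0 + 1)
                size = max(end - start, 1)
            if svtype == "CTX":
                other = [c for c in synthetic_contigs() if c != chrom]
                chrom2 = str(other[r_place.integers(len(other))])
                pos2 = int(r_place.integers(10_000, synthetic_contigs()[chrom2] - 10_000))
                end = start + 1

            rec = SVRecord(
                id=sv_id, chrom=chrom, start=start, end=end, svtype=svtype,
                svlen=size, cpx_structure=structure, cpx_type=cpx_type,
                chrom2=chrom2, pos2=pos2,
            )
            records.append(rec)
            truth_rows.append({
                "sv_id": sv_id, "svtype": svtype, "true_category": category,
                "selection_s": s_shift, "drawn_ac": int(ac),
                "global_af": ac / n_chrom,
            })
            if svtype == "MCNV":
                base = np.full(len(samples), 2, dtype=np.int16)
                n_carriers = max(1, int(ac))
                carriers = r_geno.choice(len(samples), size=min(n_carriers, len(samples)),
                                         replace=False)
                base[carriers] += r_geno.choice([-2, -1, 1, 2], size=len(carriers))
                base = np.maximum(base, 0)
                mcnv_ids.append(sv_id)
                cn_cols.append(base)
            elif svtype == "BND":
                dosage_unrel = _place_alleles(r_geno, int(ac), pop_of_sample, pop_index,
                                              config.fst, n_unrel)
                site_ids.append(sv_id)
                dosage_cols.append(dosage_unrel)
            else:
                dosage_unrel = _place_alleles(r_geno, int(ac), pop_of_sample, pop_index,
                                              config.fst, n_unrel)
                site_ids.append(sv_id)
                dosage_cols.append(dosage_unrel)

    # expand dosage to all samples (children transmitted from parents)
    all_ids = samples.sample_ids
    unrel_index = {s: i for i, s in enumerate(unrelated)}
    n_sites = len(site_ids)
    dosage = np.zeros((len(all_ids), n_sites), dtype=np.int8)
    unrel_block = (np.stack(dosage_cols, axis=1) if n_sites
                   else np.zeros((n_unrel, 0), dtype=np.int8))
    for i, s in enumerate(all_ids):
        if s in unrel_index:
            dosage[i] = unrel_block[unrel_index[s]]
    for child, father, mother in samples.trios():
        ci = all_ids.index(child)
        fd = unrel_block[unrel_index[father]]
        md = unrel_block[unrel_index[mother]]
        from_f = np.where(fd == 2, 1, np.where(fd == 1, r_trio.integers(0, 2, n_sites), 0))
        from_m = np.where(md == 2, 1, np.where(md == 1, r_trio.integers(0, 2, n_sites), 0))
        dosage[ci] = (from_f + from_m).astype(np.int8)

    # genotyping errors: each call flips to a different genotype w.p. e
    e = config.genotyping_error_rate
    if e > 0 and n_sites:
        flip = r_err.random(dosage.shape) < e
        shift = r_err.integers(1, 3, size=dosage.shape)
        dosage = np.where(flip, (dosage + shift) % 3, dosage).astype(np.int8)

    cn = None
    if cn_cols:
        cn = np.stack(cn_cols, axis=1)
    gm = GenotypeMatrix(all_ids, site_ids, dosage, mcnv_ids, cn)
    cohort = Cohort(records, samples, gm, synthetic_contigs())
    cohort.recompute_allele_stats(warn_on_mismatch=False)
    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(cohort, truth, genes, elements, None)


# --- direct helpers for module-level tests -----------------------------------

def simulate_hwe_genotypes(n_sites: int, n_samples: int, seed: int,
                           af_range=(0.05, 0.5)) -> np.ndarray:
    """Genotype matrix drawn under exact binomial HWE (for test calibration)."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(*af_range, size=n_sites)
    return rng.binomial(2, p[None, :], size=(n_samples, n_sites)).astype(np.int8)


def simulate_ld_pair(n_samples: int, rho: float, af: float, seed: int):
    """Two dosage vectors with haplotype-level allele correlation ``rho``."""
    rng = np.random.default_rng(seed)
    a = rng.random((n_samples, 2)) < af
    keep = rng.random((n_samples, 2)) < rho
    b = np.where(keep, a, rng.random((n_samples, 2)) < af)
    return a.sum(axis=1).astype(float), b.sum(axis=1).astype(float)


def simulate_gene_counts(genes: list[GeneModel], seed: int,
                         base_rate: float = 5.0,
                         covariate_effect: float = 0.5,
                         depletion_by_rank: float = 0.0) -> pd.DataFrame:
    """Per-gene rare-SV counts from a known Poisson log-linear model.

    Expected count = base_rate * (L/L0)^covariate_effect * (1 - d), where d
    increases linearly from 0 to ``depletion_by_rank`` as the constraint rank
    goes from least to most constrained (rank 1 = most constrained).
    """
    rng = np.random.default_rng(seed)
    n = len(genes)
    rows = []
    med_len = float(np.median([g.transcript_length for g in genes]))
    for g in genes:
        mu = base_rate * (g.transcript_length / med_len) ** covariate_effect
        frac = 1.0 - (g.constraint_rank - 1) / max(1, n - 1)  # 1 at rank 1
        d = depletion_by_rank * frac
        rows.append({
            "gene_id": g.gene_id, "constraint_rank": g.constraint_rank,
            "transcript_length": g.transcript_length, "n_exons": g.n_exons,
            "intron_length": g.total_intron_length,
            "true_depletion": d,
            "observed": rng.poisson(mu * (1.0 - d)),
        })
    return pd.DataFrame(rows)
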