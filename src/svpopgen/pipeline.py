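"""End-to-end pipeline: simulate or load a cohort, then run every stage.

The pipeline is deterministic given the configured seed: stage RNG streams
are derived from it, and the JSON summary is written with sorted keys and
rounded floats so identical configurations produce byte-identical output.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, aps, clinical, constraint, cpx, metachrom, popgen, sv_io
from . import synthetic

log = logging.getLogger(__name__)

ALL_STAGES = ("annotate", "popgen", "aps", "constraint", "metachrom", "cpx", "clinical")


@dataclass
class RunConfig:
    seed: int = 0
    simulate: bool = True
    sim: synthetic.SimulationConfig | None = None
    n_genes: int = 600
    vcf_path: str | None = None
    sample_table_path: str | None = None
    gene_models_path: str | None = None
    stages: tuple = ALL_STAGES
    out_dir: str = "svpg_out"
    ne: float = 10_000.0
    write_vcf: bool = False


def _round(obj, ndigits=6):
    if isinstance(obj, dict):
        return {k: _round(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        v = float(obj)
        return None if np.isnan(v) else round(v, ndigits)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and write TSV tables plus a JSON summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}

    genes = elements = track = None
    truth = None
    if config.simulate:
        sim = config.sim or synthetic.SimulationConfig(seed=config.seed)
        stage_seed = np.random.SeedSequence(config.seed).spawn(1)[0].generate_state(1)[0] % (2**31)
        genes, elements, track = synthetic.simulate_gene_models(
            config.n_genes, seed=int(stage_seed))
        syn = synthetic.simulate_cohort(sim, genes=genes, elements=elements)
        cohort, truth = syn.cohort, syn.truth_sites
        truth.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
        cohort.samples.to_tsv(out / "samples.tsv")
        if config.write_vcf:
            sv_io.write_sv_vcf(cohort, out / "cohort.vcf")
    else:
        if not config.vcf_path:
            raise RuntimeError("stage 'load' failed: no VCF path configured")
        st = (sv_io.SampleTable.from_tsv(config.sample_table_path)
              if config.sample_table_path else None)
        cohort = sv_io.read_sv_vcf(config.vcf_path, sample_table=st)

    needs_genes = {"annotate", "popgen", "aps", "constraint", "clinical"}
    if genes is None and needs_genes & set(config.stages):
        if config.gene_models_path is None:
            missing = sorted(needs_genes & set(config.stages))
            raise RuntimeError(
                f"stages {missing} require gene models: no gene_models_path configured")

    arm_map = synthetic.synthetic_arm_map()
    sites = cohort.site_frame()
    ann = None
    try:
        if "annotate" in config.stages:
            ann = annotation.annotate_cohort(cohort, genes, elements)
            ann.gene_pairs.to_csv(out / "gene_annotations.tsv", sep="\t", index=False)
            sv_io.write_sites_bed(cohort, out / "sites.bed", annotations=ann.worst)
            summary["annotate"] = {"category_counts": {
                k: int(v) for k, v in sorted(ann.category_counts.items())}}

        if "popgen" in config.stages:
            summary["popgen"] = _popgen_stage(cohort, sites, ann, config, out)

        if "aps" in config.stages and ann is not None:
            summary["aps"] = _aps_stage(cohort, sites, ann, track, config, out)

        if "constraint" in config.stages and ann is not None:
            summary["constraint"] = _constraint_stage(cohort, sites, ann, genes, out)

        if "metachrom" in config.stages:
            profiles = metachrom.profile_enrichment(cohort.analysis_records, arm_map)
            tests = metachrom.positional_tests(profiles)
            tests.to_csv(out / "positional_tests.tsv", sep="\t", index=False)
            summary["metachrom"] = {
                "n_classes": len(profiles),
                "n_significant": int(tests["significant"].sum()),
                "bonferroni_k": int(tests["bonferroni_k"].iloc[0]) if len(tests) else 0,
            }

        if "cpx" in config.stages:
            summary["cpx"] = _cpx_stage(cohort, out)

        if "clinical" in config.stages and ann is not None:
            summary["clinical"] = _clinical_stage(cohort, ann, genes, out)
    except Exception as err:
        raise RuntimeError(f"pipeline stage failed: {err}") from err

    payload = _round(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return payload


def _popgen_stage(cohort, sites, ann, config, out):
    block = popgen.cohort_summary(cohort)
    block["hwe_fraction"] = popgen.hwe_fraction(cohort)
    bi = sites[sites["is_biallelic"]]
    n_chrom = int(bi["an"].max()) if len(bi) else 0
    if n_chrom >= 2:
        k = int((bi["ac"] > 0).sum())
        theta, a_n = popgen.watterson_theta(k, n_chrom)
        rate = popgen.sv_mutation_rate(theta, config.ne, n_chromosomes=n_chrom,
                                       seed=config.seed)
        block["watterson_theta"] = theta
        block["a_n"] = a_n
        block["mutation_rate_per_birth"] = rate["rate_per_birth"]
        block["mutation_rate_ci"] = list(rate["ci"])
    if cohort.samples.trios():
        mend = popgen.mendelian_check(cohort)
        block["median_mendelian_violation_rate"] = mend["median_violation_rate"]
        block["median_de_novo_rate"] = mend["median_de_novo_rate"]
    if ann is not None and len(ann.gene_pairs):
        burden = popgen.per_genome_burden(cohort, ann.gene_pairs)
        burden.means.to_csv(out / "burden.tsv", sep="\t", index=False)
        block["mean_genes_altered"] = burden.mean("pLoF") + burden.mean("copy_gain") + burden.mean("IED")
        for cat in popgen.BURDEN_CATEGORIES:
            block[f"mean_genes_{cat}"] = burden.mean(cat)
            block[f"mean_genes_{cat}_rare"] = burden.mean(cat, "rare")
    saf = popgen.size_af_relationship(bi, seed=config.seed)
    saf.to_csv(out / "size_af.tsv", sep="\t", index=False)
    d, _ = popgen.common_dosage_matrix(cohort)
    if d.shape[1] >= 3:
        coords = popgen.pca_structure(d)
        block["pca_pc1_sd"] = float(np.std(coords[:, 0]))
    return block


def _aps_stage(cohort, sites, ann, track, config, out):
    bi = sites[sites["is_biallelic"]].merge(ann.worst, on="sv_id")
    ref = bi[bi["worst_consequence"] == "intergenic"]
    model = aps.fit_singleton_model(ref)
    model.to_json(out / "aps_model.json")
    table = aps.aps_by_category(bi, model, "worst_consequence", seed=config.seed)
    table.to_csv(out / "aps_by_category.tsv", sep="\t", index=False)
    block = {"n_reference": len(ref),
             "by_category": {row["category"]: row["aps"] for _, row in table.iterrows()}}
    if len(ann.element_pairs):
        cls = aps.score_element_classes(bi, ann.element_pairs, model, seed=config.seed)
        try:
            paired = aps.aps_full_vs_partial(cls)
            block["full_vs_partial"] = {
                "n_classes": paired["n_classes"],
                "mean_difference": paired["mean_difference"],
                "p_two_tailed": paired["p_two_tailed"]}
        except ValueError:
            pass
    if track is not None:
        cnvs = bi[bi["svtype"].isin(["DEL", "DUP"])
                  & (bi["worst_consequence"] == "intergenic")].copy()
        cnvs["conservation_sum"] = [
            track.score_sum(r.chrom, int(r.start), int(r.end))
            for r in cnvs.itertuples()]
        cons = aps.aps_conservation_correlation(cnvs, model, seed=config.seed)
        if cons.get("defined"):
            block["conservation_spearman_rho"] = cons["spearman_rho"]
    return block


def _constraint_stage(cohort, sites, ann, genes, out):
    rare_ids = set(sites.loc[sites["af"] < popgen.RARE_AF, "sv_id"])
    functional = ann.gene_pairs[
        ann.gene_pairs["category"].isin(["pLoF", "copy_gain", "IED"])
        & ann.gene_pairs["sv_id"].isin(rare_ids)]
    cov = constraint.gene_covariates(genes)
    counts = functional.groupby("gene_id").size()
    observed = cov["gene_id"].map(counts).fillna(0).to_numpy()
    model = constraint.fit_expected_counts(cov, observed, min_genes=min(500, len(cov)))
    model.fitted.to_csv(out / "gene_oe.tsv", sep="\t", index=False)
    merged = model.fitted.merge(cov[["gene_id", "constraint_rank"]], on="gene_id")
    corr = constraint.binned_constraint_correlation(merged)
    corr["bins"].to_csv(out / "constraint_bins.tsv", sep="\t", index=False)
    return {
        "aggregate_oe": float(model.fitted["observed"].sum() / model.fitted["expected"].sum()),
        "spearman_rho": corr["spearman_rho"],
        "p_two_sided": corr["p_two_sided"],
    }


def _cpx_stage(cohort, out):
    labels, ltypes = [], []
    for r in cohort.analysis_records:
        if r.svtype == "CPX" and r.cpx_structure is not None:
            labels.append(cpx.classify(r.cpx_structure))
            ltypes.append(r.cpx_type)
    if not labels:
        return {"n_complex": 0}
    summ = cpx.subclass_summary(labels)
    summ["table"].to_csv(out / "cpx_subclasses.tsv", sep="\t")
    agreement = float(np.mean([l.label == t for l, t in zip(labels, ltypes) if t]))
    return {"n_complex": summ["n_total"],
            "inversion_fraction": summ["inversion_fraction"],
            "label_agreement_with_truth": agreement}


def _clinical_stage(cohort, ann, genes, out):
    block = {}
    large = clinical.large_rare_carrier_rate(cohort)
    block["large_rare_carrier_rate"] = large["carrier_rate"]
    block["large_rare_ci"] = list(large["ci"])
    block["balanced_complex_fraction"] = large["balanced_complex_fraction"]
    if genes and len(ann.gene_pairs):
        # screen against the most constrained decile as a stand-in gene panel
        ranked = sorted(genes, key=lambda g: g.constraint_rank)
        panel = {g.gene_id for g in ranked[: max(1, len(ranked) // 10)]}
        res = clinical.gene_list_carrier_rate(cohort, ann.gene_pairs, panel)
        block["panel_carrier_rate"] = res["carrier_rate"]
        block["panel_n_qualifying"] = res["n_qualifying_svs"]
    return block
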