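"""Functional consequence annotation of SVs against gene models and elements.

Each (SV, gene) pair receives exactly one category from a fixed decision
table. Deletions removing coding sequence, insertions landing in coding
exons, and inversions/translocations/complex events with a breakpoint inside
a transcript (or covering part but not all of its coding span) are predicted
loss-of-function (pLoF). Duplications fully containing a transcript are
copy-gain; duplications with both breakpoints inside the transcript that
duplicate at least one complete coding exon are intragenic exonic
duplications (IED). Inversions spanning a whole gene are their own category.
Everything else falls through to utr_partial / intronic / promoter /
intergenic by position. CNV-vs-noncoding-element overlap is classified as
full / partial / none by containment.

Annotation is per canonical transcript (one transcript per gene); complex
SVs are labelled per constituent interval and the worst label is kept.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .sv_io import Cohort, SVRecord

GENE_CATEGORIES = (
    "pLoF", "IED", "copy_gain", "whole_gene_inversion",
    "promoter", "utr_partial", "intronic", "intergenic",
)
#: Severity order for the per-SV worst label (most severe first).
SEVERITY = {c: i for i, c in enumerate(GENE_CATEGORIES)}

ELEMENT_CATEGORIES = ("full", "partial", "none")

#: Strand-aware promoter window upstream of the TSS, bp.
PROMOTER_WINDOW = 2_000


@dataclass
class GeneModel:
    """Canonical transcript of one gene, 0-based half-open intervals.

    ``cds_start``/``cds_end`` delimit the coding span inside the transcript;
    exon bp outside it are UTR. ``constraint_rank`` is an externally supplied
    SNV-constraint rank (1 = most constrained, like a LOEUF rank).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None
    constraint_rank: int | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        prev_end = None
        for (s, e) in self.exons:
            if s >= e or s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside span or empty")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = e
        if self.cds_start is None:
            self.cds_start, self.cds_end = self.exons[0][0], self.exons[-1][1]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def transcript_length(self) -> int:
        return self.end - self.start

    @property
    def total_intron_length(self) -> int:
        return self.transcript_length - sum(e - s for s, e in self.exons)

    def coding_exons(self) -> list[tuple[int, int]]:
        """Exon pieces clipped to the coding span."""
        out = []
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs < ce:
                out.append((cs, ce))
        return out

    def promoter(self, window: int = PROMOTER_WINDOW) -> tuple[int, int]:
        if self.strand == "+":
            return (max(0, self.start - window), self.start)
        return (self.end, self.end + window)


@dataclass
class NoncodingElement:
    element_id: str
    chrom: str
    start: int
    end: int
    element_class: str = "element"


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _interval_category(start: int, end: int, svtype: str, gene: GeneModel,
                       promoter_window: int) -> str:
    """Decision table for one (interval, gene) pair; see module docstring."""
    g = gene
    coding = g.coding_exons()
    coding_bp = sum(_overlap(start, end, s, e) for s, e in coding)
    exon_bp = sum(_overlap(start, end, s, e) for s, e in g.exons)
    tx_bp = _overlap(start, end, g.start, g.end)
    total_coding = sum(e - s for s, e in coding)

    if svtype == "INS":
        # point event at `start`
        if g.start <= start < g.end:
            if any(s <= start < e for s, e in coding):
                return "pLoF"
            if any(s <= start < e for s, e in g.exons):
                return "utr_partial"
            return "intronic"
        ps, pe = g.promoter(promoter_window)
        return "promoter" if ps <= start < pe else "intergenic"

    if tx_bp == 0:
        ps, pe = g.promoter(promoter_window)
        return "promoter" if _overlap(start, end, ps, pe) > 0 else "intergenic"

    contains_gene = start <= g.start and end >= g.end
    left_inside = g.start < start < g.end
    right_inside = g.start < end < g.end
    n_bp_inside = int(left_inside) + int(right_inside)

    if svtype == "DEL":
        if coding_bp > 0:
            return "pLoF"
        return "utr_partial" if exon_bp > 0 else "intronic"

    if svtype in ("DUP", "MCNV"):
        if contains_gene:
            return "copy_gain"
        if n_bp_inside == 2:
            # both breakpoints intragenic: IED iff >=1 full coding exon duplicated
            if any(start <= s and end >= e for s, e in coding):
                return "IED"
            if exon_bp > 0:
                return "utr_partial"
            return "intronic"
        # one breakpoint inside: partial duplication, not LoF-predictable
        return "utr_partial" if exon_bp > 0 else "intronic"

    if svtype in ("INV", "CTX", "CPX"):
        if contains_gene:
            return "whole_gene_inversion" if svtype == "INV" else "utr_partial"
        if n_bp_inside == 1:
            return "pLoF"
        if 0 < coding_bp < total_coding:
            return "pLoF"
        return "utr_partial" if exon_bp > 0 else "intronic"

    raise ValueError(f"cannot classify svtype {svtype}")


def classify_gene_overlap(sv: SVRecord, gene: GeneModel,
                          promoter_window: int = PROMOTER_WINDOW) -> str:
    """Functional category of one SV against one gene's canonical transcript.

    Complex SVs are classified per constituent interval (deleted, duplicated
    and inverted segments each act as their class) and the worst category is
    returned.
    """
    if sv.is_bnd:
        raise ValueError("BND records are excluded from annotation")
    if sv.svtype == "CPX" and sv.cpx_structure is not None:
        cats = []
        for seg in sv.cpx_structure.segments:
            if seg.chrom == "*":
                continue
            if seg.copy_state == 0:
                t = "DEL"
            elif seg.copy_state == 2 and not seg.is_dispersed:
                t = "DUP"
            elif seg.orientation == "-":
                t = "INV"
            else:
                continue
            if seg.chrom == gene.chrom:
                cats.append(_interval_category(seg.start, seg.end, t, gene, promoter_window))
            if seg.is_dispersed and seg.inserted_at[0] == gene.chrom:
                cats.append(_interval_category(
                    seg.inserted_at[1], seg.inserted_at[1], "INS", gene, promoter_window))
        if not cats:
            cats = [_interval_category(sv.start, sv.end, "CPX", gene, promoter_window)]
        return min(cats, key=lambda c: SEVERITY[c])
    if sv.chrom != gene.chrom:
        return "intergenic"
    return _interval_category(sv.start, sv.end, sv.svtype, gene, promoter_window)


def classify_element_overlap(cnv: SVRecord, element: NoncodingElement) -> str:
    """full / partial / none coverage of a noncoding element by a CNV."""
    if cnv.svtype not in ("DEL", "DUP"):
        raise ValueError(f"element overlap defined for CNVs only, got {cnv.svtype}")
    if cnv.chrom != element.chrom:
        return "none"
    if cnv.start <= element.start and cnv.end >= element.end:
        return "full"
    if _overlap(cnv.start, cnv.end, element.start, element.end) > 0:
        return "partial"
    return "none"


@dataclass
class AnnotationSet:
    """Bulk annotation results for a cohort."""

    gene_pairs: pd.DataFrame      # sv_id, gene_id, category
    element_pairs: pd.DataFrame   # sv_id, element_id, element_class, category
    worst: pd.DataFrame           # sv_id, worst_consequence
    category_counts: dict = field(default_factory=dict)


def annotate_cohort(cohort: Cohort, genes: list[GeneModel],
                    elements: list[NoncodingElement] | None = None,
                    promoter_window: int = PROMOTER_WINDOW) -> AnnotationSet:
    """Classify every PASS non-BND SV against all genes and elements.

    Gene lookup uses an interval tree over transcript spans extended by the
    promoter window, so results do not depend on input record order.
    """
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        lo = min(g.start, g.promoter(promoter_window)[0])
        hi = max(g.end, g.promoter(promoter_window)[1])
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi + 1, g)

    etrees: dict[str, IntervalTree] = {}
    for el in elements or []:
        etrees.setdefault(el.chrom, IntervalTree()).addi(el.start, el.end, el)

    gene_rows, elem_rows, worst_rows = [], [], []
    for r in sorted(cohort.analysis_records, key=lambda r: r.id):
        qlo, qhi = r.start, max(r.end, r.start + 1)
        cats = []
        for iv in sorted(trees.get(r.chrom, IntervalTree()).overlap(qlo, qhi),
                         key=lambda iv: iv.data.gene_id):
            cat = classify_gene_overlap(r, iv.data, promoter_window)
            if cat != "intergenic":
                gene_rows.append({"sv_id": r.id, "gene_id": iv.data.gene_id, "category": cat})
                cats.append(cat)
        worst = (min(cats, key=lambda c: SEVERITY[c]) if cats else "intergenic")
        worst_rows.append({"sv_id": r.id, "worst_consequence": worst})
        if r.svtype in ("DEL", "DUP"):
            for iv in sorted(etrees.get(r.chrom, IntervalTree()).overlap(qlo, qhi),
                             key=lambda iv: iv.data.element_id):
                cat = classify_element_overlap(r, iv.data)
                if cat != "none":
                    elem_rows.append({
                        "sv_id": r.id, "element_id": iv.data.element_id,
                        "element_class": iv.data.element_class, "category": cat,
                    })
    gene_pairs = pd.DataFrame(gene_rows, columns=["sv_id", "gene_id", "category"])
    element_pairs = pd.DataFrame(
        elem_rows, columns=["sv_id", "element_id", "element_class", "category"])
    worst = pd.DataFrame(worst_rows, columns=["sv_id", "worst_consequence"])
    counts = worst["worst_consequence"].value_counts().to_dict()
    return AnnotationSet(gene_pairs, element_pairs, worst, counts)
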