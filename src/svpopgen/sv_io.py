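"""Cohort SV callset data model and VCF/BED/TSV readers and writers.

Internal coordinates are 0-based half-open throughout; VCF I/O converts to
and from the 1-based inclusive convention, and BED output stays 0-based
half-open. Breakend (BND) records are parsed but quarantined: they are kept
on the cohort for bookkeeping and excluded from every downstream analysis.
Multiallelic copy-number variants (MCNV) carry integer per-sample copy
numbers in a parallel matrix and take part only in per-genome counts and
positional statistics, never in biallelic statistics.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

from .cpx import AlleleStructure, structure_to_tokens, tokens_to_structure

log = logging.getLogger(__name__)

SV_TYPES = ("DEL", "DUP", "MCNV", "INS", "INV", "CPX", "CTX", "BND")
#: classes excluded from biallelic site statistics
NON_BIALLELIC = ("MCNV", "BND")
POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "OTH")


@dataclass
class SVRecord:
    """One structural variant site.

    ``start``/``end`` are 0-based half-open; for insertions ``end == start``
    (the insertion point) and ``svlen`` is the inserted length. ``ac``/``an``
    are counted over the unrelated sample subset.
    """

    id: str
    chrom: str
    start: int
    end: int
    svtype: str
    svlen: int
    filter_status: str = "PASS"
    cpx_structure: AlleleStructure | None = None
    cpx_type: str | None = None
    chrom2: str | None = None
    pos2: int | None = None
    ac: int = 0
    an: int = 0

    def __post_init__(self):
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SVTYPE {self.svtype!r}")
        if self.end < self.start:
            raise ValueError(f"{self.id}: end {self.end} < start {self.start}")
        if self.svtype != "BND" and self.svlen <= 0:
            raise ValueError(f"{self.id}: non-BND record with svlen {self.svlen}")
        if not (0 <= self.ac <= self.an) and self.an > 0:
            raise ValueError(f"{self.id}: ac {self.ac} outside [0, an={self.an}]")

    @property
    def af(self) -> float:
        return self.ac / self.an if self.an > 0 else 0.0

    @property
    def is_bnd(self) -> bool:
        return self.svtype == "BND"

    @property
    def is_pass(self) -> bool:
        return self.filter_status == "PASS"

    @property
    def is_biallelic(self) -> bool:
        return self.svtype not in NON_BIALLELIC

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2 if self.end > self.start else self.start


class SampleTable:
    """Sample metadata: population label, sex, trio links, unrelated flag."""

    COLUMNS = ["sample_id", "population", "sex", "father_id", "mother_id", "is_unrelated"]

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"sample table missing columns {sorted(missing)}")
        self.df = df.reset_index(drop=True)
        ids = set(self.df["sample_id"])
        if len(ids) != len(self.df):
            raise ValueError("duplicate sample ids")
        for col in ("father_id", "mother_id"):
            bad = set(self.df[col].dropna()) - ids - {""}
            if bad:
                raise ValueError(f"{col} references unknown samples {sorted(bad)}")

    def __len__(self):
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    @property
    def unrelated_ids(self) -> list[str]:
        return list(self.df.loc[self.df["is_unrelated"].astype(bool), "sample_id"])

    def population_of(self) -> dict[str, str]:
        return dict(zip(self.df["sample_id"], self.df["population"]))

    def trios(self) -> list[tuple[str, str, str]]:
        """(child, father, mother) for every complete trio."""
        out = []
        for _, row in self.df.iterrows():
            f, m = row["father_id"], row["mother_id"]
            if isinstance(f, str) and f and isinstance(m, str) and m:
                out.append((row["sample_id"], f, m))
        return out

    def to_tsv(self, path):
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleTable":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "father_id": str, "mother_id": str})
        df["father_id"] = df["father_id"].fillna("")
        df["mother_id"] = df["mother_id"].fillna("")
        return cls(df)

    @classmethod
    def all_unrelated(cls, sample_ids, population="OTH") -> "SampleTable":
        return cls(pd.DataFrame({
            "sample_id": list(sample_ids),
            "population": population,
            "sex": "U",
            "father_id": "",
            "mother_id": "",
            "is_unrelated": True,
        }))


@dataclass
class GenotypeMatrix:
    """Diploid dosages for biallelic sites plus copy numbers for MCNV sites.

    ``dosage`` is samples x sites with values {0,1,2} and -1 for missing;
    ``cn`` is samples x MCNV-sites with non-negative integer copy numbers.
    """

    sample_ids: list[str]
    site_ids: list[str]
    dosage: np.ndarray
    mcnv_site_ids: list[str] = field(default_factory=list)
    cn: np.ndarray | None = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.site_ids)):
            raise ValueError("dosage shape mismatch")
        if self.cn is not None:
            self.cn = np.asarray(self.cn, dtype=np.int16)
            if self.cn.shape != (len(self.sample_ids), len(self.mcnv_site_ids)):
                raise ValueError("copy-number shape mismatch")
        self._site_index = {s: i for i, s in enumerate(self.site_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    def site_column(self, site_id: str) -> np.ndarray:
        return self.dosage[:, self._site_index[site_id]]

    def sample_rows(self, sample_ids) -> np.ndarray:
        idx = [self._sample_index[s] for s in sample_ids]
        return self.dosage[idx, :]

    def allele_stats(self, sample_ids) -> tuple[np.ndarray, np.ndarray]:
        """(ac, an) per biallelic site over the given samples."""
        d = self.sample_rows(sample_ids)
        obs = d >= 0
        ac = np.where(obs, d, 0).sum(axis=0)
        an = 2 * obs.sum(axis=0)
        return ac.astype(int), an.astype(int)


@dataclass
class Cohort:
    """A loaded callset: records, sample metadata and genotypes."""

    records: list[SVRecord]
    samples: SampleTable
    genotypes: GenotypeMatrix
    contigs: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self._by_id = {r.id: r for r in self.records}
        if len(self._by_id) != len(self.records):
            raise ValueError("duplicate SV record ids")

    def record(self, sv_id: str) -> SVRecord:
        return self._by_id[sv_id]

    @property
    def analysis_records(self) -> list[SVRecord]:
        """PASS, non-BND records — the universe for all analyses."""
        return [r for r in self.records if r.is_pass and not r.is_bnd]

    @property
    def biallelic_records(self) -> list[SVRecord]:
        return [r for r in self.analysis_records if r.is_biallelic]

    def recompute_allele_stats(self, warn_on_mismatch: bool = True) -> None:
        """Set ac/an on every biallelic record from unrelated genotypes."""
        unrelated = self.samples.unrelated_ids
        ac, an = self.genotypes.allele_stats(unrelated)
        idx = {s: i for i, s in enumerate(self.genotypes.site_ids)}
        for r in self.records:
            if r.id not in idx:
                continue
            j = idx[r.id]
            if warn_on_mismatch and r.an > 0 and (r.ac != ac[j] or r.an != an[j]):
                log.warning(
                    "record %s: INFO AC/AN (%d/%d) != recomputed (%d/%d); using recomputed",
                    r.id, r.ac, r.an, int(ac[j]), int(an[j]),
                )
            r.ac, r.an = int(ac[j]), int(an[j])

    def site_frame(self) -> pd.DataFrame:
        """Per-site table of the analysis universe (PASS, non-BND)."""
        rows = []
        for r in self.analysis_records:
            rows.append({
                "sv_id": r.id, "chrom": r.chrom, "start": r.start, "end": r.end,
                "svtype": r.svtype, "svlen": r.svlen, "ac": r.ac, "an": r.an,
                "af": r.af, "is_singleton": r.ac == 1,
                "is_biallelic": r.is_biallelic,
            })
        return pd.DataFrame(rows)

    def filter(self, pass_only: bool = True, drop_bnd: bool = True) -> "Cohort":
        keep = [
            r for r in self.records
            if (not pass_only or r.is_pass) and (not drop_bnd or not r.is_bnd)
        ]
        keep_ids = [r.id for r in keep if r.id in self.genotypes._site_index]
        cols = [self.genotypes._site_index[s] for s in keep_ids]
        gm = GenotypeMatrix(
            sample_ids=self.genotypes.sample_ids,
            site_ids=keep_ids,
            dosage=self.genotypes.dosage[:, cols],
            mcnv_site_ids=self.genotypes.mcnv_site_ids,
            cn=self.genotypes.cn,
        )
        return Cohort([replace(r) for r in keep], self.samples, gm, dict(self.contigs))


# --- VCF ---------------------------------------------------------------------

_INFO_HEADERS = [
    ('INFO', 'SVTYPE', '1', 'String', 'Structural variant class'),
    ('INFO', 'SVLEN', '1', 'Integer', 'SV length in bp (inserted length for INS)'),
    ('INFO', 'END2', '1', 'Integer', 'Position of the second breakpoint for CTX'),
    ('INFO', 'CHR2', '1', 'String', 'Chromosome of the second breakpoint for CTX'),
    ('INFO', 'CPX_TYPE', '1', 'String', 'Complex SV subclass label'),
    ('INFO', 'CPX_INTERVALS', '.', 'String', 'Resolved alternate-allele structure tokens'),
    ('INFO', 'AC', 'A', 'Integer', 'Alternate allele count among unrelated samples'),
    ('INFO', 'AN', '1', 'Integer', 'Allele number among unrelated samples'),
    ('INFO', 'AF', 'A', 'Float', 'Alternate allele frequency among unrelated samples'),
]


def _build_header(cohort: Cohort) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    contigs = dict(cohort.contigs)
    for r in cohort.records:
        length = max(contigs.get(r.chrom, 0), r.end + 10_000)
        contigs[r.chrom] = length
        if r.chrom2:
            contigs[r.chrom2] = max(contigs.get(r.chrom2, 0), (r.pos2 or 0) + 10_000)
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for rec in _INFO_HEADERS:
        header.add_meta('INFO', items=[
            ('ID', rec[1]), ('Number', rec[2]), ('Type', rec[3]), ('Description', rec[4]),
        ])
    for alt in ("DEL", "DUP", "CNV", "INS", "INV", "CPX", "CTX"):
        header.add_meta('ALT', items=[('ID', alt), ('Description', f'{alt} symbolic allele')])
    header.add_meta('FORMAT', items=[
        ('ID', 'GT'), ('Number', '1'), ('Type', 'String'), ('Description', 'Genotype')])
    header.add_meta('FORMAT', items=[
        ('ID', 'CN'), ('Number', '1'), ('Type', 'Integer'), ('Description', 'Copy number')])
    header.add_meta('FILTER', items=[('ID', 'FAIL'), ('Description', 'Failed site QC')])
    for s in cohort.genotypes.sample_ids:
        header.add_sample(s)
    return header


def write_sv_vcf(cohort: Cohort, path) -> None:
    """Write the cohort as a VCF 4.2 with symbolic ALT alleles."""
    header = _build_header(cohort)
    gm = cohort.genotypes
    mcnv_idx = {s: i for i, s in enumerate(gm.mcnv_site_ids)}
    order = sorted(range(len(cohort.records)),
                   key=lambda i: (cohort.records[i].chrom, cohort.records[i].start,
                                  cohort.records[i].id))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i in order:
            r = cohort.records[i]
            rec = vf.new_record()
            rec.chrom = r.chrom
            rec.start = r.start
            alt = "CNV" if r.svtype == "MCNV" else r.svtype
            rec.alleles = ("N", f"<{alt}>")
            rec.stop = max(r.end, r.start + 1)
            rec.id = r.id
            if r.filter_status == "PASS":
                rec.filter.add("PASS")
            else:
                rec.filter.add("FAIL")
            rec.info["SVTYPE"] = r.svtype
            rec.info["SVLEN"] = r.svlen
            if r.chrom2:
                rec.info["CHR2"] = r.chrom2
                rec.info["END2"] = (r.pos2 or 0) + 1
            if r.cpx_type:
                rec.info["CPX_TYPE"] = r.cpx_type
            if r.cpx_structure is not None:
                rec.info["CPX_INTERVALS"] = tuple(
                    structure_to_tokens(r.cpx_structure).split(","))
            rec.info["AC"] = (r.ac,)
            rec.info["AN"] = r.an
            rec.info["AF"] = (r.af,)
            if r.id in gm._site_index:
                col = gm.dosage[:, gm._site_index[r.id]]
                for s, d in zip(gm.sample_ids, col):
                    if d < 0:
                        rec.samples[s]["GT"] = (None, None)
                    elif d == 0:
                        rec.samples[s]["GT"] = (0, 0)
                    elif d == 1:
                        rec.samples[s]["GT"] = (0, 1)
                    else:
                        rec.samples[s]["GT"] = (1, 1)
            elif r.svtype == "MCNV" and gm.cn is not None and r.id in mcnv_idx:
                col = gm.cn[:, mcnv_idx[r.id]]
                for s, c in zip(gm.sample_ids, col):
                    rec.samples[s]["GT"] = (None, None)
                    rec.samples[s]["CN"] = int(c)
            else:
                for s in gm.sample_ids:
                    rec.samples[s]["GT"] = (None, None)
            vf.write(rec)


def read_sv_vcf(path, sample_table: SampleTable | None = None,
                recompute_stats: bool = True) -> Cohort:
    """Read a symbolic-ALT SV VCF into a :class:`Cohort`.

    Records without SVTYPE are rejected with a logged reason; malformed
    coordinates raise with the offending record named. When a sample table is
    not given, all samples are treated as unrelated. INFO AC/AN are recomputed
    from unrelated genotypes and a mismatch with the stored INFO is warned
    about.
    """
    records: list[SVRecord] = []
    dosage_cols: list[np.ndarray] = []
    site_ids: list[str] = []
    mcnv_ids: list[str] = []
    cn_cols: list[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vf:
        sample_ids = list(vf.header.samples)
        contigs = {name: c.length or 0 for name, c in vf.header.contigs.items()}
        for lineno, rec in enumerate(vf, start=1):
            info = dict(rec.info)
            svtype = info.get("SVTYPE")
            if svtype is None:
                log.warning("record %s (#%d) rejected: missing SVTYPE", rec.id, lineno)
                continue
            if svtype not in SV_TYPES:
                log.warning("record %s (#%d) rejected: unknown SVTYPE %s", rec.id, lineno, svtype)
                continue
            start = rec.start
            end = rec.stop
            if start is None or end is None or start < 0:
                raise ValueError(f"malformed coordinates in record #{lineno} ({rec.id})")
            svlen = info.get("SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            if svtype == "INS":
                end = start  # point event internally
                if svlen is None:
                    raise ValueError(f"INS record #{lineno} ({rec.id}) lacks SVLEN")
            elif svtype == "BND":
                svlen = int(svlen) if svlen is not None else -1
            elif svtype == "CTX":
                svlen = int(svlen) if svlen else max(end - start, 1)
            else:
                if svlen is not None and end == start + int(svlen) + 1:
                    # htslib infers stop from SVLEN assuming POS is a padding
                    # base; this dialect's POS is the first affected base
                    end = start + int(svlen)
                svlen = int(svlen) if svlen is not None else end - start
            structure = None
            if "CPX_INTERVALS" in info:
                toks = info["CPX_INTERVALS"]
                if isinstance(toks, tuple):
                    toks = ",".join(toks)
                structure = tokens_to_structure(toks)
            filt = list(rec.filter.keys())
            filter_status = "PASS" if (not filt or filt == ["PASS"]) else filt[0]
            ac = info.get("AC", 0)
            if isinstance(ac, tuple):
                ac = ac[0] or 0
            an = info.get("AN", 0)
            sv = SVRecord(
                id=rec.id or f"site_{lineno}", chrom=rec.chrom, start=start,
                end=end, svtype=svtype, svlen=int(svlen) if svlen is not None else end - start,
                filter_status=filter_status, cpx_structure=structure,
                cpx_type=info.get("CPX_TYPE"),
                chrom2=info.get("CHR2"),
                pos2=(int(info["END2"]) - 1) if "END2" in info else None,
                ac=int(ac), an=int(an),
            )
            records.append(sv)
            if svtype == "MCNV":
                col = np.array(
                    [rec.samples[s].get("CN") if rec.samples[s].get("CN") is not None else 2
                     for s in sample_ids], dtype=np.int16)
                mcnv_ids.append(sv.id)
                cn_cols.append(col)
            else:
                col = np.empty(len(sample_ids), dtype=np.int8)
                for k, s in enumerate(sample_ids):
                    gt = rec.samples[s].get("GT")
                    if gt is None or any(a is None for a in gt):
                        col[k] = -1
                    else:
                        col[k] = sum(1 for a in gt if a)
                site_ids.append(sv.id)
                dosage_cols.append(col)
    if sample_table is None:
        sample_table = SampleTable.all_unrelated(sample_ids)
    dosage = (np.stack(dosage_cols, axis=1) if dosage_cols
              else np.zeros((len(sample_ids), 0), dtype=np.int8))
    cn = np.stack(cn_cols, axis=1) if cn_cols else None
    gm = GenotypeMatrix(sample_ids, site_ids, dosage, mcnv_ids, cn)
    cohort = Cohort(records, sample_table, gm, contigs)
    if recompute_stats:
        cohort.recompute_allele_stats()
    return cohort


def write_sites_bed(cohort: Cohort, path, annotations: pd.DataFrame | None = None) -> None:
    """Per-site BED (0-based half-open): one row per PASS non-BND site.

    Columns: chrom, start, end, id, svtype, svlen, af[, consequence]. The
    consequence column is filled from a per-SV worst-label table when given.
    """
    worst = {}
    if annotations is not None and len(annotations):
        worst = dict(zip(annotations["sv_id"], annotations["worst_consequence"]))
    with open(path, "w") as fh:
        cols = "#chrom\tstart\tend\tid\tsvtype\tsvlen\taf"
        if annotations is not None:
            cols += "\tconsequence"
        fh.write(cols + "\n")
        for r in sorted(cohort.analysis_records, key=lambda r: (r.chrom, r.start, r.id)):
            end = max(r.end, r.start + 1)  # INS points get width-1 rows
            row = f"{r.chrom}\t{r.start}\t{end}\t{r.id}\t{r.svtype}\t{r.svlen}\t{r.af:.6g}"
            if annotations is not None:
                row += f"\t{worst.get(r.id, 'intergenic')}"
            fh.write(row + "\n")
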