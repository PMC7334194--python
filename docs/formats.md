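# File formats

## SV VCF dialect

VCF 4.2 with symbolic ALT alleles `<DEL>`, `<DUP>`, `<CNV>` (multiallelic
CNV), `<INS>`, `<INV>`, `<CPX>`, `<CTX>`.

INFO keys:

| key | type | meaning |
|---|---|---|
| `SVTYPE` | String | one of DEL, DUP, MCNV, INS, INV, CPX, CTX, BND |
| `SVLEN` | Integer | SV length in bp; inserted length for INS |
| `END` | Integer | 1-based inclusive end |
| `CHR2`, `END2` | String/Integer | second breakpoint for CTX |
| `CPX_TYPE` | String | complex subclass label |
| `CPX_INTERVALS` | String list | resolved alternate-allele structure tokens |
| `AC`, `AN`, `AF` | | allele statistics over unrelated samples |

Coordinate convention: POS is the **first affected base** (so a deletion of
the half-open interval [1000, 2000) is written `POS=1001; END=2000;
SVLEN=1000`). Readers that instead assume the symbolic padding-base
convention will differ by one base at the start. On input, when `END`
equals `POS + SVLEN` under the padding interpretation the reader restores
the first-affected-base interval.

FORMAT: `GT` for biallelic sites; MCNV sites carry `GT=./.` and an integer
`CN` per sample.

## CPX_INTERVALS token grammar

```
token  := TYPE "_" chrom ":" start "-" end [ "@" chrom ":" pos ]
TYPE   := DEL | DUP | DUPINV | INV | INS
```

Coordinates inside tokens are 1-based inclusive. `DEL`/`DUP`/`INV` are
in-place segments (deleted / duplicated forward / inverted copy-neutral);
`DUPINV` is an inverted duplication. A trailing `@chrom:pos` marks a
dispersed segment inserted at that locus; `INS` with chrom `*` is novel
sequence of the given length. Tokens are comma-joined, ordered along the
reference. Example — a dispersed duplication with a deletion at the
insertion site:

```
CPX_INTERVALS=DUP_chrA:1001-2000@chrA:50001,DEL_chrA:49801-50200
```

## Sites BED

0-based half-open, one row per PASS non-BND site, header comment line:
`#chrom start end id svtype svlen af [consequence]`. Insertions get
width-1 rows.

## Sample table TSV

Columns `sample_id, population, sex, father_id, mother_id, is_unrelated`.
Empty parent fields mean founder; trio rows reference existing sample ids.

## Other tables

Arm maps are TSV with `chrom, arm (p|q), start, end`; gaps between p-end
and q-start are centromeres. Genomic-disorder loci are BED4+1:
`chrom, start, end, locus_id, dosage_direction (DEL|DUP)`. Conservation
tracks are 4-column BedGraph (`chrom, start, end, score`); uncovered
positions score 0. Truth tables and per-stage outputs are plain TSV with
header rows.
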