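"""Complex structural variant allele structures and subclass classification.

A resolved complex SV allele is described as an ordered list of reference
segments, each with an orientation, a copy state (0 = deleted, 1 = retained,
2 = duplicated) and, for dispersed events, the locus the copy is inserted at.
The classifier canonicalizes the structure into a breakpoint-signature string
(e.g. ``delINV``, ``dupINVdup``) and maps the signature onto the standard
subclass catalogue: the six inversion-flank classes, the symmetric
three-segment classes, dispersed duplications (``dDUP``, ``dDUP_iDEL``) and
insertions with a deletion at the insertion site (``INS_iDEL``). Structures
that reduce to a single canonical signature (a plain deletion, duplication,
inversion or insertion) are routed to their canonical class rather than being
counted as complex; anything unrecognised is ``unresolved``.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

#: Complex subclasses with mirror pairs kept distinct.
CPX_SUBCLASSES = (
    "delINV", "INVdel", "dupINV", "INVdup",
    "delINVdel", "dupINVdup", "delINVdup", "dupINVdel",
    "dDUP", "dDUP_iDEL", "INS_iDEL",
)

#: Canonical (non-complex) labels a structure may collapse to.
CANONICAL_LABELS = ("DEL", "DUP", "INV", "INS")

#: Default aggregation of mirror-image subclass pairs for reporting.
MIRROR_COLLAPSE = {
    "INVdel": "delINV",
    "INVdup": "dupINV",
    "dupINVdel": "delINVdup",
}


@dataclass(frozen=True)
class Segment:
    """One reference segment of a resolved alternate allele.

    ``chrom == "*"`` marks novel inserted sequence with no reference source;
    its start/end give only the inserted length. ``inserted_at`` is the
    (chrom, pos) a dispersed copy lands at, 0-based.
    """

    chrom: str
    start: int
    end: int
    orientation: str = "+"
    copy_state: int = 1
    inserted_at: tuple[str, int] | None = None

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"segment end {self.end} < start {self.start}")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.copy_state not in (0, 1, 2):
            raise ValueError(f"bad copy state {self.copy_state}")

    @property
    def is_dispersed(self) -> bool:
        return self.inserted_at is not None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AlleleStructure:
    """Ordered segments of one resolved alternate allele."""

    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self):
        if not self.segments:
            raise ValueError("allele structure needs at least one segment")
        placed = sorted(
            (s for s in self.segments if s.chrom != "*"),
            key=lambda s: (s.chrom, s.start),
        )
        for a, b in zip(placed, placed[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(
                    f"overlapping source segments {a.chrom}:{a.start}-{a.end} "
                    f"and {b.chrom}:{b.start}-{b.end}"
                )

    @property
    def involves_inversion(self) -> bool:
        return any(s.orientation == "-" for s in self.segments)

    def span(self) -> tuple[str, int, int]:
        """Reference footprint (chrom, min start, max end) over sourced segments."""
        placed = [s for s in self.segments if s.chrom != "*"]
        if not placed:
            s = self.segments[0]
            assert s.inserted_at is not None
            return (s.inserted_at[0], s.inserted_at[1], s.inserted_at[1] + 1)
        chrom = placed[0].chrom
        return (chrom, min(s.start for s in placed), max(s.end for s in placed))


@dataclass(frozen=True)
class SubclassLabel:
    label: str
    involves_inversion: bool


def _inplace_token(seg: Segment) -> str | None:
    if seg.copy_state == 0:
        return "del"
    if seg.copy_state == 2:
        return "dup" if seg.orientation == "+" else "dupinv"
    # copy-neutral
    return "INV" if seg.orientation == "-" else None


def canonicalize(structure: AlleleStructure) -> str:
    """Deterministic breakpoint-signature string for a structure.

    In-place segments are ordered along the reference and mapped to tokens
    (``del``/``dup``/``INV``); dispersed segments contribute ``dDUP``/``INS``
    with an ``_iDEL`` suffix when a deletion sits at the insertion point.
    Mirror-image structures yield mirror signatures (``delINV`` vs ``INVdel``);
    collapsing mirrors is a reporting choice, not done here. Idempotent in the
    sense that the signature depends only on the token sequence.
    """
    inplace = sorted(
        (s for s in structure.segments if not s.is_dispersed and s.chrom != "*"),
        key=lambda s: (s.chrom, s.start),
    )
    dispersed = [s for s in structure.segments if s.is_dispersed]

    tokens = []
    for seg in inplace:
        tok = _inplace_token(seg)
        if tok is not None:
            tokens.append(tok)

    if dispersed:
        # a deletion at a dispersed segment's insertion point is part of the
        # dispersed signature, not a flank token
        sink_dels = set()
        disp_tokens = []
        for seg in dispersed:
            sink_chrom, sink_pos = seg.inserted_at
            idel = None
            for other in inplace:
                if (
                    other.copy_state == 0
                    and other.chrom == sink_chrom
                    and other.start <= sink_pos <= other.end
                ):
                    idel = other
                    break
            base = "INS" if seg.chrom == "*" else ("dDUP" if seg.copy_state == 2 else "?")
            if idel is not None:
                sink_dels.add(id(idel))
                disp_tokens.append(base + "_iDEL")
            else:
                disp_tokens.append(base)
        tokens = [
            t
            for t, seg in zip(tokens, [s for s in inplace if _inplace_token(s)])
            if not (seg.copy_state == 0 and id(seg) in sink_dels)
        ]
        tokens.extend(disp_tokens)
    elif any(s.chrom == "*" for s in structure.segments):
        tokens.extend("INS" for s in structure.segments if s.chrom == "*")

    if not tokens:
        # a lone copy-neutral forward segment: reference-identical
        return "REF"
    return "".join(tokens)


_SIGNATURE_LABELS = {
    # canonical single-signature structures
    "del": "DEL",
    "dup": "DUP",
    "INV": "INV",
    "INS": "INS",
    "dDUP": "dDUP",
    "dDUP_iDEL": "dDUP_iDEL",
    "INS_iDEL": "INS_iDEL",
    # inversion flank classes
    "delINV": "delINV",
    "INVdel": "INVdel",
    "dupINV": "dupINV",
    "INVdup": "INVdup",
    "delINVdel": "delINVdel",
    "dupINVdup": "dupINVdup",
    "delINVdup": "delINVdup",
    "dupINVdel": "dupINVdel",
}


def classify(structure: AlleleStructure) -> SubclassLabel:
    """Assign the subclass label for a resolved structure.

    Total function: canonical single-token structures go to their canonical
    class, known complex signatures to the subclass catalogue, and anything
    else to ``unresolved``.
    """
    sig = canonicalize(structure)
    label = _SIGNATURE_LABELS.get(sig, "unresolved")
    return SubclassLabel(label=label, involves_inversion=structure.involves_inversion)


def collapse_mirrors(label: str) -> str:
    """Reporting aggregation of mirror-image subclass pairs."""
    return MIRROR_COLLAPSE.get(label, label)


def subclass_summary(
    labels: list[SubclassLabel],
    sizes=None,
    afs=None,
    collapse: bool = False,
) -> dict:
    """Per-subclass counts plus the fraction of structures involving inversion."""
    if not labels:
        raise ValueError("no labels to summarize")
    names = [collapse_mirrors(l.label) if collapse else l.label for l in labels]
    df = pd.DataFrame({"label": names})
    if sizes is not None:
        df["size"] = list(sizes)
    if afs is not None:
        df["af"] = list(afs)
    counts = df["label"].value_counts().sort_index()
    table = pd.DataFrame({"count": counts})
    if sizes is not None:
        table["median_size"] = df.groupby("label")["size"].median()
    if afs is not None:
        table["median_af"] = df.groupby("label")["af"].median()
    n_inv = sum(1 for l in labels if l.involves_inversion)
    return {
        "table": table,
        "n_total": len(labels),
        "n_inversion_involving": n_inv,
        "inversion_fraction": n_inv / len(labels),
    }


# --- VCF INFO token grammar -------------------------------------------------
# token  := TYPE "_" chrom ":" start "-" end [ "@" chrom ":" pos ]
# TYPE   := DEL | DUP | DUPINV | INV | INS
# Coordinates in tokens are 1-based inclusive (VCF convention); "*" chrom
# marks novel inserted sequence. Tokens are comma-joined in CPX_INTERVALS.

_TOKEN_RE = re.compile(
    r"^(DEL|DUPINV|DUP|INV|INS)_([^:]+):(\d+)-(\d+)(?:@([^:]+):(\d+))?$"
)


def structure_to_tokens(structure: AlleleStructure) -> str:
    parts = []
    for seg in structure.segments:
        if seg.copy_state == 0:
            t = "DEL"
        elif seg.copy_state == 2:
            t = "INS" if seg.chrom == "*" else ("DUP" if seg.orientation == "+" else "DUPINV")
        else:
            t = "INV" if seg.orientation == "-" else "REF"
        tok = f"{t}_{seg.chrom}:{seg.start + 1}-{seg.end}"
        if seg.inserted_at is not None:
            tok += f"@{seg.inserted_at[0]}:{seg.inserted_at[1] + 1}"
        parts.append(tok)
    return ",".join(parts)


def tokens_to_structure(text: str) -> AlleleStructure:
    segs = []
    for tok in text.split(","):
        m = _TOKEN_RE.match(tok.strip())
        if not m:
            raise ValueError(f"unparseable structure token {tok!r}")
        typ, chrom, s1, e1, sink_chrom, sink_pos = m.groups()
        start, end = int(s1) - 1, int(e1)
        orientation = "-" if typ in ("INV", "DUPINV") else "+"
        copy_state = {"DEL": 0, "DUP": 2, "DUPINV": 2, "INV": 1, "INS": 2}[typ]
        inserted_at = None
        if sink_chrom is not None:
            inserted_at = (sink_chrom, int(sink_pos) - 1)
        segs.append(
            Segment(chrom, start, end, orientation, copy_state, inserted_at)
        )
    return AlleleStructure(segs)
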