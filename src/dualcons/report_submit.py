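"""Submission outputs: EMBL-style flat files and registry summary
statistics.

The flat-file writer emits a minimal EMBL feature-table dialect (ID, FT
and SQ line groups) sufficient for whole-gene allele submission records:
a source feature, a CDS with a ``join(...)`` over the exon ranges and a
``/translation`` qualifier, the individual UTR/exon/intron features, and
a 60-column sequence block.  Coordinates are 1-based inclusive here and
only here.  The module's own reader round-trips the format exactly.

Summary operations reproduce registry bookkeeping: per-locus submission
breakdowns, the proportion of null/Q alleles among unique sequences, the
effect of submissions on full characterisation of the database, and
population allele frequencies over a diploid gene-copy denominator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .annotate import ExpressionClass, GeneAnnotation
from .seqcore import GeneModel

__all__ = [
    "SubmissionRecord",
    "summarize_submissions",
    "full_characterisation_stats",
    "null_q_proportions",
    "allele_frequency",
    "write_embl_flatfile",
    "read_embl_flatfile",
]

CATEGORIES = ("novel", "extension", "confirmatory")


@dataclass
class SubmissionRecord:
    """A submission-ready characterised allele sequence.

    ``companion_typings`` carries the sample's HLA-A/-B/-DRB1 typings
    (free-form strings), which accompany every submission.
    """

    sample_id: str
    locus: str
    sequence: str
    annotation: GeneAnnotation
    expression: ExpressionClass
    category: str
    companion_typings: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")
        if self.annotation.model.span != len(self.sequence):
            raise ValueError("annotation must span the full sequence")


def summarize_submissions(records) -> pd.DataFrame:
    """Per-locus submission breakdown.

    ``records`` is an iterable of :class:`SubmissionRecord` or of
    ``(locus, category)`` pairs.  Columns: novel, extended, distinct
    (novel + extended), confirmatory, total (distinct + confirmatory),
    plus a Total row.
    """
    rows = []
    for r in records:
        if isinstance(r, SubmissionRecord):
            rows.append((r.locus, r.category))
        else:
            rows.append(tuple(r))
    cols = ["novel", "extended", "distinct", "confirmatory", "total"]
    if not rows:
        return pd.DataFrame(columns=cols).rename_axis("locus")
    df = pd.DataFrame(rows, columns=["locus", "category"])
    cat_map = {"novel": "novel", "extension": "extended",
               "confirmatory": "confirmatory"}
    df["category"] = df["category"].map(cat_map)
    table = (
        df.pivot_table(index="locus", columns="category", aggfunc="size",
                       fill_value=0)
        .reindex(columns=["novel", "extended", "confirmatory"], fill_value=0)
    )
    table["distinct"] = table["novel"] + table["extended"]
    table["total"] = table["distinct"] + table["confirmatory"]
    table = table[cols]
    table.loc["Total"] = table.sum()
    table.columns.name = None
    return table.rename_axis("locus")


def _round_half_up(value: float, digits: int) -> Decimal:
    q = Decimal(1).scaleb(-digits)
    return Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP)


def full_characterisation_stats(fully_characterised: int, all_known: int) -> str:
    """Share of fully characterised alleles, as a percentage string with
    one decimal (half-up)."""
    if all_known <= 0:
        raise ValueError("all_known must be positive")
    pct = 100 * fully_characterised / all_known
    return f"{_round_half_up(pct, 1)}%"


def null_q_proportions(n_null: int, n_q: int, n_unique: int) -> str:
    """Combined null+Q count with its whole-percent share of unique
    submitted sequences, formatted ``"<count> (<pct>%)"``."""
    if n_unique <= 0:
        raise ValueError("n_unique must be positive")
    combined = n_null + n_q
    pct = _round_half_up(100 * combined / n_unique, 0)
    return f"{combined} ({pct}%)"


def allele_frequency(observations: int, total_samples: int) -> float:
    """Population frequency of an allele: observations over the diploid
    gene-copy count (2 per genotyped sample)."""
    if total_samples <= 0:
        raise ValueError("total_samples must be positive")
    if observations < 0:
        raise ValueError("observations must be non-negative")
    return observations / (2 * total_samples)


# --- EMBL-style flat files -------------------------------------------------

_FT = "FT"


def _embl_location(intervals: list[tuple[int, int]]) -> str:
    """0-based half-open intervals -> 1-based inclusive EMBL location."""
    parts = [f"{s + 1}..{e}" for s, e in intervals]
    if len(parts) == 1:
        return parts[0]
    return "join(" + ",".join(parts) + ")"


def _wrap_qualifier(key: str, value: str, width: int = 58) -> list[str]:
    text = f'/{key}="{value}"'
    lines = [text[i:i + width] for i in range(0, len(text), width)]
    return [f"{_FT}                   {l}" for l in lines]


def write_embl_flatfile(record: SubmissionRecord) -> str:
    """Render a submission record as minimal EMBL flat-file text."""
    seq = record.sequence
    model = record.annotation.model
    L = len(seq)
    lines = [
        f"ID   {record.sample_id}; SV 1; linear; genomic DNA; STD; HUM; {L} BP.",
        "XX",
        f"DE   HLA-{record.locus} allele, {record.category} sequence, "
        f"expression class {record.expression.cls}",
        "XX",
    ]
    lines.append(f"{_FT}   source          1..{L}")
    lines.extend(_wrap_qualifier("organism", "Homo sapiens"))
    lines.extend(_wrap_qualifier("mol_type", "genomic DNA"))
    cds_loc = _embl_location(model.exons)
    lines.append(f"{_FT}   CDS             {cds_loc}")
    lines.extend(_wrap_qualifier("gene", f"HLA-{record.locus}"))
    protein = record.annotation.protein.rstrip("*")
    lines.extend(_wrap_qualifier("translation", protein))
    exon_rank = 0
    for kind, s, e in model.features:
        loc = _embl_location([(s, e)])
        if kind == "exon":
            exon_rank += 1
            lines.append(f"{_FT}   exon            {loc}")
            lines.extend(_wrap_qualifier("number", str(exon_rank)))
        elif kind == "intron":
            lines.append(f"{_FT}   intron          {loc}")
            lines.extend(_wrap_qualifier("number", str(exon_rank)))
        else:
            lines.append(f"{_FT}   {'5' if kind == 'UTR5' else '3'}'UTR           {loc}")
    lines.append("XX")
    counts = {b: seq.count(b) for b in "ACGT"}
    other = L - sum(counts.values())
    lines.append(
        f"SQ   Sequence {L} BP; {counts['A']} A; {counts['C']} C; "
        f"{counts['G']} G; {counts['T']} T; {other} other;"
    )
    for i in range(0, L, 60):
        chunk = seq[i:i + 60].lower()
        blocks = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        pos = min(i + 60, L)
        lines.append(f"     {blocks:<66}{pos:>9}")
    lines.append("//")
    return "\n".join(lines) + "\n"


def read_embl_flatfile(text: str) -> dict:
    """Parse the minimal flat-file dialect written by
    :func:`write_embl_flatfile`.

    Returns a dict with ``id``, ``length``, ``features`` (kind, start,
    end in 0-based half-open), ``cds_exons``, ``translation`` and
    ``sequence`` — enough to verify an exact round trip.
    """
    features: list[tuple[str, int, int]] = []
    cds_exons: list[tuple[int, int]] = []
    seq_parts: list[str] = []
    rec_id = None
    length = None
    in_seq = False
    kind_map = {"5'UTR": "UTR5", "3'UTR": "UTR3", "exon": "exon",
                "intron": "intron"}

    def parse_span(loc: str) -> tuple[int, int]:
        a, b = loc.split("..")
        return int(a) - 1, int(b)

    qualifier_text: list[str] = []
    for line in text.splitlines():
        if line.startswith("ID"):
            parts = line[5:].split(";")
            rec_id = parts[0].strip()
            length = int(parts[-1].strip().removesuffix(" BP."))
        elif line.startswith("SQ"):
            in_seq = True
        elif line.startswith("//"):
            in_seq = False
        elif in_seq:
            seq_parts.append("".join(line.split()[:-1]))
        elif line.startswith(_FT):
            body = line[2:].strip()
            tokens = body.split(None, 1)
            if len(tokens) == 2 and tokens[0] in (*kind_map, "CDS", "source"):
                key, loc = tokens
                if key == "CDS":
                    loc = loc.removeprefix("join(").removesuffix(")")
                    cds_exons = [parse_span(p) for p in loc.split(",")]
                elif key in kind_map:
                    s, e = parse_span(loc)
                    features.append((kind_map[key], s, e))
            else:
                qualifier_text.append(body)
    # the translation qualifier may wrap over several FT lines; qualifier
    # chunks were emitted in order, so rejoin and extract it
    joined_quals = "".join(qualifier_text)
    translation = ""
    marker = '/translation="'
    if marker in joined_quals:
        after = joined_quals.split(marker, 1)[1]
        translation = after.split('"', 1)[0]
    sequence = "".join(seq_parts).upper()
    features.sort(key=lambda f: f[1])
    return {
        "id": rec_id,
        "length": length,
        "features": features,
        "cds_exons": cds_exons,
        "translation": translation,
        "sequence": sequence,
    }
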