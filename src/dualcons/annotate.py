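"""Characterisation of a final consensus sequence against a reference
allele set: closest-allele search, gene-model projection, per-feature
difference enumeration, and expression classification (normal / N / Q).

A consensus that differs from every catalogued allele is a candidate
novel allele.  Its gene model (UTR/exon/intron layout) is inherited from
the closest reference through the pairwise alignment; the spliced coding
sequence is then translated to detect premature stop codons (null, 'N',
alleles) or variants catalogued as affecting expression (questionable,
'Q', alleles).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .seqcore import (
    Alignment,
    GeneModel,
    ReferenceAllele,
    align_global,
    edit_distance,
)

__all__ = [
    "GeneAnnotation",
    "ExpressionClass",
    "AnnotationError",
    "find_closest_reference",
    "transfer_gene_model",
    "classify_expression",
    "enumerate_differences",
]

MIN_TRANSFER_IDENTITY = 0.90


class AnnotationError(ValueError):
    """Raised when a gene model cannot be transferred safely."""


@dataclass
class Difference:
    """One aligned difference between novel sequence and closest reference."""

    position: int  # reference coordinate (start of the event)
    kind: str  # snv / insertion / deletion
    feature: str  # UTR5 / exon / intron / UTR3
    ref: str
    novel: str
    codon_effect: str | None = None  # synonymous / nonsynonymous (exonic SNVs)

    def to_dict(self) -> dict:
        return {
            "position": self.position,
            "kind": self.kind,
            "feature": self.feature,
            "ref": self.ref,
            "novel": self.novel,
            "codon_effect": self.codon_effect,
        }


@dataclass
class GeneAnnotation:
    """Projected gene model and derived coding annotation for a novel
    sequence."""

    sequence: str
    reference: ReferenceAllele
    model: GeneModel  # projected onto the novel sequence
    alignment: Alignment  # novel (query) vs reference (target)
    differences: list[Difference] = field(default_factory=list)

    @property
    def cds(self) -> str:
        return self.model.cds_sequence(self.sequence)

    @property
    def protein(self) -> str:
        """Translation of the CDS up to and including the first stop.

        A frameshifted CDS is truncated to a codon multiple before
        translation."""
        cds = self.cds
        cds = cds[: len(cds) - len(cds) % 3]
        aa = str(Seq(cds).translate())
        stop = aa.find("*")
        return aa if stop < 0 else aa[: stop + 1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "reference": self.reference.name,
                "model": [list(f) for f in self.model.features],
                "differences": [d.to_dict() for d in self.differences],
                "cds_length": len(self.cds),
                "protein": self.protein,
            },
            indent=1,
        )


@dataclass(frozen=True)
class ExpressionClass:
    """Predicted expression status of an allele.

    ``cls`` is ``normal``, ``N`` (null: premature stop codon, typically
    via frameshift or nonsense SNV) or ``Q`` (questionable: carries a
    variant catalogued as affecting expression in other alleles).
    """

    cls: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.cls not in ("normal", "N", "Q"):
            raise ValueError(f"unknown expression class {self.cls!r}")


def find_closest_reference(
    novel: str, ref_set
) -> tuple[ReferenceAllele, int]:
    """Reference allele at minimal edit distance from ``novel``.

    Ties break towards the lexicographically smallest allele name so the
    choice is reproducible.
    """
    alleles = list(ref_set.alleles if hasattr(ref_set, "alleles") else ref_set)
    if not alleles:
        raise ValueError("reference set is empty")
    best = None
    for allele in alleles:
        d = edit_distance(novel, allele.sequence)
        if best is None or d < best[1] or (d == best[1] and allele.name < best[0].name):
            best = (allele, d)
    return best


def transfer_gene_model(novel: str, closest: ReferenceAllele) -> GeneAnnotation:
    """Project the closest reference's gene model onto a novel sequence.

    Feature boundaries travel through the global alignment mapping;
    insertions inside a feature extend it, and insertions at a feature
    junction join the upstream feature.  Projection is refused when
    alignment identity falls below 90% — below that the feature mapping
    is not trustworthy.
    """
    aln = align_global(novel, closest.sequence)
    if aln.identity < MIN_TRANSFER_IDENTITY:
        raise AnnotationError(
            f"alignment identity {aln.identity:.3f} below "
            f"{MIN_TRANSFER_IDENTITY:.2f}; refusing gene-model transfer "
            f"from {closest.name}"
        )
    mapping = aln.map_target_to_query()
    feats = []
    for kind, s, e in closest.model.features:
        feats.append((kind, int(mapping[s]), int(mapping[e])))
    # terminal insertions belong to the terminal UTRs
    kind, s, _ = feats[-1]
    feats[-1] = (kind, s, len(novel))
    kind, _, e = feats[0]
    feats[0] = (kind, 0, e)
    model = GeneModel(tuple(feats))
    ann = GeneAnnotation(sequence=novel, reference=closest, model=model, alignment=aln)
    ann.differences = enumerate_differences(ann)
    return ann


def _codon_effect(ref: ReferenceAllele, pos: int, alt: str) -> str | None:
    """Synonymous/nonsynonymous status of an exonic SNV at reference
    position ``pos``."""
    cds_index = 0
    for s, e in ref.model.exons:
        if s <= pos < e:
            cds_index += pos - s
            break
        cds_index += e - s
    else:
        return None
    cds = ref.model.cds_sequence(ref.sequence)
    codon_start = (cds_index // 3) * 3
    codon = cds[codon_start:codon_start + 3]
    if len(codon) < 3:
        return None
    mutated = list(codon)
    mutated[cds_index % 3] = alt
    before = str(Seq(codon).translate())
    after = str(Seq("".join(mutated)).translate())
    return "synonymous" if before == after else "nonsynonymous"


def enumerate_differences(annotation: GeneAnnotation) -> list[Difference]:
    """List every aligned difference once, with its feature kind and, for
    exonic SNVs, the codon effect.

    Runs of inserted or deleted bases are reported as single events at
    the reference position where they start.
    """
    ref = annotation.reference
    aln = annotation.alignment
    out: list[Difference] = []
    pending: tuple[str, int, str] | None = None  # (kind, ref_pos, seq)

    def feature_kind(pos: int) -> str:
        p = min(max(pos, 0), len(ref.sequence) - 1)
        return ref.model.feature_at(p)[0]

    def flush() -> None:
        nonlocal pending
        if pending is None:
            return
        kind, pos, seq = pending
        if kind == "insertion":
            out.append(Difference(pos, "insertion", feature_kind(pos), "", seq))
        else:
            out.append(Difference(pos, "deletion", feature_kind(pos), seq, ""))
        pending = None

    ref_cursor = 0
    for op, qpos, tpos in aln.walk():
        if op == "=":
            flush()
            ref_cursor = tpos + 1
        elif op == "X":
            flush()
            alt = aln.query[qpos]
            eff = None
            if feature_kind(tpos) == "exon":
                eff = _codon_effect(ref, tpos, alt)
            out.append(
                Difference(tpos, "snv", feature_kind(tpos), ref.sequence[tpos],
                           alt, eff)
            )
            ref_cursor = tpos + 1
        elif op == "I":
            if pending and pending[0] == "insertion":
                pending = (pending[0], pending[1], pending[2] + aln.query[qpos])
            else:
                flush()
                pending = ("insertion", ref_cursor, aln.query[qpos])
        else:  # D
            if pending and pending[0] == "deletion":
                pending = (pending[0], pending[1], pending[2] + ref.sequence[tpos])
            else:
                flush()
                pending = ("deletion", tpos, ref.sequence[tpos])
            ref_cursor = tpos + 1
    flush()
    return out


def classify_expression(
    annotation: GeneAnnotation, q_catalog: list[dict] | None = None
) -> ExpressionClass:
    """Predict expression status from the projected coding sequence.

    Codons are scanned 5'->3': a stop codon appearing before the
    reference protein's stop marks a null (N) allele — this covers both
    nonsense SNVs and frameshift-induced stops.  Otherwise any aligned
    difference matching an entry of the Q catalog (variants shown in
    other alleles to affect expression) yields class Q; everything else
    is normal.  Catalog entries are dicts with ``position``, ``ref`` and
    ``novel`` in reference coordinates, matched against the enumerated
    differences.
    """
    ref = annotation.reference
    ref_cds = ref.model.cds_sequence(ref.sequence)
    ref_cds = ref_cds[: len(ref_cds) - len(ref_cds) % 3]
    ref_aa = str(Seq(ref_cds).translate())
    ref_stop = ref_aa.find("*")
    ref_protein_len = ref_stop if ref_stop >= 0 else len(ref_aa)

    novel_aa = annotation.protein
    novel_stop = novel_aa.find("*")
    if novel_stop >= 0 and novel_stop < ref_protein_len:
        return ExpressionClass(
            "N", evidence=f"premature stop codon at protein position {novel_stop + 1}"
        )
    # frameshift that destroys the reference stop without an earlier stop
    if len(annotation.cds) % 3 != 0 and novel_stop < 0:
        return ExpressionClass("N", evidence="frameshift removes the stop codon")
    if q_catalog:
        for entry in q_catalog:
            for diff in annotation.differences:
                if (
                    diff.position == entry.get("position")
                    and diff.ref == entry.get("ref", diff.ref)
                    and diff.novel == entry.get("novel", diff.novel)
                ):
                    return ExpressionClass(
                        "Q",
                        evidence=f"matches expression-affecting variant "
                        f"{entry.get('id', diff.position)}",
                    )
    return ExpressionClass("normal")
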