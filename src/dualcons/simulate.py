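"""Synthetic amplicon data: reference allele sets, heterozygous samples,
and platform-specific read sets.

The generator stands in for whole-gene HLA amplicons.  Two locus templates
are provided: ``classI`` (~3.4 kb, 8 exons, the A/B/C organisation) and
``classII`` (2-3x longer, 6 exons, the DQB1/DPB1 organisation with long
introns).  A heterozygous sample is a pair of allele sequences derived
from references by a small set of edits (SNVs, indels, homopolymer length
changes) — most novel alleles differ from their closest reference in only
one or a few bases.

Error presets capture the platform asymmetry the pipeline is built
around: long single-end reads carry >10% mostly-indel error concentrated
in homopolymers, short 251 bp paired reads are accurate but their
fragments span at most ~1 kb, which bounds what they can phase.

All outputs are pure functions of their inputs and the seed; the
read-to-allele truth labels needed for evaluation travel in a sidecar,
never inside the FASTQ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .seqcore import (
    FastqRead,
    GeneModel,
    ReferenceAllele,
    edit_distance,
    homopolymer_runs,
    reverse_complement,
)

__all__ = [
    "VariantSpec",
    "SNV",
    "Insertion",
    "Deletion",
    "HomopolymerDelta",
    "DiploidTruth",
    "ErrorProfile",
    "LONG_READ_PRESET",
    "SHORT_READ_PRESET",
    "ReferenceSet",
    "ReadSet",
    "PairedReadSet",
    "make_reference_set",
    "make_diploid_sample",
    "simulate_long_reads",
    "simulate_short_reads",
    "apply_variants",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"
HOMOPOLYMER_MIN_RUN = 4  # shortest run where indel bias matters


# --- variant specifications -----------------------------------------------


@dataclass(frozen=True)
class SNV:
    pos: int
    alt: str


@dataclass(frozen=True)
class Insertion:
    pos: int  # inserted before this reference position
    seq: str


@dataclass(frozen=True)
class Deletion:
    pos: int
    length: int


@dataclass(frozen=True)
class HomopolymerDelta:
    """Lengthen (+k) or shorten (-k) the homopolymer run containing ``locus``."""

    locus: int
    delta: int


Edit = SNV | Insertion | Deletion | HomopolymerDelta


@dataclass(frozen=True)
class VariantSpec:
    """Edits applied to one reference allele to produce a haplotype."""

    edits: tuple[Edit, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "edits", tuple(self.edits))

    def intervals(self, sequence: str) -> list[tuple[int, int]]:
        """Reference interval touched by each edit (for overlap checks)."""
        out = []
        for e in self.edits:
            if isinstance(e, SNV):
                out.append((e.pos, e.pos + 1))
            elif isinstance(e, Insertion):
                out.append((e.pos, e.pos))
            elif isinstance(e, Deletion):
                out.append((e.pos, e.pos + e.length))
            else:
                runs = [r for r in homopolymer_runs(sequence, HOMOPOLYMER_MIN_RUN)
                        if r[0] <= e.locus < r[1]]
                if not runs:
                    raise ValueError(
                        f"no homopolymer run (>= {HOMOPOLYMER_MIN_RUN}) at locus {e.locus}"
                    )
                out.append(runs[0][:2])
        return out

    def validate(self, sequence: str) -> None:
        ivals = sorted(self.intervals(sequence))
        n = len(sequence)
        for s, e in ivals:
            if not (0 <= s <= e <= n):
                raise ValueError(f"edit interval [{s},{e}) outside sequence of length {n}")
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError("edits overlap")


def apply_variants(sequence: str, spec: VariantSpec) -> str:
    """Apply a variant spec to a reference sequence, right to left."""
    spec.validate(sequence)
    seq = sequence
    keyed = sorted(
        zip(spec.intervals(sequence), spec.edits), key=lambda kv: kv[0][0], reverse=True
    )
    for (s, e), edit in keyed:
        if isinstance(edit, SNV):
            if edit.alt == seq[s]:
                raise ValueError(f"SNV at {s} does not change the base ({edit.alt})")
            seq = seq[:s] + edit.alt + seq[s + 1:]
        elif isinstance(edit, Insertion):
            seq = seq[:s] + edit.seq + seq[s:]
        elif isinstance(edit, Deletion):
            seq = seq[:s] + seq[e:]
        else:  # HomopolymerDelta over run [s, e)
            base = sequence[s]
            new_len = (e - s) + edit.delta
            if new_len < 1:
                raise ValueError("homopolymer delta would delete the whole run")
            seq = seq[:s] + base * new_len + seq[e:]
    return seq


# --- diploid samples -------------------------------------------------------


@dataclass(frozen=True)
class DiploidTruth:
    """The two simulated haplotypes of a heterozygous sample, with ground truth."""

    allele1: str
    allele2: str
    source1: ReferenceAllele
    source2: ReferenceAllele
    spec1: VariantSpec
    spec2: VariantSpec

    @property
    def is_homozygous(self) -> bool:
        return self.allele1 == self.allele2

    def het_positions(self) -> list[int]:
        """Heterozygous positions projected to allele1 coordinates.

        Recomputed from a global alignment of the two haplotypes; indel
        differences are reported at the allele1 position where the
        alignment first diverges.
        """
        from .seqcore import align_edit

        if self.is_homozygous:
            return []
        aln = align_edit(self.allele1, self.allele2)
        positions = []
        for op, qpos, _ in aln.walk():
            if op == "X" and qpos is not None:
                positions.append(qpos)
            elif op == "I" and qpos is not None:
                positions.append(qpos)
            elif op == "D":
                continue
        # a deletion in allele1 (op D) has no allele1 base; attribute it to
        # the next allele1 position via a second pass
        out = sorted(set(positions))
        qi = 0
        extra = []
        for op, qpos, _ in aln.walk():
            if op == "D":
                extra.append(min(qi, len(self.allele1) - 1))
            if qpos is not None:
                qi = qpos + 1
        return sorted(set(out) | set(extra))


def make_diploid_sample(
    ref_set: "ReferenceSet",
    variant_spec1: VariantSpec,
    variant_spec2: VariantSpec,
    seed: int | None = None,
    source1: str | None = None,
    source2: str | None = None,
) -> DiploidTruth:
    """Build a two-haplotype sample from a reference set.

    Sources default to the first allele of the set for both haplotypes
    (the common case: a novel allele paired with a known one on the same
    closest reference).  ``seed`` is accepted for interface uniformity;
    the construction itself is deterministic.
    """
    r1 = ref_set[source1] if source1 else ref_set.alleles[0]
    r2 = ref_set[source2] if source2 else ref_set.alleles[0]
    return DiploidTruth(
        allele1=apply_variants(r1.sequence, variant_spec1),
        allele2=apply_variants(r2.sequence, variant_spec2),
        source1=r1,
        source2=r2,
        spec1=variant_spec1,
        spec2=variant_spec2,
    )


# --- reference sets --------------------------------------------------------


@dataclass(frozen=True)
class ReferenceSet:
    locus: str
    alleles: tuple[ReferenceAllele, ...]

    def __post_init__(self) -> None:
        names = [a.name for a in self.alleles]
        if len(set(names)) != len(names):
            raise ValueError("allele names must be unique within a reference set")

    def __getitem__(self, name: str) -> ReferenceAllele:
        for a in self.alleles:
            if a.name == name:
                return a
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.alleles)


# Feature length templates.  Class I loci (A/B/C) are ~3.4 kb with 8 exons;
# class II loci carry fewer, larger exons and much longer introns, putting
# them at 2-3x the class I length.
_CLASS_I_LAYOUT = [
    ("UTR5", 120), ("exon", 73), ("intron", 130), ("exon", 270),
    ("intron", 241), ("exon", 276), ("intron", 599), ("exon", 276),
    ("intron", 120), ("exon", 117), ("intron", 442), ("exon", 33),
    ("intron", 142), ("exon", 48), ("intron", 170), ("exon", 147),
    ("UTR3", 200),
]
_CLASS_II_LAYOUT = [
    ("UTR5", 250), ("exon", 110), ("intron", 2400), ("exon", 270),
    ("intron", 1800), ("exon", 282), ("intron", 700), ("exon", 111),
    ("intron", 500), ("exon", 24), ("intron", 900), ("exon", 250),
    ("UTR3", 380),
]
_TEMPLATES = {"classI": _CLASS_I_LAYOUT, "classII": _CLASS_II_LAYOUT}


def _model_from_layout(layout) -> GeneModel:
    feats = []
    pos = 0
    for kind, length in layout:
        feats.append((kind, pos, pos + length))
        pos += length
    return GeneModel(tuple(feats))


def make_reference_set(
    n_alleles: int,
    locus_template: str = "classI",
    divergence: float = 0.01,
    seed: int = 0,
) -> ReferenceSet:
    """Simulate a reference allele set for one locus.

    The first allele is drawn uniformly at random over ACGT (with a few
    homopolymer runs planted so downstream homopolymer handling is
    exercised); subsequent alleles differ from it by ``divergence``
    substitutions per base.  Deterministic under ``seed``.
    """
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    if locus_template not in _TEMPLATES:
        raise ValueError(f"unknown locus template {locus_template!r}")
    rng = np.random.default_rng(seed)
    model = _model_from_layout(_TEMPLATES[locus_template])
    length = model.span
    base = rng.integers(0, 4, size=length)
    seq = np.array(_BASES)[base]
    # plant homopolymer runs (length 5-9) in introns/UTRs so long-read
    # indel stress has somewhere to act
    introns = [(s, e) for k, s, e in model.features if k in ("intron", "UTR3")]
    for s, e in introns:
        if e - s < 40:
            continue
        run_len = int(rng.integers(5, 10))
        start = int(rng.integers(s + 5, e - run_len - 5))
        b = _BASES[int(rng.integers(0, 4))]
        seq[start:start + run_len] = b
    first = seq.tobytes().decode()
    prefix = {"classI": "HLA-X*", "classII": "HLA-DXB1*"}[locus_template]
    alleles = [ReferenceAllele(f"{prefix}01:01", first, model)]
    for i in range(1, n_alleles):
        n_subs = max(1, int(round(divergence * length)))
        positions = rng.choice(length, size=n_subs, replace=False)
        arr = np.frombuffer(first.encode(), dtype=np.uint8).copy()
        for p in positions:
            cur = arr[p]
            choices = _BASES[_BASES != cur]
            arr[p] = choices[int(rng.integers(0, 3))]
        alleles.append(
            ReferenceAllele(f"{prefix}{i + 1:02d}:01", arr.tobytes().decode(), model)
        )
    return ReferenceSet(locus="A" if locus_template == "classI" else "DQB1",
                        alleles=tuple(alleles))


# --- error profiles --------------------------------------------------------


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base error rates and read geometry for one platform.

    ``homopolymer_multiplier`` scales the indel rates inside homopolymer
    runs of length >= 4, emulating the indel bias of single-molecule long
    reads.  ``fragment_span_max`` applies to paired short reads only: it
    is the hard ceiling on fragment length (~1 kb on the short-read
    platform), which is what limits phasing range.
    """

    substitution_rate: float
    insertion_rate: float
    deletion_rate: float
    homopolymer_multiplier: float = 1.0
    read_length: int | None = None  # None = full amplicon (long reads)
    fragment_span_max: int | None = None
    fragment_span_min: int = 400
    paired: bool = False

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0 <= r <= 1:
                raise ValueError("error rates must lie in [0, 1]")

    @property
    def total_error(self) -> float:
        return self.substitution_rate + self.insertion_rate + self.deletion_rate


#: Long single-end reads: 13% total error, indel-dominated, amplified in
#: homopolymers — the >10% per-read error regime of single-molecule data.
LONG_READ_PRESET = ErrorProfile(
    substitution_rate=0.01,
    insertion_rate=0.06,
    deletion_rate=0.06,
    homopolymer_multiplier=2.0,
    read_length=None,
    paired=False,
)

#: Short accurate 251 bp paired reads from <=1 kb fragments.
SHORT_READ_PRESET = ErrorProfile(
    substitution_rate=0.002,
    insertion_rate=0.0,
    deletion_rate=0.0,
    read_length=251,
    fragment_span_max=1000,
    fragment_span_min=400,
    paired=True,
)


@dataclass(frozen=True)
class ReadSet:
    reads: tuple[FastqRead, ...]
    truth_labels: tuple[int, ...]  # source haplotype (1 or 2) per read

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class PairedReadSet:
    """Mate pairs (R1 forward, R2 reverse-complemented) plus truth labels."""

    pairs: tuple[tuple[FastqRead, FastqRead], ...]
    truth_labels: tuple[int, ...]
    fragment_spans: tuple[tuple[int, int], ...]  # on the source haplotype

    def __len__(self) -> int:
        return len(self.pairs)


def _mutate(seq: str, profile: ErrorProfile, rng: np.random.Generator) -> str:
    """Apply i.i.d. per-base errors; indel rates are multiplied inside
    homopolymer runs of length >= 4."""
    if profile.total_error == 0:
        return seq
    in_run = np.zeros(len(seq), dtype=bool)
    for s, e, _ in homopolymer_runs(seq, HOMOPOLYMER_MIN_RUN):
        in_run[s:e] = True
    out = []
    u = rng.random(len(seq))
    for i, ch in enumerate(seq):
        mult = profile.homopolymer_multiplier if in_run[i] else 1.0
        p_ins = profile.insertion_rate * mult
        p_del = profile.deletion_rate * mult
        p_sub = profile.substitution_rate
        x = u[i]
        if x < p_del:
            continue  # base dropped
        x -= p_del
        if x < p_ins:
            # duplicate-style insertion: homopolymer-plausible errors
            out.append(ch)
            out.append(ch if in_run[i] else _BASE_STR[int(rng.integers(0, 4))])
            continue
        x -= p_ins
        if x < p_sub:
            alts = [b for b in _BASE_STR if b != ch]
            out.append(alts[int(rng.integers(0, 3))])
        else:
            out.append(ch)
    return "".join(out)


def _qual(n: int, q: int = 30) -> str:
    return chr(q + 33) * n


def simulate_long_reads(
    truth: DiploidTruth,
    n_reads: int,
    profile: ErrorProfile = LONG_READ_PRESET,
    seed: int = 0,
) -> ReadSet:
    """Full-amplicon single-molecule reads with indel-heavy errors.

    Each read covers the whole haplotype (amplicon sequencing of a
    multi-kb product); source haplotypes are drawn 50/50.  Errors are
    i.i.d. per base with the profile's homopolymer multiplier applied
    inside runs of length >= 4.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if profile.paired:
        raise ValueError("long-read simulation takes an unpaired profile")
    rng = np.random.default_rng(seed)
    haplotypes = (truth.allele1, truth.allele2)
    reads = []
    labels = []
    for i in range(n_reads):
        src = int(rng.integers(1, 3))
        hap = haplotypes[src - 1]
        if profile.read_length is not None and profile.read_length < len(hap):
            start = int(rng.integers(0, len(hap) - profile.read_length + 1))
            template = hap[start:start + profile.read_length]
        else:
            template = hap
        seq = _mutate(template, profile, rng)
        reads.append(FastqRead(f"long_{i:05d}", seq, _qual(len(seq), 13)))
        labels.append(src)
    return ReadSet(tuple(reads), tuple(labels))


def simulate_short_reads(
    truth: DiploidTruth,
    coverage: float,
    profile: ErrorProfile = SHORT_READ_PRESET,
    seed: int = 0,
) -> PairedReadSet:
    """Paired 251 bp shotgun reads from fragments capped at ~1 kb.

    The pair count is ``round(coverage * L / (2 * read_length))`` on the
    mean haplotype length L.  R2 is the reverse complement of the
    fragment's far end.  Fragment lengths are uniform on
    [span_min, span_max] (truncated to the fragment's room on the
    haplotype), so no pair can link variants farther apart than the span
    ceiling — the short-platform phasing limit.
    """
    if not profile.paired:
        raise ValueError("short-read simulation requires a paired profile")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    rl = profile.read_length or 251
    span_max = profile.fragment_span_max or 1000
    span_min = min(profile.fragment_span_min, span_max)
    haplotypes = (truth.allele1, truth.allele2)
    mean_len = (len(truth.allele1) + len(truth.allele2)) / 2
    n_pairs = int(round(coverage * mean_len / (2 * rl)))
    pairs, labels, spans = [], [], []
    for i in range(n_pairs):
        src = int(rng.integers(1, 3))
        hap = haplotypes[src - 1]
        frag_len = int(rng.integers(span_min, span_max + 1))
        frag_len = min(frag_len, len(hap))
        start = int(rng.integers(0, len(hap) - frag_len + 1))
        frag = hap[start:start + frag_len]
        r1 = _mutate(frag[:rl], profile, rng)
        r2 = _mutate(reverse_complement(frag[-rl:]), profile, rng)
        pairs.append(
            (
                FastqRead(f"pair_{i:05d}/1", r1, _qual(len(r1))),
                FastqRead(f"pair_{i:05d}/2", r2, _qual(len(r2))),
            )
        )
        labels.append(src)
        spans.append((start, start + frag_len))
    return PairedReadSet(tuple(pairs), tuple(labels), tuple(spans))


def write_truth_sidecar(read_names, labels, path) -> None:
    """Tab-separated read-name -> source-haplotype sidecar (truth stays out
    of the FASTQ)."""
    with open(path, "w") as fh:
        fh.write("read_name\tsource_allele\n")
        for name, lab in zip(read_names, labels):
            fh.write(f"{name}\t{lab}\n")
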