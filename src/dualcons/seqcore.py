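"""Sequence and alignment primitives shared by all pipeline stages.

Coordinates are 0-based half-open everywhere in memory; the only 1-based
inclusive coordinates in the package appear in EMBL flat-file output
(:mod:`dualcons.report_submit`).

Two alignment routes are provided:

* :func:`align_global` — affine-gap (Gotoh) global alignment with a fixed,
  deterministic traceback preference (match > mismatch > deletion >
  insertion).  This is the scoring-sensitive primitive used for consensus
  vs. reference comparison and gene-model projection.
* :func:`align_edit` / :func:`edit_distance` — unit-cost alignment backed
  by edlib, used on hot paths (per-read placement) where only the edit
  path matters.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import edlib
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from numba import njit

DNA_ALPHABET = frozenset("ACGT")

__all__ = [
    "GeneModel",
    "ReferenceAllele",
    "Alignment",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "align_global",
    "align_edit",
    "edit_distance",
    "reverse_complement",
    "homopolymer_runs",
]

FEATURE_KINDS = ("UTR5", "exon", "intron", "UTR3")


class ParseError(ValueError):
    """Malformed FASTA/FASTQ or sidecar input."""


@dataclass(frozen=True)
class GeneModel:
    """UTR/exon/intron partition of a genomic allele sequence.

    ``features`` is an ordered tuple of ``(kind, start, end)`` in 0-based
    half-open coordinates that tiles the sequence without gaps or overlaps:
    UTR5, then alternating exons and introns, then UTR3.
    """

    features: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        feats = tuple((str(k), int(s), int(e)) for k, s, e in self.features)
        object.__setattr__(self, "features", feats)
        self.validate()

    def validate(self) -> None:
        if not self.features:
            raise ValueError("gene model has no features")
        prev_end = None
        for kind, start, end in self.features:
            if kind not in FEATURE_KINDS:
                raise ValueError(f"unknown feature kind {kind!r}")
            if end <= start:
                raise ValueError(f"empty/inverted feature {kind} [{start},{end})")
            if prev_end is not None and start != prev_end:
                raise ValueError("features must tile the sequence contiguously")
            prev_end = end
        if self.features[0][0] != "UTR5" or self.features[-1][0] != "UTR3":
            raise ValueError("model must start with UTR5 and end with UTR3")
        inner = [k for k, _, _ in self.features[1:-1]]
        for i, kind in enumerate(inner):
            expect = "exon" if i % 2 == 0 else "intron"
            if kind != expect:
                raise ValueError("exons and introns must alternate")
        if inner and inner[-1] != "exon":
            raise ValueError("last internal feature must be an exon")

    @property
    def span(self) -> int:
        return self.features[-1][2] - self.features[0][1]

    @property
    def exons(self) -> list[tuple[int, int]]:
        """Exon intervals in rank order (rank 1..n)."""
        return [(s, e) for k, s, e in self.features if k == "exon"]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def feature_at(self, pos: int) -> tuple[str, int, int]:
        """Feature containing position ``pos``."""
        for feat in self.features:
            if feat[1] <= pos < feat[2]:
                return feat
        raise IndexError(f"position {pos} outside gene model span")

    def cds_sequence(self, sequence: str) -> str:
        """Spliced exon sequence (the coding sequence)."""
        return "".join(sequence[s:e] for s, e in self.exons)


@dataclass(frozen=True)
class ReferenceAllele:
    """A named full-length allele sequence plus its gene model."""

    name: str
    sequence: str
    model: GeneModel

    def __post_init__(self) -> None:
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(f"non-ACGT characters in {self.name}: {sorted(bad)}")
        if self.model.span != len(self.sequence):
            raise ValueError(
                f"gene model span {self.model.span} != sequence length "
                f"{len(self.sequence)} for {self.name}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


# --- alignment -------------------------------------------------------------

# CIGAR-like ops, all relative to (query, target):
#   "=" match        consumes query + target
#   "X" mismatch     consumes query + target
#   "D" deletion     gap in query, consumes target only
#   "I" insertion    gap in target, consumes query only
_OPS = ("=", "X", "D", "I")


@dataclass
class Alignment:
    """Pairwise global alignment between a query and a target.

    ``ops`` is a list of ``(op, length)`` with op in ``=XDI``; consumed
    query length equals ``len(query)`` and consumed target length equals
    ``len(target)``.
    """

    query: str
    target: str
    ops: list[tuple[str, int]]
    score: float = 0.0

    def __post_init__(self) -> None:
        q = sum(n for op, n in self.ops if op in "=XI")
        t = sum(n for op, n in self.ops if op in "=XD")
        if q != len(self.query) or t != len(self.target):
            raise ValueError(
                f"alignment consumes ({q},{t}) but sequences are "
                f"({len(self.query)},{len(self.target)})"
            )

    @property
    def n_matches(self) -> int:
        return sum(n for op, n in self.ops if op == "=")

    @property
    def n_mismatches(self) -> int:
        return sum(n for op, n in self.ops if op == "X")

    @property
    def n_gaps(self) -> int:
        return sum(n for op, n in self.ops if op in "DI")

    @property
    def identity(self) -> float:
        total = sum(n for _, n in self.ops)
        return self.n_matches / total if total else 0.0

    def edit_distance(self) -> int:
        return sum(n for op, n in self.ops if op != "=")

    def walk(self) -> Iterator[tuple[str, int | None, int | None]]:
        """Yield ``(op, query_pos, target_pos)`` per aligned column.

        Positions are ``None`` on the gapped side.
        """
        qi = ti = 0
        for op, n in self.ops:
            for _ in range(n):
                if op in "=X":
                    yield op, qi, ti
                    qi += 1
                    ti += 1
                elif op == "I":
                    yield op, qi, None
                    qi += 1
                else:  # D
                    yield op, None, ti
                    ti += 1

    def map_target_to_query(self) -> np.ndarray:
        """Monotonic projection of every target coordinate onto the query.

        Returns an array of length ``len(target) + 1`` mapping each target
        boundary to the corresponding query boundary (insertions in the
        query ahead of a target position shift subsequent boundaries).
        """
        mapping = np.zeros(len(self.target) + 1, dtype=np.int64)
        qi = ti = 0
        for op, n in self.ops:
            if op in "=X":
                for _ in range(n):
                    mapping[ti] = qi
                    qi += 1
                    ti += 1
            elif op == "I":
                qi += n
            else:  # D
                for _ in range(n):
                    mapping[ti] = qi
                    ti += 1
        mapping[len(self.target)] = qi
        return mapping


# Traceback codes: 0 = diagonal from M, 1 = from D(gap-in-query), 2 = from I
@njit(cache=True)
def _gotoh_fill(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = len(q), len(t)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    D = np.full((n + 1, m + 1), NEG)  # gap in query (consumes target)
    I = np.full((n + 1, m + 1), NEG)  # gap in target (consumes query)
    # traceback: which matrix each cell's best predecessor lives in
    tbM = np.zeros((n + 1, m + 1), dtype=np.int8)
    tbD = np.zeros((n + 1, m + 1), dtype=np.int8)
    tbI = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        D[0, j] = gap_open + gap_extend * (j - 1)
        tbD[0, j] = 1
    for i in range(1, n + 1):
        I[i, 0] = gap_open + gap_extend * (i - 1)
        tbI[i, 0] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if q[i - 1] == t[j - 1] else mismatch
            # M: diagonal step; prefer M then D then I on ties
            best = M[i - 1, j - 1]
            code = 0
            if D[i - 1, j - 1] > best:
                best = D[i - 1, j - 1]
                code = 1
            if I[i - 1, j - 1] > best:
                best = I[i - 1, j - 1]
                code = 2
            M[i, j] = best + s
            tbM[i, j] = code
            # D: gap in query, from the left
            open_d = M[i, j - 1] + gap_open
            ext_d = D[i, j - 1] + gap_extend
            alt_d = I[i, j - 1] + gap_open
            best = open_d
            code = 0
            if ext_d > best:
                best = ext_d
                code = 1
            if alt_d > best:
                best = alt_d
                code = 2
            D[i, j] = best
            tbD[i, j] = code
            # I: gap in target, from above
            open_i = M[i - 1, j] + gap_open
            ext_i = I[i - 1, j] + gap_extend
            alt_i = D[i - 1, j] + gap_open
            best = open_i
            code = 0
            if alt_i > best:
                best = alt_i
                code = 1
            if ext_i > best:
                best = ext_i
                code = 2
            I[i, j] = best
            tbI[i, j] = code
    return M, D, I, tbM, tbD, tbI


def align_global(
    query: str,
    target: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
) -> Alignment:
    """Optimal affine-gap global alignment (Gotoh) of two DNA sequences.

    The traceback is deterministic: on score ties the preference order is
    match/mismatch (diagonal) > deletion (gap in query) > insertion
    (gap in target), so all downstream results are reproducible.
    """
    if not query or not target:
        raise ValueError("align_global requires non-empty sequences")
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    M, D, I, tbM, tbD, tbI = _gotoh_fill(
        q, t, float(match), float(mismatch), float(gap_open), float(gap_extend)
    )
    n, m = len(query), len(target)
    # endpoint preference mirrors the step preference
    score = M[n, m]
    state = 0
    if D[n, m] > score:
        score, state = D[n, m], 1
    if I[n, m] > score:
        score, state = I[n, m], 2
    rev_ops: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            rev_ops.append("=" if query[i - 1] == target[j - 1] else "X")
            state = tbM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            rev_ops.append("D")
            state = tbD[i, j]
            j -= 1
        else:
            rev_ops.append("I")
            state = tbI[i, j]
            i -= 1
    rev_ops.reverse()
    return Alignment(query, target, _run_length(rev_ops), float(score))


def _run_length(ops: Sequence[str]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op in ops:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((op, 1))
    return out


@njit(cache=True)
def _banded_fill(q, t, lo, hi, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m = len(t)
    W = 0
    for j in range(m + 1):
        w = hi[j] - lo[j] + 1
        if w > W:
            W = w
    NEG = -1e18
    M = np.full((m + 1, W), NEG)
    D = np.full((m + 1, W), NEG)
    I = np.full((m + 1, W), NEG)
    tbM = np.zeros((m + 1, W), dtype=np.int8)
    tbD = np.zeros((m + 1, W), dtype=np.int8)
    tbI = np.zeros((m + 1, W), dtype=np.int8)

    # column j=0: only gaps in target (consume query)
    for i in range(lo[0], hi[0] + 1):
        k = i - lo[0]
        if i == 0:
            M[0, k] = 0.0
        else:
            I[0, k] = gap_open + gap_extend * (i - 1)
            tbI[0, k] = 2
    for j in range(1, m + 1):
        off = lo[j]
        offp = lo[j - 1]
        for i in range(lo[j], hi[j] + 1):
            k = i - off
            # M: diagonal from (i-1, j-1)
            bm = NEG
            cm = 0
            ip = i - 1
            if lo[j - 1] <= ip <= hi[j - 1]:
                kp = ip - offp
                bm = M[j - 1, kp]
                cm = 0
                if D[j - 1, kp] > bm:
                    bm = D[j - 1, kp]
                    cm = 1
                if I[j - 1, kp] > bm:
                    bm = I[j - 1, kp]
                    cm = 2
            if bm > NEG / 2 and i >= 1:
                s = match if q[i - 1] == t[j - 1] else mismatch
                M[j, k] = bm + s
                tbM[j, k] = cm
            # D: from (i, j-1), gap in query
            if lo[j - 1] <= i <= hi[j - 1]:
                kp = i - offp
                bd = M[j - 1, kp] + gap_open
                cd = 0
                if D[j - 1, kp] + gap_extend > bd:
                    bd = D[j - 1, kp] + gap_extend
                    cd = 1
                if I[j - 1, kp] + gap_open > bd:
                    bd = I[j - 1, kp] + gap_open
                    cd = 2
                D[j, k] = bd
                tbD[j, k] = cd
            # I: from (i-1, j), gap in target
            if i - 1 >= lo[j]:
                kp = i - 1 - off
                bi = M[j, kp] + gap_open
                ci = 0
                if D[j, kp] + gap_open > bi:
                    bi = D[j, kp] + gap_open
                    ci = 1
                if I[j, kp] + gap_extend > bi:
                    bi = I[j, kp] + gap_extend
                    ci = 2
                I[j, k] = bi
                tbI[j, k] = ci
    return M, D, I, tbM, tbD, tbI


def _path_centers(query: str, target: str) -> np.ndarray:
    """Query position at each target boundary along the edlib optimal
    unit-cost path (the guide line for banded affine realignment)."""
    res = edlib.align(query, target, mode="NW", task="path")
    centers = np.zeros(len(target) + 1, dtype=np.int64)
    qi = ti = 0
    num = ""
    centers[0] = 0
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            for _ in range(n):
                qi += 1
                ti += 1
                centers[ti] = qi
        elif ch == "I":  # consumes query
            qi += 1 * n
            centers[ti] = qi
        else:  # D consumes target
            for _ in range(n):
                ti += 1
                centers[ti] = qi
    centers[len(target)] = len(query)
    return centers


def align_banded(
    query: str,
    target: str,
    band: int = 48,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
) -> Alignment:
    """Affine-gap global alignment restricted to a band around the
    unit-cost optimal path.

    Affine scoring keeps substitutions aligned as mismatches instead of
    letting them drift into gap pairs, which matters when counting
    per-column evidence from indel-heavy long reads; the band (guided by
    the edlib path) keeps the cost near-linear.  For sequences whose
    optimal affine path leaves the band the result is a best-in-band
    alignment, not the global optimum.
    """
    if not query or not target:
        raise ValueError("align_banded requires non-empty sequences")
    n, m = len(query), len(target)
    centers = _path_centers(query, target)
    lo = np.maximum(centers - band, 0)
    hi = np.minimum(centers + band, n)
    # keep the band connected and anchored at the corners
    lo[0] = 0
    hi[-1] = n
    lo[-1] = min(lo[-1], n)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    M, D, I, tbM, tbD, tbI = _banded_fill(
        q, t, lo, hi, float(match), float(mismatch), float(gap_open),
        float(gap_extend),
    )
    k_end = n - lo[m]
    score = M[m, k_end]
    state = 0
    if D[m, k_end] > score:
        score, state = D[m, k_end], 1
    if I[m, k_end] > score:
        score, state = I[m, k_end], 2
    rev_ops: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        k = i - lo[j]
        if state == 0:
            rev_ops.append("=" if query[i - 1] == target[j - 1] else "X")
            state = tbM[j, k]
            i -= 1
            j -= 1
        elif state == 1:
            rev_ops.append("D")
            state = tbD[j, k]
            j -= 1
        else:
            rev_ops.append("I")
            state = tbI[j, k]
            i -= 1
    rev_ops.reverse()
    return Alignment(query, target, _run_length(rev_ops), float(score))


def align_edit(query: str, target: str) -> Alignment:
    """Unit-cost global alignment via edlib (fast path for read placement)."""
    if not query or not target:
        raise ValueError("align_edit requires non-empty sequences")
    res = edlib.align(query, target, mode="NW", task="path")
    ops: list[tuple[str, int]] = []
    num = ""
    # edlib CIGAR: I consumes query, D consumes target — same as ours
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return Alignment(query, target, ops, float(-res["editDistance"]))


def edit_distance(a: str, b: str) -> int:
    """Unit-cost (Levenshtein) distance between two sequences."""
    if not a or not b:
        return max(len(a), len(b))
    return int(edlib.align(a, b, mode="NW", task="distance")["editDistance"])


_COMP = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def homopolymer_runs(seq: str, min_len: int = 4) -> list[tuple[int, int, str]]:
    """All homopolymer runs of length >= ``min_len`` as (start, end, base)."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j, seq[i]))
        i = j
    return runs


# --- FASTA / FASTQ ---------------------------------------------------------


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(name, sequence)`` pairs."""
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append((rec.id, str(rec.seq).upper()))
    except ValueError as exc:
        raise ParseError(f"{path}: malformed FASTA: {exc}") from exc
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    """Write FASTA with sequence lines wrapped at ``width`` columns."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


@dataclass(frozen=True)
class FastqRead:
    name: str
    sequence: str
    quality: str  # Sanger PHRED+33

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ParseError(
                f"read {self.name}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )


def read_fastq(path) -> list[FastqRead]:
    """Read FASTQ (PHRED+33); malformed records raise :class:`ParseError`
    naming the offending line."""
    reads: list[FastqRead] = []
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lineno += 1
            if not header.startswith("@"):
                raise ParseError(f"{path}:{lineno}: expected '@' header")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise ParseError(f"{path}:{lineno}: truncated record")
            lineno += 3
            if not plus.startswith("+"):
                raise ParseError(f"{path}:{lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}:{lineno}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            reads.append(FastqRead(header[1:].strip().split()[0], seq.upper(), qual))
    return reads


def write_fastq(reads: Iterable[FastqRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")
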