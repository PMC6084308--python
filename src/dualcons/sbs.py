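"""Short-read consensus: pileup construction, per-position calling with
heterozygote detection, and phase-block analysis.

Short accurate reads call bases and heterozygous positions very reliably,
but two heterozygous positions can only be phased when some sequenced
fragment covers both.  With fragments capped near 1 kb, hets farther
apart than that fall into separate phase blocks and whole-gene phasing is
undefined — the failure mode that motivates bringing in long reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import edlib
import numpy as np

from .seqcore import Alignment, align_banded, align_edit, reverse_complement
from .simulate import PairedReadSet

__all__ = ["Pileup", "ConsensusTrack", "build_pileup", "call_consensus", "phase_hets"]

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_BASE = "ACGT"
DEL = 4  # deletion row in the count matrix


@dataclass
class Pileup:
    """Per-reference-position base counts over placed reads.

    ``counts`` is (L, 5): columns A, C, G, T, deletion.  Insertions are
    keyed by the reference position they precede.  ``n_unplaced`` counts
    reads that could not be placed (or tied between placements and were
    dropped to avoid double-counting).
    """

    backbone: str
    counts: np.ndarray
    insertions: dict[int, list[str]] = field(default_factory=dict)
    n_unplaced: int = 0
    # per placed fragment: {ref_pos: base_or_'-'} for phasing/clustering
    read_observations: list[dict[int, str]] = field(default_factory=list)
    # per placed fragment: {ref_pos: inserted_seq_before_pos}
    read_insertions: list[dict[int, str]] = field(default_factory=list)

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def _place_read(seq: str, backbone: str) -> tuple[int, Alignment, bool] | None:
    """Best placement of a read on the backbone.

    Reads spanning most of the backbone (amplicon-length long reads) get
    a global banded affine alignment: affine gap scoring keeps true
    substitutions aligned as mismatches instead of drifting into gap
    pairs, which matters for per-column evidence from indel-heavy reads.
    Shorter (shotgun) reads are placed semi-globally with edlib, trying
    both orientations.  Returns (start, alignment, is_reverse), or None
    when the read is unalignable or tied between two placements.
    """
    if len(seq) >= 0.8 * len(backbone):
        fwd = align_banded(seq, backbone)
        rev = align_banded(reverse_complement(seq), backbone)
        if fwd.score == rev.score:
            return None
        best_aln, is_rev = (fwd, False) if fwd.score > rev.score else (rev, True)
        if best_aln.identity < 0.5:
            return None
        return 0, best_aln, is_rev
    best = None
    for is_rev, s in ((False, seq), (True, reverse_complement(seq))):
        res = edlib.align(s, backbone, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        if best is None or res["editDistance"] < best[0]:
            best = (res["editDistance"], res, s, is_rev, len(res["locations"]))
        elif res["editDistance"] == best[0]:
            best = (best[0], best[1], best[2], best[3], best[4] + len(res["locations"]))
    if best is None:
        return None
    dist, res, s, is_rev, n_locs = best
    if dist > 0.3 * len(seq):
        return None  # unalignable
    locs = res["locations"]
    if n_locs > 1 and not all(l == locs[0] for l in locs):
        return None  # ambiguous placement: drop rather than double-count
    start, end = locs[0]
    target = backbone[start:end + 1]
    aln = _cigar_to_alignment(s, target, res["cigar"])
    return start, aln, is_rev


def _cigar_to_alignment(query: str, target: str, cigar: str) -> Alignment:
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            # edlib CIGAR: I consumes query, D consumes target — same as ours
            ops.append((ch, int(num)))
            num = ""
    return Alignment(query, target, ops)


def _accumulate(
    pileup: Pileup, start: int, aln: Alignment
) -> tuple[dict[int, str], dict[int, str]]:
    obs: dict[int, str] = {}
    ins_obs: dict[int, str] = {}
    pending_ins = ""

    def flush(ref_pos: int) -> None:
        nonlocal pending_ins
        if pending_ins:
            pileup.insertions.setdefault(ref_pos, []).append(pending_ins)
            ins_obs[ref_pos] = ins_obs.get(ref_pos, "") + pending_ins
            pending_ins = ""

    for op, qpos, tpos in aln.walk():
        if op in "=X":
            ref_pos = start + tpos
            flush(ref_pos)
            base = aln.query[qpos]
            if base in _BASE_IDX:
                pileup.counts[ref_pos, _BASE_IDX[base]] += 1
                obs[ref_pos] = base
        elif op == "D":
            ref_pos = start + tpos
            flush(ref_pos)
            pileup.counts[ref_pos, DEL] += 1
            obs[ref_pos] = "-"
        else:  # insertion relative to backbone
            pending_ins += aln.query[qpos]
    flush(start + len(aln.target))
    return obs, ins_obs


def build_pileup(reads, backbone: str) -> Pileup:
    """Place reads on a backbone and accumulate per-position counts.

    ``reads`` is a :class:`~dualcons.simulate.PairedReadSet`, an iterable
    of FastqRead, or an iterable of raw sequences.  Mates of a pair share
    one observation record so fragment-level phasing can use them jointly.
    """
    pileup = Pileup(
        backbone=backbone,
        counts=np.zeros((len(backbone), 5), dtype=np.int64),
    )
    if isinstance(reads, PairedReadSet):
        groups = [[p[0].sequence, p[1].sequence] for p in reads.pairs]
    else:
        groups = [[getattr(r, "sequence", r)] for r in reads]
    for group in groups:
        obs: dict[int, str] = {}
        ins: dict[int, str] = {}
        for seq in group:
            placed = _place_read(seq, backbone)
            if placed is None:
                pileup.n_unplaced += 1
                continue
            start, aln, _ = placed
            o, i = _accumulate(pileup, start, aln)
            obs.update(o)
            ins.update(i)
        if obs:
            pileup.read_observations.append(obs)
            pileup.read_insertions.append(ins)
    return pileup


@dataclass
class ConsensusTrack:
    """Per-position consensus calls over a backbone.

    ``status`` holds ``hom`` / ``het`` / ``low_coverage`` per position;
    ``alleles`` holds the called base(s) — one for hom, two for het.
    ``sequence`` is the majority-haplotype string (het positions take the
    majority base), with deletions removed and majority insertions
    spliced in.
    """

    backbone: str
    status: list[str]
    alleles: list[tuple[str, ...]]
    sequence: str
    het_positions: list[int]
    phase_blocks: list[list[int]] = field(default_factory=list)
    homopolymer_ambiguous: list[int] = field(default_factory=list)

    @property
    def phasing_defined(self) -> bool:
        """Whole-gene phasing is defined when all hets sit in one block."""
        return len(self.phase_blocks) <= 1

    def to_json(self) -> str:
        d = {
            "backbone": self.backbone,
            "status": self.status,
            "alleles": [list(a) for a in self.alleles],
            "sequence": self.sequence,
            "het_positions": self.het_positions,
            "phase_blocks": self.phase_blocks,
            "homopolymer_ambiguous": self.homopolymer_ambiguous,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ConsensusTrack":
        d = json.loads(text)
        return cls(
            backbone=d["backbone"],
            status=d["status"],
            alleles=[tuple(a) for a in d["alleles"]],
            sequence=d["sequence"],
            het_positions=d["het_positions"],
            phase_blocks=[list(b) for b in d["phase_blocks"]],
            homopolymer_ambiguous=d["homopolymer_ambiguous"],
        )


def call_consensus(
    pileup: Pileup,
    min_coverage: int = 10,
    het_band: tuple[float, float] = (0.25, 0.75),
) -> ConsensusTrack:
    """Call a per-position consensus with heterozygote detection.

    A position is heterozygous when the minor of the top two symbols
    (bases or deletion) carries a fraction of coverage inside
    ``het_band``; under ``min_coverage`` it is flagged low_coverage and
    the backbone base is retained.
    """
    lo, hi = het_band
    if not 0 <= lo < hi <= 1:
        raise ValueError(f"invalid het band {het_band}")
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    L = len(pileup.backbone)
    status: list[str] = []
    alleles: list[tuple[str, ...]] = []
    seq_parts: list[str] = []
    hets: list[int] = []
    symbols = "ACGT-"
    for i in range(L):
        row = pileup.counts[i]
        cov = int(row.sum())
        ins_here = pileup.insertions.get(i, [])
        if cov < min_coverage:
            status.append("low_coverage")
            alleles.append((pileup.backbone[i],))
            seq_parts.append(pileup.backbone[i])
            continue
        order = np.argsort(row, kind="stable")[::-1]
        top, second = int(order[0]), int(order[1])
        frac_second = row[second] / cov
        # majority insertion before this position enters the sequence
        if len(ins_here) * 2 > cov:
            from collections import Counter

            ins_seq = Counter(ins_here).most_common(1)[0][0]
            seq_parts.append(ins_seq)
        if lo <= frac_second <= hi:
            status.append("het")
            pair = tuple(sorted(symbols[b] for b in (top, second)))
            alleles.append(pair)
            hets.append(i)
            maj = symbols[top]
            if maj != "-":
                seq_parts.append(maj)
        else:
            status.append("hom")
            maj = symbols[top]
            alleles.append((maj,))
            if maj != "-":
                seq_parts.append(maj)
    track = ConsensusTrack(
        backbone=pileup.backbone,
        status=status,
        alleles=alleles,
        sequence="".join(seq_parts),
        het_positions=hets,
    )
    return track


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def phase_hets(track: ConsensusTrack, pileup: Pileup) -> list[list[int]]:
    """Group het positions into phase blocks by fragment co-coverage.

    Two hets are linked when at least one fragment (read pair counted as
    one observation) covers both with a consistent pair of het alleles;
    blocks are the transitive closure of that relation.  More than one
    block means whole-gene phasing is undefined.  The result is stored on
    the track and returned.
    """
    hets = track.het_positions
    if not hets:
        track.phase_blocks = []
        return []
    het_alleles = {p: set(track.alleles[p]) for p in hets}
    uf = _UnionFind(hets)
    for obs in pileup.read_observations:
        covered = [p for p in hets if p in obs and obs[p] in het_alleles[p]]
        for a, b in zip(covered, covered[1:]):
            uf.union(a, b)
    blocks: dict[int, list[int]] = {}
    for p in hets:
        blocks.setdefault(uf.find(p), []).append(p)
    out = [sorted(v) for _, v in sorted(blocks.items())]
    track.phase_blocks = out
    return out
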