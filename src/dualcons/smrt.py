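"""Long-read stage: informative-position detection, 2-way read clustering
by allele, and per-allele preliminary consensus with homopolymer-ambiguity
flagging.

Long single-molecule reads span the whole amplicon, so a heterozygous
sample can be separated into its two alleles by clustering reads on the
bases they carry at informative (putatively heterozygous) positions.
Per-allele majority consensus is then accurate everywhere except in
homopolymer runs, where the indel-heavy error process can leave the run
length genuinely undecidable from long reads alone; such loci are flagged
ambiguous and deferred to short-read polishing.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .sbs import Pileup, build_pileup
from .seqcore import homopolymer_runs

__all__ = [
    "ClusterAssignment",
    "AlleleConsensus",
    "call_informative_positions",
    "cluster_long_reads",
    "build_allele_consensus",
]

_SYMBOLS = "ACGT-"
UNASSIGNED = 0


@dataclass
class ClusterAssignment:
    """Per-read allele assignment from informative-position signatures.

    ``labels[i]`` is 1, 2 or 0 (unassigned) for read i; ``signatures[i]``
    is the read's base vector over the informative positions ('.' where
    the read shows neither candidate base).  ``consistency`` is the mean
    agreement of assigned reads with their cluster centroid, in [0, 1].
    """

    labels: tuple[int, ...]
    signatures: tuple[str, ...]
    informative_positions: tuple[int, ...]
    consistency: float
    homozygous: bool = False

    def cluster_indices(self, label: int) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l == label]


def call_informative_positions(
    pileup: Pileup,
    freq_window: tuple[float, float] = (0.30, 0.70),
    min_coverage: int = 10,
) -> list[int]:
    """Positions whose second-most-frequent symbol sits in ``freq_window``.

    Candidates whose minor symbol is a deletion inside a homopolymer run
    of the backbone are excluded: there the minor fraction is dominated
    by platform indel error, and run lengths are handled by the
    homopolymer mode caller downstream.
    """
    lo, hi = freq_window
    if not 0 <= lo <= hi <= 1:
        raise ValueError(f"invalid frequency window {freq_window}")
    in_run = np.zeros(len(pileup.backbone), dtype=bool)
    for s, e, _ in homopolymer_runs(pileup.backbone):
        in_run[s:e] = True
    out = []
    for i in range(len(pileup.backbone)):
        row = pileup.counts[i]
        cov = int(row.sum())
        if cov < min_coverage:
            continue
        order = np.argsort(row, kind="stable")[::-1]
        second = int(order[1])
        if lo <= row[second] / cov <= hi:
            if _SYMBOLS[second] == "-" and in_run[i]:
                continue
            out.append(i)
    return out


def cluster_long_reads(
    pileup: Pileup,
    informative_positions: list[int],
    max_mismatch_frac: float = 0.40,
) -> ClusterAssignment:
    """Separate long reads into the two alleles of a heterozygous sample.

    Each read is reduced to its symbols at the informative positions.  At
    every position the two candidate alleles are the two most frequent
    symbols; columns are phase-oriented against the first informative
    position by majority co-occurrence, after which the two cluster
    centroids are the all-first and all-second vectors.  A read joins the
    centroid it agrees with at the majority of its covered positions;
    reads disagreeing with their best centroid at more than
    ``max_mismatch_frac`` of positions (or tied) stay unassigned.

    With no informative positions the sample is treated as homozygous and
    every read falls into a single cluster.
    """
    n_reads = len(pileup.read_observations)
    if not informative_positions:
        return ClusterAssignment(
            labels=tuple([1] * n_reads),
            signatures=tuple([""] * n_reads),
            informative_positions=(),
            consistency=1.0,
            homozygous=True,
        )
    positions = list(informative_positions)
    # candidate symbol pair per position
    cands = []
    for p in positions:
        order = np.argsort(pileup.counts[p], kind="stable")[::-1]
        cands.append((_SYMBOLS[int(order[0])], _SYMBOLS[int(order[1])]))
    # read x position matrix: 0 = first candidate, 1 = second, -1 = neither
    mat = np.full((n_reads, len(positions)), -1, dtype=np.int8)
    sigs = []
    for i, obs in enumerate(pileup.read_observations):
        sig = []
        for k, p in enumerate(positions):
            sym = obs.get(p)
            if sym == cands[k][0]:
                mat[i, k] = 0
                sig.append(sym)
            elif sym == cands[k][1]:
                mat[i, k] = 1
                sig.append(sym)
            else:
                sig.append(".")
        sigs.append("".join(sig))
    # orient columns relative to column 0 by majority co-occurrence
    flip = np.zeros(len(positions), dtype=bool)
    for k in range(1, len(positions)):
        both = (mat[:, 0] >= 0) & (mat[:, k] >= 0)
        if not both.any():
            continue
        same = int((mat[both, 0] == mat[both, k]).sum())
        diff = int(both.sum()) - same
        flip[k] = diff > same
    oriented = mat.copy()
    for k in np.nonzero(flip)[0]:
        col = oriented[:, k]
        col[col >= 0] = 1 - col[col >= 0]
    labels = []
    agreements = []
    for i in range(n_reads):
        defined = oriented[i] >= 0
        n_def = int(defined.sum())
        if n_def == 0:
            labels.append(UNASSIGNED)
            continue
        ones = int(oriented[i, defined].sum())
        frac_one = ones / n_def
        mism = min(frac_one, 1 - frac_one)
        if mism > max_mismatch_frac or frac_one == 0.5:
            labels.append(UNASSIGNED)
            continue
        labels.append(2 if frac_one > 0.5 else 1)
        agreements.append(1 - mism)
    consistency = float(np.mean(agreements)) if agreements else 0.0
    return ClusterAssignment(
        labels=tuple(labels),
        signatures=tuple(sigs),
        informative_positions=tuple(positions),
        consistency=consistency,
        homozygous=False,
    )


@dataclass
class AlleleConsensus:
    """Preliminary per-allele consensus with homopolymer-ambiguity flags.

    ``ambiguous_runs`` lists backbone homopolymer runs (start, end, base)
    whose modal read-supported length carried less than the support
    threshold (or was tied) — the loci long reads cannot decide alone.
    """

    sequence: str
    backbone: str
    n_reads: int
    ambiguous_runs: list[tuple[int, int, str]] = field(default_factory=list)
    run_length_calls: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "backbone": self.backbone,
            "n_reads": self.n_reads,
            "ambiguous_runs": [list(r) for r in self.ambiguous_runs],
            "run_length_calls": {str(k): v for k, v in self.run_length_calls.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlleleConsensus":
        return cls(
            sequence=d["sequence"],
            backbone=d["backbone"],
            n_reads=d["n_reads"],
            ambiguous_runs=[tuple(r) for r in d["ambiguous_runs"]],
            run_length_calls={int(k): v for k, v in d["run_length_calls"].items()},
        )


def _observed_run_length(obs: dict[int, str], ins: dict[int, str],
                         start: int, end: int, base: str) -> int | None:
    """Run length a single read supports at backbone run [start, end).

    None when the read does not span the run (needs anchor columns on
    both sides)."""
    if (start - 1) not in obs or end not in obs:
        return None
    length = sum(1 for p in range(start, end) if obs.get(p) == base)
    for p in range(start, end + 1):
        inserted = ins.get(p, "")
        length += sum(1 for ch in inserted if ch == base)
    return length


def build_allele_consensus(
    pileup: Pileup,
    read_indices: list[int] | None = None,
    min_coverage: int = 5,
    run_support: float = 0.60,
) -> AlleleConsensus:
    """Majority consensus over one read cluster, with homopolymer run
    lengths called as the mode over spanning reads.

    A run whose modal length has support below ``run_support`` (or ties
    with another length) is flagged ambiguous; the preliminary call still
    uses the (smallest) modal length, but downstream polishing must
    confirm it.
    """
    backbone = pileup.backbone
    if read_indices is None:
        read_indices = list(range(len(pileup.read_observations)))
    if not read_indices:
        raise ValueError("cluster is empty")
    obs_list = [pileup.read_observations[i] for i in read_indices]
    ins_list = [pileup.read_insertions[i] for i in read_indices]
    L = len(backbone)
    counts = np.zeros((L, 5), dtype=np.int64)
    sym_idx = {s: i for i, s in enumerate(_SYMBOLS)}
    for obs in obs_list:
        for p, sym in obs.items():
            counts[p, sym_idx[sym]] += 1
    ins_counter: dict[int, Counter] = {}
    for ins in ins_list:
        for p, seq in ins.items():
            ins_counter.setdefault(p, Counter())[seq] += 1
    runs = homopolymer_runs(backbone)
    in_run = np.zeros(L, dtype=bool)
    for s, e, _ in runs:
        in_run[s:e] = True
    # column-majority call outside homopolymer runs
    calls: list[str] = []
    for p in range(L):
        if in_run[p]:
            calls.append("")  # filled from run-length mode below
            continue
        cov = int(counts[p].sum())
        ins_here = ins_counter.get(p, Counter())
        prefix = ""
        if ins_here and sum(ins_here.values()) * 2 > max(cov, 1):
            prefix = ins_here.most_common(1)[0][0]
        if cov < min_coverage:
            calls.append(prefix + backbone[p])
            continue
        best = int(np.argsort(counts[p], kind="stable")[::-1][0])
        sym = _SYMBOLS[best]
        calls.append(prefix + ("" if sym == "-" else sym))
    # homopolymer runs: modal length over spanning reads
    ambiguous = []
    run_calls = {}
    cons = AlleleConsensus("", backbone, len(read_indices))
    for s, e, base in runs:
        lengths = []
        for obs, ins in zip(obs_list, ins_list):
            l = _observed_run_length(obs, ins, s, e, base)
            if l is not None:
                lengths.append(l)
        if not lengths:
            modal, support, tied = e - s, 0.0, False
        else:
            hist = Counter(lengths)
            top = hist.most_common()
            modal, top_n = top[0]
            tied = len(top) > 1 and top[1][1] == top_n
            if tied:
                modal = min(l for l, n in top if n == top_n)
            support = top_n / len(lengths)
        run_calls[s] = {"length": int(modal), "support": round(support, 4),
                        "n_spanning": len(lengths)}
        if tied or support < run_support:
            ambiguous.append((s, e, base))
        calls[s] = base * modal  # whole run emitted at its first column
    cons.sequence = "".join(calls)
    cons.ambiguous_runs = ambiguous
    cons.run_length_calls = run_calls
    return cons
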