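"""Rule engine for the dual redundant strategy, plus short-read polishing
of long-read haplotype consensus.

The two sequencing routes are analysed independently; whenever their
consensus sequences disagree, each disagreement is classified against the
closest reference allele and a workflow action is derived:

* a long-read-only deviation from the reference is treated as a platform
  sequencing error — the short-read consensus is submitted (rule 1);
* a short-read-only deviation is unexpected (short-read consensus quality
  is extremely high) — the analysis is repeated (rule 2);
* when the whole-gene short-read sequence is not phase-defined and the
  long-read data suffers indel trouble, the cluster-then-polish procedure
  is run to derive an accurate phased consensus (rule 3).

When rules could fire together the engine applies 2 over 3 over 1:
repeating the analysis is the safest action, and polishing dominates
plain submission.  Full concordance is submitted directly.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .sbs import ConsensusTrack, Pileup, build_pileup
from .seqcore import Alignment, align_edit, homopolymer_runs
from .simulate import PairedReadSet
from .smrt import AlleleConsensus

__all__ = [
    "ConflictCategory",
    "Conflict",
    "Action",
    "Decision",
    "compare_tracks",
    "decide",
    "polish_consensus",
    "audit_positions",
]


class ConflictCategory(str, Enum):
    SMRT_ONLY_DEVIATION = "SMRT_only_deviation"
    SBS_ONLY_DEVIATION = "SBS_only_deviation"
    CONCORDANT_DEVIATION = "concordant_deviation"
    HOMOPOLYMER_INDEL = "homopolymer_indel"
    PHASE_GAP = "phase_gap"


@dataclass(frozen=True)
class Conflict:
    """One classified disagreement at a reference position.

    ``sbs_call`` and ``smrt_call`` are the allele sets each route
    supports at the position ('-' marks a deletion, lower-case prefix
    'i:' an insertion string before the position).
    """

    position: int
    reference: str
    sbs_call: tuple[str, ...]
    smrt_call: tuple[str, ...]
    category: ConflictCategory

    def to_dict(self) -> dict:
        return {
            "position": self.position,
            "reference": self.reference,
            "sbs_call": list(self.sbs_call),
            "smrt_call": list(self.smrt_call),
            "category": self.category.value,
        }


class Action(str, Enum):
    SUBMIT_SBS = "SUBMIT_SBS"
    REPEAT_ANALYSIS = "REPEAT_ANALYSIS"
    RUN_DR2S = "RUN_DR2S"
    SUBMIT_CONCORDANT = "SUBMIT_CONCORDANT"


#: rule id attached to each conflict category when the decision fires
_RULE_IDS = {
    ConflictCategory.SMRT_ONLY_DEVIATION: "rule1",
    ConflictCategory.HOMOPOLYMER_INDEL: "rule1/rule3",
    ConflictCategory.SBS_ONLY_DEVIATION: "rule2",
    ConflictCategory.PHASE_GAP: "rule3",
    ConflictCategory.CONCORDANT_DEVIATION: "concordant",
}


@dataclass
class Decision:
    """Outcome of the rule engine for one sample."""

    action: Action
    justification: list[dict] = field(default_factory=list)
    final_sequences: tuple[str, ...] | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "action": self.action.value,
                "justification": self.justification,
                "final_sequences": list(self.final_sequences)
                if self.final_sequences
                else None,
            },
            indent=1,
        )


def _calls_per_reference_position(
    consensus: str, reference: str
) -> tuple[list[str], dict[int, str]]:
    """Project a consensus onto reference coordinates.

    Returns per-position symbols ('-' for deleted reference bases) and
    insertion strings keyed by the reference position they precede.
    """
    aln = align_edit(consensus, reference)
    calls = [""] * len(reference)
    insertions: dict[int, str] = {}
    pending = ""
    for op, qpos, tpos in aln.walk():
        if op in "=X":
            if pending:
                insertions[tpos] = insertions.get(tpos, "") + pending
                pending = ""
            calls[tpos] = consensus[qpos]
        elif op == "D":
            if pending:
                insertions[tpos] = insertions.get(tpos, "") + pending
                pending = ""
            calls[tpos] = "-"
        else:
            pending += consensus[qpos]
    if pending:
        insertions[len(reference)] = insertions.get(len(reference), "") + pending
    return calls, insertions


def _sbs_run_lengths(track: ConsensusTrack, s: int, e: int, base: str) -> set[int]:
    """Run lengths the short-read track supports over reference run
    [s, e) of ``base``.

    A heterozygous base/deletion column splits the supported lengths
    (one allele keeps the base, the other deletes it)."""
    full = 0
    het_del = 0
    for pos in range(s, e):
        alleles = set(track.alleles[pos])
        if base in alleles:
            full += 1
            if "-" in alleles:
                het_del += 1
    lengths = {full}
    if het_del:
        lengths.add(full - het_del)
    return lengths


def _classify_run(
    start: int,
    base: str,
    ref_len: int,
    sbs_lengths: set[int],
    smrt_lengths: set[int],
    smrt_flagged: bool,
) -> Conflict | None:
    """Category for one homopolymer run from the length sets of the two
    routes.

    An ambiguity flag on either long-read haplotype marks the run as
    long-read indel trouble regardless of the modal lengths — that is
    the state the cluster-then-polish procedure exists for."""
    sbs_dev = sbs_lengths != {ref_len}
    smrt_dev = smrt_lengths != {ref_len} or smrt_flagged
    if not sbs_dev and not smrt_dev:
        return None
    fmt_ref = base * ref_len
    sbs_call = tuple(f"{base}x{n}" for n in sorted(sbs_lengths))
    smrt_call = tuple(f"{base}x{n}" for n in sorted(smrt_lengths))
    if smrt_flagged:
        cat = ConflictCategory.HOMOPOLYMER_INDEL
    elif sbs_dev and smrt_dev and sbs_lengths == smrt_lengths:
        cat = ConflictCategory.CONCORDANT_DEVIATION
    elif smrt_dev and not sbs_dev:
        cat = ConflictCategory.HOMOPOLYMER_INDEL
    else:
        cat = ConflictCategory.SBS_ONLY_DEVIATION
    return Conflict(start, fmt_ref, sbs_call, smrt_call, cat)


def compare_tracks(
    sbs_track: ConsensusTrack,
    smrt_pair: tuple[AlleleConsensus, ...],
    reference: str,
) -> list[Conflict]:
    """Classify every disagreement between the short-read track, the
    long-read haplotype pair, and the closest reference.

    All calls are projected onto reference coordinates.  At each
    position the short-read call set (both alleles at a het) and the
    long-read call set (the two haplotype consensus bases) are compared
    with the reference base:

    * both deviate identically  -> concordant_deviation (a real variant)
    * only long reads deviate   -> homopolymer_indel when the deviation
      is an indel inside a reference homopolymer run, else
      SMRT_only_deviation
    * the short-read call deviates and long reads do not confirm it
      (including discordant double deviations) -> SBS_only_deviation

    Inside a reference homopolymer run the two routes may place an
    equivalent indel at different columns (gap placement in a run is
    arbitrary), so runs are compared at run level — the set of run
    lengths each route supports — rather than column by column.

    A phase_gap conflict is appended for every gap between consecutive
    short-read phase blocks (whole-gene phasing undefined).
    """
    if sbs_track.backbone != reference:
        raise ValueError("SBS track must be called against the closest reference")
    runs = homopolymer_runs(reference)
    in_run = np.zeros(len(reference) + 1, dtype=bool)
    for s, e, _ in runs:
        in_run[max(0, s - 1):e + 1] = True

    smrt_calls = []
    smrt_ins = []
    for hap in smrt_pair:
        c, i = _calls_per_reference_position(hap.sequence, reference)
        smrt_calls.append(c)
        smrt_ins.append(i)

    conflicts: list[Conflict] = []
    # column-level comparison outside homopolymer runs
    for pos in range(len(reference)):
        if in_run[pos]:
            continue
        ref_base = reference[pos]
        sbs_set = frozenset(sbs_track.alleles[pos])
        smrt_set = frozenset(c[pos] for c in smrt_calls if c[pos])
        if not smrt_set:
            smrt_set = frozenset({ref_base})
        sbs_dev = sbs_set != {ref_base}
        smrt_dev = smrt_set != {ref_base}
        if not sbs_dev and not smrt_dev:
            continue
        if sbs_dev and smrt_dev and sbs_set == smrt_set:
            cat = ConflictCategory.CONCORDANT_DEVIATION
        elif smrt_dev and not sbs_dev:
            cat = ConflictCategory.SMRT_ONLY_DEVIATION
        else:
            cat = ConflictCategory.SBS_ONLY_DEVIATION
        conflicts.append(
            Conflict(pos, ref_base, tuple(sorted(sbs_set)),
                     tuple(sorted(smrt_set)), cat)
        )
    # run-level comparison: supported run lengths per route
    for s, e, base in runs:
        ref_len = e - s
        sbs_lengths = _sbs_run_lengths(sbs_track, s, e, base)
        smrt_lengths = set()
        flagged = False
        for hap in smrt_pair:
            call = hap.run_length_calls.get(s)
            smrt_lengths.add(call["length"] if call else ref_len)
            flagged = flagged or (s, e, base) in hap.ambiguous_runs
        conflict = _classify_run(
            s, base, ref_len, sbs_lengths, smrt_lengths, flagged
        )
        if conflict is not None:
            conflicts.append(conflict)
    # insertion-only disagreements outside runs
    all_ins_pos = set()
    for i in smrt_ins:
        all_ins_pos.update(i)
    for pos in sorted(all_ins_pos):
        if in_run[min(pos, len(reference))]:
            continue
        ins_set = frozenset(i.get(pos, "") for i in smrt_ins)
        if ins_set == {""}:
            continue
        conflicts.append(
            Conflict(pos, "", ("",), tuple(sorted(ins_set)),
                     ConflictCategory.SMRT_ONLY_DEVIATION)
        )
    # phase gaps between consecutive short-read phase blocks
    blocks = sbs_track.phase_blocks
    for left, right in zip(blocks, blocks[1:]):
        conflicts.append(
            Conflict(
                position=right[0],
                reference=reference[right[0]],
                sbs_call=("?",),
                smrt_call=("?",),
                category=ConflictCategory.PHASE_GAP,
            )
        )
    return sorted(conflicts, key=lambda c: (c.position, c.category.value))


def decide(
    conflicts: list[Conflict],
    sbs_phasing_defined: bool,
    precedence: tuple[Action, ...] = (
        Action.REPEAT_ANALYSIS,
        Action.RUN_DR2S,
        Action.SUBMIT_SBS,
    ),
) -> Decision:
    """Map a conflict list to a workflow action (total, deterministic).

    Default precedence: any short-read-only deviation forces a repeat;
    otherwise undefined phasing together with indel/phase trouble runs
    the cluster-then-polish procedure; otherwise long-read-only
    deviations are dismissed as platform error and the short-read
    consensus is submitted; with no conflicts the concordant sequence is
    submitted.
    """
    cats = {c.category for c in conflicts}
    justification = [
        {"position": c.position, "category": c.category.value,
         "rule": _RULE_IDS[c.category]}
        for c in conflicts
    ]
    triggers = {
        Action.REPEAT_ANALYSIS: ConflictCategory.SBS_ONLY_DEVIATION in cats,
        Action.RUN_DR2S: (not sbs_phasing_defined)
        and (
            ConflictCategory.HOMOPOLYMER_INDEL in cats
            or ConflictCategory.PHASE_GAP in cats
        ),
        Action.SUBMIT_SBS: ConflictCategory.SMRT_ONLY_DEVIATION in cats
        or ConflictCategory.HOMOPOLYMER_INDEL in cats,
    }
    for action in precedence:
        if triggers[action]:
            return Decision(action=action, justification=justification)
    return Decision(action=Action.SUBMIT_CONCORDANT, justification=justification)


def polish_consensus(
    preliminary_pair: tuple[AlleleConsensus, AlleleConsensus],
    short_reads: PairedReadSet,
    min_coverage: int = 5,
) -> tuple[str, str]:
    """Correct two preliminary long-read haplotype consensus sequences
    with short reads (the polishing half of the cluster-then-polish
    procedure).

    Each short-read fragment is mapped to the haplotype it matches
    better.  Fragments matching both haplotypes equally span a region
    where the two preliminary sequences are indistinguishable; they are
    kept as shared evidence.  Per haplotype, a pileup of its specific
    (better-matching) fragments recalls every position where the
    short-read majority contradicts the preliminary call — in particular
    the flagged ambiguous homopolymer run lengths; where specific
    coverage is insufficient (for example runs near the amplicon ends,
    out of linkage range of any het site), the shared evidence is pooled
    in, which is unbiased wherever the alleles truly agree.  Positions
    where short reads agree with the preliminary call are never edited.

    The assignment distance is computed against run-length-collapsed
    copies of the haplotypes: homopolymer run lengths in a preliminary
    long-read consensus are exactly what polishing must still correct,
    so letting them attract or repel reads would route the corrective
    evidence to the wrong haplotype.  Substitution differences (the
    phased het sites) are untouched by the collapse and decide the
    assignment.
    """
    import re

    import edlib

    hap_seqs = [h.sequence for h in preliminary_pair]
    # runs of >= 3 collapse to 2: any run-length difference of the
    # error-prone classes (2 vs 3, and everything longer) becomes
    # invisible to the assignment, while isolated bases and true
    # substitution hets keep their full discriminating power
    masked = [re.sub(r"(.)\1{2,}", lambda m: m.group(1) * 2, h) for h in hap_seqs]
    assigned: list[list] = [[], []]
    tied: list = []
    for pair in short_reads.pairs:
        dists = []
        for hap in masked:
            d = 0
            for mate in pair:
                best = None
                from .seqcore import reverse_complement

                for s in (mate.sequence, reverse_complement(mate.sequence)):
                    r = edlib.align(s, hap, mode="HW", task="distance")
                    dd = r["editDistance"]
                    if dd >= 0 and (best is None or dd < best):
                        best = dd
                d += best if best is not None else len(mate.sequence)
            dists.append(d)
        if dists[0] == dists[1]:
            tied.append(pair)
        else:
            assigned[0 if dists[0] < dists[1] else 1].append(pair)
    shared_reads = [m for p in tied for m in p]
    polished = []
    for hap, pairs in zip(hap_seqs, assigned):
        specific = build_pileup([m for p in pairs for m in p], hap)
        shared = build_pileup(shared_reads, hap)
        polished.append(_majority_rewrite(specific, shared, min_coverage))
    return tuple(polished)


def _majority_rewrite(
    specific: Pileup, shared: Pileup, min_coverage: int
) -> str:
    """Rewrite the backbone wherever the short-read majority contradicts it.

    Specific (haplotype-assigned) evidence decides a position whenever it
    reaches ``min_coverage``; otherwise the shared evidence is pooled in.
    """
    out = []
    L = len(specific.backbone)
    symbols = "ACGT-"
    for p in range(L):
        cov_sp = int(specific.counts[p].sum())
        if cov_sp >= min_coverage:
            counts = specific.counts[p]
            ins_here = specific.insertions.get(p, [])
            cov = cov_sp
        else:
            counts = specific.counts[p] + shared.counts[p]
            ins_here = specific.insertions.get(p, []) + shared.insertions.get(p, [])
            cov = int(counts.sum())
        if ins_here and len(ins_here) * 2 > max(cov, 1):
            out.append(Counter(ins_here).most_common(1)[0][0])
        if cov < min_coverage:
            out.append(specific.backbone[p])
            continue
        best = int(np.argsort(counts, kind="stable")[::-1][0])
        sym = symbols[best]
        if sym != "-":
            out.append(sym)
    tail = specific.insertions.get(L, []) + shared.insertions.get(L, [])
    tail_cov = int((specific.counts[L - 1] + shared.counts[L - 1]).sum())
    if tail and len(tail) * 2 > max(tail_cov, 1):
        out.append(Counter(tail).most_common(1)[0][0])
    return "".join(out)


def audit_positions(consensus_length: int, n_true_differences: int) -> tuple[int, int]:
    """Split a consensus into masking-prone and artifact-prone positions.

    For a novel allele with ``d`` true differences from its closest
    reference over a consensus of length ``L``, a sequencing error can
    mask a true difference at exactly the ``d`` variant positions, while
    at the remaining ``L - d`` positions it can only introduce an
    artificial difference.  The asymmetry (d << L) is why a deviation
    seen by a single platform is overwhelmingly likely to be an artifact.
    """
    if not 0 <= n_true_differences <= consensus_length:
        raise ValueError("need 0 <= d <= L")
    return n_true_differences, consensus_length - n_true_differences
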