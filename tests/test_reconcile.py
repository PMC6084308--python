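"""Rule engine: conflict classification, workflow decision, polishing,
and the masking/artifact position audit."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dualcons import (
    Action,
    ConflictCategory,
    audit_positions,
    compare_tracks,
    decide,
    polish_consensus,
)
from dualcons.reconcile import Conflict, _classify_run
from dualcons.sbs import ConsensusTrack
from dualcons.smrt import AlleleConsensus

from _oracles import classify_conflict_case, rule_engine_oracle

CATEGORIES = [c.value for c in ConflictCategory]


def _conflict(cat: str, pos: int = 0) -> Conflict:
    return Conflict(pos, "A", ("A",), ("A",), ConflictCategory(cat))


def _track(backbone: str, sequence: str | None = None, het=None, blocks=None):
    het = het or {}
    status = []
    alleles = []
    for i, b in enumerate(backbone):
        if i in het:
            status.append("het")
            alleles.append(tuple(sorted(het[i])))
        else:
            status.append("hom")
            alleles.append((b,))
    track = ConsensusTrack(
        backbone=backbone,
        status=status,
        alleles=alleles,
        sequence=sequence if sequence is not None else backbone,
        het_positions=sorted(het),
        phase_blocks=blocks if blocks is not None else ([sorted(het)] if het else []),
    )
    return track


def _smrt(backbone: str, sequence: str | None = None, run_calls=None, ambiguous=None):
    return AlleleConsensus(
        sequence=sequence if sequence is not None else backbone,
        backbone=backbone,
        n_reads=10,
        ambiguous_runs=ambiguous or [],
        run_length_calls=run_calls or {},
    )


class TestCompareTracks:
    def test_identical_inputs_give_empty_list(self):
        ref = "ACGTACGTACGTAAAACGT"
        track = _track(ref)
        pair = (_smrt(ref), _smrt(ref))
        assert compare_tracks(track, pair, ref) == []

    def test_smrt_only_polyA_deletion_is_homopolymer_indel(self):
        """Long reads show a deletion inside a poly-A run while short
        reads match the reference: one conflict, homopolymer indel."""
        ref = "ACGTC" + "A" * 8 + "GTCGT"
        track = _track(ref)
        hap = _smrt(
            ref,
            sequence=ref.replace("A" * 8, "A" * 7),
            run_calls={5: {"length": 7, "support": 0.5, "n_spanning": 10}},
            ambiguous=[(5, 13, "A")],
        )
        conflicts = compare_tracks(track, (hap, _smrt(ref)), ref)
        assert len(conflicts) == 1
        assert conflicts[0].category is ConflictCategory.HOMOPOLYMER_INDEL
        assert conflicts[0].position == 5

    def test_sbs_only_snv_detected(self):
        ref = "ACGTACGTCGTCGT"
        novel = "ACGTACCTCGTCGT"
        track = _track(ref, sequence=novel)
        track.alleles[6] = ("C",)
        pair = (_smrt(ref), _smrt(ref))
        conflicts = compare_tracks(track, pair, ref)
        assert [c.category for c in conflicts] == [ConflictCategory.SBS_ONLY_DEVIATION]

    def test_concordant_deviation_is_a_real_variant(self):
        ref = "ACGTACGTCGTCGT"
        novel = "ACGTACCTCGTCGT"
        track = _track(ref, sequence=novel)
        track.alleles[6] = ("C",)
        pair = (_smrt(ref, sequence=novel), _smrt(ref, sequence=novel))
        conflicts = compare_tracks(track, pair, ref)
        assert [c.category for c in conflicts] == [
            ConflictCategory.CONCORDANT_DEVIATION
        ]

    def test_phase_gap_emitted_per_block_boundary(self):
        ref = "ACGTACGTCGTCGTACGTACGT"
        track = _track(
            ref,
            het={2: {"G", "T"}, 18: {"A", "C"}},
            blocks=[[2], [18]],
        )
        pair = (_smrt(ref), _smrt(ref))
        cats = [c.category for c in compare_tracks(track, pair, ref)]
        assert cats.count(ConflictCategory.PHASE_GAP) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_column_categories_match_case_oracle(self, seed):
        """Randomized run-free toy triples classify identically to an
        exhaustive case analysis."""
        rng = np.random.default_rng(seed)
        ref = "ACGT" * 13  # period 4: no homopolymer runs
        ref = ref[:50]
        novel = list(ref)
        for p in (5, 20, 35):  # spaced edits cannot create a run >= 4
            novel[p] = "ACGT"[("ACGT".index(ref[p]) + int(rng.integers(1, 4))) % 4]
        sbs_seq = "".join(novel) if rng.random() < 0.5 else ref
        smrt_seq = "".join(novel) if rng.random() < 0.5 else ref
        track = _track(ref, sequence=sbs_seq)
        for i, b in enumerate(sbs_seq):
            track.alleles[i] = (b,)
        track.status = ["hom"] * 50
        pair = (_smrt(ref, sequence=smrt_seq), _smrt(ref, sequence=smrt_seq))
        conflicts = compare_tracks(track, pair, ref)
        for c in conflicts:
            want = classify_conflict_case(
                c.reference, frozenset(c.sbs_call), frozenset(c.smrt_call), False
            )
            assert c.category.value == want

    def test_run_level_tie_flag_dominates(self):
        c = _classify_run(0, "A", 8, {8}, {8}, smrt_flagged=True)
        assert c.category is ConflictCategory.HOMOPOLYMER_INDEL
        assert _classify_run(0, "A", 8, {8}, {8}, smrt_flagged=False) is None


class TestDecide:
    @pytest.mark.parametrize(
        "cats,phased,action",
        [
            (["SMRT_only_deviation"], True, Action.SUBMIT_SBS),
            (["SBS_only_deviation"], True, Action.REPEAT_ANALYSIS),
            (["homopolymer_indel"], False, Action.RUN_DR2S),
            (["phase_gap"], False, Action.RUN_DR2S),
            ([], True, Action.SUBMIT_CONCORDANT),
            (["concordant_deviation"], True, Action.SUBMIT_CONCORDANT),
            (["homopolymer_indel"], True, Action.SUBMIT_SBS),
        ],
    )
    def test_single_category_rules(self, cats, phased, action):
        conflicts = [_conflict(c, i) for i, c in enumerate(cats)]
        assert decide(conflicts, phased).action is action

    def test_total_over_category_power_set(self):
        """Every subset of conflict categories maps to exactly the action
        the plainly-stated rule precedence demands (2 over 3 over 1)."""
        for subset in itertools.chain.from_iterable(
            itertools.combinations(CATEGORIES, r) for r in range(len(CATEGORIES) + 1)
        ):
            for phased in (True, False):
                conflicts = [_conflict(c, i) for i, c in enumerate(subset)]
                got = decide(conflicts, phased).action.value
                assert got == rule_engine_oracle(set(subset), phased), (subset, phased)

    def test_justification_cites_a_rule_per_conflict(self):
        conflicts = [_conflict("SMRT_only_deviation", 5), _conflict("phase_gap", 9)]
        decision = decide(conflicts, False)
        assert len(decision.justification) == 2
        assert all("rule" in j for j in decision.justification)


class TestPolish:
    def _pair_and_reads(self, class1_refs, seed=7):
        from dualcons import (
            LONG_READ_PRESET,
            SHORT_READ_PRESET,
            build_pileup,
            cluster_long_reads,
            make_diploid_sample,
            simulate_long_reads,
            simulate_short_reads,
        )
        from dualcons.cli_config import PipelineConfig, default_variant_specs
        from dualcons.smrt import build_allele_consensus, call_informative_positions

        spec1, spec2 = default_variant_specs(class1_refs, PipelineConfig())
        truth = make_diploid_sample(class1_refs, spec1, spec2)
        backbone = class1_refs.alleles[0].sequence
        long_reads = simulate_long_reads(truth, 100, LONG_READ_PRESET, seed=seed)
        short = simulate_short_reads(truth, 100, SHORT_READ_PRESET, seed=seed + 1)
        pileup = build_pileup(long_reads.reads, backbone)
        info = call_informative_positions(pileup)
        assignment = cluster_long_reads(pileup, info)
        pair = tuple(
            build_allele_consensus(pileup, assignment.cluster_indices(l))
            for l in (1, 2)
        )
        return truth, pair, short

    def test_concordant_reads_leave_consensus_unchanged(self, class1_refs):
        """Noiseless short reads from exactly the preliminary pair do not
        edit a single position (no-regression)."""
        from dualcons.simulate import DiploidTruth, ErrorProfile, simulate_short_reads
        from dualcons.smrt import AlleleConsensus

        a = class1_refs.alleles[0].sequence
        b = class1_refs.alleles[1].sequence
        pair = (_smrt(a, sequence=a), _smrt(b, sequence=b))
        fake_truth = DiploidTruth(a, b, class1_refs.alleles[0],
                                  class1_refs.alleles[1], None, None)
        profile = ErrorProfile(0.0, 0.0, 0.0, read_length=251,
                               fragment_span_max=1000, paired=True)
        reads = simulate_short_reads(fake_truth, 60, profile, seed=3)
        polished = polish_consensus(pair, reads)
        assert polished == (a, b)

    def test_ambiguous_polyA_resolved_to_truth(self, class1_refs):
        """The poly-A state: the run flagged ambiguous on both haplotypes
        is recalled from short reads, recovering 9 on one haplotype and 8
        on the other."""
        truth, pair, short = self._pair_and_reads(class1_refs)
        polished = polish_consensus(pair, short)
        assert sorted(polished) == sorted((truth.allele1, truth.allele2))


class TestAuditPositions:
    def test_worked_class1_example(self):
        assert audit_positions(3404, 4) == (4, 3400)

    @pytest.mark.parametrize("L,d", [(100, 0), (100, 100), (1, 1)])
    def test_degenerate_inputs(self, L, d):
        assert audit_positions(L, d) == (d, L - d)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            audit_positions(10, 11)

    @given(st.integers(0, 10**6), st.integers(0, 10**6))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_conserves_total_length(self, L, d):
        if d > L:
            L, d = d, L
        masking, artifact = audit_positions(L, d)
        assert masking + artifact == L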