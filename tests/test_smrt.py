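"""Long-read route: informative positions, allele clustering, preliminary
consensus with homopolymer-ambiguity flags."""

import numpy as np
import pytest

from dualcons import (
    LONG_READ_PRESET,
    VariantSpec,
    build_allele_consensus,
    build_pileup,
    call_informative_positions,
    cluster_long_reads,
    make_diploid_sample,
    simulate_long_reads,
)
from dualcons.seqcore import homopolymer_runs
from dualcons.simulate import SNV, ErrorProfile


def _snv_spec(ref, positions):
    return VariantSpec(
        tuple(SNV(p, "ACGT"[("ACGT".index(ref[p]) + 1) % 4]) for p in positions)
    )


@pytest.fixture(scope="module")
def snv_het(class1_refs):
    """4-SNV heterozygote with its 100x long-read pileup (13% error)."""
    backbone = class1_refs.alleles[0].sequence
    positions = [204, 510, 1873, 3131]
    t = make_diploid_sample(class1_refs, _snv_spec(backbone, positions), VariantSpec())
    reads = simulate_long_reads(t, 100, LONG_READ_PRESET, seed=8)
    pileup = build_pileup(reads.reads, backbone)
    return t, positions, reads, pileup


class TestInformativePositions:
    def test_recovers_exactly_the_truth_hets(self, snv_het):
        _, positions, _, pileup = snv_het
        assert call_informative_positions(pileup) == positions

    def test_homozygote_yields_empty_list(self, class1_refs):
        backbone = class1_refs.alleles[0].sequence
        t = make_diploid_sample(class1_refs, VariantSpec(), VariantSpec())
        reads = simulate_long_reads(t, 60, LONG_READ_PRESET, seed=2)
        pileup = build_pileup(reads.reads, backbone)
        assert call_informative_positions(pileup) == []

    def test_degenerate_window_returns_every_covered_position(self, class1_refs):
        backbone = class1_refs.alleles[0].sequence
        t = make_diploid_sample(class1_refs, VariantSpec(), VariantSpec())
        reads = simulate_long_reads(t, 30, ErrorProfile(0.0, 0.0, 0.0), seed=3)
        pileup = build_pileup(reads.reads, backbone)
        got = call_informative_positions(pileup, freq_window=(0.0, 1.0))
        # with the whole interval as window every covered position
        # qualifies, except run positions whose (zero-count) runner-up
        # symbol is the deletion — those stay excluded by design
        covered = [i for i in range(len(backbone)) if pileup.coverage[i] >= 10]
        in_run = set()
        for s, e, _ in homopolymer_runs(backbone):
            in_run.update(range(s, e))
        expected = [i for i in covered if i not in in_run]
        assert got == expected


class TestClustering:
    def test_assignment_accuracy_against_truth(self, snv_het):
        """Reads separate into the two alleles at >=99% accuracy under the
        13% indel-heavy preset."""
        _, positions, reads, pileup = snv_het
        assignment = cluster_long_reads(pileup, positions)
        labels = np.array(assignment.labels)
        truth = np.array(reads.truth_labels)
        direct = (labels == truth).mean()
        swapped = (labels == (3 - truth)).mean()
        assert max(direct, swapped) >= 0.99
        assert not assignment.homozygous

    def test_identical_reads_get_same_label(self, class1_refs):
        backbone = class1_refs.alleles[0].sequence
        positions = [204, 510]
        t = make_diploid_sample(
            class1_refs, _snv_spec(backbone, positions), VariantSpec()
        )
        reads = simulate_long_reads(t, 40, ErrorProfile(0.0, 0.0, 0.0), seed=4)
        pileup = build_pileup(reads.reads, backbone)
        assignment = cluster_long_reads(pileup, positions)
        by_seq = {}
        for read, label in zip(reads.reads, assignment.labels):
            by_seq.setdefault(read.sequence, set()).add(label)
        assert all(len(v) == 1 for v in by_seq.values())

    def test_homozygous_input_single_cluster_flag(self, class1_refs):
        backbone = class1_refs.alleles[0].sequence
        t = make_diploid_sample(class1_refs, VariantSpec(), VariantSpec())
        reads = simulate_long_reads(t, 20, LONG_READ_PRESET, seed=5)
        pileup = build_pileup(reads.reads, backbone)
        assignment = cluster_long_reads(pileup, [])
        assert assignment.homozygous
        assert set(assignment.labels) == {1}


class TestAlleleConsensus:
    def test_noiseless_cluster_recovers_allele(self, class1_refs):
        backbone = class1_refs.alleles[0].sequence
        positions = [204, 510]
        t = make_diploid_sample(
            class1_refs, _snv_spec(backbone, positions), VariantSpec()
        )
        reads = simulate_long_reads(t, 30, ErrorProfile(0.0, 0.0, 0.0), seed=6)
        pileup = build_pileup(reads.reads, backbone)
        assignment = cluster_long_reads(pileup, positions)
        for label in (1, 2):
            idx = assignment.cluster_indices(label)
            cons = build_allele_consensus(pileup, idx)
            src = t.allele1 if reads.truth_labels[idx[0]] == 1 else t.allele2
            assert cons.sequence == src
            assert cons.ambiguous_runs == []

    def test_consensus_matches_truth_outside_homopolymers(self, class1_refs):
        """Under the 13% indel-heavy preset at ~50x per cluster, the
        preliminary consensus equals truth outside homopolymer runs in at
        least 19 of 20 seeded replicates."""
        backbone = class1_refs.alleles[0].sequence
        positions = [204, 510, 1873, 3131]
        t = make_diploid_sample(
            class1_refs, _snv_spec(backbone, positions), VariantSpec()
        )
        successes = 0
        for seed in range(20):
            reads = simulate_long_reads(t, 100, LONG_READ_PRESET, seed=100 + seed)
            pileup = build_pileup(reads.reads, backbone)
            assignment = cluster_long_reads(pileup, positions)
            ok = True
            for label in (1, 2):
                idx = assignment.cluster_indices(label)
                cons = build_allele_consensus(pileup, idx)
                majority_src = np.bincount(
                    [reads.truth_labels[i] for i in idx]
                ).argmax()
                src = t.allele1 if majority_src == 1 else t.allele2
                ok = ok and _equal_outside_runs(cons.sequence, src)
            successes += ok
        assert successes >= 19

    def test_deletion_biased_polyA_is_flagged_ambiguous(self, class1_refs):
        """A poly-A run under deletion-biased errors ends with no modal
        run length at >=60% support: the locus carries an ambiguity flag."""
        backbone = class1_refs.alleles[0].sequence
        t = make_diploid_sample(class1_refs, VariantSpec(), VariantSpec())
        profile = ErrorProfile(
            0.005, 0.01, 0.18, homopolymer_multiplier=3.0
        )
        reads = simulate_long_reads(t, 60, profile, seed=7)
        pileup = build_pileup(reads.reads, backbone)
        cons = build_allele_consensus(pileup)
        runs = homopolymer_runs(backbone)
        longest = max(runs, key=lambda r: r[1] - r[0])
        assert longest in cons.ambiguous_runs

    def test_label_swap_symmetry(self, snv_het):
        _, positions, _, pileup = snv_het
        assignment = cluster_long_reads(pileup, positions)
        c1 = build_allele_consensus(pileup, assignment.cluster_indices(1))
        c2 = build_allele_consensus(pileup, assignment.cluster_indices(2))
        assert {c1.sequence, c2.sequence} == {
            build_allele_consensus(pileup, assignment.cluster_indices(2)).sequence,
            build_allele_consensus(pileup, assignment.cluster_indices(1)).sequence,
        }
        assert c1.sequence != c2.sequence

    def test_empty_cluster_rejected(self, snv_het):
        _, _, _, pileup = snv_het
        with pytest.raises(ValueError):
            build_allele_consensus(pileup, [])


def _equal_outside_runs(consensus: str, truth: str) -> bool:
    """Compare consensus to truth with homopolymer-run lengths excised.

    Runs of length >= 3 are collapsed to length 3 in both strings: a
    length-4 homopolymer (the shortest run whose length call is deferred
    to polishing) whose length was miscalled by one appears as a 3-run in
    the consensus, so collapsing at >= 4 would leak run-length errors
    into the off-run comparison."""
    import re

    def collapse(s: str) -> str:
        return re.sub(r"(.)\1{2,}", lambda m: m.group(1) * 3, s)

    return collapse(consensus) == collapse(truth)
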