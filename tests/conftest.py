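import pytest

from dualcons import (
    GeneModel,
    ReferenceAllele,
    VariantSpec,
    make_diploid_sample,
    make_reference_set,
)
from dualcons.simulate import SNV, HomopolymerDelta


@pytest.fixture(scope="session")
def class1_refs():
    """Small class I reference set shared across tests."""
    return make_reference_set(4, "classI", divergence=0.01, seed=42)


@pytest.fixture(scope="session")
def toy_gene():
    """A 900 bp three-exon toy gene with a clean ORF in its CDS.

    The CDS (462 bp) is ATG + GCT codon repeats + TAA spread over three
    exons, so single-base edits have predictable codon effects.
    """
    import numpy as np

    rng = np.random.default_rng(99)
    bases = "ACGT"
    feats = (
        ("UTR5", 0, 100),
        ("exon", 100, 172),
        ("intron", 172, 289),
        ("exon", 289, 559),
        ("intron", 559, 700),
        ("exon", 700, 820),
        ("UTR3", 820, 900),
    )
    model = GeneModel(feats)
    cds_len = sum(e - s for _, s, e in feats if _ == "exon")  # 462
    cds = "ATG" + "GCT" * (cds_len // 3 - 2) + "TAA"
    seq = []
    cds_iter = iter(cds)
    for kind, s, e in feats:
        if kind == "exon":
            seq.append("".join(next(cds_iter) for _ in range(e - s)))
        else:
            seq.append("".join(bases[rng.integers(0, 4)] for _ in range(e - s)))
    return ReferenceAllele("TOY*01:01", "".join(seq), model)


@pytest.fixture(scope="session")
def het_sample(class1_refs):
    """Default study heterozygote: 4 SNVs on allele1, poly-run -1 on allele2."""
    from dualcons.cli_config import PipelineConfig, default_variant_specs

    spec1, spec2 = default_variant_specs(class1_refs, PipelineConfig())
    return make_diploid_sample(class1_refs, spec1, spec2)
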