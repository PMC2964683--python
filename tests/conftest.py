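"""Shared fixtures: synthetic templates at several scales.

Everything is generated programmatically and deterministically; no
data files are read.
"""

import random

import pytest

from ctpp_design.constraint_fitness import ConstraintConfig
from ctpp_design.fixtures_oracle import (
    PLANT_VECTOR,
    PLANT_VECTOR_SMALL,
    SyntheticTemplateSpec,
    generate_template,
)
from ctpp_design.sequence_model import ChromosomeVector, TemplateDNA


@pytest.fixture(scope="session")
def default_cfg():
    return ConstraintConfig()


@pytest.fixture(scope="session")
def planted_template(default_cfg):
    """Full-scale (500 bp flanks) template with an embedded defect-free design."""
    spec = SyntheticTemplateSpec(plant_zero_set=True, seed=1)
    t, manifest = generate_template(spec, default_cfg)
    return t, manifest


@pytest.fixture(scope="session")
def tiny_cfg():
    """Constraint config restricting all primers to 20-mers (small search space)."""
    return ConstraintConfig(len_min=20, len_max=20)


@pytest.fixture(scope="session")
def tiny_planted(tiny_cfg):
    """Small planted instance whose chromosome space is fully enumerable."""
    spec = SyntheticTemplateSpec(
        flank_length=160,
        plant_zero_set=True,
        plant_vector=PLANT_VECTOR_SMALL,
        seed=11,
    )
    t, manifest = generate_template(spec, tiny_cfg)
    return t, manifest


@pytest.fixture(scope="session")
def toy_template():
    """241-base random template with an M (A/C) SNP at the center."""
    rng = random.Random(99)
    bases = [rng.choice("ACGT") for _ in range(241)]
    s0 = 120
    bases[s0] = "M"
    return TemplateDNA(
        sequence="".join(bases),
        snp_index=s0,
        allele_major="A",
        allele_minor="C",
        record_id="toy241",
    )


# reference CTPP set for an A/C SNP, validated by gel electrophoresis:
# four 20-mers with products 228/105/294 bp; the Pf1/Pr1 GC% values
# (30/35) serve as oracles.
REF_PF1 = "GATTATTAGTAGTTTCTGCA"
REF_PR1 = "TTCTTTATGAATACCAGACG"
REF_PF2 = "AGAAAGTTACAGACTAGCAA"
REF_PR2 = "ATGTTTAATCTCTGAGAAGA"


@pytest.fixture(scope="session")
def reference_primers():
    return {
        "Pf1": REF_PF1,
        "Pr1": REF_PR1,
        "Pf2": REF_PF2,
        "Pr2": REF_PR2,
    }


def make_primer_set(pf1, pr1, pf2, pr2, pl1=228, pl2=105):
    """Assemble a CTPPPrimerSet directly from four primer strings.

    Coordinates are synthesized from the lengths; useful for testing
    the constraint functions on hand-picked sequences.
    """
    from ctpp_design.sequence_model import CTPPPrimerSet

    rl1, fl2 = len(pr1), len(pf2)
    pl3 = pl1 + pl2 - rl1 - fl2 + 1
    snp = 501
    return CTPPPrimerSet(
        pf1=pf1, pr1=pr1, pf2=pf2, pr2=pr2,
        fs1=snp + rl1 - pl1, fe1=snp + rl1 - pl1 + len(pf1) - 1,
        rs1=snp, re1=snp + rl1 - 1,
        fs2=snp - fl2 + 1, fe2=snp,
        rs2=snp - fl2 + pl2 - len(pr2) + 1, re2=snp - fl2 + pl2,
        pl1=pl1, pl2=pl2, pl3=pl3,
    )
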