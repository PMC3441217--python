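"""Shared fixtures: a small handcrafted reference set and cheap simulations."""

from __future__ import annotations

import pytest

from smallrna_devatlas.io import ReferenceSet
from smallrna_devatlas.simulate import SimulationConfig, generate_reference_set


def revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


MIR_A = "TGAGGTAGTAGGTTGTATAGTT"  # 22 nt
MIR_B = "ACTGGCCTACAAAGTCCCAGT"  # 21 nt
EXT5_A, EXT3_A = "GCAAC", "TCGGA"
EXT5_B, EXT3_B = "ATCGT", "GGATC"
LOOP = "AAGAAACA"


def make_precursor(mature: str, ext5: str, ext3: str) -> tuple[str, int]:
    arm = ext5 + mature + ext3
    return arm + LOOP + revcomp(arm), len(ext5)


@pytest.fixture
def tiny_refset() -> ReferenceSet:
    """Two handcrafted miRNAs plus one rRNA/tRNA decoy each."""
    pre_a, off_a = make_precursor(MIR_A, EXT5_A, EXT3_A)
    pre_b, off_b = make_precursor(MIR_B, EXT5_B, EXT3_B)
    rrna = (
        "GGCTACCACATCCAAGGAAGGCAGCAGGCGCGCAAATTACCCACTCCCGACCCGGGGAGG"
        "TAGTGACGAAAAATAACAATACAGGAC"
    )
    trna = (
        "GCATTGGTGGTTCAGTGGTAGAATTCTCGCCTGCCACGCGGGAGGCCCGGGTTCGATTCC"
        "CGGCCAATGCA"
    )
    genome = "TTAACG" * 8 + pre_a + "ACGTTG" * 8 + pre_b + "GTCAAT" * 8
    refset = ReferenceSet(
        mature={"mirA": MIR_A, "mirB": MIR_B},
        precursors={"pre-mirA": pre_a, "pre-mirB": pre_b},
        mature_offsets={"pre-mirA": [("mirA", off_a)], "pre-mirB": [("mirB", off_b)]},
        class_libraries={"rRNA": {"rRNA-1": rrna}, "tRNA": {"tRNA-1": trna}},
        genome={"chr1": genome},
        snp_table={("mirA", 7)},
    )
    refset.validate()
    return refset


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """Reduced-scale configuration used by cheap property tests."""
    return SimulationConfig(
        rng_seed=11, mirna_count=20, reads_per_replicate=2000
    )


@pytest.fixture(scope="session")
def small_refset(small_sim_config) -> ReferenceSet:
    return generate_reference_set(small_sim_config)
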