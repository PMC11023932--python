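import numpy as np
import pytest

from pegquant.design import AmpliconReference, EditSpec, PegRNADesign
from pegquant.simulate import random_editing_locus


@pytest.fixture(scope="session")
def spacer20():
    return "GACGTTACCGGATTCACGAT"


@pytest.fixture(scope="session")
def plus_amplicon(spacer20):
    """Amplicon with the spacer at [20,40) and a TGG PAM at [40,43)."""
    rng = np.random.default_rng(11)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    left = bytes(rng.choice(bases, size=20)).decode()
    right = bytes(rng.choice(bases, size=37)).decode()
    seq = left + spacer20 + "TGG" + right
    return AmpliconReference("plus_amp", seq)


@pytest.fixture(scope="session")
def sub_design(plus_amplicon, spacer20):
    """+5 1-bp substitution design matching plus_amplicon (+ strand, cut 37)."""
    ref_base = plus_amplicon.sequence[41]  # cut 37, +5 -> index 41
    alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref_base]
    return PegRNADesign(
        spacer=spacer20,
        intended_edit=EditSpec("substitution", 5, ref_base, alt),
        rt_template="AGCUCGAUU",
    )


@pytest.fixture(scope="session")
def sim_locus():
    """Random 200-nt locus + matched 2-bp substitution design at +7."""
    return random_editing_locus(length=200, seed=42)
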