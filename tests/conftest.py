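import pytest

from crisprselect.amplicon import example_design, make_design


@pytest.fixture(scope="session")
def exon_design():
    """Demo amplicon with an exon-targeting guide (cut in the exon)."""
    return example_design(intron_guide=False)


@pytest.fixture(scope="session")
def intron_design():
    """Single-allele editing demo amplicon (cut in the intron)."""
    return example_design(intron_guide=True)


@pytest.fixture(scope="session")
def two_region_design():
    """The 200-bp exon[0,100) + intron[100,200) design used in examples."""
    import numpy as np

    rng = np.random.default_rng(7)
    ref = "".join(rng.choice(list("ACGT"), size=200))

    def sub(pos):
        alt = next(b for b in "ACGT" if b != ref[pos])
        return (pos, ref[pos], alt)

    return make_design(
        name="two-region",
        reference=ref,
        regions=[(0, 100, "exon"), (100, 200, "intron")],
        cut_site=98,
        mut_substitutions=[sub(95), sub(96)],
        wtstar_substitutions=[sub(90), sub(91)],
    )
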