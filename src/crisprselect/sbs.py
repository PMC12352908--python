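"""Single-base-substitution channel definitions (COSMIC ordering).

The 96 channels index pyrimidine-centered substitutions by their 5' and
3' flanking bases: substitution type major (C>A, C>G, C>T, T>A, T>C,
T>G), trinucleotide alphabetical minor. Purine-reference mutations are
counted on the reverse-complement strand.
"""

from __future__ import annotations

COMPLEMENT = str.maketrans("ACGT", "TGCA")

SUB_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def sbs96_channels() -> list[str]:
    """COSMIC-ordered channel labels, e.g. ``A[C>A]A``."""
    return [
        f"{five}[{sub}]{three}"
        for sub in SUB_TYPES
        for five in "ACGT"
        for three in "ACGT"
    ]


CHANNELS96 = sbs96_channels()
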