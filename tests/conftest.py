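import numpy as np
import pytest

from poolscreen import (
    Amplicon,
    SgRNA,
    SgRNALibrary,
    build_library,
    example_screen_library,
)


@pytest.fixture(scope="session")
def screen_library() -> SgRNALibrary:
    """The canonical screen layout: 96 genes x 5 + 5 Hoxa9 + 1 NTC = 486."""
    return example_screen_library()


@pytest.fixture()
def tiny_library() -> SgRNALibrary:
    """Three genes x 2 guides + 1 NTC with hand-chosen spacers."""
    spacers = [
        "AAAACCCCGGGGTTTTAAAA",
        "CCCCGGGGTTTTAAAACCCC",
        "GGGGTTTTAAAACCCCGGGG",
        "TTTTAAAACCCCGGGGTTTT",
        "ACGTACGTACGTACGTACGT",
        "TGCATGCATGCATGCATGCA",
        "AATTCCGGAATTCCGGAATT",
    ]
    return build_library(
        ["GeneA", "GeneB", "GeneC"],
        sgrnas_per_gene=2,
        n_nontargeting=1,
        spacers=spacers,
    )


@pytest.fixture(scope="session")
def amplicon() -> Amplicon:
    """A 120-bp amplicon with the protospacer implanted at position 50 (+)."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    seq = "".join(bases[rng.integers(0, 4, 120)])
    spacer = seq[50:70]
    amp = Amplicon("amp1", seq, spacer)
    assert amp.strand == "+" and amp.spacer_start == 50
    return amp
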