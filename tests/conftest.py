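import numpy as np
import pytest

from twm.formats_io import CHANNELS, SignatureMatrix, VariantRecord


@pytest.fixture
def disjoint_pair() -> SignatureMatrix:
    """Two signatures with disjoint support: uniform on channels 0-47 / 48-95."""
    probs = np.zeros((2, 96))
    probs[0, :48] = 1 / 48
    probs[1, 48:] = 1 / 48
    return SignatureMatrix(["BLOCK1", "BLOCK2"], probs)


@pytest.fixture
def uv_heavy_signatures() -> SignatureMatrix:
    """Melanoma-style candidate set with distinguishable random profiles."""
    rng = np.random.default_rng(7)
    ids = ["SBS1", "SBS2", "SBS3", "SBS5", "SBS7a", "SBS7b", "SBS13", "SBS38", "SBS40"]
    probs = rng.dirichlet(np.full(96, 0.1), size=len(ids))
    return SignatureMatrix(ids, probs)


def make_variant(**kw) -> VariantRecord:
    base = dict(
        case_id="case1", chrom="chr1", pos=100, ref="C", alt="T",
        vaf=0.5, gene="TERT", pathogenic=False, ctx5="A", ctx3="A",
    )
    base.update(kw)
    return VariantRecord(**base)


@pytest.fixture
def variant_factory():
    return make_variant
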