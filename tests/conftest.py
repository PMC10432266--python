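import numpy as np
import pytest

from polyphage.mining import AnnotatedContig, GeneFeature


@pytest.fixture
def rng():
    return np.random.default_rng(20230726)


def make_contig(length, features, seq=None, cid="ctg"):
    feats = [
        GeneFeature(contig_id=cid, start=s, end=e, strand=st, label=lab)
        for (lab, st, s, e) in features
    ]
    return AnnotatedContig(id=cid, length=length, features=feats, sequence=seq)


@pytest.fixture
def contig_factory():
    return make_contig
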