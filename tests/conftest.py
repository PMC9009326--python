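import numpy as np
import pytest

from operonmerge.expression import ExpressionProfile
from operonmerge.io_formats import GeneCatalog, GeneRecord

T8 = np.arange(0.0, 24.0, 3.0)  # 8 timepoints over one diel cycle


def make_profile(gene_id, values, timepoints=None):
    t = T8 if timepoints is None else np.asarray(timepoints, dtype=float)
    return ExpressionProfile(gene_id, t, np.asarray(values, dtype=float))


def make_catalog(strands, contig="c1"):
    """Catalog of len(strands) genes laid out left to right on one contig."""
    records = [
        GeneRecord(f"g{i + 1}", contig, strand, i * 1000, i * 1000 + 900)
        for i, strand in enumerate(strands)
    ]
    return GeneCatalog(records)


@pytest.fixture
def catalog4_plus():
    return make_catalog("++++")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
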