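import numpy as np
import pytest

from famseq.core_io import Cohort, VariantSite
from famseq.pedigree import parse_ped_text

SIB_PED = """\
fam fa 0 0 1 1
fam mo 0 0 2 1
fam a1 fa mo 1 2
fam a2 fa mo 2 2
fam u1 fa mo 1 1
fam u2 fa mo 2 1
"""

SIB_SAMPLES = ["fa", "mo", "a1", "a2", "u1", "u2"]


@pytest.fixture
def sib_pedigree():
    return parse_ped_text(SIB_PED)


def make_variant(i=0, chrom="1", gene="G1", consequence="missense", **kw):
    defaults = dict(chrom=chrom, pos=100 + 10 * i, ref="G", alt="T",
                    gene=gene, consequence=consequence)
    defaults.update(kw)
    return VariantSite(**defaults)


def build_cohort(variants, samples, gt, ped=None, dp=None, ad=None):
    """Hand-built cohort; gt rows are per-variant dosages (-1 missing)."""
    gt = np.asarray(gt, dtype=np.int8)
    if gt.ndim == 1:
        gt = gt[None, :]
    return Cohort(list(variants), list(samples), gt,
                  None if dp is None else np.asarray(dp, dtype=np.int32),
                  None if ad is None else np.asarray(ad, dtype=np.int32),
                  pedigree=ped)


@pytest.fixture
def fixture_tables():
    from famseq.core_io import load_fixtures

    return load_fixtures()
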