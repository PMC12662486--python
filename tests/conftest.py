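import numpy as np
import pytest
from hypothesis import settings

from mrmediate.harmonize import HarmonizedPair

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")
from mrmediate.sumstats import SummaryStatRecord, SummaryStatSet


def make_pairs(bx, by, sy, sx=None, prefix="rs"):
    """Harmonized pairs from plain arrays (sx defaults to tiny: exposure
    effects treated as known, the first-order Wald assumption)."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float) * np.ones_like(bx)
    sx = (
        np.full_like(bx, 1e-8)
        if sx is None
        else np.asarray(sx, dtype=float) * np.ones_like(bx)
    )
    return [
        HarmonizedPair(
            snp_id=f"{prefix}{i + 1}",
            beta_exp=float(bx[i]),
            se_exp=float(sx[i]),
            beta_out=float(by[i]),
            se_out=float(sy[i]),
            action="kept",
        )
        for i in range(len(bx))
    ]


def make_record(snp_id="rs1", ea="A", oa="G", beta=0.1, se=0.02, pval=1e-6,
                eaf=0.3, n=10000):
    return SummaryStatRecord(
        snp_id=snp_id, effect_allele=ea, other_allele=oa,
        beta=beta, se=se, pval=pval, eaf=eaf, n=n,
    )


def make_set(records, trait_id="trait", trait_type="metabolite"):
    return SummaryStatSet(trait_id=trait_id, trait_type=trait_type,
                          records=list(records))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def simple_pairs():
    """Five homogeneous instruments on an exact line through the origin."""
    bx = np.array([0.10, 0.15, 0.20, 0.25, 0.30])
    return make_pairs(bx, 0.3 * bx, sy=0.02)
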