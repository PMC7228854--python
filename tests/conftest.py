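from __future__ import annotations

import numpy as np
import pytest

from tsmr.instruments import HarmonizedSet, _wald
from tsmr.sumstats import SummaryStatRecord, SummaryStatTable


def hset_from_arrays(bx, sx, by, sy, ids=None,
                     exposure_type="continuous", outcome_type="continuous"):
    """Build a kept-only HarmonizedSet straight from effect arrays."""
    bx, sx, by, sy = (np.asarray(a, dtype=float) for a in (bx, sx, by, sy))
    ids = ids or [f"rs{i + 1}" for i in range(bx.size)]
    instruments = [
        _wald(ids[i], bx[i], sx[i], by[i], sy[i], None, None)
        for i in range(bx.size)
    ]
    return HarmonizedSet("X", "Y", instruments,
                         exposure_type=exposure_type, outcome_type=outcome_type)


def make_record(snp="rs1", ea="A", oa="G", beta=0.1, se=0.01, pval=1e-9,
                eaf=0.3, n=10000.0, trait_type="continuous", **kw):
    return SummaryStatRecord(snp_id=snp, effect_allele=ea, other_allele=oa,
                             beta=beta, se=se, pval=pval, eaf=eaf, n=n,
                             trait_type=trait_type, **kw)


def make_table(records, name="trait", trait_type="continuous"):
    return SummaryStatTable(name, trait_type, list(records))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_hset(rng):
    """20 strong instruments with mild heterogeneity."""
    L = 20
    sx = rng.uniform(0.002, 0.005, L)
    bx = rng.uniform(0.02, 0.06, L) * rng.choice([-1, 1], L)
    sy = rng.uniform(0.002, 0.005, L)
    by = 0.1 * bx + rng.normal(0, 1, L) * sy
    return hset_from_arrays(bx, sx, by, sy)
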