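import numpy as np
import pandas as pd
import pytest

from metamr import HarmonizedSet, SummaryStats


def make_sumstats(trait_id, rows):
    """Build a SummaryStats from (snp_id, chrom, pos, ea, oa, eaf, beta, se, p, n) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                 "eaf", "beta", "se", "pvalue", "n"],
    )
    return SummaryStats(trait_id, df)


def make_harmonized(b_exp, b_out, se_out, se_exp=None, n_exp=10000.0, n_out=100000.0):
    b_exp = np.asarray(b_exp, dtype=float)
    b_out = np.asarray(b_out, dtype=float)
    se_out = np.broadcast_to(np.asarray(se_out, dtype=float), b_exp.shape)
    if se_exp is None:
        se_exp = np.full_like(b_exp, 0.01)
    else:
        se_exp = np.broadcast_to(np.asarray(se_exp, dtype=float), b_exp.shape)
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(len(b_exp))],
            "b_exp": b_exp,
            "se_exp": se_exp,
            "b_out": b_out,
            "se_out": se_out,
            "eaf": 0.3,
            "n_exp": n_exp,
            "n_out": n_out,
        }
    )
    return HarmonizedSet("exp", "out", df)


@pytest.fixture
def harmonized_clean():
    """A 6-SNP harmonized set generated exactly on the line b_out = 0.4*b_exp plus jitter."""
    rng = np.random.default_rng(11)
    b_exp = rng.uniform(0.05, 0.3, 6)
    b_out = 0.4 * b_exp + rng.normal(0, 0.005, 6)
    return make_harmonized(b_exp, b_out, se_out=0.01)
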