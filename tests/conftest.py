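"""Shared fixtures: small synthetic data sets reused across test modules."""

from math import lgamma

import numpy as np
import pandas as pd
import pytest

from exitkit import methylome as meth
from exitkit import synthetic

_LG = [lgamma(i + 1) for i in range(400)]


def lchoose(n: int, k: int) -> float:
    return _LG[n] - _LG[k] - _LG[n - k]


def hypergeom_tails(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Independent tail-sum oracle for Fisher tests on [[a, b], [c, d]].

    Enumerates the hypergeometric pmf over the full support with
    log-factorial arithmetic: returns (upper tail, lower tail, two-sided
    mass of terms <= observed).
    """
    N, K, n = a + b + c + d, a + c, a + b
    lden = lchoose(N, n)
    lo, hi = max(0, n - (N - K)), min(n, K)
    pmf = {
        j: np.exp(lchoose(K, j) + lchoose(N - K, n - j) - lden) for j in range(lo, hi + 1)
    }
    p_obs = pmf[a]
    over = sum(v for j, v in pmf.items() if j >= a)
    under = sum(v for j, v in pmf.items() if j <= a)
    two = sum(v for v in pmf.values() if v <= p_obs * (1 + 1e-7))
    return min(over, 1.0), min(under, 1.0), min(two, 1.0)


@pytest.fixture(scope="session")
def methylome_run():
    """One full synthetic methylome with planted DMRs, filtered and tiled."""
    chrom = {"chr1": 400 * 800}
    design = synthetic.make_design()
    planted = synthetic.plant_dmr_tiles(chrom, n_loss=40, n_gain=5, seed=11)
    sim = synthetic.make_methylome(chrom, design, planted, depth_mean=20, seed=11)
    filtered = {k: meth.filter_cpgs(v) for k, v in sim.samples.items()}
    common = meth.intersect_common_cpgs(filtered)
    tiles = meth.tile_methylation(common)
    return sim, tiles


def pool(sim, tiles, condition: str, timepoint: str) -> pd.DataFrame:
    des = sim.design
    ids = des.loc[
        (des["condition"] == condition) & (des["timepoint"] == timepoint), "sample_id"
    ].tolist()
    return meth.pool_group(tiles, ids)


def truth_index(truth_df: pd.DataFrame, direction: str) -> pd.MultiIndex:
    sub = truth_df.loc[truth_df["direction"] == direction]
    return pd.MultiIndex.from_frame(sub[["chrom", "start"]])
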