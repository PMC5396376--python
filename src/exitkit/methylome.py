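"""Tile-based RRBS methylome analysis.

CpG records are per-sample frames (chrom, pos, meth, unmeth) with 0-based
positions. The workflow mirrors standard tile-based differential
methylation: depth/coverage filtering per sample, restriction to CpGs
covered in every sample, pooled methylation in anchored 400 bp tiles with
at least three CpGs, and two-sided Fisher exact tests on pooled counts with
Benjamini-Hochberg correction. Tiles moving more than 20 percentage points
at q < 0.05 are called differentially methylated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import bh_adjust, fisher_two_sided_p

logger = logging.getLogger(__name__)

DIFF_THRESHOLD = 20.0
Q_THRESHOLD = 0.05


def filter_cpgs(
    records: pd.DataFrame,
    min_depth: int = 5,
    top_coverage_fraction: float = 0.001,
) -> pd.DataFrame:
    """Drop low-depth CpGs, then the top coverage fraction of one sample.

    Sites with coverage below ``min_depth`` are removed; then sites with
    coverage *strictly above* the (1 - fraction) empirical quantile
    (linear-interpolation definition) of the remaining coverages go too —
    the standard guard against PCR-duplicated outlier sites.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not 0.0 <= top_coverage_fraction < 0.5:
        raise ValueError("top_coverage_fraction must lie in [0, 0.5)")
    if records.empty:
        logger.warning("filter_cpgs: empty input")
        return records.copy()
    cov = records["meth"] + records["unmeth"]
    kept = records.loc[cov >= min_depth]
    n_depth = len(records) - len(kept)
    if kept.empty:
        logger.warning("filter_cpgs: no site reaches min_depth=%d", min_depth)
        return kept.copy()
    if top_coverage_fraction > 0:
        cov = kept["meth"] + kept["unmeth"]
        cutoff = np.quantile(cov, 1.0 - top_coverage_fraction)
        out = kept.loc[cov <= cutoff]
    else:
        out = kept
    logger.info(
        "filter_cpgs: removed %d below depth, %d above coverage quantile",
        n_depth, len(kept) - len(out),
    )
    return out.reset_index(drop=True)


def intersect_common_cpgs(samples: Mapping[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Restrict every sample to the (chrom, pos) sites present in all samples."""
    if len(samples) < 2:
        raise ValueError("need at least two samples to intersect")
    common: pd.MultiIndex | None = None
    for df in samples.values():
        idx = pd.MultiIndex.from_frame(df[["chrom", "pos"]])
        common = idx if common is None else common.intersection(idx)
    if len(common) == 0:
        logger.warning("intersect_common_cpgs: empty intersection")
    out = {}
    for name, df in samples.items():
        indexed = df.set_index(["chrom", "pos"])
        sub = indexed.loc[indexed.index.isin(common)].sort_index()
        out[name] = sub.reset_index()
    return out


def methylation_histogram(records: pd.DataFrame, bin_width: float = 5.0) -> pd.Series:
    """Counts of sites per methylation% bin: [0,5), [5,10), ..., [95,100]."""
    if 100.0 % bin_width != 0:
        raise ValueError("bin_width must divide 100")
    pct = 100.0 * records["meth"] / (records["meth"] + records["unmeth"])
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    counts, _ = np.histogram(pct, bins=edges)  # last bin closed at 100
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 2)]
    labels.append(f"[{edges[-2]:g},{edges[-1]:g}]")
    return pd.Series(counts, index=labels, name="n_sites")


def tile_methylation(
    samples: Mapping[str, pd.DataFrame],
    tile_size: int = 400,
    min_cpgs: int = 3,
) -> pd.DataFrame:
    """Pool common CpGs into anchored, non-overlapping tiles.

    Tiles start at multiples of ``tile_size`` from coordinate 0; a CpG at
    position p belongs to tile [p // tile_size * tile_size, +tile_size).
    Tiles holding fewer than ``min_cpgs`` common CpGs are dropped. Returns a
    frame indexed by (chrom, start) with end, n_cpgs and per-sample pooled
    meth/unmeth counts and coverage-weighted methylation percent.
    """
    names = list(samples)
    ref = samples[names[0]]
    ref_sites = pd.MultiIndex.from_frame(ref[["chrom", "pos"]])
    for name in names[1:]:
        sites = pd.MultiIndex.from_frame(samples[name][["chrom", "pos"]])
        if not ref_sites.equals(sites):
            raise ValueError(
                f"sample {name!r} has a different CpG site set; intersect_common_cpgs first"
            )

    tile_start = (ref["pos"] // tile_size) * tile_size
    key = pd.DataFrame({"chrom": ref["chrom"].to_numpy(), "start": tile_start.to_numpy()})
    grouped = key.groupby(["chrom", "start"], sort=True)
    n_cpgs = grouped.size().rename("n_cpgs")

    out = pd.DataFrame({"n_cpgs": n_cpgs})
    out["end"] = out.index.get_level_values("start") + tile_size
    for name in names:
        df = samples[name]
        agg = (
            pd.DataFrame(
                {
                    "chrom": df["chrom"].to_numpy(),
                    "start": (df["pos"] // tile_size * tile_size).to_numpy(),
                    "meth": df["meth"].to_numpy(),
                    "unmeth": df["unmeth"].to_numpy(),
                }
            )
            .groupby(["chrom", "start"], sort=True)
            .sum()
        )
        out[f"meth_{name}"] = agg["meth"]
        out[f"unmeth_{name}"] = agg["unmeth"]
    out = out.loc[out["n_cpgs"] >= min_cpgs]
    for name in names:
        total = out[f"meth_{name}"] + out[f"unmeth_{name}"]
        out[f"pct_{name}"] = 100.0 * out[f"meth_{name}"] / total
    return out


def pool_group(tiles: pd.DataFrame, sample_ids: Sequence[str]) -> pd.DataFrame:
    """Sum per-sample tile counts over a replicate group."""
    meth = sum(tiles[f"meth_{s}"] for s in sample_ids)
    unmeth = sum(tiles[f"unmeth_{s}"] for s in sample_ids)
    return pd.DataFrame(
        {
            "end": tiles["end"],
            "n_cpgs": tiles["n_cpgs"],
            "meth": meth,
            "unmeth": unmeth,
            "pct": 100.0 * meth / (meth + unmeth),
        },
        index=tiles.index,
    )


@dataclass
class DMRSummary:
    n_tiles: int
    n_hyper: int
    n_hypo: int

    @property
    def pct_hyper(self) -> float:
        return 100.0 * self.n_hyper / self.n_tiles if self.n_tiles else float("nan")

    @property
    def pct_hypo(self) -> float:
        return 100.0 * self.n_hypo / self.n_tiles if self.n_tiles else float("nan")


def call_dmrs(
    tiles_a: pd.DataFrame,
    tiles_b: pd.DataFrame,
    diff_threshold: float = DIFF_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Per-tile differential methylation between two pooled groups.

    Inputs are pooled tile frames from :func:`pool_group` over an identical
    tile universe. Each tile's 2x2 pooled count table is tested with a
    two-sided Fisher exact test; q is Benjamini-Hochberg over all tested
    tiles. Status is ``hyper``/``hypo`` (B gained/lost relative to A) iff
    |meth_diff| > diff_threshold and q < q_threshold.
    """
    if not tiles_a.index.equals(tiles_b.index):
        only_a = tiles_a.index.difference(tiles_b.index)
        only_b = tiles_b.index.difference(tiles_a.index)
        first = (list(only_a) + list(only_b))[0]
        raise ValueError(f"tile universes differ; first mismatch: {first}")
    meth_a = tiles_a["meth"].to_numpy(np.int64)
    unmeth_a = tiles_a["unmeth"].to_numpy(np.int64)
    meth_b = tiles_b["meth"].to_numpy(np.int64)
    unmeth_b = tiles_b["unmeth"].to_numpy(np.int64)

    diff = tiles_b["pct"].to_numpy() - tiles_a["pct"].to_numpy()
    p = fisher_two_sided_p(meth_a, unmeth_a, meth_b, unmeth_b)
    q = bh_adjust(p)
    status = np.where(
        (np.abs(diff) > diff_threshold) & (q < q_threshold),
        np.where(diff > 0, "hyper", "hypo"),
        "not_significant",
    )
    return pd.DataFrame(
        {
            "end": tiles_a["end"],
            "n_cpgs": tiles_a["n_cpgs"],
            "meth_a": meth_a,
            "unmeth_a": unmeth_a,
            "meth_b": meth_b,
            "unmeth_b": unmeth_b,
            "pct_a": tiles_a["pct"],
            "pct_b": tiles_b["pct"],
            "meth_diff": diff,
            "p": p,
            "q": q,
            "status": status,
        },
        index=tiles_a.index,
    )


def dmr_summary(calls: pd.DataFrame) -> DMRSummary:
    return DMRSummary(
        n_tiles=len(calls),
        n_hyper=int((calls["status"] == "hyper").sum()),
        n_hypo=int((calls["status"] == "hypo").sum()),
    )


def classify_temporal(calls: pd.DataFrame, label: str = "") -> pd.DataFrame:
    """Partition tiles of a t1 -> t2 comparison into gain / loss / stable.

    Gain means hypermethylated at the later timepoint; percentages are of
    all tiles tested in this comparison.
    """
    cls = calls["status"].map({"hyper": "gain", "hypo": "loss"}).fillna("stable")
    counts = cls.value_counts().reindex(["gain", "loss", "stable"], fill_value=0)
    out = pd.DataFrame(
        {
            "comparison": label,
            "n_tiles": counts,
            "pct_of_all_tiles": 100.0 * counts / len(calls) if len(calls) else np.nan,
        }
    )
    out.index.name = "class"
    return out


def temporal_classes(calls: pd.DataFrame) -> pd.Series:
    """Per-tile gain/loss/stable labels for a t1 -> t2 comparison."""
    return calls["status"].map({"hyper": "gain", "hypo": "loss"}).fillna("stable")


def maintained_acquisition(
    dmrs_t1_t2: pd.DataFrame,
    tiles_t2: pd.DataFrame,
    tiles_t3: pd.DataFrame,
    diff_threshold: float = DIFF_THRESHOLD,
) -> pd.DataFrame:
    """Track whether early-gained tiles keep their methylation later on.

    For every gain DMR of the t1 -> t2 comparison, report pooled methylation
    at t2 and t3 and flag the tile ``lost`` when t3 drops more than
    ``diff_threshold`` percentage points below t2.
    """
    gains = dmrs_t1_t2.loc[dmrs_t1_t2["status"] == "hyper"]
    pct_t2 = tiles_t2.loc[gains.index, "pct"]
    pct_t3 = tiles_t3.loc[gains.index, "pct"]
    return pd.DataFrame(
        {
            "pct_acquired": pct_t2,
            "pct_later": pct_t3,
            "drop": pct_t2 - pct_t3,
            "lost": (pct_t2 - pct_t3) > diff_threshold,
        },
        index=gains.index,
    )
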