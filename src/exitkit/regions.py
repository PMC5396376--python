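"""Genomic region classes, promoter CpG-density classification and
per-class methylation dynamics.

Region labels follow the usual methylome partition: enhancers (padded 1 kb),
CpG islands, methylation canyons, transposable elements, high/low-CpG
promoters (split at CpG observed/expected 0.29), exons, introns and a
catch-all ``other``. A tile belongs to a class when it overlaps it by at
least one base; multi-class overlaps are resolved by a configurable
precedence order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HCP_LCP_THRESHOLD = 0.29
DEFAULT_PRECEDENCE = (
    "CGI", "canyon", "HCP", "LCP", "enhancer", "TE", "exon", "intron", "other",
)


def extend_intervals(
    intervals: pd.DataFrame,
    pad: int = 1_000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Pad intervals by ``pad`` bp both ways, clip to chromosomes, merge overlaps."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    df = intervals.copy()
    df["start"] = df["start"] - pad
    df["end"] = df["end"] + pad
    if chrom_lengths is not None:
        df["start"] = df["start"].clip(lower=0)
        df["end"] = [
            min(e, chrom_lengths[c]) for c, e in zip(df["chrom"], df["end"])
        ]
    else:
        df["start"] = df["start"].clip(lower=0)
    return merge_intervals(df)


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly-overlapping intervals, per chromosome."""
    rows = []
    for chrom, sub in intervals.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_start = cur_end = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_start is None:
                cur_start, cur_end = s, e
            elif s <= cur_end:
                cur_end = max(cur_end, e)
            else:
                rows.append({"chrom": chrom, "start": cur_start, "end": cur_end})
                cur_start, cur_end = s, e
        if cur_start is not None:
            rows.append({"chrom": chrom, "start": cur_start, "end": cur_end})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def cpg_obs_exp(sequence: str) -> float:
    """CpG observed/expected ratio: (N_CpG * L) / (N_C * N_G).

    N bases are excluded from the base counts and from L; a CpG dinucleotide
    is only counted when both positions are called. Returns 0 when the
    sequence contains no C or no G.
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    invalid = set(seq) - set("ACGTN")
    if invalid:
        raise ValueError(f"non-ACGTN symbols in sequence: {sorted(invalid)}")
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cpg = sum(1 for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G")
    length = len(seq) - seq.count("N")
    if n_c * n_g == 0:
        return 0.0
    return (n_cpg * length) / (n_c * n_g)


def split_promoters_hcp_lcp(
    promoters: pd.DataFrame,
    genome: Mapping[str, str],
    threshold: float = HCP_LCP_THRESHOLD,
) -> dict[str, pd.DataFrame]:
    """Partition promoter windows into HCP (ratio > threshold) and LCP.

    The boundary is strict: a promoter at exactly the threshold is LCP.
    """
    ratios = []
    for row in promoters.itertuples(index=False):
        if row.chrom not in genome:
            raise KeyError(f"promoter chromosome {row.chrom!r} not in genome")
        seq = str(genome[row.chrom][row.start : row.end])
        if row.end > len(genome[row.chrom]) or row.start < 0:
            raise ValueError(f"promoter {row.chrom}:{row.start}-{row.end} outside genome")
        ratios.append(cpg_obs_exp(seq))
    ratios = np.array(ratios)
    out = promoters.copy()
    out["cpg_obs_exp"] = ratios
    hcp = out.loc[ratios > threshold].reset_index(drop=True)
    lcp = out.loc[ratios <= threshold].reset_index(drop=True)
    return {"HCP": hcp, "LCP": lcp}


def _overlap_lookup(intervals: pd.DataFrame):
    """Build per-chromosome merged interval arrays for fast >=1 bp overlap tests."""
    merged = merge_intervals(intervals)
    table = {}
    for chrom, sub in merged.groupby("chrom", sort=False):
        table[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
    return table


def annotate_tiles(
    tiles: pd.DataFrame,
    region_classes: Mapping[str, pd.DataFrame],
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> pd.Series:
    """Assign each tile the highest-precedence region class it overlaps.

    A tile overlapping no class gets ``other``. ``precedence`` must only
    name known classes (plus ``other``) and must cover all provided classes.
    """
    known = set(region_classes) | {"other"}
    unknown = [l for l in precedence if l not in known]
    if unknown:
        raise ValueError(f"unknown labels in precedence: {unknown}")
    missing = [l for l in region_classes if l not in precedence]
    if missing:
        raise ValueError(f"precedence does not cover classes: {missing}")

    lookups = {label: _overlap_lookup(df) for label, df in region_classes.items()}
    labels = np.full(len(tiles), "other", dtype=object)
    unassigned = np.ones(len(tiles), dtype=bool)
    t_chrom = tiles["chrom"].to_numpy()
    t_start = tiles["start"].to_numpy()
    t_end = tiles["end"].to_numpy()
    for label in precedence:
        if label == "other" or not unassigned.any():
            continue
        table = lookups[label]
        for chrom, (starts, ends) in table.items():
            mask = unassigned & (t_chrom == chrom)
            if not mask.any():
                continue
            # candidate merged interval: the last one starting before tile end
            j = np.searchsorted(starts, t_end[mask], side="left") - 1
            hit = (j >= 0) & (ends[np.clip(j, 0, None)] > t_start[mask])
            rows = np.flatnonzero(mask)[hit]
            labels[rows] = label
            unassigned[rows] = False
    return pd.Series(labels, index=tiles.index, name="region_class")


def region_delta_distribution(
    pct_t1: pd.Series,
    pct_t2: pd.Series,
    labels: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tile methylation change (t2 - t1) grouped by region class.

    Returns (long frame with one row per labeled tile plus a ``genome``
    aggregate, summary frame with median, IQR and fraction |delta| > 20 per
    label).
    """
    if not pct_t1.index.equals(pct_t2.index):
        raise ValueError("tile universes differ between timepoints")
    delta = pct_t2 - pct_t1
    long = pd.DataFrame({"label": labels.reindex(delta.index), "delta": delta})
    genome = pd.DataFrame({"label": "genome", "delta": delta})
    long = pd.concat([long, genome])

    def _summ(g: pd.Series) -> pd.Series:
        return pd.Series(
            {
                "n": len(g),
                "median": g.median(),
                "iqr": g.quantile(0.75) - g.quantile(0.25),
                "frac_gt20": (g.abs() > 20).mean(),
            }
        )

    summary = long.groupby("label")["delta"].apply(_summ).unstack()
    return long, summary


@dataclass
class MetageneProfile:
    """Coverage-weighted mean methylation% in 5'->3' bins around gene bodies."""

    upstream: np.ndarray
    body: np.ndarray
    downstream: np.ndarray
    flank_bp: int
    n_genes: int

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.upstream, self.body, self.downstream])


def metagene_profile(
    records: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = 10_000,
    body_bins: int = 40,
    flank_bins: int = 20,
) -> MetageneProfile:
    """Methylation profile over gene bodies and fixed flanks, strand-aware.

    Gene bodies are length-normalized into ``body_bins``; flanks use fixed
    width bins. Minus-strand genes are reversed so bins always run 5'->3'.
    Bin values are coverage-weighted means over all contributing CpGs;
    bins with no CpG are NaN. Genes shorter than ``body_bins`` bp are
    excluded (logged). When a ``biotype`` column is present, only
    protein-coding genes are used.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if "biotype" in genes.columns:
        genes = genes.loc[genes["biotype"] == "protein_coding"]
    n_bins = flank_bins + body_bins + flank_bins
    meth_sum = np.zeros(n_bins)
    cov_sum = np.zeros(n_bins)

    by_chrom = {
        chrom: sub.sort_values("pos").reset_index(drop=True)
        for chrom, sub in records.groupby("chrom", sort=False)
    }
    n_used = 0
    for gene in genes.itertuples(index=False):
        length = gene.end - gene.start
        if length < body_bins:
            logger.info("metagene_profile: gene %s shorter than body_bins, excluded", gene.gene_id)
            continue
        sub = by_chrom.get(gene.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, gene.start - flank, side="left")
        hi = np.searchsorted(pos, gene.end + flank, side="left")
        if hi <= lo:
            n_used += 1
            continue
        p = pos[lo:hi]
        meth = sub["meth"].to_numpy()[lo:hi].astype(float)
        cov = meth + sub["unmeth"].to_numpy()[lo:hi]

        bins = np.empty(len(p), dtype=int)
        upstream = p < gene.start
        downstream = p >= gene.end
        body = ~upstream & ~downstream
        if flank > 0:
            bins[upstream] = ((p[upstream] - (gene.start - flank)) * flank_bins // flank)
            bins[downstream] = (
                flank_bins + body_bins + (p[downstream] - gene.end) * flank_bins // flank
            )
        bins[body] = flank_bins + (p[body] - gene.start) * body_bins // length
        if gene.strand == "-":
            bins = n_bins - 1 - bins
        np.add.at(meth_sum, bins, meth)
        np.add.at(cov_sum, bins, cov)
        n_used += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(cov_sum > 0, 100.0 * meth_sum / cov_sum, np.nan)
    return MetageneProfile(
        upstream=profile[:flank_bins],
        body=profile[flank_bins : flank_bins + body_bins],
        downstream=profile[flank_bins + body_bins :],
        flank_bp=flank,
        n_genes=n_used,
    )
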