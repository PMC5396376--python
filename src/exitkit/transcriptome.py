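"""Expression-level utilities around a consumed differential-expression table.

TPM conversion, the three-step informative-gene filter (biotype, expression,
variability), DEG thresholding (|log2FC| > 1 and p < 0.01), pi-value ranking
(-log10(q) * log2FC) for preranked enrichment, DEG persistence between
timepoints, and 1 - Spearman / average-linkage hierarchical clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

SHORT_NONCODING = ("miRNA", "snRNA", "snoRNA", "rRNA", "tRNA", "misc_RNA", "scaRNA", "sRNA")
LFC_THRESHOLD = 1.0
P_THRESHOLD = 0.01
DEFAULT_LFC_BINS = (1.0, 2.0, 4.0, np.inf)


def counts_to_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: length-normalized rates scaled to 1e6 per sample."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:10]
        raise KeyError(f"genes missing a length: {missing}")
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0])[:10]
        raise ValueError(f"non-positive gene lengths: {bad}")
    rate = counts.div(lengths, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


@dataclass
class GeneFilter:
    """Three sequential filters selecting informative genes.

    1. Drop short-noncoding biotypes.
    2. Keep genes with TPM >= ``min_tpm`` in >= ``min_samples`` samples
       (both boundaries inclusive).
    3. Drop the ``drop_low_variability_fraction`` least variable genes,
       variability = SD of log2(TPM + 1) across samples; boundary ties
       resolved deterministically by (variability, gene_id) order.

    Step 3's cutoff is *fitted* on first use and stored, so the fitted
    filter is idempotent: re-applying it to its own output keeps every
    gene. (A re-fit on the filtered output would move the variability
    quantile and trim again; fitting once is the meaningful semantics.)
    """

    short_noncoding_labels: tuple[str, ...] = SHORT_NONCODING
    min_tpm: float = 5.0
    min_samples: int = 3
    drop_low_variability_fraction: float = 0.2
    variability_cutoff_: float | None = field(default=None, repr=False)

    def apply(self, tpm: pd.DataFrame, biotypes: pd.Series) -> pd.Index:
        biotypes = biotypes.reindex(tpm.index)
        if biotypes.isna().any():
            missing = list(biotypes.index[biotypes.isna()])[:10]
            raise KeyError(f"genes missing a biotype label: {missing}")
        step1 = tpm.loc[~biotypes.isin(self.short_noncoding_labels)]
        expressed = (step1 >= self.min_tpm).sum(axis=1) >= self.min_samples
        step2 = step1.loc[expressed]
        variability = np.log2(step2 + 1.0).std(axis=1, ddof=1)
        if self.variability_cutoff_ is None:
            order = variability.reset_index()
            order.columns = ["gene_id", "var"]
            order = order.sort_values(["var", "gene_id"], kind="mergesort")
            n_drop = int(np.floor(self.drop_low_variability_fraction * len(order)))
            dropped = set(order["gene_id"].iloc[:n_drop])
            # cutoff = variability of the first kept gene; re-application
            # keeps everything at or above it
            self.variability_cutoff_ = (
                float(order["var"].iloc[n_drop]) if n_drop < len(order) else np.inf
            )
            keep = [g for g in step2.index if g not in dropped]
            return pd.Index(keep)
        return step2.index[variability >= self.variability_cutoff_]


def filter_genes(
    tpm: pd.DataFrame,
    biotypes: pd.Series,
    short_noncoding_labels: tuple[str, ...] = SHORT_NONCODING,
    min_tpm: float = 5.0,
    min_samples: int = 3,
    drop_low_variability_fraction: float = 0.2,
) -> pd.Index:
    """Convenience wrapper fitting a fresh :class:`GeneFilter`."""
    flt = GeneFilter(
        short_noncoding_labels=short_noncoding_labels,
        min_tpm=min_tpm,
        min_samples=min_samples,
        drop_low_variability_fraction=drop_low_variability_fraction,
    )
    return flt.apply(tpm, biotypes)


def deg_call(
    de_table: pd.DataFrame,
    lfc_threshold: float = LFC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    lfc_bins: tuple[float, ...] = DEFAULT_LFC_BINS,
) -> pd.DataFrame:
    """DEG status per gene: up iff log2FC > 1 and p < 0.01 (strict), down symmetric.

    Also bins |log2FC| of DEGs into (1,2], (2,4], >4 style bins. Genes with
    missing p are reported not-significant with a warning.
    """
    lfc = de_table["log2fc"]
    p = de_table["p"]
    n_missing = int(p.isna().sum())
    if n_missing:
        logger.warning("deg_call: %d genes with missing p reported ns", n_missing)
    sig = p.notna() & (p < p_threshold)
    status = np.where(
        sig & (lfc > lfc_threshold), "up",
        np.where(sig & (lfc < -lfc_threshold), "down", "ns"),
    )
    edges = list(lfc_bins)
    bin_labels = [
        f"({edges[i]:g},{edges[i + 1]:g}]" if np.isfinite(edges[i + 1]) else f">{edges[i]:g}"
        for i in range(len(edges) - 1)
    ]
    abs_bin = pd.cut(lfc.abs(), bins=edges, labels=bin_labels)
    out = de_table.copy()
    out["deg_status"] = status
    out["lfc_bin"] = abs_bin.where(out["deg_status"] != "ns", other=pd.NA)
    return out


def pi_rank(de_table: pd.DataFrame) -> pd.DataFrame:
    """Genes ranked by pi-value = -log10(q) * log2FC, descending.

    q-values of exactly 0 are clamped to the smallest positive q observed
    (keeps ranks, avoids infinities). The result is suitable for export as
    an RNK-style two-column table.
    """
    q = de_table["q"].astype(float).copy()
    if (q < 0).any() or (q > 1).any():
        raise ValueError("q-values must lie in [0, 1]")
    positive = q[q > 0]
    floor = positive.min() if len(positive) else 1e-300
    q = q.clip(lower=floor)
    pi = -np.log10(q) * de_table["log2fc"]
    out = de_table.copy()
    out["pi_value"] = pi
    return out.sort_values("pi_value", ascending=False, kind="mergesort")


def deg_persistence(status_t1: pd.Series, status_t2: pd.Series) -> dict:
    """Fraction of t1 up-DEGs still up at t2 (and down analogue), plus switchers.

    Returns NaN fractions when a t1 class is empty. The t1 up set is
    partitioned into persisters (still up), switchers (now down) and
    dropouts (now ns); symmetrically for down.
    """
    if not status_t1.index.equals(status_t2.index):
        status_t2 = status_t2.reindex(status_t1.index)
        if status_t2.isna().any():
            raise ValueError("gene universes differ between timepoints")
    out = {}
    for direction, opposite in (("up", "down"), ("down", "up")):
        t1_set = status_t1.index[status_t1 == direction]
        if len(t1_set) == 0:
            logger.warning("deg_persistence: no %s-DEGs at t1", direction)
            out[f"persistence_{direction}"] = np.nan
            out[f"n_{direction}_t1"] = 0
            out[f"switchers_{direction}"] = 0
            out[f"dropouts_{direction}"] = 0
            continue
        later = status_t2.loc[t1_set]
        out[f"persistence_{direction}"] = float((later == direction).mean())
        out[f"n_{direction}_t1"] = int(len(t1_set))
        out[f"switchers_{direction}"] = int((later == opposite).sum())
        out[f"dropouts_{direction}"] = int((later == "ns").sum())
    return out


@dataclass
class ClusterResult:
    distance: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str]
    newick: str


def correlation_cluster(matrix: pd.DataFrame, axis: int = 1) -> ClusterResult:
    """UPGMA clustering on 1 - Spearman correlation distances.

    ``axis=1`` clusters columns (samples), ``axis=0`` rows. Ties in the
    underlying values get average ranks. Leaf order is deterministic: at
    every merge the subtree containing the smaller minimum input index
    goes left. Zero-variance items have undefined correlations and raise.
    """
    data = matrix if axis == 0 else matrix.T
    if data.shape[0] < 2:
        raise ValueError("need at least two items to cluster")
    if data.shape[1] < 3:
        raise ValueError("need at least three observations per item")
    variances = data.var(axis=1)
    dead = list(variances.index[variances == 0])
    if dead:
        raise ValueError(f"zero-variance items cannot be correlated: {dead}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(data.T).statistic
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-item case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    labels = list(data.index)
    linkage = average(squareform(dist, checks=False))

    n = len(labels)
    min_leaf: dict[int, int] = {i: i for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for i, (a, b, _, _) in enumerate(linkage):
        a, b = int(a), int(b)
        node = n + i
        left, right = (a, b) if min_leaf[a] <= min_leaf[b] else (b, a)
        children[node] = (left, right)
        min_leaf[node] = min(min_leaf[a], min_leaf[b])

    def _leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        l, r = children[node]
        return _leaves(l) + _leaves(r)

    def _newick(node: int, parent_height: float) -> str:
        if node < n:
            return f"{labels[node]}:{parent_height:.6g}"
        l, r = children[node]
        height = float(linkage[node - n, 2])
        inner = f"({_newick(l, height)},{_newick(r, height)})"
        return f"{inner}:{max(parent_height - height, 0.0):.6g}"

    root = n + len(linkage) - 1
    order = [labels[i] for i in _leaves(root)]
    newick = _newick(root, float(linkage[-1, 2])).rsplit(":", 1)[0] + ";"
    return ClusterResult(
        distance=pd.DataFrame(dist, index=labels, columns=labels),
        linkage=linkage,
        leaf_order=order,
        newick=newick,
    )
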