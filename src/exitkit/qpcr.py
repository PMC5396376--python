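"""High-throughput RT-qPCR processing.

The workflow follows the standard panel-QC route for microfluidic qPCR:
drop assays detected in fewer than half the samples, drop outlier samples
by a robust rule on per-sample detection scores, quantile-normalize Ct
values, impute missing wells from biological replicates, then express
everything relative to an overall limit of detection (LOD), defined as the
75% quantile of normalized Ct plus a constant of 10 cycles:

    log2 expression = LOD - normalized Ct,   absolute ~ 2 ** log2 expression.

Wells undetected across a whole replicate group sit at the LOD (log2
expression 0). Quantile conventions are linear-interpolation (NumPy
default) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOD_CONSTANT = 10.0
MAD_SCALE = 1.4826  # normal-consistency factor for the MAD


def filter_assays(
    ct: pd.DataFrame,
    detected: pd.DataFrame,
    quality: pd.DataFrame | None = None,
    min_detection: float = 0.5,
    quality_floor: float = 0.0,
) -> pd.Index:
    """Retain assays detected in at least ``min_detection`` of samples.

    Wells whose quality score falls below ``quality_floor`` count as
    undetected before the fraction is computed. The boundary is inclusive:
    exactly 50% detection is retained.
    """
    if not 0.0 <= min_detection <= 1.0:
        raise ValueError("min_detection must lie in [0, 1]")
    eff = detected.astype(bool)
    if quality is not None and quality_floor > 0:
        eff = eff & (quality >= quality_floor)
    frac = eff.mean(axis=1)
    kept = ct.index[frac >= min_detection]
    logger.info("filter_assays: retained %d of %d assays", len(kept), len(ct))
    return kept


def remove_outlier_samples(
    detected: pd.DataFrame,
    quality: pd.DataFrame | None = None,
    k: float = 3.0,
) -> tuple[pd.Index, pd.DataFrame]:
    """Flag samples whose aggregate detection score is a low outlier.

    The per-sample score is the mean over assays of the detection
    probability (the detected flag weighted by the well quality when
    available). A sample is an outlier when its score falls below
    median - k * MAD (MAD scaled by 1.4826 for normal consistency).
    Returns (retained sample index, per-sample report).
    """
    if detected.shape[1] < 4:
        raise ValueError("need at least four samples for outlier detection")
    prob = detected.astype(float)
    if quality is not None:
        prob = prob * quality
    score = prob.mean(axis=0)
    med = float(score.median())
    if np.isinf(k):
        threshold = -np.inf
    else:
        mad = MAD_SCALE * float((score - med).abs().median())
        threshold = med - k * mad
    outlier = score < threshold
    if outlier.all():
        raise ValueError("all samples flagged as outliers; degenerate panel")
    report = pd.DataFrame({"score": score, "outlier": outlier})
    removed = list(score.index[outlier])
    if removed:
        logger.info("remove_outlier_samples: removed %s", removed)
    return score.index[~outlier], report


def _reference_distribution(sorted_cols: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Mean of per-sample sorted observed values on a common quantile grid."""
    m = max(len(v) for v in sorted_cols)
    grid = np.linspace(0.0, 1.0, m) if m > 1 else np.array([0.5])
    acc = np.zeros_like(grid)
    for v in sorted_cols:
        if len(v) == 1:
            acc += v[0]
        else:
            pos = np.linspace(0.0, 1.0, len(v))
            acc += np.interp(grid, pos, v)
    return grid, acc / len(sorted_cols)


def quantile_normalize(ct: pd.DataFrame) -> pd.DataFrame:
    """Classical quantile normalization over the observed (non-NaN) wells.

    Per sample, sorted observed values are replaced by cross-sample rank
    means; tied raw values receive the mean of the implicated rank means.
    Samples with unequal numbers of observed wells are aligned through
    linear interpolation of the reference distribution on [0, 1].
    """
    cols = list(ct.columns)
    sorted_cols = []
    for c in cols:
        v = ct[c].dropna().to_numpy(float)
        if len(v) == 0:
            raise ValueError(f"sample {c!r} has no observed values")
        sorted_cols.append(np.sort(v))
    grid, ref = _reference_distribution(sorted_cols)

    out = ct.copy().astype(float)
    for c in cols:
        col = ct[c]
        obs = col.dropna()
        n = len(obs)
        order = np.argsort(obs.to_numpy(), kind="mergesort")
        pos = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
        mapped = np.interp(pos, grid, ref)
        normalized = np.empty(n)
        normalized[order] = mapped
        series = pd.Series(normalized, index=obs.index)
        # ties: average the assigned reference values within each tie group
        series = series.groupby(obs).transform("mean")
        out.loc[series.index, c] = series
    return out


def impute_replicates(
    ct_norm: pd.DataFrame, replicate_groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Fill missing wells with the assay mean over the sample's replicate group.

    Wells missing in every replicate stay NaN; they are set to the LOD at
    expression time. ``replicate_groups`` must cover every sample.
    """
    flat = [s for v in replicate_groups.values() for s in v]
    uncovered = [c for c in ct_norm.columns if c not in flat]
    if uncovered:
        raise ValueError(f"replicate_groups do not cover samples: {uncovered}")
    out = ct_norm.copy()
    for _, members in replicate_groups.items():
        members = [m for m in members if m in out.columns]
        if not members:
            continue
        block = out[members]
        group_mean = block.mean(axis=1)
        for m in members:
            miss = block[m].isna() & group_mean.notna()
            out.loc[miss, m] = group_mean[miss]
    return out


def quantile_normalize_impute(
    ct: pd.DataFrame, replicate_groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Quantile normalization followed by replicate-mean imputation."""
    return impute_replicates(quantile_normalize(ct), replicate_groups)


@dataclass
class ExpressionResult:
    lod: float
    ct_norm: pd.DataFrame  # NaN wells replaced by the LOD
    log2_expr: pd.DataFrame
    abs_expr: pd.DataFrame


def lod_and_express(ct_norm: pd.DataFrame, constant: float = LOD_CONSTANT) -> ExpressionResult:
    """Overall LOD (pooled Q75 of normalized Ct + constant) and expression.

    log2 expression = LOD - normalized Ct; absolute = 2 ** log2. Wells still
    missing after imputation are placed exactly at the LOD (log2 = 0).
    """
    values = ct_norm.to_numpy(float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("no observed Ct values")
    lod = float(np.quantile(finite, 0.75)) + constant
    filled = ct_norm.fillna(lod)
    log2_expr = lod - filled
    return ExpressionResult(
        lod=lod, ct_norm=filled, log2_expr=log2_expr, abs_expr=2.0 ** log2_expr
    )


def process_panel(
    ct: pd.DataFrame,
    detected: pd.DataFrame,
    quality: pd.DataFrame | None,
    replicate_groups: Mapping[str, Sequence[str]],
    min_detection: float = 0.5,
    outlier_k: float = 3.0,
    lod_constant: float = LOD_CONSTANT,
) -> tuple[ExpressionResult, dict]:
    """Full pipeline: assay filter, outlier removal, QN + imputation, LOD expression."""
    ct = ct.where(detected.astype(bool))
    assays = filter_assays(ct, detected, quality, min_detection=min_detection)
    ct, detected = ct.loc[assays], detected.loc[assays]
    quality = quality.loc[assays] if quality is not None else None

    samples, report = remove_outlier_samples(detected, quality, k=outlier_k)
    ct = ct[samples]
    groups = {
        g: [s for s in members if s in set(samples)]
        for g, members in replicate_groups.items()
    }
    groups = {g: m for g, m in groups.items() if m}
    completed = quantile_normalize_impute(ct, groups)
    result = lod_and_express(completed, constant=lod_constant)
    info = {
        "retained_assays": list(assays),
        "retained_samples": list(samples),
        "outlier_report": report,
    }
    return result, info
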