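"""Synthetic genomes, methylomes, count matrices, Ct tables and peak sets.

Every generator is a pure function of its parameters and seed, and exports
the planted ground truth (:class:`~exitkit.truth.TruthTables`) so each
downstream analysis stage can be validated closed-loop, without external
downloads.

The methylome generator encodes the temporal structure of an
ESC-differentiation experiment contrasting a control line with a knockout:
both conditions gain methylation between the first and second timepoint at
about a third of all tiles, the control then holds its methylome stable,
while the knockout loses methylation at a planted subset of tiles at the
final timepoint (and may gain at a small planted set). Differentially
methylated tiles are planted with effect sizes comfortably above the caller
threshold so recovery tests are well-posed.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import io as ekio
from .stats import bh_adjust
from .truth import TruthTables

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

# minimum planted |delta| (percentage points): caller threshold (20) + 5
MIN_PLANTED_DELTA = 25.0


# ---------------------------------------------------------------------------
# genome & annotation
# ---------------------------------------------------------------------------

def make_genome(
    chrom_lengths: Mapping[str, int], gc_fraction: float = 0.45, seed: int = 0
) -> dict[str, str]:
    """I.i.d. random genome at the requested GC content.

    Bases are drawn independently with P(C) = P(G) = gc_fraction / 2.
    """
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    probs = [at, gc, gc, at]
    return {
        chrom: "".join(rng.choice(_BASES, size=length, p=probs))
        for chrom, length in chrom_lengths.items()
    }


@dataclass
class Annotation:
    """Gene table plus named region-class interval sets."""

    genes: pd.DataFrame  # gene_id, chrom, strand, tss, start, end, exon_starts, exon_ends, biotype
    regions: dict[str, pd.DataFrame]  # label -> BED-like frame (chrom, start, end, name)
    chrom_lengths: dict[str, int]

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        ekio.write_gene_table(self.genes, os.path.join(outdir, "genes.tsv"))
        for label, df in self.regions.items():
            ekio.write_bed(df, os.path.join(outdir, f"regions_{label}.bed"))


_DEFAULT_BIOTYPES = {"protein_coding": 0.8, "lincRNA": 0.1, "miRNA": 0.1}


def make_annotation(
    n_genes: int,
    chrom_lengths: Mapping[str, int],
    biotype_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (2_000, 8_000),
    intergenic_range: tuple[int, int] = (500, 3_000),
) -> Annotation:
    """Place non-overlapping genes sequentially and draw auxiliary region sets.

    Region classes (enhancer, CGI, canyon, TE) are drawn uniformly on the
    chromosomes; all classes are guaranteed non-empty.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    mix = dict(biotype_mix or _DEFAULT_BIOTYPES)
    labels = sorted(mix)
    probs = np.array([mix[l] for l in labels], dtype=float)
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    rows = []
    ci, cursor = 0, 0
    for g in range(n_genes):
        length = int(rng.integers(*gene_length_range))
        gap = int(rng.integers(*intergenic_range))
        while ci < len(chroms) and cursor + gap + length > chrom_lengths[chroms[ci]]:
            ci, cursor = ci + 1, 0
        if ci >= len(chroms):
            raise ValueError(
                f"cannot fit gene {g + 1} of {n_genes}: chromosomes exhausted "
                f"({n_genes - g} genes overflow)"
            )
        start = cursor + gap
        end = start + length
        cursor = end
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else end - 1
        n_exons = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2, replace=False)) if n_exons > 1 else np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [length]])
        exon_starts = [start + int(bounds[2 * i]) for i in range(n_exons)]
        exon_ends = [start + int(bounds[2 * i + 1]) for i in range(n_exons)]
        rows.append(
            {
                "gene_id": f"gene{g + 1:05d}",
                "chrom": chroms[ci],
                "strand": strand,
                "tss": tss,
                "start": start,
                "end": end,
                "exon_starts": ",".join(map(str, exon_starts)),
                "exon_ends": ",".join(map(str, exon_ends)),
                "biotype": labels[int(rng.choice(len(labels), p=probs))],
            }
        )
    genes = pd.DataFrame(rows)

    def _uniform_regions(label: str, n: int, length_range: tuple[int, int]) -> pd.DataFrame:
        recs = []
        lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
        for i in range(n):
            chrom = chroms[int(rng.choice(len(chroms), p=lens / lens.sum()))]
            size = int(rng.integers(*length_range))
            size = min(size, chrom_lengths[chrom] - 1)
            start = int(rng.integers(0, chrom_lengths[chrom] - size))
            recs.append({"chrom": chrom, "start": start, "end": start + size, "name": f"{label}{i + 1}"})
        return pd.DataFrame(recs)

    regions = {
        "enhancer": _uniform_regions("enh", max(3, n_genes // 5), (500, 1_500)),
        "CGI": _uniform_regions("cgi", max(3, n_genes // 4), (400, 1_200)),
        "canyon": _uniform_regions("canyon", max(2, n_genes // 20), (5_000, 15_000)),
        "TE": _uniform_regions("te", max(5, n_genes // 2), (200, 600)),
    }
    return Annotation(genes=genes, regions=regions, chrom_lengths=dict(chrom_lengths))


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def make_design(
    conditions: Sequence[str] = ("ctrl", "ko"),
    timepoints: Sequence[str] = ("d0", "d4", "d6"),
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Sample sheet for a conditions x timepoints x replicates layout."""
    rows = [
        {"sample_id": f"{c}_{t}_r{r + 1}", "condition": c, "timepoint": t}
        for c in conditions
        for t in timepoints
        for r in range(n_replicates)
    ]
    return pd.DataFrame(rows)


@dataclass
class MethylomeSim:
    samples: dict[str, pd.DataFrame]  # sample_id -> CpG records (chrom, pos, meth, unmeth)
    truth: TruthTables
    design: pd.DataFrame
    tile_truth: pd.DataFrame  # per tile: chrom, start, end, baseline, gained

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        for sample_id, records in self.samples.items():
            ekio.write_bismark_coverage(records, os.path.join(outdir, f"{sample_id}.cov"))
        self.design.to_csv(os.path.join(outdir, "design.tsv"), sep="\t", index=False)
        self.tile_truth.to_csv(os.path.join(outdir, "truth_tiles.tsv"), sep="\t", index=False)
        self.truth.write(outdir)


def _anchored_tiles(chrom_lengths: Mapping[str, int], tile_size: int) -> pd.DataFrame:
    frames = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length - tile_size + 1, tile_size)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts}))
    tiles = pd.concat(frames, ignore_index=True)
    tiles["end"] = tiles["start"] + tile_size
    return tiles


def plant_dmr_tiles(
    chrom_lengths: Mapping[str, int],
    n_loss: int = 100,
    n_gain: int = 0,
    loss_delta: float = -30.0,
    gain_delta: float = 30.0,
    tile_size: int = 400,
    seed: int = 0,
) -> pd.DataFrame:
    """Choose distinct anchored tiles to carry planted DMRs.

    Loss tiles lose ``loss_delta`` points in the knockout at the last
    timepoint; gain tiles gain ``gain_delta``. Magnitudes below the caller
    threshold plus a 5-point margin are rejected.
    """
    for delta in (loss_delta, gain_delta):
        if (n_loss if delta == loss_delta else n_gain) and abs(delta) < MIN_PLANTED_DELTA:
            raise ValueError(
                f"planted |delta| must be >= {MIN_PLANTED_DELTA} percentage points, got {delta}"
            )
    tiles = _anchored_tiles(chrom_lengths, tile_size)
    if n_loss + n_gain > len(tiles):
        raise ValueError("more planted DMRs than available tiles")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(tiles), size=n_loss + n_gain, replace=False)
    planted = tiles.iloc[idx].reset_index(drop=True)
    planted["direction"] = ["loss"] * n_loss + ["gain"] * n_gain
    planted["delta"] = [loss_delta] * n_loss + [gain_delta] * n_gain
    return planted


def make_methylome(
    chrom_lengths: Mapping[str, int],
    design: pd.DataFrame,
    planted_dmrs: pd.DataFrame | None = None,
    depth_mean: float = 20.0,
    seed: int = 0,
    tile_size: int = 400,
    cpgs_per_tile: tuple[int, int] = (6, 12),
    gain_fraction: float = 0.34,
    gain_range: tuple[float, float] = (0.25, 0.40),
    hypo_mode_weight: float = 0.55,
    nb_size: float = 4.0,
    cpg_jitter_sd: float = 0.03,
) -> MethylomeSim:
    """Beta-binomial CpG methylomes over anchored tiles with planted DMRs.

    Per-tile baselines are drawn from a bimodal Beta mixture (hypo mode
    Beta(1,9), hyper mode Beta(9,1)) so per-site 5%-bin histograms are
    bimodal, as in real CpG methylomes. Coverage is truncated negative
    binomial (``nb_size`` controls over-dispersion, minimum one read);
    methylated counts are binomial at the programmed proportion.

    Trajectory: at timepoints after the first, a ``gain_fraction`` subset of
    tiles (both conditions) rises by a uniform draw from ``gain_range``.
    Planted DMRs act on the *last* timepoint of the *second* condition in
    ``design`` (loss tiles are picked from the gained set so they have
    headroom to fall).
    """
    if depth_mean < 1:
        raise ValueError("depth_mean must be >= 1")
    tiles = _anchored_tiles(chrom_lengths, tile_size)
    n_tiles = len(tiles)
    rng = np.random.default_rng(seed)

    conditions = list(dict.fromkeys(design["condition"]))
    timepoints = list(dict.fromkeys(design["timepoint"]))
    perturbed_condition = conditions[-1]
    final_timepoint = timepoints[-1]

    # per-tile baseline from the bimodal Beta mixture
    hypo = rng.random(n_tiles) < hypo_mode_weight
    base = np.where(hypo, rng.beta(1, 9, n_tiles), rng.beta(9, 1, n_tiles))
    base = np.clip(base, 0.02, 0.98)

    # global gain programme shared by both conditions
    gained = np.zeros(n_tiles, dtype=bool)
    if len(timepoints) > 1 and gain_fraction > 0:
        candidates = np.flatnonzero(base < 0.5)
        n_gain_tiles = min(int(round(gain_fraction * n_tiles)), len(candidates))
        gained[rng.choice(candidates, size=n_gain_tiles, replace=False)] = True
    gain_amount = np.where(gained, rng.uniform(*gain_range, n_tiles), 0.0)

    tile_key = tiles.set_index(["chrom", "start"]).index

    # resolve planted rows to tile indices
    planted = (
        planted_dmrs.copy()
        if planted_dmrs is not None
        else pd.DataFrame(columns=["chrom", "start", "end", "direction", "delta"])
    )
    if len(planted):
        small = np.abs(planted["delta"].to_numpy(float)) < MIN_PLANTED_DELTA
        if small.any():
            raise ValueError(
                f"planted |delta| must be >= {MIN_PLANTED_DELTA} percentage points"
            )
        mid = (planted["start"] + planted["end"]) // 2
        planted["start"] = (mid // tile_size) * tile_size
        planted["end"] = planted["start"] + tile_size
        locs = tile_key.get_indexer(pd.MultiIndex.from_frame(planted[["chrom", "start"]]))
        if (locs < 0).any():
            bad = planted.loc[locs < 0]
            raise ValueError(f"planted DMRs outside the genome: {bad.to_dict('records')}")
        planted["tile_index"] = locs
        # loss tiles follow the acquired-then-lost trajectory: they join the
        # gain programme (so the methylation they later lose was newly laid
        # down) and keep headroom for the full drop; gain tiles start low
        for i, row in planted.iterrows():
            j = int(row["tile_index"])
            if row["direction"] == "loss":
                need = abs(row["delta"]) / 100.0 + 0.07
                gained[j] = True
                if gain_amount[j] == 0.0:
                    gain_amount[j] = float(rng.uniform(*gain_range))
                base[j] = min(max(base[j], need - gain_amount[j]), 0.95 - gain_amount[j])
            else:
                ceil = 0.98 - row["delta"] / 100.0
                gained[j] = False
                gain_amount[j] = 0.0
                base[j] = min(base[j], max(0.02, ceil - 0.05))

    # programmed proportion per (condition, timepoint, tile)
    p_levels: dict[tuple[str, str], np.ndarray] = {}
    for cond in conditions:
        for ti, tp in enumerate(timepoints):
            p = base.copy()
            if ti > 0:
                p = np.clip(p + gain_amount, 0.02, 0.98)
            p_levels[(cond, tp)] = p
    if len(planted):
        key = (perturbed_condition, final_timepoint)
        p = p_levels[key].copy()
        j = planted["tile_index"].to_numpy(int)
        p[j] = np.clip(p[j] + planted["delta"].to_numpy(float) / 100.0, 0.02, 0.98)
        p_levels[key] = p

    # CpG sites, shared across all samples
    n_cpg = rng.integers(cpgs_per_tile[0], cpgs_per_tile[1] + 1, size=n_tiles)
    tile_of_site = np.repeat(np.arange(n_tiles), n_cpg)
    offsets = np.concatenate(
        [np.sort(rng.choice(tile_size - 1, size=k, replace=False)) for k in n_cpg]
    )
    site_pos = tiles["start"].to_numpy()[tile_of_site] + offsets
    site_chrom = tiles["chrom"].to_numpy()[tile_of_site]
    site_jitter = rng.normal(0.0, cpg_jitter_sd, size=len(site_pos))

    nb_p = nb_size / (nb_size + depth_mean)
    samples: dict[str, pd.DataFrame] = {}
    for row in design.itertuples(index=False):
        p_site = np.clip(p_levels[(row.condition, row.timepoint)][tile_of_site] + site_jitter, 0.01, 0.99)
        cov = np.maximum(1, rng.negative_binomial(nb_size, nb_p, size=len(p_site)))
        meth = rng.binomial(cov, p_site)
        samples[row.sample_id] = pd.DataFrame(
            {"chrom": site_chrom, "pos": site_pos, "meth": meth, "unmeth": cov - meth}
        )

    if len(planted):
        counts = pd.Series(tile_of_site).value_counts()
        planted["recoverable"] = [
            counts.get(int(j), 0) >= 3 for j in planted["tile_index"]
        ]
        for _, row in planted.loc[~planted["recoverable"]].iterrows():
            logger.warning(
                "planted DMR %s:%d-%d falls in a tile with <3 CpGs; flagged unrecoverable",
                row["chrom"], row["start"], row["end"],
            )
        planted["contrast"] = f"{perturbed_condition}:{final_timepoint}"
    truth = TruthTables(
        planted_dmrs=planted.drop(columns=["tile_index"], errors="ignore").reset_index(drop=True)
    )
    tile_truth = tiles.assign(baseline=base, gained=gained, gain_amount=gain_amount)
    return MethylomeSim(samples=samples, truth=truth, design=design.copy(), tile_truth=tile_truth)


# ---------------------------------------------------------------------------
# promoter motifs
# ---------------------------------------------------------------------------

_HALF_SITES = ("CACCTG", "TACCTG")  # concrete instances of YACCTG
_HALF_SITE_PATTERNS = ("[CT]ACCTG", "CAGGT[AG]")  # plus- and minus-strand half-sites


def _scrub_half_sites(seq_list: list[str], start: int, end: int) -> None:
    """Destroy every half-site occurrence in [start, end) in place."""
    import re

    window = "".join(seq_list[start:end])
    pat = re.compile("|".join(f"(?=({p}))" for p in _HALF_SITE_PATTERNS))
    for _ in range(10):  # mutations can create new sites; iterate to a fixed point
        hits = [m.start() for m in pat.finditer(window)]
        if not hits:
            break
        for h in hits:
            mid = h + 2
            window = window[:mid] + ("T" if window[mid] != "T" else "A") + window[mid + 1 :]
    seq_list[start:end] = list(window)


def plant_promoter_motifs(
    genome: Mapping[str, str],
    genes: pd.DataFrame,
    gene_ids: Sequence[str],
    flank: int = 2_000,
    max_gap: int = 40,
    seed: int = 0,
) -> tuple[dict[str, str], TruthTables]:
    """Plant exactly one bipartite half-site pair in each selected promoter.

    All YACCTG half-sites (either strand) are first scrubbed from *every*
    gene's promoter window so that afterwards a promoter carries a
    bipartite site iff its gene was selected — truth is exact, provided
    promoter windows do not overlap between genes. The pair uses concrete
    YACCTG instances with a uniform gap in [0, max_gap].
    """
    rng = np.random.default_rng(seed)
    seqs = {c: list(s) for c, s in genome.items()}
    windows = {}
    for gene in genes.itertuples(index=False):
        L = len(seqs[gene.chrom])
        w = (max(0, gene.tss - flank), min(L, gene.tss + flank))
        windows[gene.gene_id] = (gene.chrom, w)
        _scrub_half_sites(seqs[gene.chrom], *w)
    unknown = set(gene_ids) - set(windows)
    if unknown:
        raise KeyError(f"genes not in annotation: {sorted(unknown)}")
    for gene_id in gene_ids:
        chrom, (w0, w1) = windows[gene_id]
        a = _HALF_SITES[int(rng.integers(len(_HALF_SITES)))]
        b = _HALF_SITES[int(rng.integers(len(_HALF_SITES)))]
        gap = int(rng.integers(0, max_gap + 1))
        total = len(a) + gap + len(b)
        pos = int(rng.integers(w0, w1 - total))
        site = a + "".join(seqs[chrom][pos + len(a) : pos + len(a) + gap]) + b
        seqs[chrom][pos : pos + total] = list(site)
    out = {c: "".join(s) for c, s in seqs.items()}
    return out, TruthTables(planted_motif_promoters=list(gene_ids))


# ---------------------------------------------------------------------------
# counts / differential expression
# ---------------------------------------------------------------------------

@dataclass
class CountsSim:
    counts: pd.DataFrame  # genes x samples
    lengths: pd.Series
    biotypes: pd.Series
    de_table: pd.DataFrame  # log2fc, p, q per gene for the built-in contrast
    truth: TruthTables
    groups: dict[str, list[str]]

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        ekio.write_table(self.counts, os.path.join(outdir, "counts.tsv"))
        meta = pd.DataFrame({"length": self.lengths, "biotype": self.biotypes})
        ekio.write_table(meta, os.path.join(outdir, "gene_meta.tsv"))
        ekio.write_table(self.de_table, os.path.join(outdir, "de_table.tsv"))
        self.truth.write(outdir)


def nb_two_group_test(
    counts: pd.DataFrame, samples_a: Sequence[str], samples_b: Sequence[str]
) -> pd.DataFrame:
    """Simple per-gene two-group comparison on size-factor-normalized counts.

    Normalization uses median-of-ratios size factors (robust to asymmetric
    differential expression, unlike total-count scaling). The test is a
    Welch t on log2(normalized count + 1); log2FC is the difference of group
    means on that scale (B minus A); q by Benjamini-Hochberg. This is the
    closed-loop stand-in for the external differential-expression model
    whose per-gene (log2FC, p, q) table the pipeline consumes.
    """
    with np.errstate(divide="ignore"):
        logc = np.log(counts.to_numpy(dtype=float))
    finite = np.isfinite(logc).all(axis=1)
    log_geo = logc[finite].mean(axis=1)
    size_factors = np.exp(np.median(logc[finite] - log_geo[:, None], axis=0))
    norm = counts / size_factors
    log = np.log2(norm + 1.0)
    a = log[list(samples_a)].to_numpy()
    b = log[list(samples_b)].to_numpy()
    lfc = b.mean(axis=1) - a.mean(axis=1)
    t = sps.ttest_ind(b, a, axis=1, equal_var=False)
    out = pd.DataFrame({"log2fc": lfc, "p": t.pvalue}, index=counts.index)
    out["q"] = bh_adjust(out["p"])
    return out


def make_counts(
    gene_ids: Sequence[str],
    planted_log2fc: Mapping[str, float] | None = None,
    n_reps: tuple[int, int] = (3, 3),
    dispersion: float = 0.05,
    baseline_range: tuple[float, float] = (200.0, 2_000.0),
    biotypes: Mapping[str, str] | None = None,
    contrast: str = "b_vs_a",
    seed: int = 0,
) -> CountsSim:
    """Negative-binomial count matrix for a two-group design with planted DEGs.

    Counts ~ NB(mean = baseline * 2^(log2fc * [group B]), dispersion alpha):
    variance = mu + alpha * mu^2. Baselines are log-uniform over
    ``baseline_range``. The built-in two-group test provides the consumed
    (log2FC, p, q) table, and truth is exported.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if min(n_reps) < 2:
        raise ValueError("need >= 2 replicates per group")
    gene_ids = list(gene_ids)
    planted = dict(planted_log2fc or {})
    unknown = set(planted) - set(gene_ids)
    if unknown:
        raise ValueError(f"planted DEGs not in gene list: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    n = len(gene_ids)
    baseline = np.exp(rng.uniform(np.log(baseline_range[0]), np.log(baseline_range[1]), n))
    lfc_true = np.array([planted.get(g, 0.0) for g in gene_ids])

    samples_a = [f"a_r{i + 1}" for i in range(n_reps[0])]
    samples_b = [f"b_r{i + 1}" for i in range(n_reps[1])]
    size = 1.0 / dispersion  # NB "number of successes" parameterization

    def _draw(mu: np.ndarray, n_cols: int) -> np.ndarray:
        p = size / (size + mu)
        return rng.negative_binomial(size, p[:, None], size=(n, n_cols))

    mat = np.hstack([_draw(baseline, len(samples_a)), _draw(baseline * 2.0 ** lfc_true, len(samples_b))])
    counts = pd.DataFrame(mat, index=gene_ids, columns=samples_a + samples_b)
    counts.index.name = "gene_id"
    lengths = pd.Series(rng.integers(500, 5_000, n), index=gene_ids, name="length")
    if biotypes is None:
        biotypes = {g: "protein_coding" for g in gene_ids}
    bio = pd.Series({g: biotypes[g] for g in gene_ids}, name="biotype")

    de_table = nb_two_group_test(counts, samples_a, samples_b)
    truth = TruthTables(
        planted_degs=pd.DataFrame(
            {"gene_id": list(planted), "contrast": contrast, "true_log2fc": list(planted.values())}
        )
    )
    return CountsSim(
        counts=counts,
        lengths=lengths,
        biotypes=bio,
        de_table=de_table,
        truth=truth,
        groups={"a": samples_a, "b": samples_b},
    )


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

@dataclass
class CtSim:
    ct: pd.DataFrame  # assays x samples, NaN where undetected
    detected: pd.DataFrame
    quality: pd.DataFrame
    replicate_groups: dict[str, list[str]]
    truth: TruthTables
    planted_log2fc: pd.DataFrame  # assay_id, contrast, true_log2fc

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        ekio.write_table(self.ct, os.path.join(outdir, "ct.tsv"))
        ekio.write_table(self.detected.astype(int), os.path.join(outdir, "detected.tsv"))
        ekio.write_table(self.quality, os.path.join(outdir, "quality.tsv"))
        self.planted_log2fc.to_csv(os.path.join(outdir, "truth_ct_log2fc.tsv"), sep="\t", index=False)
        self.truth.write(outdir)


def _default_replicate_groups(sample_ids: list[str], size: int = 3) -> dict[str, list[str]]:
    return {
        f"g{i // size + 1}": sample_ids[i : i + size] for i in range(0, len(sample_ids), size)
    }


def make_ct_table(
    n_assays: int,
    n_samples: int,
    replicate_groups: Mapping[str, Sequence[str]] | None = None,
    dropout_rate: float = 0.05,
    n_outlier_samples: int = 0,
    planted_log2fc: Mapping[str, float] | None = None,
    contrast: tuple[str, str] | None = None,
    seed: int = 0,
    outlier_shift: float = 6.0,
    outlier_extra_dropout: float = 0.45,
) -> CtSim:
    """Normal-model Ct table with dropout, planted outlier samples and fold changes.

    Ct per well = assay level (U(18, 30)) + sample shift (N(0, 0.5)) + noise
    (N(0, 0.25)). Outlier samples get a +``outlier_shift`` cycle global shift
    (>= 5) and strongly elevated dropout. ``planted_log2fc`` lowers the Ct of
    ``contrast[1]``-group samples by the given log2 amount (one cycle = one
    log2 unit of expression).
    """
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must lie in [0, 1)")
    assay_ids = [f"assay{i + 1:03d}" for i in range(n_assays)]
    sample_ids = [f"s{i + 1:02d}" for i in range(n_samples)]
    if replicate_groups is None:
        groups = _default_replicate_groups(sample_ids)
    else:
        groups = {g: list(v) for g, v in replicate_groups.items()}
        flat = [s for v in groups.values() for s in v]
        if sorted(flat) != sorted(sample_ids) or len(flat) != len(set(flat)):
            raise ValueError("replicate_groups must partition the sample set")

    planted = dict(planted_log2fc or {})
    unknown = set(planted) - set(assay_ids)
    if unknown:
        raise ValueError(f"planted fold-change assays not in panel: {sorted(unknown)}")
    if planted and contrast is None:
        raise ValueError("contrast=(group_ref, group_alt) required with planted_log2fc")

    rng = np.random.default_rng(seed)
    assay_level = rng.uniform(18.0, 30.0, n_assays)
    sample_shift = rng.normal(0.0, 0.5, n_samples)
    outliers = sorted(rng.choice(sample_ids, size=n_outlier_samples, replace=False))
    out_mask = np.array([s in outliers for s in sample_ids])
    sample_shift = sample_shift + np.where(out_mask, outlier_shift, 0.0)

    ct = assay_level[:, None] + sample_shift[None, :] + rng.normal(0.0, 0.25, (n_assays, n_samples))
    if planted:
        alt = set(groups[contrast[1]])
        alt_cols = np.array([s in alt for s in sample_ids])
        for assay, lfc in planted.items():
            ct[assay_ids.index(assay), alt_cols] -= lfc

    drop_p = np.where(out_mask, min(0.95, dropout_rate + outlier_extra_dropout), dropout_rate)
    detected = rng.random((n_assays, n_samples)) >= drop_p[None, :]
    quality = np.where(detected, rng.uniform(0.6, 1.0, (n_assays, n_samples)), 0.0)
    ct = np.where(detected, ct, np.nan)

    mk = lambda arr: pd.DataFrame(arr, index=assay_ids, columns=sample_ids)
    truth = TruthTables(outlier_samples=outliers)
    lfc_df = pd.DataFrame(
        {
            "assay_id": list(planted),
            "contrast": f"{contrast[1]}_vs_{contrast[0]}" if contrast else "",
            "true_log2fc": list(planted.values()),
        }
    )
    return CtSim(
        ct=mk(ct),
        detected=mk(detected),
        quality=mk(quality),
        replicate_groups=groups,
        truth=truth,
        planted_log2fc=lfc_df,
    )


# ---------------------------------------------------------------------------
# ChIP peaks
# ---------------------------------------------------------------------------

@dataclass
class PeaksSim:
    peaks: pd.DataFrame  # chrom, start, end, name
    truth: TruthTables

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        ekio.write_bed(self.peaks, os.path.join(outdir, "peaks.bed"))
        self.truth.write(outdir)


def make_peaks(
    regions_of_interest: pd.DataFrame,
    n_target: int,
    n_background: int,
    jitter_sd: float,
    chrom_lengths: Mapping[str, int],
    seed: int = 0,
    halfwidth_range: tuple[int, int] = (75, 200),
) -> PeaksSim:
    """Peaks centered on region midpoints (Gaussian jitter) plus uniform background."""
    if n_target > len(regions_of_interest):
        raise ValueError("n_target exceeds the number of regions of interest")
    rng = np.random.default_rng(seed)
    regions = regions_of_interest.reset_index(drop=True)
    names = (
        regions["name"].astype(str)
        if "name" in regions.columns
        else pd.Series([f"region{i}" for i in range(len(regions))])
    )

    rows = []
    targets: list[str] = []
    idx = rng.choice(len(regions), size=n_target, replace=False)
    for k, i in enumerate(idx):
        r = regions.iloc[i]
        mid = int((r["start"] + r["end"]) // 2 + np.rint(rng.normal(0.0, jitter_sd)))
        hw = int(rng.integers(*halfwidth_range))
        length = chrom_lengths[r["chrom"]]
        start, end = mid - hw, mid + hw
        if start < 0 or end > length:
            logger.info("peak at %s:%d clipped to chromosome bounds", r["chrom"], mid)
            start, end = max(0, start), min(length, end)
        rows.append({"chrom": r["chrom"], "start": start, "end": end, "name": f"target_peak{k + 1}"})
        targets.append(str(names.iloc[i]))

    chroms = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    for k in range(n_background):
        chrom = chroms[int(rng.choice(len(chroms), p=lens / lens.sum()))]
        hw = int(rng.integers(*halfwidth_range))
        mid = int(rng.integers(hw, chrom_lengths[chrom] - hw))
        rows.append(
            {"chrom": chrom, "start": mid - hw, "end": mid + hw, "name": f"bg_peak{k + 1}"}
        )
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return PeaksSim(peaks=peaks, truth=TruthTables(planted_peak_targets=targets))
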