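"""Bipartite E-box motif scanning and promoter enrichment.

Zeb2 binds DNA through two zinc-finger clusters that each contact a
CACCT(G)-class half-site, so a functional site is a *pair* of half-sites
within a bounded gap. Two parameterizations ship as presets:

- ``methods``: two YACCTG half-sites, gap <= 40 bp (the default);
- ``results-fig2d``: CACCTG plus CACCT, gap <= 45 bp.

Hits are searched on both strands (minus-strand hits by scanning the
reverse complement) and reported in plus-strand coordinates. Enrichment of
promoters carrying >= 1 site among differentially expressed genes versus
the genome-wide promoter background uses one-sided Fisher exact tests.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import fisher_one_sided_p, odds_ratio

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]", "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

PRESETS = {
    "methods": {"motif_a": "YACCTG", "motif_b": "YACCTG", "max_gap": 40},
    "results-fig2d": {"motif_a": "CACCTG", "motif_b": "CACCT", "max_gap": 45},
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def iupac_regex(pattern: str) -> str:
    try:
        return "".join(IUPAC[ch] for ch in pattern.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC symbol {exc.args[0]!r} in pattern {pattern!r}") from exc


def find_motif(sequence: str, pattern: str) -> list[tuple[int, int]]:
    """All (possibly overlapping) occurrences of an IUPAC pattern, as [start, end)."""
    regex = re.compile(f"(?=({iupac_regex(pattern)}))")
    width = len(pattern)
    return [(m.start(), m.start() + width) for m in regex.finditer(sequence.upper())]


def _pairs(first: list[tuple[int, int]], second: list[tuple[int, int]], max_gap: int):
    for s1, e1 in first:
        for s2, e2 in second:
            gap = s2 - e1
            if 0 <= gap <= max_gap:
                yield s1, e1, s2, e2, gap


def scan_bipartite(
    sequence: str,
    motif_a: str = "YACCTG",
    motif_b: str = "YACCTG",
    max_gap: int = 40,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Find all non-overlapping half-site pairs with gap in [0, max_gap].

    The gap runs from the end of the first half-site to the start of the
    second (0 means adjacent; half-sites never overlap). When the two
    half-site motifs differ, both orders (a-then-b and b-then-a) are
    counted once each. Minus-strand hits are located on the reverse
    complement and reported in plus-strand coordinates; ``start_first``
    etc. always refer to scan orientation. Rows are sorted by
    (strand, start_first).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    seq = sequence.upper()

    def _scan_strand(s: str, strand: str) -> list[dict]:
        occ_a = find_motif(s, motif_a)
        occ_b = find_motif(s, motif_b)
        found = set(_pairs(occ_a, occ_b, max_gap))
        if motif_a.upper() != motif_b.upper():
            found |= set(_pairs(occ_b, occ_a, max_gap))
        rows = []
        for s1, e1, s2, e2, gap in found:
            if strand == "+":
                c1, c2 = (s1, e1), (s2, e2)
            else:  # map reverse-complement coordinates back to plus strand
                L = len(s)
                c1, c2 = (L - e1, L - s1), (L - e2, L - s2)
            rows.append(
                {
                    "strand": strand,
                    "start_first": c1[0], "end_first": c1[1],
                    "start_second": c2[0], "end_second": c2[1],
                    "gap": gap,
                    "site_first": s[s1:e1], "site_second": s[s2:e2],
                }
            )
        return rows

    rows = _scan_strand(seq, "+")
    if both_strands:
        rows += _scan_strand(reverse_complement(seq), "-")
    out = pd.DataFrame(
        rows,
        columns=[
            "strand", "start_first", "end_first", "start_second", "end_second",
            "gap", "site_first", "site_second",
        ],
    )
    return out.sort_values(["strand", "start_first", "start_second"]).reset_index(drop=True)


def extract_promoters(
    genes: pd.DataFrame,
    genome: Mapping[str, str],
    flank: int = 2_000,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Promoter windows [TSS - flank, TSS + flank) with plus-strand sequence.

    Windows are clipped at chromosome ends (flagged in the ``clipped``
    column). Sequences are returned as plus-strand text for all genes.
    """
    windows = []
    seqs: dict[str, str] = {}
    for gene in genes.itertuples(index=False):
        if gene.chrom not in genome:
            raise KeyError(f"gene {gene.gene_id}: unknown chromosome {gene.chrom!r}")
        chrom_seq = genome[gene.chrom]
        length = len(chrom_seq)
        start, end = gene.tss - flank, gene.tss + flank
        clipped = start < 0 or end > length
        if clipped:
            logger.info("promoter of %s clipped to chromosome bounds", gene.gene_id)
        start, end = max(0, start), min(length, end)
        windows.append(
            {
                "gene_id": gene.gene_id, "chrom": gene.chrom, "strand": gene.strand,
                "start": start, "end": end, "clipped": clipped,
            }
        )
        seqs[gene.gene_id] = str(chrom_seq[start:end]).upper()
    return pd.DataFrame(windows), seqs


def promoter_hit_table(sequences: Mapping[str, str], **scan_kwargs) -> pd.DataFrame:
    """Per-gene bipartite-hit count and presence flag."""
    rows = []
    for gene_id, seq in sequences.items():
        hits = scan_bipartite(seq, **scan_kwargs)
        rows.append({"gene_id": gene_id, "n_hits": len(hits), "has_hit": len(hits) > 0})
    out = pd.DataFrame(rows, columns=["gene_id", "n_hits", "has_hit"])
    return out.set_index("gene_id")


@dataclass
class EnrichmentResult:
    k_fg: int
    n_fg: int
    k_bg: int
    n_bg: int
    odds_ratio: float
    p_over: float
    p_under: float


def fisher_enrichment(k_fg: int, n_fg: int, k_bg: int, n_bg: int) -> EnrichmentResult:
    """One-sided Fisher exact tests on the 2x2 table
    [[k_fg, n_fg - k_fg], [k_bg, n_bg - k_bg]].

    ``p_over`` is the upper hypergeometric tail (over-representation of the
    motif among foreground promoters), ``p_under`` the lower tail. The odds
    ratio gets a Haldane 0.5 correction when any cell is zero.
    """
    if min(k_fg, n_fg, k_bg, n_bg) < 0:
        raise ValueError("counts must be non-negative")
    if k_fg > n_fg or k_bg > n_bg:
        raise ValueError("hit counts cannot exceed set sizes")
    if n_fg < 1 or n_bg < 1:
        raise ValueError("set sizes must be >= 1")
    a, b, c, d = k_fg, n_fg - k_fg, k_bg, n_bg - k_bg
    return EnrichmentResult(
        k_fg=k_fg, n_fg=n_fg, k_bg=k_bg, n_bg=n_bg,
        odds_ratio=float(odds_ratio(a, b, c, d)),
        p_over=float(fisher_one_sided_p(a, b, c, d, "greater")),
        p_under=float(fisher_one_sided_p(a, b, c, d, "less")),
    )


def deg_motif_report(
    deg_partitions: Mapping[str, Sequence[str]],
    hit_table: pd.DataFrame,
    background: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Enrichment of motif-bearing promoters per DEG partition vs background.

    ``deg_partitions`` maps partition names (e.g. up/down/all) to gene id
    lists; the background defaults to every gene in the hit table and, per
    the genome-wide convention, includes the foreground genes. Empty
    partitions are omitted with a warning.
    """
    bg_ids = list(background) if background is not None else list(hit_table.index)
    missing_bg = [g for g in bg_ids if g not in hit_table.index]
    if missing_bg:
        raise KeyError(f"background genes missing from hit table: {missing_bg[:10]}")
    has_hit = hit_table["has_hit"]
    k_bg = int(has_hit.loc[bg_ids].sum())
    n_bg = len(bg_ids)

    rows = []
    for name, ids in deg_partitions.items():
        ids = list(ids)
        if not ids:
            logger.warning("deg_motif_report: partition %r is empty, omitted", name)
            continue
        missing = [g for g in ids if g not in hit_table.index]
        if missing:
            raise KeyError(f"DEG ids missing from hit table: {missing[:10]}")
        res = fisher_enrichment(int(has_hit.loc[ids].sum()), len(ids), k_bg, n_bg)
        rows.append(
            {
                "partition": name, "k_fg": res.k_fg, "n_fg": res.n_fg,
                "k_bg": res.k_bg, "n_bg": res.n_bg, "odds_ratio": res.odds_ratio,
                "p_over": res.p_over, "p_under": res.p_under,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["partition", "k_fg", "n_fg", "k_bg", "n_bg", "odds_ratio", "p_over", "p_under"],
    )
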