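"""Planted ground truth exported next to every synthetic data set.

Every generator in :mod:`exitkit.synthetic` returns one of these alongside
its data files, so recovery tests read generated files plus truth and never
re-derive hidden state.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

_DMR_COLS = ["chrom", "start", "end", "direction", "delta", "contrast", "recoverable"]
_DEG_COLS = ["gene_id", "contrast", "true_log2fc"]


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame(columns=columns)


@dataclass
class TruthTables:
    """Planted features of a synthetic data set.

    planted_dmrs: one row per differentially methylated tile
        (chrom, start, end, direction in {gain, loss}, delta in percentage
        points, contrast label, recoverable flag).
    planted_degs: one row per differentially expressed gene.
    planted_motif_promoters: gene ids whose promoter carries >=1 bipartite site.
    planted_peak_targets: region ids that received centered ChIP peaks.
    outlier_samples: sample ids generated as low-quality outliers.
    """

    planted_dmrs: pd.DataFrame = field(default_factory=lambda: _empty(_DMR_COLS))
    planted_degs: pd.DataFrame = field(default_factory=lambda: _empty(_DEG_COLS))
    planted_motif_promoters: list[str] = field(default_factory=list)
    planted_peak_targets: list[str] = field(default_factory=list)
    outlier_samples: list[str] = field(default_factory=list)

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        self.planted_dmrs.to_csv(os.path.join(outdir, "truth_dmrs.tsv"), sep="\t", index=False)
        self.planted_degs.to_csv(os.path.join(outdir, "truth_degs.tsv"), sep="\t", index=False)
        for name, values in [
            ("truth_motif_promoters.tsv", self.planted_motif_promoters),
            ("truth_peak_targets.tsv", self.planted_peak_targets),
            ("truth_outlier_samples.tsv", self.outlier_samples),
        ]:
            pd.Series(values, name="id", dtype=object).to_csv(
                os.path.join(outdir, name), sep="\t", index=False
            )

    @classmethod
    def read(cls, outdir: str | os.PathLike) -> "TruthTables":
        outdir = os.fspath(outdir)

        def _list(name: str) -> list[str]:
            df = pd.read_csv(os.path.join(outdir, name), sep="\t")
            return [] if df.empty else df["id"].astype(str).tolist()

        return cls(
            planted_dmrs=pd.read_csv(
                os.path.join(outdir, "truth_dmrs.tsv"), sep="\t", dtype={"chrom": str}
            ),
            planted_degs=pd.read_csv(os.path.join(outdir, "truth_degs.tsv"), sep="\t"),
            planted_motif_promoters=_list("truth_motif_promoters.tsv"),
            planted_peak_targets=_list("truth_peak_targets.tsv"),
            outlier_samples=_list("truth_outlier_samples.tsv"),
        )
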