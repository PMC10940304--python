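"""FPKM matrix handling: log transform, low-expression filter, DE summary.

The upstream read processing (alignment, assembly, abundance estimation,
differential testing) is consumed, not reproduced: inputs are an FPKM table
(genes x samples) and a differential-expression table with log2 fold
changes and FDR values.  Filtering is the family-analysis rule — genes
whose arithmetic mean FPKM across all samples is strictly below 1 are
discarded before any transformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FPKM_THRESHOLD = 1.0
FDR_CUTOFF = 0.05


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM values; ``transformed`` marks log2(FPKM+1) state."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    transformed: bool = False

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def read_fpkm(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return ExpressionMatrix(values=df.astype(float))


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "tissue", "condition_pair", "log2fc", "fdr"}
    if not required.issubset(df.columns):
        raise ValueError(f"DE table needs columns {sorted(required)}")
    return df


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(FPKM + 1); refuses to transform twice."""
    if m.transformed:
        raise ValueError("matrix is already log2(FPKM+1)-transformed")
    return ExpressionMatrix(values=np.log2(m.values + 1.0), transformed=True)


def filter_low_expression(
    m: ExpressionMatrix, threshold: float = FPKM_THRESHOLD
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes with mean FPKM strictly below ``threshold`` (raw scale).

    A mean exactly at the threshold is kept.  Returns the kept matrix and
    the dropped gene ids.
    """
    if m.transformed:
        raise ValueError("filter operates on raw FPKM, before transformation")
    means = m.values.mean(axis=1)
    dropped = list(means.index[means < threshold])
    kept = ExpressionMatrix(values=m.values.drop(index=dropped), transformed=False)
    return kept, dropped


def de_summary(det: pd.DataFrame, fdr_cutoff: float = FDR_CUTOFF) -> pd.DataFrame:
    """Per tissue x condition counts of significant up/down genes.

    Significant means ``fdr < fdr_cutoff``; up is ``log2fc > 0``, down is
    ``log2fc < 0``.  A significant row with log2fc exactly 0 counts as
    neither and is logged.
    """
    if ((det["fdr"] < 0) | (det["fdr"] > 1)).any():
        raise ValueError("FDR values must lie in [0, 1]")
    rows = []
    for (tissue, pair), grp in det.groupby(["tissue", "condition_pair"], sort=True):
        sig = grp[grp["fdr"] < fdr_cutoff]
        up = sig[sig["log2fc"] > 0]
        down = sig[sig["log2fc"] < 0]
        n_zero = len(sig) - len(up) - len(down)
        if n_zero:
            logger.warning(
                "%s/%s: %d significant gene(s) with log2FC == 0 counted neither up nor down",
                tissue, pair, n_zero,
            )
        rows.append(
            {
                "tissue": tissue,
                "condition_pair": pair,
                "n_up": len(up),
                "n_down": len(down),
                "up_genes": ",".join(sorted(up["gene_id"])),
                "down_genes": ",".join(sorted(down["gene_id"])),
            }
        )
    return pd.DataFrame(
        rows, columns=["tissue", "condition_pair", "n_up", "n_down", "up_genes", "down_genes"]
    )


def stage_specificity(
    m: ExpressionMatrix, groups: dict[str, list[str]] | None = None
) -> pd.DataFrame:
    """Per-gene dominant sample group and specificity score, on raw FPKM.

    Score is (max group mean) / (sum of group means); a uniform gene scores
    1/n_groups, a one-group gene scores 1.  Zero-total genes get a NaN
    score and a flag.  The dominant group is the first maximum in column
    order (deterministic).
    """
    if groups is None:
        groups = {s: [s] for s in m.samples}
    means = pd.DataFrame(
        {g: m.values[cols].mean(axis=1) for g, cols in groups.items()}
    )
    total = means.sum(axis=1)
    argmax = means.idxmax(axis=1)  # first max in column order
    score = means.max(axis=1) / total
    out = pd.DataFrame(
        {
            "dominant_group": argmax,
            "specificity": score,
            "undefined": total == 0,
        }
    )
    out.loc[out["undefined"], "specificity"] = float("nan")
    out.loc[out["undefined"], "dominant_group"] = ""
    out.index.name = "gene_id"
    return out


def cluster_order(m: ExpressionMatrix) -> list[str]:
    """Gene order for heatmap-style output: complete linkage, correlation
    distance, on transformed rows.  Constant rows sort first (correlation
    undefined; distance treated as maximal)."""
    from scipy.cluster.hierarchy import complete, leaves_list
    from scipy.spatial.distance import pdist

    vals = m.values if m.transformed else np.log2(m.values + 1.0)
    if len(vals) < 3:
        return list(vals.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = pdist(vals.values, metric="correlation")
    d = np.nan_to_num(d, nan=2.0)
    order = leaves_list(complete(d))
    return [vals.index[i] for i in order]
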