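"""Expression-derived evidence layers.

Tissue-specificity z-scores, the expressed-gene filter, fold-change
differential gene sets and Fisher's-exact gene-set enrichment. These layers
score and validate an inferred risk-gene set against transcriptomic and
proteomic evidence; differential-expression statistics themselves (DESeq,
LIMMA, MAST) are consumed as pre-computed gene sets, not re-derived here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "load_expression_matrix",
    "tissue_specificity_z",
    "expressed_gene_filter",
    "differential_gene_set",
    "EnrichmentResult",
    "fisher_enrichment",
]


def load_expression_matrix(path) -> pd.DataFrame:
    """Load a genes x tissues/samples TSV (first column gene id, header labels)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if (df.values < 0).any():
        raise ValueError("expression matrix contains negative values")
    if df.columns.duplicated().any():
        raise ValueError("duplicate column labels")
    return df


def tissue_specificity_z(
    mat: pd.DataFrame,
    gene: str,
    tissue: str,
    ddof: int = 1,
    log_transform: bool = False,
) -> float:
    """Tissue-specificity z-score of one gene in one tissue.

    z_E(i, t) = (E(i, t) - <E(i)>) / delta_E(i), the gene's expression in
    tissue t standardized against its own mean and SD across all tissues.
    The SD uses the sample estimator (ddof=1) by default. A constant gene
    (zero SD) returns 0 with a warning rather than raising, so genome-wide
    sweeps never abort. ``log_transform`` applies log2(x + 1) first.
    """
    if gene not in mat.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    if tissue not in mat.columns:
        raise KeyError(f"tissue {tissue!r} not in matrix")
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    row = mat.loc[gene].astype(float)
    if log_transform:
        row = np.log2(row + 1.0)
    sd = row.std(ddof=ddof)
    if sd == 0:
        logger.warning("gene %s constant across tissues; z set to 0", gene)
        return 0.0
    return float((row[tissue] - row.mean()) / sd)


def expressed_gene_filter(
    mat: pd.DataFrame,
    cpm_threshold: float = 0.5,
    sample_fraction: float = 0.9,
) -> set[str]:
    """Genes expressed at CPM >= threshold in over ``sample_fraction`` of samples.

    The value comparison is inclusive (>= 0.5) but the sample-fraction
    comparison is strict (> 90%), matching the stated filter exactly.
    """
    frac = (mat >= cpm_threshold).mean(axis=1)
    return set(frac.index[frac > sample_fraction].astype(str))


def differential_gene_set(
    case_mean: dict[str, float] | pd.Series,
    control_mean: dict[str, float] | pd.Series,
    fc_threshold: float = 1.2,
    pseudocount: float = 1e-9,
) -> set[str]:
    """Two-sided fold-change gene set: max(case/ctrl, ctrl/case) > threshold.

    Both over- and under-expression count as differential. Zero means are
    stabilized with a small pseudocount. Requires a shared gene universe.
    """
    case = pd.Series(case_mean, dtype=float)
    ctrl = pd.Series(control_mean, dtype=float)
    shared = case.index.intersection(ctrl.index)
    if len(shared) == 0:
        raise ValueError("case and control gene universes are disjoint")
    c = case[shared] + pseudocount
    k = ctrl[shared] + pseudocount
    fc = np.maximum(c / k, k / c)
    return set(shared[fc > fc_threshold].astype(str))


@dataclass
class EnrichmentResult:
    """Fisher's exact test of overlap between two gene sets in a universe."""

    overlap: int
    n_a: int
    n_b: int
    n_universe: int
    odds_ratio: float  # inf when a zero cell makes it undefined upward
    p_value: float

    @property
    def table(self) -> list[list[int]]:
        k, a, b, n = self.overlap, self.n_a, self.n_b, self.n_universe
        return [[k, a - k], [b - k, n - a - b + k]]


def fisher_enrichment(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> EnrichmentResult:
    """Two-sided Fisher's exact test on the 2x2 overlap table.

    The table partitions the universe into (a AND b, a only, b only, rest);
    the odds ratio is the unconditional ad/bc (inf/0 on zero cells).
    """
    if len(universe) < 2:
        raise ValueError("universe must have at least 2 genes")
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("set_a and set_b must be subsets of the universe")
    k = len(set_a & set_b)
    a, b, n = len(set_a), len(set_b), len(universe)
    table = np.array([[k, a - k], [b - k, n - a - b + k]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(
        overlap=k, n_a=a, n_b=b, n_universe=n,
        odds_ratio=float(odds), p_value=float(p),
    )
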