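"""Differential-expression screen for short developmental time series.

A gene is called significant in a condition when its expression is unusual
relative to the other genes measured in the same condition, by either of two
deterministic threshold rules:

* mean rule: the gene's time-averaged expression is at least one cross-gene
  standard deviation above the cross-gene mean of those time averages,
  ``mean_t(G) >= mean_g(mean_t) + sd_g(mean_t)``;
* variability rule: the gene's temporal standard deviation is at least one
  cross-gene standard deviation above the cross-gene mean of those
  standard deviations, ``sd_t(G) >= mean_g(sd_t) + sd_g(sd_t)``.

Subscript ``t`` denotes statistics taken along a gene's time series,
subscript ``g`` statistics taken across genes.  Both comparisons are
inclusive.  A perfectly flat gene (``sd_t = 0``) is never selected by the
variability rule — a constant series is not "highly fluctuating" even when
the whole matrix is flat and the threshold degenerates to zero.

Root-specific gene sets are derived by leaf exclusion: genes significant in
a root condition are dropped if they are also significant in the leaf track,
either of the matching season (default) or of any season (strict mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ConditionKey, ExpressionMatrix


@dataclass
class SignificanceStats:
    """Per-gene time statistics plus the cross-gene thresholds."""

    condition: ConditionKey
    mean_t: pd.Series  # per-gene mean over timepoints
    sd_t: pd.Series  # per-gene sd over timepoints
    mu_of_means: float
    sd_of_means: float
    mu_of_sds: float
    sd_of_sds: float
    sd_mode: str = "sample"

    @property
    def t1_threshold(self) -> float:
        return self.mu_of_means + self.sd_of_means

    @property
    def t2_threshold(self) -> float:
        return self.mu_of_sds + self.sd_of_sds


@dataclass
class SignificantGeneSet:
    """Selected genes for one condition, with the criterion that fired."""

    condition: ConditionKey
    genes: set[str]
    basis: dict[str, str]  # gene -> "mean" | "variability" | "both"

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def compute_stats(matrix: ExpressionMatrix, sd_mode: str = "sample") -> SignificanceStats:
    """Compute per-gene time statistics and cross-gene thresholds.

    ``sd_mode`` selects the standard-deviation denominator in both the time
    and gene directions: ``"sample"`` (n-1, the default of common
    spreadsheet functions) or ``"population"`` (n).
    """
    if sd_mode not in ("sample", "population"):
        raise ValueError(f"sd_mode must be 'sample' or 'population', got {sd_mode!r}")
    ddof = 1 if sd_mode == "sample" else 0
    if len(matrix.genes) < 2:
        raise ValueError(f"{matrix.condition.label}: need >= 2 genes, got {len(matrix.genes)}")
    if matrix.n_timepoints < 2:
        raise ValueError(
            f"{matrix.condition.label}: need >= 2 timepoints, got {matrix.n_timepoints}"
        )
    mean_t = matrix.values.mean(axis=1)
    sd_t = matrix.values.std(axis=1, ddof=ddof)
    return SignificanceStats(
        condition=matrix.condition,
        mean_t=mean_t,
        sd_t=sd_t,
        mu_of_means=float(mean_t.mean()),
        sd_of_means=float(mean_t.std(ddof=ddof)),
        mu_of_sds=float(sd_t.mean()),
        sd_of_sds=float(sd_t.std(ddof=ddof)),
        sd_mode=sd_mode,
    )


def select_significant(stats: SignificanceStats) -> SignificantGeneSet:
    """Apply the mean / variability rules (inclusive thresholds, OR logic)."""
    genes: set[str] = set()
    basis: dict[str, str] = {}
    t1, t2 = stats.t1_threshold, stats.t2_threshold
    for gene in stats.mean_t.index:
        by_mean = stats.mean_t[gene] >= t1
        by_var = stats.sd_t[gene] > 0 and stats.sd_t[gene] >= t2
        if by_mean or by_var:
            genes.add(gene)
            basis[gene] = "both" if (by_mean and by_var) else ("mean" if by_mean else "variability")
    return SignificantGeneSet(condition=stats.condition, genes=genes, basis=basis)


def screen(matrix: ExpressionMatrix, sd_mode: str = "sample") -> SignificantGeneSet:
    """Convenience: compute_stats followed by select_significant."""
    return select_significant(compute_stats(matrix, sd_mode=sd_mode))


def root_specific(
    root_sets: dict[ConditionKey, SignificantGeneSet],
    leaf_sets: dict[ConditionKey, SignificantGeneSet],
    mode: str = "season",
) -> dict[ConditionKey, SignificantGeneSet]:
    """Drop genes from root sets that are also significant in leaf tracks.

    ``mode="season"`` excludes each root condition's genes found in the leaf
    set of the same season; ``mode="global"`` excludes the union of leaf
    sets over both seasons.  Basis annotations of surviving genes are kept.
    """
    if mode not in ("season", "global"):
        raise ValueError(f"leaf exclusion mode must be 'season' or 'global', got {mode!r}")
    global_leaf: set[str] = set()
    for s in leaf_sets.values():
        global_leaf |= s.genes
    out: dict[ConditionKey, SignificantGeneSet] = {}
    for cond, rset in root_sets.items():
        if mode == "season":
            excl = set()
            for lcond, lset in leaf_sets.items():
                if lcond.season == cond.season:
                    excl |= lset.genes
        else:
            excl = global_leaf
        kept = rset.genes - excl
        out[cond] = SignificantGeneSet(
            condition=cond,
            genes=kept,
            basis={g: b for g, b in rset.basis.items() if g in kept},
        )
    return out


def stats_report(stats: SignificanceStats, selected: SignificantGeneSet) -> pd.DataFrame:
    """Per-condition report table: one row per gene with thresholds and call."""
    rows = []
    for gene in sorted(stats.mean_t.index):
        rows.append(
            {
                "gene_id": gene,
                "mean_t": stats.mean_t[gene],
                "sd_t": stats.sd_t[gene],
                "t1_threshold": stats.t1_threshold,
                "t2_threshold": stats.t2_threshold,
                "selected": gene in selected.genes,
                "basis": selected.basis.get(gene, ""),
            }
        )
    return pd.DataFrame(rows)
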