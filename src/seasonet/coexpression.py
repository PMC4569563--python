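"""Per-condition Pearson co-expression networks and cross-condition comparison.

Gene pairs whose expression time series correlate with |PCC| at or above a
threshold (default 0.5, inclusive) form an undirected network per
condition.  Zero-variance (flat) genes have undefined correlation; such
pairs are excluded with a warning rather than assigned 0, since assigning 0
would silently assert independence.

Two condition networks are compared pair-wise on edge identity (pairs are
order-free): an edge present in both is *sign-flipped* when the product of
its two correlations is negative, otherwise shared with the same sign;
everything else is unique to one network.  Sign flips between seasonal
crops are the analysis's readout of condition-dependent regulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ConditionKey, ExpressionMatrix, PrecipitationSeries

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def _pair(a: str, b: str) -> Pair:
    """Canonical order-free pair key."""
    return (a, b) if a <= b else (b, a)


def pearson(x, y) -> float:
    """Product-moment correlation between two equal-length series.

    Returns NaN (the undefined-correlation signal) when either series has
    zero variance; the caller decides how to treat it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    if x.size < 3:
        raise ValueError(f"need >= 3 paired observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def pairwise_pcc(matrix: ExpressionMatrix, genes=None) -> pd.DataFrame:
    """Symmetric PCC table over the requested genes (default: all).

    The diagonal is defined as 1.  Entries involving a zero-variance gene
    are NaN (flagged undefined, never silently 0).
    """
    if genes is None:
        genes = matrix.genes
    genes = list(genes)
    unknown = [g for g in genes if g not in matrix.values.index]
    if unknown:
        raise KeyError(f"genes absent from matrix: {unknown}")
    data = matrix.values.loc[genes].to_numpy(dtype=float)
    flat = np.ptp(data, axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    corr = np.atleast_2d(corr)
    corr[flat, :] = np.nan
    corr[:, flat] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=genes, columns=genes)


@dataclass(frozen=True)
class CoexpressionEdge:
    """Undirected correlation edge; ``pair`` is sorted, so {a,b} == {b,a}."""

    pair: Pair
    pcc: float
    condition: ConditionKey

    @property
    def sign(self) -> int:
        return 1 if self.pcc >= 0 else -1


@dataclass
class ConditionNetwork:
    """Thresholded co-expression network for one condition."""

    condition: ConditionKey | None
    nodes: set[str]
    edges: dict[Pair, float] = field(default_factory=dict)  # pair -> pcc
    threshold: float = 0.5

    def __post_init__(self) -> None:
        for (a, b), r in self.edges.items():
            if a == b:
                raise ValueError(f"self-edge on {a}")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a},{b}) endpoint outside node set")
            if abs(r) < self.threshold:
                raise ValueError(f"edge ({a},{b}) below threshold: |{r}| < {self.threshold}")

    @property
    def edge_list(self) -> list[CoexpressionEdge]:
        return [
            CoexpressionEdge(pair=p, pcc=r, condition=self.condition)
            for p, r in sorted(self.edges.items())
        ]

    def __len__(self) -> int:
        return len(self.edges)


def build_network(
    pcc_table: pd.DataFrame,
    nodes,
    threshold: float = 0.5,
    condition: ConditionKey | None = None,
) -> ConditionNetwork:
    """Keep every defined pair with |PCC| >= threshold (inclusive).

    Pairs with undefined correlation (a flat gene) are excluded with a
    logged warning.
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    nodes = sorted(nodes)
    missing = [g for g in nodes if g not in pcc_table.index]
    if missing:
        raise KeyError(f"nodes absent from PCC table: {missing}")
    edges: dict[Pair, float] = {}
    n_undefined = 0
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            r = float(pcc_table.at[a, b])
            if np.isnan(r):
                n_undefined += 1
                continue
            if abs(r) >= threshold:
                edges[_pair(a, b)] = r
    if n_undefined:
        logger.warning(
            "%d gene pair(s) had undefined correlation (flat series) and were excluded",
            n_undefined,
        )
    return ConditionNetwork(
        condition=condition, nodes=set(nodes), edges=edges, threshold=threshold
    )


def network_from_matrix(
    matrix: ExpressionMatrix, nodes=None, threshold: float = 0.5
) -> ConditionNetwork:
    """Convenience: pairwise PCC over ``nodes`` then threshold."""
    nodes = sorted(nodes) if nodes is not None else matrix.genes
    table = pairwise_pcc(matrix, nodes)
    return build_network(table, nodes, threshold=threshold, condition=matrix.condition)


@dataclass
class NetworkComparison:
    """Edge-identity partition of two condition networks."""

    shared_same_sign: set[Pair]
    shared_sign_flipped: set[Pair]
    unique_a: set[Pair]
    unique_b: set[Pair]

    @property
    def n_shared(self) -> int:
        return len(self.shared_same_sign) + len(self.shared_sign_flipped)

    @property
    def unique_fraction_a(self) -> float:
        total = self.n_shared + len(self.unique_a)
        return len(self.unique_a) / total if total else float("nan")

    @property
    def unique_fraction_b(self) -> float:
        total = self.n_shared + len(self.unique_b)
        return len(self.unique_b) / total if total else float("nan")


def compare_networks(a: ConditionNetwork, b: ConditionNetwork) -> NetworkComparison:
    """Partition the two edge sets into shared (same sign / sign-flipped)
    and unique pairs.

    A pair counts as sign-flipped only when it exceeds the threshold in
    *both* networks with correlations of opposite sign (pcc_a * pcc_b < 0);
    a pair above threshold in one network and below in the other is unique,
    not flipped.
    """
    pairs_a, pairs_b = set(a.edges), set(b.edges)
    shared = pairs_a & pairs_b
    flipped = {p for p in shared if a.edges[p] * b.edges[p] < 0}
    return NetworkComparison(
        shared_same_sign=shared - flipped,
        shared_sign_flipped=flipped,
        unique_a=pairs_a - shared,
        unique_b=pairs_b - shared,
    )


def env_response(gene_series, precip: PrecipitationSeries) -> float:
    """Correlation of one gene's series with aligned precipitation.

    Ranks environment-driven genes (expression tracking rainfall) against
    network-driven ones; NaN when either series is constant.
    """
    return pearson(gene_series, precip.values)


def env_response_table(
    matrix: ExpressionMatrix, precip: PrecipitationSeries, genes=None
) -> pd.DataFrame:
    genes = list(genes) if genes is not None else matrix.genes
    rows = [
        {
            "gene_id": g,
            "condition": matrix.condition.label,
            "pcc_precipitation": env_response(matrix.series(g), precip),
        }
        for g in sorted(genes)
    ]
    return pd.DataFrame(rows)
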