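"""TF-target network extraction from a co-expression network.

Co-expression edges touching at least one annotated transcription factor
are retained; the TF endpoint is labelled the putative regulator.  Because
the parent edges are symmetric correlations, TF -> target orientation is a
regulatory hypothesis (to be checked against promoter evidence), not a
causal claim; TF-TF edges keep both orientations and carry a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .coexpression import ConditionNetwork, Pair
from .model import ConditionKey


@dataclass(frozen=True)
class TRNEdge:
    tf: str
    target: str
    pcc: float
    condition: ConditionKey | None
    tf_tf: bool

    @property
    def pair(self) -> Pair:
        a, b = self.tf, self.target
        return (a, b) if a <= b else (b, a)


@dataclass
class TRN:
    condition: ConditionKey | None
    edges: list[TRNEdge]
    tf_set: set[str]

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def pairs(self) -> set[Pair]:
        return {e.pair for e in self.edges}


def extract_trn(network: ConditionNetwork, tf_set: set[str]) -> TRN:
    """Keep exactly the edges with at least one endpoint in ``tf_set``.

    TF-TF edges are listed in both orientations with ``tf_tf=True``;
    target-target edges are dropped.  Deterministic edge order (by pair,
    then regulator).
    """
    if not tf_set:
        raise ValueError("tf_set is empty; annotate at least one transcription factor")
    edges: list[TRNEdge] = []
    for (a, b), r in sorted(network.edges.items()):
        a_tf, b_tf = a in tf_set, b in tf_set
        if not (a_tf or b_tf):
            continue
        if a_tf and b_tf:
            edges.append(TRNEdge(tf=a, target=b, pcc=r, condition=network.condition, tf_tf=True))
            edges.append(TRNEdge(tf=b, target=a, pcc=r, condition=network.condition, tf_tf=True))
        elif a_tf:
            edges.append(TRNEdge(tf=a, target=b, pcc=r, condition=network.condition, tf_tf=False))
        else:
            edges.append(TRNEdge(tf=b, target=a, pcc=r, condition=network.condition, tf_tf=False))
    return TRN(condition=network.condition, edges=edges, tf_set=set(tf_set))


def hub_degree(trn: TRN) -> list[tuple[str, int]]:
    """Per-TF count of distinct non-TF targets, descending.

    Ties break lexicographically by gene id so the ranking is deterministic.
    A hub — a TF regulating many targets — is the network's candidate
    master regulator.
    """
    targets: dict[str, set[str]] = {e.tf: set() for e in trn.edges}
    for e in trn.edges:
        if not e.tf_tf:
            targets[e.tf].add(e.target)
    return sorted(
        ((tf, len(ts)) for tf, ts in targets.items()),
        key=lambda kv: (-kv[1], kv[0]),
    )


def trn_table(trn: TRN) -> pd.DataFrame:
    rows = [
        {
            "tf": e.tf,
            "target": e.target,
            "pcc": e.pcc,
            "condition": e.condition.label if e.condition else "",
            "tf_tf": e.tf_tf,
        }
        for e in trn.edges
    ]
    return pd.DataFrame(rows, columns=["tf", "target", "pcc", "condition", "tf_tf"])
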