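"""End-to-end orchestration: screen -> root-specific filter -> networks ->
comparisons -> TRN -> promoters -> element scan -> edge confirmation.

Every intermediate is written as a plain TSV and every network additionally
as Cytoscape-readable SIF and GraphML, so each stage can be inspected or
re-run independently.  A run is fully determined by its inputs and
configuration: re-running with the same config reproduces a byte-identical
output tree, and the report carries a config hash as provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .coexpression import (
    ConditionNetwork,
    NetworkComparison,
    compare_networks,
    env_response_table,
    network_from_matrix,
)
from .expression_io import (
    align_precipitation,
    load_annotations,
    load_expression,
    load_precipitation,
    reconcile_annotations,
)
from .model import ConditionKey, SEASONS
from .promoter import (
    confirm_edges,
    evidence_table,
    extract_promoter,
    hits_table,
    load_elements,
    load_genome,
    open_gff,
    scan_promoter,
    write_promoters_fasta,
)
from .significance import compute_stats, root_specific, select_significant, stats_report
from .trn import TRN, extract_trn, hub_degree, trn_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    expression: str
    annotations: str | None = None
    precipitation: dict[str, str] = field(default_factory=dict)  # season -> path
    genome: str | None = None
    gff: str | None = None
    elements: str | None = None
    out_dir: str = "seasonet_out"
    pcc_threshold: float = 0.5
    promoter_len: int = 2000
    sd_mode: str = "sample"
    leaf_exclusion_mode: str = "season"
    network_scope: str = "subset"  # or "union"

    def validate(self) -> None:
        if not 0 <= self.pcc_threshold <= 1:
            raise ValueError(f"pcc_threshold must be in [0, 1], got {self.pcc_threshold}")
        if self.promoter_len < 1:
            raise ValueError("promoter_len must be positive")
        if self.sd_mode not in ("sample", "population"):
            raise ValueError(f"invalid sd_mode {self.sd_mode!r}")
        if self.leaf_exclusion_mode not in ("season", "global"):
            raise ValueError(f"invalid leaf_exclusion_mode {self.leaf_exclusion_mode!r}")
        if self.network_scope not in ("subset", "union"):
            raise ValueError(f"invalid network_scope {self.network_scope!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return {
            "expression": self.expression,
            "annotations": self.annotations,
            "precipitation": dict(sorted(self.precipitation.items())),
            "genome": self.genome,
            "gff": self.gff,
            "elements": self.elements,
            "out_dir": self.out_dir,
            "pcc_threshold": self.pcc_threshold,
            "promoter_len": self.promoter_len,
            "sd_mode": self.sd_mode,
            "leaf_exclusion_mode": self.leaf_exclusion_mode,
            "network_scope": self.network_scope,
        }

    @property
    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def network_to_graph(network: ConditionNetwork, tf_set: set[str] | None = None) -> nx.Graph:
    g = nx.Graph()
    for node in sorted(network.nodes):
        g.add_node(node, is_tf=bool(tf_set and node in tf_set))
    for (a, b), r in sorted(network.edges.items()):
        g.add_edge(
            a,
            b,
            pcc=float(r),
            sign=1 if r >= 0 else -1,
            condition=network.condition.label if network.condition else "",
        )
    return g


def trn_to_graph(trn: TRN) -> nx.DiGraph:
    g = nx.DiGraph()
    for e in trn.edges:
        g.add_node(e.tf, is_tf=True)
        g.add_node(e.target, is_tf=e.target in trn.tf_set)
        g.add_edge(
            e.tf,
            e.target,
            pcc=float(e.pcc),
            sign=1 if e.pcc >= 0 else -1,
            condition=e.condition.label if e.condition else "",
            tf_tf=e.tf_tf,
        )
    return g


def export_network(obj, fmt: str, path) -> None:
    """Write a co-expression network or TRN as SIF or GraphML.

    SIF uses interaction type ``pp`` for co-expression edges and ``reg``
    for directed TF -> target edges.
    """
    path = Path(path)
    if fmt == "sif":
        lines = []
        if isinstance(obj, TRN):
            for e in obj.edges:
                lines.append(f"{e.tf}\treg\t{e.target}")
        elif isinstance(obj, ConditionNetwork):
            for (a, b) in sorted(obj.edges):
                lines.append(f"{a}\tpp\t{b}")
        else:
            raise TypeError(f"cannot export {type(obj).__name__}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        g = trn_to_graph(obj) if isinstance(obj, TRN) else network_to_graph(obj)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}; use 'sif' or 'graphml'")


def read_sif(path) -> set[tuple[str, str]]:
    """Parse a SIF file back to an order-free edge-pair set."""
    pairs = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        a, _, b = line.split("\t")
        pairs.add((a, b) if a <= b else (b, a))
    return pairs


def _comparison_row(label_a: str, label_b: str, cmp: NetworkComparison) -> dict:
    return {
        "network_a": label_a,
        "network_b": label_b,
        "shared_same_sign": len(cmp.shared_same_sign),
        "shared_sign_flipped": len(cmp.shared_sign_flipped),
        "unique_a": len(cmp.unique_a),
        "unique_b": len(cmp.unique_b),
        "unique_fraction_a": cmp.unique_fraction_a,
        "unique_fraction_b": cmp.unique_fraction_b,
        "flipped_pairs": ";".join(f"{a}-{b}" for a, b in sorted(cmp.shared_sign_flipped)),
    }


def run_all(config: PipelineConfig) -> dict:
    """Execute the whole analysis; returns the run report (also written as
    ``report.json`` in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrices = load_expression(config.expression)
    annset = load_annotations(config.annotations) if config.annotations else None
    if annset is not None:
        annset = reconcile_annotations(annset, matrices)
    tf_set = annset.tf_set if annset else set()

    # --- significance screen per condition -------------------------------
    screens = {}
    for cond in sorted(matrices):
        stats = compute_stats(matrices[cond], sd_mode=config.sd_mode)
        selected = select_significant(stats)
        screens[cond] = selected
        stats_report(stats, selected).to_csv(
            out / f"significance_{cond.label}.tsv", sep="\t", index=False
        )

    root_screens = {c: s for c, s in screens.items() if c.is_root}
    leaf_screens = {c: s for c, s in screens.items() if not c.is_root}
    specific = root_specific(root_screens, leaf_screens, mode=config.leaf_exclusion_mode)
    for cond, sset in sorted(specific.items()):
        pd.DataFrame(
            {"gene_id": sorted(sset.genes), "basis": [sset.basis[g] for g in sorted(sset.genes)]}
        ).to_csv(out / f"root_specific_{cond.label}.tsv", sep="\t", index=False)

    # --- per-condition networks ------------------------------------------
    union_nodes = sorted(set().union(*(s.genes for s in specific.values())) if specific else set())
    networks: dict[ConditionKey, ConditionNetwork] = {}
    for cond, sset in sorted(specific.items()):
        nodes = union_nodes if config.network_scope == "union" else sorted(sset.genes)
        nodes = [g for g in nodes if g in matrices[cond].values.index]
        if len(nodes) < 2:
            networks[cond] = ConditionNetwork(
                condition=cond, nodes=set(nodes), edges={}, threshold=config.pcc_threshold
            )
        else:
            networks[cond] = network_from_matrix(
                matrices[cond], nodes, threshold=config.pcc_threshold
            )
        net = networks[cond]
        pd.DataFrame(
            [
                {"gene_a": a, "gene_b": b, "pcc": r, "sign": 1 if r >= 0 else -1}
                for (a, b), r in sorted(net.edges.items())
            ],
            columns=["gene_a", "gene_b", "pcc", "sign"],
        ).to_csv(out / f"network_{cond.label}.tsv", sep="\t", index=False)
        export_network(net, "sif", out / f"network_{cond.label}.sif")
        export_network(net, "graphml", out / f"network_{cond.label}.graphml")

    # --- cross-condition comparisons -------------------------------------
    conds = sorted(networks)
    comparison_rows = []
    comparisons: dict[tuple[ConditionKey, ConditionKey], NetworkComparison] = {}
    for i, ca in enumerate(conds):
        for cb in conds[i + 1 :]:
            cmp = compare_networks(networks[ca], networks[cb])
            comparisons[(ca, cb)] = cmp
            comparison_rows.append(_comparison_row(ca.label, cb.label, cmp))
    pd.DataFrame(comparison_rows).to_csv(out / "network_comparisons.tsv", sep="\t", index=False)

    # --- TRN extraction and hubs ------------------------------------------
    trns: dict[ConditionKey, TRN] = {}
    hub_rows = []
    if tf_set:
        for cond, net in sorted(networks.items()):
            trn = extract_trn(net, tf_set)
            trns[cond] = trn
            trn_table(trn).to_csv(out / f"trn_{cond.label}.tsv", sep="\t", index=False)
            export_network(trn, "sif", out / f"trn_{cond.label}.sif")
            export_network(trn, "graphml", out / f"trn_{cond.label}.graphml")
            for tf, deg in hub_degree(trn):
                hub_rows.append({"condition": cond.label, "tf": tf, "n_targets": deg})
        pd.DataFrame(hub_rows, columns=["condition", "tf", "n_targets"]).to_csv(
            out / "hub_ranking.tsv", sep="\t", index=False
        )

    # --- promoters, scan, confirmation ------------------------------------
    evidence_rows = pd.DataFrame()
    n_confirmed = n_unconfirmed = 0
    if config.genome and config.gff and config.elements and trns:
        genome = load_genome(config.genome)
        db = open_gff(config.gff)
        elements = load_elements(config.elements)
        wanted = sorted({e.target for trn in trns.values() for e in trn.edges}
                        | {e.tf for trn in trns.values() for e in trn.edges})
        promoters = {}
        for gene in wanted:
            try:
                promoters[gene] = extract_promoter(genome, db, gene, max_len=config.promoter_len)
            except (KeyError, ValueError) as exc:
                logger.warning("promoter extraction failed for %s: %s", gene, exc)
        write_promoters_fasta(promoters, out / "promoters.fa")
        all_hits = []
        for gene in sorted(promoters):
            all_hits.extend(scan_promoter(promoters[gene], elements))
        hits_table(all_hits).to_csv(out / "motif_hits.tsv", sep="\t", index=False)
        evs = []
        family_map = annset.family_map if annset else {}
        for cond, trn in sorted(trns.items()):
            evs.extend(confirm_edges(trn, promoters, elements, family_map))
        evidence_rows = evidence_table(evs)
        evidence_rows.to_csv(out / "edge_evidence.tsv", sep="\t", index=False)
        n_confirmed = int((evidence_rows["status"] == "confirmed").sum()) if len(evidence_rows) else 0
        n_unconfirmed = int((evidence_rows["status"] == "unconfirmed").sum()) if len(evidence_rows) else 0

    # --- environment response ---------------------------------------------
    if config.precipitation:
        env_rows = []
        for cond, net in sorted(networks.items()):
            path = config.precipitation.get(cond.season)
            if not path:
                continue
            precip = align_precipitation(load_precipitation(path), matrices[cond])
            env_rows.append(env_response_table(matrices[cond], precip, sorted(specific[cond].genes)))
        if env_rows:
            pd.concat(env_rows, ignore_index=True).to_csv(
                out / "env_response.tsv", sep="\t", index=False
            )

    # --- report ------------------------------------------------------------
    report = {
        "provenance": {
            "tool": "seasonet",
            "version": __version__,
            "config_hash": config.config_hash,
            "config": {k: v for k, v in config.to_dict().items() if k != "out_dir"},
        },
        "significant_counts": {c.label: len(s.genes) for c, s in sorted(screens.items())},
        "root_specific_counts": {c.label: len(s.genes) for c, s in sorted(specific.items())},
        "root_specific_genes": {c.label: sorted(s.genes) for c, s in sorted(specific.items())},
        "edge_counts": {c.label: len(n) for c, n in sorted(networks.items())},
        "comparisons": comparison_rows,
        "hub_ranking": hub_rows,
        "edge_evidence": {
            "confirmed": n_confirmed,
            "unconfirmed": n_unconfirmed,
            "total": int(len(evidence_rows)),
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
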