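"""Promoter extraction and IUPAC cis-element scanning.

Promoters are defined as up to 2000 bp upstream of the translation start
site (TLS, the first base of the coding sequence) — not the transcription
start site, so annotated 5'UTRs fall inside the "promoter" by design.
Coordinates follow GFF3: 1-based, inclusive.  On the plus strand the
promoter is the genomic interval ``[max(1, TLS - max_len), TLS - 1]`` read
forward; on the minus strand it is ``[TLS + 1, min(chrom_len, TLS + max_len)]``
reverse-complemented, so the returned sequence always reads 5'->3' towards
the gene.  Truncation at a chromosome boundary shortens the region ("up to"
2000 bp).

The scanner matches IUPAC degenerate consensi exactly (presence/absence, no
position-weight scoring) on both strands, overlapping matches included.
An ``N`` in the promoter matches nothing; IUPAC codes in the consensus
match their standard nucleotide sets.  Hit offsets are relative to the TLS
in gene orientation: offset -1 is the base immediately upstream of the
start codon, and a hit's offset is the position of the 5'-most base of its
matched window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .model import CisElement
from .trn import TRN, TRNEdge

#: IUPAC degenerate nucleotide codes -> matched base sets.
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp_iupac(consensus: str) -> str:
    """Reverse complement of an IUPAC consensus (degenerate codes included)."""
    return consensus.upper().translate(_COMPLEMENT)[::-1]


def _iupac_regex(consensus: str) -> re.Pattern:
    parts = []
    for letter in consensus.upper():
        if letter not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {letter!r} in consensus {consensus!r}")
        bases = IUPAC[letter]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({''.join(parts)}))")


@dataclass
class PromoterRegion:
    """Up-to-2-kb upstream-of-TLS region, oriented 5'->3' towards the gene."""

    gene: str
    chrom: str
    start: int  # 1-based inclusive, genomic
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene}: strand must be + or -")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"{self.gene}: coordinate span {self.end - self.start + 1} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def fasta_header(self) -> str:
        return f"{self.gene}|{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class MotifHit:
    element: CisElement
    gene: str
    offset: int  # 5'-most base of the match, relative to TLS; -1 = just upstream
    strand: str  # relative to the gene
    matched: str  # literal promoter substring (gene orientation)


@dataclass
class EdgeEvidence:
    """Promoter-based verdict on one TF -> target regulatory hypothesis."""

    edge: TRNEdge
    hits: list[MotifHit]
    status: str  # confirmed | unconfirmed | no-promoter | no-element

    @property
    def n_hits(self) -> int:
        return len(self.hits)


def _tls_and_strand(db: gffutils.FeatureDB, gene: str) -> tuple[str, int, str, gffutils.Feature]:
    try:
        feature = db[gene]
    except gffutils.FeatureNotFoundError:
        raise KeyError(f"gene {gene!r} absent from the GFF3 annotation") from None
    mrnas = list(db.children(feature, featuretype="mRNA", order_by="start"))
    parent = mrnas[0] if mrnas else feature  # primary transcript = first listed
    cds = list(db.children(parent, featuretype="CDS", order_by="start"))
    if not cds:
        raise ValueError(f"gene {gene!r} has no CDS feature; cannot place the TLS")
    strand = feature.strand
    if strand not in "+-":
        raise ValueError(f"gene {gene!r} has no strand; cannot orient the promoter")
    tls = min(c.start for c in cds) if strand == "+" else max(c.end for c in cds)
    return feature.seqid, tls, strand, feature


def load_genome(fasta_path) -> dict[str, str]:
    """Chromosome id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}


def open_gff(gff_path) -> gffutils.FeatureDB:
    return gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )


def extract_promoter(
    genome: dict[str, str],
    db: gffutils.FeatureDB,
    gene: str,
    max_len: int = 2000,
) -> PromoterRegion:
    """Extract the up-to-``max_len`` bp promoter upstream of the gene's TLS."""
    chrom, tls, strand, _ = _tls_and_strand(db, gene)
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} absent from genome FASTA")
    seq = genome[chrom]
    chrom_len = len(seq)
    if strand == "+":
        if tls <= 1:
            raise ValueError(f"gene {gene!r}: TLS at position 1, empty promoter")
        start, end = max(1, tls - max_len), tls - 1
        region = seq[start - 1 : end]
    else:
        if tls >= chrom_len:
            raise ValueError(f"gene {gene!r}: TLS at chromosome end, empty promoter")
        start, end = tls + 1, min(chrom_len, tls + max_len)
        region = str(Seq(seq[start - 1 : end]).reverse_complement())
    return PromoterRegion(gene=gene, chrom=chrom, start=start, end=end, strand=strand, sequence=region)


def scan_promoter(region: PromoterRegion, elements: list[CisElement]) -> list[MotifHit]:
    """All matches of each element on both strands of the promoter.

    Overlapping matches are reported; hits are sorted by offset then strand.
    A minus-strand hit means the element's consensus occurs on the strand
    opposite the promoter sequence; its ``matched`` string is still the
    promoter-orientation substring of the window.
    """
    seq = region.sequence.upper()
    length = len(seq)
    hits: list[MotifHit] = []
    for element in elements:
        for strand, consensus in (("+", element.consensus), ("-", revcomp_iupac(element.consensus))):
            pattern = _iupac_regex(consensus)
            for m in pattern.finditer(seq):
                i = m.start()
                hits.append(
                    MotifHit(
                        element=element,
                        gene=region.gene,
                        offset=i - length,
                        strand=strand,
                        matched=seq[i : i + len(consensus)],
                    )
                )
    hits.sort(key=lambda h: (h.offset, h.strand, h.element.name))
    return hits


def confirm_edges(
    trn: TRN,
    promoters: dict[str, PromoterRegion],
    elements: list[CisElement],
    family_map: dict[str, str],
) -> list[EdgeEvidence]:
    """Check each TF -> target edge for the TF family's elements in the
    target's promoter.

    ``confirmed`` requires at least one hit; a missing target promoter gives
    status ``no-promoter`` and a TF family with no element in the table
    gives ``no-element`` (neither is counted as evidence against the edge).
    TF-TF edges arrive in both orientations from the TRN and are evaluated
    per orientation.
    """
    if not elements:
        raise ValueError("element table is empty")
    by_family: dict[str, list[CisElement]] = {}
    for el in elements:
        by_family.setdefault(el.tf_family, []).append(el)
    evidence: list[EdgeEvidence] = []
    for edge in trn.edges:
        family = family_map.get(edge.tf)
        if family is None:
            raise KeyError(f"TF {edge.tf!r} has no tf_family annotation")
        fam_elements = by_family.get(family, [])
        if not fam_elements:
            evidence.append(EdgeEvidence(edge=edge, hits=[], status="no-element"))
            continue
        region = promoters.get(edge.target)
        if region is None:
            evidence.append(EdgeEvidence(edge=edge, hits=[], status="no-promoter"))
            continue
        hits = scan_promoter(region, fam_elements)
        evidence.append(
            EdgeEvidence(edge=edge, hits=hits, status="confirmed" if hits else "unconfirmed")
        )
    return evidence


def load_elements(path) -> list[CisElement]:
    """Element table TSV: name, tf_family, iupac_consensus."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("name", "tf_family", "iupac_consensus"):
        if col not in df.columns:
            raise ValueError(f"element TSV missing column {col!r}")
    return [
        CisElement(name=r["name"], tf_family=r["tf_family"], consensus=r["iupac_consensus"])
        for _, r in df.iterrows()
    ]


def write_promoters_fasta(promoters: dict[str, PromoterRegion], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(promoters):
            p = promoters[gene]
            fh.write(f">{p.fasta_header}\n{p.sequence}\n")


def hits_table(hits: list[MotifHit]) -> pd.DataFrame:
    rows = [
        {
            "gene": h.gene,
            "element": h.element.name,
            "tf_family": h.element.tf_family,
            "offset": h.offset,
            "strand": h.strand,
            "matched": h.matched,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=["gene", "element", "tf_family", "offset", "strand", "matched"])


def evidence_table(evidence: list[EdgeEvidence]) -> pd.DataFrame:
    rows = [
        {
            "tf": ev.edge.tf,
            "target": ev.edge.target,
            "condition": ev.edge.condition.label if ev.edge.condition else "",
            "status": ev.status,
            "n_hits": ev.n_hits,
        }
        for ev in evidence
    ]
    return pd.DataFrame(rows, columns=["tf", "target", "condition", "status", "n_hits"])
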