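"""Promoter extraction (FASTA+GFF3) and IUPAC cis-element scanning."""

import numpy as np
import pytest

from seasonet.model import CisElement
from seasonet.promoter import (
    PromoterRegion,
    confirm_edges,
    extract_promoter,
    load_genome,
    open_gff,
    revcomp_iupac,
    scan_promoter,
)
from seasonet.trn import TRN, TRNEdge

from oracles import revcomp_oracle, scan_oracle

GCC = CisElement(name="GCC-box", tf_family="AP2/EREBP", consensus="GCCGCC")


def _region(seq, gene="G1"):
    return PromoterRegion(gene=gene, chrom="chr1", start=1, end=len(seq),
                          strand="+", sequence=seq)


@pytest.fixture
def mini_genome(tmp_path):
    """One 5000-bp chromosome with a plus-strand gene (TLS 3001), a
    plus-strand gene near the boundary (TLS 150) and a minus-strand gene
    (TLS 2500 on its own 5000-bp chromosome)."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    chr1 = "".join(bases[rng.integers(0, 4, 5000)])
    chr2 = "".join(bases[rng.integers(0, 4, 5000)])
    fasta = tmp_path / "genome.fa"
    fasta.write_text(f">chr1\n{chr1}\n>chr2\n{chr2}\n")
    gff = tmp_path / "genes.gff3"
    lines = ["##gff-version 3"]
    for gene, chrom, start, end, strand in [
        ("plus_far", "chr1", 3001, 3300, "+"),
        ("plus_near", "chr1", 150, 449, "+"),
        ("minus", "chr2", 2200, 2500, "-"),
        ("no_cds", "chr2", 4000, 4100, "+"),
    ]:
        lines.append(f"{chrom}\tt\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gene}")
        if gene != "no_cds":
            lines.append(f"{chrom}\tt\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID={gene}.1;Parent={gene}")
            lines.append(f"{chrom}\tt\tCDS\t{start}\t{end}\t.\t{strand}\t0\tID={gene}.c;Parent={gene}.1")
    gff.write_text("\n".join(lines) + "\n")
    return load_genome(fasta), open_gff(gff), {"chr1": chr1, "chr2": chr2}


class TestExtractPromoter:
    def test_full_length_plus_strand(self, mini_genome):
        genome, db, raw = mini_genome
        p = extract_promoter(genome, db, "plus_far")
        assert (p.start, p.end, p.strand) == (1001, 3000, "+")
        assert len(p) == 2000
        assert p.sequence == raw["chr1"][1000:3000]

    def test_truncated_at_chromosome_start(self, mini_genome):
        """TLS at 150 leaves only 149 bp: 'up to' 2000 means truncation."""
        genome, db, raw = mini_genome
        p = extract_promoter(genome, db, "plus_near")
        assert (p.start, p.end) == (1, 149)
        assert len(p) == 149
        assert p.sequence == raw["chr1"][:149]

    def test_minus_strand_reverse_complemented(self, mini_genome):
        genome, db, raw = mini_genome
        p = extract_promoter(genome, db, "minus")
        assert (p.start, p.end, p.strand) == (2501, 4500, "-")
        assert p.sequence == revcomp_oracle(raw["chr2"][2500:4500])

    def test_absent_gene_and_missing_cds_are_errors(self, mini_genome):
        genome, db, _ = mini_genome
        with pytest.raises(KeyError, match="ghost"):
            extract_promoter(genome, db, "ghost")
        with pytest.raises(ValueError, match="no CDS"):
            extract_promoter(genome, db, "no_cds")

    def test_shorter_max_len(self, mini_genome):
        genome, db, raw = mini_genome
        p = extract_promoter(genome, db, "plus_far", max_len=100)
        assert (p.start, p.end, len(p)) == (2901, 3000, 100)


class TestScanPromoter:
    def test_worked_single_hit(self):
        """GCCGCC in AAGCCGCCTT: one plus-strand hit whose 5'-most base sits
        8 bp upstream of the TLS; the reverse strand has no GGCGGC."""
        hits = scan_promoter(_region("AAGCCGCCTT"), [GCC])
        assert len(hits) == 1
        h = hits[0]
        assert (h.offset, h.strand, h.matched) == (-8, "+", "GCCGCC")

    def test_degenerate_code_matches(self):
        el = CisElement(name="e", tf_family="f", consensus="RCCGCC")
        hits = scan_promoter(_region("TTACCGCCTT"), [el])
        assert [h.matched for h in hits if h.strand == "+"] == ["ACCGCC"]

    def test_empty_promoter_no_hits(self):
        assert scan_promoter(_region(""), [GCC]) == []

    def test_promoter_n_matches_nothing(self):
        hits = scan_promoter(_region("AAGCCGNCTT"), [GCC])
        assert hits == []

    def test_invalid_consensus_letter_is_an_error(self):
        with pytest.raises(ValueError, match="IUPAC"):
            CisElement(name="bad", tf_family="f", consensus="GCXGCC")

    def test_overlapping_matches_reported(self):
        el = CisElement(name="e", tf_family="f", consensus="ATAT")
        hits = scan_promoter(_region("ATATATAT"), [el])
        plus = [h.offset for h in hits if h.strand == "+"]
        assert plus == [-8, -6, -4]

    def test_matches_sliding_window_oracle(self, rng):
        """1000 random (sequence, IUPAC consensus) pairs: the regex scanner
        agrees exactly with a naive per-position oracle on both strands."""
        letters = np.array(list("ACGTRYSWKMBDHVN"))
        bases = np.array(list("ACGTN"))
        for _ in range(1000):
            seq = "".join(bases[rng.integers(0, 5, int(rng.integers(10, 60)))])
            cons = "".join(letters[rng.integers(0, 15, int(rng.integers(4, 8)))])
            el = CisElement(name="e", tf_family="f", consensus=cons)
            got = sorted((h.offset + len(seq), h.strand) for h in scan_promoter(_region(seq), [el]))
            assert got == scan_oracle(seq, cons)

    def test_reverse_complement_strand_symmetry(self, rng):
        """Scanning the reverse-complemented promoter returns the same hit
        multiset with strands swapped and windows mirrored."""
        bases = np.array(list("ACGT"))
        for _ in range(50):
            seq = "".join(bases[rng.integers(0, 4, 40)])
            cons = "".join(bases[rng.integers(0, 4, 5)])
            el = CisElement(name="e", tf_family="f", consensus=cons)
            fwd = scan_promoter(_region(seq), [el])
            rev = scan_promoter(_region(revcomp_oracle(seq)), [el])
            m = len(cons)

            def key(h, length):
                i = h.offset + length
                return (i, h.strand)

            mirrored = sorted(
                (len(seq) - (h.offset + len(seq)) - m, {"+": "-", "-": "+"}[h.strand])
                for h in rev
            )
            assert sorted(key(h, len(seq)) for h in fwd) == mirrored

    def test_revcomp_iupac_involution(self):
        assert revcomp_iupac("RYSWKMBDHVN") == revcomp_oracle("RYSWKMBDHVN")
        assert revcomp_iupac(revcomp_iupac("GCCGCWR")) == "GCCGCWR"


class TestConfirmEdges:
    def _trn(self, pairs):
        edges = [TRNEdge(tf=tf, target=t, pcc=0.9, condition=None, tf_tf=False)
                 for tf, t in pairs]
        return TRN(condition=None, edges=edges, tf_set={tf for tf, _ in pairs})

    def test_planted_element_confirms_edge(self):
        promoters = {"t1": _region("TTTGCCGCCAAA", gene="t1")}
        out = confirm_edges(self._trn([("TF1", "t1")]), promoters, [GCC],
                            {"TF1": "AP2/EREBP"})
        assert out[0].status == "confirmed" and out[0].n_hits >= 1

    def test_ablated_promoter_flips_to_unconfirmed(self, rng):
        """Removing the element (shuffled promoter of the same composition)
        turns a confirmed target into an unconfirmed one — the pattern of a
        correlated pair lacking the binding site."""
        promoter = "TT" * 10 + "GCCGCC" + "AA" * 10
        shuffled = promoter
        while "GCCGCC" in shuffled or "GGCGGC" in shuffled:
            chars = list(promoter)
            rng.shuffle(chars)
            shuffled = "".join(chars)
        trn = self._trn([("TF1", "t1"), ("TF1", "t2")])
        promoters = {"t1": _region(promoter, "t1"), "t2": _region(shuffled, "t2")}
        out = confirm_edges(trn, promoters, [GCC], {"TF1": "AP2/EREBP"})
        status = {ev.edge.target: ev.status for ev in out}
        assert status == {"t1": "confirmed", "t2": "unconfirmed"}

    def test_missing_promoter_and_missing_family_element(self):
        trn = self._trn([("TF1", "t1"), ("TF2", "t2")])
        promoters = {"t2": _region("A" * 20, "t2")}
        out = confirm_edges(trn, promoters, [GCC],
                            {"TF1": "AP2/EREBP", "TF2": "MYB"})
        status = {ev.edge.target: ev.status for ev in out}
        assert status["t1"] == "no-promoter"   # promoter absent
        assert status["t2"] == "no-element"    # no MYB element in the table

    def test_empty_trn_and_empty_elements(self):
        trn = TRN(condition=None, edges=[], tf_set={"TF1"})
        assert confirm_edges(trn, {}, [GCC], {}) == []
        with pytest.raises(ValueError, match="empty"):
            confirm_edges(trn, {}, [], {})
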