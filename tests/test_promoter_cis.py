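"""Promoter extraction and cis-element counting."""

import pandas as pd
import pytest

from zfscan.io_formats import GeneModel, Transcript
from zfscan.promoter_cis import (
    Promoter,
    element_count_matrix,
    extract_upstream,
    load_motif_table,
    reverse_complement,
    scan_motifs,
)


def gene(gene_id, chrom, strand, start, end):
    return GeneModel(gene_id, chrom, strand, start, end,
                     transcripts=[Transcript("t", [(start, end)], [(start, end)])])


class TestExtractUpstream:
    def test_plus_strand(self):
        chrom = "A" * 3000 + "C" * 2000 + "G" * 1000
        prom = extract_upstream({"c": chrom}, gene("g", "c", "+", 5001, 5500))
        assert prom.sequence == "C" * 2000
        assert not prom.truncated

    def test_minus_strand_reverse_complements(self):
        chrom = "A" * 1000 + "G" * 2000 + "A" * 1000
        prom = extract_upstream({"c": chrom}, gene("g", "c", "-", 1, 1000))
        assert prom.sequence == "C" * 2000
        assert not prom.truncated

    def test_truncated_at_contig_start(self):
        chrom = "A" * 10000
        prom = extract_upstream({"c": chrom}, gene("g", "c", "+", 501, 900))
        assert len(prom.sequence) == 500
        assert prom.truncated

    def test_gene_at_position_one_gives_empty_flagged(self):
        prom = extract_upstream({"c": "A" * 100}, gene("g", "c", "+", 1, 50))
        assert prom.sequence == "" and prom.truncated

    def test_unknown_chromosome_raises(self):
        with pytest.raises(KeyError):
            extract_upstream({"c": "AAAA"}, gene("g", "zzz", "+", 2, 3))


class TestScanMotifs:
    def motifs(self, rows):
        return pd.DataFrame(rows, columns=["motif_id", "consensus", "stimulus"])

    def test_planted_three_hits(self):
        table = self.motifs([("ABRE", "ACGTG", "Abscisic acid")])
        prom = Promoter("g", "AA" + "ACGTG" + "AAAA" + "ACGTG" + "AA" + "ACGTG" + "A", False)
        hits = scan_motifs(prom, table)
        assert [h.strand for h in hits] == ["sense"] * 3
        assert [h.offset for h in hits] == [2, 11, 18]

    def test_iupac_degeneracy(self):
        table = self.motifs([("EBOX", "CANNTG", "Light")])
        hits = scan_motifs(Promoter("g", "AACAGGTGAA", False), table)
        assert len(hits) == 1 and hits[0].offset == 2

    def test_empty_promoter(self):
        table = self.motifs([("ABRE", "ACGTG", "ABA")])
        assert scan_motifs(Promoter("g", "", False), table) == []

    def test_antisense_detection(self):
        table = self.motifs([("MBS", "CAACTG", "Drought")])
        hits = scan_motifs(Promoter("g", "TT" + reverse_complement("CAACTG") + "TT", False), table)
        assert len(hits) == 1 and hits[0].strand == "antisense"

    def test_palindrome_counted_once_as_sense(self):
        table = self.motifs([("PAL", "ACGT", "X")])
        hits = scan_motifs(Promoter("g", "CCACGTCC", False), table)
        assert len(hits) == 1 and hits[0].strand == "sense"

    def test_strand_mirror_property(self):
        table = load_motif_table()
        seq = "AACACGTGCCCAACTGAATTCCGAAACC"
        fwd = scan_motifs(Promoter("g", seq, False), table)
        rev = scan_motifs(Promoter("g", reverse_complement(seq), False), table)
        assert sorted(h.motif_id for h in fwd) == sorted(h.motif_id for h in rev)


class TestCountMatrix:
    def test_counts_and_totals(self):
        table = pd.DataFrame(
            [("ABRE", "ACGTG", "Abscisic acid"), ("MBS", "CAACTG", "Drought")],
            columns=["motif_id", "consensus", "stimulus"],
        )
        from zfscan.promoter_cis import PromoterHit

        hits = [PromoterHit("g1", "ABRE", i, "sense") for i in (0, 10, 20)]
        hits += [PromoterHit("g1", "MBS", i, "sense") for i in (40, 50)]
        m = element_count_matrix(hits, table, gene_ids=["g1", "g2"])
        assert m.loc["g1", "Abscisic acid"] == 3
        assert m.loc["g1", "Drought"] == 2
        assert m.loc["g1", "total"] == 5
        assert m.loc["g2", "total"] == 0  # zero row retained
        assert int(m.drop(columns="total").values.sum()) == len(hits)

    def test_unknown_motif_raises(self):
        from zfscan.promoter_cis import PromoterHit

        table = pd.DataFrame([("A", "ACGTG", "x")], columns=["motif_id", "consensus", "stimulus"])
        with pytest.raises(KeyError):
            element_count_matrix([PromoterHit("g", "nope", 0, "sense")], table)


class TestDefaultTable:
    def test_loads_and_validates(self):
        table = load_motif_table()
        assert {"ABRE", "MBS", "LTR", "DRE"} <= set(table["motif_id"])
        assert table["motif_id"].is_unique


class TestPlantedRecovery:
    def test_counts_equal_plan_including_minus_strand_and_truncated(self, default_spec):
        from zfscan import synthetic_data
        from zfscan.io_formats import read_gff3

        genome, gff_text, truth = synthetic_data.generate_genome_and_gff(default_spec)
        import tempfile, os

        with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as fh:
            fh.write(gff_text)
            path = fh.name
        try:
            genes = read_gff3(path)
        finally:
            os.unlink(path)
        table = load_motif_table()
        gd = {r.id: r.residues for r in genome}
        strands = set()
        saw_truncated = False
        for g in genes:
            prom = extract_upstream(gd, g, default_spec.promoter_length)
            counts: dict[str, int] = {}
            for h in scan_motifs(prom, table):
                counts[h.motif_id] = counts.get(h.motif_id, 0) + 1
            plan = {
                m: c
                for m, c in default_spec.promoter_motif_plan[g.gene_id].items()
                if c > 0
            }
            assert counts == plan, g.gene_id
            assert prom.truncated == truth[g.gene_id]["truncated"]
            strands.add(g.strand)
            saw_truncated |= prom.truncated
        assert strands == {"+", "-"}
        assert saw_truncated
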