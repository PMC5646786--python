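"""Flanking-gene synteny verdicts: orientation, gaps, thresholds, IO."""

import pytest

from sweepoverlap import (
    SyntenyNeighborhood,
    compare_neighborhoods,
    confirm_orthology,
    read_neighborhoods_tsv,
    write_neighborhoods_tsv,
)


def nb(species, up, down, focal="DCC"):
    return SyntenyNeighborhood(
        species=species, focal=focal, upstream=tuple(up), downstream=tuple(down)
    )


BASE = nb("amh", ("U1", "U2", "U3"), ("D1", "D2", "D3"))


class TestNeighborhoodValidation:
    def test_flank_count_bounds(self):
        with pytest.raises(ValueError):
            nb("amh", (), ("D1",))
        with pytest.raises(ValueError):
            nb("amh", tuple(f"U{i}" for i in range(9)), ("D1",))

    def test_repeated_flank_rejected(self):
        with pytest.raises(ValueError, match="repeated"):
            nb("amh", ("U1",), ("U1",))

    def test_focal_among_flanks_rejected(self):
        with pytest.raises(ValueError, match="focal"):
            nb("amh", ("DCC",), ("D1",))

    def test_linear_sequence_order(self):
        assert BASE.sequence == ("U3", "U2", "U1", "DCC", "D1", "D2", "D3")


class TestCompareNeighborhoods:
    def test_identical_neighborhoods_conserved(self):
        verdict = compare_neighborhoods(BASE, nb("cat", BASE.upstream, BASE.downstream))
        assert verdict.shared_flanks == 6
        assert verdict.order_consistent and verdict.conserved

    def test_full_reversal_conserved(self):
        flipped = nb("cat", BASE.downstream, BASE.upstream)
        assert compare_neighborhoods(BASE, flipped).conserved

    def test_disjoint_flanks_not_conserved(self):
        other = nb("cat", ("X1", "X2", "X3"), ("Y1", "Y2", "Y3"))
        verdict = compare_neighborhoods(BASE, other)
        assert verdict.shared_flanks == 0 and not verdict.conserved

    def test_mismatched_focal_rejected(self):
        with pytest.raises(ValueError, match="focal"):
            compare_neighborhoods(BASE, nb("cat", ("U1",), ("D1",), focal="BRAF"))

    def test_single_insertion_tolerated(self):
        # DCC-like case: one lineage-specific gene inserted next to the focal
        inserted = nb("cattle", BASE.upstream, ("NEW", "D1", "D2"))
        verdict = compare_neighborhoods(BASE, inserted, min_shared=4, max_insertions=1)
        assert verdict.shared_flanks == 5
        assert verdict.conserved

    def test_insertion_beyond_budget_rejected(self):
        inserted = nb("cattle", BASE.upstream, ("NEW", "NEW2", "D1"))
        verdict = compare_neighborhoods(BASE, inserted, min_shared=4, max_insertions=1)
        assert not verdict.order_consistent

    def test_shuffled_order_not_conserved(self):
        shuffled = nb("dog", ("D2", "U1", "D3"), ("U3", "D1", "U2"))
        verdict = compare_neighborhoods(BASE, shuffled)
        assert verdict.shared_flanks == 6 and not verdict.order_consistent

    def test_symmetry(self):
        other = nb("cat", ("U2", "U1", "Z1"), ("D1", "Z2", "D3"))
        forward = compare_neighborhoods(BASE, other)
        backward = compare_neighborhoods(other, BASE)
        assert forward.conserved == backward.conserved
        assert forward.shared_flanks == backward.shared_flanks

    def test_reversal_invariance(self):
        other = nb("cat", ("U2", "U1", "Z1"), ("D1", "Z2", "D3"))
        direct = compare_neighborhoods(BASE, other)
        reversed_b = compare_neighborhoods(BASE, other.reversed_())
        assert direct.conserved == reversed_b.conserved

    def test_threshold_monotonicity(self):
        other = nb("cat", ("U1", "U2", "Z1"), ("D1", "NEW", "D2"))
        for min_shared in range(1, 7):
            for max_ins in range(0, 4):
                strict = compare_neighborhoods(BASE, other, min_shared, max_ins)
                relaxed = compare_neighborhoods(BASE, other, min_shared, max_ins + 1)
                looser = compare_neighborhoods(
                    BASE, other, max(1, min_shared - 1), max_ins
                )
                if strict.conserved:
                    assert relaxed.conserved and looser.conserved


class TestConfirmOrthology:
    def test_identical_panel_conserved(self):
        panel = [BASE] + [
            nb(sp, BASE.upstream, BASE.downstream) for sp in ("cat", "dog", "cattle", "horse")
        ]
        conserved, verdicts = confirm_orthology("DCC", panel)
        assert conserved and len(verdicts) == 4

    def test_one_shuffled_species_breaks_panel(self):
        shuffled = nb("horse", ("D2", "U1", "D3"), ("U3", "D1", "U2"))
        panel = [BASE, nb("cat", BASE.upstream, BASE.downstream), shuffled]
        conserved, verdicts = confirm_orthology("DCC", panel)
        assert not conserved
        assert sum(not v.conserved for v in verdicts) == 1

    def test_amh_used_as_reference(self):
        panel = [nb("cat", BASE.upstream, BASE.downstream), BASE]
        _, verdicts = confirm_orthology("DCC", panel)
        assert all(v.species_pair[0] == "amh" for v in verdicts)

    def test_single_neighborhood_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            confirm_orthology("DCC", [BASE])


class TestTsvRoundTrip:
    def test_write_then_read(self, tmp_path):
        path = tmp_path / "nb.tsv"
        panel = [BASE, nb("cat", ("U1", "U2"), ("D1", "D2"))]
        write_neighborhoods_tsv(panel, path)
        loaded = read_neighborhoods_tsv(path)
        assert {n.species for n in loaded} == {"amh", "cat"}
        amh = next(n for n in loaded if n.species == "amh")
        assert amh.upstream == BASE.upstream and amh.downstream == BASE.downstream

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("species\tfocal\tside\n")
        with pytest.raises(ValueError, match="rank"):
            read_neighborhoods_tsv(path)


class TestGffHelper:
    GFF = """##gff-version 3
chr1\t.\tgene\t1000\t2000\t.\t+\t.\tID=g1;Name=UP2;gene_biotype=protein_coding
chr1\t.\tgene\t3000\t4000\t.\t-\t.\tID=g2;Name=UP1;gene_biotype=protein_coding
chr1\t.\tgene\t4100\t4200\t.\t+\t.\tID=g3;Name=MIR9;gene_biotype=miRNA
chr1\t.\tgene\t5000\t6000\t.\t+\t.\tID=g4;Name=DCC;gene_biotype=protein_coding
chr1\t.\tgene\t7000\t8000\t.\t+\t.\tID=g5;Name=DN1;gene_biotype=protein_coding
chr1\t.\tgene\t9000\t9500\t.\t+\t.\tID=g6;Name=DN2;gene_biotype=protein_coding
"""

    def test_neighborhood_extraction(self, tmp_path):
        pytest.importorskip("gffutils")
        from sweepoverlap import neighborhood_from_gff

        path = tmp_path / "anno.gff3"
        path.write_text(self.GFF)
        nbh = neighborhood_from_gff(path, "DCC", "amh", flanks_per_side=2)
        assert nbh.upstream == ("UP1", "UP2")  # nearest first, miRNA skipped
        assert nbh.downstream == ("DN1", "DN2")
        assert nbh.chrom == "chr1"

    def test_missing_focal_rejected(self, tmp_path):
        pytest.importorskip("gffutils")
        from sweepoverlap import neighborhood_from_gff

        path = tmp_path / "anno.gff3"
        path.write_text(self.GFF)
        with pytest.raises(ValueError, match="not found"):
            neighborhood_from_gff(path, "NOPE", "amh")
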