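"""Gene model loading, coordinate mapping and isoform construction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcgrseq.gene_models import (DomainInterval, Exon, GeneModel,
                                 GeneModelError, build_isoform,
                                 gene_isoforms, genomic_to_transcript,
                                 load_gene_config, transcript_to_genomic,
                                 translate_cds)


class TestLoadConfig:
    def test_signal_peptide_offsets(self, genes):
        # offsets implied by paired ORF/mature coordinates of each gene
        assert genes["FCGR1"].signal_peptide_len == 17
        assert genes["FCGR2A"].signal_peptide_len == 35
        assert genes["FCGR2B"].signal_peptide_len == 45
        assert genes["FCGR3"].signal_peptide_len == 54

    def test_mature_offset_is_105_nt_for_fcgr2a(self, fcgr2a):
        assert 3 * fcgr2a.signal_peptide_len == 105

    def test_strands(self, genes):
        assert [genes[g].strand for g in
                ("FCGR1", "FCGR2A", "FCGR2B", "FCGR3")] == ["-", "-", "-",
                                                            "+"]

    def test_overlapping_exons_rejected(self, fcgr1):
        bad = GeneModel(
            gene_id="BAD", chromosome="chr1", strand="+",
            exons=[Exon("1", 1, 60, 1000, 1059),
                   Exon("2", 61, 120, 1050, 1109)],
            orf_start_in_transcript=1, signal_peptide_len=0,
            domains=[DomainInterval(1, 39, "extracellular-D1")],
            contact_residues=frozenset(),
            reference_transcript="ATG" + "GCT" * 38 + "TAA")
        with pytest.raises(GeneModelError, match="overlap"):
            bad.validate()

    def test_orf_not_multiple_of_three_rejected(self):
        bad = GeneModel(
            gene_id="BAD", chromosome="chr1", strand="+",
            exons=[Exon("1", 1, 10, 1, 10)],
            orf_start_in_transcript=1, signal_peptide_len=0,
            domains=[DomainInterval(1, 2, "extracellular-D1")],
            contact_residues=frozenset(),
            reference_transcript="ATGGCTTAAC")
        with pytest.raises(GeneModelError, match="divisible by 3"):
            bad.validate()

    def test_contact_residue_outside_extracellular_rejected(self, fcgr1):
        bad = GeneModel(
            gene_id="BAD", chromosome="chr1", strand="+",
            exons=[Exon("1", 1, 12, 1, 12)],
            orf_start_in_transcript=1, signal_peptide_len=0,
            domains=[DomainInterval(1, 1, "extracellular-D1"),
                     DomainInterval(2, 3, "cytoplasmic")],
            contact_residues=frozenset({2}),
            reference_transcript="ATGGCTGCTTAA")
        with pytest.raises(GeneModelError, match="contact residue"):
            bad.validate()


class TestCoordinateMapping:
    @pytest.mark.parametrize("gene_id,gpos,ref,alt,tpos,tref,talt", [
        # one printed row per exon of each gene
        ("FCGR1", 101378924, "A", "G", 134, "T", "C"),
        ("FCGR1", 101374528, "G", "A", 457, "C", "T"),
        ("FCGR1", 101373136, "C", "T", 603, "G", "A"),
        ("FCGR2A", 89431476, "C", "T", 114, "G", "A"),
        ("FCGR2A", 89427299, "G", "T", 489, "C", "A"),
        ("FCGR2A", 89419246, "T", "G", 907, "A", "C"),
        ("FCGR2B", 89331119, "T", "C", 532, "A", "G"),
        ("FCGR2B", 89326856, "A", "G", 846, "T", "C"),
        ("FCGR3", 89392794, "G", "A", 805, "G", "A"),
        ("FCGR3", 89387025, "G", "T", 184, "G", "T"),
        ("FCGR3", 89390827, "A", "G", 634, "A", "G"),
    ])
    def test_published_coordinate_pairs(self, genes, gene_id, gpos, ref,
                                        alt, tpos, tref, talt):
        gene = genes[gene_id]
        assert genomic_to_transcript(gene, gpos, ref, alt) == \
            (tpos, tref, talt)
        assert transcript_to_genomic(gene, tpos) == gpos

    def test_intronic_position_rejected(self, fcgr1):
        with pytest.raises(GeneModelError, match="not exonic"):
            genomic_to_transcript(fcgr1, 101374000)

    def test_tpos_beyond_transcript_rejected(self, fcgr1):
        with pytest.raises(GeneModelError):
            transcript_to_genomic(fcgr1, fcgr1.transcript_length + 1)

    def test_mapping_is_a_bijection_on_every_gene(self, genes):
        for gene in genes.values():
            gmapped = set()
            for t in range(1, gene.transcript_length + 1):
                g = transcript_to_genomic(gene, t)
                assert genomic_to_transcript(gene, g) == t
                gmapped.add(g)
            assert len(gmapped) == gene.transcript_length

    def test_minus_strand_affine_constant_per_exon(self, fcgr2a):
        # within one exon gpos + tpos is constant for a minus-strand gene
        exon = fcgr2a.exon_for_t(489)
        consts = {transcript_to_genomic(fcgr2a, t) + t
                  for t in range(exon.t_start, exon.t_end + 1)}
        assert consts == {89427788}


class TestTranslation:
    def test_minimal_orf(self):
        assert translate_cds("ATGGCTTAA") == "MA"

    def test_requires_atg(self):
        with pytest.raises(GeneModelError, match="ATG"):
            translate_cds("TTGGCTTAA")

    def test_empty_cds(self):
        with pytest.raises(GeneModelError):
            translate_cds("AT")

    def test_reference_proteins_have_expected_lengths(self, genes):
        # ORF length minus stop, in residues
        for gene in genes.values():
            assert len(gene.protein) == (gene.transcript_length - 3) // 3


def _insertion_diff(ref_prot, alt_prot):
    """(start 1-based, inserted length) of a pure insertion."""
    p = 0
    while p < len(ref_prot) and ref_prot[p] == alt_prot[p]:
        p += 1
    k = len(alt_prot) - len(ref_prot)
    assert alt_prot[p + k:] == ref_prot[p:]
    return p + 1, k


class TestBuildIsoform:
    def test_empty_edit_list_is_identity(self, fcgr2b):
        iso = build_isoform(fcgr2b, [])
        assert iso.transcript_seq == fcgr2b.reference_transcript
        assert iso.protein_seq == fcgr2b.protein

    def test_exon6_cassette_inserts_19_residues_at_mature_257(self,
                                                              fcgr2b):
        base = build_isoform(fcgr2b, [])
        inc = build_isoform(fcgr2b, [{"type": "include_exon", "exon": "6"}])
        assert len(inc.transcript_seq) - len(base.transcript_seq) == 57
        start, k = _insertion_diff(base.protein_seq, inc.protein_seq)
        assert k == 19
        assert start - fcgr2b.signal_peptide_len == 257

    def test_15nt_splice_extension_inserts_5_residues_at_207(self, fcgr2a):
        base = build_isoform(fcgr2a, [])
        ext = build_isoform(fcgr2a, [{"type": "extend_exon_5prime",
                                      "exon": "5",
                                      "seq": "GGTGCTTCAGGTGCT"}])
        start, k = _insertion_diff(base.protein_seq, ext.protein_seq)
        assert k == 5
        assert start - fcgr2a.signal_peptide_len == 207

    def test_inframe_length_arithmetic(self, fcgr2b):
        # protein length change = net in-frame nt change / 3
        for edits, delta_nt in [
            ([{"type": "include_exon", "exon": "6"}], 57),
            ([{"type": "ins_codon", "after_t": 30, "seq": "GCT"}], 3),
            ([{"type": "include_exon", "exon": "6"},
              {"type": "ins_codon", "after_t": 30, "seq": "GCT"}], 60),
        ]:
            iso = build_isoform(fcgr2b, edits)
            assert len(iso.protein_seq) - len(fcgr2b.protein) == delta_nt // 3

    def test_oversized_extension_rejected(self, fcgr2a):
        with pytest.raises(GeneModelError, match="exceeds exon"):
            build_isoform(fcgr2a, [{"type": "extend_exon_5prime",
                                    "exon": "5", "seq": "A" * 100}])

    def test_configured_isoform_sets(self, genes):
        assert len(gene_isoforms(genes["FCGR2A"])) == 4
        assert len(gene_isoforms(genes["FCGR2B"])) == 4
        assert len(gene_isoforms(genes["FCGR3"])) == 2
        assert gene_isoforms(genes["FCGR1"]) == []


_GENES = load_gene_config()


@settings(max_examples=25, deadline=None)
@given(st.data())
def test_roundtrip_random_positions(data):
    gene = _GENES[data.draw(st.sampled_from(sorted(_GENES)))]
    t = data.draw(st.integers(1, gene.transcript_length))
    assert genomic_to_transcript(gene, transcript_to_genomic(gene, t)) == t
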