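# Gene models for the four rhesus macaque Fc gamma receptor amplicons.
#
# Transcript coordinates are ORF-based (position 1 = A of the start codon)
# and the packaged reference transcripts cover the ORF plus stop codon only.
# Exon boundaries are synthetic: the published variant tables determine one
# affine constant per exon (gpos + tpos for minus-strand genes, gpos - tpos
# for the plus-strand gene) and the exon label for each variant; boundaries
# are padded around those constraints.  Domain intervals and Fc-contact
# residue sets use mature-protein numbering (position 1 = first residue
# after the leader; leader residues are negative, zero is skipped).
transcripts_fasta: fcgr_transcripts.fasta
genes:
  - gene_id: FCGR1
    chromosome: chr1
    strand: "-"
    transcript_id: FCGR1_ref
    orf_start_in_transcript: 1
    signal_peptide_len: 17
    exons:
      - {label: "1", t_start: 1,   t_end: 30,   g_start: 101379090, g_end: 101379119}
      - {label: "2", t_start: 31,  t_end: 60,   g_start: 101379030, g_end: 101379059}
      - {label: "3", t_start: 61,  t_end: 270,  g_start: 101378788, g_end: 101378997}
      - {label: "4", t_start: 271, t_end: 480,  g_start: 101374505, g_end: 101374714}
      - {label: "5", t_start: 481, t_end: 1119, g_start: 101372620, g_end: 101373258}
    domains:
      - {start: 1,   end: 90,  label: extracellular-D1}
      - {start: 91,  end: 180, label: extracellular-D2}
      - {start: 181, end: 292, label: extracellular-other}
      - {start: 293, end: 313, label: transmembrane}
      - {start: 314, end: 355, label: cytoplasmic}
    contact_residues: [85, 86, 87, 88, 109, 110, 111, 113, 114, 115, 116, 117,
                       119, 124, 125, 126, 127, 128, 129, 131, 132,
                       155, 156, 157, 158, 159]
    contact_source: 4W40/4ZNE
    isoforms: []

  - gene_id: FCGR2A
    chromosome: chr1
    strand: "-"
    transcript_id: FCGR2A_ref
    orf_start_in_transcript: 1
    signal_peptide_len: 35
    exons:
      - {label: "1", t_start: 1,   t_end: 45,  g_start: 89432215, g_end: 89432259}
      - {label: "2", t_start: 46,  t_end: 90,  g_start: 89432070, g_end: 89432114}
      - {label: "3", t_start: 91,  t_end: 300, g_start: 89431290, g_end: 89431499}
      - {label: "4", t_start: 301, t_end: 723, g_start: 89427065, g_end: 89427487}
      - {label: "5", t_start: 724, t_end: 789, g_start: 89425211, g_end: 89425276}
      - {label: "6", t_start: 790, t_end: 820, g_start: 89422180, g_end: 89422210}
      - {label: "7", t_start: 821, t_end: 933, g_start: 89419220, g_end: 89419332}
    domains:
      - {start: 1,   end: 85,  label: extracellular-D1}
      - {start: 86,  end: 170, label: extracellular-D2}
      - {start: 171, end: 215, label: extracellular-other}
      - {start: 216, end: 240, label: transmembrane}
      - {start: 241, end: 275, label: cytoplasmic}
    contact_residues: [86, 87, 110, 114, 116, 117, 125, 126, 127, 129, 131,
                       155, 156, 157]
    contact_source: 3RY6
    isoforms:
      # Four reference isoforms: every combination of a single-residue
      # leader deletion and a 15-nt alternative 5' splice extension of
      # exon 5 (5 extra residues at mature 207-211).
      - isoform_id: FCGR2A_NM_001257300.1
        protein_id: NP_001244229.1
        edits: []
      - isoform_id: FCGR2A_XM_015113136.2
        protein_id: XP_014968622.2
        edits:
          - {type: del_codon, codon: 12}
      - isoform_id: FCGR2A_XM_028846297.1
        protein_id: XP_028702130.1
        edits:
          - {type: extend_exon_5prime, exon: "5", seq: GGTGCTTCAGGTGCT}
      - isoform_id: FCGR2A_XM_028846295.1
        protein_id: XP_028702128.1
        edits:
          - {type: del_codon, codon: 12}
          - {type: extend_exon_5prime, exon: "5", seq: GGTGCTTCAGGTGCT}

  - gene_id: FCGR2B
    chromosome: chr1
    strand: "-"
    transcript_id: FCGR2B_ref
    orf_start_in_transcript: 1
    signal_peptide_len: 45
    exons:
      - {label: "1", t_start: 1,   t_end: 90,  g_start: 89332210, g_end: 89332299}
      - {label: "2", t_start: 91,  t_end: 180, g_start: 89332020, g_end: 89332109}
      - {label: "3", t_start: 181, t_end: 300, g_start: 89331700, g_end: 89331819}
      - {label: "4", t_start: 301, t_end: 690, g_start: 89330961, g_end: 89331350}
      - {label: "5", t_start: 691, t_end: 780, g_start: 89329220, g_end: 89329309}
      - {label: "7", t_start: 781, t_end: 903, g_start: 89326799, g_end: 89326921}
      - {label: "8", t_start: 904, t_end: 960, g_start: 89325540, g_end: 89325596}
    # 57-nt in-frame cassette (19 residues inserted at mature 257 when
    # included).  The label follows the source annotation's numbering.
    cassette_exons:
      - label: "6"
        after_t: 903
        seq: GGAGATCACAAGAAACTGGAGGAATCCAGTGCCGCTGAAAATACTATTACCTACTCA
        g_start: 89325700
        g_end: 89325756
    domains:
      - {start: 1,   end: 85,  label: extracellular-D1}
      - {start: 86,  end: 170, label: extracellular-D2}
      - {start: 171, end: 237, label: extracellular-other}
      - {start: 238, end: 256, label: transmembrane}
      - {start: 257, end: 274, label: cytoplasmic}
    contact_residues: [85, 86, 87, 110, 113, 117, 119, 126, 127, 128, 129,
                       130, 131, 157, 158, 159, 160]
    contact_source: 3WJJ
    isoforms:
      - isoform_id: FCGR2B_XM_015113204.2
        protein_id: XP_014968690.1
        edits: []
      - isoform_id: FCGR2B_XM_015113196.2
        protein_id: XP_014968682.1
        edits:
          - {type: include_exon, exon: "6"}
      - isoform_id: FCGR2B_NM_001271648.2
        protein_id: NP_001258577.2
        edits:
          - {type: ins_codon, after_t: 30, seq: GCT}
      - isoform_id: FCGR2B_NM_001257302.1
        protein_id: NP_001244231.1
        edits:
          - {type: include_exon, exon: "6"}
          - {type: ins_codon, after_t: 30, seq: GCT}

  - gene_id: FCGR3
    chromosome: chr1
    strand: "+"
    transcript_id: FCGR3_ref
    orf_start_in_transcript: 1
    signal_peptide_len: 54
    exons:
      - {label: "1", t_start: 1,   t_end: 90,  g_start: 89384001, g_end: 89384090}
      - {label: "2", t_start: 91,  t_end: 180, g_start: 89386591, g_end: 89386680}
      - {label: "3", t_start: 181, t_end: 420, g_start: 89387022, g_end: 89387261}
      - {label: "4", t_start: 421, t_end: 690, g_start: 89390614, g_end: 89390883}
      - {label: "5", t_start: 691, t_end: 843, g_start: 89392680, g_end: 89392832}
    domains:
      - {start: 1,   end: 85,  label: extracellular-D1}
      - {start: 86,  end: 170, label: extracellular-D2}
      - {start: 171, end: 195, label: extracellular-other}
      - {start: 196, end: 208, label: transmembrane}
      - {start: 209, end: 226, label: cytoplasmic}
    contact_residues: [158]
    contact_source: 7KCZ
    isoforms:
      # The reference isoforms differ only by a single-residue insertion in
      # the leader; accession-level duplicates of the same structure are not
      # sequence-identifiable, so one representative of each structure is
      # modelled.
      - isoform_id: FCGR3_NM_001271657.1
        protein_id: NP_001258586.1
        edits: []
      - isoform_id: FCGR3_XM_015113175.2
        protein_id: XP_014968661.2
        edits:
          - {type: ins_codon, after_t: 30, seq: GCT}
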