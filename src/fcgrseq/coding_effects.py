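"""Coding-effect classification and dual-numbered notation rendering.

Variants are classified against the gene's principal transcript and
rendered in four notations: ORF-numbered nucleotide (``c.T134C``),
ORF-numbered protein (``p.V45A``), mature-transcript nucleotide (``T83C``)
and mature-protein residue (``V28A``).  The protein dialect follows the
conventions of receptor-polymorphism screening tables rather than strict
HGVS: frameshifts are written ``p.V23fs`` without a ``Ter`` extension, and
an in-frame insertion whose new residues precede an existing residue is
written as a delins of that residue (``p.R299delinsDR``).

Mature numbering subtracts the leader: residue ``i`` maps to
``i - L`` when past the leader and to the negative index ``i - L - 1``
inside it (there is no residue zero); nucleotides shift by ``3 L``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .gene_models import GeneModel, GeneModelError, translate_cds

CATEGORIES = {
    "synonymous SNP",
    "nonsynonymous SNP",
    "stop-gain SNP",
    "stop-loss SNP",
    "frameshift insertion",
    "frameshift deletion",
    "non-frameshift insertion",
    "non-frameshift deletion",
    "UTR",
}

#: Description strings used in the cohort variant tables.
TABLE_DESCRIPTION = {
    "synonymous SNP": "synonymous SNP",
    "nonsynonymous SNP": "nonsynonymous SNP",
    "stop-gain SNP": "stop-gain SNP",
    "stop-loss SNP": "stop-loss SNP",
    "frameshift insertion": "fs insertion",
    "frameshift deletion": "fs deletion",
    "non-frameshift insertion": "non-fs insertion",
    "non-frameshift deletion": "non-fs deletion",
    "UTR": "UTR",
}


@dataclass(frozen=True)
class TranscriptVariant:
    """A variant in ORF (transcript) coordinates, transcript-strand alleles.

    kind 'snv':  ``tpos`` is the substituted base, ref/alt single bases.
    kind 'ins':  inserted ``alt`` goes between ``tpos`` and ``tpos + 1``.
    kind 'del':  ``ref`` bases starting at ``tpos`` are removed.
    """

    kind: str
    tpos: int
    ref: str = ""
    alt: str = ""

    def __post_init__(self):
        if self.kind not in ("snv", "ins", "del"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == "snv" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError("snv requires single-base alleles")
        if self.ref == self.alt:
            raise ValueError("reference and alternate alleles are identical")


@dataclass(frozen=True)
class CodingEffect:
    category: str
    annovar_nt: str
    annovar_aa: str
    mature_nt: str
    mature_aa: str
    mature_residue_index: int
    codon_index: int
    is_dup: bool = False


def locate_codon(orf_nt_pos: int) -> tuple[int, int]:
    """Codon index and 1-based offset within the codon for an ORF position."""
    if orf_nt_pos < 1:
        raise ValueError("ORF positions start at 1")
    return math.ceil(orf_nt_pos / 3), (orf_nt_pos - 1) % 3 + 1


def to_mature_nt(orf_nt_pos: int, gene: GeneModel) -> int:
    """Mature-transcript nucleotide index; values <= 0 are in the leader."""
    if orf_nt_pos < 1:
        raise ValueError("ORF positions start at 1")
    return orf_nt_pos - 3 * gene.signal_peptide_len


def to_mature_aa(annovar_aa_index: int, gene: GeneModel) -> int:
    """Mature residue index; leader residues are negative, zero is skipped."""
    if annovar_aa_index < 1:
        raise ValueError("ORF residue indices start at 1")
    L = gene.signal_peptide_len
    if annovar_aa_index > L:
        return annovar_aa_index - L
    return annovar_aa_index - L - 1


def _apply_to_transcript(variant: TranscriptVariant, seq: str) -> str:
    i = variant.tpos
    if variant.kind == "snv":
        if seq[i - 1] != variant.ref:
            raise GeneModelError(
                f"reference mismatch at ORF {i}: transcript has "
                f"{seq[i - 1]}, variant claims {variant.ref}")
        return seq[:i - 1] + variant.alt + seq[i:]
    if variant.kind == "ins":
        return seq[:i] + variant.alt + seq[i:]
    if seq[i - 1:i - 1 + len(variant.ref)] != variant.ref:
        raise GeneModelError(f"reference mismatch for deletion at ORF {i}")
    return seq[:i - 1] + seq[i - 1 + len(variant.ref):]


def _protein_diff(ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal replaced region between two proteins.

    Returns ``(prefix_len, removed, inserted)`` where ``removed`` is
    ``ref[prefix : len(ref) - suffix]`` and likewise for ``inserted``.
    """
    p = 0
    while p < min(len(ref), len(alt)) and ref[p] == alt[p]:
        p += 1
    s = 0
    while (s < min(len(ref), len(alt)) - p
           and ref[len(ref) - 1 - s] == alt[len(alt) - 1 - s]):
        s += 1
    return p, ref[p:len(ref) - s], alt[p:len(alt) - s]


def _aa(code: str) -> str:
    return "X" if code == "*" else code


def classify_effect(variant: TranscriptVariant, gene: GeneModel
                    ) -> CodingEffect:
    """Classify a transcript variant and render all four notations."""
    orf_len = len(gene.orf_seq)
    if variant.tpos > orf_len or variant.tpos < 1:
        return CodingEffect("UTR", f"c.{variant.tpos}", "", "", "",
                            0, 0)

    ref_seq = gene.reference_transcript
    ref_prot = gene.protein
    L = gene.signal_peptide_len

    if variant.kind == "snv":
        if ref_seq[variant.tpos - 1] != variant.ref:
            raise GeneModelError(
                f"reference mismatch at ORF {variant.tpos}: transcript has "
                f"{ref_seq[variant.tpos - 1]}, variant claims {variant.ref}")
        codon_idx, offset = locate_codon(variant.tpos)
        start = (codon_idx - 1) * 3
        ref_codon = ref_seq[start:start + 3]
        alt_codon = (ref_codon[:offset - 1] + variant.alt
                     + ref_codon[offset:])
        from Bio.Seq import Seq
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if ref_aa == alt_aa:
            category = "synonymous SNP"
        elif alt_aa == "*":
            category = "stop-gain SNP"
        elif ref_aa == "*":
            category = "stop-loss SNP"
        else:
            category = "nonsynonymous SNP"
        m_nt = to_mature_nt(variant.tpos, gene)
        m_aa = to_mature_aa(codon_idx, gene)
        return CodingEffect(
            category=category,
            annovar_nt=f"c.{variant.ref}{variant.tpos}{variant.alt}",
            annovar_aa=f"p.{_aa(ref_aa)}{codon_idx}{_aa(alt_aa)}",
            mature_nt=f"{variant.ref}{m_nt}{variant.alt}",
            mature_aa=f"{_aa(ref_aa)}{m_aa}{_aa(alt_aa)}",
            mature_residue_index=m_aa,
            codon_index=codon_idx,
        )

    # --- indels ---------------------------------------------------------
    from .amplicon_caller import normalize_indel
    if variant.kind == "ins":
        anchor, seq, is_dup = normalize_indel("ins", variant.tpos,
                                              variant.alt, ref_seq)
        net = len(seq)
        if is_dup:
            p1, p2 = anchor + 1, anchor + len(seq)
            pos_nt = f"{p1}dup" if len(seq) == 1 else f"{p1}_{p2}dup"
            m1, m2 = to_mature_nt(p1, gene), to_mature_nt(p2, gene)
            mat_nt = f"{m1}dup" if len(seq) == 1 else f"{m1}_{m2}dup"
            nt_name, mat_name = f"c.{pos_nt}{seq}", f"{mat_nt}{seq}"
        else:
            m1 = to_mature_nt(anchor, gene)
            nt_name = f"c.{anchor}_{anchor + 1}ins{seq}"
            mat_name = f"{m1}_{m1 + 1}ins{seq}"
        mutant = ref_seq[:anchor] + seq + ref_seq[anchor:]
    else:
        anchor, seq, _ = normalize_indel("del", variant.tpos,
                                         variant.ref, ref_seq)
        net = -len(seq)
        p1, p2 = anchor, anchor + len(seq) - 1
        m1, m2 = to_mature_nt(p1, gene), to_mature_nt(p2, gene)
        if len(seq) == 1:
            nt_name, mat_name = f"c.{p1}del{seq}", f"{m1}del{seq}"
        else:
            nt_name = f"c.{p1}_{p2}del{seq}"
            mat_name = f"{m1}_{m2}del{seq}"
        mutant = ref_seq[:anchor - 1] + ref_seq[anchor - 1 + len(seq):]

    frameshift = net % 3 != 0
    mut_prot = translate_cds(mutant, gene.orf_start_in_transcript)

    if frameshift:
        category = ("frameshift insertion" if net > 0
                    else "frameshift deletion")
        p, _, _ = _protein_diff(ref_prot, mut_prot)
        idx = min(p + 1, len(ref_prot))
        aa = ref_prot[idx - 1]
        aa_name = f"p.{aa}{idx}fs"
        mat_aa = f"{aa}{to_mature_aa(idx, gene)}fs"
        m_idx = to_mature_aa(idx, gene)
    else:
        category = ("non-frameshift insertion" if net > 0
                    else "non-frameshift deletion")
        p, removed, inserted = _protein_diff(ref_prot, mut_prot)
        if net > 0 and not removed:
            # pure insertion of `inserted` before ref residue p + 1
            idx = p + 1
            aa = ref_prot[idx - 1] if idx <= len(ref_prot) else "X"
            aa_name = f"p.{aa}{idx}delins{inserted}{aa}"
            mat_aa = f"{aa}{to_mature_aa(idx, gene)}delins{inserted}{aa}"
        elif net < 0 and not inserted:
            idx = p + 1
            if len(removed) == 1:
                aa_name = f"p.{removed}{idx}del"
                mat_aa = f"{removed}{to_mature_aa(idx, gene)}del"
            else:
                j = idx + len(removed) - 1
                aa_name = (f"p.{removed[0]}{idx}_{removed[-1]}{j}del")
                mat_aa = (f"{removed[0]}{to_mature_aa(idx, gene)}_"
                          f"{removed[-1]}{to_mature_aa(j, gene)}del")
        else:
            idx = p + 1
            j = idx + max(len(removed), 1) - 1
            aa_name = f"p.{removed or '-'}{idx}delins{inserted}"
            mat_aa = f"{removed or '-'}{to_mature_aa(idx, gene)}delins{inserted}"
        m_idx = to_mature_aa(idx, gene)

    return CodingEffect(
        category=category,
        annovar_nt=nt_name,
        annovar_aa=aa_name,
        mature_nt=mat_name,
        mature_aa=mat_aa,
        mature_residue_index=m_idx,
        codon_index=locate_codon(anchor if variant.kind != "snv"
                                 else variant.tpos)[0],
        is_dup=variant.kind == "ins" and is_dup,
    )


def format_hgvs_c(effect: CodingEffect) -> str:
    return effect.annovar_nt


def format_hgvs_p(effect: CodingEffect) -> str:
    return effect.annovar_aa
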