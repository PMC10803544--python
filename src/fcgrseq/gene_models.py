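"""Gene and isoform models for FcγR amplicon analysis.

A :class:`GeneModel` describes one Fcγ receptor gene as sequenced by
full-length cDNA amplicons: an ordered exon list carrying the genomic ↔
transcript coordinate relation, the open reading frame, the leader
(signal-peptide) length that separates ORF numbering from mature-protein
numbering, protein domain intervals, and the set of residues at the
receptor–IgG Fc interface.

Two coordinate systems are used throughout the package:

* **ORF (transcript) numbering** — nucleotide/residue 1 is the start of the
  open reading frame, leader included.
* **Mature-protein numbering** — residue 1 is the first residue after
  leader cleavage; leader residues carry negative indices (zero is
  skipped).

Within one exon the genomic and transcript coordinates are related by an
affine constant: ``gpos + tpos = K`` on the minus strand and
``gpos - tpos = K`` on the plus strand.  Alleles are reverse-complemented
for minus-strand genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq

DOMAIN_LABELS = {
    "signal",
    "extracellular-D1",
    "extracellular-D2",
    "extracellular-other",
    "transmembrane",
    "cytoplasmic",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class GeneModelError(ValueError):
    """Raised when a gene-model configuration violates an invariant."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Exon:
    label: str
    t_start: int
    t_end: int
    g_start: int
    g_end: int

    def __len__(self) -> int:
        return self.t_end - self.t_start + 1


@dataclass(frozen=True)
class CassetteExon:
    """An optionally included exon, absent from the principal transcript."""

    label: str
    after_t: int          # inserted between after_t and after_t + 1
    seq: str
    g_start: int
    g_end: int


@dataclass(frozen=True)
class DomainInterval:
    start: int
    end: int
    label: str


@dataclass(frozen=True)
class IsoformModel:
    """A splice isoform materialized from a gene model plus edits."""

    isoform_id: str
    gene_id: str
    splice_structure: tuple
    transcript_seq: str
    protein_seq: str
    protein_id: str = ""


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    exons: list[Exon]
    orf_start_in_transcript: int
    signal_peptide_len: int
    domains: list[DomainInterval]
    contact_residues: frozenset[int]
    reference_transcript: str
    contact_source: str = ""
    cassette_exons: list[CassetteExon] = field(default_factory=list)
    isoform_defs: list[dict] = field(default_factory=list)

    # -- derived ---------------------------------------------------------
    @property
    def transcript_length(self) -> int:
        return len(self.reference_transcript)

    @property
    def orf_seq(self) -> str:
        return self.reference_transcript[self.orf_start_in_transcript - 1:]

    @property
    def protein(self) -> str:
        """ORF-numbered translation (leader included, stop excluded)."""
        return translate_cds(self.reference_transcript,
                             self.orf_start_in_transcript)

    @property
    def mature_protein(self) -> str:
        return self.protein[self.signal_peptide_len:]

    def exon_for_t(self, tpos: int) -> Exon:
        for exon in self.exons:
            if exon.t_start <= tpos <= exon.t_end:
                return exon
        raise GeneModelError(
            f"{self.gene_id}: transcript position {tpos} beyond transcript")

    def exon_for_g(self, gpos: int) -> Exon:
        for exon in self.exons:
            if exon.g_start <= gpos <= exon.g_end:
                return exon
        raise GeneModelError(
            f"{self.gene_id}: genomic position {gpos} is not exonic")

    def cassette(self, label: str) -> CassetteExon:
        for cas in self.cassette_exons:
            if cas.label == label:
                return cas
        raise GeneModelError(f"{self.gene_id}: no cassette exon '{label}'")

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.gene_id}: strand must be + or -")
        if self.signal_peptide_len < 0:
            raise GeneModelError(f"{self.gene_id}: signal_peptide_len < 0")

        expected_t = 1
        prev_g = None
        for exon in self.exons:
            if exon.t_start != expected_t:
                raise GeneModelError(
                    f"{self.gene_id}: exons not contiguous in transcript "
                    f"order at exon {exon.label}")
            if exon.t_end < exon.t_start or exon.g_end < exon.g_start:
                raise GeneModelError(
                    f"{self.gene_id}: malformed interval in exon {exon.label}")
            if (exon.g_end - exon.g_start) != (exon.t_end - exon.t_start):
                raise GeneModelError(
                    f"{self.gene_id}: exon {exon.label} genomic and "
                    f"transcript spans differ")
            if prev_g is not None:
                if self.strand == "-" and exon.g_end >= prev_g[0]:
                    raise GeneModelError(
                        f"{self.gene_id}: exons overlap or are not in "
                        f"descending genomic order (minus strand), exon "
                        f"{exon.label}")
                if self.strand == "+" and exon.g_start <= prev_g[1]:
                    raise GeneModelError(
                        f"{self.gene_id}: exons overlap or are not in "
                        f"ascending genomic order (plus strand), exon "
                        f"{exon.label}")
            prev_g = (exon.g_start, exon.g_end)
            expected_t = exon.t_end + 1
        if expected_t - 1 != self.transcript_length:
            raise GeneModelError(
                f"{self.gene_id}: exons cover {expected_t - 1} nt but the "
                f"reference transcript has {self.transcript_length}")

        orf = self.orf_seq
        if len(orf) % 3:
            raise GeneModelError(
                f"{self.gene_id}: ORF length {len(orf)} not divisible by 3")
        if not orf.startswith("ATG"):
            raise GeneModelError(f"{self.gene_id}: ORF does not start at ATG")
        if str(Seq(orf[-3:]).translate()) != "*":
            raise GeneModelError(f"{self.gene_id}: ORF lacks terminal stop")

        mature_len = len(self.mature_protein)
        covered = 0
        prev_end = 0
        for dom in self.domains:
            if dom.label not in DOMAIN_LABELS:
                raise GeneModelError(
                    f"{self.gene_id}: unknown domain label '{dom.label}'")
            if dom.start != prev_end + 1:
                raise GeneModelError(
                    f"{self.gene_id}: domain intervals overlap or leave a "
                    f"gap at {dom.start}")
            covered += dom.end - dom.start + 1
            prev_end = dom.end
        if prev_end != mature_len:
            raise GeneModelError(
                f"{self.gene_id}: domains cover 1..{prev_end} but the mature "
                f"protein has {mature_len} residues")

        for res in self.contact_residues:
            label = self.domain_label(res)
            if not label.startswith("extracellular"):
                raise GeneModelError(
                    f"{self.gene_id}: contact residue {res} lies in "
                    f"'{label}', outside the extracellular domains")

        for cas in self.cassette_exons:
            if len(cas.seq) != cas.g_end - cas.g_start + 1:
                raise GeneModelError(
                    f"{self.gene_id}: cassette exon {cas.label} sequence and "
                    f"genomic span differ")

    def domain_label(self, mature_index: int) -> str:
        """Domain label for a mature residue index (negative = leader)."""
        if mature_index < 0:
            return "signal"
        if mature_index == 0:
            raise GeneModelError("mature index 0 does not exist")
        for dom in self.domains:
            if dom.start <= mature_index <= dom.end:
                return dom.label
        raise GeneModelError(
            f"{self.gene_id}: mature index {mature_index} beyond protein")


# ---------------------------------------------------------------------------
# coordinate mapping
# ---------------------------------------------------------------------------

def genomic_to_transcript(gene: GeneModel, gpos: int,
                          ref: str | None = None, alt: str | None = None):
    """Map an exonic genomic position (and optional alleles) to ORF numbering.

    Returns ``tpos`` alone, or ``(tpos, tref, talt)`` when alleles are given.
    Alleles are reverse-complemented for minus-strand genes.
    """
    exon = gene.exon_for_g(gpos)
    if gene.strand == "-":
        tpos = (exon.g_start + exon.t_end) - gpos
    else:
        tpos = gpos - (exon.g_start - exon.t_start)
    if ref is None:
        return tpos
    if gene.strand == "-":
        return tpos, revcomp(ref), revcomp(alt)
    return tpos, ref, alt


def transcript_to_genomic(gene: GeneModel, tpos: int) -> int:
    exon = gene.exon_for_t(tpos)
    if gene.strand == "-":
        return (exon.g_start + exon.t_end) - tpos
    return tpos + (exon.g_start - exon.t_start)


# ---------------------------------------------------------------------------
# translation and isoform construction
# ---------------------------------------------------------------------------

def translate_cds(transcript_seq: str, orf_start: int = 1) -> str:
    """Translate from ``orf_start`` (1-based) to the first stop codon.

    The ORF must begin with ATG; the stop is not included in the result.
    """
    cds = transcript_seq[orf_start - 1:]
    if not cds.startswith("ATG"):
        raise GeneModelError(f"no ATG at ORF start (found {cds[:3]!r})")
    trimmed = cds[:len(cds) - len(cds) % 3]
    if not trimmed:
        raise GeneModelError("empty coding sequence")
    return str(Seq(trimmed).translate(to_stop=True))


def apply_edits(gene: GeneModel, edits) -> str:
    """Apply splice edits (in principal-transcript coordinates) to the
    reference transcript and return the isoform transcript sequence."""
    events = []  # (position after which to act, kind, payload)
    for edit in edits:
        kind = edit["type"]
        if kind == "include_exon":
            cas = gene.cassette(edit["exon"])
            events.append((cas.after_t, "ins", cas.seq))
        elif kind == "extend_exon_5prime":
            exon = next((e for e in gene.exons if e.label == edit["exon"]),
                        None)
            if exon is None:
                raise GeneModelError(
                    f"{gene.gene_id}: no exon '{edit['exon']}'")
            seq = edit["seq"]
            if len(seq) > len(exon):
                raise GeneModelError(
                    f"{gene.gene_id}: splice extension of {len(seq)} nt "
                    f"exceeds exon {exon.label} length {len(exon)}")
            events.append((exon.t_start - 1, "ins", seq))
        elif kind == "ins_codon":
            events.append((edit["after_t"], "ins", edit["seq"]))
        elif kind == "del_codon":
            codon = edit["codon"]
            events.append((3 * (codon - 1), "del", 3))
        else:
            raise GeneModelError(f"unknown splice edit type '{kind}'")

    seq = gene.reference_transcript
    for pos, kind, payload in sorted(events, reverse=True):
        if kind == "ins":
            seq = seq[:pos] + payload + seq[pos:]
        else:
            seq = seq[:pos] + seq[pos + payload:]
    return seq


def build_isoform(gene: GeneModel, splice_structure,
                  isoform_id: str = "", protein_id: str = "") -> IsoformModel:
    """Materialize an isoform's transcript and protein from splice edits."""
    transcript = apply_edits(gene, splice_structure)
    protein = translate_cds(transcript, gene.orf_start_in_transcript)
    return IsoformModel(
        isoform_id=isoform_id or f"{gene.gene_id}_isoform",
        gene_id=gene.gene_id,
        splice_structure=tuple(
            tuple(sorted(e.items())) for e in splice_structure),
        transcript_seq=transcript,
        protein_seq=protein,
        protein_id=protein_id,
    )


def gene_isoforms(gene: GeneModel) -> list[IsoformModel]:
    """All configured reference isoforms, principal first if defined."""
    out = []
    for spec in gene.isoform_defs:
        out.append(build_isoform(gene, spec.get("edits", []),
                                 isoform_id=spec["isoform_id"],
                                 protein_id=spec.get("protein_id", "")))
    return out


# ---------------------------------------------------------------------------
# configuration loading
# ---------------------------------------------------------------------------

def default_config_path() -> Path:
    return Path(__file__).parent / "data" / "fcgr_genes.yaml"


def load_gene_config(config_path: str | Path | None = None
                     ) -> dict[str, GeneModel]:
    """Load and validate gene models from a YAML config plus FASTA.

    Returns a mapping ``gene_id -> GeneModel``.  With no argument the
    packaged FcγR fixture models are loaded.
    """
    path = Path(config_path) if config_path else default_config_path()
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    fasta = path.parent / cfg["transcripts_fasta"]
    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta), "fasta")}

    genes: dict[str, GeneModel] = {}
    for g in cfg["genes"]:
        tid = g["transcript_id"]
        if tid not in seqs:
            raise GeneModelError(f"{g['gene_id']}: transcript {tid} missing "
                                 f"from {fasta.name}")
        gene = GeneModel(
            gene_id=g["gene_id"],
            chromosome=g["chromosome"],
            strand=g["strand"],
            exons=[Exon(str(e["label"]), e["t_start"], e["t_end"],
                        e["g_start"], e["g_end"]) for e in g["exons"]],
            orf_start_in_transcript=g.get("orf_start_in_transcript", 1),
            signal_peptide_len=g["signal_peptide_len"],
            domains=[DomainInterval(d["start"], d["end"], d["label"])
                     for d in g["domains"]],
            contact_residues=frozenset(g.get("contact_residues", [])),
            contact_source=g.get("contact_source", ""),
            reference_transcript=seqs[tid],
            cassette_exons=[CassetteExon(str(c["label"]), c["after_t"],
                                         c["seq"], c["g_start"], c["g_end"])
                            for c in g.get("cassette_exons", [])],
            isoform_defs=g.get("isoforms", []),
        )
        gene.validate()
        genes[gene.gene_id] = gene
    return genes
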