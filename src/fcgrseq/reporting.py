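"""Report assembly, file I/O and the end-to-end pipeline.

``run_pipeline`` composes the stages — simulate (or load reads) → align →
call → annotate → aggregate → filter → isoform quantification → interface
classification — into a :class:`CohortReport`, mirroring how a screening
study turns per-animal amplicon reads into cohort variant tables and an
isoform abundance matrix.  All writers are atomic (write-to-temp, rename)
and every threshold lives in one config mapping with the screening
defaults (2% variant retention, 1% isoform filters).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .amplicon_caller import (CallerParams, ScoringParams, VariantCall,
                              align_read, build_pileup, call_genotypes)
from .coding_effects import (TABLE_DESCRIPTION, TranscriptVariant,
                             classify_effect)
from .cohort_stats import (CohortVariantRecord, aggregate_cohort,
                           filter_min_fraction)
from .gene_models import GeneModel, gene_isoforms, load_gene_config
from .isoform_quant import (abundance_matrix, filter_isoform_set,
                            isoform_carrier_stats, quantify_animal)
from .structure_map import assign_table_domain, classify_interface
from .synthetic_cohort import CohortSpec, VariantSpec, simulate_cohort

log = logging.getLogger("fcgrseq")

VARIANT_TABLE_COLUMNS = ["Variant", "Description", "Exon", "ANNOVAR NT",
                         "ANNOVAR AA", "Transcript NT", "Mature protein AA",
                         "Domain", "% Carriers"]

DEFAULT_THRESHOLDS = {
    "min_carrier_fraction": 0.02,
    "min_isoform_abundance": 0.01,
    "isoform_carrier_threshold": 0.01,
    "interface_window": 2,
}


@dataclass
class CohortReport:
    variant_tables: dict[str, pd.DataFrame]
    variant_records: dict[str, list[CohortVariantRecord]]
    abundance: pd.DataFrame
    isoform_carriers: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def digest(self) -> str:
        h = hashlib.sha256()
        for gene in sorted(self.variant_tables):
            h.update(self.variant_tables[gene].to_csv(index=False).encode())
        h.update(self.abundance.round(10).to_csv().encode())
        h.update(self.isoform_carriers.to_csv(index=False).encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# atomic file helpers
# ---------------------------------------------------------------------------

def _atomic_write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), suffix=".tmp")
    with os.fdopen(fd, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def write_fastq(reads, path: str | Path, quality: int = 40) -> None:
    records = []
    for read_id, seq in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        records.append(rec)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path: str | Path):
    import gzip
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        return [(rec.id, str(rec.seq).upper())
                for rec in SeqIO.parse(fh, "fastq")]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _vcf_site(call: VariantCall, genes: dict[str, GeneModel]):
    """(pos, ref, alt) plus-strand VCF representation of a call."""
    if call.kind == "snv":
        return call.gpos, call.gref, call.galt
    if call.kind == "ins":
        return call.gpos, call.gref, call.galt
    # deletion: anchor on the plus-strand base before the deleted run
    gene = genes[call.gene_id]
    pos = call.gpos - 1
    from .gene_models import genomic_to_transcript, revcomp
    try:
        tb = genomic_to_transcript(gene, pos)
        base = gene.reference_transcript[tb - 1]
        anchor = revcomp(base) if gene.strand == "-" else base
    except Exception:
        anchor = "N"
    return pos, anchor + call.gref, anchor


def write_vcf(call_sets: dict[str, list[VariantCall]],
              genes: dict[str, GeneModel], path: str | Path) -> None:
    """Write a multi-sample VCF 4.2 (one sample column per animal)."""
    animals = sorted(call_sets)
    sites: dict[tuple, dict[str, str]] = {}
    meta: dict[tuple, VariantCall] = {}
    for animal, calls in call_sets.items():
        for call in calls:
            pos, ref, alt = _vcf_site(call, genes)
            key = (call.chromosome, pos, ref, alt, call.gene_id)
            gt = "0/1" if call.zygosity == "het" else "1/1"
            sites.setdefault(key, {})[animal] = gt
            meta.setdefault(key, call)

    lines = [
        "##fileformat=VCFv4.2",
        f"##source=fcgrseq-{__version__}",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">',
        '##INFO=<ID=TPOS,Number=1,Type=Integer,'
        'Description="ORF transcript position">',
        '##INFO=<ID=CARRIERS,Number=1,Type=Integer,'
        'Description="Carrier animals">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in sorted({k[0] for k in sites}):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(animals))
    for key in sorted(sites, key=lambda k: (k[0], k[1], k[3])):
        chrom, pos, ref, alt, gene_id = key
        gts = sites[key]
        info = (f"GENE={gene_id};TPOS={meta[key].tpos};"
                f"CARRIERS={len(gts)}")
        row = [chrom, str(pos), ".", ref, alt, ".", "PASS", info, "GT"]
        row += [gts.get(a, "0/0") for a in animals]
        lines.append("\t".join(row))
    _atomic_write(Path(path), "\n".join(lines) + "\n")


def read_vcf(path: str | Path, genes: dict[str, GeneModel]
             ) -> dict[str, list[VariantCall]]:
    """Read a cohort VCF back into per-animal calls (via pysam)."""
    import pysam
    from .amplicon_caller import _make_call, normalize_indel
    from .gene_models import genomic_to_transcript, revcomp

    call_sets: dict[str, list[VariantCall]] = {}
    try:
        vcf = pysam.VariantFile(str(path))
    except Exception as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    call_sets = {s: [] for s in vcf.header.samples}
    for rec in vcf:
        gene = genes[rec.info["GENE"]]
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) == 1 and len(alt) == 1:
            kind = "snv"
            t, tref, talt = genomic_to_transcript(gene, rec.pos, ref, alt)
            pos_t, seq_t = t, talt
        elif len(alt) > len(ref) and alt.startswith(ref):
            kind = "ins"
            ins = alt[len(ref):]
            if gene.strand == "-":
                pos_t = genomic_to_transcript(gene, rec.pos) - 1
                seq_t = revcomp(ins)
            else:
                pos_t = genomic_to_transcript(gene, rec.pos)
                seq_t = ins
        elif len(ref) > len(alt) and ref.startswith(alt):
            kind = "del"
            dele = ref[len(alt):]
            if gene.strand == "-":
                pos_t = genomic_to_transcript(gene, rec.pos + len(dele))
                seq_t = revcomp(dele)
            else:
                pos_t = genomic_to_transcript(gene, rec.pos + 1)
                seq_t = dele
        else:
            raise ValueError(f"unsupported VCF allele pair {ref}>{alt}")
        for sample in rec.samples.values():
            gt = sample["GT"]
            if gt is None or not any(gt):
                continue
            zyg = "hom" if all(a == 1 for a in gt if a is not None) else "het"
            call_sets[sample.name].append(
                _make_call(gene, kind, pos_t, seq_t, zyg, 0, 1))
    return call_sets


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def annotate_call(call: VariantCall, gene: GeneModel,
                  window: int = 2):
    """(effect, table domain, interface class) for one call."""
    if call.kind == "snv":
        tv = TranscriptVariant("snv", call.tpos, call.tref, call.talt)
    elif call.kind == "ins":
        tv = TranscriptVariant("ins", call.tpos, "", call.talt)
    else:
        tv = TranscriptVariant("del", call.tpos, call.tref, "")
    effect = classify_effect(tv, gene)
    if effect.category == "UTR":
        return effect, "", ""
    domain = assign_table_domain(effect.mature_residue_index, gene)
    iface = ""
    if effect.category == "nonsynonymous SNP":
        iface = classify_interface(effect.mature_residue_index, gene,
                                   window).interface_class
    return effect, domain, iface


def variant_table(records: list[CohortVariantRecord]) -> pd.DataFrame:
    rows = []
    for r in sorted(records, key=lambda r: -r.carrier_count):
        eff = r.effect
        rows.append({
            "Variant": r.variant_key,
            "Description": TABLE_DESCRIPTION.get(eff.category, eff.category)
            if eff else "",
            "Exon": r.exon,
            "ANNOVAR NT": eff.annovar_nt if eff else "",
            "ANNOVAR AA": eff.annovar_aa if eff else "",
            "Transcript NT": eff.mature_nt if eff else "",
            "Mature protein AA": eff.mature_aa if eff else "",
            "Domain": r.domain,
            "% Carriers": f"{r.percent_display} "
                          f"({r.carrier_count}/{r.cohort_size})",
        })
    return pd.DataFrame(rows, columns=VARIANT_TABLE_COLUMNS)


def write_variant_table(records, path: str | Path) -> None:
    df = records if isinstance(records, pd.DataFrame) \
        else variant_table(records)
    _atomic_write(Path(path), df.to_csv(sep="\t", index=False))


def write_isoform_tables(abundance: pd.DataFrame, carriers: pd.DataFrame,
                         matrix_path: str | Path,
                         table_path: str | Path) -> None:
    _atomic_write(Path(matrix_path),
                  abundance.to_csv(sep="\t", index_label="animal"))
    _atomic_write(Path(table_path), carriers.to_csv(sep="\t", index=False))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _spec_from_config(cfg: dict) -> CohortSpec:
    sim = cfg.get("simulate", {})
    variants = [VariantSpec(**v) for v in sim.get("variants", [])]
    return CohortSpec(
        n_animals=cfg.get("n_animals", 206),
        variant_specs=variants,
        isoform_mixture=sim.get("isoform_mixture", {}),
        depth=sim.get("depth", 50),
        error_rate=sim.get("error_rate", 0.002),
        indel_error_rate=sim.get("indel_error_rate", 0.0002),
        seed=cfg.get("seed", 0),
        genes=cfg.get("genes", []),
    )


def load_pipeline_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    cfg["_digest"] = hashlib.sha256(
        Path(path).read_bytes()).hexdigest()
    return cfg


def run_pipeline(config: dict | str | Path) -> CohortReport:
    """Execute the full analysis described by a config mapping.

    The config references gene models and either a simulation spec
    (``simulate:``) or a directory of per-animal FASTQ files
    (``reads_dir``, files named ``{animal}_{gene}.fastq``).
    """
    if not isinstance(config, dict):
        config = load_pipeline_config(config)
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    caller_params = CallerParams(**config.get("caller", {}))
    scoring = ScoringParams(**config.get("scoring", {}))

    try:
        genes = load_gene_config(config.get("gene_config"))
    except Exception as exc:
        raise RuntimeError(f"stage gene-models failed: {exc}") from exc
    gene_ids = config.get("genes") or sorted(genes)
    missing = [g for g in gene_ids if g not in genes]
    if missing:
        raise RuntimeError(f"stage gene-models failed: unknown gene(s) "
                           f"{missing}")

    # -- stage: obtain reads -------------------------------------------
    if "simulate" in config:
        spec = _spec_from_config(config)
        spec.genes = gene_ids
        log.info("simulate: %d animals, depth %d", spec.n_animals,
                 spec.depth)
        reads, truth = simulate_cohort(spec, genes)
    elif "reads_dir" in config:
        reads = _load_reads_dir(Path(config["reads_dir"]), gene_ids)
        truth = None
    else:
        raise RuntimeError("stage input failed: config needs 'simulate' "
                           "or 'reads_dir'")

    # -- stage: align + call -------------------------------------------
    call_sets: dict[str, dict[str, list[VariantCall]]] = {
        g: {} for g in gene_ids}
    for animal, per_gene in reads.items():
        for gene_id in gene_ids:
            gene = genes[gene_id]
            alns = [align_read(seq, gene.reference_transcript, scoring,
                               read_id=rid, gene_id=gene_id)
                    for rid, seq in per_gene.get(gene_id, [])]
            n_invalid = sum(not a.valid for a in alns)
            if n_invalid:
                log.info("%s/%s: %d invalid alignments dropped", animal,
                         gene_id, n_invalid)
            pile = build_pileup(alns, gene.reference_transcript)
            calls, _ = call_genotypes(pile, gene, caller_params)
            call_sets[gene_id][animal] = calls

    # -- stage: aggregate + annotate + filter --------------------------
    cohort_size = len(reads)
    tables, recs = {}, {}
    window = thresholds["interface_window"]
    for gene_id in gene_ids:
        gene = genes[gene_id]
        records = aggregate_cohort(
            call_sets[gene_id], cohort_size,
            annotate=lambda c, g=gene: annotate_call(c, g, window))
        retained = filter_min_fraction(
            records, thresholds["min_carrier_fraction"])
        log.info("%s: %d variants, %d retained at >=%.0f%%", gene_id,
                 len(records), len(retained),
                 100 * thresholds["min_carrier_fraction"])
        recs[gene_id] = retained
        tables[gene_id] = variant_table(retained)

    # -- stage: isoform quantification ---------------------------------
    per_animal: dict[str, dict[str, float]] = {}
    protein_ids: dict[str, str] = {}
    for gene_id in gene_ids:
        isos = gene_isoforms(genes[gene_id])
        if len(isos) < 2:
            continue
        protein_ids.update({i.isoform_id: i.protein_id for i in isos})
        for animal, per_gene in reads.items():
            if not per_gene.get(gene_id):
                continue
            props = quantify_animal(per_gene[gene_id], isos, scoring)
            per_animal.setdefault(animal, {}).update(props)
    if per_animal:
        abundance = abundance_matrix(per_animal)
        abundance = filter_isoform_set(
            abundance, thresholds["min_isoform_abundance"])
        carriers = isoform_carrier_stats(
            abundance, cohort_size,
            thresholds["isoform_carrier_threshold"], protein_ids)
    else:
        abundance = pd.DataFrame()
        carriers = pd.DataFrame(columns=["Nucleotide Isoform",
                                         "Translated Protein Isoform",
                                         "Carriers", "% Carriers"])

    report = CohortReport(
        variant_tables=tables,
        variant_records=recs,
        abundance=abundance,
        isoform_carriers=carriers,
        metadata={
            "tool_version": __version__,
            "seed": config.get("seed", 0),
            "cohort_size": cohort_size,
            "thresholds": thresholds,
            "config_digest": config.get("_digest", ""),
        },
    )
    if truth is not None:
        report.metadata["simulated"] = True

    out_dir = config.get("output_dir")
    if out_dir:
        out = Path(out_dir)
        for gene_id, table in tables.items():
            write_variant_table(table, out / f"{gene_id}_variants.tsv")
        write_vcf({a: [c for g in gene_ids
                       for c in call_sets[g].get(a, [])]
                   for a in reads}, genes, out / "cohort.vcf")
        write_isoform_tables(abundance, carriers,
                             out / "isoform_abundance.tsv",
                             out / "isoform_carriers.tsv")
        _atomic_write(out / "run_metadata.json",
                      json.dumps({**report.metadata,
                                  "report_digest": report.digest()},
                                 indent=1))
    return report


def _load_reads_dir(reads_dir: Path, gene_ids) -> dict:
    reads: dict[str, dict[str, list]] = {}
    for path in sorted(reads_dir.glob("*.fastq*")):
        stem = path.name.split(".fastq")[0]
        try:
            animal, gene_id = stem.rsplit("_", 1)
        except ValueError:
            continue
        if gene_id in gene_ids:
            reads.setdefault(animal, {})[gene_id] = read_fastq(path)
    if not reads:
        raise RuntimeError(f"stage input failed: no FASTQ files matching "
                           f"'{{animal}}_{{gene}}.fastq' in {reads_dir}")
    return reads
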