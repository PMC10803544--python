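"""Synthetic cohort generator: CCS-like amplicon reads with known truth.

Emulates the study design this package targets: full-length cDNA amplicons
of each Fcγ receptor gene from a cohort of animals (default 206), sequenced
as high-accuracy long reads.  Each animal carries a diploid genotype for
every configured variant and, per gene, a mixture of splice isoforms; reads
are full-length copies of a (haplotype × isoform) template with independent
substitution and rare single-base indel errors.

Genotypes can be drawn under Hardy–Weinberg equilibrium from an allele
frequency, or assigned to an exact number of carrier animals so that
published carrier counts can be reproduced without sampling noise.

Defaults (depth 50 reads per gene per animal, substitution rate 2e-3,
indel rate 2e-4) are simulator choices representative of circular-consensus
long-read accuracy; the emulated study reports no per-animal depths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gene_models import (GeneModel, IsoformModel, build_isoform,
                          gene_isoforms, genomic_to_transcript, revcomp)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class VariantSpec:
    """A variant to spike into the cohort, VCF-style plus-strand alleles.

    For SNVs ``ref``/``alt`` are single bases at ``gpos``; for insertions
    ``alt`` = ``ref`` + inserted plus-strand sequence with ``gpos`` the
    anchor base.  Exactly one of ``allele_frequency`` (Hardy–Weinberg
    sampling) or ``carrier_count`` (exact assignment, heterozygous
    carriers) must be set.
    """

    gene_id: str
    gpos: int
    ref: str
    alt: str
    allele_frequency: float | None = None
    carrier_count: int | None = None

    def __post_init__(self):
        if (self.allele_frequency is None) == (self.carrier_count is None):
            raise ValueError(
                "set exactly one of allele_frequency / carrier_count")
        if self.allele_frequency is not None and not (
                0.0 <= self.allele_frequency <= 1.0):
            raise ValueError("allele frequency outside [0, 1]")


@dataclass
class CohortSpec:
    n_animals: int = 206
    variant_specs: list[VariantSpec] = field(default_factory=list)
    #: gene_id -> {"weights": {isoform_id: w}} or
    #: {"dirichlet": alpha} (per-animal random mixture over that gene's
    #: configured isoforms); genes absent here express the principal only
    isoform_mixture: dict = field(default_factory=dict)
    depth: int = 50
    error_rate: float = 0.002
    indel_error_rate: float = 0.0002
    seed: int = 0
    genes: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0 <= self.error_rate < 1 and 0 <= self.indel_error_rate < 1):
            raise ValueError("error rates must be in [0, 1)")
        for mix in self.isoform_mixture.values():
            if "weights" in mix:
                w = np.array(list(mix["weights"].values()), dtype=float)
                if (w < 0).any() or w.sum() <= 0:
                    raise ValueError("mixture weights must be nonnegative "
                                     "and sum to a positive value")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    animals: list[str]
    #: animal -> {variant_key: "het" | "hom"}
    genotypes: dict
    #: animal -> gene_id -> {isoform_id: proportion}
    isoform_props: dict

    def carrier_count(self, variant_key: str) -> int:
        return sum(1 for a in self.animals
                   if variant_key in self.genotypes[a])

    def variant_carrier_counts(self) -> dict:
        keys = {k for a in self.animals for k in self.genotypes[a]}
        return {k: self.carrier_count(k) for k in sorted(keys)}

    def isoform_carrier_counts(self, threshold: float = 0.01) -> dict:
        out: dict[str, int] = {}
        for a in self.animals:
            for props in self.isoform_props[a].values():
                for iso, p in props.items():
                    if p > threshold:
                        out[iso] = out.get(iso, 0) + 1
        return out


def variant_key(gene: GeneModel, spec: VariantSpec) -> str:
    if len(spec.alt) > len(spec.ref):      # insertion
        return f"{gene.chromosome}:{spec.gpos}:>{spec.alt[len(spec.ref):]}"
    return f"{gene.chromosome}:{spec.gpos}:{spec.ref}>{spec.alt}"


def _to_transcript_variant(gene: GeneModel, spec: VariantSpec):
    """(kind, transcript position/anchor, transcript alt seq)."""
    if len(spec.ref) == 1 and len(spec.alt) == 1:
        t, _, talt = genomic_to_transcript(gene, spec.gpos, spec.ref,
                                           spec.alt)
        return "snv", t, talt
    if len(spec.alt) > len(spec.ref) and spec.alt.startswith(spec.ref):
        ins = spec.alt[len(spec.ref):]
        if gene.strand == "-":
            # plus-strand insertion after gpos = transcript insertion
            # after t(gpos) - 1
            t = genomic_to_transcript(gene, spec.gpos) - 1
            return "ins", t, revcomp(ins)
        return "ins", genomic_to_transcript(gene, spec.gpos), ins
    raise ValueError(f"unsupported variant spec {spec}")


def sample_genotypes(spec: CohortSpec, genes: dict[str, GeneModel],
                     rng: np.random.Generator | None = None) -> dict:
    """Diploid alternate-allele copy numbers per animal and variant.

    Returns ``animal_index -> {variant_key: copies}`` with copies in
    {1, 2}.  Hardy–Weinberg mode draws copies ~ Binomial(2, af);
    carrier-count mode marks exactly ``carrier_count`` animals as
    heterozygous carriers.
    """
    rng = rng or np.random.default_rng(spec.seed)
    genotypes: dict[int, dict[str, int]] = {
        i: {} for i in range(spec.n_animals)}
    for vs in spec.variant_specs:
        gene = genes[vs.gene_id]
        key = variant_key(gene, vs)
        if vs.carrier_count is not None:
            if vs.carrier_count > spec.n_animals:
                raise ValueError("carrier_count exceeds cohort size")
            carriers = rng.choice(spec.n_animals, size=vs.carrier_count,
                                  replace=False)
            for i in carriers:
                genotypes[int(i)][key] = 1
        else:
            copies = rng.binomial(2, vs.allele_frequency,
                                  size=spec.n_animals)
            for i in np.nonzero(copies)[0]:
                genotypes[int(i)][key] = int(copies[i])
    return genotypes


def _edit_offset_events(gene: GeneModel, isoform: IsoformModel):
    """(principal position, delta) events describing the isoform's
    coordinate shift relative to the principal transcript."""
    events = []
    for edit in isoform.splice_structure:
        d = dict(edit)
        kind = d["type"]
        if kind == "include_exon":
            cas = gene.cassette(d["exon"])
            events.append((cas.after_t, len(cas.seq)))
        elif kind == "extend_exon_5prime":
            exon = next(e for e in gene.exons if e.label == d["exon"])
            events.append((exon.t_start - 1, len(d["seq"])))
        elif kind == "ins_codon":
            events.append((d["after_t"], len(d["seq"])))
        elif kind == "del_codon":
            events.append((3 * (d["codon"] - 1), -3))
    return sorted(events)


def _shift_to_isoform(tpos: int, events) -> int:
    """Map a principal-transcript position into isoform coordinates."""
    shift = 0
    for pos, delta in events:
        if delta > 0 and pos < tpos:
            shift += delta
        elif delta < 0:
            if pos < tpos <= pos - delta:
                raise ValueError(
                    f"variant at transcript {tpos} falls in a region absent "
                    f"from the isoform")
            if tpos > pos - delta:
                shift += delta
    return tpos + shift


def build_haplotypes(gene: GeneModel, isoform: IsoformModel,
                     hap_variants: tuple[list, list]) -> tuple[str, str]:
    """Apply each haplotype's variants to the isoform transcript.

    ``hap_variants`` holds, per haplotype, ``(kind, tpos, alt)`` tuples in
    principal-transcript coordinates; variants are applied right-to-left so
    earlier coordinates stay valid.
    """
    events = _edit_offset_events(gene, isoform)
    out = []
    for variants in hap_variants:
        seq = isoform.transcript_seq
        placed = sorted(
            ((_shift_to_isoform(t, events), kind, alt)
             for kind, t, alt in variants), reverse=True)
        seen = set()
        for t, kind, alt in placed:
            if t in seen:
                raise ValueError(
                    f"conflicting variants at transcript position {t}")
            seen.add(t)
            if kind == "snv":
                seq = seq[:t - 1] + alt + seq[t:]
            elif kind == "ins":
                seq = seq[:t] + alt + seq[t:]
            elif kind == "del":
                seq = seq[:t - 1] + seq[t - 1 + len(alt):]
            else:
                raise ValueError(f"unknown variant kind {kind}")
        out.append(seq)
    return out[0], out[1]


def _mutate_read(seq: str, error_rate: float, indel_rate: float,
                 rng: np.random.Generator) -> str:
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = codes.size
    n_sub = rng.binomial(n, error_rate)
    if n_sub:
        pos = rng.choice(n, size=n_sub, replace=False)
        for p in pos:
            choices = _BASES[_BASES != codes[p]]
            codes[p] = choices[rng.integers(len(choices))]
    out = codes.tobytes().decode()
    n_indel = rng.binomial(n, indel_rate)
    if n_indel:
        for p in sorted(rng.choice(n, size=n_indel, replace=False),
                        reverse=True):
            if rng.random() < 0.5:
                base = chr(_BASES[rng.integers(4)])
                out = out[:p] + base + out[p:]
            elif len(out) > 1:
                out = out[:p] + out[p + 1:]
    return out


def emit_reads(templates: list[str], weights, depth: int,
               error_rate: float, indel_error_rate: float,
               rng: np.random.Generator, prefix: str = "read"
               ) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Draw ``depth`` full-length reads from weighted templates.

    Returns the reads and the per-template draw counts.  Read names carry
    only a serial number.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    picks = rng.choice(len(templates), size=depth, p=w)
    reads = []
    for i, k in enumerate(picks):
        seq = _mutate_read(templates[k], error_rate, indel_error_rate, rng)
        reads.append((f"{prefix}{i:05d}", seq))
    counts = np.bincount(picks, minlength=len(templates))
    return reads, counts


def _gene_isoform_set(gene: GeneModel) -> list[IsoformModel]:
    isos = gene_isoforms(gene)
    if not isos:
        isos = [build_isoform(gene, [], isoform_id=f"{gene.gene_id}_ref")]
    return isos


def _animal_mixture(gene: GeneModel, isos, mix_spec, rng) -> np.ndarray:
    if mix_spec is None:
        w = np.zeros(len(isos))
        w[0] = 1.0
        return w
    if "weights" in mix_spec:
        w = np.array([mix_spec["weights"].get(i.isoform_id, 0.0)
                      for i in isos], dtype=float)
        if w.sum() <= 0:
            raise ValueError(f"{gene.gene_id}: empty isoform mixture")
        return w / w.sum()
    alpha = mix_spec.get("dirichlet", 1.0)
    alpha = np.full(len(isos), float(alpha)) if np.isscalar(alpha) \
        else np.asarray(alpha, dtype=float)
    return rng.dirichlet(alpha)


def simulate_cohort(spec: CohortSpec, genes: dict[str, GeneModel],
                    out_dir: str | Path | None = None
                    ) -> tuple[dict, SimTruth]:
    """Simulate the whole cohort.

    Returns ``(reads, truth)`` where ``reads[animal][gene_id]`` is a list
    of ``(read_id, sequence)``.  With ``out_dir`` set, one FASTQ per animal
    and gene plus a JSON truth sidecar are also written.  Deterministic for
    a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    gene_ids = spec.genes or sorted(
        {vs.gene_id for vs in spec.variant_specs}
        | set(spec.isoform_mixture))
    if not gene_ids:
        raise ValueError("no genes to simulate")
    animals = [f"RM{i + 1:03d}" for i in range(spec.n_animals)]

    genotypes = sample_genotypes(spec, genes, rng)
    iso_sets = {g: _gene_isoform_set(genes[g]) for g in gene_ids}
    tvariants = {}  # gene -> [(key, kind, tpos, alt)]
    for vs in spec.variant_specs:
        gene = genes[vs.gene_id]
        kind, t, alt = _to_transcript_variant(gene, vs)
        tvariants.setdefault(vs.gene_id, []).append(
            (variant_key(gene, vs), kind, t, alt))

    reads_out: dict[str, dict[str, list]] = {}
    truth_gt: dict[str, dict[str, str]] = {}
    truth_props: dict[str, dict[str, dict[str, float]]] = {}

    for idx, animal in enumerate(animals):
        reads_out[animal] = {}
        truth_props[animal] = {}
        truth_gt[animal] = {}
        for gene_id in gene_ids:
            gene = genes[gene_id]
            isos = iso_sets[gene_id]
            mixture = _animal_mixture(
                gene, isos, spec.isoform_mixture.get(gene_id), rng)
            truth_props[animal][gene_id] = {
                iso.isoform_id: float(p) for iso, p in zip(isos, mixture)}

            hap_vars: tuple[list, list] = ([], [])
            for key, kind, t, alt in tvariants.get(gene_id, []):
                copies = genotypes[idx].get(key, 0)
                if copies == 2:
                    hap_vars[0].append((kind, t, alt))
                    hap_vars[1].append((kind, t, alt))
                    truth_gt[animal][key] = "hom"
                elif copies == 1:
                    hap_vars[int(rng.integers(2))].append((kind, t, alt))
                    truth_gt[animal][key] = "het"

            templates, weights = [], []
            for iso, p in zip(isos, mixture):
                h1, h2 = build_haplotypes(gene, iso, hap_vars)
                templates += [h1, h2]
                weights += [p / 2, p / 2]
            reads, _ = emit_reads(
                templates, weights, spec.depth, spec.error_rate,
                spec.indel_error_rate, rng, prefix=f"{animal}_{gene_id}_")
            reads_out[animal][gene_id] = reads

    truth = SimTruth(animals, truth_gt, truth_props)
    if out_dir is not None:
        _write_cohort(Path(out_dir), reads_out, truth)
    return reads_out, truth


def _write_cohort(out_dir: Path, reads_out: dict, truth: SimTruth) -> None:
    from .reporting import write_fastq
    out_dir.mkdir(parents=True, exist_ok=True)
    for animal, per_gene in reads_out.items():
        for gene_id, reads in per_gene.items():
            write_fastq(reads, out_dir / f"{animal}_{gene_id}.fastq")
    sidecar = {
        "animals": truth.animals,
        "genotypes": truth.genotypes,
        "isoform_proportions": truth.isoform_props,
    }
    (out_dir / "truth.json").write_text(json.dumps(sidecar, indent=1))


def load_truth(path: str | Path) -> SimTruth:
    data = json.loads(Path(path).read_text())
    return SimTruth(data["animals"], data["genotypes"],
                    data["isoform_proportions"])
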