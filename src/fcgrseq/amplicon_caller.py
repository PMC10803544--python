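"""Read alignment, pileup construction and diploid genotype calling.

Full-length amplicon reads are aligned to the gene's principal transcript
with global (Needleman–Wunsch/Gotoh) affine-gap alignment — appropriate
because the reads span the whole amplicon, so both ends are informative.
The dynamic program is a numba kernel; a gap of length ``k`` costs
``gap_open + k * gap_extend``.

Genotypes are called from per-column allele counts with simple thresholds
(documented in :class:`CallerParams`): an alternate allele supported by at
least ``min_alt_reads`` reads is called heterozygous when its fraction
falls inside ``het_fraction_range`` and homozygous above
``hom_fraction_min``.  Columns below ``min_depth`` are reported as
uncallable rather than silently absent.  Indels are left-normalized so
that duplications are canonically placed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .gene_models import GeneModel, revcomp, transcript_to_genomic

_NEG = np.int32(-(10 ** 7))

# op codes in alignment tracebacks
OP_MATCH, OP_MISMATCH, OP_INS, OP_DEL = 0, 1, 2, 3

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i
_BASES = "ACGT"


def encode_seq(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringParams:
    match: int = 2
    mismatch: int = -4
    gap_open: int = -4
    gap_extend: int = -2
    #: minimum score per read base for a usable alignment (substitute for a
    #: mapping-quality cutoff, which has no meaning with one reference)
    min_score_per_base: float = 1.0


@dataclass(frozen=True)
class CallerParams:
    min_depth: int = 10
    min_alt_reads: int = 3
    het_fraction_range: tuple[float, float] = (0.25, 0.75)
    hom_fraction_min: float = 0.8


@dataclass
class ReadAlignment:
    read_id: str
    gene_id: str
    score: int
    valid: bool
    ops: np.ndarray        # OP_* codes, one per alignment column
    ref_pos: np.ndarray    # 1-based transcript position (anchor for OP_INS)
    read_pos: np.ndarray   # 1-based read position (0 for OP_DEL)
    read_codes: np.ndarray


@dataclass(frozen=True)
class PileupColumn:
    tpos: int
    depth: int
    allele_counts: dict


@dataclass
class Pileup:
    ref_seq: str
    depth: np.ndarray                      # (L + 1,), index 0 unused
    base_counts: np.ndarray                # (L + 1, 4)
    ins_counts: dict = field(default_factory=dict)  # (anchor, seq) -> n
    del_counts: dict = field(default_factory=dict)  # (start, seq) -> n
    n_reads: int = 0

    def column(self, tpos: int) -> PileupColumn:
        counts = {}
        for b in range(4):
            c = int(self.base_counts[tpos, b])
            if c:
                counts[_BASES[b]] = c
        for (anchor, seq), c in self.ins_counts.items():
            if anchor == tpos:
                counts[f"+{seq}"] = c
        for (start, seq), c in self.del_counts.items():
            if start == tpos:
                counts[f"-{seq}"] = c
        return PileupColumn(tpos, int(self.depth[tpos]), counts)

    def columns(self):
        for t in range(1, len(self.depth)):
            yield self.column(t)


@dataclass(frozen=True)
class VariantCall:
    gene_id: str
    chromosome: str
    gpos: int
    gref: str
    galt: str
    tpos: int
    tref: str
    talt: str
    kind: str              # snv | ins | del
    zygosity: str          # het | hom
    alt_count: int
    depth: int
    allele_fraction: float
    genomic_key: str
    exon: str = ""


# ---------------------------------------------------------------------------
# Gotoh global alignment (numba)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gotoh(x, y, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = x.size, y.size
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    E = np.empty((n + 1, m + 1), dtype=np.int32)
    F = np.empty((n + 1, m + 1), dtype=np.int32)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.uint8)   # 0 diag, 1 E, 2 F
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)   # 1 = extended
    ptrF = np.zeros((n + 1, m + 1), dtype=np.uint8)

    H[0, 0] = 0
    E[0, 0] = _NEG
    F[0, 0] = _NEG
    for j in range(1, m + 1):
        E[0, j] = gap_open + gap_extend * j
        H[0, j] = E[0, j]
        F[0, j] = _NEG
        ptrH[0, j] = 1
        ptrE[0, j] = 1
    for i in range(1, n + 1):
        F[i, 0] = gap_open + gap_extend * i
        H[i, 0] = F[i, 0]
        E[i, 0] = _NEG
        ptrH[i, 0] = 2
        ptrF[i, 0] = 1

    for i in range(1, n + 1):
        xi = x[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open + gap_extend
            e_ext = E[i, j - 1] + gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            else:
                E[i, j] = e_open
                ptrE[i, j] = 0
            f_open = H[i - 1, j] + gap_open + gap_extend
            f_ext = F[i - 1, j] + gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_open
                ptrF[i, j] = 0
            s = match if xi == y[j - 1] else mismatch
            diag = H[i - 1, j - 1] + s
            best = diag
            ptr = 0
            if E[i, j] > best:
                best = E[i, j]
                ptr = 1
            if F[i, j] > best:
                best = F[i, j]
                ptr = 2
            H[i, j] = best
            ptrH[i, j] = ptr

    # traceback
    cap = n + m
    ops = np.empty(cap, dtype=np.uint8)
    rpos = np.empty(cap, dtype=np.int32)
    qpos = np.empty(cap, dtype=np.int32)
    k = cap
    i, j = n, m
    state = 0  # 0 H, 1 E, 2 F
    while i > 0 or j > 0:
        if state == 0:
            state = ptrH[i, j]
            if state == 0:
                k -= 1
                ops[k] = OP_MATCH if x[i - 1] == y[j - 1] else OP_MISMATCH
                rpos[k] = i
                qpos[k] = j
                i -= 1
                j -= 1
        elif state == 1:
            k -= 1
            ops[k] = OP_INS
            rpos[k] = i
            qpos[k] = j
            if ptrE[i, j] == 0:
                state = 0
            j -= 1
        else:
            k -= 1
            ops[k] = OP_DEL
            rpos[k] = i
            qpos[k] = 0
            if ptrF[i, j] == 0:
                state = 0
            i -= 1
    return H[n, m], ops[k:], rpos[k:], qpos[k:]


@njit(cache=True)
def _accumulate(ops, rpos, qpos, read_codes, depth,
                base_counts):  # pragma: no cover
    for k in range(ops.size):
        op = ops[k]
        if op == OP_MATCH or op == OP_MISMATCH:
            t = rpos[k]
            depth[t] += 1
            b = read_codes[qpos[k] - 1]
            if b < 4:
                base_counts[t, b] += 1
        elif op == OP_DEL:
            depth[rpos[k]] += 1


@njit(cache=True)
def _score_pair(x, y, match, mismatch, gap_open,
                gap_extend):  # pragma: no cover
    """Score-only Gotoh with O(m) memory, for read-isoform compatibility."""
    n, m = x.size, y.size
    H = np.empty(m + 1, dtype=np.int32)
    E = np.empty(m + 1, dtype=np.int32)
    F = np.empty(m + 1, dtype=np.int32)
    H[0] = 0
    E[0] = _NEG
    for j in range(1, m + 1):
        H[j] = gap_open + gap_extend * j
        E[j] = H[j]
        F[j] = _NEG
    for i in range(1, n + 1):
        diag = H[0]
        H[0] = gap_open + gap_extend * i
        F[0] = H[0]
        xi = x[i - 1]
        for j in range(1, m + 1):
            e = max(H[j - 1] + gap_open + gap_extend, E[j - 1] + gap_extend)
            f = max(H[j] + gap_open + gap_extend, F[j] + gap_extend)
            s = match if xi == y[j - 1] else mismatch
            h = diag + s
            if e > h:
                h = e
            if f > h:
                h = f
            diag = H[j]
            H[j] = h
            E[j] = e
            F[j] = f
    return H[m]


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def align_read(read_seq: str, reference_transcript: str,
               scoring: ScoringParams = ScoringParams(),
               read_id: str = "", gene_id: str = "") -> ReadAlignment:
    """Optimal global affine-gap alignment of one read to the transcript."""
    codes = encode_seq(read_seq)
    ref_codes = encode_seq(reference_transcript)
    if codes.size == 0 or ref_codes.size == 0:
        return ReadAlignment(read_id, gene_id, int(_NEG), False,
                             np.empty(0, np.uint8), np.empty(0, np.int32),
                             np.empty(0, np.int32), codes)
    score, ops, rpos, qpos = _gotoh(
        ref_codes, codes, scoring.match, scoring.mismatch,
        scoring.gap_open, scoring.gap_extend)
    valid = score >= scoring.min_score_per_base * codes.size
    return ReadAlignment(read_id, gene_id, int(score), bool(valid),
                         ops, rpos, qpos, codes)


def alignment_score(read_seq: str, reference: str,
                    scoring: ScoringParams = ScoringParams()) -> int:
    """Alignment score only (linear memory); used for isoform scoring."""
    a, b = encode_seq(reference), encode_seq(read_seq)
    if a.size == 0 or b.size == 0:
        return int(_NEG)
    return int(_score_pair(a, b, scoring.match, scoring.mismatch,
                           scoring.gap_open, scoring.gap_extend))


def _indel_events(aln: ReadAlignment):
    """Yield ('ins', anchor, seq) / ('del', start, seq) runs."""
    ops = aln.ops
    k = 0
    n = ops.size
    while k < n:
        if ops[k] == OP_INS:
            anchor = int(aln.ref_pos[k])
            chars = []
            while k < n and ops[k] == OP_INS and int(aln.ref_pos[k]) == anchor:
                chars.append(_BASES[aln.read_codes[aln.read_pos[k] - 1]]
                             if aln.read_codes[aln.read_pos[k] - 1] < 4
                             else "N")
                k += 1
            yield "ins", anchor, "".join(chars)
        elif ops[k] == OP_DEL:
            start = int(aln.ref_pos[k])
            end = start
            while k < n and ops[k] == OP_DEL:
                end = int(aln.ref_pos[k])
                k += 1
            yield "del", start, None, end
        else:
            k += 1


def build_pileup(alignments, reference_transcript: str) -> Pileup:
    """Per-position allele counts over the valid alignments of one gene."""
    L = len(reference_transcript)
    depth = np.zeros(L + 1, dtype=np.int64)
    base_counts = np.zeros((L + 1, 4), dtype=np.int64)
    pile = Pileup(reference_transcript, depth, base_counts)
    for aln in alignments:
        if not aln.valid:
            continue
        pile.n_reads += 1
        _accumulate(aln.ops, aln.ref_pos, aln.read_pos, aln.read_codes,
                    depth, base_counts)
        for ev in _indel_events(aln):
            if ev[0] == "ins":
                key = (ev[1], ev[2])
                pile.ins_counts[key] = pile.ins_counts.get(key, 0) + 1
            else:
                start, end = ev[1], ev[3]
                key = (start, reference_transcript[start - 1:end])
                pile.del_counts[key] = pile.del_counts.get(key, 0) + 1
    return pile


def normalize_indel(kind: str, pos: int, seq: str, reference: str
                    ) -> tuple[int, str, bool]:
    """Left-align an indel; detect duplications.

    For ``ins`` the input/output position is the anchor (insertion goes
    after it); for ``del`` it is the first deleted base.  Returns
    ``(position, sequence, is_duplication)``.  Idempotent.
    """
    if kind == "ins":
        anchor, s = pos, seq
        while anchor >= 1 and reference[anchor - 1] == s[-1]:
            s = reference[anchor - 1] + s[:-1]
            anchor -= 1
        is_dup = reference[anchor:anchor + len(s)] == s
        return anchor, s, is_dup
    if kind == "del":
        start, k = pos, len(seq)
        while start > 1 and reference[start - 2] == reference[start + k - 2]:
            start -= 1
        return start, reference[start - 1:start - 1 + k], False
    raise ValueError(f"not an indel kind: {kind}")


def right_shift_ins(anchor: int, seq: str, reference: str
                    ) -> tuple[int, str]:
    """Rightmost equivalent transcript placement of an insertion.

    Genomic plus-strand left-alignment of a minus-strand gene's insertion
    corresponds to the rightmost transcript placement.
    """
    s = seq
    while anchor < len(reference) and reference[anchor] == s[0]:
        s = s[1:] + reference[anchor]
        anchor += 1
    return anchor, s


def right_shift_del(start: int, length: int, reference: str) -> int:
    """Rightmost equivalent transcript start of a deletion."""
    while (start + length - 1 < len(reference)
           and reference[start - 1] == reference[start + length - 1]):
        start += 1
    return start


def _genomic_snv(gene: GeneModel, tpos: int, tref: str, talt: str):
    g = transcript_to_genomic(gene, tpos)
    if gene.strand == "-":
        return g, revcomp(tref), revcomp(talt)
    return g, tref, talt


def _genomic_ins(gene: GeneModel, anchor: int, seq: str):
    """Plus-strand anchor position and inserted sequence for a transcript
    insertion after ``anchor``."""
    if gene.strand == "-":
        return transcript_to_genomic(gene, anchor + 1), revcomp(seq)
    return transcript_to_genomic(gene, anchor), seq


def call_genotypes(pileup: Pileup, gene: GeneModel,
                   params: CallerParams = CallerParams()
                   ) -> tuple[list[VariantCall], list[int]]:
    """Threshold diploid genotyping of one animal's pileup.

    Returns ``(calls, uncallable_positions)``; positions whose depth falls
    below ``min_depth`` are reported uncallable rather than dropped.
    """
    lo, hi = params.het_fraction_range
    ref = pileup.ref_seq
    calls: list[VariantCall] = []
    uncallable: list[int] = []

    candidates: dict[int, list] = {}
    for t in range(1, len(ref) + 1):
        d = int(pileup.depth[t])
        if d < params.min_depth:
            uncallable.append(t)
            continue
        ref_code = _CODE[ord(ref[t - 1])]
        for b in range(4):
            if b == ref_code:
                continue
            c = int(pileup.base_counts[t, b])
            if c >= params.min_alt_reads:
                candidates.setdefault(t, []).append(("snv", t, _BASES[b], c))
    for (anchor, seq), c in pileup.ins_counts.items():
        if c >= params.min_alt_reads and anchor >= 1:
            d = int(pileup.depth[anchor]) if anchor < len(pileup.depth) else 0
            if d >= params.min_depth:
                candidates.setdefault(anchor, []).append(("ins", anchor, seq, c))
    for (start, seq), c in pileup.del_counts.items():
        if c >= params.min_alt_reads:
            d = int(pileup.depth[start])
            if d >= params.min_depth:
                candidates.setdefault(start, []).append(("del", start, seq, c))

    for t in sorted(candidates):
        # multi-allelic sites: keep the top two alleles only
        alleles = sorted(candidates[t], key=lambda a: -a[3])[:2]
        for kind, pos, seq, count in alleles:
            d = int(pileup.depth[pos])
            frac = count / d
            if lo <= frac <= hi:
                zyg = "het"
            elif frac >= params.hom_fraction_min:
                zyg = "hom"
            else:
                continue
            calls.append(_make_call(gene, kind, pos, seq, zyg, count, d))
    return calls, uncallable


def _make_call(gene: GeneModel, kind: str, pos: int, seq: str,
               zygosity: str, count: int, depth: int) -> VariantCall:
    chrom = gene.chromosome
    ref = gene.reference_transcript
    if kind == "snv":
        tref = ref[pos - 1]
        g, R, A = _genomic_snv(gene, pos, tref, seq)
        return VariantCall(gene.gene_id, chrom, g, R, A, pos, tref, seq,
                           "snv", zygosity, count, depth, count / depth,
                           f"{chrom}:{g}:{R}>{A}",
                           exon=gene.exon_for_t(pos).label)
    if kind == "ins":
        anchor, s, _ = normalize_indel("ins", pos, seq, ref)
        if gene.strand == "-":
            g_anchor, g_seq = right_shift_ins(anchor, s, ref)
        else:
            g_anchor, g_seq = anchor, s
        g, plus_seq = _genomic_ins(gene, g_anchor, g_seq)
        exon = gene.exon_for_t(max(anchor, 1)).label
        if gene.strand == "-":
            # the plus-strand base at the anchor is transcript base anchor+1
            plus_base = revcomp(ref[g_anchor]) if g_anchor < len(ref) else "N"
        else:
            plus_base = ref[g_anchor - 1] if g_anchor >= 1 else "N"
        return VariantCall(gene.gene_id, chrom, g, plus_base,
                           plus_base + plus_seq, anchor, "", s,
                           "ins", zygosity, count, depth, count / depth,
                           f"{chrom}:{g}:>{plus_seq}", exon=exon)
    # deletion
    start, s, _ = normalize_indel("del", pos, seq, ref)
    k = len(s)
    if gene.strand == "-":
        start_g = right_shift_del(start, k, ref)
        g_lo = transcript_to_genomic(gene, start_g + k - 1)
        plus_del = revcomp(ref[start_g - 1:start_g - 1 + k])
    else:
        g_lo = transcript_to_genomic(gene, start)
        plus_del = s
    return VariantCall(gene.gene_id, chrom, g_lo, plus_del, "", start, s, "",
                       "del", zygosity, count, depth, count / depth,
                       f"{chrom}:{g_lo}:{plus_del}>",
                       exon=gene.exon_for_t(start).label)


def call_animal(reads, gene: GeneModel,
                scoring: ScoringParams = ScoringParams(),
                params: CallerParams = CallerParams()) -> list[VariantCall]:
    """Convenience: align reads, build the pileup and call genotypes."""
    alns = [align_read(seq, gene.reference_transcript, scoring,
                       read_id=rid, gene_id=gene.gene_id)
            for rid, seq in reads]
    pile = build_pileup(alns, gene.reference_transcript)
    calls, _ = call_genotypes(pile, gene, params)
    return calls
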