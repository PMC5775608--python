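"""Structural classification of ERV loci and LTR annotation.

The taxonomy mirrors how ERV integrants degrade in germ lines:

* ``provirus`` — two complete LTRs (U3+R+U5 at both ends) flanking the
  internal region; the LTR pair is identical at integration, so its divergence
  dates the insertion.
* ``processed_pseudogene`` — an L1-retrotransposed copy of an ERV transcript:
  the transcript starts in the 5' R and ends in the 3' R, so the copy lacks
  the 5' LTR's U3 and the 3' LTR's U5 and carries a poly-A tail.
* ``solitary_ltr`` — a single LTR left after LTR-LTR homologous recombination
  removed the internal region and one LTR.
* ``undefined`` — internal sequence present but both LTRs absent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from Bio import Align
from Bio.Seq import Seq

from .io_core import PipelineConfig, ValidationError, revcomp
from .synthetic_data import ERVModel

logger = logging.getLogger("ervography")


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


_LOCAL = _local_aligner()


def local_align_stats(a: str, b: str):
    """Best local alignment of a vs b: (matches, cols, a_start, a_end, b_start, b_end)."""
    if not a or not b:
        return 0, 0, 0, 0, 0, 0
    alns = _LOCAL.align(a, b)
    if len(alns) == 0 or alns.score <= 0:
        return 0, 0, 0, 0, 0, 0
    aln = alns[0]
    blocks_a, blocks_b = aln.aligned
    matches = 0
    aligned_residue_cols = 0
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        aligned_residue_cols += ae - as_
        matches += sum(1 for x, y in zip(a[as_:ae], b[bs:be]) if x == y)
    # count gap columns between blocks as alignment columns
    cols = aligned_residue_cols
    for i in range(1, len(blocks_a)):
        cols += max(blocks_a[i][0] - blocks_a[i - 1][1],
                    blocks_b[i][0] - blocks_b[i - 1][1])
    a_start, a_end = blocks_a[0][0], blocks_a[-1][1]
    b_start, b_end = blocks_b[0][0], blocks_b[-1][1]
    return matches, cols, a_start, a_end, b_start, b_end


@dataclass
class LTRAnnotation:
    ltr5_interval: tuple[int, int] | None = None   # locus-relative, oriented
    ltr3_interval: tuple[int, int] | None = None
    ltr_identity: float | None = None              # defined only when both present
    has_u3_5prime: bool = False
    has_u5_3prime: bool = False
    ltr5_evidence: bool = False                    # any partial LTR match at the 5' end
    ltr3_evidence: bool = False
    polyA: bool = False
    tsd: str | None = None

    @property
    def pair_found(self) -> bool:
        return self.ltr5_interval is not None and self.ltr3_interval is not None


@dataclass
class Putein:
    gene: str
    aa_seq: str
    frame: int
    strand: str
    start: int          # nt, consensus coordinates (+ strand)
    end: int
    disrupted: bool


@dataclass
class PuteinSet:
    puteins: dict = field(default_factory=dict)  # gene -> Putein | None

    def __getitem__(self, gene: str) -> Putein | None:
        return self.puteins.get(gene)


# ---------------------------------------------------------------------------
# LTR detection
# ---------------------------------------------------------------------------

def _segment_present(segment: str, window: str, config: PipelineConfig) -> bool:
    """Is >= segment_coverage of the model segment locally aligned in the window
    at >= segment_min_identity?"""
    if not window:
        return False
    matches, cols, a_start, a_end, *_ = local_align_stats(segment, window)
    if cols == 0:
        return False
    coverage = (a_end - a_start) / len(segment)
    identity = matches / cols
    return coverage >= config.segment_coverage and identity >= config.segment_min_identity


def _find_tsd(flank5: str, flank3: str, max_offset: int = 16) -> str | None:
    """Exact 3-8 nt terminal duplication; the 3' copy may sit just past a
    poly-A tail, hence the small search offset into the 3' flank."""
    for length in range(8, 2, -1):
        if len(flank5) < length:
            continue
        probe = flank5[-length:]
        idx = flank3[:max_offset + length].find(probe)
        if idx != -1:
            return probe
    return None


def detect_ltrs(locus_seq: str, model: ERVModel,
                config: PipelineConfig | None = None,
                flank5: str = "", flank3: str = "") -> LTRAnnotation:
    """Annotate LTRs of an oriented locus sequence.

    ``locus_seq`` and the flanks must be in element (query) orientation.
    Terminal windows of 1.5x the model LTR length are aligned against each
    other to pair LTRs; U3/U5 presence is decided by local-alignment coverage
    of the model's U3/U5 segments; poly-A is called when >= 8 of 12 terminal
    nt (of the locus or the immediately following flank) are A.
    """
    config = config or PipelineConfig()
    if len(locus_seq) < 200:
        raise ValidationError("locus too short (< 200 nt) for LTR annotation")
    ann = LTRAnnotation()
    L = len(locus_seq)
    w = int(1.5 * model.ltr_len)
    w5 = min(w, L // 2)
    w3 = min(w, L - L // 2)
    win5 = locus_seq[:w5]
    win3 = locus_seq[L - w3:]

    # LTR pairing: terminal windows aligned against each other
    if w5 >= config.ltr_pair_min_len and w3 >= config.ltr_pair_min_len:
        matches, cols, a_s, a_e, b_s, b_e = local_align_stats(win5, win3)
        if cols >= config.ltr_pair_min_len and matches / cols >= config.ltr_pair_min_identity:
            ann.ltr5_interval = (a_s, a_e)
            ann.ltr3_interval = (L - w3 + b_s, L - w3 + b_e)
            ann.ltr_identity = matches / cols

    # U3 at the 5' end, U5 at the 3' end (complete-LTR signature)
    ann.has_u3_5prime = _segment_present(model.u3_seq(), win5, config)
    ann.has_u5_3prime = _segment_present(model.u5_seq(), win3, config)

    # any partial-LTR evidence at either end (truncated LTRs of pseudogenes)
    def _ltr_evidence(window: str) -> bool:
        matches, cols, *_ = local_align_stats(model.ltr_seq, window)
        return cols >= config.min_hit_len and matches / cols >= config.segment_min_identity

    ann.ltr5_evidence = ann.has_u3_5prime or _ltr_evidence(win5)
    ann.ltr3_evidence = ann.has_u5_3prime or _ltr_evidence(win3)

    # poly-A: terminal 12 nt of the locus, or the 12 nt just 3' of it
    tail = locus_seq[-12:]
    after = flank3[:12]
    ann.polyA = (tail.count("A") >= 8) or (len(after) >= 8 and after.count("A") >= 8)

    if flank5 and flank3:
        ann.tsd = _find_tsd(flank5, flank3)
    return ann


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def has_internal_hit(locus, model: ERVModel) -> bool:
    """Does any discovery hit of the locus cover the query's internal region?

    Falls back to a k-mer screen when the locus carries no hit records
    (constructed inputs).
    """
    int_lo = model.ltr_len
    int_hi = model.ltr_len + len(model.internal_seq)
    hits = getattr(locus, "hits", None)
    if hits:
        for h in hits:
            ov = min(h.query_end, int_hi) - max(h.query_start, int_lo)
            if ov >= 50:
                return True
        return False
    seq = locus if isinstance(locus, str) else locus.oriented_sequence()
    k = 12
    internal_kmers = {model.internal_seq[i:i + k]
                      for i in range(len(model.internal_seq) - k + 1)}
    count = sum(1 for i in range(len(seq) - k + 1) if seq[i:i + k] in internal_kmers)
    return count >= 20


def classify_locus(locus, annotation: LTRAnnotation, model: ERVModel,
                   config: PipelineConfig | None = None) -> str:
    """Assign the structural class; decision order
    solitary_ltr -> provirus -> processed_pseudogene -> undefined.

    ``locus`` may be an ERVLocus (hits used to test internal-region coverage)
    or a plain oriented sequence string.
    """
    config = config or PipelineConfig()
    seq = locus if isinstance(locus, str) else locus.oriented_sequence()
    internal = has_internal_hit(locus, model)
    if not internal and len(seq) <= 2.0 * model.ltr_len:
        return "solitary_ltr"
    if annotation.pair_found and annotation.has_u3_5prime and annotation.has_u5_3prime:
        return "provirus"
    if internal and (annotation.ltr5_evidence or annotation.ltr3_evidence
                     or annotation.polyA):
        if annotation.pair_found and (annotation.has_u3_5prime
                                      or annotation.has_u5_3prime):
            # one complete-looking LTR: one-sided L1 truncation; audit trail
            logger.warning("locus classified processed_pseudogene with one "
                           "complete-looking LTR")
        return "processed_pseudogene"
    return "undefined"


# ---------------------------------------------------------------------------
# LTR-divergence dating
# ---------------------------------------------------------------------------

@dataclass
class AgeEstimate:
    age_mya: float
    ci_low: float
    ci_high: float
    distance: float
    aligned_len: int
    unreliable: bool


def ltr_age(ltr5: str, ltr3: str, rate: float,
            config: PipelineConfig | None = None) -> AgeEstimate:
    """Date an insertion from 5'-3' LTR divergence: age = d_K2P / (2 * rate).

    Both LTRs accumulate substitutions independently after integration, hence
    the factor 2. A binomial 95% CI on the raw difference proportion is
    propagated to the age through the K2P correction's local scale factor.
    Estimates from alignments < 200 nt or with d > 0.3 are flagged unreliable.
    """
    from .comparative import k2p_distance, pairwise_align

    if not ltr5 or not ltr3:
        raise ValidationError("both LTRs are required for dating")
    if min(len(ltr5), len(ltr3)) < 200:
        raise ValidationError("LTR too short/truncated for reliable dating (< 200 nt)")
    if rate <= 0:
        raise ValidationError("substitution rate must be positive")
    a_aln, b_aln = pairwise_align(ltr5, ltr3)
    pairs = [(x, y) for x, y in zip(a_aln, b_aln)
             if x not in "-N" and y not in "-N"]
    n = len(pairs)
    diff = sum(1 for x, y in pairs if x != y)
    d = k2p_distance(a_aln, b_aln)
    unreliable = n < 200 or (math.isfinite(d) and d > 0.3) or not math.isfinite(d)
    p = diff / n if n else 0.0
    se = math.sqrt(p * (1 - p) / n) if n else 0.0
    scale = (d / p) if (p > 0 and math.isfinite(d)) else 1.0
    d_lo = max(0.0, (p - 1.96 * se) * scale)
    d_hi = (p + 1.96 * se) * scale
    age = d / (2 * rate) if math.isfinite(d) else math.inf
    return AgeEstimate(age_mya=age, ci_low=d_lo / (2 * rate),
                       ci_high=d_hi / (2 * rate), distance=d,
                       aligned_len=n, unreliable=unreliable)


# ---------------------------------------------------------------------------
# ORFs / puteins
# ---------------------------------------------------------------------------

def _orfs_in_frame(seq: str, frame: int, strand: str, total_len: int,
                   relaxed: bool = False):
    """Yield (aa_seq, nt_start, nt_end) for ORFs; coordinates on the + strand
    of the original sequence. Strict mode requires an ATG start; relaxed mode
    lets an ORF start at the frame/segment start (degraded elements often
    lose their initiator codon)."""
    sub = seq[frame:]
    sub = sub[:len(sub) - len(sub) % 3]
    if not sub:
        return
    protein = str(Seq(sub).translate())
    start = 0 if relaxed else None
    for i, aa in enumerate(protein + "*"):
        if aa == "*":
            if start is not None and i > start:
                nt_s = frame + 3 * start
                nt_e = frame + 3 * i
                aa_seq = protein[start:i]
                if strand == "+":
                    yield aa_seq, nt_s, nt_e
                else:
                    yield aa_seq, total_len - nt_e, total_len - nt_s
            start = i + 1 if relaxed else None
        elif aa == "M" and start is None:
            start = i


def find_puteins(consensus: str, model: ERVModel,
                 config: PipelineConfig | None = None,
                 relaxed: bool = False) -> PuteinSet:
    """Extract putative proteins (puteins) for gag/pol/env from a consensus.

    Three-frame translation on both strands; for each gene the longest ORF
    whose nucleotide span overlaps the model's gene segment is reported.
    Genes whose best ORF covers < 80% of the model gene length are flagged
    ``disrupted`` (stop-codon interruption / decay). ``relaxed`` lets ORFs
    start at a segment boundary instead of requiring ATG.
    """
    if len(consensus) < 1000:
        raise ValidationError("consensus too short (< 1 kb) for putein extraction")
    total = len(consensus)
    candidates = []  # (aa_seq, start, end, frame, strand)
    for strand in ("+", "-"):
        s = consensus if strand == "+" else revcomp(consensus)
        for frame in range(3):
            for aa_seq, nt_s, nt_e in _orfs_in_frame(s, frame, strand, total,
                                                     relaxed=relaxed):
                candidates.append((aa_seq, nt_s, nt_e, frame, strand))
    out = PuteinSet()
    def _overlaps(nt_s: int, nt_e: int, strand: str, g_lo: int, g_hi: int) -> bool:
        # gene segments are in model orientation; a minus-strand ORF's
        # position in its own reading orientation is the mirrored interval,
        # so a reverse-complemented consensus maps back onto the model
        if strand == "-":
            nt_s, nt_e = total - nt_e, total - nt_s
        return min(nt_e, g_hi) - max(nt_s, g_lo) > 0

    for gene, (g_lo, g_hi) in model.gene_intervals().items():
        best = None
        for aa_seq, nt_s, nt_e, frame, strand in candidates:
            if not _overlaps(nt_s, nt_e, strand, g_lo, g_hi):
                continue
            if best is None or len(aa_seq) > len(best[0]):
                best = (aa_seq, nt_s, nt_e, frame, strand)
        if best is None:
            out.puteins[gene] = None
            continue
        aa_seq, nt_s, nt_e, frame, strand = best
        gene_len = g_hi - g_lo
        out.puteins[gene] = Putein(gene=gene, aa_seq=aa_seq, frame=frame,
                                   strand=strand, start=nt_s, end=nt_e,
                                   disrupted=(nt_e - nt_s) < 0.8 * gene_len)
    return out
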