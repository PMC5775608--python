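"""BLAT-like seed-and-extend similarity search and locus assembly.

A k-mer index over the plus strand of each genome seeds both-strand searches
(the reverse complement of the query is searched for minus-strand hits).
Seeds are chained by diagonal proximity and extended with banded local
alignment (match +1, mismatch -1, gap open -4, gap extend -1); hits below the
length or identity floors are discarded, and same-strand hits closer than
``merge_gap`` on the target are merged into loci with flanking sequence
attached. The identity floor (60%) is deliberately permissive so that
divergent "ERV-like" relatives of the query remain discoverable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kernels import banded_local_align, encode, kmer_codes
from .io_core import GenomeSequence, GenomicInterval, PipelineConfig, ValidationError, revcomp

logger = logging.getLogger("ervography")


@dataclass
class Hit:
    """One local alignment of the query against a genome (target always + strand)."""

    query_start: int
    query_end: int
    target: GenomicInterval
    strand: str
    percent_identity: float   # fraction in [0, 1]
    aligned_len: int
    score: float


@dataclass
class ERVLocus:
    """One merged candidate locus with its flanking context."""

    locus_id: str
    species_id: str
    interval: GenomicInterval
    strand: str
    hits: list[Hit]
    flank5: str
    flank3: str
    sequence: str
    structure: str = "unclassified"
    flank5_truncated: bool = False
    flank3_truncated: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def percent_identity(self) -> float:
        total = sum(h.aligned_len for h in self.hits)
        if total == 0:
            return 0.0
        return sum(h.percent_identity * h.aligned_len for h in self.hits) / total

    def oriented_sequence(self) -> str:
        """Locus sequence in the orientation of the query."""
        return self.sequence if self.strand == "+" else revcomp(self.sequence)


class SeedIndex:
    """Sorted-array k-mer index over the plus strand of one contig."""

    def __init__(self, genome: GenomeSequence, k: int):
        if k < 8:
            raise ValidationError("seed k must be >= 8")
        if k > len(genome.seq):
            raise ValidationError(
                f"k={k} exceeds sequence length {len(genome.seq)}")
        self.genome = genome
        self.k = k
        self.codes = encode(genome.seq)
        kcodes, positions = kmer_codes(self.codes, k)
        order = np.argsort(kcodes, kind="stable")
        self.kmers_sorted = kcodes[order]
        self.pos_sorted = positions[order]

    def __len__(self) -> int:
        return self.kmers_sorted.size

    def positions(self, kmer_code: int) -> np.ndarray:
        lo = np.searchsorted(self.kmers_sorted, kmer_code, "left")
        hi = np.searchsorted(self.kmers_sorted, kmer_code, "right")
        return self.pos_sorted[lo:hi]

    def seed_matches(self, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All (query_pos, target_pos) seed pairs for a query."""
        qk, qpos = kmer_codes(query_codes, self.k)
        if qk.size == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        lo = np.searchsorted(self.kmers_sorted, qk, "left")
        hi = np.searchsorted(self.kmers_sorted, qk, "right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        q_out = np.repeat(qpos, counts)
        # gather the variable-length position runs
        t_out = np.empty(total, dtype=np.int64)
        off = 0
        for i in np.nonzero(counts)[0]:
            c = counts[i]
            t_out[off:off + c] = self.pos_sorted[lo[i]:hi[i]]
            off += c
        return q_out, t_out


def build_seed_index(genome: GenomeSequence, k: int) -> SeedIndex:
    """Index every non-N k-mer position of the genome (plus strand only)."""
    return SeedIndex(genome, k)


def _chain_seeds(qpos: np.ndarray, tpos: np.ndarray, band: int,
                 chain_gap: int, min_seeds: int = 2):
    """Group seeds into chains by diagonal proximity, then by target spacing."""
    if qpos.size == 0:
        return
    diag = tpos - qpos
    order = np.lexsort((tpos, diag))
    diag_s, tpos_s, qpos_s = diag[order], tpos[order], qpos[order]
    # split where the diagonal jumps beyond the band
    breaks = np.nonzero(np.diff(diag_s) > band)[0] + 1
    for grp in np.split(np.arange(diag_s.size), breaks):
        if grp.size == 0:
            continue
        t_grp, q_grp = tpos_s[grp], qpos_s[grp]
        t_order = np.argsort(t_grp, kind="stable")
        t_sorted, q_sorted = t_grp[t_order], q_grp[t_order]
        sub_breaks = np.nonzero(np.diff(t_sorted) > chain_gap)[0] + 1
        for sub in np.split(np.arange(t_sorted.size), sub_breaks):
            if sub.size >= min_seeds:
                yield q_sorted[sub], t_sorted[sub]


def search(query: str, genome: GenomeSequence | SeedIndex,
           config: PipelineConfig | None = None) -> list[Hit]:
    """Find local alignments of ``query`` on both strands of ``genome``.

    Target coordinates are always reported on the plus strand with a strand
    flag. Hits shorter than ``min_hit_len`` or below ``min_hit_identity`` are
    discarded.
    """
    config = config or PipelineConfig()
    index = genome if isinstance(genome, SeedIndex) else SeedIndex(genome, config.seed_k)
    if len(query) < index.k:
        raise ValidationError(f"query ({len(query)} nt) shorter than k={index.k}")
    k = index.k
    tlen = len(index.genome.seq)
    contig = index.genome.contig_id
    pad = 150
    band = config.band
    hits: list[Hit] = []
    seen = set()
    for strand in ("+", "-"):
        qseq = query if strand == "+" else revcomp(query)
        qcodes = encode(qseq)
        lq = qcodes.size
        qpos, tpos = index.seed_matches(qcodes)
        for cq, ct in _chain_seeds(qpos, tpos, band, config.chain_gap):
            qlo = max(0, int(cq.min()) - pad)
            qhi = min(lq, int(cq.max()) + k + pad)
            tlo = max(0, int(ct.min()) - pad)
            thi = min(tlen, int(ct.max()) + k + pad)
            diag = ct - cq
            shift = tlo - qlo
            dlo = int(diag.min()) - band - shift
            dhi = int(diag.max()) + band - shift
            score, qs, qe, ts, te, matches, cols = banded_local_align(
                np.ascontiguousarray(qcodes[qlo:qhi]),
                np.ascontiguousarray(index.codes[tlo:thi]), dlo, dhi,
                np.float32(1.0), np.float32(-1.0), np.float32(-4.0), np.float32(-1.0))
            if cols < config.min_hit_len or cols == 0:
                continue
            identity = matches / cols
            if identity < config.min_hit_identity:
                continue
            t_start, t_end = tlo + ts, tlo + te
            if strand == "+":
                q_start, q_end = qlo + qs, qlo + qe
            else:
                q_start, q_end = len(query) - (qlo + qe), len(query) - (qlo + qs)
            key = (q_start, q_end, t_start, t_end, strand)
            if key in seen or t_end <= t_start:
                continue
            seen.add(key)
            hits.append(Hit(query_start=q_start, query_end=q_end,
                            target=GenomicInterval(contig, t_start, t_end),
                            strand=strand, percent_identity=identity,
                            aligned_len=int(cols), score=float(score)))
    hits.sort(key=lambda h: (h.target.start, h.target.end, h.strand))
    return hits


def merge_hits(hits: list[Hit], genome: GenomeSequence,
               config: PipelineConfig | None = None) -> list[ERVLocus]:
    """Merge same-strand hits within ``merge_gap`` into loci and attach flanks.

    Merging is transitive (a sweep over coordinate-sorted hits), idempotent in
    effect and independent of input order; locus ids are deterministic
    ``species.contig.start-end``.
    """
    config = config or PipelineConfig()
    species = genome.species_id
    loci: list[ERVLocus] = []
    glen = len(genome.seq)
    for strand in ("+", "-"):
        strand_hits = sorted((h for h in hits if h.strand == strand),
                             key=lambda h: (h.target.start, h.target.end))
        cluster: list[Hit] = []

        def flush():
            if not cluster:
                return
            start = min(h.target.start for h in cluster)
            end = max(h.target.end for h in cluster)
            f5_start = max(0, start - config.flank_len)
            f3_end = min(glen, end + config.flank_len)
            locus = ERVLocus(
                locus_id=f"{species}.{genome.contig_id}.{start}-{end}",
                species_id=species,
                interval=GenomicInterval(genome.contig_id, start, end),
                strand=strand,
                hits=list(cluster),
                flank5=genome.seq[f5_start:start],
                flank3=genome.seq[end:f3_end],
                sequence=genome.seq[start:end],
                flank5_truncated=f5_start > start - config.flank_len,
                flank3_truncated=f3_end < end + config.flank_len,
            )
            if locus.flank5_truncated or locus.flank3_truncated:
                logger.warning("locus %s: flank truncated at contig end", locus.locus_id)
            loci.append(locus)

        for h in strand_hits:
            if cluster and h.target.start - max(x.target.end for x in cluster) > config.merge_gap:
                flush()
                cluster = []
            cluster.append(h)
        flush()
    # transitively merge any overlapping loci across strands is NOT done:
    # opposite-strand overlaps are distinct hits by contract; same-strand
    # overlaps cannot survive the sweep above.
    loci.sort(key=lambda l: (l.interval.contig_id, l.interval.start, l.interval.end))
    return loci


def discover(query: str, genome: GenomeSequence,
             config: PipelineConfig | None = None,
             index: SeedIndex | None = None) -> list[ERVLocus]:
    """search + merge_hits convenience wrapper."""
    config = config or PipelineConfig()
    idx = index if index is not None else SeedIndex(genome, config.seed_k)
    hits = search(query, idx, config)
    loci = merge_hits(hits, genome, config)
    logger.info("discover[%s]: %d hits -> %d loci", genome.species_id,
                len(hits), len(loci))
    return loci
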