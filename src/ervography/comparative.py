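"""Alignment-based comparative statistics.

Global pairwise alignment (affine gaps), progressive profile MSA with a
k-mer-distance NJ guide tree, majority-rule consensus, CpG-stripped
p-distance, Kimura 2-parameter distance, canonical neighbor-joining with
deterministic tie-breaking, split bootstrap support, and windowed dot-plots.

CpG stripping note: spontaneous deamination of methylated CpG makes those
sites hypermutable, so distance estimates exclude any alignment column that
is the C or the G of a CpG dinucleotide in *either* row (gap-skipping when
testing adjacency) before pairwise deletion is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import Align

from ._kernels import encode, profile_align_path
from .io_core import ValidationError, revcomp

logger = logging.getLogger("ervography")


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------

def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


_GLOBAL = _global_aligner()


def pairwise_align(a: str, b: str) -> tuple[str, str]:
    """Global alignment with affine gaps (match +1, mismatch -1, open -4,
    extend -1); the first optimal alignment is returned deterministically."""
    if not a or not b:
        raise ValidationError("cannot align empty sequences")
    aln = _GLOBAL.align(a, b)[0]
    return str(aln[0]), str(aln[1])


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------

def _kmer_distance(seqs: list[str], k: int = 6) -> np.ndarray:
    sets = [{s[i:i + k] for i in range(len(s) - k + 1)} for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            denom = min(len(sets[i]), len(sets[j])) or 1
            d[i, j] = d[j, i] = 1.0 - inter / denom
    return d


def _profile(rows: list[str]) -> np.ndarray:
    """(L, 5) column frequencies over A,C,G,T,gap; N spread uniformly."""
    L = len(rows[0])
    prof = np.zeros((L, 5), dtype=np.float32)
    for row in rows:
        arr = np.frombuffer(row.encode(), dtype=np.uint8)
        for ci, ch in enumerate("ACGT"):
            prof[:, ci] += arr == ord(ch)
        prof[:, 4] += arr == ord("-")
        isn = arr == ord("N")
        prof[:, :4] += 0.25 * isn[:, None]
    prof /= len(rows)
    return prof


def _merge_groups(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    pa = _profile(rows_a)
    pb = _profile(rows_b)
    nza = pa[:, :4].sum(axis=1)
    nzb = pb[:, :4].sum(axis=1)
    sab = (2.0 * (pa[:, :4] @ pb[:, :4].T) - np.outer(nza, nzb)).astype(np.float32)
    path = profile_align_path(sab, np.float32(-4.0), np.float32(-1.0))
    out_a, out_b = [], []
    ia = ib = 0
    cols_a, cols_b = [], []
    for step in path:
        if step == 0:
            cols_a.append(ia); ia += 1
            cols_b.append(ib); ib += 1
        elif step == 1:
            cols_a.append(ia); ia += 1
            cols_b.append(-1)
        else:
            cols_a.append(-1)
            cols_b.append(ib); ib += 1
    for row in rows_a:
        out_a.append("".join(row[c] if c >= 0 else "-" for c in cols_a))
    for row in rows_b:
        out_b.append("".join(row[c] if c >= 0 else "-" for c in cols_b))
    return out_a, out_b


def progressive_msa(seqs: list[str], precomputed: list[str] | None = None) -> list[str]:
    """Progressive profile MSA; rows returned in input order.

    The guide tree is neighbor-joining on a shared-k-mer distance; profiles
    are merged by global profile-profile alignment. ``precomputed`` lets a
    caller substitute an externally produced alignment (same order, equal
    lengths), which is validated and returned as-is.
    """
    if precomputed is not None:
        if len(precomputed) != len(seqs):
            raise ValidationError("precomputed alignment row count mismatch")
        if len({len(r) for r in precomputed}) != 1:
            raise ValidationError("precomputed alignment rows differ in length")
        for row, seq in zip(precomputed, seqs):
            if row.replace("-", "") != seq:
                raise ValidationError("precomputed alignment does not round-trip its input")
        return list(precomputed)
    if len(seqs) == 0:
        raise ValidationError("no sequences to align")
    if len(seqs) == 1:
        return [seqs[0]]
    if len(seqs) == 2:
        a, b = pairwise_align(seqs[0], seqs[1])
        return [a, b]
    d = _kmer_distance(seqs)
    labels = [str(i) for i in range(len(seqs))]
    merges = _nj_merge_order(DistanceMatrix(labels, d))
    groups: dict[str, tuple[list[int], list[str]]] = {
        lab: ([i], [seqs[i]]) for i, lab in enumerate(labels)}
    for new_label, left, right in merges:
        idx_l, rows_l = groups.pop(left)
        idx_r, rows_r = groups.pop(right)
        rows_l, rows_r = _merge_groups(rows_l, rows_r)
        groups[new_label] = (idx_l + idx_r, rows_l + rows_r)
    (_, (order, rows)), = groups.items()
    out = [None] * len(seqs)
    for i, row in zip(order, rows):
        out[i] = row
    return out


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

@dataclass
class ConsensusSequence:
    seq: str
    support: list[float]

    def __len__(self) -> int:
        return len(self.seq)


def majority_consensus(alignment: list[str], min_support: float = 0.5) -> ConsensusSequence:
    """Majority-rule consensus: per column the most frequent residue wins;
    columns where gaps hold a strict majority are deleted; residue ties give N."""
    if len(alignment) < 2:
        raise ValidationError("consensus requires >= 2 rows")
    if len({len(r) for r in alignment}) != 1:
        raise ValidationError("alignment rows differ in length")
    n = len(alignment)
    arr = np.array([list(r) for r in alignment])
    out = []
    support = []
    for col in arr.T:
        gaps = int((col == "-").sum())
        if gaps * 2 > n:
            continue
        vals, counts = np.unique(col[col != "-"], return_counts=True)
        best = counts.max()
        winners = vals[counts == best]
        residue = winners[0] if len(winners) == 1 else "N"
        out.append(residue)
        support.append(best / n)
    return ConsensusSequence(seq="".join(out), support=support)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _cpg_columns(row: str) -> set[int]:
    """Columns that are the C or G of a CpG in this row, skipping gaps."""
    cols = set()
    prev_idx = None
    for i, ch in enumerate(row):
        if ch == "-":
            continue
        if prev_idx is not None and row[prev_idx] == "C" and ch == "G":
            cols.add(prev_idx)
            cols.add(i)
        prev_idx = i
    return cols


def p_distance_cpg_stripped(a_aligned: str, b_aligned: str) -> float:
    """p-distance with pairwise deletion after removal of CpG dinucleotides.

    Columns belonging to a CpG in either row are removed first, then columns
    with a gap or N in either row; returns NaN (flagged) if nothing remains.
    """
    if len(a_aligned) != len(b_aligned):
        raise ValidationError("aligned rows differ in length")
    drop = _cpg_columns(a_aligned) | _cpg_columns(b_aligned)
    n = 0
    diff = 0
    for i, (x, y) in enumerate(zip(a_aligned, b_aligned)):
        if i in drop or x in "-N" or y in "-N":
            continue
        n += 1
        diff += x != y
    if n == 0:
        logger.warning("p-distance undefined: no comparable columns")
        return math.nan
    return diff / n


_PURINE = frozenset("AG")


def k2p_counts(a_aligned: str, b_aligned: str) -> tuple[int, int, int]:
    """(n, transitions, transversions) after pairwise deletion of gaps/N."""
    if len(a_aligned) != len(b_aligned):
        raise ValidationError("aligned rows differ in length")
    n = ts = tv = 0
    for x, y in zip(a_aligned, b_aligned):
        if x in "-N" or y in "-N":
            continue
        n += 1
        if x != y:
            if (x in _PURINE) == (y in _PURINE):
                ts += 1
            else:
                tv += 1
    return n, ts, tv


def k2p_distance(a_aligned: str, b_aligned: str) -> float:
    """Kimura 2-parameter distance d = -1/2 ln((1-2P-Q) sqrt(1-2Q));
    saturated pairs (non-positive log argument) return inf."""
    n, ts, tv = k2p_counts(a_aligned, b_aligned)
    if n == 0:
        logger.warning("K2P undefined: no comparable columns")
        return math.nan
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        logger.warning("K2P saturated pair (P=%.3f, Q=%.3f)", P, Q)
        return math.inf
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9, equal_nan=True):
            raise ValidationError("distance matrix must be symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


def k2p_matrix(labels: list[str], alignment: list[str]) -> DistanceMatrix:
    """Pairwise K2P distances; sequences causing saturated (infinite) pairs
    are dropped greedily, with a warning, until all entries are finite."""
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = k2p_distance(alignment[i], alignment[j])
    keep = list(range(n))
    while True:
        bad_counts = [np.sum(~np.isfinite(m[i, keep])) for i in keep]
        if not any(bad_counts):
            break
        worst = keep[int(np.argmax(bad_counts))]
        logger.warning("excluding %s from NJ: saturated distances", labels[worst])
        keep.remove(worst)
    idx = np.ix_(keep, keep)
    return DistanceMatrix([labels[i] for i in keep], m[idx])


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _nj_merge_order(dm: DistanceMatrix):
    """Canonical NJ agglomeration; yields (new_label, left, right) merges.

    Ties on the Q criterion break toward the lexicographically smallest
    (left, right) label pair. Internal labels are '(left,right)'.
    """
    labels = list(dm.labels)
    d = {a: {b: dm.matrix[i, j] for j, b in enumerate(labels)}
         for i, a in enumerate(labels)}
    merges = []
    active = sorted(labels)
    while len(active) > 2:
        n = len(active)
        r = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * d[a][b] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        new = f"({a},{b})"
        merges.append((new, a, b))
        d[new] = {}
        for c in active:
            if c in (a, b):
                continue
            d[new][c] = d[c][new] = 0.5 * (d[a][c] + d[b][c] - d[a][b])
        d[new][new] = 0.0
        active.remove(a)
        active.remove(b)
        active.append(new)
        active.sort()
    if len(active) == 2:
        a, b = active
        merges.append((f"({a},{b})", a, b))
    return merges


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical neighbor joining (Q criterion); returns an unrooted dendropy
    tree (trifurcating seed node). Negative branch lengths clamp to 0 with a
    warning; ties break by label order."""
    labels = list(dm.labels)
    if len(labels) < 3:
        raise ValidationError("NJ requires >= 3 labels")
    if not np.all(np.isfinite(dm.matrix)):
        raise ValidationError("NJ requires finite distances (saturated pairs excluded)")
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = {}
    for lab in labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes[lab] = nd
    d = {a: {b: float(dm.get(a, b)) for b in labels} for a in labels}
    active = sorted(labels)

    def clamp(x: float) -> float:
        if x < 0:
            logger.warning("NJ: negative branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * d[a][b] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        la = 0.5 * d[a][b] + (r[a] - r[b]) / (2 * (n - 2))
        lb = d[a][b] - la
        new = f"({a},{b})"
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        nodes[a].edge.length = clamp(la)
        parent.add_child(nodes[b])
        nodes[b].edge.length = clamp(lb)
        nodes[new] = parent
        d[new] = {}
        for c in active:
            if c in (a, b):
                continue
            d[new][c] = d[c][new] = 0.5 * (d[a][c] + d[b][c] - d[a][b])
        d[new][new] = 0.0
        active.remove(a)
        active.remove(b)
        active.append(new)
        active.sort()
    root = tree.seed_node
    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (d[a][b] + d[a][c] - d[b][c])
        lb = 0.5 * (d[a][b] + d[b][c] - d[a][c])
        lc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
        for lab, ln in ((a, la), (b, lb), (c, lc)):
            root.add_child(nodes[lab])
            nodes[lab].edge.length = clamp(ln)
    else:  # exactly 2 active (can only happen for 3-taxon input reduced once)
        a, b = active
        root.add_child(nodes[a])
        nodes[a].edge.length = clamp(d[a][b] / 2)
        root.add_child(nodes[b])
        nodes[b].edge.length = clamp(d[a][b] / 2)
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def tree_splits(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions, each represented by the side not containing
    the lexicographically first taxon. Zero-length internal edges are treated
    as unresolved (collapsed), so a star-like tree yields no splits."""
    taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
    first = taxa[0]
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        if node.edge.length is not None and node.edge.length <= 1e-12:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if first in side:
            side = frozenset(taxa) - side
        if 1 < len(side) < len(taxa) - 1:
            out.add(side)
    return out


def same_topology(t1: dendropy.Tree, t2: dendropy.Tree) -> bool:
    return tree_splits(t1) == tree_splits(t2)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(labels: list[str], alignment: list[str],
                      tree_builder=None, reps: int = 100,
                      seed: int | None = None) -> dict[frozenset, float]:
    """Column bootstrap: support (%) of each split of the original tree.

    ``tree_builder(labels, alignment) -> dendropy.Tree`` defaults to NJ on
    K2P distances. Seeded and reproducible.
    """
    if len(alignment) < 4:
        raise ValidationError("bootstrap requires >= 4 rows")

    def default_builder(labs, aln):
        return nj_tree(k2p_matrix(labs, aln))

    builder = tree_builder or default_builder
    base = builder(labels, alignment)
    targets = tree_splits(base)
    counts = {s: 0 for s in targets}
    rng = np.random.default_rng(seed)
    L = len(alignment[0])
    arr = np.array([list(r) for r in alignment])
    for _rep in range(reps):
        cols = rng.integers(0, L, size=L)
        rows = ["".join(row) for row in arr[:, cols]]
        try:
            rep_tree = builder(labels, rows)
        except ValidationError:
            continue
        rep_splits = tree_splits(rep_tree)
        for s in targets:
            if s in rep_splits:
                counts[s] += 1
    return {s: 100.0 * c / reps for s, c in counts.items()}


# ---------------------------------------------------------------------------
# dot-plot
# ---------------------------------------------------------------------------

@dataclass
class DotPlot:
    window: int
    step: int
    a_starts: np.ndarray
    b_starts: np.ndarray
    identity: np.ndarray          # (na, nb) fraction per window pair
    threshold: float
    identity_rc: np.ndarray | None = None

    @property
    def highlight(self) -> np.ndarray:
        return self.identity >= self.threshold

    @property
    def highlight_rc(self) -> np.ndarray | None:
        if self.identity_rc is None:
            return None
        return self.identity_rc >= self.threshold


def _window_matrix(a_codes: np.ndarray, b_codes: np.ndarray,
                   window: int, step: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a_starts = np.arange(0, a_codes.size - window + 1, step)
    b_starts = np.arange(0, b_codes.size - window + 1, step)
    A = np.lib.stride_tricks.sliding_window_view(a_codes, window)[::step]
    B = np.lib.stride_tricks.sliding_window_view(b_codes, window)[::step]
    ident = np.empty((A.shape[0], B.shape[0]), dtype=np.float32)
    for i in range(A.shape[0]):
        ident[i] = (B == A[i]).mean(axis=1)
    return a_starts, b_starts, ident


def dotplot(a: str, b: str, window: int = 100, step: int = 25,
            threshold: float = 0.5, both_strands: bool = False) -> DotPlot:
    """Windowed ungapped identity between all window pairs of two sequences;
    a pair is highlighted when identity >= threshold (the 50%/100-nt rule)."""
    if window > len(a) or window > len(b):
        raise ValidationError("window exceeds sequence length")
    a_codes = encode(a)
    b_codes = encode(b)
    a_starts, b_starts, ident = _window_matrix(a_codes, b_codes, window, step)
    ident_rc = None
    if both_strands:
        _, _, ident_rc = _window_matrix(a_codes, encode(revcomp(b)), window, step)
    return DotPlot(window=window, step=step, a_starts=a_starts,
                   b_starts=b_starts, identity=ident, threshold=threshold,
                   identity_rc=ident_rc)
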