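"""Forward simulator: evolves genomes down a dated species tree while planting
ERV insertion events of three structural classes, with full ground truth.

The generator emulates the colonization dynamics of a gammaretrovirus-like
ERV group in a catarrhine-like clade: a formation-rate peak on the deepest
shared branch (the root stem, i.e. the interval between the split from the
sister parvorder and the basal in-group divergence), a roughly 1:2
provirus:processed-pseudogene mechanism mix, occasional post-insertion
LTR-LTR recombination producing solitary LTRs, and optional per-species locus
deletion. Neutral substitutions accumulate at ``subst_rate`` per site per MY
under a two-class transition-biased model (kappa = transition bias).

Coordinate bookkeeping: every event has an insertion point in root-genome
coordinates; insertions never nest and are kept a minimum distance apart so
that each locus' flanks stay clean single-copy background (see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import decode, encode
from .io_core import GenomeSequence, PipelineConfig, SpeciesTree, ValidationError, revcomp

logger = logging.getLogger("ervography")

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = ["".join((a, b, c))
                 for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if "".join((a, b, c)) not in _STOPS]


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=length, p=p).astype(np.uint8))


def _random_orf(rng: np.random.Generator, length: int) -> str:
    """ATG + sense codons + stop, exactly ``length`` nt (length forced to 3k, k>=3)."""
    ncod = max(3, length // 3)
    body = rng.choice(len(_SENSE_CODONS), size=ncod - 2)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"


# ---------------------------------------------------------------------------
# ERV model
# ---------------------------------------------------------------------------

@dataclass
class ERVModel:
    """Reference element: LTR (U3|R|U5) + internal (pre_gag|gag|pol|env) + LTR."""

    ltr_seq: str
    internal_seq: str
    u3_len: int
    r_len: int
    u5_len: int
    pre_gag_len: int
    gag_len: int
    pol_len: int
    env_len: int
    tsd_len: int = 4
    polya_len: int = 12

    def __post_init__(self) -> None:
        if self.u3_len + self.r_len + self.u5_len != len(self.ltr_seq):
            raise ValidationError("U3+R+U5 must partition the LTR")
        if (self.pre_gag_len + self.gag_len + self.pol_len + self.env_len
                != len(self.internal_seq)):
            raise ValidationError("pre_gag+gag+pol+env must partition the internal region")
        for name in ("u3_len", "r_len", "u5_len", "pre_gag_len", "gag_len",
                     "pol_len", "env_len", "tsd_len", "polya_len"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"ERVModel segment {name} must be positive")

    # -- canonical sequences ------------------------------------------------

    @property
    def ltr_len(self) -> int:
        return len(self.ltr_seq)

    @property
    def provirus_seq(self) -> str:
        return self.ltr_seq + self.internal_seq + self.ltr_seq

    @property
    def pseudogene_seq(self) -> str:
        """L1-processed copy: 5' LTR lacks U3, 3' LTR lacks U5, poly-A tail."""
        ltr5 = self.ltr_seq[self.u3_len:]              # R + U5
        ltr3 = self.ltr_seq[:self.u3_len + self.r_len]  # U3 + R
        return ltr5 + self.internal_seq + ltr3 + "A" * self.polya_len

    @property
    def query_seq(self) -> str:
        """LTR-internal-LTR assembled reference used for similarity search."""
        return self.provirus_seq

    def u3_seq(self) -> str:
        return self.ltr_seq[:self.u3_len]

    def u5_seq(self) -> str:
        return self.ltr_seq[self.u3_len + self.r_len:]

    def gene_intervals(self) -> dict[str, tuple[int, int]]:
        """gag/pol/env intervals in provirus coordinates."""
        base = self.ltr_len + self.pre_gag_len
        out = {}
        for gene, length in (("gag", self.gag_len), ("pol", self.pol_len),
                             ("env", self.env_len)):
            out[gene] = (base, base + length)
            base += length
        return out

    def element_seq(self, mechanism: str) -> str:
        if mechanism == "provirus":
            return self.provirus_seq
        if mechanism == "processed_pseudogene":
            return self.pseudogene_seq
        raise ValidationError(f"unknown mechanism {mechanism!r}")

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ERVModel":
        return cls(**data)

    @classmethod
    def random(cls, rng: np.random.Generator, ltr_len: int = 780,
               internal_len: int = 7000, tsd_len: int = 4,
               polya_len: int = 12) -> "ERVModel":
        """Random model with ORF-structured gag/pol/env (proportions HERV-like)."""
        u3 = int(round(ltr_len * 0.45))
        r = int(round(ltr_len * 0.10))
        u5 = ltr_len - u3 - r
        pre = int(round(internal_len * 0.10))
        gag = (int(round(internal_len * 0.20)) // 3) * 3
        pol = (int(round(internal_len * 0.45)) // 3) * 3
        env = internal_len - pre - gag - pol
        internal = (random_dna(rng, pre) + _random_orf(rng, gag)
                    + _random_orf(rng, pol) + _random_orf(rng, env))
        # _random_orf emits exactly 3*(len//3) nt; pad the pre-gag to keep totals
        pad = internal_len - len(internal)
        if pad > 0:
            internal = random_dna(rng, pad) + internal
        elif pad < 0:
            internal = internal[-internal_len:]
        gag_r = (gag // 3) * 3
        pol_r = (pol // 3) * 3
        env_r = (env // 3) * 3
        pre_r = internal_len - gag_r - pol_r - env_r
        return cls(ltr_seq=random_dna(rng, ltr_len), internal_seq=internal,
                   u3_len=u3, r_len=r, u5_len=u5,
                   pre_gag_len=pre_r, gag_len=gag_r, pol_len=pol_r, env_len=env_r,
                   tsd_len=tsd_len, polya_len=polya_len)


# ---------------------------------------------------------------------------
# mutation model
# ---------------------------------------------------------------------------

def _mutate_codes(codes: np.ndarray, mu: float, kappa: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply Poisson-distributed substitution hits per site, transition-biased."""
    if mu < 0:
        raise ValidationError("expected substitutions/site must be >= 0")
    out = codes.copy()
    if mu == 0 or out.size == 0:
        return out
    hits = rng.poisson(mu, size=out.size)
    hits[out >= 4] = 0  # never mutate N
    max_hits = int(hits.max()) if hits.size else 0
    denom = kappa + 2.0
    for step in range(1, max_hits + 1):
        idx = np.nonzero(hits >= step)[0]
        if idx.size == 0:
            break
        u = rng.random(idx.size)
        xor = np.where(u < kappa / denom, 2,
                       np.where(u < (kappa + 1.0) / denom, 1, 3)).astype(np.uint8)
        out[idx] ^= xor
    return out


def mutate(seq: str, expected_subs_per_site: float, kappa: float = 2.0,
           rng: np.random.Generator | None = None) -> str:
    """Neutral substitution of a DNA string; length preserved, Ns untouched.

    Each site receives a Poisson(mu) number of substitution hits; each hit is
    a transition with probability kappa/(kappa+2), else one of the two
    transversions. Multiple hits compose, so the realized p-distance follows
    the usual 1-exp saturation curve.
    """
    if rng is None:
        rng = np.random.default_rng()
    return decode(_mutate_codes(encode(seq), expected_subs_per_site, kappa, rng))


# ---------------------------------------------------------------------------
# LTR-LTR recombination
# ---------------------------------------------------------------------------

def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(1 for x, y in zip(a[:n], b[:n]) if x == y) / n


def apply_ltr_recombination(element_seq: str, ltr_len: int,
                            rng: np.random.Generator | None = None,
                            crossover: int | None = None,
                            mechanism: str = "provirus") -> str:
    """Collapse a provirus to a solitary LTR by LTR-LTR homologous recombination.

    The recombinant is the 5' part of the 5' LTR joined to the 3' part of the
    3' LTR at a homologous crossover position; the internal region and one LTR
    are eliminated. Processed pseudogenes are rejected: their truncated LTRs
    lack the homology needed for this recombination.
    """
    if mechanism != "provirus":
        raise ValidationError(
            "LTR recombination applies to proviruses only; processed pseudogenes "
            "lack the homologous LTR pair")
    if len(element_seq) < 2 * ltr_len:
        raise ValidationError("element shorter than two LTRs")
    ltr5 = element_seq[:ltr_len]
    ltr3 = element_seq[-ltr_len:]
    if _identity(ltr5, ltr3) < 0.80:
        raise ValidationError("LTRs are < 80% identical; homologous recombination "
                              "is not plausible")
    if crossover is None:
        if rng is None:
            rng = np.random.default_rng()
        crossover = int(rng.integers(1, ltr_len))
    if not (0 < crossover < ltr_len):
        raise ValidationError("crossover must fall inside the LTR")
    return ltr5[:crossover] + ltr3[crossover:]


# ---------------------------------------------------------------------------
# events and truth
# ---------------------------------------------------------------------------

@dataclass
class InsertionEvent:
    locus_id: str
    branch_id: str
    mechanism: str                      # provirus | processed_pseudogene
    insertion_point: int                # root-genome coordinate
    strand: str
    time_fraction: float                # position along the branch (0 = branch start)
    recombination_branch: str | None = None
    later_recombination: dict = field(default_factory=dict)  # species -> bool
    later_deletion: dict = field(default_factory=dict)       # species -> bool


class TruthTable:
    """Ground-truth per (locus, species) realized state, interval and sequence."""

    STATES = ("full", "solitary_ltr", "empty", "deleted_region")

    def __init__(self, rows: list[dict]):
        cols = ["locus_id", "species_id", "state", "contig_id", "start", "end",
                "strand", "mechanism", "branch_id", "recombination_branch", "seq"]
        self.df = pd.DataFrame(rows, columns=cols)

    def __len__(self) -> int:
        return self.df["locus_id"].nunique()

    def state_matrix(self) -> pd.DataFrame:
        """loci x species table of realized states."""
        if self.df.empty:
            return pd.DataFrame()
        return self.df.pivot(index="locus_id", columns="species_id", values="state")

    def presence_species(self, locus_id: str) -> list[str]:
        sub = self.df[(self.df.locus_id == locus_id)
                      & self.df.state.isin(["full", "solitary_ltr"])]
        return sorted(sub.species_id)


@dataclass
class SimulationResult:
    genomes: list[GenomeSequence]
    truth: TruthTable
    events: list[InsertionEvent]
    model: ERVModel
    tree: SpeciesTree


def default_branch_rates(tree: SpeciesTree, peak_rate: float = 0.25,
                         young_ratio: float = 0.1) -> dict[str, float]:
    """Insertion intensities (events/MY): peak on the root stem (the deepest
    shared branch, emulating the main colonization wave), ``young_ratio`` of
    the peak on all younger branches."""
    root_id = tree.root.branch_id
    return {bid: (peak_rate if bid == root_id else peak_rate * young_ratio)
            for bid, _len in tree.branches()}


class _Record:
    """Per-lineage realized copy of one event."""

    __slots__ = ("event", "elem", "tsd3", "recombined")

    def __init__(self, event, elem, tsd3):
        self.event = event
        self.elem = elem      # uint8 codes, model orientation
        self.tsd3 = tsd3      # uint8 codes, 3' TSD copy (plus-strand genome orientation)
        self.recombined = False

    def copy(self):
        r = _Record(self.event, self.elem.copy(), self.tsd3.copy())
        r.recombined = self.recombined
        return r


def simulate(tree: SpeciesTree, model: ERVModel,
             rates: dict[str, float] | None = None,
             config: PipelineConfig | None = None,
             rng: np.random.Generator | int | None = None, *,
             background_len: int = 1_000_000,
             gc_content: float = 0.5,
             n_events: int | None = None,
             n_recombinations: int = 0,
             recombination_prob: float = 0.0,
             deletion_prob: float = 0.0,
             pseudogene_fraction: float = 2.0 / 3.0) -> SimulationResult:
    """Evolve one contig per species down the tree, planting ERV insertions.

    Events are drawn Poisson per branch with intensity ``rates[branch] x
    branch length`` (or exactly ``n_events`` allocated multinomially across
    branches by those weights). Mechanisms are provirus with probability
    ``1 - pseudogene_fraction`` (default mix 1:2 provirus:pseudogene).
    ``n_recombinations`` plants that many LTR-LTR recombinations on branches
    strictly below provirus insertion branches; ``deletion_prob`` removes each
    (event, descendant species) copy independently by clean excision.
    """
    config = config or PipelineConfig()
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    rates = rates if rates is not None else default_branch_rates(tree)
    branch_ids = [bid for bid, _ in tree.branches()]
    for bid in rates:
        if bid not in branch_ids:
            raise ValidationError(f"rate given for unknown branch {bid!r}")

    # --- capacity check (before any drawing) -------------------------------
    weights = np.array([rates.get(bid, 0.0) * length for bid, length in tree.branches()])
    lam_total = float(weights.sum())
    expected_n = n_events if n_events is not None else lam_total
    max_elem = max(len(model.provirus_seq), len(model.pseudogene_seq))
    if 10.0 * expected_n * max_elem > background_len:
        raise ValidationError(
            f"infeasible: expected {expected_n:.1f} insertions x {max_elem} nt "
            f"element needs >= {10 * expected_n * max_elem:.0f} nt background "
            f"(10x capacity rule), have {background_len}")

    # --- draw per-branch event counts --------------------------------------
    if n_events is not None:
        if weights.sum() <= 0:
            raise ValidationError("all insertion intensities are zero")
        counts = rng.multinomial(n_events, weights / weights.sum())
    else:
        counts = rng.poisson(weights)
    n_total = int(counts.sum())

    # --- insertion points: uniform with a separation floor -----------------
    min_sep = config.merge_gap + config.flank_len + 100
    margin = config.flank_len + 200
    usable = background_len - 2 * margin - max(0, n_total - 1) * min_sep
    if n_total > 0 and usable <= 0:
        raise ValidationError(
            f"cannot place {n_total} insertions {min_sep} nt apart in "
            f"{background_len} nt of background")
    points = np.array([], dtype=np.int64)
    if n_total > 0:
        raw = np.sort(rng.integers(0, usable, size=n_total))
        points = raw + margin + np.arange(n_total) * min_sep

    # --- assemble events (locus ids ordered by genomic position) -----------
    events: list[InsertionEvent] = []
    flat_branches = []
    for (bid, _length), c in zip(tree.branches(), counts):
        flat_branches.extend([bid] * int(c))
    mechs = np.where(rng.random(n_total) < pseudogene_fraction,
                     "processed_pseudogene", "provirus")
    strands = np.where(rng.random(n_total) < 0.5, "+", "-")
    tmp = []
    for i, bid in enumerate(flat_branches):
        tmp.append((bid, mechs[i], strands[i], float(rng.random())))
    ev_order = rng.permutation(n_total)  # decouple branch from genomic position
    for rank, pt in enumerate(points):
        bid, mech, strand, tfrac = tmp[ev_order[rank]]
        events.append(InsertionEvent(
            locus_id=f"L{rank + 1:04d}", branch_id=bid, mechanism=str(mech),
            insertion_point=int(pt), strand=str(strand), time_fraction=tfrac))

    # --- recombination planting -------------------------------------------
    def _strict_descendant_branches(bid: str) -> list[str]:
        node = tree.node_for_branch(bid)
        return [n.branch_id for n in node.preorder_iter() if n is not node]

    eligible = [ev for ev in events if ev.mechanism == "provirus"
                and _strict_descendant_branches(ev.branch_id)]
    recomb_events: list[InsertionEvent] = []
    if n_recombinations > 0:
        if len(eligible) < n_recombinations:
            raise ValidationError(
                f"requested {n_recombinations} recombinations but only "
                f"{len(eligible)} proviruses sit on internal branches")
        pick = rng.choice(len(eligible), size=n_recombinations, replace=False)
        recomb_events = [eligible[i] for i in sorted(pick)]
    elif recombination_prob > 0:
        recomb_events = [ev for ev in eligible if rng.random() < recombination_prob]
    for ev in recomb_events:
        cands = _strict_descendant_branches(ev.branch_id)
        ev.recombination_branch = cands[int(rng.integers(0, len(cands)))]
        for sp in tree.leaves_below(ev.recombination_branch):
            ev.later_recombination[sp] = True

    # --- deletion planting --------------------------------------------------
    if deletion_prob > 0:
        for ev in events:
            for sp in tree.leaves_below(ev.branch_id):
                if rng.random() < deletion_prob:
                    ev.later_deletion[sp] = True

    events_by_branch: dict[str, list[InsertionEvent]] = {}
    for ev in events:
        events_by_branch.setdefault(ev.branch_id, []).append(ev)

    logger.info("simulate: %d events (%d proviruses, %d pseudogenes), "
                "%d recombinations, background %d nt",
                n_total, sum(e.mechanism == "provirus" for e in events),
                sum(e.mechanism == "processed_pseudogene" for e in events),
                len(recomb_events), background_len)

    # --- walk the tree ------------------------------------------------------
    rate = config.subst_rate
    kappa = config.kappa
    root_bg = encode(random_dna(rng, background_len, gc=gc_content))
    genomes: list[GenomeSequence] = []
    truth_rows: list[dict] = []
    all_species = tree.species

    def process_edge(node, bg: np.ndarray, records: dict) -> tuple[np.ndarray, dict]:
        length = node.edge.length or 0.0
        bid = node.branch_id
        bg = _mutate_codes(bg, rate * length, kappa, rng)
        records = {lid: r.copy() for lid, r in records.items()}
        for r in records.values():
            r.elem = _mutate_codes(r.elem, rate * length, kappa, rng)
            r.tsd3 = _mutate_codes(r.tsd3, rate * length, kappa, rng)
        for ev in events_by_branch.get(bid, ()):
            elem = encode(model.element_seq(ev.mechanism))
            residence = rate * length * (1.0 - ev.time_fraction)
            elem = _mutate_codes(elem, residence, kappa, rng)
            p = ev.insertion_point
            tsd3 = bg[p:p + model.tsd_len].copy()
            tsd3 = _mutate_codes(tsd3, residence, kappa, rng)
            records[ev.locus_id] = _Record(ev, elem, tsd3)
        for lid, r in records.items():
            if r.event.recombination_branch == bid and not r.recombined:
                r.elem = encode(apply_ltr_recombination(
                    decode(r.elem), model.ltr_len, rng=rng))
                r.recombined = True
        return bg, records

    def realize_leaf(species: str, bg: np.ndarray, records: dict) -> None:
        parts = []
        pos = 0
        out_len = 0
        tsd = model.tsd_len
        per_locus: dict[str, dict] = {}
        for lid in sorted(records, key=lambda l: records[l].event.insertion_point):
            r = records[lid]
            ev = r.event
            if ev.later_deletion.get(species):
                per_locus[lid] = {"state": "deleted_region"}
                continue
            p = ev.insertion_point
            parts.append(bg[pos:p + tsd])
            out_len += (p + tsd) - pos
            oriented = r.elem if ev.strand == "+" else encode(revcomp(decode(r.elem)))
            start = out_len
            parts.append(oriented)
            out_len += oriented.size
            parts.append(r.tsd3)
            out_len += r.tsd3.size
            pos = p + tsd
            per_locus[lid] = {
                "state": "solitary_ltr" if r.recombined else "full",
                "start": start, "end": start + oriented.size,
                "strand": ev.strand, "seq": decode(oriented),
            }
        parts.append(bg[pos:])
        out_len += bg.size - pos
        genome_codes = np.concatenate(parts) if parts else bg
        genomes.append(GenomeSequence(species_id=species, contig_id="chr1",
                                      seq=decode(genome_codes)))
        for ev in events:
            info = per_locus.get(ev.locus_id)
            row = {"locus_id": ev.locus_id, "species_id": species,
                   "contig_id": "chr1", "start": None, "end": None,
                   "strand": None, "mechanism": ev.mechanism,
                   "branch_id": ev.branch_id,
                   "recombination_branch": ev.recombination_branch, "seq": None}
            if info is None:
                row["state"] = "empty"
            elif info["state"] == "deleted_region":
                row["state"] = "deleted_region"
            else:
                row.update(info)
            truth_rows.append(row)

    def walk(node, bg, records):
        bg, records = process_edge(node, bg, records)
        if node.is_leaf():
            realize_leaf(node.taxon.label, bg, records)
        else:
            for child in node.child_nodes():
                walk(child, bg, records)

    walk(tree.root, root_bg, {})
    genomes.sort(key=lambda g: g.species_id)
    truth = TruthTable(truth_rows)

    # consistency: every realized element matches its genome slice exactly
    by_sp = {g.species_id: g for g in genomes}
    for row in truth_rows:
        if row["state"] in ("full", "solitary_ltr"):
            sl = by_sp[row["species_id"]].seq[row["start"]:row["end"]]
            assert sl == row["seq"], "truth/genome inconsistency"

    assert set(t for t in (g.species_id for g in genomes)) == set(all_species)
    return SimulationResult(genomes=genomes, truth=truth, events=events,
                            model=model, tree=tree)
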