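"""Flank-anchored cross-species ortholog mapping and Dollo-style dating.

An insertion is orthologous across species when the same pre-integration site
(established by the 5' and 3' flanking sequence) carries it in both. Each
locus' flanks are searched in every other genome; a concordant flank pair
(same contig, same strand, correct order, sane spacing) brackets a candidate
interval whose content decides the state:

* ``full`` — element-scale ERV match between the flanks;
* ``solitary_ltr`` — only an LTR-length match (LTR-LTR recombination);
* ``empty`` — flanks (near-)directly juxtaposed: the pre-insertion allele;
* ``unresolved`` — flanks unmapped/discordant or assembly-gap interference;
  never a guess.

Formation dating is Dollo parsimony: an insertion is gained once, on the stem
branch of the LCA of all species carrying it (solitary LTRs count as
presence — the element was there, only its internal part was lost), and may
be lost independently in any descendant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import GenomeSequence, GenomicInterval, PipelineConfig, SpeciesTree
from .locus_discovery import ERVLocus, SeedIndex, search

logger = logging.getLogger("ervography")

STATE_CODES = {"full": "F", "solitary_ltr": "S", "empty": "E", "unresolved": "U"}


@dataclass
class OrthologState:
    state: str                                  # full | solitary_ltr | empty | unresolved
    interval: GenomicInterval | None = None     # candidate interval in the target
    flank5_identity: float | None = None
    flank3_identity: float | None = None
    note: str = ""


def _best_flank_hit(flank: str, index: SeedIndex, config: PipelineConfig):
    if len(flank) < config.flank_min_len:
        return None
    hits = [h for h in search(flank, index, config)
            if h.aligned_len >= config.flank_min_len
            and h.percent_identity >= config.flank_min_identity]
    if not hits:
        return None
    return max(hits, key=lambda h: h.score)


def map_locus(locus: ERVLocus, target: GenomeSequence | SeedIndex, query: str,
              config: PipelineConfig | None = None,
              ltr_len_hint: int | None = None) -> OrthologState:
    """Map one locus into a target genome via its flanks and type the site.

    ``query`` is the ERV reference (LTR-internal-LTR); ``ltr_len_hint``
    separates element-scale from LTR-scale matches (default: a third of the
    query length).
    """
    config = config or PipelineConfig()
    index = target if isinstance(target, SeedIndex) else SeedIndex(target, config.seed_k)
    genome = index.genome
    if ltr_len_hint is None:
        ltr_len_hint = max(config.min_hit_len, len(query) // 3)

    h5 = _best_flank_hit(locus.flank5, index, config)
    h3 = _best_flank_hit(locus.flank3, index, config)
    if h5 is None or h3 is None:
        return OrthologState("unresolved", note="flank unmapped")
    if h5.target.contig_id != h3.target.contig_id:
        return OrthologState("unresolved", note="flanks on different contigs")
    if h5.strand != h3.strand:
        return OrthologState("unresolved", note="flank strands discordant")
    ids = dict(flank5_identity=h5.percent_identity, flank3_identity=h3.percent_identity)
    if h5.strand == "+":
        inner_lo, inner_hi = h5.target.end, h3.target.start
    else:  # whole region inverted in the target: 3' flank comes first
        inner_lo, inner_hi = h3.target.end, h5.target.start
    gap = inner_hi - inner_lo
    max_span = max(2 * len(locus.sequence), len(query) + 2 * config.merge_gap)
    if gap > max_span or gap < -2 * config.flank_len:
        return OrthologState("unresolved", note="flank spacing implausible", **ids)
    if gap <= config.empty_site_slack:
        iv = (GenomicInterval(genome.contig_id, inner_lo, inner_hi)
              if gap > 0 else None)
        return OrthologState("empty", interval=iv, **ids)
    candidate = genome.seq[inner_lo:inner_hi]
    iv = GenomicInterval(genome.contig_id, inner_lo, inner_hi)
    if "N" * 20 in candidate:
        return OrthologState("unresolved", interval=iv, note="assembly gap in interval", **ids)
    if len(candidate) < config.seed_k:
        return OrthologState("unresolved", interval=iv, note="interval too short", **ids)
    cand_genome = GenomeSequence(genome.species_id, genome.contig_id, candidate)
    cand_hits = search(query, SeedIndex(cand_genome, config.seed_k), config)
    if not cand_hits:
        return OrthologState("unresolved", interval=iv, note="no ERV match in interval", **ids)
    # union coverage of hit target intervals
    spans = sorted((h.target.start, h.target.end) for h in cand_hits)
    cover = 0
    cur_lo, cur_hi = spans[0]
    for lo, hi in spans[1:]:
        if lo > cur_hi:
            cover += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    cover += cur_hi - cur_lo
    if cover >= 1.5 * ltr_len_hint:
        return OrthologState("full", interval=iv, **ids)
    return OrthologState("solitary_ltr", interval=iv, **ids)


# ---------------------------------------------------------------------------
# cross-species clustering and matrix
# ---------------------------------------------------------------------------

class OrthologMatrix:
    """Locus clusters x species states plus per-cluster inferences."""

    def __init__(self, species: list[str]):
        self.species = species
        self.states: dict[str, dict[str, str]] = {}         # cid -> species -> state
        self.members: dict[str, list[ERVLocus]] = {}        # cid -> member loci
        self.formation_branch: dict[str, str | None] = {}
        self.losses: dict[str, list[tuple[str, str]]] = {}  # cid -> [(species, kind)]
        self.recombinations: dict[str, list[str]] = {}      # cid -> [branch_id]
        self.cluster_class: dict[str, str] = {}
        self.flags: dict[str, list[str]] = {}

    @property
    def cluster_ids(self) -> list[str]:
        return sorted(self.states)

    def row(self, cid: str) -> dict[str, str]:
        return self.states[cid]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid in self.cluster_ids:
            row = {"cluster_id": cid}
            row.update({sp: STATE_CODES[self.states[cid][sp]] for sp in self.species})
            row["formation_branch"] = self.formation_branch.get(cid) or "NA"
            row["class"] = self.cluster_class.get(cid, "NA")
            row["members"] = ";".join(l.locus_id for l in self.members[cid])
            rows.append(row)
        return pd.DataFrame(rows)


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller key becomes root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def build_matrix(loci_by_species: dict[str, list[ERVLocus]],
                 genomes: dict[str, GenomeSequence],
                 tree: SpeciesTree, query: str,
                 config: PipelineConfig | None = None,
                 structures: dict[str, str] | None = None,
                 ltr_len_hint: int | None = None,
                 indexes: dict[str, SeedIndex] | None = None) -> OrthologMatrix:
    """Cluster loci across species by reciprocal flank mapping and complete
    the presence/absence matrix over every species.

    Two loci are the same insertion iff each one's flank-bracketed candidate
    interval in the other's genome overlaps the other locus. Conflicting
    chains (A~B, B~C without A~C, or two same-species loci in one cluster)
    merge with a "conflict" flag.
    """
    config = config or PipelineConfig()
    structures = structures or {}
    species = tree.species
    indexes = indexes or {}
    for sp, g in genomes.items():
        indexes.setdefault(sp, SeedIndex(g, config.seed_k))

    # map every locus into every other species once
    map_results: dict[tuple[str, str], OrthologState] = {}
    for sp in species:
        for locus in loci_by_species.get(sp, []):
            for other in species:
                if other == sp:
                    continue
                map_results[(locus.locus_id, other)] = map_locus(
                    locus, indexes[other], query, config, ltr_len_hint)

    # reciprocal clustering
    uf = _UnionFind()
    locus_lookup: dict[str, ERVLocus] = {}
    for sp in species:
        for locus in loci_by_species.get(sp, []):
            locus_lookup[locus.locus_id] = locus
            uf.find(locus.locus_id)

    def _maps_into(a: ERVLocus, b: ERVLocus) -> bool:
        st = map_results.get((a.locus_id, b.species_id))
        return (st is not None and st.interval is not None
                and st.state in ("full", "solitary_ltr")
                and st.interval.overlaps(b.interval))

    for sp_i, sp_j in ((a, b) for a in species for b in species if a < b):
        for la in loci_by_species.get(sp_i, []):
            for lb in loci_by_species.get(sp_j, []):
                if _maps_into(la, lb) and _maps_into(lb, la):
                    uf.union(la.locus_id, lb.locus_id)

    clusters: dict[str, list[ERVLocus]] = {}
    for lid, locus in locus_lookup.items():
        clusters.setdefault(uf.find(lid), []).append(locus)

    sp_order = {sp: i for i, sp in enumerate(species)}
    ordered = sorted(clusters.values(),
                     key=lambda ms: (min(sp_order[m.species_id] for m in ms),
                                     min(m.interval.start for m in ms)))
    matrix = OrthologMatrix(species)
    for i, members in enumerate(ordered):
        cid = f"C{i + 1:04d}"
        members = sorted(members, key=lambda m: (sp_order[m.species_id],
                                                 m.interval.start))
        matrix.members[cid] = members
        matrix.flags[cid] = []
        if len({m.species_id for m in members}) < len(members):
            matrix.flags[cid].append("conflict")
            logger.warning("cluster %s: multiple loci from one species merged", cid)
        row: dict[str, str] = {}
        member_by_sp = {}
        for m in members:
            member_by_sp.setdefault(m.species_id, m)
        for sp in species:
            if sp in member_by_sp:
                m = member_by_sp[sp]
                cls = structures.get(m.locus_id)
                if cls is None:
                    hint = ltr_len_hint or len(query) // 3
                    cls = ("solitary_ltr" if len(m.sequence) <= 2.0 * hint
                           else "full")
                row[sp] = "solitary_ltr" if cls == "solitary_ltr" else "full"
            else:
                votes = [map_results.get((m.locus_id, sp)) for m in members]
                votes = [v.state for v in votes if v is not None]
                for preferred in ("full", "solitary_ltr", "empty"):
                    if preferred in votes:
                        row[sp] = preferred
                        break
                else:
                    row[sp] = "unresolved"
        matrix.states[cid] = row

        # structural class of the cluster
        classes = [structures.get(m.locus_id, "unclassified") for m in members]
        if "provirus" in classes:
            matrix.cluster_class[cid] = "provirus"
        elif "processed_pseudogene" in classes:
            matrix.cluster_class[cid] = "processed_pseudogene"
        elif classes and all(c == "solitary_ltr" for c in classes):
            matrix.cluster_class[cid] = "solitary_only"
        else:
            matrix.cluster_class[cid] = "undefined"

        branch, losses = assign_formation_branch(row, tree)
        matrix.formation_branch[cid] = branch
        matrix.losses[cid] = losses
        matrix.recombinations[cid] = infer_recombination_events(
            row, tree, cluster_class=matrix.cluster_class[cid])
    logger.info("build_matrix: %d loci -> %d clusters over %d species",
                len(locus_lookup), len(ordered), len(species))
    return matrix


# ---------------------------------------------------------------------------
# Dollo formation-branch assignment
# ---------------------------------------------------------------------------

def assign_formation_branch(row: dict[str, str], tree: SpeciesTree
                            ) -> tuple[str | None, list[tuple[str, str]]]:
    """Dollo rule: formation on the stem branch of the LCA of all presence
    species (solitary LTRs count as presence); descendant absences are losses
    (``empty``) or no-calls (``unresolved``). Returns (branch_id, events)."""
    presence = [sp for sp, st in row.items() if st in ("full", "solitary_ltr")]
    if not presence:
        logger.warning("no presence species in row; no formation branch assigned")
        return None, []
    branch = tree.mrca_branch(presence)
    events = []
    for sp in tree.leaves_below(branch):
        if row.get(sp) == "empty":
            events.append((sp, "loss"))
        elif row.get(sp) == "unresolved":
            events.append((sp, "no_call"))
    return branch, events


def infer_recombination_events(row: dict[str, str], tree: SpeciesTree,
                               cluster_class: str = "provirus") -> list[str]:
    """LTR-LTR recombination calls: each maximal clade whose members are all
    ``solitary_ltr`` while a full-state relative exists yields one call on
    that clade's stem branch. Processed-pseudogene clusters are excluded
    (their truncated LTRs cannot recombine homologously)."""
    solitary = {sp for sp, st in row.items() if st == "solitary_ltr"}
    full = {sp for sp, st in row.items() if st == "full"}
    if not solitary or not full:
        return []
    if cluster_class == "processed_pseudogene":
        logger.warning("recombination signal in a processed-pseudogene cluster; "
                       "calls suppressed")
        return []
    calls = []
    root = tree.root

    def visit(node, parent_all_solitary: bool):
        clade = set(node.clade)
        all_sol = clade <= solitary
        if all_sol and not parent_all_solitary:
            calls.append(node.branch_id)
        for child in node.child_nodes():
            visit(child, all_sol)

    visit(root, False)
    return sorted(calls)


def formation_report(matrix: OrthologMatrix, tree: SpeciesTree) -> pd.DataFrame:
    """Per-branch formation counts by structural class; every cluster lands in
    exactly one cell (clusters without an assignable branch get 'unassigned')."""
    classes = ["provirus", "processed_pseudogene", "undefined", "solitary_only"]
    branch_order = [bid for bid, _ in tree.branches()]
    counts = {bid: {c: 0 for c in classes} for bid in branch_order}
    counts["unassigned"] = {c: 0 for c in classes}
    for cid in matrix.cluster_ids:
        branch = matrix.formation_branch.get(cid) or "unassigned"
        cls = matrix.cluster_class.get(cid, "undefined")
        if cls not in classes:
            cls = "undefined"
        counts.setdefault(branch, {c: 0 for c in classes})[cls] += 1
    rows = []
    for bid in list(branch_order) + ["unassigned"]:
        node_age = tree.node_age(bid) if bid != "unassigned" else np.nan
        row = {"branch": bid, "node_age_mya": node_age}
        row.update(counts[bid])
        row["total"] = sum(counts[bid].values())
        rows.append(row)
    return pd.DataFrame(rows)
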