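"""Shared data model, standard-format I/O and configuration.

Coordinates are 0-based half-open internally; 1-based UCSC-style coordinates
appear only in human-facing reports. Sequences are uppercase DNA over
``{A,C,G,T,N}``; other IUPAC ambiguity letters are rejected in strict mode or
coerced to ``N`` when ``PipelineConfig.n_policy == "coerce"``.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("ervography")

VALID_ALPHABET = frozenset("ACGTN")
_IUPAC_EXTRA = frozenset("RYSWKMBDHVU")


class FormatError(ValueError):
    """Raised for malformed input files (FASTA/Newick/BED/TSV)."""


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant (e.g. non-ultrametric tree)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """One contig of one species' genome assembly."""

    species_id: str
    contig_id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValidationError(
                f"empty sequence for {self.species_id}/{self.contig_id}")
        bad = set(self.seq) - VALID_ALPHABET
        if bad:
            raise ValidationError(
                f"invalid characters {sorted(bad)} in {self.species_id}/{self.contig_id}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a contig."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start},{self.end}) on {self.contig_id}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.contig_id == other.contig_id
                and self.start < other.end and other.start < self.end)

    def to_ucsc(self) -> str:
        """1-based inclusive, report-facing."""
        return f"{self.contig_id}:{self.start + 1}-{self.end}"


@dataclass
class PipelineConfig:
    """Tunable knobs shared across pipeline stages (defaults are the study conditions)."""

    flank_len: int = 500              # nt of 5'/3' flanking sequence anchoring orthology
    dotplot_window: int = 100         # nt window for dot-plot identity
    dotplot_threshold: float = 0.50   # identity fraction highlighting a window pair
    dotplot_step: int = 25
    bootstrap_reps: int = 100
    seed_k: int = 12                  # k-mer size of the seed index
    merge_gap: int = 2000             # nt; same-strand hits closer than this merge into one locus
    min_hit_len: int = 100
    min_hit_identity: float = 0.60    # keeps divergent "ERV-like" elements discoverable
    band: int = 32                    # extension band half-width (diagonals)
    chain_gap: int = 700              # nt; max seed spacing within one chain
    subst_rate: float = 2.2e-3        # substitutions/site/MY (neutral primate-like)
    kappa: float = 2.0                # transition/transversion rate bias
    flank_min_identity: float = 0.75  # ortholog flank acceptance
    flank_min_len: int = 300
    empty_site_slack: int = 50        # nt; max residual gap still called an empty site
    ltr_pair_min_len: int = 200       # nt; min LTR-LTR alignment to pair terminal repeats
    ltr_pair_min_identity: float = 0.70
    segment_coverage: float = 0.50    # U3/U5 presence: min covered fraction of model segment
    segment_min_identity: float = 0.70
    n_policy: str = "strict"          # "strict" rejects IUPAC ambiguity, "coerce" maps to N
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("flank_len", "dotplot_window", "bootstrap_reps", "seed_k",
                     "merge_gap", "min_hit_len", "band", "flank_min_len",
                     "ltr_pair_min_len", "dotplot_step", "chain_gap"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"config field {name} must be positive")
        if not (0.0 < self.dotplot_threshold <= 1.0):
            raise ValidationError("dotplot_threshold must be in (0,1]")
        if self.subst_rate < 0:
            raise ValidationError("subst_rate must be >= 0")
        if self.n_policy not in ("strict", "coerce"):
            raise ValidationError("n_policy must be 'strict' or 'coerce'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class SpeciesTree:
    """Rooted ultrametric species tree with node ages in MYa.

    Branches (edges) are identified by the sorted ``+``-joined set of leaf
    labels below them, e.g. ``"chimp+human"`` for the human-chimp stem; the
    root's own stem edge has the id of the full leaf set and hosts events that
    predate the basal split.
    """

    AGE_TOL = 1e-6

    def __init__(self, tree: dendropy.Tree, root_stem_length: float = 0.0):
        self._tree = tree
        tree.seed_node.edge.length = root_stem_length or tree.seed_node.edge.length or 0.0
        self._compute_ages()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path, root_stem_length: float = 0.0) -> "SpeciesTree":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                        and "(" not in source):
            with open(source) as fh:
                text = fh.read()
        else:
            text = str(source)
        try:
            tree = dendropy.Tree.get(data=text, schema="newick",
                                     rooting="force-rooted")
        except Exception as exc:  # dendropy raises assorted error types
            raise FormatError(f"could not parse Newick tree: {exc}") from exc
        return cls(tree, root_stem_length=root_stem_length)

    @classmethod
    def default_catarrhini(cls) -> "SpeciesTree":
        """Six-species catarrhine topology with approximate divergence ages in MYa.

        Root (human-rhesus split) at 30 MYa; the 13-MY root stem represents
        the interval back to the catarrhine/platyrrhine separation (~43 MYa),
        the period hosting the bulk of ERV-W-like germ-line colonization.
        """
        newick = ("(((((human:7,chimp:7):2,gorilla:9):8,orangutan:17):3,"
                  "gibbon:20):10,rhesus:30);")
        return cls.from_newick(newick, root_stem_length=13.0)

    # -- internals ----------------------------------------------------------

    def _compute_ages(self) -> None:
        leaves = self._tree.leaf_node_iter()
        depths = {}
        for leaf in leaves:
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                if node.edge.length is None:
                    raise FormatError(f"branch above {self._label(node)} lacks a length")
                d += node.edge.length
                node = node.parent_node
            depths[leaf.taxon.label] = d
        if not depths:
            raise FormatError("tree has no leaves")
        dmax = max(depths.values())
        offending = [lab for lab, d in depths.items()
                     if abs(d - dmax) > self.AGE_TOL * max(1.0, dmax)]
        if offending:
            raise ValidationError(
                "tree is not ultrametric; offending leaves: " + ", ".join(sorted(offending)))
        # node age = distance to any descendant leaf
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                node.age = 0.0
            else:
                child = node.child_nodes()[0]
                node.age = child.age + child.edge.length
        for node in self._tree.preorder_node_iter():
            node.clade = tuple(sorted(l.taxon.label for l in node.leaf_iter()))
            node.branch_id = "+".join(node.clade)

    @staticmethod
    def _label(node) -> str:
        return node.taxon.label if node.taxon else "<internal>"

    # -- queries ------------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self):
        return self._tree.seed_node

    @property
    def root_age(self) -> float:
        return self.root.age

    @property
    def species(self) -> list[str]:
        return sorted(l.taxon.label for l in self._tree.leaf_node_iter())

    def node_for_branch(self, branch_id: str):
        for node in self._tree.preorder_node_iter():
            if node.branch_id == branch_id:
                return node
        raise KeyError(f"no branch {branch_id!r} in tree")

    def branches(self) -> list[tuple[str, float]]:
        """(branch_id, length in MY) in preorder; includes the root stem."""
        return [(n.branch_id, n.edge.length or 0.0)
                for n in self._tree.preorder_node_iter()]

    def leaves_below(self, branch_id: str) -> tuple[str, ...]:
        return self.node_for_branch(branch_id).clade

    def mrca_branch(self, species: Iterable[str]) -> str:
        """Branch id of the stem edge above the MRCA of the given species."""
        wanted = set(species)
        missing = wanted - set(self.species)
        if missing:
            raise KeyError(f"species not in tree: {sorted(missing)}")
        node = self._tree.mrca(taxon_labels=sorted(wanted))
        return node.branch_id

    def node_age(self, branch_id: str) -> float:
        return self.node_for_branch(branch_id).age

    def is_ancestor_branch(self, ancestor_id: str, descendant_id: str) -> bool:
        return set(self.leaves_below(descendant_id)) <= set(self.leaves_below(ancestor_id))

    def path_length(self, a: str, b: str) -> float:
        """Patristic distance (MY) between two leaves."""
        if not hasattr(self, "_pdm"):
            self._pdm = self._tree.phylogenetic_distance_matrix()
        ta = self._tree.taxon_namespace.get_taxon(a)
        tb = self._tree.taxon_namespace.get_taxon(b)
        return self._pdm.patristic_distance(ta, tb)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()


def read_species_tree(path: str | Path, root_stem_length: float = 0.0) -> SpeciesTree:
    """Read a dated Newick tree (branch lengths in MY) and validate ultrametricity."""
    return SpeciesTree.from_newick(path, root_stem_length=root_stem_length)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _clean_seq(raw: str, n_policy: str, where: str) -> str:
    seq = raw.upper()
    extra = set(seq) - VALID_ALPHABET
    if extra:
        if extra - _IUPAC_EXTRA - {"-"}:
            raise FormatError(f"non-nucleotide characters {sorted(extra - _IUPAC_EXTRA)} in {where}")
        if n_policy == "coerce":
            seq = "".join("N" if c in extra else c for c in seq)
        else:
            raise FormatError(
                f"ambiguity characters {sorted(extra)} in {where} (strict mode; "
                "set n_policy='coerce' to map them to N)")
    return seq


def read_fasta(path: str | Path, species_id: str | None = None,
               n_policy: str = "strict") -> list[GenomeSequence]:
    """Read a multi-record FASTA into GenomeSequence records.

    ``species_id`` defaults to the file stem; record ids become contig ids.
    """
    path = Path(path)
    if species_id is None:
        species_id = path.stem
    records = []
    with open(path) as fh:
        text = fh.read()
    if text.strip() and not text.lstrip().startswith(">"):
        first_bad = text.lstrip().splitlines()[0][:30]
        raise FormatError(f"not FASTA: file starts with {first_bad!r}")
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if not rec.id:
            raise FormatError(f"record with empty header in {path}")
        seq = _clean_seq(str(rec.seq), n_policy, f"{path}:{rec.id}")
        if not seq:
            raise FormatError(f"empty record {rec.id!r} in {path}")
        records.append(GenomeSequence(species_id=species_id, contig_id=rec.id, seq=seq))
    if not records:
        raise FormatError(f"no records in {path}")
    seen = set()
    for r in records:
        key = (r.species_id, r.contig_id)
        if key in seen:
            raise FormatError(f"duplicate contig id {r.contig_id!r} in {path}")
        seen.add(key)
    logger.info("read_fasta: %d records from %s", len(records), path)
    return records


def write_fasta(seqs: Sequence, path: str | Path) -> None:
    """Write (name, seq) pairs or GenomeSequence records to FASTA."""
    records = []
    for item in seqs:
        if isinstance(item, GenomeSequence):
            records.append(SeqRecord(Seq(item.seq), id=item.contig_id, description=""))
        else:
            name, seq = item
            records.append(SeqRecord(Seq(seq), id=name, description=""))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------

def write_bed(loci, path: str | Path, contig_lengths: dict | None = None) -> None:
    """Write loci as BED6 (name = locus id, score = percent identity x 10)."""
    with open(path, "w") as fh:
        for locus in loci:
            iv = locus.interval
            if contig_lengths is not None:
                clen = contig_lengths.get(iv.contig_id)
                if clen is not None and iv.end > clen:
                    raise ValidationError(
                        f"locus {locus.locus_id} interval end {iv.end} exceeds "
                        f"contig {iv.contig_id} length {clen}")
            score = int(round(locus.percent_identity * 1000))
            fh.write(f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{locus.locus_id}\t"
                     f"{score}\t{locus.strand}\n")


def read_bed(path: str | Path) -> list[dict]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns, got {len(parts)}")
            rows.append({
                "contig_id": parts[0], "start": int(parts[1]), "end": int(parts[2]),
                "name": parts[3], "score": int(parts[4]), "strand": parts[5],
            })
    return rows


def write_tsv(table, path: str | Path, comment_lines: Sequence[str] = ()) -> None:
    """Write a pandas DataFrame as TSV with optional leading '#' comment lines."""
    with open(path, "w", newline="") as fh:
        for line in comment_lines:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_tsv(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# misc sequence helpers shared across stages
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
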