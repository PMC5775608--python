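# Methods

## Scope and model

The package reconstructs the colonization history of an endogenous
retrovirus (ERV) group across a clade of genomes from three kinds of
evidence: (i) sequence similarity to an LTR–internal–LTR reference, (ii) the
structural state of each locus, and (iii) the presence or absence of the
insertion at the orthologous position in each species. The central modelling
assumptions are the standard ones for ERV presence/absence work:

* **Single gain, rare loss (Dollo).** A germ-line integration happens once;
  the same element at the same flanking position in two species is the same
  event. Losses (locus deletion, or internal-region loss by LTR–LTR
  recombination) can happen independently per lineage but re-gain at the
  same site cannot.
* **Neutral divergence.** After integration, loci accumulate substitutions
  at a clock-like rate, so LTR-pair divergence dates an insertion
  (`age = d_K2P / (2r)`) and flank similarity decays predictably with
  species divergence.
* **Mechanistic locus classes.** Proviruses carry two complete LTRs
  (U3+R+U5 at both ends). L1-mediated processed pseudogenes are copies of
  the proviral *transcript*, which starts at the 5' R and ends at the 3' R:
  they lack the 5' LTR's U3 and the 3' LTR's U5, end in a poly-A tract and
  are flanked by target-site duplications. Solitary LTRs are single LTRs
  left by homologous recombination between the two LTRs of a provirus —
  a mechanism unavailable to processed pseudogenes, whose truncated LTRs
  share too little homology.

## Pipeline stages

**Discovery** (`locus_discovery`). A sorted-array index of all non-N 12-mers
of each genome seeds both-strand searches (the query's reverse complement is
looked up against the plus-strand index). Seeds are chained by diagonal
proximity (band 32 diagonals, chain gap 700 nt) and each chain is extended
with banded local alignment (match +1, mismatch −1, gap open −4, gap extend
−1). Hits shorter than 100 nt or below 60% identity are dropped; the
permissive identity floor deliberately keeps divergent "ERV-like" relatives
of the query discoverable. Same-strand hits within 2 kb merge into one locus,
which carries 500 nt flanks (truncated with a warning at contig ends).

**Classification** (`structure`). Terminal windows of 1.5× the reference LTR
length are locally aligned against each other; a pair of LTRs is reported at
≥200 aligned nt and ≥70% identity. U3/U5 presence is judged by
local-alignment coverage (≥50% of the model segment at ≥70% identity) of the
model's U3 against the 5' window and U5 against the 3' window. Poly-A is
called when ≥8 of 12 terminal nt (of the locus or of the sequence
immediately 3' of it — discovery trims the untemplated tail off the locus
interval) are A; TSDs are exact 3–8 nt terminal duplications of the flanks,
searched across a small offset to skip the poly-A. Decision order:
solitary LTR (no internal-region hit, LTR-scale length) → provirus (paired
LTRs with U3 and U5 at the proper ends) → processed pseudogene (internal
region plus truncated-LTR evidence and/or poly-A) → undefined. The ambiguous
"one complete plus one truncated LTR" case resolves to processed pseudogene
with a logged warning, since L1 truncation is one-sided in practice.

**Orthology** (`orthology`). Each locus' flanks are searched in every other
genome; a flank anchors when ≥300 of its 500 nt align at ≥75% identity. A
concordant pair (same contig and strand, correct order, spacing within
2× locus length) brackets a candidate interval: residual gap ≤50 nt (one TSD
plus micro-indel slack) is an empty, pre-insertion site; an element-scale
ERV match (union hit coverage ≥1.5× the LTR length) is `full`; an LTR-scale
match only is `solitary_ltr`; anything else — unmapped or discordant flanks,
an interval crossing a ≥20 nt N-run, or an interval with no ERV match — is
`unresolved`, never a guess. Loci cluster across species by reciprocal flank
mapping (each maps into the other's interval); chain conflicts merge with a
flag. Formation branches follow the Dollo rule above; recombination calls
are one per maximal all-solitary clade when a full-state relative exists.

**Comparative statistics** (`comparative`). Global pairwise alignment uses
the same affine scores as extension. The progressive MSA builds a
neighbor-joining guide tree from shared-6-mer distances and merges profiles
with a global profile–profile DP (gap open −4, extend −1; gap state opens
from the match state only, which makes the traceback deterministic).
Majority consensus deletes columns where gaps hold a strict majority and
emits N on residue ties. p-distances remove every column that is the C or G
of a CpG in *either* row (gap-skipping adjacency) before pairwise deletion —
the conservative reading of "removal of CpG dinucleotides", chosen because
CpG hypermutability contaminates whichever row carries the dinucleotide.
K2P distances flag saturated pairs as infinite; `k2p_matrix` drops the
offending sequences greedily (warning) before NJ. NJ is the canonical
Q-criterion algorithm with ties broken by label order and negative branch
lengths clamped to zero with a warning. Bootstrap resamples alignment
columns; split support is the percentage of replicates containing each
original split, with zero-length internal edges treated as unresolved.

## The synthetic-data generator

`synthetic_data.simulate` evolves one contig per species down a dated,
ultrametric tree (the packaged default is a six-species catarrhine-like
topology — human, chimp, gorilla, orangutan, gibbon, rhesus — with node ages
7/9/17/20/30 MYa and a 13 MY root stem reaching back to the split from the
sister parvorder). What it emulates:

* **Insertion waves.** Events are Poisson per branch with intensity
  `rate × branch length` (or an exact total allocated multinomially). The
  default rate profile peaks on the root stem and is 10× lower on younger
  branches, reproducing the "major early wave, then decline" temporal shape;
  no quantitative per-MY formation rate is asserted anywhere, so the peak
  level (0.25 events/MY) is a package choice sized to the default 1 Mb
  background.
* **Mechanism mix.** Provirus vs processed pseudogene at 1:2 by default —
  ERV-W-like groups are dominated by L1-processed copies, with roughly two
  pseudogene formations per true proviral integration during the main
  colonization period.
* **Element anatomy.** The reference element is random DNA with an
  HERV-like layout: LTR = U3(45%)+R(10%)+U5(45%); internal =
  pre-gag(10%)+gag(20%)+pol(45%)+env(25%), with gag/pol/env generated as
  intact ORFs so putein extraction has a defined truth. Pseudogene copies
  are emitted as R+U5 + internal + U3+R + poly-A(12); every insertion
  duplicates a 4 nt target site.
* **Post-insertion fates.** LTR–LTR recombination collapses a provirus to a
  single chimeric LTR (5' part of the 5' LTR joined to the 3' part of the
  3' LTR at a uniform homologous crossover). Recombinations are planted on a
  branch strictly below the insertion branch, so a full-state sister always
  remains: a recombination realized in *every* carrier is mathematically
  indistinguishable from a solitary insertion under the inference contract,
  and planting only identifiable events keeps the ground truth meaningful.
  Optional per-species deletion excises the element plus one TSD copy,
  restoring a pre-insertion-like allele (truth records it as
  `deleted_region`, distinct from never-inserted).
* **Divergence.** Substitutions accumulate at `subst_rate` (default
  2.2e-3/site/MY, a standard neutral primate-like rate — the package's
  choice, exposed as config) under the K2P jump chain: per-site Poisson hit
  counts, each hit a transition with probability κ/(κ+2) (κ default 2).
  Because the process *is* the K2P chain, the K2P estimator is unbiased for
  `rate × path length`, which the test suite exploits.

Two generator constraints exist purely to keep ground truth well-defined:
insertions never nest (rejection of occupied sites), and insertion points
keep a minimum separation of `merge_gap + flank_len + 100` nt in root
coordinates. Without the separation floor, two independent insertions could
fall within the hit-merging distance (or inside each other's flanks) and no
method could recover them as distinct loci — the floor removes an ambiguity
of the synthetic world, not a weakness of the inference.

**What the simulator does not emulate** — and hence what passing tests do
not show about real genomes: assembly gaps and errors, segmental
duplications and nested/fragmented elements, ectopic gene conversion between
loci, indel mutation (off by default), rate variation across sites and
lineages (no CpG hypermutability, although the distance code strips CpGs),
selection, and subfamily structure within the ERV group. Real flanks are
repeat-rich rather than unique random DNA, so real flank-anchoring is
harder than it is here.

## Numerical and design choices

* Coordinates are 0-based half-open internally; 1-based inclusive only in
  report strings. Branches are named by the sorted `+`-joined leaf set below
  them, which makes every inference deterministic and comparable.
* Seed-and-extend replaces a full BLAT reimplementation: the contract is
  recall at the divergences in play (≤~30%), which chained 12-mers with
  banded extension achieve at desk scale. The identity floor (60%) and
  minimum hit length (100 nt) are explicit configuration, not an inference
  about any external tool's internal cutoffs.
* Alignment tie-breaking is deterministic everywhere (first-optimal
  alignment; leftmost-longest in the banded extension; label order in NJ).
* Age CIs propagate a binomial 95% interval on the raw difference
  proportion through the K2P correction's local scale factor; estimates
  from <200 aligned nt or with d > 0.3 are flagged unreliable rather than
  suppressed.
* Ambiguity letters beyond N are rejected by default (`n_policy="strict"`)
  with an explicit `"coerce"` switch; how N-runs affect absence calls is a
  config decision (`unresolved` on ≥20 nt runs), since there is no uniquely
  correct treatment of assembly gaps.
* The run manifest records config, input checksums, seed and timestamps;
  all report tables are byte-deterministic given a seed, and the manifest is
  the one file allowed to differ (wall-clock timestamps) between identical
  runs.

## Problem sizes

Default test and acceptance runs use a scaled element (LTR 400 nt, internal
2 kb — the layout, not the length, carries the signal) with 150 planted loci
on 4.5 Mb backgrounds, chosen so the full pipeline remains a few minutes of
one-CPU work while every structural signature (U3/U5 segments ≥100 nt,
LTR pair ≥200 nt alignable) stays comfortably above the detection
thresholds. The simulator accepts full-size elements (780 nt LTR, 7 kb
internal, the package defaults) for realistic-scale runs.

## Known limitations

Orthology assumes collinear flanks: inversions or translocations between
species yield `unresolved`, not a breakpoint-aware call. Clustering is
pairwise-reciprocal and can merge chains through an intermediate species
(flagged `conflict`). The progressive MSA is a contract implementation for
desk-scale inputs, not a competitor to dedicated aligners; an external
alignment can be substituted through the `precomputed` hook. ML tree search
is out of scope; NJ with bootstrap is the supported tree method.
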