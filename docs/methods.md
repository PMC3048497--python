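# Methods

This note documents the models, thresholds and numerical choices behind
`tlpcensus`, what the synthetic-data generators do and do not emulate, and
the design decisions taken where the problem was genuinely open.

## Domain delimitation

The thaumatin domain is delimited by two short boundary motifs:
`N-x-C-x(3)-V/I-W` at the N-terminal end (8 residues, read with exactly
three wildcards between the cysteine and the V/I) and `Y-x-I/V-x-F-C-x` at
the C-terminal end (7 residues). Wildcards match the 20 standard residues
but **not** the ambiguity letter X: an unknown residue cannot certify a
boundary. Matches may overlap; all are reported.

When several motif pairs exist, the domain is the (N, C) pair spanning the
longest region whose length lies inside the configured bounds, with ties
broken toward the smallest start — a deterministic policy that favours
full-length domains. If no pair fits the bounds, the longest pair is kept
so that validation can name the length failure; if only one boundary is
found, the domain extends to the corresponding protein end and is marked
incomplete.

Completeness requires both motifs, a length in `[min_len, max_len]`
(defaults **120–330 aa**) and at least `min_cys` cysteines (default
**8**). The length band admits small-TLP domains near 150 aa and the long
ascomycete domains near 280 aa while rejecting fragments; the cysteine
floor is half the canonical 16. All three are config keys
(`domain.min_len/max_len/min_cys`). Failure reasons enumerate *every*
violated criterion, so census reports can say why a model was dropped.
Signal peptides are not trimmed: domain coverage is reported against the
full precursor length (typical synthetic scaffolds give ≈ 0.956, consistent
with the domain covering ~95 % of a mature TLP).

## Architecture classification

Decision tree, evaluated on the delimited domain:

* no complete domain → **incomplete**;
* a kinase region downstream of the domain → **tlp_kinase**, or
  **small_tlp_kinase** when the domain also meets the small criteria;
* otherwise domain length < `small_cutoff` (default **180 aa**, the
  midpoint of the ~150 vs ~215 aa bimodality) *and* cysteine count in
  **[9, 11]** → **small**;
* otherwise cysteine count in **[14, 16]** → **typical**; any other count
  is still labelled typical but flagged `atypical_cysteine_count` in the
  evidence.

The cysteine bands tolerate the 1–2 residue deviations seen in divergent
fungal and animal sequences instead of demanding exact 16/10 counts.

**Kinase detection** is a self-contained three-anchor heuristic rather
than a profile HMM: a glycine-rich loop `G-x-G-x-x-G`, a catalytic
`H-x-D`, and the activation-segment `D-x-G` must occur in order, with
start-to-start spacings of 60–140 and 15–45 residues respectively; the
region is anchored at the glycine loop, extended 170 residues past
`D-x-G` (clipped to the protein) and must reach 200 residues. The two
catalytic aspartates are those of the `H-x-D` and `D-x-G` anchors and are
reported in per-protein coordinates. Because this is a motif heuristic,
divergent kinase domains whose anchors deviate from the patterns would be
missed (false negatives); all windows are config keys.

**Transmembrane detection** uses the classic Kyte–Doolittle rule: the
maximal-scoring window of length 19 is reported when its mean hydropathy
reaches 1.6. X scores 0 (neutral). When domain and kinase coordinates are
known the search is restricted to the region between them, where the
small-TLP-kinase architecture places its TM stretch.

**REDDD scoring.** The five acidic-cleft positions are given as ungapped
positions on a reference row and mapped through that row's gap structure
to alignment columns. Every row is scored per position as *identical* (the
canonical R, E, D, D, D letter), *equivalent* (charge-preserving swaps
only: K for R, D/E interchange), or *divergent*; a gap is divergent. A
sequence is "fully conserved" when no position is divergent. Broader
physicochemical equivalence (e.g. Q for E) is deliberately not accepted.

**Column conservation** bins the count of distinct non-gap residues per
column into four levels: 1 → level 1, 2–3 → level 2, 4–6 → level 3,
≥ 7 → level 4. X counts as a residue kind; an all-gap column is level 1.

## Physicochemical descriptors

Molecular weight is the sum of average residue masses plus one water
(18.0153 Da); X is an error, since an unknown residue has no defined mass.
Net charge at a given pH is the Henderson–Hasselbalch sum over the
N-terminus, C-terminus and the D, E, C, Y (acidic) and H, K, R (basic)
side chains. The default pKa set is the EMBOSS table (N-term 8.6, C-term
3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1), packaged as a
swappable mapping: published pI values depend on the tool's pKa choices,
so no specific published range is promised to reproduce exactly.

The isoelectric point is found by bisection on pH ∈ [0, 14]. Net charge is
strictly decreasing in pH, so the root is unique; bisection continues
until the net charge is below `tol` (default 1e-4) *and* the bracket is
narrower than 1e-6 pH units — the second condition matters for short
peptides whose titration curve is nearly flat around the root (the
two-group case GG lands exactly on the pKa midpoint 6.10).

## Phylogeny

Distances follow the classic amino-acid chain: per pair, alignment columns
where either row has a gap **or X** are excluded (pairwise deletion; X is
unscoreable), p = differing/usable sites, and the Poisson correction
d = −ln(1 − p). Pairs with zero usable columns or p ≥ 1 are flagged
undefined; tree building refuses such matrices and names the pairs.

Neighbour-Joining is the Saitou–Nei agglomeration with the standard
Q-criterion and two-point branch-length formulas. Determinism and
degeneracy choices:

* Q ties are broken on the lexicographically smallest pair of cluster
  representatives (the minimum leaf label in each cluster), so floating-
  point coincidences cannot make runs differ.
* Negative branch estimates at a join are clamped to zero with the deficit
  moved to the sibling branch (their sum, the joined distance, is
  preserved); at the final three-taxon resolution negatives are clamped to
  zero.
* An all-zero distance matrix (e.g. identical sequences) returns an
  unresolved star rather than an arbitrary tie-broken resolved topology;
  a star has no internal edges, hence no supports.

Bootstrap resamples columns with replacement, one seeded generator driving
all replicates, and rebuilds the full chain per replicate. Support of an
internal edge is the fraction of **all** replicates containing its
bipartition; replicates whose resampled matrix has undefined pairs support
nothing and are tallied in a diagnostics field rather than silently
dropped. Newick output carries branch lengths to 6 decimals and supports
as integer percentages (rounded half-up) on internal nodes.

Clade assignment expands anchor leaf sets: each clade is the minimal
subtree spanning its anchors plus the leaves attached directly to that
subtree's internal nodes. This is the unique reading consistent with the
intended behaviours — a single anchor claims only itself, two cherry
anchors claim the cherry, and two anchors spanning the root path of a
quartet absorb all four leaves. Leaves claimed by several clades, or by
none, are `unplaced`.

## Genomics

All interval arithmetic is 0-based half-open and strand-agnostic (strand
affects reporting only). A tandem cluster is a maximal run of family genes
on one chromosome in which each next family gene starts at most `gap_bp`
(default **100 kb**) after the previous one's end; runs below `min_size`
(default 3) are dropped. The default gap comfortably recovers an 11-gene /
350 kb array (mean inter-gene gap ≈ 33 kb) while not chaining across
megabase voids. The span runs from the first gene's start to the last
gene's end, and a cluster is *exclusive* when no non-family gene overlaps
the span. TE coverage is computed on interval unions after clipping to the
region, per class and overall, so overlaps are never double-counted;
enrichment against user-supplied genome-background fractions is a plain
ratio (no significance test — the quantity of interest is descriptive).
Background fractions are configuration inputs, not recomputed.

## Synthetic data

The generators define the package's study conditions:

* **Scaffolds.** Typical: 215-residue domain, 16 cysteines, 5-residue
  leader/tail (total 225 aa). Small: 150-residue domain, 10 cysteines.
  Kinase fusions: 25-aa leader, domain, 20-aa linker, 19-residue
  hydrophobic TM stretch, 20-aa linker, 320-aa kinase segment with the
  anchor triad planted at offsets 0/100/130, 31-aa tail — 650 aa total for
  the typical-domain fusion. Two cysteines sit inside the boundary motifs;
  the rest are evenly spaced through the domain body (a fixed template, so
  coordinates are stable across seeds). REDDD letters are planted at fixed
  fractional offsets. Filler alphabets exclude C/N/Y/W everywhere and
  additionally G/H/D plus strong hydrophobics downstream of the domain, so
  planted motifs are provably the only ones present and ground truth is
  exact. This is also the honest limitation: real sequences carry noisy
  motif context, signal peptides and length variation that these scaffolds
  do not, so round-trip accuracy on them demonstrates correctness of the
  decision logic, not real-data sensitivity.
* **Evolution.** Sites evolve independently under the 20-state uniform-
  jump chain (rate 1 substitution per site per unit branch length, jumps
  uniform over the other 19 residues), implemented via its exact
  transition marginal: on a branch of length b each site resamples
  uniformly over all 20 letters with probability 1 − e^(−20b/19).
  Expected pairwise difference between leaves at path distance d is
  E[p] = (19/20)(1 − e^(−20d/19)), a function of d alone; the matching
  estimator d̂ = −(19/20) ln(1 − (20/19) p) is provided alongside the
  plain Poisson correction (which under-corrects by ≈ 0.04 at d = 1).
  Frozen positions (cysteines/REDDD, for classifier fixtures) never
  change; phylogeny fixtures freeze nothing so distances stay unbiased.
  No indels, no rate heterogeneity, no empirical exchangeabilities.
* **Loci.** Family genes are laid out as one evenly spaced array whose
  span is exact by construction (defaults: 11 genes × 2 kb over 350 kb);
  exon counts are planted per gene with 200-bp introns. Repeat intervals
  are tiled non-overlapping inside the span in ≤ 4 kb pieces with 1 kb
  spacers until each class reaches its planned bp exactly (defaults:
  Gypsy 37 %, DNA transposons 10 %, Copia 5 % — 52 % total); infeasible
  plans (> 100 %, or not fitting the span) raise.

## Problem sizes and verification

The validation suite runs the pipeline at these sizes: 200 scaffolds per
architecture for classification round-trips; 1,000 random sequences
against a brute-force motif matcher; 500 random additive matrices
(4–8 leaves) for exact NJ recovery plus 200 perturbed 5-leaf instances
against exhaustive least-squares search (≥ 95 % agreement expected —
near-additive matrices can legitimately split the two criteria); distance
recovery at d ∈ {0.1, 0.5, 1.0} over 10,000 columns within 0.05;
6-taxon/2,000-column bootstrap at 1,000 replicates with true splits
supported ≥ 0.95; 500 random peptides against a 1e-5 pH grid; 1,000
random interval fixtures against per-base counting. Independent
cross-checks against scikit-bio's NJ and dendropy's Robinson–Foulds
distance guard the from-scratch implementations. `scripts/acceptance.py`
recomputes all of this from a single seed.

## Known limitations

* Kinase and TM detection are heuristics; they are calibrated for the
  anchor motifs and hydropathy of well-behaved kinase fusions, not for
  divergent pseudokinases.
* Allele deduplication between genome assembly versions is out of scope
  and not guessed at.
* Trees on real alignments depend on upstream alignment quality (manual
  curation included); correctness claims rest on synthetic recovery, not
  on leaf-by-leaf agreement with any published tree.
* The pI and MW values depend on the packaged tables; swap the pKa table
  to mimic other tools.
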