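# Methods

## Coordinate model

All computation happens in gene-rank space: genes are sorted by
(start, end, gene_id) per chromosome and indexed 0..n−1. Block sizes,
gaps, windows and breakpoints are counted in genes, never base pairs;
bp coordinates are carried through unchanged for export only. BED
(0-based half-open) and GFF3 (1-based closed) are both normalized to
ranks on load, which removes dialect ambiguity from the core. The GFF3
feature type and ID attribute are configurable because annotation sets
disagree about whether gene models live on `gene` or `mRNA` records.

## Anchor chaining

A synteny block is a chain of anchors strictly monotone in both
genomes (increasing in the target for `+`, decreasing for `-`) in
which consecutive anchors skip at most `gap_size` gene ranks on either
side (a rank difference of `gap_size + 1`). Chains shorter than
`block_size` anchors are discarded. Defaults are `block_size = 5`,
`gap_size = 5`.

Chaining is done per (query chromosome, target chromosome) cell:

* **Small cells** (≤ `exact_limit` = 12 anchors, no gene shared by two
  anchors): the decomposition maximizing the total number of chained
  anchors over anchor-disjoint valid chains is found by branch and
  bound. Exactness here is cheap and removes the greedy pathologies
  that occur on dense small instances.
* **Large cells**: greedy best-chain-first. The highest-scoring chain
  (score = anchor count; `+` preferred on ties, then the deterministic
  first-argmax backtrack of the DP) is extracted, and anchors sharing
  a gene with it **inside its bounding box** are removed before the
  search repeats. The box scope matters: tandem-array anchors
  interleave with the chain and are consumed (preventing spurious
  parallel blocks and depth inflation), while a genuine second
  homoeologous copy of the same region on the same chromosome pair
  lies outside the box and remains chainable. An unrestricted
  "one gene, one chain" rule would erase exactly the multi-copy
  signal a triplication study needs.

Syntenic depth of a reference gene counts the blocks whose query span
covers its rank; span coverage includes non-anchor genes inside a
block, matching the dot-plot notion of regional multiplicity.

## Microsynteny clusters

Syntenic gene pairs (the union of anchors inside retained blocks) form
a graph whose connected components are the clusters; components
spanning fewer than `min_species` (default 2) species are dropped.
Phylogenomic profiles are copy-number matrices with columns ordered by
average-linkage hierarchical clustering on Euclidean distance;
shared-cluster counts are reported per exact clade combination, so the
single-clade entries are the lineage-specific counts and the all-clade
entry the conserved count.

## Fission/fusion counting

The descendant is painted by its blocks against the reference
(overlapping query spans resolved toward more anchors, then earlier
start; segments shorter than `min_segment` = 3 genes dropped as
fractionation debris). Runs of segments that are exactly an internal
inversion — reversing and flipping the run makes both flanking
junctions collinear — are normalized away first, so counts are
invariant to internal inversions. A junction between consecutive
segments counts as a **fusion** unless the second segment is a
collinear continuation of the first on the same reference chromosome
(orientation-consistent, rank gap within `adjacency_tol` = 5).
Counting only junctions whose two sides map to *different* reference
chromosomes would silently miss every fusion that joins two fragments
of the same reference chromosome, which in a triplicated genome is
common (three copies of every chromosome exist to be fused).
**Fissions** follow from the Euler relation
`S = max(F + C_d − ploidy·C_r, 0)` with `C_d`/`C_r` the painted
descendant / represented reference chromosome counts.

The estimator is exact on loss-free histories without breakpoint
reuse (verified over seeded replicates). Known biases, stated rather
than corrected: reciprocal-translocation junctions are counted as
fusions; heavy fractionation fuzzes segment ends and can create or
hide junctions at the tolerance margin; a tail inversion is
observationally identical to a fission plus flipped fusion and is
counted as the latter.

## Ancestral-block reconstruction (levels 1–4)

* **Level 2** merges ingroup-consecutive level-1 blocks whose outgroup
  spans are on the same chromosome, orientation-consistent, and
  adjacent within `merge_tol` ranks (gap or overlap). Blocks under
  `merge_min_size` = 3 anchors may be absorbed but cannot seed a
  merge. `merge_tol` defaults to 15: at per-copy retention ~0.4 the
  gap between consecutive surviving anchors exceeds 5 ranks about
  every 25 genes (0.59⁶ per position), so a tolerance at the chaining
  gap size would shatter blocks with spurious boundaries, whereas
  gaps over 15 (probability 0.59¹⁶ per position) are almost always
  genuine breakpoints.
* **Regions**: the outgroup is divided into `n_regions` (default 16
  on 8 chromosomes) contiguous rank regions, allocated to chromosomes
  by gene count (D'Hondt, at least one each). A cut candidate is a
  clustered level-2 block boundary supported by endpoints from at
  least `min_support` = 3 distinct ingroup chromosomes within a
  10-rank window — a boundary seen by one lineage copy is a
  rearrangement scar, not an ancestral region boundary, since a true
  regional boundary leaves ends in all three homoeologous copies.
  Where no supported boundary exists near the balanced position, the
  cut falls back to the gene-count quantile (the midpoint for two
  regions per chromosome). An `"auto"` mode instead cuts where the
  set of covering ingroup chromosomes changes persistently.
* **Level 3** distributes each region's blocks over three homoeolog
  slots by a deterministic greedy interval 3-colouring, processing
  blocks by outgroup start: a block goes to a slot where it overlaps
  no assigned span (complementarity), preferring the slot that
  already holds its ingroup-chromosome neighbour (proximity), then
  the emptiest slot, then label order. Blocks straddling a region cut
  are split with anchors partitioned by outgroup rank. If no slot is
  conflict-free the block is placed with minimal overlap and logged;
  the no-overlap tiling is a hard invariant outside that logged set.
* **Level 4** sorts each slot's blocks by median outgroup anchor rank
  and flips any block whose anchor steps run against the outgroup
  order more than half the time.

The model genome concatenates each slot's level-4 blocks into
pseudo-chromosomes (`agb01a` … `agb16c`), claiming each ingroup gene
at most once, with a provenance map in both directions. Slot labels
a/b/c are arbitrary per set — the three homoeologs are too
homogeneous to phase into biological subgenomes — so recovery is
always evaluated up to relabelling: homoeologous-set accuracy under
the best bijective matching (Hungarian on the contingency table) and
slot phasing by adjusted Rand index.

Further genomes are mapped by lifting their anchors to the reference
descendant onto model coordinates, chaining, and labelling every gene
inside a painted block span with its AGB.

## Fractionation statistics

A reference (outgroup) gene is *retained* in a homoeolog slot when a
syntenic ortholog of it lies in that slot — from block paintings in
real mode, or from simulation truth in test mode. Retention is
averaged in sliding windows (window 100, step 50, final partial
window kept if ≥ step genes); `combined` is the row sum with ceiling
3.0 (300%), attained exactly iff loss-free. Painting-based presence
is biased low because genes in dropped micro-blocks and unchained
tails are invisible; truth-based presence is exact. Reciprocity is
the mean pairwise Pearson correlation of per-window retention
deviations (negative under a shared retention budget, ~0 under
independent loss; zero-variance slots report NaN).

**Ks/Ka (NG86).** Synonymous site counts per codon are the fraction
of single-base changes that preserve the amino acid, with changes to
stop codons counted as nonsynonymous so sites always sum to three per
codon; sites are averaged over the two sequences. Differences in
multi-hit codons are averaged over all substitution orders that avoid
stop codons (if every order hits a stop, all orders are used — a
stated convention for pathological codons). Jukes–Cantor correction
`ks = −¾ ln(1 − 4/3·ps)`; a non-positive log argument sets the
saturated flag instead of a number. The implementation is checked to
1e-9 against an independent pathway-enumeration oracle.

## Retained triplicated genes

The copy matrix marks, per reference gene, species and slot, whether
a syntenic copy is present. A gene is an RTG when **each** slot is
present in at least `species_fraction` (default 0.8) of species; the
RTG count is monotone non-increasing in this threshold. With four
surveyed species the 0.8 default requires every species to retain
every slot, which together with painting attrition makes real-mode
calling conservative (high precision, recall well below the
truth-mode value) — the two modes are reported side by side in
`analysis/06_rtg_analysis.py`.

Hotspots: non-overlapping 50-gene windows on the model genome; the
null shuffles RTG labels over genes (seeded, 1000 permutations). The
flag threshold is the randomized upper-5% quantile of the pooled null
counts — randomizing at the discrete boundary keeps the null flag
rate at the nominal level, which integer count thresholds cannot do.
Zero planted RTGs flag nothing.

Enrichment is a per-label two-sided Fisher exact test on the 2×2
(in/out of the RTG set × has/lacks label) with Benjamini–Hochberg
correction across labels; the default background is the genes
placeable on the model genome (synteny-conditional), not a whole
proteome. Tissue specificity uses
`tau = Σ(1 − xᵢ/max)/(n − 1)` (NaN for all-zero vectors,
scale-invariant) and groups are contrasted with a two-sided
Mann–Whitney test, with z-scored expression exported for heatmaps.

## The simulator

The generator reproduces the study design the analysis assumes:

* a diploid ancestor (8 chromosomes × 500 genes by default) and an
  outgroup that inherits it unchanged (outgroup-specific
  rearrangement counts exist but default to 0 — the outgroup is the
  coordinate system, chosen in such studies precisely for minimal
  rearrangement);
* a two-step triplication simulated without divergence between the
  steps (no tetraploid-stage-specific loss — no rates exist to
  separate the steps, and slot homogeneity is the observed pattern);
* per-descendant fractionation: each 100-gene window draws a
  retention triple from a symmetric Dirichlet (concentration 3)
  scaled to a fixed budget of 3 × per-copy retention and capped at 1
  by water-filling, which keeps the triple exchangeable and the
  budget exact — hence locally biased, globally unbiased, reciprocal
  retention with per-copy marginal mean exactly `retention_mean`
  (0.41). The planted loss-immune fraction (2%) always survives, and
  the remaining genes' budget is rescaled so the overall marginal
  still equals `retention_mean`. Per-gene survival is Bernoulli given
  the window triple; no run-length deletion structure is modelled.
* rearrangements in the order fission → fusion → inversion →
  translocation (defaults 2/2/3/1 per descendant lineage), with
  breakpoints sampled uniformly over unused inter-gene gaps.
  Identifiability constraints, stated as generator semantics:
  fission/translocation breakpoints keep ≥ `min_fission_fragment`
  (5) genes per fragment (smaller fragments are invisible to any
  block-based method), fusions never recreate a broken adjacency,
  and inversions are internal (a tail inversion is indistinguishable
  from fission + flipped fusion);
* truth homoeologous sets are the outgroup chromosome halves by gene
  count (the regions a triplication study defines on its outgroup);
* expression: 12 tissues; each planted paralog gets one preferred
  tissue (log-normal around TPM 50 vs background 2), one tissue per
  slot without replacement; all other genes are flat around TPM 10.
  Ortholog anchor lists (outgroup→descendant and
  descendant↔descendant, same-subgenome) are emitted as truth.

What the simulator does **not** emulate — and what passing recovery
tests therefore do not establish about real data: sequence-level
divergence of anchors (anchors are truth, so homology inference
errors are out of scope by design), tandem duplication and gene
transposition, transposable elements, run-length fractionation,
divergence between the two polyploidization steps, homoeologous
exchange after the triplication, and assembly error. Real genomes
will also break the balanced-regions prior of `define_regions` more
often than the simulator does.

## Numerical and procedural choices

* Determinism everywhere: one `numpy` Generator seeded from the
  config drives a simulation; chaining, colouring and ordering break
  ties by fixed positional rules; TSV output uses fixed float
  formatting; the pipeline manifest (stage status, parameters,
  SHA-256 of every artifact, no timestamps) is byte-identical across
  reruns of one config.
* Pipeline stages communicate only via on-disk TSV/BED/JSON, so any
  stage can be replaced or inspected; a stage failure aborts with the
  stage named and partial outputs retained.
* Problem sizes: the default simulation (4,000 ancestral genes, four
  descendants) runs the full pipeline in a few seconds on one CPU;
  the recovery analyses use 10–20 seeded replicates. Loss-free
  fission/fusion recovery is run at `block_size 2, gap_size 5,
  min_segment 1` — with no fractionation noise there is nothing for
  the conservative thresholds to filter, and `block_size 5` would
  merely blind the estimator to legal 5-gene fission fragments.
* Degenerate inputs: empty annotations and anchor lists yield empty
  results rather than errors wherever a downstream default is
  well-defined (empty painting, zero depth, no hotspots); validation
  errors are raised for structurally invalid input (empty BED
  intervals, duplicate gene ids, non-codon sequences, thresholds
  outside their domain).

## Known limitations

* The fission/fusion estimator's exactness guarantee is limited to
  loss-free, reuse-free histories; under default fractionation it
  inherits painting noise, and translocations inflate the fusion
  count by design.
* Real-mode retention and RTG recall are biased low by block-coverage
  attrition (quantified in the analysis scripts); cross-species
  presence is routed through the reference descendant's model
  genome, compounding attrition for non-reference species.
* Region cuts rely on either strong multi-copy boundary support or
  balanced quantiles; a genuinely unbalanced ancestral region
  structure with weak boundary signal would be mis-cut.
* `phylogenomic_profile` orders columns for display; it is not a
  phylogenetic inference. Subgenome phasing is explicitly not
  attempted.
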