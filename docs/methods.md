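# Methods

## The problem

The fungal nuclear ribosomal internal transcribed spacer (ITS) region —
ITS1, the 5.8S rRNA gene, and ITS2 — is the standard fungal DNA barcode.
The two spacers are hypervariable and indel-rich; the ~160 nt 5.8S between
them is strongly conserved. Across genus or class boundaries, whole-ITS
pairwise similarity routinely drops below 70%, which puts multiple
alignment — and therefore tree-based placement of unidentified
"environmental" sequences — at the edge of what automated aligners handle
well. A conserved block embedded in barely alignable flanks is a known
hazard: an aligner (or the guide trees feeding it) can lock onto the 5.8S
and drag spacer residues out of register.

`anchorlign` implements and compares four strategies for this regime:

1. **baseline_whole** — a single progressive alignment pass of the whole
   ITS plus a distance tree (the traditional one-shot control);
2. **coest_whole** — iterative alignment/tree co-estimation on the whole
   ITS;
3. **coest_anchored** — every record's 5.8S is excised and replaced by a
   single 16-character constant anchor before co-estimation, so alignment
   is driven purely by the spacers while ITS1 and ITS2 stay separated;
4. **coest_58s_reincluded** — the anchored strategy's best alignment with
   the true 5.8S block (aligned separately) spliced back in place of the
   anchor, then tree and support estimated from the combined alignment.

Because real multi-accession datasets are not bundled, a first-class
synthetic generator produces ITS-like datasets with known tree, known
alignment, known region annotations and known group labels, so every stage
is tested against ground truth.

## Synthetic ITS evolution

*Topology.* A Yule (pure-birth) tree on `n_taxa` leaves (default 32),
rescaled so the root-to-tip height equals `depth_scale` expected
substitutions/site at the 5.8S rate (default 0.06). Leaves are
partitioned into `n_groups` clade-defined groups (default 4, standing in
for genera); `n_queries` leaves (default 8) have their labels masked as
"environmental", with at least one labelled reference left per group.

*Substitutions.* Jukes–Cantor per branch, with per-region rate
multipliers relative to the 5.8S unit rate — default (8, 1, 8) for
(ITS1, 5.8S, ITS2). JC was chosen deliberately so the truth model stays
simpler than anything the inference side could exploit; the
conserved-core/variable-flank contrast is the only structure that matters.

*Indels.* Per branch and region, a Poisson number of events with mean
`indel_rate × region_length × branch_length` (default rate 0.10/site in
the spacers, 0 in the 5.8S — the gene is length-conserved in reality),
geometric lengths (mean 3 nt), insertion/deletion equiprobable. Insertion
columns are propagated into a global column registry, so the generator
emits the exact true alignment; degapping any row reproduces that leaf's
residues.

*Artifacts.* Database-style defects are injected into seeded record
subsets: reverse-complemented submissions (default 10%; these lose their
region annotation, as a flipped record's forward-coordinate annotation no
longer applies), ITS2-truncated records (5%), and fragments clipped below
a usable length (5%, to 150 nt). A chimera flag exists in the
configuration but no chimeras are generated and no detector is provided.

*Calibration.* The defaults put simulated datasets in the empirical
similarity regime of congeneric/intergeneric ITS comparisons: measured on
the default configuration, between-group whole-ITS similarity averages
≈0.57 (generally below 0.70) and within-group pairs range down to ≈0.67.
Region lengths default to (180, 160, 180) nt.

*What the generator does not emulate* — and hence what green tests do not
establish about real data: among-site rate heterogeneity within a region,
base-composition bias, sequencing error, chimeras, alignment-ambiguous
repeats, and taxon sampling as uneven as real databases. Real 5.8S genes
also carry their own (slow) phylogenetic signal structure that a JC
simulation only caricatures.

## Data preparation

*Pairwise similarity* is the number of identically paired residues in one
optimal end-to-end affine-gap alignment divided by the alignment length,
gaps included. Default scoring is +5 match / −4 mismatch, gap open 10,
gap extend 0.5 (a gap of length L costs `open + (L−1)·extend`). Ambiguity
codes count as matches only when literally identical. Ties in the DP are
broken diagonal ≻ up ≻ left, and the two inputs are ordered canonically
before alignment so similarity is exactly symmetric.

*Orientation.* Records submitted in reverse complement are detected by a
k-mer vote (k = 8). The reference pool is first made self-consistent:
orientations are relaxed greedily, flipping one reference whenever that
strictly increases the total same-orientation k-mer sharing over all
reference pairs (a bounded objective, so the sweep terminates; the
majority as-submitted orientation is retained). Every record is then
compared against the corrected pool in both orientations; equal counts —
including zero/zero — are reported as unresolved rather than guessed.
The single-pass pooled vote was abandoned after it demonstrably flipped
correctly-oriented records whose nearest relatives were themselves
mis-oriented.

*Filters.* Records strictly shorter than `min_length` (default 200 nt —
a configuration value, not an empirical claim) and, optionally, records
lacking an ITS2 interval are excluded with per-record reasons.

## The anchor

The anchor is the aperiodic 16-mer `AATGTCCGCTGGACAT`, constant across
all records. Aperiodicity matters: a periodic motif (e.g. `ACGT`
repeated) lets an aligner register two anchor copies at a nonzero offset
with zero mismatch cost, silently splitting the block; the chosen motif
has at most 3/16 self-matches under any shift. The motif is configurable.

Re-insertion aligns the excised 5.8S substrings among themselves (they
are conserved, so a single progressive pass suffices), locates the anchor
block in the anchored alignment, and splices the 5.8S block into its
place. One numerical subtlety: when the anchor's terminal residue equals
the adjacent spacer residue, optimal alignments exist that slide a gap
across the block boundary at no score change, leaving a row's anchor a
column or two out of register. These score-equivalent variants are
canonicalised before excision (each deviant row is rewritten locally
within a ±24-column window so its anchor occupies the consensus block);
an anchor that is absent or strays beyond that window indicates genuine
misalignment and raises an error instead. The splice is an exact inverse:
degapped output rows equal the original ungapped residues.

## Co-estimation

Each run starts from a guide tree built by neighbor joining on alignment-
free k-mer distances (`1 − shared/min(total)`, k = 8); runs after the
first perturb the starting distances with seeded multiplicative noise
(±5%) to emulate independent search trajectories (run 0 is unperturbed,
so one run of one iteration is exactly the single-pass baseline). Each
iteration aligns the sequences progressively along the current guide
(profile–profile, affine gaps, "once a gap, always a gap"; profile
columns are residue-frequency vectors over the non-gap mass — gaps carry
no weight, so a conserved column keeps its full match reward however
gappy the subalignments), re-estimates the tree (JC distances with
pairwise gap deletion, saturation capped at d = 5.0 when p ≥ 0.75, then
NJ with a deterministic lowest-lexicographic tie rule and negative branch
lengths clamped to zero), and scores the pair by Felsenstein-pruning
log-likelihood under JC with gaps as missing data. The best-scored
(alignment, tree) pair across all runs and iterations is kept, with the
full score trace.

This is a deliberate simplification of full simultaneous
alignment-and-tree estimation: there is no divide-and-conquer
decomposition or alignment merging; the previous alignment influences the
next only through the re-estimated guide tree. The JC likelihood on an NJ
tree is a selection score with the same monotone intent as a full ML
score, chosen because it is closed-form and testable against a
brute-force state-sum oracle.

## Support and placement

Branch support is the bootstrap frequency of each internal bipartition of
the point-estimate tree among trees rebuilt from column-resampled
alignments (default 100 replicates). The conventional "significantly
supported" threshold of 0.94 is configuration (a 0.95 preset also
exists), and everything downstream is estimator-agnostic — a Bayesian
posterior estimator could fill the same slot without touching any
decision rule. A majority-rule consensus (splits with frequency strictly
above 0.5, built by clade nesting, polytomies allowed) is provided for
tree samples.

Placement walks each query leaf tip-to-root on a midpoint-rooted copy of
the support tree (midpoint rooting is implemented directly because the
midpoint can fall exactly on an internal node; outgroup rooting is
available). The first enclosing clade with support above the threshold
and at least one labelled reference decides: uniform reference label →
assign; mixed labels → keep walking outward; none found → unassigned with
a reason. Raising the threshold can only shrink the assigned set.

## Evaluation

Alignment columns are classified over their unambiguous, non-gap
residues: *constant* (one state, ≥2 residues), *parsimony-informative*
(≥2 states each in ≥2 sequences), *parsimony-uninformative* (variable but
not informative), *other* (<2 scorable residues). Gaps and ambiguity
codes are missing data — whether gap-containing columns should count as
constant is genuinely convention-dependent, so the convention here is
declared and enforced by a brute-force recount in the tests. Reported
percentages round half away from zero.

Tree quality: group monophyly (a group is monophyletic iff it is one side
of some edge's bipartition, unrooted convention), the fraction of
internal edges supported above threshold, Robinson–Foulds distance to the
truth tree (normalised by 2(n−3)), and long-branch flags (terminal branch
strictly exceeding 5× the median terminal length — "extremely long" has
no standard definition, so the factor is configurable). Alignment
accuracy against the simulated truth uses the sum-of-pairs score
(fraction of true homologous residue pairs reproduced) and the column
score (fraction of truth columns reproduced exactly).

## The standard study and what it shows

The package's standard comparison runs the four strategies on 20 seeded
datasets (32 taxa, flank multiplier 8, 8 masked queries, 2 co-estimation
runs × 10 iterations, 100 bootstrap replicates per strategy — sizes
chosen so the whole study completes in minutes on one core; the same
study is what `scripts/acceptance.py` recomputes). Under these
conditions, co-estimation clearly beats the single-pass baseline on
topology (median normalised RF ≈ 0.12 vs ≈ 0.18), the anchored strategy
has the highest share of parsimony-informative columns (as expected once
the conserved block is constant), and query placement at the 0.94
threshold recovers the true group for essentially every assigned query
(≥ 0.99 mean accuracy in all strategies, with ~86% of queries assigned
under the re-included strategy).

One directional expectation is *not* reproduced in this regime: the 5.8S
re-included strategy comes out slightly behind whole-ITS co-estimation on
median RF (0.16 vs 0.12) and supported-branch fraction (0.61 vs 0.66).
The anchored route's rationale presumes that the conserved 5.8S actively
misleads whole-sequence alignment; this package's profile aligner
computes a global optimum per merge with frequency-based column scoring,
so the conserved block anchors the whole-ITS alignment correctly instead
of corrupting it, while the anchored route pays for guide trees built
without the 5.8S signal. The advantage of excising a conserved core is
therefore aligner-dependent, and with this aligner, at this divergence
depth, it does not materialise. The simulation defaults were fixed by the
similarity calibration above and are not adjusted per result.

## Known limitations

- NJ on JC distances is the only tree estimator; no ML/Bayesian backend.
- The co-estimation loop can cycle between a small set of
  alignment/tree pairs rather than converge; the best-so-far selection
  makes this harmless but means iteration counts are not a convergence
  guarantee.
- Bootstrap frequencies are a proxy for clade support, not posterior
  probabilities; absolute thresholds (0.94) inherit that caveat.
- Region boundaries must be supplied (by the generator or the user);
  there is no de novo ITS region detection.
- Alignment accuracy scores are only defined for strategies whose rows
  degap to the original residues, so the anchored alignment itself (whose
  rows contain the artificial anchor) reports no accuracy.
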