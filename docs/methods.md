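# Methods

This note documents the statistical models, algorithms, parameter defaults
and known limitations of the `cucsyn` pipeline. Notation: r is the meiotic
recombination fraction per meiosis; R is the observed recombinant fraction
among inbred lines; cM are Kosambi centiMorgans unless stated otherwise.

## Segregation screening

Each marker is tested by Pearson goodness-of-fit: F2 genotype counts
(n_A, n_H, n_B) against 1:2:1 (df = 2), RIL counts against 1:1 on the two
homozygote classes (df = 1). Distortion is declared at P < 0.01 with no
multiple-testing correction — the screen is diagnostic, and a Bonferroni
correction at ~400 markers would hide genuinely distorted regions.
Residual RIL heterozygotes are excluded from the 1:1 test; a marker whose
heterozygote fraction exceeds 5% (far above the (1/2)^7 ≈ 0.78% expected
after selfing to F8) is flagged in the log. Distorted markers are reported
but not removed from mapping.

## Two-point recombination fractions

**F2 (codominant).** The 3×3 joint genotype table is a multinomial whose
class probabilities follow from two independent gametes, each recombinant
with probability r; the double-heterozygote class pools the cis and trans
phases, P(H,H) = ((1−r)² + r²)/2. The MLE is found by EM: every class
contributes a known number of recombinant gametes except (H,H), whose
expectation 2r²/((1−r)²+r²) is imputed in the E-step; the M-step divides
expected recombinant gametes by 2n. The iteration starts at r = 0.25, is
clamped to [0, 0.5], and stops at |Δr| < 1e-12 (at most 1,000 iterations).
The EM log-likelihood is nondecreasing (tested), and the fixed point agrees
with a 5,001-point likelihood grid to 1e-3 on random tables (tested). All
pairs are estimated simultaneously with vectorized indicator-matrix
products, so the full 401-marker panel (~80,000 pairs) takes well under a
second.

**Selfed RIL.** Heterozygous calls are treated as missing; among lines
typed A/B at both markers, the observed recombinant fraction R is mapped to
the meiotic scale by the Haldane–Waddington fixed point for selfing series,
r = R/(2 − 2R), treating F8 lines as fully inbed (RIL∞). The bias of this
approximation at F8 is far below the sampling error at n = 80 and is
therefore accepted. R ≥ 0.5 clamps to r = 0.5 with LOD 0.

**LOD.** Both estimators report LOD = [lnL(r̂) − lnL(0.5)]/ln 10. Pairs
with fewer than 10 informative individuals are flagged unreliable and
excluded from grouping (mirroring unplaceable markers in practice).

## Grouping, ordering, map distances

Linkage groups are single-linkage connected components of the graph with an
edge wherever LOD ≥ 4.0, r̂ < 0.5 and the pair is reliable; groups are
numbered by descending size with lexicographic tie-breaks, and singletons
are reported as unplaced. Within a group, the order minimizes the sum of
adjacent recombination fractions (SARF): greedy insertion seeded with the
most distant reliable pair, then window-2/3 permutation passes until no
improvement. The orientation is normalized so the lexicographically smaller
terminal marker comes first (a genetic map has no intrinsic left/right).
Missing within-group estimates are filled by additive Kosambi distance
along the shortest reliable path. Positions accumulate Kosambi distances
d = 25·ln((1+2r)/(1−2r)) from adjacent r̂, starting each group at 0.0 cM;
the inverse is r = 0.5·tanh(d/50).

**Junction splitting.** With ~80,000 pairwise tests per population, about
one spuriously significant pair per map is expected even at LOD 4, and a
single false edge chains two chromosomes into one component. Ordered groups
are therefore split wherever the adjacent interval exceeds 22 cM or the
boundary is bridged by fewer than two significant pairs. The 22 cM value
separates the two populations of junctions: a false LOD ≥ 4 edge at n ≈ 91
cannot show r̂ much below 0.24 (≈ 26 cM), because a smaller r̂ would imply
a likelihood deviation that is astronomically unlikely under independence,
whereas genuine adjacent intervals on maps of this density essentially
never reach 22 cM. Splitting a true chromosome is benign — the fragments
are re-assigned to the same chromosome downstream (the original RIL-based
maps of this system were themselves heavily fragmented, 22 groups for 12
chromosomes) — while an unsplit fusion corrupts the synteny table, so the
rule is deliberately asymmetric.

**Chromosome assignment of groups.** Groups are relegated to source
chromosomes by majority vote among their previously mapped markers; a
fragment with none inherits votes from population-map groups sharing
markers with it, and failing that, the label of the group to which it shows
the strongest residual two-point linkage at the grouping threshold. Groups
that still cannot be assigned are excluded from per-chromosome synteny.

## Heterogeneity test and consensus merging

For each adjacent pair of shared markers the two populations' likelihoods
are compared by G = 2[lnL₁(r̂₁) + lnL₂(r̂₂) − lnL₁(r̂p) − lnL₂(r̂p)], where
the pooled MLE r̂p maximizes the joint likelihood on the meiotic scale
(bounded scalar optimization; the F2 likelihood is the multinomial above
and the RIL likelihood the binomial in R(r) = 2r/(1+2r)). P-values come
from χ²(1); markers in pairs with P < 0.05 are excluded as anchors. The
test's type-I error calibrates to 0.05 at the study's sample sizes
(1,000-replicate simulation, tested). Identical MLEs short-circuit to
G = 0 exactly, which also covers the degenerate all-/no-recombinant case.

Merging is fixed-order: reference (F2) loci keep their order and
positions; anchors retained on both maps define piecewise-linear frame maps
from each second-map group into the reference frame; second-map-only loci
are interpolated between their flanking anchors (terminal-segment slope
beyond the ends, but loci more than 25 cM beyond a terminal anchor are left
unplaced — no reliable projection exists, and unchecked extrapolation can
drag loci across group boundaries). Anchor consensus positions are the
information-weighted mean (weights = population sizes) of the reference
position and the second map's neighbour-interpolated estimate; a final
monotone pass and shift put each group back at 0.0 cM. Anchors whose
second-map order conflicts with the reference are demoted to ordinary loci
via a longest-increasing-subsequence filter. Order preservation of the
reference is by construction and verified on random merges.

Mean marker interval in summaries is (group length)/(locus count) to one
decimal — the convention of the study's published summary table — not
length/(loci − 1).

## Virtual PCR

A primer pair amplifies wherever the forward primer matches one strand and
the reverse primer's reverse complement lies downstream on the same strand,
with product size in [40, 5,000] bp, at most one mismatch per primer and no
mismatch in the 3′-terminal 3 bases (cross-species primers tolerate
internal mismatches but a 3′ mismatch blocks extension). These four
parameters are exposed in `VpcrParams`; the defaults are a deliberately
permissive cross-species setting chosen so that uniqueness remains
meaningful. Coordinates are 1-based inclusive on the forward strand;
repeat-interval overlap tests are half-open internally (BED convention).
The search seeds by pigeonhole — with ≤ m mismatches one of m+1 primer
slices must match exactly, so exact slice occurrences generate candidates
verified in full — and equals an independent position-by-position scan on
random 50 kb instances (tested). Markers are classified unique (exactly one
product genome-wide), multi-copy, no-hit, or repeat-region (unique hit
inside an annotated repeat; excluded from anchoring).

Gene/EST markers are anchored by exact 31-mer seeding and gapless
extension, scored by identity × coverage with thresholds 0.9 and 0.5; ties
between distinct locations return multi-copy. A full local aligner is
deliberately out of scope: conserved coding regions between these genomes
exceed 90% identity, where gapless extension is sufficient.

## Chromosome assignment and blocks

A consensus marker present on the target genome's reference map is assigned
directly. Otherwise its unique scaffold hit is assigned to the chromosome
carried by ≥ 2/3 of the scaffold's reference markers, at their median cM —
the median resists the marker clustering that recombination suppression
produces; scaffolds split across chromosomes without a 2/3 majority are
ambiguous, and scaffolds with no mapped marker leave the query unanchored.

Along each source chromosome the assigned loci (unanchored/ambiguous loci
are transparent) are partitioned into the minimal number of runs such that
each run starts and ends on its own target chromosome and absorbs at most
one interleaved discordant locus (`max_gap_markers = 1`, config-exposed);
ties prefer the longest leftmost run. The partition is computed by dynamic
programming and matches an exhaustive oracle on all short target strings
(tested); a greedy left-to-right scan is *not* equivalent under a gap
budget, which is why the DP is used. Runs with fewer than 2 members are
reported as singletons, not blocks, so genuine two-marker blocks survive.
Block colinearity is Kendall τ between source and target positions, with
|τ| ≥ 0.8 as the (package's own) operational cutoff for colinear/inverted;
fewer than 3 positioned members is undetermined. The correspondence table
and the stacked-segment block views for both genomes are derived from the
same block list, so the partner relation is symmetric by construction.

## The synthetic scenario

The generator instantiates the study system at its published scale:

- **Ancestral genome**: 12 chromosomes with the consensus map's
  per-chromosome lengths (1,029 cM total) and locus counts (401 markers);
  marker genetic positions uniform per chromosome; physical scale
  1,000 bp/cM (sequence content only has to support primer search, so a
  compact genome keeps everything fast); per-marker unique random 20–24 nt
  primer pairs flanking 150–300 bp amplicons, spaced so amplicons never
  overlap.
- **Rearrangement scenario** (the planted truth): derived chromosome 1 =
  II+XII alternating, 2 = V + half XI + half III, 3 = IV+VI side-by-side,
  4 = VII with half VIII nested, 5 = IX+X alternating, 6 = remaining halves
  of III+VIII+XI, 7 = I intact with one inversion of its middle 40%. All
  breakpoints snap outside planted amplicons, so rearrangement never
  destroys a marker (assembly artifacts are not the object of study).
- **Scaffolds**: lognormal sizes (mean 9 kb, σ = 0.5, min 2.5 kb), cut
  points again snapped outside amplicons.
- **Reference resource**: 1,244 dedicated target-genome loci (the size of
  the published mapping resource for this system, which is ~3× denser than
  the query panel) placed uniformly along the derived genome, plus 20% of
  surviving panel markers "already mapped" (≈ 79/401 in the study), which
  anchor directly.
- **Populations**: crossovers between adjacent loci with Haldane
  (no-interference) probabilities; F2 = two independent gametes; RIL =
  seven rounds of selfing from the F1, reproducing the (1/2)^7 residual
  heterozygosity. Each marker is scored in the F2 with probability 0.8 and
  in the RIL with probability 0.5 — chosen once to reproduce the study's
  partial overlap (323 and 335 mapped loci, 79 shared, out of 401) —
  and 2% of calls are set missing.
- **Corruption** (off by default): no-hit (amplicon scrambled in place),
  multi-copy (amplicon copied onto another scaffold's end), mis-anchor
  (amplicon moved to a different chromosome), with truth labels retained
  for robustness tests.

Distances are *estimated* with Kosambi although crossovers are *simulated*
under Haldane, matching the estimation convention of the field; the
resulting map-length bias is expected and only recombination fractions,
order and block recovery are asserted — never absolute map lengths.

What passing the end-to-end test shows — and what it does not. The
simulator emulates marker geometry, meiosis, scaffold structure and the
anchoring chain, so exact recovery of the planted correspondence
demonstrates that the pipeline's inference logic is sound at the study's
sample sizes and marker densities. It does not emulate sequence evolution
between the genomes, segregation distortion, genotyping error beyond
missingness, assembly gaps/chimeras, or tandem repeat families; real-data
hit rates (e.g. the study's ~20% no-hit fraction) therefore have no
synthetic counterpart unless corruption rates are switched on.

## Numerical and degenerate-input choices

EM tolerance 1e-12; pooled-MLE optimization bounded to (1e-9, 0.5−1e-9)
with xatol 1e-12; Kosambi round-trip exact to 1e-10 over r ∈ [0.01, 0.49];
percentages one-decimal round-half-up (a single published truncation-style
figure, 1,123/2,442 printed as 45.9%, is not reproducible under any
rounding rule and is excluded from checks); empty genotype columns raise
"empty marker"; LOD-threshold 99 degenerates cleanly to all-singleton maps
and an empty block list; deterministic tie-breaks throughout (lexicographic
marker ids, descending group sizes), so outputs are a pure function of
(inputs, config, seed), and all stage seeds derive from one root seed via
`SeedSequence`.

## Problem sizes used by the test suite

The acceptance checks run the full pipeline at study scale (401 markers,
91 F2 + 80 RIL individuals, ~1.2 Mb of scaffold sequence), 100-instance
oracle comparisons for the EM estimator and the virtual-PCR search,
exhaustive segmentation strings to length 8, 1,000 null replicates for the
heterogeneity test's type-I error, and 5,000 simulated lines for the F8
residual-heterozygosity check; unit tests use smaller versions of the same
constructions.

## Known limitations

- Two-point ordering only; no multipoint likelihood and no interference
  model (Kosambi enters only through the distance transform).
- The merge is an anchor-interpolation scheme, not a joint multipoint
  re-estimate: it is transparent and order-preserving by construction, but
  its anchor positions are weighted compromises, not MLEs.
- Dominant markers (RAPD/AFLP) are out of scope for merging and synteny,
  as in the study.
- Sequence anchoring is gapless; diverged or spliced queries need a real
  aligner.
- The ≥ 2/3 scaffold majority and |τ| ≥ 0.8 cutoffs are pragmatic
  operational choices, config-exposed but not claimed to be optimal.
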