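# Methods

This note documents the models implemented in `u6phylo`, the conventions
and parameter defaults, what the synthetic-data generators do and do not
emulate, and the design choices made where the methodology was genuinely
open.

## Variant model and site policy

Variants are rCRS-relative events: transitions (bare position),
transversions (position + base), insertions (position + `.index` + base),
deletions (`d`), and back-mutations (`!`, a reversion to the ancestral
state). Heteroplasmic records (IUPAC ambiguity codes such as `146Y`)
parse to flagged variants. Coordinates are 1-based, intervals closed;
HVS-I is taken as 16024–16365, the conventional bound for
control-region surveys.

Two site classes are excluded from distances and classification under the
default policy, switchable per call: the 16519 hotspot, and length
variation of the homopolymeric C-tracts around positions 310 and 16189
(tract insertions and 16183C-type transversions). These sites mutate so
fast that they carry no stable phylogenetic signal; whether a given
published survey included them is rarely stated, so the default here is
exclusion and the flag is explicit.

Haplotype distance is the size of the symmetric difference of the two
variant sets, restricted to the intersection of the covered ranges. On a
common range this is a metric; across ranges it is the best available
comparison and is what the π machinery uses.

## The shipped U6 tree

`u6phylo/data/u6_tree.tsv` encodes a 71-node U6 haplogroup tree. The
defining-mutation lists of the named subclades (e.g. U6a7a1a: 2672,
11929; U6b1: 9738, 15431; U6a3c: 146, 291.1A, 960d, 1809, 5554A, 6182,
11272, 15380) follow the published refinement of the U6 phylogeny. The
file is nevertheless a *reconstruction*: for internal nodes whose motifs
are not established in that refinement, the tree carries package-chosen
diagnostics — HVS-I positions implied by the eight-way sorting (U6a1a:
16189; U6a1b: 16235; U6d1: 16261), PhyloTree-style motifs where they are
well known (U6: 3348, 16172; U6a: 7805, 14179), and otherwise placeholder
coding transitions chosen not to collide with any established position.
An intermediate `U6b'd` node (16219, 16311) joins the U6b and U6d sister
clades; U6c hangs directly from the root, matching the fact that its
basal HVS-I haplotype lacks 16219. All classification validation runs on
haplotypes simulated down this same tree, so what the tests establish is
the correctness of the scoring machinery, not the per-node fidelity of
the reconstruction to any external tree file.

## Classification

`classify_profile` scores every root-to-node path: a defining variant is
*scoreable* if it lies inside the profile's covered range (and passes the
site policy); the path score is matched − missing over scoreable motifs,
with unit weights. Unscoreable motifs count neither way — this is what
makes HVS-I fragments classifiable at all. Ties break to the deeper
node, then the lexicographically smaller name; the tie-break is
deliberate and documented rather than principled, since no scoring rule
is canonical for motif-based calling. A consequence worth knowing: for a
partial sequence, a child clade whose whole motif is unscoreable ties its
parent and wins on depth, so the call names the deepest clade *consistent
with* the observed range rather than the shallowest proven one. The
`matched`/`missing` counts in the result always let a user recover the
conservative reading.

Back-mutation motifs count as matched only when the profile carries the
explicit `!` token. Data sets that do not annotate reversions will score
such motifs as a missing ancestral variant; this is a documented
limitation of motif matching without full sequence context.

`classify_hvr1` is a fixed decision tree over the diagnostic HVS-I
positions, evaluated in priority order (U6c → U6d → U6b1 → U6b → the U6a
splits), which makes the eight categories exhaustive and mutually
exclusive by construction. The 16311 ambiguity between U6b and U6d is
resolved in favour of U6d only when a U6d subgroup marker (16261 or
16174) co-occurs; bare 16311 goes to U6b. The basal-U6 precondition is
the presence of 16172 and 16219; note that basal U6c HVS-I haplotypes
can lack 16219, so surveys that type U6c from 16169+16189 alone should
relax the precondition upstream. U6b3 haplotypes carry 16278 (a U6a
category marker) but their 16311 routes them to U6b first, which is the
only self-consistent reading of the published sorting.

## Rho dating and the Saillard error

For a rooted mutation-count tree, ρ is the multiplicity-weighted mean
number of mutations from each sampled lineage to the focal node, and

σ² = (1/N²) · Σ_branches lᵢ · nᵢ²

with lᵢ the branch's mutation count, nᵢ its sampled descendants, N the
total sample. Ages are linear: age = ρ × 3,624 years per mutation
(default clock for the complete molecule), and the standard error scales
identically. No purifying-selection correction is applied — published
ages computed with a corrected calculator will differ from linear ages,
increasingly so for older clades; the correction is out of scope here
and the clock is a single tunable parameter (`ClockModel`).

Mutation counting is event-based: transitions, transversions, indels and
reversions each count one, matching the clock's event semantics. The
±1.96σ interval is a normal approximation; its coverage is validated by
simulation (star genealogies, 50 tips, 10 ky true age: nominal 95%
within ±3 points at 2,000 replicates).

## Pedigree mutation rate

The estimator is k/T for k germline substitutions in T transmissions.
Two exact 95% intervals are always computed: Clopper–Pearson (binomial
inversion via beta quantiles) and the exact Poisson interval (gamma
quantiles on the event count); k = 0 yields a one-sided upper bound. The
two are reported side by side because published pedigree intervals are
frequently not reproducible by any single standard method — for the
classic 1-in-90 case both exact methods put the lower bound near 0.0003,
well below some printed intervals; the package reports its own methods
and does not chase agreement.

Unit conversion: rate/(L·G)·10⁶ substitutions per site per million
years, with L = 16,569 bp and G ∈ {20, 25, 30} years by convention, and
an explicit halving step for the male transmission bias (mutations
arising in sons are never transmitted). Reporting precision follows the
field: rates to 3–4 decimals, ages to the year internally and to the
nearest thousand in narrative output.

## Wave-of-advance arithmetic

Fisher's reaction–diffusion relation r = 2√(gm) is used in both
directions: frontier speed from a route length and an elapsed time
between clade ages, and migration rate m = r²/(4g) from a speed and a
growth rate (default Paleolithic g = 0.007/yr). `wave_chain` carries
*both* the unrounded values and the printed-precision ones (speed to two
decimals, m to one decimal, years/km to the nearest thousand): published
chains feed the reported two-decimal speed into the inversion, and with
r = 5000 km / 9000 yr that distinction is visible (m = 11.2 from the
reported 0.56, 11.0 unrounded). The unrounded speed feeds the radius
computation. m is dimensionally km²/yr in Fisher's equation; the km/yr
convention of frontier-speed chains is preserved numerically and flagged
here. The elapsed time between clade ages is itself taken at the
precision the chain states it (35.3 − 26.2 ky quoted as 9,000 years).

## Frequency tables, π, permutation test, PCA

The survey table layout is one row per population: sample size, U6
carrier count, and counts over the eight categories. The shipped
worldwide survey is stored in its printed form (percentages) and
converted to integer counts by rounding the carrier count against N and
apportioning category counts by largest remainder, then re-validating
the row sums; this reconstruction is exact for the worked rows (e.g.
Brazil: 8 of 1,400 = 0.57%, split 1 and 7 = 12.5/87.5) and within one
count elsewhere.

π is the mean pairwise haplotype distance over all unordered pairs; its
standard error is the square root of Tajima's (1983) variance
V = (n+1)/(3(n−1))·π + 2(n²+n+3)/(9n(n−1))·π², the form standard
diversity software implements for "mean number of pairwise differences".
Group comparison uses a two-sided label-shuffling permutation test on
|π_A − π_B| with an add-one p estimate, seeded and reproducible; the
procedure behind published diversity p-values is typically unstated, so
no exact agreement is claimed. Gradients are plain Pearson correlations
with t-test p-values. PCA standardises category frequencies to the
correlation scale, drops constant columns with a warning, and fixes each
component's sign so its largest-magnitude loading is positive; published
ordinations are reproduced qualitatively (cluster memberships), not in
coordinates, since the original software and scaling are unstated.

## Synthetic data: what it does and does not emulate

* **Star genealogies**: tip branch lengths Poisson with mean
  true_age/clock — exactly the event-count process the linear clock
  assumes. No topology beyond the star, no rate heterogeneity, no
  purifying selection: passing calibration tests shows the estimator is
  correct *under its own model*, not that real trees are star-like.
* **Haplotypes**: each sample carries the union of defining variants on
  its clade's root path; a reversion motif removes the reverted ancestral
  variant and leaves the explicit `!` token. Optional noise adds private
  transitions at uniform positions (HVS-I weighted at 10% by default,
  roughly the region's share of observable variation in mixed surveys).
  No recurrent mutation at motif positions unless noise happens to be
  enabled, and no missing data: 100% classifier recovery on clean data is
  therefore a correctness check of the scorer, not an accuracy claim for
  real HVS-I surveys, where motif-based calling is known to be
  misleading in edge cases.
* **Pedigrees**: k ~ Binomial(T, rate) with uniform event placement —
  the sampling model of the rate estimator, without heteroplasmy
  dynamics or somatic/germline ambiguity.
* **Survey rows**: carrier counts Binomial(N, freq), category counts
  multinomial — the sampling model of the table statistics.

All generators are pure functions of (config, seed) using NumPy's
`default_rng`; identical seeds give bitwise-identical outputs.

## Numerical conventions and degenerate inputs

Rounding happens at the reporting layer only, except where a published
derivation itself consumed a rounded figure (the wave chain, above).
Zero-length trees give ρ = σ = 0; a node with no sampled descendants is
an error. Empty range intersections give empty profiles, not errors; a
profile whose range overlaps no diagnostic position classifies to the
root with a warning flag. Zero-carrier survey rows are valid but their
composition is flagged undefined. Permutation tests below 100 shuffles
warn; constant vectors make correlations NaN with a warning rather than
raising.

## Problem sizes used in validation

The test suite validates the dating estimators against brute-force
enumeration on 1,000 random trees of up to 12 tips, interval calibration
on 2,000 simulated star genealogies of 50 tips, classifier recovery on
1,000 haplotypes over 20 named clades, and the HVS-I partition over all
2⁸ diagnostic-position combinations. These sizes give Monte Carlo noise
comfortably inside the stated tolerances while keeping the default suite
fast.

## Known limitations

* Linear clock only; no purifying-selection correction, no Bayesian or
  maximum-likelihood dating, no skyline inference.
* No de-novo network/tree construction; the shipped tree is an encoded
  reconstruction, and unprinted internal motifs are package choices.
* No sequence alignment; FASTA input must be pre-aligned with positions
  deducible by fixed offset.
* Real-data quantities that require the full complete-genome and HVS-I
  datasets (clade ages of the published tables, regional π values and
  their p-values) are out of scope; the estimators are validated on
  synthetic stand-ins instead.
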