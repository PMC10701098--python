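# Methods

This note documents the models, estimators, and numerical choices behind
`phylofrag`, and what the synthetic-data calibrations do and do not show
about real data.

## Coalescent simulator

Gene trees are generated backward in time on a rooted, dated, binary
species tree.  Within a branch carrying `k` lineages and diploid effective
size `Ne`, coalescences occur at total rate `k(k−1)/2` per `2Ne`
generations; at each speciation node the children's surviving lineages
merge into the parent branch; above the root the process runs to a single
lineage under the root-branch `Ne`.  Introgression is a pulse: at the
stated time, every lineage currently in the recipient branch jumps to the
donor branch independently with probability γ.  This instantaneous,
per-lineage admixture model is the one under which D and f4-ratio theory is
derived, which makes the simulator a fair null and alternative generator
for those tests.  There is no recombination within a locus and loci are
unlinked, matching the per-window independence assumption of the window
pipeline.  All internal times are generations; years appear only at
configuration I/O through the generation time (default 3.8 yr).  The
default mutation rate is 0.86×10⁻⁸ per site per generation, a typical
felid pedigree-scaled value.

Sequence evolution is i.i.d. across sites, JC69 by default (closed-form
per-branch substitution probability) with an HKY option (matrix
exponential of the rate matrix, normalized to one expected substitution
per unit branch length).  Genome assembly concatenates loci, injects
per-sample missing data as geometric-length runs of `N` (mean 500 bp by
default — long runs mimic mapping dropouts better than i.i.d. missing
sites) and a shared repeat-like mask track built the same way.  The mask is
*returned*, not applied, so the masking step of the window pipeline can be
exercised; run-length overshoot means the realized masked fraction slightly
exceeds the target (by at most about one mean run length per draw).

The packaged example model is an eight-species cat radiation plus outgroup
whose node ages follow published whole-genome estimates for the ocelot
lineage (root 4.45 Ma, with the subsequent splits at 4.04, 3.83, 3.72,
2.39, 1.62 Ma; the one node not reported, joining the two youngest sister
pairs, is set to 1.9 Ma) and whose two pulses (γ = 0.33, 0.32) emulate the
strongest inferred exchanges in that system.  Per-branch `Ne` values are
illustrative only — the source system's branch-specific sizes are unknown —
so the example reproduces qualitative discordance levels, not quantitative
ones.

## Window pipeline

Coordinates are 0-based half-open everywhere (BED convention).  Gaps are
treated as `N` on ingestion since consensus genomes are positionally
homologous by construction and gap semantics are undefined.  Missing
fractions are computed after masking, matching the mask-then-filter order
of the standard workflow; the 60% missing-data filter uses a strict
inequality (a sample at exactly 0.60 keeps the window).  Trailing
sub-window remainders are dropped rather than padded so all windows are
directly comparable.  Parsimony-informative sites are columns with at
least two states each carried by at least two samples, evaluated on
non-`N` residues.

## Distances and trees

Window distances are uncorrected p-distances with pairwise deletion; the
counts (mismatches, comparable sites) are carried alongside the derived
fractions so that the genome-wide matrix can be formed as a ratio of sums.
That mode equals the p-distance of the concatenated alignment exactly — an
identity the tests assert bit-for-bit — and is the default; the literal
sum-of-per-window-distances mode is kept behind a flag for fidelity to
summary pipelines that add fractional matrices.  Pairs with zero
comparable sites abort with a named error; silent imputation would bias
trees.

Neighbor joining uses the Saitou–Nei Q-criterion with a deterministic
tie-break (lexicographically smallest label pair, tracked through merges by
the smallest contained leaf).  Negative branch-length estimates are
retained with a warning (clamping is an option) because the additivity
identities used as oracles require them.  Bootstrap support for the
genome tree resamples the window matrix list with replacement and reports
the percentage of replicates containing each bipartition of the full-data
tree.  Outgroup rooting places the root on the outgroup's pendant edge
with the pendant length kept on the outgroup side, preserving all
leaf-to-leaf path lengths.

## Consensus and discordance

Clades are counted as rooted clusters after rooting every tree on the
fixed study outgroup (the "monophyletic group" convention of SumTrees-style
summarization), with per-clade denominators restricted to trees containing
all of the clade's members so pruned tree sets stay meaningful.  The
greedy consensus accepts clades in descending count order whenever
compatible with those already accepted — no frequency cutoff — with
deterministic ties (smaller clade first, then lexicographic).  It
therefore refines majority rule, which the property tests check on random
tree sets.

Node conflict decomposes each consensus clade's support into concordant
trees, the most frequent conflicting clade (a tree's smallest cluster
properly overlapping the target, ties lexicographic), and the remainder.
The LSI of a taxon is the mean over pairs of other taxa of the maximum
rooted-triplet resolution frequency (range [1/3, 1]); the "difference"
variant (max minus second) is available behind a flag.  Trees should be
rooted on the outgroup and the outgroup pruned before computing LSI —
triplets containing the outgroup are resolved by the rooting itself and
would only dilute the index.  BAF removes the focal taxon from each local
tree and matches the induced attachment bipartition *exactly* against the
consensus-minus-taxon edges; near-misses are counted as unmapped rather
than assigned to a nearest edge, which would require an arbitrary tree
metric.  The split-frequency table (random 20% subsample, 20% inclusion
threshold, median edge weights) is the analytic content of a consensus
network; drawing the network is out of scope.

The exhaustive quartet species tree enumerates all unrooted binary
topologies (feasible to 10 taxa), scores each by the number of induced
quartets shared with the tree set, and reports ties explicitly.  Under the
MSC the most frequent quartet resolution is the species quartet, so the
maximizer is a consistent species-tree estimate.

## Introgression statistics

Site patterns are computed from derived-allele frequencies with the
outgroup's major allele as ancestral: per biallelic site,
ABBA = (1−p₁)p₂p₃(1−p₄), BABA = p₁(1−p₂)p₃(1−p₄), BBAA = p₁p₂(1−p₃)(1−p₄).
Frequencies come from however many samples a taxon has (a single
pseudohaploid gives frequencies in {0,1}), and sites are cut into
contiguous jackknife blocks of near-equal usable-site counts (default 20)
— equal information per block rather than equal bp.  Standard errors use
the weighted delete-one block jackknife of Busing et al. (1999); an SE of
zero is flagged and Z/p reported as undefined, never as infinity.

The f4-ratio splits the donor's samples between the numerator and
denominator quartets; with a single pseudohaploid donor sample the
estimator is unavailable and flagged.  A property of this classical
estimator worth stating: its expectation is γ multiplied by the fraction
of the donor's drift shared since the pulse, so it recovers γ itself only
when the pulse is recent relative to the donor's branch.  The calibration
studies therefore place the pulse near the present (200 generations), where
the expectation is γ and the simulations recover it to well within ±0.05.

f-branch aggregates trio-wise f4-ratios onto species-tree branches as the
minimum over a branch's descendant leaves of the median over valid
third-taxon configurations, with negative values clamped to zero and
donor-inside-branch cells undefined; the intermediate median table is
emitted for audit, since aggregation order is the easiest place for such a
statistic to go wrong silently.

The branch-length mixture models a triplet's internal branch lengths as
(1−π₂)·Exp(λ) + π₂·(θ + Exp(λ)): ILS-only discordance produces exponential
internal branches from zero, whereas discordance locked in by gene flow
adds an offset θ > 0.  Sharing λ between components keeps the model
identifiable with three parameters (π₂, λ, θ).  Fitting alternates EM
updates of (π₂, λ) in closed form with a bounded one-dimensional profile
search for θ, accepted only when it improves the observed-data
log-likelihood, so the likelihood trace is monotone; three initializations
(median, upper quartile, one random) guard against local optima.  Model
choice is by BIC against the single-exponential null, with an
"introgression" verdict requiring ΔBIC > 10 (configurable).  On pure null
draws θ → 0 makes the two components coincide and π₂ unidentifiable, which
is why π₂ is only reported under an introgression verdict.

## Diversity and demography

Percentage pairwise distances are labeled π within species and Dxy between
species.  Windowed heterozygosity (default 200 kb) reports per-window
het/callable with genome mean and interquartile range; zero-callable
windows are flagged and excluded from summaries.

ROH segmentation is a two-state HMM over windowed het counts with
Binomial(callable, θ_state) emissions: θ_ROH is fixed at the prior 2×10⁻⁴
per bp while the background rate is re-estimated by EM from the
forward–backward posteriors; the per-window switch probability defaults to
0.01 and the posterior cutoff for calling a window ROH to 0.9.
Heterozygosity is then re-estimated inside and outside the called
segments.  This count-based HMM is deliberately simpler than
genotype-likelihood ROH callers: it shares their contract (segments,
genome fraction, het in/out, posterior track) but starts from called
genotypes, so depth- and quality-driven uncertainty is out of scope.  The
model refuses to run when the estimated background rate does not exceed
the ROH prior, since the two states are then not separable.

The rCCR series is 2λ_cross/(λ₁+λ₂) per time segment on a shared
segmentation; the population split time is the first crossing of half the
series maximum scanning from the most recent segment toward the past,
linearly interpolated between segment midpoints (the simplest defensible
rule; more elaborate smoothing would suggest precision the piecewise input
does not have).  The estimate is invariant to rescaling all rates and
stable under refinement of the discretization to within the interpolation
resolution.

## Calibration studies and their limits

`phylofrag.studies` holds the simulation experiments shared by the test
suite and `scripts/acceptance.py`, so the study conditions live in one
place.  Default problem sizes — 10,000 loci for triplet calibration, 100
replicates of 1,000 loci for consensus recovery, 100 replicates of 2×10⁵
sites for D/f4 calibration and 1.5×10⁵ for f-branch, 20 replicates of
n = 2,000 for the mixture EM, 3 Mb genomes for ROH — run in minutes on one
CPU while leaving every target comfortably resolvable; each function
scales with its arguments when more precision is wanted.

What passing these calibrations shows: the simulator matches coalescent
theory (and an independent simulator, msprime, in the tests), the
estimators are unbiased where theory says they should be, exact identities
hold bit-for-bit, and detection statistics have their nominal error rates
under the model that generated the data.  What it does not show: robustness
to reference bias, mapping error, depth-dependent genotyping error,
intra-window recombination, or non-pulse (continuous) gene flow — none of
which the generator emulates.  Real-data magnitudes (heterozygosity
levels, ROH content, split dates) depend on those factors and on
branch-specific `Ne` values that the example configuration only
illustrates.
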