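# Methods

## Model

The unit of analysis is the per-sequence *distance-to-nearest*: within each
group of sequences sharing a V gene, J gene and junction length, the
minimum length-normalized Hamming distance from a sequence to any other
group member with a different junction string. Sequences with clonal
relatives populate a low-distance mode (somatic hypermutation plus
residual sequencing error), sequences without relatives a high-distance
mode (distances between unrelated junctions). The pooled distances x are
modeled as

    f(x) = λ₁ f₁(x | φ₁) + λ₂ f₂(x | φ₂),   λ₁ + λ₂ = 1,

with each fᵢ Gaussian (μ, σ) or Gamma (k, θ) and component 1 defined as
the one with the smaller mean (relabeled after fitting if needed). The
Gamma family is the usual winner on repertoire-like data because the
low-distance mode is positively skewed; the Gaussian remains available for
symmetric modes, and the best family pair is chosen by maximum fitted
log-likelihood with ties going to Gamma/Gamma, then to fewer Gaussian
components.

True/false positive/negative rates for "has a clonal relative" at a
threshold t are areas under the weighted component densities over the
observed range (t₁, t₂) = (min x, max x), using closed-form CDFs (Gaussian
error function; regularized lower incomplete gamma). Sensitivity
TP/(TP+FN) and specificity TN/(TN+FP) follow, and the reported threshold
maximizes w·SEN + (1−w)·SPC (default w = 0.5) over a uniform grid strictly
inside (t₁, t₂). Clonal partitions are connected components of the graph
with edges where the junction distance is below t, computed per
V/J/length group — identical to cutting a single-linkage dendrogram at t
without building it.

## Fitting procedure

1. **Initialization.** A standard two-component Gaussian mixture
   (k-means-started EM, seeded, `sklearn.mixture.GaussianMixture`)
   estimates λ, μᵢ, σᵢ. Where a Gamma component is requested, (μ, σ) is
   moment-translated to k = μ²/σ², θ = σ²/μ.
2. **EM refinement.** E-step: posterior responsibilities via log-sum-exp.
   M-step: λ from the mean responsibility; Gaussian parameters by weighted
   closed form; Gamma parameters by weighted maximum likelihood — θ =
   x̄_w/k with k the unique root of log k − ψ(k) = log x̄_w − (log x)̄_w,
   solved by bracketed Brent iteration (the left side is strictly
   decreasing in k). This weighted-ML M-step keeps the likelihood
   non-decreasing; fitting components separately to hard-assigned subsets
   (available as `method="hard"`) biases parameters near the component
   overlap and is provided only for comparison.

Numerical choices: relative log-likelihood tolerance 1e-6, at most 1000
iterations; a λ floor of 1e-3 per component prevents collapse onto a
single component (a collapsed fit is uninformative for thresholding and
surfaces as a degenerate/failed fit rather than a silent answer); distances
are strictly positive by construction but are additionally clipped to
≥ 1e-9 before Gamma fitting; the Gamma shape is capped at 1e10 (the
near-Gaussian limit) when the weighted sample is nearly degenerate. At
least 20 distances with two distinct values are required for any fit.

## Distance and clustering conventions

* Gene calls are matched at **gene level** by default (allele suffixes
  `*NN` stripped; allele-level matching by option) because allele calls
  are unreliable and allele differences should not split clones.
  Multi-assigned calls are deduplicated, sorted and used whole as the
  group key, so ambiguous calls co-cluster only when the ambiguity is
  identical; a first-call policy is not applied.
* `N` mismatches every base **and another `N`** — ambiguity never deflates
  a distance. String identity overrides this rule where identity matters:
  exact duplicate junctions are never each other's nearest neighbor, and
  they always co-cluster for any t > 0.
* Nearest-neighbor search runs **within V/J/length groups** by default:
  that is the distribution the downstream clustering actually thresholds.
  A global scope (equal lengths only, V/J ignored) is available.
* The dendrogram cut is **strict** (merge iff distance < t), matching the
  open interval of the threshold search and making the all-singleton
  partition reachable; `link="le"` gives the closed cut.
* The threshold grid has 1,000 uniform interior points; junction distances
  are multiples of 1/length, so this over-resolves any realistic dataset.
  Objective ties resolve to the smallest t, favoring specificity.
* Pairwise distances are computed exactly (O(m²) per group, chunked to
  bound memory); groups are small relative to the repertoire, and no
  approximate nearest-neighbor structure is used.

## Synthetic repertoires

The simulator emulates repertoires with known clonal structure: each clone
draws an independent uniform-random germline junction (length from a
configurable distribution over in-frame lengths 33–57, V/J from small IGHV
and IGHJ pools), and members arise by re-introducing substitutions along
lineage branches — each branch substitutes Binomial(length, rate) distinct
positions, uniformly to one of the three alternative bases, so the
expected parent–child distance is rate × length. Lineages grow as random
recursive trees (each member descends from a uniformly chosen earlier
sequence) or stars; a configurable fraction of clones are singletons.
Defaults (200 clones, geometric multi-member clone sizes with mean 3,
per-branch rate 0.02, 30% singletons) produce a clearly bimodal
distance-to-nearest distribution at a few hundred sequences.

What the simulator does **not** reproduce: V(D)J recombination structure
(germlines are unrelated random sequences, so inter-clone distances
concentrate near 0.75 — farther right than in real repertoires, where
junctions share recombination biases), somatic hypermutation hot spots,
indels, and sequencing-error/UMI structure (errors act simply as extra
mutation rate). Passing validation on these data therefore demonstrates
the correctness of the estimator and the pipeline, not its performance on
repertoires with closely spaced modes.

A consequence of discrete mutation counts worth knowing: with low
per-branch rates and small clones, some clones consist entirely of
identical sequences. Their members count as having clonal relatives, but
their distance-to-nearest is measured to an *unrelated* sequence, placing
them under the high mode; the actual sensitivity curve then saturates
below 1 while the estimated curve reaches 1. The validation configuration
(`well_separated_config`: geometric mean clone size 5, rate 0.03, lengths
45–57) realizes the regime the estimator is built for — intra-clone
nearest distances concentrated below 0.05, inter-clone near 0.75, with
all-identical clones rare. Under it, squared Pearson correlations between
estimated and actual sensitivity/specificity curves are ≥ 0.9 (measured in
the acceptance suite), and similarly for the spike-in specificity design.

## Evaluation designs

*Actual* performance uses per-sequence semantics matching the estimator: a
sequence is condition-positive when its true clone has ≥ 2 members and
predicted-positive when its distance-to-nearest is below t; an all-pairs
definition was considered and rejected as mismatched to what the mixture
areas estimate. R² is the squared Pearson correlation between actual and
estimated values over the threshold grid (50 points by default), skipping
grid points where either side is undefined.

The spike-in design simulates one base individual and n−1 foreign
individuals from independent seeds, adds one randomly drawn sequence per
foreign individual to the base, refits the mixture and asks how often
spikes remain singleton clones (clones cannot span individuals, so any
merge is a false positive). Each of the default 10 replicates resamples
the spikes; the replicate mean actual and estimated specificity curves are
compared by R². A spike's singleton status at every t is derived from its
minimum distance to any other member of its V/J/length group (with exact
copies at distance 0), which is exactly its single-linkage singleton
condition; the equivalence against full repartitioning is verified in the
tests. Spikes landing in a group with no other member are unchallenged and
counted, with their fraction reported in the diagnostics.

## Problem sizes and defaults

The shipped validation runs use repertoires of roughly 500–950 sequences
(200–230 clones), 20-individual spike-in designs with 10 replicates, and
50-point evaluation grids; mixture recovery is checked on 20 seeded draws
of n = 10,000 from a known Gamma/Gamma mixture. All stochastic steps take
explicit seeds, identical seeds reproduce simulator output byte for byte
and thresholds bit for bit, and every CLI run writes a manifest with its
resolved parameters.

## Known limitations

* Two components only; repertoires whose distance-to-nearest is unimodal
  or multi-modal (e.g. very shallow sampling, mixed loci) violate the
  model, and a visual check of the fit is recommended — the report carries
  everything needed to redraw it (`clonedist threshold --figure`).
* The estimated sensitivity saturates once the low component's CDF
  reaches 1, while true intra-clonal distance tails can be heavier; the
  estimate is best read as a lower bound near the threshold.
* Gene-level call matching assumes IMGT-style `GENE*ALLELE` strings.
* Heavy-chain only: paired heavy/light grouping is out of scope.
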