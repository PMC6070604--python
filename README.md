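# clonedist

Model-based distance-threshold inference for partitioning B cell receptor
(BCR) repertoires into clones.

## The problem

B cells descended from one naive ancestor (a *clone*) diversify by somatic
hypermutation, so clonal relatives in AIRR-seq data have similar — not
identical — junction sequences. The standard partitioning recipe first
groups sequences by V gene, J gene and junction length, then clusters each
group by single-linkage on the length-normalized Hamming distance of the
junction and cuts the dendrogram at a fixed distance threshold. The hard
part is choosing that threshold, and knowing how good the resulting clones
are.

`clonedist` infers the threshold from the *distance-to-nearest*
distribution: for each sequence, the minimum distance to any other
non-identical sequence in its V/J/length group. With both clonally related
sequences and singletons present this distribution is bimodal, and is
modeled as a two-component mixture

```
f(x) = λ₁ f₁(x | φ₁) + λ₂ f₂(x | φ₂),    λ₁ + λ₂ = 1,
```

where each component is Gaussian (μ, σ) or Gamma (shape k, scale θ);
component 1 is the low-distance (clonally related) mode. The fit is
initialized from a standard two-Gaussian mixture (moment-translated to
Gamma where needed) and refined by EM with responsibility-weighted
maximum-likelihood M-steps; the family pair is chosen by likelihood, and a
Gamma/Gamma mixture typically wins on repertoire-like data.

Classification rates at a candidate threshold t within the observed
distance range (t₁, t₂) are areas under the weighted component densities,

```
TP = λ₁[F₁(t) − F₁(t₁)]    FN = λ₁[F₁(t₂) − F₁(t)]
FP = λ₂[F₂(t) − F₂(t₁)]    TN = λ₂[F₂(t₂) − F₂(t)]
```

giving study-specific estimates SEN = TP/(TP+FN) and SPC = TN/(TN+FP). The
reported threshold maximizes (SEN(t) + SPC(t))/2 over t₁ < t < t₂ (an
exposed weight generalizes this to w·SEN + (1−w)·SPC). Clones are then the
connected components of the sub-threshold distance graph within each
V/J/length group — exactly a single-linkage dendrogram cut, in O(m²) per
group and O(n) for the threshold search itself.

Because the truth is never known for real data, the package also ships the
validation machinery: a seeded simulator of clonally structured
repertoires (per-lineage germlines, substitutions re-introduced along
lineage branches, configurable singleton fraction), ground-truth
actual-vs-estimated performance curves with their R² agreement, and the
spike-in specificity design (single sequences from foreign individuals
must come out as singleton clones).

## Worked example

```
clonedist simulate --seed 7 --output rep.tsv --truth truth.tsv
# simulated 529 sequences in 200 clones

clonedist dist --input rep.tsv --output dist.tsv
clonedist threshold --input dist.tsv --model auto --seed 1 --report report.json
# threshold=0.276931 SEN=1.0000 SPC=1.0000

clonedist clones --input rep.tsv --threshold auto --seed 1 --output clones.tsv
# threshold=0.276931 n_clones=200 n_sequences=529
```

`report.json` records the fitted families, λ and φ for both components,
the log-likelihood, (t₁, t₂) and the SEN/SPC estimates at the chosen
threshold; `clones.tsv` is the input table with a `clone_id` column
appended. The numbers above say: the low mode (clonal relatives, fitted
Gamma mean ≈ 0.038) and high mode (singletons, fitted mean ≈ 0.73) are so
well separated that the optimizer puts the cut at 0.28 with essentially
perfect estimated sensitivity and specificity — and the 200 inferred
clones match the simulation's truth. On real data the modes are closer and the reported
SEN/SPC quantify the unavoidable trade-off.

Inputs are AIRR Rearrangement TSVs (`sequence_id`, `v_call`, `j_call`,
`junction`) or the uppercase Change-O dialect, auto-detected. Gene calls
are matched at gene level by default (allele suffixes ignored;
`--v-level allele` to change).

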