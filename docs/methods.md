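# Methods

`cas9repair` analyses the mutagenic outcomes of Cas9-generated
double-strand breaks (DSBs) measured at synthetic target constructs across
a panel of DNA-repair-gene knockout cell lines. This note describes the
models and procedures the package implements, the conventions it fixes
where several were possible, what the synthetic screen generator does and
does not emulate, and the numerical choices that matter.

## Coordinates and the indel calculus

A target is a construct sequence carrying a 20bp protospacer and an NGG
PAM on the given strand. SpCas9 cuts bluntly between the 4th and 3rd base
upstream of the PAM, so the 0-based cut index is `c = pam_start - 3` and
the cut lies between `sequence[c-1]` (the PAM-distal flank) and
`sequence[c]` (the PAM-proximal flank). Strand-flipped (CCN) targets are
out of scope; libraries are assumed pre-oriented.

An outcome is an edit `(a, b, insert)`: the half-open interval `[a, b)` is
replaced by `insert`. Many coordinate representations describe the same
mutated molecule — a deletion between two copies of a repeated sequence
can be written at every offset of the repeat, and likewise for insertions
next to runs. `canonicalize` first removes insert bases that merely
re-create deleted reference bases, then shifts the remaining edit
maximally 5′ (minimal `a`). The 5′ direction is an arbitrary but fixed
choice; microhomology length and all category assignments are invariant
to it. Canonicalization is idempotent and, by a property-checked
invariant, every equivalent same-size deletion window maps to the same
representative.

**Microhomology.** For a canonical deletion `[a, b)`, `mh_length` is the
largest `k` with `sequence[a:a+k] == sequence[b:b+k]`. This equals exactly
(number of distinct same-size deletion windows producing the identical
molecule) − 1, which is the operational meaning of "deletion between
microhomologies". Inside a homopolymer run longer than twice the deletion
this raw value can exceed the deletion size; classified outcomes
therefore carry `min(mh_length, deletion_size)` so that the
inter-homology distance `d = deletion_size − mh_len` is never negative.

**Directionality.** For a pure deletion, `L = max(0, c − a)` and
`R = max(0, b − c)` count deleted bases PAM-distal and PAM-proximal of
the cut; the directionality statistic is `max(L, R)/(L + R)`. Any 1bp
deletion — and any deletion entirely on one side of the cut — has
directionality 1 by definition. It is evaluated on the canonical form.

## The ten outcome categories

Pure deletions: 1bp (`D1`), 2bp (`D2`), 3–9bp and 10bp+ each split by
microhomology (`D3_9_MH`/`D3_9`, `D10P_MH`/`D10P`). 1–2bp insertions
whose equivalence class includes the cut position are compared with the
same-length sequence on each side of the cut: matches to the PAM-distal
side go to `I12_DIST`, to the PAM-proximal side to `I12_PROX`. Everything
else — longer insertions, off-cut insertions, flank-mismatching 1–2bp
insertions, and compound insertion-deletions — is `OTHER_I_MH` when the
insert (≥2bp) occurs verbatim in the 10bp of retained sequence adjacent
to the edit ("templated"), else `OTHER_I`.

Conventions fixed here (all configurable):

- The "with microhomology" split uses `mh_len >= 1`. This is the minimal
  nontrivial threshold; the knob exists for sensitivity analyses.
- 1–2bp insertions matching both flanks are binned with `I12_DIST` in
  category tables, because the PAM-distal templating mechanism dominates;
  the `flank_match` annotation keeps `BOTH` distinct for
  insertion-specific analyses.
- The templated-insertion window is 10bp per flank with a minimum match
  of 2bp; no principled value exists, so it is exposed and logged.
- 2bp deletions are not microhomology-split.

## Screen processing

The pipeline applies, in order: (1) remove any target whose profile in
*any* sample (line × replicate × timepoint) has fewer than 100 mutated
reads; (2) remove outcomes observed in exactly one read summed across all
samples of a target; (3) pool replicates and timepoints by summing reads.
Frequencies are fractions of mutated reads per (line, target) and sum to
one. Log2 fold changes versus control add a frequency pseudocount of
0.001 (0.1%) to both numerator and denominator; the same pseudocount is
used for category-level, outcome-level and clustering fold changes for
uniformity, since it is the only value stated for the analysis.

Profile divergences are Kullback-Leibler divergences in bits (log base 2
everywhere, matching the log2 fold-change convention). 0.5 reads are
added to every outcome of the union support before normalizing, which
keeps divergences finite on disjoint supports. Model evaluation uses the
directed divergence D(measured ‖ predicted) — the loss direction — while
replicate-replicate comparisons default to the symmetric average, since
replicates have no natural direction.

## Clustering of knockout-response profiles

Rows are (target, outcome) pairs retained when the outcome is present in
the control profile and in at least 10 knockout lines; the row vector is
the outcome's log2 fold change in each knockout. Rows are embedded in 2D
with UMAP (`min_dist=0`, `n_neighbors=50`, fixed seed, which also forces
single-threaded, reproducible execution) and grouped with seeded k-means
(K=7 by default). K-means on the embedding is the simplest reproducible
reading of "grouping the embedded outcomes"; a DBSCAN alternative sits
behind a flag, and neither the cluster numbering nor identities of any
particular run are claimed to be meaningful — only their compositions and
enrichment patterns. Cluster summaries are exact re-normalizations of one
contingency table (per-category distribution across clusters, and
per-cluster composition), knockout enrichment is the within-cluster mean
of column-z-scored fold changes, and per-cluster deletion directionality
is reported for microhomology-free deletions with a seeded percentile
bootstrap.

## Microhomology kinetics

Every pure deletion with (capped) microhomology `s >= 2` contributes an
observation at `(s, d = deletion_size − s)`; `d` is the distance between
the ends of the two homology copies, the only definition consistent with
deletion-window geometry (`d + s == deletion_size` is asserted). Mean
frequency per `(s, d)` bin (bins with fewer than 3 observations are
dropped) is fit with `y = A·exp(B·d)` per microhomology size 2–15 and per
line, by unweighted nonlinear least squares on raw `y` initialized from a
log-linear regression. Fitting the binned means rather than per-outcome
points is a choice; a per-point flag exists. Amplitudes `A` are expected
to increase with `s` and rates `B` to be negative.

Because frequencies are compositional, the decay rate a screen encodes
differs slightly from the generator's nominal `B`: an MH candidate's own
weight also enters its target's normalizer, and the effect grows with the
amplitude `A_s`. The exported ground truth therefore provides
`realized_mh_fits()` — the law obtained from the exact generative
probabilities — and recovery is measured against it. On sampled screens
at ~10⁶ pooled reads per target the fitted `B` matches the realized value
to well under 1% for `s ∈ {2,3,4}`; the realized-vs-nominal gap itself is
2–9% over that range.

## Outcome-frequency prediction

The candidate space per target is every deletion of up to 30bp whose
window spans or touches the cut (`a <= c <= a+L`; 495 windows before
deduplication; a flag restricts to strict spanning) and every 1–2bp
insertion within 3bp of the cut (140 before deduplication), canonicalized
and deduplicated. Observed outcomes outside the space (e.g. compound
indels) are dropped with their read fraction logged; under the default
generator that fraction is a few percent.

Each candidate gets binary features: outcome type, deletion size (one-hot
1–10 plus 11–15/16–20/21–30 bins), left/right boundary offsets from the
cut, microhomology length (0–15, 16+), insertion length and inserted
sequence, flank-match flags, nucleotide identity at six positions around
the cut and at the deletion junctions, plus declared pairwise products
(size×MH, left×right offsets, insert×flank, insert×context). The schema
is versioned; its dimensionality (1,950 in v1) is a property of this
reconstruction, not a conformance target. Features constant within a
target cancel in the softmax and act only through their products.

One model per cell line scores all candidates of a target with a linear
function of the features; predicted frequencies are the softmax within
the target. Training minimizes `Σ_t KL(m_t ‖ p_t) + λ‖w‖²` where `m_t`
are measured frequencies after adding 0.5 reads per candidate, with
L-BFGS and analytic gradients (`λ = 1e-3`, gradient tolerance 1e-6 by
default; none of these are claims about any external implementation).
Targets are split 90/10 at the target level — not the outcome level — so
no target contributes to both sides. Evaluation reports per-target
divergence (bits) and Pearson r at three levels: individual candidate
frequencies, the ten category frequencies, and the per-target in-frame
fraction (summed frequency of outcomes whose net length change is a
multiple of 3).

## The synthetic screen generator

The generator stands in for the unavailable sequencing data and defines
the study conditions for all recovery tests. Defaults: 2,838 targets
(random protospacers + NGG embedded in a fixed shared context), 18
knockout lines plus control, 2 replicates, 2 timepoints drawn i.i.d. (the
real screen's timepoints were pooled because they agreed; drift is not
modelled), log-normal mutated-read depth (median 1,000 per sample-target,
σ_log 0.3).

Per-target control probabilities put weight `min(α·e^{γs}, cap)·e^{Bd}`
on MH deletions (α=0.0085, γ=0.45, B=−0.12), a sharply size-decaying plus
flat background on non-homologous deletions, flank-dependent weight on
1bp insertions (PAM-distal T/A targets ~3× more insertion-prone than G/C;
the proximal share follows per-base propensities T>A>C>G), small weights
for 2bp duplications, and a ~2% compound tail. These values were
calibrated once so the control composition matches the screen's reported
control profile (long MH deletions ~27%, medium MH deletions ~21%,
PAM-distal insertions ~15%, 1–2bp deletions ~13%) and then frozen.
Knockout lines multiply category weights by `2^lfc` before
renormalization; because frequencies are compositional the realized fold
changes differ from the nominal ones, and the exported `GroundTruth`
stores the exact post-normalization probabilities, from which realized
category fold changes and the realized MH law are derived.

What the generator does *not* emulate: sequencing error, guide dropout
from toxicity, cell-cycle or timepoint drift, target-specific chromatin
effects, outcome-level (as opposed to category-level) knockout
specificity beyond the built-in laws, and any correlation between
replicates beyond shared truth. Passing recovery tests therefore
demonstrates that the estimators are correct and well-calibrated under
the assumed measurement model, not that real screens are free of the
confounders above.

## Degenerate inputs and numerical edge cases

Identity edits are rejected at construction and at canonicalization (an
edit that reproduces the reference is not an outcome). Targets with zero
mutated reads are excluded from frequency tables with a warning.
Zero-variance fold-change columns z-score to zero with a warning.
Exponential fits require ≥3 distinct distances and report non-convergence
with NaN parameters rather than raising. All stochastic stages
(simulation, splits, bootstraps, embedding) take explicit seeds and are
reproducible; problem sizes in the test suite (60–500 targets, depths
10³–2.5×10⁵) were chosen as the smallest screens at which each recovery
statistic is comfortably stable.
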