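# Methods

This note records the models implemented, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and
the numerical conventions that make results reproducible.

## Topic model

The corpus model is standard LDA: θ_d ~ Dirichlet(α·1_K) per document,
φ_k ~ Dirichlet(β·1_V) per topic, token topics z ~ Categorical(θ_d),
words w ~ Categorical(φ_z). Inference is **collapsed Gibbs sampling**:
θ and φ are integrated out and token assignments are resampled from

    p(z_i = k | ·) ∝ (n_dk^{−i} + α) · (n_kv^{−i} + β) / (n_k^{−i} + Vβ).

Collapsed Gibbs was chosen over variational inference because it is
fully specifiable in a few lines, exact in the limit, and trivially
seed-deterministic: all uniform variates are pre-generated from a
single PCG64 stream keyed by the config seed, so a given (corpus,
config) pair yields bit-identical assignments on any machine. The
inner loop is numba-compiled; a 20k-token corpus sweeps 100 iterations
in well under a second.

Defaults: α = 50/K and β = 0.1 (the conventional symmetric priors for
policy-scale corpora), 100 full sweeps, estimates read from the final
count state with no burn-in discard and no sample averaging. All of
these are configurable; the flat-100-sweep, final-state convention is a
declared dialect, adequate in the sparse-mixture regimes the package
targets (see the recovery experiment below) but not a converged
posterior summary in general.

**Perplexity** uses the plug-in per-token likelihood
P̂(v|d) = Σ_k θ̂_dk φ̂_kv on the training corpus. The true marginal
P(w_d | α, β) is intractable; the plug-in estimate is a declared
dialect, suitable for comparing topic counts on the same corpus, not
for cross-corpus comparison. Empty documents are skipped (they carry
N_d = 0 and receive the prior-mean mixture 1/K).

**UMass coherence** is computed from document frequencies of each
topic's top-N terms, with ε = 1 (the conventional smoothing value) and
N = 10 by default. N = 10 is the common reporting choice; raising it
toward the 20–30 words used for manual topic labelling dilutes the
score with tail terms and, on small corpora, can request terms that
occur in no document (an error, by contract).

**Topic-number selection** fits one model per candidate K (same seed
per K) and selects the K maximising mean coherence, ties toward
smaller K; perplexity is recorded for inspection only, since it
decreases near-monotonically in K on training data. A measured
limitation: UMass coherence is biased toward small K. Merged topics
surface high-frequency terms with high co-document counts, so a K
below the truth often outscores the true structure — on planted
3-topic corpora the *planted* topics score below a fitted 2-topic
merge, and the argmax rule selects K = 2 in most runs regardless of
the top-term count. The curves should therefore be read the way
practitioners read them: as one input to a judgment call, not an
automatic oracle. The selection rule is kept because it is the
declared, deterministic convention; its bias is documented here and
exercised by the test suite.

## Synthetic corpora and the recovery experiment

`generate_lda_corpus` samples exactly the generative process above and
retains θ and φ. Its document-mixture default is **α = 0.5**: sparse
mixtures in which each document is dominated by a few topics, which is
what real policy texts look like and what keeps the planted topics
identifiable. This deliberately differs from the fitting default
α = 50/K: in the large-α limit every θ_d collapses to the uniform
vector and the per-token word law becomes the fixed mixture
(1/K)Σ_k φ_k, under which φ is not identifiable at all. Concretely, at
α = 50/K = 16.7 the planted mixtures are 1/3 ± 0.07 and the
best-permutation total-variation error of φ̂ plateaus around 0.1–0.2
however long the chain runs — that is posterior spread, not inference
error, since the same sampler reaches TV ≈ 0.02–0.03 in the sparse
regime.

The recovery experiment fits with the generator's own priors (the
well-posed, matched-prior setup) at the default problem size K = 3,
V = 60, D = 200, documents of 100 tokens: best-permutation mean TV
distance between φ̂ and the planted φ is below 0.10 for every seed
tested (typically 0.02–0.03 at 100 sweeps). Topic strengths at D = 500
land within 0.05 of 1/K, and corpus-wide term frequencies at D = 2000
match the planted mixture Σ_k mean(θ_·k)·φ_kv within 0.02 TV.

What the generators do **not** emulate: natural-language word order and
syntax (irrelevant to bag-of-words consumers), realistic vocabulary
growth (Zipfian tails), document-length variation, or topic
correlation. Passing tests therefore demonstrate correctness of the
inference and bookkeeping under the model's own assumptions, not
performance on real segmented Chinese policy prose.

Tokenization is pluggable (whitespace default); no segmenter is
bundled, so Chinese text should be pre-segmented upstream. Synonym
maps are applied exactly once — no transitive closure — which keeps
normalization deterministic and puts the burden of canonical maps on
the user. The vocabulary is ordered by (corpus frequency descending,
then lexicographic) so every downstream index and export is
reproducible; the minimum document frequency defaults to 1.

## Instrument tallies

The default frame is the 17-subtool Rothwell taxonomy (6 supply, 6
environment, 5 demand). *Medical insurance* is shipped as an opt-in
demand-side extension rather than a default member because it is
tallied in practice but sits outside the base taxonomy; either framing
is expressible in config. Shares are percentages rounded **half-up**
at a precision flag (1 dp by default, 2 dp where finer reporting is
wanted); half-up is used throughout, in rational/decimal arithmetic,
so printed digits never depend on binary-float artifacts. Within-
category shares of an empty category are undefined and omitted rather
than forced to a value.

## PMC index

Scoring conventions, chosen to be exact and auditable:

- secondary indicators are strictly binary; validation names the first
  missing or non-binary entry and its policy;
- a primary score is the exact rational mean of its secondaries,
  rounded half-up to 2 dp **before** summation, and the sum is
  re-rounded to 2 dp. Rounding before summation is the convention that
  reproduces published 2-dp PMC tables (e.g. scores of
  1 + 0.67 + 1 + 1 + 1 + 0.7 + 1 + 0.6 + 1 summing to 7.97); summing
  unrounded fractions and rounding once can differ by ±0.01;
- rating bins are half-open on the left ([4, 6), [6, 8)) and closed at
  9, applied to the 2-dp value, matching the conventional "4–5.99"
  style bin labels;
- cohort ranks are competition ranks on descending PMC (ties share the
  smaller rank, first-seen order); cohort means are 2-dp means of the
  2-dp per-policy values.

One grid subtlety: a primary with T secondaries can only realise
scores k/T. The packaged reference grid contains one value (0.2 on a
six-indicator primary) that no binary coding can produce exactly —
the grid is stored as printed, and the nearest achievable profile
(1/6 → 0.17) is used where an underlying coding is needed.

The PMC surface interpolates the row-major 3×3 primary-score matrix
bilinearly onto a grid_density² lattice (default 33²). Bilinear was
chosen because it is the simplest interpolant that preserves the nine
anchor values exactly; corner fidelity and edge-midpoint averaging are
the asserted properties. Flatter surfaces indicate more internally
consistent policy design.

## Reproducibility and degenerate inputs

Every stochastic routine takes an explicit seed; CLI artifacts are
written atomically (temp file + rename) and byte-identical across
reruns with the same inputs and seeds. Degenerate cases are defined,
not accidental: empty documents are carried but excluded from fitting;
K = 1 yields all-equal assignments and θ̂ = 1 exactly; a single-term
coherence list scores 0 (empty pair sum); V < K warns; an all-empty
corpus, an empty vocabulary after filtering, a zero grand total and an
out-of-range index all raise with context.

## Problem sizes used by the test suite

The suite exercises the sampler at the default recovery size (200
documents × 100 tokens, V = 60, K ∈ {2..5}, seeds 1–10), the mixture
identity at D = 2000, and PMC monotonicity on 1,000 random codings —
sizes at which the full suite completes in well under a minute while
leaving the statistical assertions comfortable margins.
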