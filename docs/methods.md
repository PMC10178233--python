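# Methods

## Data model

Input is one aligned sequence–structure matrix per species: ITS2 alleles as
Vienna triplets (header / aligned RNA sequence / dot-bracket), with optional
`count=N` copy counts in headers.  The internal alphabet is RNA; T is mapped
to U on read because the structures are RNA folds.  Ambiguity codes other
than N are rejected: the doublet encoding below is defined only for
unambiguous bases, gaps and N.  Alleles observed with a single copy are
removed before analysis (they are indistinguishable from
sequencing/assembly artifacts); the filter is idempotent and an empty result
is legal — downstream stages then skip the species.

## Consensus structure and partition

Each candidate base pair (i, j) is scored by the fraction of alleles whose
structure contains it; pairs with support ≥ the threshold (default 0.70) are
retained, then made non-crossing and one-pairing-per-column by greedy
acceptance in decreasing support (ties: smaller opening, then closing,
position).  The threshold is interpreted as per-pair support; whole-structure
identity was the other plausible reading and per-pair support was chosen
because it degrades gracefully when alleles disagree locally.  Columns inside
retained pairs form the *paired* region (encoded as one 16-state doublet per
pair, gap/N on either side = missing); the rest are *unpaired* (4-state,
gap/N = missing).  Coordinates are 0-based internally; reports print 1-based.
Pseudoknots are outside Vienna notation's expressivity and are not modeled.
De novo thermodynamic folding is deliberately not implemented: the pipeline
consumes structures (homology-predicted or simulated) rather than predicting
them.

## Composition statistics

Per-allele GC is 100·(G+C)/(A+C+G+U) over the selected columns, ignoring
gaps/N; species GC is the unweighted mean over distinct alleles (copy counts
are ignored, mirroring analysis of distinct variants; whether copy-count
weighting is preferable is undecidable from the study design, and the
unweighted choice is recorded in run metadata).  GC homogeneity is the
sample SD (n−1) of per-allele GC.  K is the mean, over unordered allele
pairs, of the count of differing positions where both alleles have a real
base (pairwise deletion, the DnaSP convention).  Spearman correlation and
Shapiro–Wilk tests wrap scipy.stats; constant vectors are rejected rather
than returning NaN.  A per-column base-frequency table stands in for
sequence-logo rendering.

## Substitution models

All models are reversible continuous-time Markov chains q_ij = s_ij π_j,
normalized to unit mean rate (−Σ πᵢ qᵢᵢ = 1), so branch lengths are expected
substitutions per site.  Unpaired columns: HKY85 (κ) or REV (6
exchangeabilities).  Paired sites: a doublet family over the 16 ordered pairs
with zero rate between doublets differing at both positions (no double
substitutions), either with free stationary frequencies (the default,
"RNA16") or with frequencies constrained to products of nucleotide
frequencies ("RNA16P"); and a 7-state lumping (AU, GU, GC, UA, UG, CG, MM)
with single-base edges among pairs plus pair↔MM edges, again with free or
product-constrained frequencies ("RNA7", "RNA7P").  These families share the
properties the downstream statistics use — single-change constraint, rate
matrix, stationary frequencies — without cloning any particular legacy
parameter count, which is not recoverable from published descriptions.

The likelihood is Felsenstein pruning over a guide tree (neighbor-joining on
Jukes–Cantor distances with pairwise deletion; negative NJ branch lengths
clamped to 0; saturated pairs, p ≥ 0.75, are an error naming the pair).
Unpaired columns are 4-state sites; each base pair is one 16- (or 7-) state
site; missing symbols are marginalized.  Site patterns are compressed once
per fit.  Likelihood is invariant to root placement for these reversible
models (tested).

ML fitting maximizes the pruning likelihood by bounded L-BFGS-B over
transformed parameters (log exchangeabilities with the first fixed at 1 for
identifiability, log κ, softmax frequency weights), with branch lengths fixed
at the NJ estimates by default and jointly optimized on request
(log-transformed).  A weak ridge penalty (0.01·‖θ‖², excluded from the
reported logL) anchors exchangeabilities the data leave unidentified at 1
instead of letting them drift to the box bounds; on informative data its
effect is negligible.  Multi-start jitter is seeded; fits are deterministic.
Non-convergence is flagged on the result, never raised.

Model selection uses AICc = −2logL + 2k + 2k(k+1)/(n−k−1) with n = number of
partition sites (one per pair + one per unpaired column) for *every*
candidate, including the DNA-only one (which scores both sides of each pair
as 4-state columns); a common n keeps the ranking comparable across state
spaces.  k counts all optimized parameters, branch lengths included when they
are optimized.

The Metropolis–Hastings sampler moves over the same transformed coordinates
with an iid Normal(0, scale=2) prior on them (this gives a proper,
directly checkable prior-only mode; the induced priors are lognormal on rates
and logistic-normal on frequencies).  The proposal step adapts toward 30%
acceptance during burn-in and is frozen afterward, preserving detailed
balance for the retained draws.  Equilibrium is declared by a doubling rule:
rerun at 2× iterations and require every posterior-mean coordinate to move
by <1% relative (floored at 0.1 absolute near zero).  ML is the primary
estimator; the sampler serves the equilibrium-state analyses.

## GC dynamics

* **GC\*, unpaired**: u = Σ_{i∈{A,U}, j∈{G,C}} πᵢ q_ij / (π_A+π_U),
  v = the reverse sum / (π_G+π_C); GC\* = 100·u/(u+v).  For any reversible
  model this equals 100·(π_G+π_C) (detailed-balance identity, asserted to
  1e−10 in tests), so the formula is validated independently of the fit.
* **GC\*, paired**: solve πQ = 0 and report 100·Σ_d π_d·g(d), g(d) = G/C
  fraction of doublet d (the lumped MM state counts 0.5).  The
  stationary-composition definition was chosen over a flux-based one because
  it is exactly the long-run simulated composition (checked against forward
  simulation).
* **Trend**: increasing / decreasing / stable by comparing GC\* with current
  GC at a tolerance (default 0.1 percentage points).
* **Formation rates**: rate-matrix entries q(source→target) — not fluxes
  π·q — summed over the six single-change routes into each of GC, CG and of
  AU, UA; the GC:AU ratio is scale-invariant.  Stationary frequencies of
  GC-type and AU-type pairs are reported separately for the
  frequency–mutability view.  On the 7-state space MM is the single mismatch
  source.
* **Mismatch conversion**: each unordered mismatch (A·G, A·C, C·U, G·U) maps
  to its two ordered doublets; the one-side repair rates into the GC-type and
  AU-type Watson–Crick destinations (A·G→CG / AU, A·C→GC / AU, C·U→CG / AU,
  G·U→GC / AU) are averaged over orderings, eight route groups in total.
  Requires the 16-state model; the 7-state lumping loses mismatch identity
  and is rejected with an explanation.  G·U plays both roles — wobble
  intermediate in formation rates, repairable mismatch here — deliberately.

Percent-difference phrasings ("x% higher") are ambiguous between r and r−1;
the package reports plain ratios only.

## Synthetic generator

`SynthConfig` defaults are the study conditions and are not tuned per run:
alignment length 260 (240–277 is the realistic ITS2 range), paired fraction
0.46, four stems with ≥3-nt loops, base frequencies (0.18, 0.32, 0.32, 0.18)
giving ~64% unpaired GC, stem doublet frequencies as nucleotide products
boosted ×20 for Watson–Crick and ×8 for wobble pairs (~70% paired GC at
λ = 1, ~85% at λ = 3), κ = 4, Yule species tree of depth 0.3
substitutions/site, allele star-tree divergence 0.1, concerted-evolution
branch 0.5, geometric copy counts with mean 5 (so the singleton filter is
exercised), gBGC multiplier λ = 3.

gBGC is a single multiplier λ on all rate-matrix entries *into* GC-type
doublets; destination-column scaling keeps the chain reversible with new
stationary π′_j ∝ c_j π_j, so the compositional consequence of the bias is
exact rather than approximate.  Homogenization h couples to the bias as
λ_eff = 1 + (λ−1)·h, applied on each species' terminal and
concerted-evolution branches: gene conversion is one event that both
homogenizes (alleles diverge on a star tree of depth (1−h)·allele
divergence, so h→1 gives K→0) and converts with GC bias.  This coupling is
the package's own generative stand-in — no mechanistic
recombination/unequal-crossover model is attempted — and it produces the
expected signature: a negative species-level K–paired-GC Spearman correlation
on an h-grid at λ > 1, with no forced trend in unpaired GC.

What the generator does *not* emulate: indels (the alignment is fixed-length),
per-allele structure variation (all alleles carry the true structure, so the
consensus step is exercised but not stressed), rate heterogeneity across
sites, pseudoknots, and mechanistic recombination.  Passing tests therefore
demonstrate correctness of the statistics and estimators under the assumed
process, not robustness to alignment error or structure misprediction in
real data.

## Numerical choices and problem sizes

Matrix exponentials via scipy's expm with rows renormalized after clipping
tiny negative round-off; stationary distributions via null space (reducible
chains are an error).  Optimizer tolerance 1e−10 in the penalized objective,
box bounds ±15 on transformed parameters.  Parameter-recovery and
model-comparison tests run at 6–10 taxa and 400–2000 columns; the pipeline
tests at 3 species with reduced optimizer iterations; the acceptance script
pools ten 10-species replicates for the correlation signature.  These sizes
were chosen to make the statistical assertions stable across seeds while the
whole suite stays lightweight.

## Known limitations

Branch lengths fixed at NJ estimates bias rate estimates when divergence is
high (joint optimization is available and used in the recovery analyses).
Exchangeabilities of rarely observed states are weakly identified on small
matrices; the ridge keeps them finite but per-species formation-rate ratios
from few alleles remain noisy, and should be read in aggregate.  AICc with
n = partition sites is one defensible convention among several for mixed
state spaces.  The MCMC sampler has a single chain and simple adaptation;
it is adequate for fixed-tree parameter posteriors, not for tree inference,
which is out of scope.
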