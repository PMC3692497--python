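# Methods

## Scope and model overview

The package implements a five-stage analysis chain for dating
cartilaginous-fish divergences from nuclear protein-coding genes:
orthology screening by local-alignment bit scores, amino-acid
maximum-likelihood phylogenetics, a log-likelihood topology-acceptance
test, Bayesian relaxed-clock node dating under fossil calibrations, and
relative-rate quantification. All stages consume and produce standard
text formats (FASTA, Newick, TSV) and are driven from Python; the
synthetic-data module generates statistically faithful inputs for every
stage, so the full chain is testable end-to-end without any sequence
download.

## Substitution model

Amino-acid evolution is modelled with the Jones–Taylor–Thornton (JTT)
exchangeabilities and frequencies (the canonical published 20×20 table,
embedded verbatim). The generator is built as `Q_ij = S_ij π_j`, rows
normalised to zero sum and the expected equilibrium rate scaled to one
substitution per site, so branch lengths are in substitutions/site.
Among-site rate variation uses k = 4 equal-probability discrete-gamma
categories represented by their **category means** (the CODEML/PHYML
convention, computed from regularised incomplete gamma functions rather
than quadrature). An optional invariant class takes probability `p_inv`;
the variable categories are rescaled by `1/(1 − p_inv)` so the marginal
mean rate stays one. Gaps and `X` are fully ambiguous states
(conditional likelihood 1) in likelihood computations and count as
missing data for complete deletion and end trimming. Transition
probabilities come from one symmetric eigendecomposition of
`Π^{1/2} Q Π^{-1/2}` fixed per model; the same eigenbasis accelerates the
per-branch likelihood in the optimizer hot loop.

## Likelihood engine and optimizers

Per-site log-likelihoods are computed by Felsenstein pruning over
compressed site patterns, with per-pattern rescaling engaged only when
conditionals underflow. Branch lengths are optimized coordinate-wise:
each round walks the tree in postorder, refreshes the conditional of the
visited node from its already-refreshed children, and solves the 1-D
problem on each branch with bounded Brent (branch lengths clamped to
[1e-8, 20]); rounds repeat until the log-likelihood gain is below 1e-6.
The gamma shape α is estimated by bounded search on log α over
[0.02, 100], alternated with branch-length re-optimization; a boundary
solution warns. Pairwise ML distances maximize the two-sequence
likelihood over a single distance; a flat likelihood at the bound warns
and returns the bound.

Tree search starts from a neighbor-joining tree on pairwise ML distances
(NJ ties broken on the lexicographically smallest cluster-label pair, so
the result is input-order invariant; negative length estimates are
clamped to zero) and hill-climbs over nearest-neighbor interchanges.
Candidate neighbors are scored with a coarse branch-length pass
(3 rounds, tolerance 1e-2) warm-started from the current tree; the
accepted move is refined to full tolerance. This two-level scheme changes
no decisions on the test problems but makes the search several-fold
faster.

## Topology acceptance (1-SE rule)

For a gene whose ML topology differs from the assumed species phylogeny,
branch lengths (and optionally α) are re-optimized separately on both
topologies and the per-site log-likelihood difference vector `d_i` is
formed. The standard error follows the Kishino–Hasegawa normal
approximation `SE = sqrt(n · var(d_i))` (ddof = 1); a site-resampling
(RELL-style) bootstrap SE is available as a cross-check and agrees within
sampling error. The gene is accepted when `|ΔlogL|/SE < 1`; a ratio of
exactly 1, or SE = 0 with a nonzero difference, rejects (the conservative
reading of a rule stated only for < 1 and > 1). Identical topologies
short-circuit to (0, 0, accepted).

## Relaxed-clock dating

**Model.** A fixed rooted topology; internal-node ages `t` in units of
100 My (Ma at all interfaces); one rate per branch with
`log r ~ Normal(log μ, σ²)` i.i.d. (independent-rates clock; no mean
correction, so μ is the median rate). Hyperpriors are gamma:
`μ ~ G(1, 5.2)` and `σ² ~ G(1, 5.6)` per 100-My unit — the priors used
with a ~3000-site vertebrate concatenation. Uncalibrated node ages are
uniform conditional on the root age (each contributes a `1/t_root`
volume factor) subject to parent-older-than-child ordering; the root
needs an upper bound and, if its calibration does not provide one, the
oldest calibration maximum (×1.5) is used with a loud warning.

**Calibrations.** Soft min/max bounds place 95% mass uniformly between
the bounds, a power tail below the minimum and a shifted-exponential
tail above the maximum, each carrying 2.5% and continuous at the bounds;
the density integrates to one and has a closed-form CDF (used for
prior-recovery tests). A maximum-only variant is uniform on (0, U) with
an exponential 2.5% tail. Hard lower bounds are −∞ below the bound and
flat above, bounded in practice by the ordering and the root prior.

**Sampler.** Metropolis-within-Gibbs sweeps over ages (sliding window,
rejected outside the local ordering interval), log-rates, log-μ and
log-σ² (with Jacobian terms), windows auto-tuned to 20–40% acceptance
during burn-in and frozen afterwards. Two likelihood modes exist:

- *exact* — full pruning likelihood with branch lengths `r·Δt`
  (reference mode; practical for small alignments);
- *approximate* (default) — a normal approximation around the ML branch
  lengths of the unrooted topology, one term per branch with the SD from
  the observed Fisher information (finite-difference curvature of the
  per-branch log-likelihood at its MLE). A diagonal approximation is
  used rather than a full Hessian; the two root-child branches are
  merged into the single identifiable root-spanning branch whose
  predicted length is `r₁·Δt₁ + r₂·Δt₂`.

The production schedule (50 000 burn-in cycles, every 20th of 4 000 000
cycles kept, 200 000 samples, two replicate chains) is the default
`ChainSettings`; the test suite and examples use a scaled desk schedule
(5 000 burn-in, 20 000 samples, thinning 2) that leaves Monte-Carlo error
well below the 2% replicate-agreement tolerance on the 12-taxon problem.

**Validation.** Because an interacting set of calibrations plus ordering
constraints makes the marginal prior at a node differ from its
calibration density (the standard caveat for calibrated node-age
priors), the prior-recovery test samples a configuration where the
identity is exact — a single soft-bounded root — and checks the sampled
CDF against the closed form (KS < 0.05 at 10⁴ samples). On the simulated
12-species study design the sampler is validated by truth coverage
(true ages of the two chondrichthyan nodes inside the 95% CI in ≥ 16/20
replicates) and replicate-chain agreement (posterior age means within
2%). Convergence reporting includes an effective-sample-size estimate
per parameter (Geyer initial-positive-sequence autocorrelation
estimator, FFT-based), verified against the AR(1) closed form
`n(1−ρ)/(1+ρ)`.

## Relative rates

For an ingroup pair (A, B) with outgroup C, the ancestor-to-tip
distances are `K_OA = (K_AB + K_AC − K_BC)/2` and symmetrically for B;
`K_OA + K_OB = K_AB` holds to machine precision. Triangle violations and
negative decompositions are reported as-is with warnings (clamping would
hide rate-test failures). Absolute rates divide `K_O` by the divergence
time and are reported in 10⁻⁸ substitutions/site/year. The reporting
layer rounds distances and rates to 3 decimals and fold ratios (taken
between *reported* rates) to 1 decimal, using decimal half-up rounding
after snapping binary float dust at 10 decimals — this reproduces the
conventional table formatting exactly (e.g. 0.0675 → 0.068). Two cells
of the published Hox A table do not follow from its own printed rounded
distances (the upstream analysis evidently used unrounded values); they
are documented and excluded from exact comparisons.

## Orthology screen

The local-alignment core is Smith–Waterman with affine gaps via
Biopython's `PairwiseAligner` (BLOSUM62, BLAST gap convention: a gap of
length k costs open + k·extend, defaults 11/1), floored at zero (the
empty alignment), and converted to bits with the gapped Karlin–Altschul
constants λ = 0.267, κ = 0.041. The screen rule is strict: ties between
the outgroup score and either ingroup score fail. The copy-number filter
fails a gene only when its hit count strictly exceeds the threshold
(default 500). Alignment end trimming removes leading/trailing columns
until the first run of `window` (default 20) consecutive columns with at
least `min_occupancy` (default 0.9) non-missing fraction among the
reference (chondrichthyan) taxa; both thresholds are caller-visible
parameters since the procedure they formalise was described without
numbers. Exclusion of the more divergent teleost duplicate (from the
teleost-specific genome duplication) is an explicit helper that keeps
the candidate with the smaller ML distance to a non-teleost reference,
never an automatic step.

## Synthetic data

`simulate_alignment` draws root states from the model frequencies, one
rate class per site (invariant class included), and evolves states down
each branch with `exp(Q · rate · duration · class_rate)`; branch rates
are log-normal draws or explicit per-branch multipliers. All randomness
derives from one seed through `SeedSequence` spawning, so sub-generators
are independently reproducible.

The gene-family generator emulates the screen's operating conditions:
a six-species family (human outgroup; chimaera query; two sharks, two
rays) with splits at 454/421/306/150 Ma, 300-site queries (the real
marker genes span ~100–400 aa), median rate 0.06 substitutions/site per
100 My, Γ shape 0.6, log-rate drift σ² = 0.02, and a 2.5× faster human
branch — the documented several-fold tetrapod/chondrichthyan rate
difference is precisely what gives the bit-score rule its margin; with
rate-equal lineages the 454-vs-421 Ma margin is comparable to the
per-gene stochastic noise and the rule would be near-chance, which is
worth knowing when interpreting the screen on taxa without such a rate
contrast. Optional pre-gnathostome duplications (default 550 Ma) with
per-species copy retention reproduce hidden-paralogy hazards: ingroup
databases retaining only the out-paralog are caught by the rule
(ingroup hits become more distant than the outgroup), whereas an
outgroup that lost the ortholog only looks *more* distant and passes —
a real blind spot of the rule that the tests document rather than hide.

The dating fixture rebuilds the published study layout: 12 species
(four tetrapods, three teleosts, three chondrichthyans, two outgroups),
11 internal nodes, and a 19-constraint calibration design — soft min/max
bounds on the eight non-chondrichthyan ingroup nodes, a maximum-only
bound adjacent to the root, and hard lower bounds at the two
chondrichthyan nodes (410 Ma; 250 or 190 Ma depending on constraint
set). The constraint values follow the standard fossil compilation the
study cites; the full constraint table itself is unpublished, so this
fixture is a synthetic reconstruction, and the truth node ages are the
study's posterior means used purely as simulation parameters, never as
reproduction targets. Scenario defaults (2000 sites, α = 0.55, median
rate 0.08 substitutions/site per 100 My, σ² = 0.04) mirror the scale of
the real 20-gene concatenation (2973 sites, per-gene α mostly 0.3–1.0,
sub-unit root-to-tip divergence).

What passing these tests does **not** show about real data: the
simulator evolves i.i.d. sites under the same model family the inference
assumes (no alignment error, no compositional heterogeneity, no
among-gene rate differences, no missing data), so coverage results speak
to the correctness of the machinery, not to model adequacy on empirical
alignments.

## Numerical choices and conventions

- Column intervals 0-based half-open; ages internally in 100-My units,
  Ma at every interface; branch lengths substitutions/site.
- NJ ties and teleost-duplicate ties break lexicographically
  (determinism).
- Branch lengths clamped to [1e-8, 20]; α search on [0.02, 100];
  optimizer tolerance 1e-6 log-units.
- Concatenation requires identical taxon sets and errors with the
  symmetric difference; `pad_missing=True` gap-fills instead (for the
  occasional gene missing one core species).
- Equal-tail 95% credible intervals; kernel densities on a 512-point
  grid; `ci_low ≤ median ≤ ci_high` is asserted.
- MCMC traces store time units and rates per time unit; summaries
  convert to Ma.

## Known limitations

- The approximate dating likelihood is diagonal-normal; strong
  correlations between adjacent branch lengths are ignored (adequate on
  the test problems, as the exact-mode smoke tests and coverage study
  show, but a full-Hessian mode would be the next refinement).
- Exact-mode MCMC recomputes the full pruning likelihood per proposal
  and is only practical for small alignments.
- The NNI search is a single-path hill climb; on hard topologies a
  multi-start or SPR search would be stronger.
- The screen consumes peptides; six-frame translation of ESTs, assembly
  and gene prediction are out of scope, as are alignment construction
  and E-value statistics.
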