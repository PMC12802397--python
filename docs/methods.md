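# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `sortscreen`. Everything quantitative stated here is
computed by the test suite, the `analysis/` drivers, or
`scripts/acceptance.py`.

## The screen model

A sort-based CRISPRi activity screen measures, for every gene, whether its
knockdown changes the probability that a cell mounts a stimulus-induced
calcium response. The simulator (`sortscreen.simulate`) reproduces the
generative chain of such a screen rather than drawing fold changes
directly:

1. **Library and infection.** A manifest of sgRNA elements (19–20 nt
   protospacers, unique, uniform length) targets each gene with ~5 guides
   plus ~2.5% non-targeting controls (NTCs). Infection at low MOI
   (default 0.4) is modeled purely as a multiplicity filter: with Poisson
   integration counts, only single-integration cells are retained, so the
   effective cells-per-element is `coverage × P(K=1 | K≥1)`. Per-element
   day-0 cell numbers are Poisson around that mean (default coverage
   1000×). Double-integration genetics is deliberately not modeled — low
   MOI exists precisely to make it negligible.

2. **Knockdown and responder state.** Each targeting sgRNA has a knockdown
   efficacy k ∈ [0,1] ~ Beta(6, 1.5) (mean 0.8, emulating well-designed
   "top-5" guides); NTCs have k = 0. A wild-type cell responds to the
   stimulus (and therefore photoconverts) with probability p₀ = 0.5; a
   planted gene effect multiplies the *odds* of responding, attenuated by
   efficacy on the log-odds scale:
   p_i = σ( logit p₀ + k_i · ln m_g ).
   Neutral genes (m = 1) and NTCs sit exactly at p₀, so the null is exact
   by construction. m < 1 is a positive regulator of the response
   (knockdown blunts it), m > 1 a negative regulator.

3. **Growth and the dropout arm.** Before sorting, cells undergo ≥ 6
   doublings; a gene's fitness f multiplies growth per doubling,
   attenuated by efficacy (growth = f^(k·doublings)). The survival screen
   compares day-0 and endpoint abundances; the FACS arm sorts the *grown*
   population, so fitness effects propagate into bin counts — which is why
   screens need the survival confound check.

4. **Sorting.** Each cell's red/green log-ratio comes from one of two
   Gaussian components (responder N(1, 0.6), non-responder N(−1, 0.6),
   natural-log scale). Gates are the population's top and bottom 35%
   quantiles, found by root-solving the two-component mixture survival
   function — gating happens on fluorescence *before* sequencing, matching
   the physical order of operations. In the default aggregate mode each
   element's cells are split Binomial(n_i, p_i) into components and each
   component contributes its exact tail mass beyond the gates; an explicit
   per-cell mode exists and agrees with the aggregate mode
   (tests), but at 20k elements × 1000× coverage the aggregate mode is the
   only desk-scale option.

5. **Sequencing.** Reads per sample default to 1000 × the library size
   (the paper-scale depth bound is a lower bound of 500×; the default is
   configurable). Counts are multinomial over bin masses; with
   `dispersion > 0` the weights are gamma-jittered first, giving
   negative-binomial-like overdispersion. All randomness flows from one
   seed; identical configs give identical outputs.

The simulator also fabricates the secondary-assay inputs: two-component
log-normal flow events (hidden responder labels retained), imaging traces
(baseline + step-then-exponential-decay transient + white noise, truth
peaks recorded), 4PL dose–response tables, and qPCR Ct tables
forward-simulated from a known fold change.

## Hit calling

Counts → CPM with pseudocount 1 (avoids infinite log ratios; column sums
10⁶ exactly) → per-replicate log2(low/high) (or endpoint/day0) averaged
across replicate pairs → gene statistics:

- **Rank-sum p vs NTCs.** Each gene's sgRNA log2FCs are tested two-sided
  against the pooled NTC log2FCs. Because every gene group in a screen has
  one of a few sizes against the same pool size, the exact Mann–Whitney
  null pmf is computed once per size pair by the standard counting
  recurrence and reused — this makes exact tests on ~25,000 gene and
  quasi-gene groups take seconds. Cross-group ties fall back to the normal
  approximation with tie correction. The implementation is checked
  per-gene against `scipy.stats.mannwhitneyu`.

- **Quasi-gene empirical FDR.** The null distribution of phenotype scores
  is built from pseudo-genes: groups of NTC sgRNAs of the modal per-gene
  size, drawn without replacement within a draw and with replacement
  across draws (10× the real gene count by default), scored exactly like
  genes. One deliberate detail: a quasi-gene is tested against the NTC
  pool *minus its own members*, because a real gene's sgRNAs are never in
  the pool either; including them shrinks quasi p-values toward the null
  center and would make the null slightly too tight. FDR(t) is the
  directional tail-fraction ratio, capped at 1, and each gene receives the
  q-value-style minimum over all thresholds that still include it, so FDR
  is non-increasing in score magnitude. An add-one (Phipson–Smyth)
  correction on the null tail was evaluated and rejected: with a 10×
  quasi null it floors the FDR of an isolated true hit at ~0.1,
  sacrificing lone-hit detection for negligible gain elsewhere.

- **Phenotype score and classes.** score = effect × (−log10 p); strong
  hits at FDR < 0.05, weak at FDR < 0.1, direction from the effect sign.
  Ranking is by descending score with lexicographic tie-break.

### Calibration properties (and two honest caveats)

Under the global null the pipeline is conservative: across 20 all-neutral
screens (500 genes × 5 sgRNAs, 50 NTCs) the mean strong-hit fraction is
~10⁻³, far below 0.05. With 50 planted positive regulators among 2,000
genes (odds multiplier 0.1, efficacy ≥ 0.8, coverage 1000×, depth 1000×),
sensitivity is 1.0 and mean precision ≈ 0.95 across seeds.

Two statistical facts should temper expectations:

1. **Gene p-values are exchangeable but not independent.** Every gene is
   tested against the same finite NTC pool. Conditional on an atypical
   pool, all p-values shift together; a one-sample KS test of the 500
   p-values against Uniform(0,1) therefore rejects in roughly a third of
   null screens at a 50-NTC pool even though each p-value is marginally
   exactly uniform (the same experiment with an independent pool per gene
   passes at the nominal rate). This is intrinsic to control-pool designs,
   not a miscalibration.

2. **FDR is controlled in expectation, not per run.** The realized
   false-discovery proportion at the 0.05 cut fluctuates with the luck of
   the NTC draw (a narrow NTC sample under-disperses the quasi null); its
   mean matches the nominal level, but individual screens can land a few
   points above or below. No resampling-FDR procedure bounds per-run FDP.

## Cross-screen comparisons

Pearson correlation of phenotype scores over shared genes (symmetric,
affine-invariant); recall of a reference gene list above a score threshold
with a full sweep curve; top-N hit-status overlap tables; hypergeometric
over-representation P(X ≥ k) of gene sets among hits with BH adjustment
across sets. The enrichment universe is the set of genes targeted by the
library — a screen cannot nominate untested genes — matching how pathway
denominators are counted in practice. Enrichment p-values are verified
against exhaustive subset enumeration for small universes.

## Readout quantification

- **Tail gating** uses the order statistics directly: with k = ⌊q·n⌋, the
  low bin is every event strictly below the (k+1)-th smallest ratio and
  the high bin strictly above the (k+1)-th largest. Distinct ratios give
  exactly k events per bin; a tie group spanning a cut stays whole in the
  middle, so an all-tied sample yields two empty bins with a warning
  rather than an arbitrary split.
- **Integrated calcium activity** is the per-sample *median* red/green
  ratio (robust to the long-tailed ratio distribution), summarized as
  mean ± SEM *over biological samples* — never over cells — and reported
  relative to a reference condition (reference ≡ 1; invariant to any
  global intensity rescaling). Events with green ≤ 0 are dropped and
  counted.
- **ΔF/F0**: F₀ is the baseline-window mean (cells with F₀ ≤ 0 excluded
  with a reason); the peak is the post-stimulation maximum, with the
  window running to the end of the trace by default because the emulated
  transients decay slowly. For noisy traces the raw maximum is biased
  upward by extreme-value selection (≈ +7% at SNR 10 over 120-frame
  traces); an optional Savitzky–Golay pre-smoothing (polyorder 2, window
  ≈ ⅓ of the decay constant; 11 frames for the default transient) brings
  the bias to < 1% while the unsmoothed default keeps noiseless traces
  exact.
- **4PL fits** minimize least squares on
  r(x) = bottom + (top − bottom)/(1 + (EC50/x)^hill) with EC50 on the log
  scale, bottom ≥ 0 and top ≥ bottom by parameterization (bottom + span),
  and five deterministic EC50 initializations spread across the dose
  range; the best SSE wins, the convergence flag is honest, and hill < 0
  is flagged rather than hidden. Noiseless data is recovered to ≤ 10⁻⁶
  relative error; at 8 two-fold dilutions × 3 replicates with noise at 5%
  of the range, the Monte-Carlo mean EC50 is within a few percent of
  truth while single fits scatter ~14% — dose–response precision at that
  noise is information-limited, not an optimizer artifact.
- **ΔΔCt**: relative expression 2^(−ΔΔCt) against a reference gene
  (default Gapdh) and control condition; replicate groups with Ct SD >
  0.5 cycles are flagged. The inversion of a forward-simulated fold
  change is exact in the noiseless limit.
- **Relative secretion**: per-well fold of the reference-condition mean,
  summarized mean ± SEM over wells; scale-invariant. Whether "relative"
  values normalize to an NTC/vehicle mean or another baseline is
  configurable (reference condition argument), defaulting to the
  control-condition mean.

## What the simulator does and does not emulate

It reproduces the *statistical* structure that matters for the pipeline:
planted effect directions and magnitudes, guide-efficacy heterogeneity,
coverage and depth bookkeeping, sorting-gate geometry, fitness dropout,
and overdispersed counts. It does not emulate UV-dose photophysics,
puromycin selection kinetics, PCR chimeras, guide-specific off-target
effects, correlated biological replicates, or spectral/debris artifacts in
flow data (event tables arrive pre-gated). Passing tests therefore show
that the statistics behave correctly under a faithful sampling model —
not that any particular biological hit list is reproduced; real screens
add systematic noise sources the null model does not contain.

## Numerical and design choices

- Pseudocount 1 (CPM space) before logs; all-zero sample columns are
  errors, not silently dropped.
- Replicates: per-replicate log ratios averaged when bins pair by
  replicate number; otherwise frequencies are averaged per role first.
- Counting matches the forward strand at a fixed offset (auto-detected by
  scanning the first 1,000 reads for the exact-match-maximizing offset);
  under `one_mismatch`, the unique minimum-distance protospacer within
  Hamming radius 1 wins and ties are unmapped; quality scores are
  ignored. The fast hash matcher is validated against an exhaustive
  all-pairs Hamming oracle.
- Problem sizes in the test suite and acceptance script (e.g. 20 null
  screens at 500 genes, one 2,000-gene recovery screen, 10⁴-read counting
  oracles) are chosen so the whole validation runs in well under a minute
  per component on a laptop-class single core while keeping Monte-Carlo
  error comfortably inside the asserted margins.
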