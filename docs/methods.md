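# Methods

## Objectives

A channel histogram has L = 256 bins with probabilities `p_j`. K strictly
increasing integer thresholds in [1, 255] induce K+1 half-open classes
`[0, t_1), [t_1, t_2), …, [t_K, 256)`.

**Kapur entropy** sums the Shannon entropies (natural log, so fitness is in
nats) of the normalized within-class distributions. Empty bins contribute 0
via the `0·ln 0 := 0` convention, and an entirely empty class contributes 0;
this keeps the objective finite everywhere and makes it non-decreasing in K
(adding a threshold can always be undone by an empty class). The fitness is
bounded by `(K+1)·ln 256`.

**Otsu between-class variance** is `Σ_i ω_i (μ_i − μ_T)²` with the same
empty-class convention; it is bounded by the total histogram variance.

Both are evaluated from three prefix-sum arrays (`Σp`, `Σ p ln p`, `Σ j p`),
giving O(K) per evaluation after O(L) setup — the per-class entropy over
bins [lo, hi) is `ln ω − s/ω` with `ω` and `s` read off the prefix sums.

**Exhaustive oracle.** `brute_force_optimum` enumerates every threshold
vector for K ≤ 3 using the same prefix tables, vectorized over the trailing
threshold(s), and returns the lexicographically smallest maximizer (ties
broken by strict improvement in lexicographic enumeration order). We
enumerate the full [1, 255] range rather than only the occupied-bin span:
restriction would be faster but changes which of the tied maximizers is
lexicographically first on degenerate histograms, and full-range
vectorized enumeration is already fast (≈0.2 s at K = 3). The reported
fitness is recomputed through the scalar evaluation path so oracle and
search are compared on identical arithmetic.

## Search

Agents live in continuous [1, 255]^K. Decoding sorts the coordinates,
rounds half-up, clips to [1, 255], pushes duplicate values upward and spills
downward where 255 is reached — the standard repair that keeps every
decoded vector a valid threshold combination. Objective values are memoized
by decoded integer tuple; the memo cannot change results, only skip
re-evaluations.

**WOA.** Per agent per iteration a scalar `p ~ U[0,1)` picks the spiral
branch (`p ≥ 0.5`) with `l ~ U[−1,1]` and spiral shape `b = 1` (the
literature gives the spiral constant no value; 1 is the conventional
choice), otherwise scalars `A = 2ar − a` and `C = 2r′` are drawn fresh and
`|A| < 1` selects encircling the best-so-far solution versus searching
around a uniformly drawn agent. `a = 2 − 2t/t_max` decays linearly, so `A`
is confined to [−1, 1] from iteration `t_max/2` on — the point where plain
WOA loses its global-search branch. Positions are clamped to the bounds
after every move.

**DE.** rand/1/bin with SF = 0.5 and CR = 0.9; partners `r1, r2, r3` are
sampled without replacement from the population excluding the target.
Selection is greedy *for maximization* (the textbook statement is for
minimization): the trial replaces the target only when strictly better, so
ties keep the incumbent and a constant landscape leaves the population
fixed.

**Hybrid routing.** Each generation the population mean fitness f̄ is
computed before anyone moves; agents with `f_i > f̄` take a DE step, the
rest a WOA step. Routing is per agent (not per coordinate). Generations are
synchronous: moves read a snapshot of positions, fitness and the
best-so-far attractor taken at the generation start, which makes runs
independent of agent order and reproducible from a single seed. A
consequence worth noting: when all agents tie, every `f_i ≤ f̄`, so only
WOA moves fire.

Defaults are 30 agents and 500 generations — the conventional benchmark
budget for this method family — with one RNG stream per run. Best-so-far
fitness is recorded per generation, so convergence histories are
non-decreasing by construction.

## Segmentation

RGB images are thresholded channel by channel (channel c uses seed
`random_state + c`, so one seed fixes a whole run); the reported total
fitness is the per-channel sum, with per-channel values always retained.
Reconstruction replaces each pixel by the *rounded class-mean* gray level of
its class. The rule is not canonical in the literature — midpoints of the
threshold interval are an alternative — but class means minimize the
per-class squared error, which is the quantity PSNR then measures, and the
rounded mean stays inside its class, making reconstruction idempotent.
Segmented channels therefore contain at most K+1 distinct values. Only
8-bit inputs are accepted (16-bit images are rejected rather than rescaled).

## Quality measures

- **PSNR** `= 10 log10(255²/MSE)`, MSE pooled over all pixels and channels;
  identical images report `+inf` (serialized as `inf`), never an exception.
- **SSIM** uses the standard local formulation — 11×11 Gaussian window,
  σ = 1.5, K1 = 0.01, K2 = 0.03, L = 255 — via scikit-image, averaged over
  channels for RGB. A `mode="global"` switch evaluates the same formula
  once on whole-image moments; it exists because the single-formula variant
  is the one that admits closed-form checks (e.g. constant-0 vs constant-255
  gives exactly `c1/(255² + c1)`).
- **FSIM** is implemented in-package (no pre-installed library provides it):
  phase congruency from a log-Gabor bank (4 scales × 4 orientations, minimum
  wavelength 6, scale multiplier 2, σ_onf 0.55, angular spread π/4/1.2),
  computed as summed orientation energy over summed amplitude; gradients by
  the Scharr operator; similarity constants T1 = 0.85, T2 = 160, exponents
  α = β = 1; RGB scored on luminance 0.299R + 0.587G + 0.114B. Images with
  a side below 16 pixels are rejected (below the filter-bank support).
  Identical images score exactly 1 because both similarity maps collapse
  to 1.
- **Fitness STD** is the sample standard deviation (n−1 denominator) over
  repeated runs; it requires at least two values.

Windowed SSIM and FSIM are local-structure measures and are deliberately
*not* invariant under row shuffling of both images; the global SSIM variant
and PSNR are.

## Statistical comparisons

The rank-sum test reports the midrank sum of the first sample, with an
exact p-value (full enumeration) when both samples have fewer than 10
observations without ties, and the continuity-corrected normal
approximation otherwise; two-sided at α = 0.05, and the `h` flag is
`p < 0.05`. The Friedman test ranks methods within each (image, K, run)
block with midranks and uses the tie-corrected chi-square
`(k−1)[Σ_j R_j² − B²k(k+1)²/4]/[A − Bk(k+1)²/4]` (A = sum of squared
ranks), which reduces to the classical statistic without ties and supports
k = 2 methods.

## Synthetic fixtures

`generate_image` draws pixels i.i.d. from a Gaussian mixture over [0, 255]
(rounded half-up, clipped), reproducing the one property of the real
benchmark images — natural, satellite and MR — that thresholding exercises:
a controlled multimodal histogram. `random_mixture` fixes the "realistic"
profile used throughout the tests: 2–4 modes at least 40 gray levels apart
in [20, 235], standard deviations 8–16, weights within a 3:1 ratio, 128×128
pixels. What the generator does *not* emulate is spatial structure — pixels
are exchangeable, there are no edges, textures or smooth regions — so
passing tests validate histogram-domain behavior (threshold placement,
fitness, reconstruction error) but say nothing about spatially aware
segmentation quality on real scenes; SSIM/FSIM values on these fixtures
exercise the metric code rather than perceptual claims.

Noise corruption adds `255·n` with `n ~ Normal(mean, variance)` on the unit
intensity scale — so the protocol's variance ladder
{0.00625, 0.0125, 0.025, 0.05, 0.1} means noise SDs of 8%–32% of the
intensity range — then rounds half-up and clips (no wrapping). The noise
mean defaults to 0. Variance 0 returns the input unchanged.

## Experiment harness

`run_experiment` executes every (image, K, objective, algorithm) cell for
`n_runs` repetitions with run seeds `base_seed + run index`, records
fitness/PSNR/SSIM/FSIM per run, and aggregates means and sample STD per
cell. Outputs are plain CSV and a rerun of the same spec is bit-identical.
Rank-sum tables pair the baseline against each competitor on matched
(image, K, objective, run) cells pooled across the campaign; Friedman
tables use (image, objective, run) blocks per K.

## Problem sizes in tests

The bundled test and acceptance protocols use 128×128 fixtures, 21
histograms for the enumeration-oracle comparison (K ≤ 3, 30 agents, 200
generations), and 12 images at K = 12 under the full 30×500 budget for the
hybrid-versus-WOA comparison — sizes chosen so the whole suite documents
the method's behavior in minutes while keeping the search budgets at their
conventional values where the claim depends on them.

## Known limitations

- Phase congruency follows the common log-Gabor construction but is not a
  bit-exact port of any particular reference implementation; FSIM values
  are comparable within this package, not across implementations.
- Kapur's criterion on near-degenerate histograms (e.g. two spikes) can
  prefer *not* separating well-separated masses at K = 1 — the entropy of a
  merged two-point class exceeds the zero entropy of two singleton classes.
  This is a property of the criterion, not a search failure; Otsu separates
  such histograms correctly.
- The brute-force oracle is limited to K ≤ 3; higher-K claims are
  supported by paired comparisons between searches, not by certified
  optima.
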