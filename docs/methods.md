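# Methods

This note documents the statistical model behind each stage of the
pipeline, the defaults and why they were chosen, what the simulator does
and does not emulate, and the numerical conventions.

## Rhythm detection

Each gene × experiment series is fit by fixed-period cosinor regression:
ordinary least squares of y on {1, cos ωt, sin ωt} with ω = 2π/24 h⁻¹.
The period is fixed at exactly 24 h because the data the pipeline targets
are entrained light:dark time courses; no period scan is performed.
Replicates enter as independent observations at their Zeitgeber time —
no averaging — which preserves residual degrees of freedom. Significance is
the F-test of the two harmonic coefficients against the intercept-only
model, (2, n−3) df. Two degenerate limits are handled explicitly: a
constant series returns amplitude 0 and p = 1, and an exactly
noise-free series returns p = 0 rather than dividing by a zero residual
sum of squares.

The regression input is log2(TPM+1) by default (`log_transform=False`
fits raw TPM). The log transform stabilizes the multiplicative
mean–variance relationship of RNA-seq abundances and makes amplitudes
interpretable as log2 fold-changes about the mesor; the +1 offset keeps
zeros finite at the cost of compressing very low-expressed genes — which
the median-TPM filter removes anyway.

## The consensus criterion and its analytic FDR

A gene is called cycling when p < 0.1 in both experiments *and* the two
phase estimates agree within 3 h of circular distance. Both inequalities
are strict; the criterion's boundary has measure zero so this choice does
not move the false-positive calculus. Under the no-rhythm null, OLS
p-values are exactly uniform (Gaussian noise) and the two experiments are
independent, and a null gene's fitted phase is uniform on the circle when
the design points are balanced over the cycle — so the chance of passing is
p_thr² · (2·Δφ_thr/24) = 0.1²·(6/24) = 0.0025. Multiplying by the number of
genes tested gives the expected false-discovery count, and dividing that by
the number of detections gives the FDR estimate (capped at 1). The
threshold sweep recomputes detections and this analytic FDR over a grid of
(p, Δφ) thresholds; detection counts are monotone in both thresholds by
construction.

Note the phase-uniformity argument needs only *one* experiment's null
phase to be uniform: the phase-agreement probability is 6/24 whenever the
two estimates are independent and at least one is uniform. This matters
because the two-day uneven sampling scheme makes the null phase estimate
slightly non-uniform; the single-day evenly spaced scheme is exactly
uniform, so the product formula holds for the pair.

## Expression filter

A gene is retained iff, within each experiment separately, its median TPM
across all samples of a condition (replicates pooled) exceeds 5 strictly in
at least one of the two conditions. The per-experiment reading is the
stricter, reproducibility-oriented interpretation of "consistently across
the two experiments"; pooling replicates is the simplest median that uses
every sample. The filter is idempotent and invariant to sample order.

## Circular statistics

All public interfaces use hours on a 24-h circle; radians are internal.
The signed difference Δφ(φ₁, φ₂) = arg(e^{i2πφ₁/24} e^{−i2πφ₂/24})·24/2π
lies in (−12, 12]; positive values are phase advances of φ₁ over φ₂, and
the antipodal boundary is mapped to +12 so the interval is half-open. The
absolute difference min(|φ₁−φ₂|, 24−|φ₁−φ₂|) is the geodesic metric on the
circle and always equals |Δφ|.

* **Circular mean** — argument of the mean unit vector; an antipodal pair
  (zero resultant) is an error, not a silent 0.
* **Circular correlation** — Jammalamadaka–SenGupta coefficient; rotation
  invariant, 1 for a constant shift.
* **Watson–Wheeler test** — the Mardia uniform-scores two-sample test:
  pooled circular ranks (average ranks on ties) mapped to uniform scores,
  W = 2Σ(C_g²+S_g²)/n_g, p from χ² with 2 df. A warning is issued below 10
  observations per sample, where the χ² approximation is poor.
* **Circular median test** — realized as an exact two-sided binomial sign
  test about the hypothesized median: observations strictly on either
  half-circle are counted, boundary observations (at the median or its
  antipode) carry no sign information and are dropped. For a 61-vs-18
  split this gives p = 1.27×10⁻⁶.
* **von Mises mixture** — two components fit by EM on the angles; the
  concentration update inverts A(κ) = I₁(κ)/I₀(κ) with the Best–Fisher
  approximation refined by Newton steps, capped at κ = 10⁴ so point-mass
  components stay finite (the log-density uses exponentially scaled Bessel
  functions and never overflows). Ten seeded restarts are kept by final
  log-likelihood; means are reported in ZT hours sorted ascending.

## Network phase organization

The network is consumed as an undirected two-column edge list; self-loops
and duplicate edges are dropped on load and the analysis runs on the
largest connected component (ties broken by the lexicographically smallest
member). Geodesic distances are unweighted shortest paths; the profile
routine computes them by BFS through the full graph, so paths may pass
through genes that are not cyclers.

For all unordered cycler pairs at distance d ∈ {1..d_max} the absolute
phase difference is collected; each bin's median is the profile statistic
(medians, not means, because |Δφ| per bin is bounded and skewed), and the
medians are regressed on d by OLS with a two-sided t-test on the slope,
df = (#non-empty bins) − 2. d_max defaults to 6: distance bins beyond that
are sparse on pathway-union networks and the regression df of 4 matches
the six-bin design. Empty bins are dropped from the regression and logged,
never imputed.

The permutation null re-places the cycling-gene *set* uniformly without
replacement over all component nodes, keeping the observed phase multiset
attached in fixed order, and recomputes the per-distance medians; 5000
permutations by default, refusing fewer than 100. Because the phase
multiset is fixed, the pairwise |Δφ| values are computed once and only the
distance pattern is resampled. Per distance the 0.025/0.975 null quantiles
are reported along with the add-one two-sided empirical p-value
2·min(r, 1−r), r = (1+#{null ≤ obs})/(n_perm+1), which is never exactly 0
and is super-uniform under the null. The alternative reading of the null —
shuffling phases among the observed cycler positions — conditions on the
observed placement; re-placing the set answers "would any random gene set
of this size look this organized?", which matches the question the profile
asks, and is the implemented default.

Control analyses: two-sample Kolmogorov–Smirnov comparisons of degree
distributions (cyclers vs cyclers, cyclers vs all genes) check that
detected cyclers are not simply hubs, and a one-sided Wilcoxon rank-sum
test of pairwise distances (cyclers vs all pairs) quantifies network
localization.

## The simulator

`simdata` generates what the analysis assumes and nothing more:
log2-expression = baseline + A·cos(2π(t−φ)/24)·1[cycling] + N(0, σ), then
TPM = 2^x − 1 floored at 0. Gene-level truth (flags, phases, amplitudes,
baselines) is a function of the config seed alone, so both experiments see
the same rhythms; only measurement noise is redrawn per experiment ×
condition. Defaults: 5% cyclers per condition, amplitudes uniform on
[0.5, 2] log2 units, baseline N(4, 1.5²) log2-TPM, noise σ = 0.5 log2
units — values chosen to make detection succeed at realistic but not
trivial signal-to-noise for bulk RNA-seq, with per-gene F-tests spanning
the interesting p-value range. Phases follow a two-component von Mises
mixture (peaks ZT 2/20 for the warm condition, ZT 8.5/22 for the cold,
κ = 2) or a unimodal model; genes cycling at both temperatures carry a
built-in 1.9-h phase advance (jitter SD 0.75 h) at 18 °C relative to 25 °C,
so the phase-advance statistics have a known truth to recover.

Sampling schemes mirror the two study arms: V1 is ZT02–ZT24 every 2 h with
two replicates (24 samples); V2 is a two-day design collapsed modulo 24 —
2-hourly single replicates over day 4 (ZT4–22) and day 5 (ZT0–18) plus a
~6-hourly second replicate (27 samples).

What the simulator does **not** emulate: count noise and TPM
renormalization coupling across genes (each gene's noise is independent
log-normal), gene–gene expression correlation, transient dynamics after an
environmental shift (timestamps are treated as steady-state), library-size
or batch effects, and non-sinusoidal waveforms. Passing recovery and
calibration tests therefore demonstrates correctness of the estimators
under the model's own assumptions, not robustness to real-data artifacts.

Network generation is separate (`NetSimConfig`): Watts–Strogatz (default,
connected variant), Barabási–Albert, Erdős–Rényi or path graphs. In
assortative mode the cyclers occupy a breadth-first region grown from a
deterministic root (smallest node label, overridable), with phases
anchor + step·depth + N(0, σ) mod 24, so the profile slope has a known
target; in random mode placements and phases are exchangeable — the null.
The deterministic root makes noiseless constructions exactly reproducible
(on a path graph the median |Δφ| at distance d equals step·d exactly).
One constraint to keep in mind when choosing step sizes: circular phase
differences saturate at 12 h, so once step·depth exceeds ~12 the profile
bends back down; recovery of the step from the slope is only meaningful in
the pre-wrap regime.

The end-to-end bundle generator maps cycling genes onto assortatively
placed nodes by circular phase rank. When the true phase distribution
spans the full circle but the drift field spans less, this rank matching
stretches the effective per-hop step accordingly — the demo configuration
uses a 2 h/hop step on a deep low-rewiring graph so the pre-wrap regime
covers most of the profile.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit seed; the pipeline fans one
global seed out to per-stage child seeds via `numpy.random.SeedSequence`,
so stages re-run in isolation reproduce the full run's results, and two
runs with the same config are byte-identical (timestamps live only in the
manifest). The acceptance script measures the dual-criterion chance-pass
rate on 500,000 simulated null genes — chosen so the binomial relative
error on a probability of 0.0025 is ~3% — and the test suite's
calibration checks use 2000 repetitions (Watson–Wheeler type-I error) and
60 repetitions × 150 permutations (permutation-null super-uniformity),
sizes at which Monte-Carlo error is small compared to the tolerances
asserted.

## Known limitations

* The harmonic F-test assumes Gaussian residuals on the fitted scale;
  heavy-tailed noise inflates the single-experiment false-positive rate,
  which the dual-experiment criterion mitigates but does not remove.
* The analytic FDR treats genes as independent; co-expression would make
  the false-cycler count over-dispersed around its expectation.
* The Watson–Wheeler χ²(2) p-value is asymptotic; below ~10 observations
  per group it is unreliable (a warning is raised).
* The mixture EM can merge components when the true modes are closer than
  their spread; restarts reduce but do not eliminate the risk.
* Geodesic distance ignores edge semantics (activation vs inhibition,
  pathway multiplicity); the profile treats the network as a simple graph.
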