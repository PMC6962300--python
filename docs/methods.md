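# Methods

## Model and procedure

The package treats a subject-level connectome as a symmetric weight matrix
`w_ij` (N×N, zero diagonal) and studies one-step information transfer on the
network obtained by discarding weak connections. All analyses factor into
five stages.

**Thresholding.** The subject-specific cut-off is w_t = ⟨|w|⟩ + n·σ_|w|,
with both statistics computed over the off-diagonal entries. The multiplier
n is the swept parameter: n ≪ 0 retains everything (w_t < 0), large n
disconnects the network. Retention uses the strict inequality |w_ij| > w_t;
ties are dropped. Retained weights keep their signs.

**Ternary transfer.** A stimulus S assigns each node +1 or −1 with
probability p each, 0 otherwise. The response of node j is the classified
weighted input r_j = σ(Σ_{i≠j} w̃_ij s_i), where σ maps the pre-activation
into {+1, 0, −1} using the band [−t*, t*] with t* = max(w_t, 0). Two
conventions here are genuinely open and fixed as follows: the sum runs over
the *thresholded* weights (the thresholded network is the object under
study), and a negative cut-off degenerates to the plain sign rule (the
literal classification cases overlap when w_t < 0; taking t* = 0 removes
the contradictory branch and produces the observed flat response regime at
low thresholds). The model is single-step; responses are never fed back.

**Information.** Pairwise transfer is the plug-in mutual information
m(i,j) = H(s_i) + H(r_j) − H(s_i,r_j) in bits (base 2 throughout),
estimated from the empirical 3×3 state table over the K repeated stimuli.
No bias correction is applied: with the default K = 100 the plug-in value
is itself the quantity of interest, and all comparisons across conditions
share the same K. Averaging excludes i = j: ⟨m(j)⟩ = Σ_{i≠j} m(i,j)/(N−1),
and the network value is the mean of ⟨m(j)⟩ over the N targets. Tiny
negative values from floating-point cancellation (> −10⁻¹²) are clamped to
zero; anything more negative raises, since the plug-in estimator cannot
produce it.

**Energies.** Wiring cost E_W = Σ a_ij counts retained ordered pairs;
Hopfield energy E_H = −Σ r_i w̃_ij r_j is the bias-free signed interaction
energy of a response state; activity cost E_A = Σ |r_i w̃_ij r_j| is its
unsigned counterpart. All three sum over ordered off-diagonal pairs with no
factor ½, so each undirected edge contributes twice and the ratios E_H/E_W
and E_W/E_A are internally consistent. Per condition, E_H and E_A are the
means over the K response states; ratios are formed from batch means and
flagged NaN (never thrown) when a denominator is zero.

**Patterns and structure.** Overlap between two responses is the fraction
of nodes in exactly equal states — silent–silent agreements count, which is
what drives overlap back to 1 on over-thresholded (all-silent) networks —
averaged over all K(K−1)/2 unordered pairs. Topology is summarized by the
largest-component fraction and global transitivity (3·triangles/triples,
not mean local clustering), with ΔC(i) = C(i) − C(i+1) available along an
ascending threshold series. Node strengths ns_i = Σ_j |w̃_ij| are computed
on the thresholded matrix (they must vary with n to be informative along
the sweep).

## Strength-distribution fit

Strengths are modelled by the upper-truncated power law
p(ns) ∝ (ns_max − ns)^γ on [ns_min, ns_max], i.e. a power-function law in
u = ns_max − ns. The fitting procedure is: lower bound fixed at
ns_min = min(ns); for each candidate ns_max on a 50-point grid spanning
(max(ns)·(1+10⁻⁶), max(ns) + 2·range(ns)], the exponent has the closed-form
conditional MLE γ̂ = 1/mean(ln((ns_max−ns_min)/(ns_max−ns_i))) − 1; the
candidate minimizing the two-sided KS distance between the model CDF and
the empirical CDF is selected. The KS statistic is the exact step-function
supremum max_k max(|F(x₍k₎) − k/n|, |F(x₍k₎) − (k−1)/n|). A mean/sd normal
fit to the same sample supplies the comparison KS distance.

This estimator is deterministic, fast, and optimizes the criterion the
analysis reports (KS distance). Its statistical limit is worth stating: the
truncation point is a non-regular parameter whose estimation error shrinks
only like n^(−1/(γ+1)), so for steep exponents (γ = 4) single-sample
estimates of γ carry a standard deviation near 0.2 even at n = 10⁴ — a
Monte-Carlo comparison against the continuous profile MLE shows the same
dispersion, so this is an information limit, not an estimator defect.
Recovery checks therefore average over replicate draws.

## Synthetic data

Three generators define the study conditions:

- **Null ensemble** — symmetric matrices with i.i.d. uniform [−1, 1]
  weights, zero diagonal; default N = 177, 1,000 matrices. Matrix k draws
  from an independent stream keyed (seed, k), so subsets are reproducible.
- **Factor model** — node series x_i(t) = a_i g(t) + b_i f_c(i)(t) + ε_i(t)
  with a standard-normal global signal loading a_i = 0.8 on a random 10% of
  nodes (hubs, a_i = 0 elsewhere), four equal communities with loading
  b_i = 0.5, unit-sd noise, T = 200 time points, N = 120; the output is the
  Pearson correlation matrix. The hub nodes share the global factor, so
  their correlations — and hence node strengths — are systematically
  elevated, producing the right-skewed strength distribution characteristic
  of empirical connectomes. These defaults are fixed in the parameter
  dataclass so every test and example runs the same conditions.
- **Strength sampler** — exact inverse-CDF draws from the truncated power
  law for estimator-recovery tests: u = u_max·v^(1/(γ+1)), ns = ns_max − u.

What the factor model does *not* emulate: spatial embedding and
distance-dependent connectivity, subject-level heterogeneity beyond the
seed, negative-correlation structure (anticorrelated networks), and
measurement artifacts. Passing sweep tests on it therefore demonstrates
that the pipeline's phenomenology (interior MI maximum, overlap minimum,
percolation with threshold, MI–overlap trade-off) emerges from hub/community
correlation structure alone — not that empirical matrices will place those
extrema at the same thresholds.

## Numerical and design choices

- Diagonals are zeroed on ingestion (self-correlations are artifacts) and
  excluded from every statistic; near-symmetric input is symmetrized by
  averaging with a warning, asymmetry beyond 10⁻⁶ being a data problem the
  caller should know about but not a fatal one.
- σ_|w| is the sample standard deviation (ddof = 1) over all N(N−1) ordered
  off-diagonal entries; at connectome sizes the distinction from the
  population form is ~10⁻⁵ relative but fixing it makes results
  bit-reproducible.
- Stimulus streams are keyed deterministically by (root seed, subject
  index, threshold index, p index), so any sweep cell can be regenerated in
  isolation and identical configurations give bit-identical tables.
- Aggregation computes per-subject metrics first, then across-subject mean
  and sample sd per (n, p) condition; correlation analyses operate on these
  condition-level means, mirroring how mean curves are compared across
  quantities. Degenerate cases (single subject, zero variance, empty
  network, all-silent batch) yield NaN-flagged fields rather than raising.
- The sweep's strength fit is skipped with NaN outputs when a condition
  leaves fewer than 10 distinct strengths (heavily over-thresholded
  networks).
- Default grid n ∈ [−2, 2] in steps of 0.2, p ∈ {0.1, 0.05, 0.01},
  K = 100: p = 0.05 maximizes transfer and is the default focus; K = 100
  matches the repeated-stimulus design the plug-in MI is calibrated to.

## Problem sizes

Tests and examples run at sizes chosen to make Monte-Carlo error negligible
relative to the asserted effects while keeping the suite quick: the null
ensemble at its full 1,000 × (N = 177) scale (the cancellation check takes
a few seconds), synthetic cohorts of 5–20 factor-model subjects for sweep
phenomenology, 10⁴-sample draws × 5 replicates for estimator recovery, and
exhaustive ternary enumeration (3^N states) for oracle equivalence at
N ≤ 6.

## Known limitations

- The MI plateau around its maximum is flat (≈3% over several grid steps on
  factor-model cohorts), so the *location* of the maximum is far less
  stable than its existence; analyses that need the peak position should
  report the plateau, not a single n.
- Plug-in MI at K = 100 is biased upward by state-table sparsity; values
  are comparable across conditions at fixed K but not across different K.
- The truncated-power-law exponent is weakly identified for steep γ (see
  above); fitted γ along a sweep is noisy wherever networks are sparse.
- One-step transfer ignores recurrent dynamics; all energies are
  interaction terms of the instantaneous state, not metabolic quantities.
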