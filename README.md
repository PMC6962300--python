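# connectoflux

Information-transfer analysis of weighted brain connectivity networks.

Resting-state fMRI and DTI connectomes arrive as symmetric N×N weight
matrices `w_ij` (inter-regional correlations or tract strengths). This
package asks how much information such a network can pass in one step, what
that transfer costs energetically, and how both depend on which connections
are kept. It is aimed at researchers analysing subject-level connectivity
matrices (e.g. the plain-text matrix dumps distributed by connectome
databases) or studying the same questions on synthetic ensembles.

## Model

Each subject's network is thresholded with the subject-specific cut-off

    w_t = ⟨|w|⟩ + n · σ_|w|

keeping connections with |w_ij| > w_t (strict). Random ternary stimuli
S ∈ {−1, 0, +1}^N — each node +1 or −1 with probability p, silent otherwise
— are propagated one step:

    r_j = σ( Σ_{i≠j} w̃_ij s_i ),   σ: +1 above t*, −1 below −t*, else 0,

with w̃ the thresholded weights and t* = max(w_t, 0). Over K repeated
stimuli the package measures, per (subject, n, p) condition:

- **mutual information** m(i,j) = H(s_i) + H(r_j) − H(s_i, r_j) (plug-in,
  bits), averaged as ⟨m(j)⟩ = Σ_i m(i,j)/(N−1) and m = Σ_j ⟨m(j)⟩/N;
- **wiring cost** E_W = Σ a_ij, **Hopfield energy** E_H = −Σ r_i w̃_ij r_j
  (bias-free), **activity cost** E_A = Σ |r_i w̃_ij r_j|, plus the
  normalized E_H/E_W and E_W/E_A;
- **pattern overlap** h(j,j′) = Σ_i π(r_i^j, r_i^j′)/N averaged over all
  response pairs (1 − normalized Hamming distance);
- **topology**: largest-component fraction and transitivity C;
- **node strengths** ns_i = Σ_j |w̃_ij| with the upper-truncated power-law
  fit p(ns) ∝ (ns_max − ns)^γ, scored by Kolmogorov–Smirnov distance
  D = max|p_e − p_c| against a normal-fit baseline.

A synthetic-data module generates every input class the analysis needs:
uniform-weight null matrices on [−1, 1], hub/community-structured
correlation matrices with right-skewed strengths (latent-factor model), and
direct draws from the truncated power law for estimator checks.

## Worked example

`python examples/04_threshold_sweep.py` sweeps n ∈ [−2, 2] on five
hub-structured synthetic subjects at p = 0.05, K = 100:

```
    n  MI (bits)   E_H/E_W  overlap    LCC
 -2.0     0.0210   -0.0295   0.5008  1.000
 +0.0     0.0385   -0.0684   0.3667  1.000
 +0.8     0.0392   -0.0889   0.3371  1.000
 +1.4     0.0396   -0.0723   0.3580  1.000
 +2.0     0.0366   -0.0501   0.5038  0.908

Pearson r(MI, overlap) across thresholds = -0.854
MI maximum at n = +1.4; overlap minimum at n = +0.8
```

Reading the numbers: below n ≈ −1 the cut-off is negative, every connection
survives, responses saturate and MI flattens near 0.021 bits. As the
threshold rises MI climbs to an interior maximum while the normalized
Hopfield energy reaches its minimum and response overlap its minimum in the
same region — the "optimal state". Past it the network fragments (LCC drops
below 1) and over-inactivated, all-zero responses drive overlap back up.
The negative MI–overlap correlation quantifies the trade-off between
transfer efficiency and response redundancy.

The other examples demonstrate single-stimulus propagation
(`01_threshold_and_respond.py`), Hopfield-energy cancellation on the null
ensemble (`02_null_model_energy.py`; mean E_H/E_W ≈ +2.3·10⁻⁴ over 100
matrices) and strength-distribution fitting (`03_strength_distribution_fit.py`;
γ = 2 recovered as 1.85 with KS distance 0.005 vs 0.097 for the normal fit).

A thin CLI mirrors the library for shell workflows:

```
connectoflux generate --out-dir mats --model factor --count 20 --seed 0
connectoflux sweep --matrix-dir mats --p 0.05 --out results.tsv
connectoflux fit --matrix-dir mats --n 0 --out fits.tsv
connectoflux report --results results.tsv --p 0.05 --out correlations.tsv
```

## Not in scope

Raw fMRI/DTI preprocessing and matrix construction, atlas/NIfTI handling,
multi-step avalanche dynamics, Hopfield bias terms, and statistical
inference on the figure-level correlations.
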