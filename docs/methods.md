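# Methods

## Model

The package treats each rhythmically firing unit as a noisy phase oscillator.
With ϕᵢ the unwrapped phase of unit *i* (one cycle = 2π, one spike per
cycle at ϕ ≡ 0 mod 2π),

    dϕᵢ/dt = ωᵢ + Σ_{j≠i} Γᵢⱼ(ϕᵢ − ϕⱼ) + ξᵢ(t),      ⟨ξᵢ(t)ξᵢ(s)⟩ = 2Dᵢ δ(t−s),

each Γᵢⱼ being 2π-periodic and represented by a finite Fourier series with
coefficients in rad/ms. The constant Fourier term of incoming couplings is
inseparable from ωᵢ; the estimator therefore reports the effective
frequency ω̂ᵢ = ωᵢ + Σⱼ a⁽⁰⁾ᵢⱼ and the harmonics m ≥ 1. The model assumes
weak coupling (phase reduction valid), stationarity over the recording, one
spike per cycle, and noise that is white in phase.

For a symmetric pair the phase difference Δϕ obeys dΔϕ/dt = Γ_odd(Δϕ)
= Γ(Δϕ) − Γ(−Δϕ); its zeros with negative slope are the stable locked
states. `stable_phase_differences` brackets all simple zeros by a sign-scan
(default 1024 grid points) refined by bisection to 1e−10 rad, and
classifies them with the *analytic* derivative of the sine series — no
finite-difference tolerance. Zeros whose slope is within 1e−9 of zero are
labelled "degenerate" rather than silently assigned; an identically zero
odd part raises an error (every phase difference neutral). Asymmetric pairs
get the generalized difference function Γᵢⱼ(Δϕ) − Γⱼᵢ(−Δϕ) as a documented
extension.

## Spike-to-phase reconstruction

A spike marks phase zero; between consecutive spikes tₛ, tₛ₊₁ the phase is
linear, ϕ(t) = 2πs + 2π(t−tₛ)/(tₛ₊₁−tₛ). All observed units are sampled on
one global uniform grid anchored at the common analysis window
[max first spike, min last spike] — a shared grid keeps pairwise phase
differences Δϕᵢⱼ(τ) well defined even though the per-interval sample count
(tₛ₊₁−tₛ)/Δt is generally non-integer. Samples outside a unit's spike
support are excluded for all units (phase is undefined there). The default
grid step is the pooled mean inter-spike interval divided by 64, enough to
resolve the within-cycle variation of Δϕ for up to five harmonics.

## Conjugate Bayesian estimation

The regression response is the phase increment δ(τ) = (ϕ(τ+1) − ϕ(τ))/Δt,
modelled as Normal(ω̂ + Σⱼ Γᵢⱼ(Δϕᵢⱼ(τ)), σ²) with σ² ≡ 2D/Δt. The design
row is [1, cos Δϕᵢⱼ, sin Δϕᵢⱼ, cos 2Δϕᵢⱼ, …] per sender, width
P = 1 + 2M(N−1). The joint prior over (coefficients, σ²) is
normal-inverse-gamma, c | σ² ~ N(χ, σ²Σ), σ² ~ InvGamma(α, β); the update

    Σ′ = (Σ⁻¹ + FᵀF)⁻¹,  χ′ = Σ′(Fᵀδ + Σ⁻¹χ),  α′ = α + T/2,
    β′ = β + ½(δᵀδ + χᵀΣ⁻¹χ − χ′ᵀΣ′⁻¹χ′)

and the log evidence (marginal likelihood) are closed-form; both are
validated against a dense grid quadrature of likelihood × prior and the
pointwise identity evidence = likelihood × prior / posterior. All linear
algebra goes through Cholesky factorizations of the precision matrices,
with an escalating diagonal jitter (1e−10…1e−6 of the mean diagonal) before
failing loudly — the design is genuinely near-singular when the network
synchronizes, and that case must surface, not vanish.

Prior defaults are weakly informative and configurable: χ = 0,
Σ = 10⁶·I (prior scale 10³ per coefficient), α = β = 10⁻³. With these the
posterior mean approaches least squares at large T while evidence
comparisons across harmonic counts remain proper.

### One row per receiver cycle

Linear interpolation makes δ *constant within each inter-spike interval*:
every fine-grid sample inside one receiver cycle repeats the same cycle-
averaged velocity. Feeding those duplicated rows to the update as
independent observations would deflate posterior coefficient SDs by
√(samples per cycle) (≈8 at the default grid) and correspondingly bias the
noise-intensity readout D̂ = E[σ²]·Δt/2 low. `fit_receiver` therefore
collapses the regression to one row per receiver cycle: the response is the
cycle-mean increment and each regressor is the within-cycle average of its
basis function (computed on the fine grid, so no harmonic attenuation from
the averaging window), and Δt in the σ² = 2D/Δt convention becomes the
collapsed row spacing (≈ the receiver's mean ISI). On simulated data this
yields calibrated posterior spreads and recovers D to within a few percent
at 1000 cycles (see the worked example: D̂ = 4.10e−4 vs 4.00e−4 true). The
raw fine-grid mode (`row_mode="grid"`) remains available and is what the
design/regression contracts are tested on.

### Harmonic selection and credible bands

For each receiver the candidate harmonic counts M = 1…5 share one design
built at M = 5; each candidate uses the corresponding column subset, and
the evidence-maximizing M wins (ties toward the smaller M). The posterior
of the linear functional g(Δϕ)ᵀc (the interaction curve at one phase
difference) is a scaled Student-t with 2α degrees of freedom and scale²
= (β/α)·gᵀΣg; `interaction_credible_band` returns pointwise central
intervals (pointwise, not simultaneous, bands).

## Synthetic study conditions

`generate_network` draws directed in-degree-regular graphs (every receiver
has exactly k_in senders, chosen uniformly without replacement), natural
frequencies ωᵢ = (2π/period_mean)(1 + νᵢ) with νᵢ ~ N(0, sigma_rel²)
redrawn while non-positive (preserving oscillator semantics; a distribution
deviation only at implausibly large sigma_rel), and one shared coupling
template on every edge. Templates: `caseA_like` Γ = −s·sin Δϕ (single
stable difference at 0) and `caseB_like` Γ = −0.2s·sin Δϕ − s·sin 2Δϕ
(bistable at 0 and π).

`simulate_phases` integrates the SDE by Euler–Maruyama with default step
h = mean period/1000 (spike-time error far below the estimator's sampling
interval), emitting a spike at the linearly interpolated crossing of each
2π multiple; the inner loop is numba-compiled with a bit-identical numpy
fallback, and all randomness comes from a seeded generator. Units whose
drift is non-positive on more than 5% of steps are flagged and warned as
non-oscillating.

Default conditions: 64 units, k_in = 8, sigma_rel = 0.1, D = 4e−4 rad²/ms,
coupling scale 0.025 rad/ms; desk-scale studies use 8 units/k_in = 3 and
16 units/k_in = 4 at scale 0.05, following the inverse-degree rule
k_in × scale = const (larger networks get proportionally weaker synapses to
keep total input, and hence firing, comparable — exposed as the `n_units`
sweep preset).

**Choice of the frequency scale.** Only dimensionless ratios govern the
dynamics; with the coupling amplitude fixed at 0.05 rad/ms and disorder at
10%, the mean period sets the disorder-to-coupling ratio
sigma_rel·ω₀ / (k_in·s). For the heterogeneous condition to be
*asynchronous* (drifting phase differences — the regime in which spike data
sample all phase relations and the estimator works) that ratio must exceed
~1; at ratio ≪ 1 the network locks globally even with disorder. The package
fixes period_mean = 1.5 ms (ratio ≈ 2–3 for the desk-scale networks),
which reproduces the intended pair of regimes: asynchronous at
sigma_rel = 0.1, globally locked at sigma_rel = 0. Data lengths are
counted in cycles of the population-mean period.

## Evaluation and connectivity inference

* Coefficient L² distance: both interaction functions are zero-padded
  per-harmonic to a common count and the root-sum-of-squared coefficient
  differences is returned (constant terms excluded — they live in ω̂).
  Unmodelled harmonics of the reference are penalized against zero. A
  `sqrt=False` option returns the plain sum of squares.
* Summed power Pᵢⱼ = Σₘ (a⁽ᵐ⁾² + b⁽ᵐ⁾²) of each estimated interaction
  (posterior-mean coefficients), normalized by the maximum over the
  considered pairs; Otsu's threshold — computed by exhaustive search over
  midpoints of consecutive sorted unique values (exact for the few hundred
  pairs handled here; ties toward the smaller threshold; identical values
  are a surfaced error, never a silent guess) — binarizes them into an
  estimated adjacency.
* MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), diagonal
  excluded, with the standard 0-on-zero-denominator convention (warned).
* Coherence κᵢⱼ = Σ xᵢxⱼ / √(Σxᵢ Σxⱼ) on binned binary spike indicators;
  κ saturates with bin size under synchrony and grows roughly linearly
  under asynchronous firing. The square-root normalizations of κ, the L²
  distance and the MCC are used throughout (they are required for the
  perfect-agreement values 1 to be attained).

## Theoretical interactions from phase response curves

Given a receiver PRC Z(τ) (phase shift per unit perturbation, phase
convention 2π per cycle so that Z·f = 2π/T along the cycle) and a sender
input waveform w·k(t) emitted at the sender's phase zero, the averaged
interaction is Γ(Δϕ) = (1/T)∫₀ᵀ Z(τ)·w·k((τ − ΔϕT/2π) mod T) dτ. The
quadrature integrates in the sender frame so the wrap-point jump of causal
kernels (exponential, bi-exponential — both normalized to unit integral per
period) sits at the interval endpoints, keeping the trapezoid rule second
order; delta kernels reduce analytically to a PRC lookup. A discrete
least-squares Fourier fit (up to harmonic 5) makes the result directly
comparable with estimated interactions via the L² distance, and
`odd_part_scan` flags bifurcations of the stable locked set across firing
periods.

`adjoint_prc` computes Z for user-supplied smooth limit-cycle ODEs: the
cycle is located by long integration plus Poincaré-section period
refinement, the adjoint equation dZ/dt = −J(x(t))ᵀZ is integrated backward
(its periodic solution is the attractor of the backward flow) with
per-period renormalization, and the result is normalized pointwise to
Z·f = 2π/T with phase zero at the section crossing. It is exercised on
analytic oscillators (radial isochron clock) in the tests; conductance-based
neuron models are deliberately out of scope, but any right-hand side with a
Jacobian callback is accepted.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
desk scale: 8-unit (in-degree 3) and 16-unit (in-degree 4) networks, 100 to
1000 cycles of spikes (≈10³–10⁴ spikes per network), 5–10 seeds per study;
the full suite completes in a few minutes on one CPU. Scenario presets
support the larger sweeps (network size, noise, partial observation) at
correspondingly longer runtimes.

## What the generator does and does not emulate

It reproduces the statistical structure the estimator is sensitive to:
frequency heterogeneity, white phase noise, sparse random directed
connectivity, inhibitory-style mono-/bistable coupling, and the
synchronous/asynchronous regime dichotomy. It does *not* emulate
conductance-based membrane dynamics, synaptic kinetics, bursting,
refractoriness, spike-sorting errors, non-stationarity, or heterogeneous
synaptic weights. Passing tests therefore demonstrate correctness of the
method under its own generative assumptions — the regime where phase
reduction holds — not performance on raw electrophysiology.

## Known limitations

* **Near-locked pairs.** Mutually coupled units whose frequency difference
  falls below the pairwise locking threshold (≈2·|b₁|) freeze their phase
  difference. Their interaction estimate then rests on small noise-driven
  excursions: coefficients are attenuated toward the identified local
  value/slope combination, and because the within-cycle interpolation error
  is systematic there, the posterior is locally overconfident — such edges
  can sit several posterior SDs from truth, and their reduced power
  occasionally costs a false negative in connectivity inference even at
  1000 cycles. With Gaussian frequency disorder a fraction
  (≈13% at the desk-scale conditions) of edges is always in this regime;
  this is the same frozen-phase-difference limit that makes the fully
  synchronized (sigma_rel = 0, D = 0) condition fail outright, and it sets
  the realistic ceiling of the summed-power/Otsu inference between MCC
  ≈ 0.95 and 1 per network at 1000 cycles.
* **Sender frequency degeneracy.** Two *senders* whose frequencies nearly
  coincide (locked to each other, or simply drifting together) present
  almost-collinear regressor columns to a common receiver; the fit then
  splits the true coupling between them — attenuating the true edge and
  raising a spurious one — even when both drift rapidly relative to the
  receiver. Only a sparsity-promoting prior could disambiguate this, which
  is out of scope here.
* **Interpolation bias.** Linear phase interpolation discards within-cycle
  velocity modulation; what remains identifiable is the cycle-averaged
  dynamics. Biases scale with (coupling strength)/(ω) and vanish in the
  weak-coupling limit.
* **D̂ convention.** D̂ = E[σ²]·Δt/2 is meaningful only with Δt equal to the
  spacing of the rows actually used (the per-cycle collapse sets this
  automatically); with duplicated fine-grid rows the same formula
  underestimates D by the duplication factor.
* **Partial observation.** Unobserved senders are simply absent regressors;
  their influence is absorbed into ω̂, D̂ and (spuriously) observed senders'
  couplings. The subset scenario quantifies, but does not correct, this.
* **No sparsity prior.** Couplings are estimated densely; regularization
  (e.g. group lasso across a sender's harmonics) is out of scope.
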