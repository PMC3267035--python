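# Methods

## Scientific problem

Auditory information can reach the amygdala two ways: indirectly, relayed
through auditory thalamus (MGB) and primary auditory cortex (A1), or
directly through a monosynaptic thalamo-amygdala projection.  Whether the
direct ("low") route contributes functionally to evoked responses in
humans is a model-comparison question: given trial-averaged MEG evoked
fields, is the group data better explained by an effective-connectivity
network that includes the direct MGB→AMY link (dual-route model, **CS**)
or by one restricted to the cortical relay (**C**)?  Because the putative
advantage of the direct route is speed, the comparison is run over an
*increasing peristimulus window* — fitting both models to the data in
[0, T] for T = 50, 60, …, 250 ms — so that evidence can be localised in
time: a fast subcortical route should matter most for early windows.

This package implements that entire inference chain on synthetic data with
known ground truth: network definition, neural-mass simulation, a synthetic
MEG forward model, multi-subject dataset generation, variational-Laplace
inversion, random-effects Bayesian model selection (RFX-BMS), and the
window-sweep orchestration with early/late epoch summaries.

## Network models

Both architectures are bilateral six-node networks, {MGB, A1, AMY} × {L, R},
with no interhemispheric connections (hemispheres are treated as
non-interacting; nothing in the hypothesis space distinguishes them).
Per hemisphere, CS has forward connections MGB→A1, A1→AMY, MGB→AMY and
backward connections A1→MGB, AMY→A1; C is CS minus the two MGB→AMY links.
Backward connections are kept in *both* models so the contrast isolates the
direct subcortical link; a `include_backward` switch builds feed-forward
variants.  Five validation models replace the amygdala with other plausible
bilateral sources — hippocampus (HIPP), a second A1-adjacent pair (A1plus),
inferior colliculus (IC), superior temporal gyrus (STG), and STG without
its A1→STG forward afferents (STG_nf; the direct MGB→STG link remains, so
the network stays forward-reachable — the removal is recorded in the model's
`notes`).

Extrinsic conduction delays are 16 ms, except the direct thalamic
projections (MGB→AMY and its substitutes), which get 8 ms: the anatomical
rationale of the subcortical route is that it is monosynaptic and fast, and
an undifferentiated delay would suppress exactly the latency advantage the
hypothesis space is about.

## Source dynamics

Each source is a three-subpopulation convolution-style neural mass (spiny
stellate, pyramidal, inhibitory interneurons).  Every synaptic channel
obeys the critically damped kernel

    x'' = (H/τ)·inflow − (2/τ)·x' − x/τ²,

with excitatory (H_e = 4 mV, τ_e = 4 ms) and inhibitory
(H_i = 32 mV, τ_i = 16 ms) parameters.  Inflows combine
sigmoid-transformed firing of afferent populations: forward afferents
target the stellate population, backward afferents the pyramidal and
inhibitory populations, and intrinsic loops are closed by couplings
γ₁..γ₄ = (50, 40, 12, 12).  The firing sigmoid
S(v) = s_max·[σ(r(v−v₀)) − σ(−r·v₀)] (r = 0.56 /mV, v₀ = 6 mV) is centred
so the resting state is an *exact* fixed point, and scaled by
s_max = 0.012 — the usual rate-constant convention that expresses
population output in rate units per millisecond.  Without this scale the
γ values above sit far outside the linearly stable regime (small-signal
loop gain ≈ 170); with it, worst-case loop gains stay below one and
responses are damped mV-scale transients.  Extrinsic coupling strengths
are `base·exp(log-gain)` with forward base 64, backward base 32; the
log-gains are the estimable connectivity parameters.

Exogenous drive enters at both MGB nodes as a gamma bump (onset 0 ms, peak
16 ms, dispersion 8 ms).  Integration is fixed-step classical RK4
(default dt = 1 ms) with all delayed quantities read from a history buffer
by linear interpolation; per-node output is pyramidal depolarization
scaled by a per-region output gain.  Correctness checks: rest stability to
machine precision over 1 s, and step-halving changes the output by < 1%
relative RMS.

At prior-mean parameters these choices produce MGB activity peaking near
40 ms, A1 near 75 ms, and — only when the direct route is present —
amygdala activity onsetting before 50 ms; without it, amygdala activity
begins only after ~75 ms and peaks past 100 ms.  That latency dissociation
is asserted as an ordering across jittered parameter draws, not as a
specific millisecond value.

## Synthetic forward model

Sensors are 64 points on the upper hemisphere of a helmet at radius 1.25
(relative to a unit head sphere — MEG sensors stand off the scalp).
Sources sit at region-specific eccentricities
(A1 0.85, STG 0.90, A1X 0.85, AMY 0.55, HIPP 0.45, IC 0.35, MGB 0.30) with
tangential orientations (seeded small jitter).  Gains follow a
dipole-in-a-sphere-flavoured form: tangential-dipole angular pattern,
inverse-square field decay with distance, and explicit radial attenuation
`eccentricity**depth_power` (default 1).  This is a stand-in, not a head
model; consequently only *orderings* of the relative-sensitivity statistic
(100 × RMS column norm of a region / RMS column norm of A1) are
meaningful.  On the packaged geometry: HIPP ≈ 27% < AMY ≈ 35% < A1 = 100%
< STG ≈ 119%, the qualitative ordering expected of real whole-head MEG,
which reports substantially milder depth penalties than a bare
inverse-cube synthetic field would give — the reason the defaults use
sensor standoff and inverse-square decay.

## Synthetic study

The generator emulates a 12-subject auditory oddball study in an emotional
face context: standards (1000 Hz) and deviants (1100 Hz) with 90%/10%
probability, 70 ms tones every 700 ms, contexts neutral/happy/fearful,
giving 6 evoked averages per subject over [0, 250] ms at a 4 ms
observation grid (63 samples).  Condition effects are input-amplitude
multipliers only: standards 1.0 regardless of context; deviants
1.5 × (1.0, 1.1, 1.2) for neutral/happy/fearful — a surprise boost graded
by emotional salience.  Per-subject connectivity jitters the prior-mean
log-gains with sd 0.125; the jitter stream is keyed per connection so that
nested architectures generated from the same seed share all common
randomness (their datasets then differ only through the extra pathway's
dynamics).

The ground-truth dual-route datasets add +0.8 to the MGB→AMY log-gains
(the "early-route regime"): a direct route strong enough that amygdala
activity onsets near 38 ms and carries a clear early sensor footprint.
With a weak direct route the cortical-only model can mimic the data by
implausibly shortening the stimulus latency, and the early-window
comparison loses its discriminative point.

Sensor noise on an evoked average is white with sd = noise_sd/√n_trials;
per-context trial counts default to 900 standards / 100 deviants (the
source study does not report counts; these are config values).  The
default single-trial sd of 1.0 gives deviant-average amplitude SNR ≈ 8 —
realistic for averaged evoked fields.  Not emulated: spatially correlated
sensor noise, trial-level variability, artifacts, head-position
differences, or any real anatomy; passing recovery tests therefore shows
the chain is correct and well-calibrated at realistic SNR, not that it
would succeed on arbitrary real recordings.

## Inversion

One (subject, condition, window) fit maximises the Laplace free energy

    F = −(λ/2)‖y − g(θ)‖² + (N/2)ln λ − (N/2)ln 2π
        − ½(θ−θ₀)ᵀΣ₀⁻¹(θ−θ₀) − ½ln|Σ₀| + ½ln|Σ_θ|

over log-space parameters θ and noise precision λ, with
Σ_θ = (λJᵀJ + Σ₀⁻¹)⁻¹ and J the prediction Jacobian by central finite
differences (step 10⁻³; all perturbed simulations run as one batched
integration).  Updates are Gauss–Newton with Levenberg damping; λ is
re-estimated each outer iteration from its stationary condition
λ = N/‖r‖² (capped at 10¹² so noiseless self-consistency fits stay
finite).  A candidate step is evaluated *fully* — including its own
Jacobian and log-determinant — and rejected with increased damping if it
would lower F, so the recorded F trace is non-decreasing by construction.
Convergence: ΔF < 0.01 nats for 3 consecutive iterations, max 64.

Estimable parameters are deliberately few (13–15): connection log-gains
(prior N(0, 1/16)), stimulus log-amplitude (N(0, 1/4)) and log-peak-latency
(N(0, 1/16)), and one output log-gain per region (N(0, 1/16)); all
biophysical constants are fixed.  Absent connections are structurally
zero, never estimated-to-zero, so nested model comparison is structural.
Data are reduced to the top 8 principal spatial modes of each window
before fitting (N counts retained modes × samples); the mode count, priors
and baseline handling are implementation choices — the source study reports
none of them.  Accuracy is the Pearson correlation between predicted and
observed channel×time data.

## Group model selection

Fixed-effects group log Bayes factors sum per-subject evidence
differences.  RFX-BMS places a Dirichlet prior (α₀ = 1) on population
model frequencies and iterates the standard variational updates
(`u_nk ∝ exp(l_nk + ψ(α_k) − ψ(Σα))`, `α = α₀ + Σ u`) to convergence
(tol 10⁻⁶ on α).  Exceedance probabilities are Monte Carlo estimates from
Dir(α) with 10⁵ seeded samples; expected probabilities are α/Σα.  The
headline quantity is the exceedance probability (expected probabilities
are always reported alongside), and epoch summaries take the median across
windows.  The test suite cross-checks the variational posterior against an
independent Gibbs sampler of the same hierarchy; the agreement bound
(0.02) is meaningful in the moderate-evidence regime (per-subject evidence
differences of a few nats) — with very weak evidence the variational
approximation is known to deviate more, which is a property of the scheme,
not of this implementation.  Log Bayes factors are categorised on the
standard bands (weak/positive/strong/very strong at 1, 3, 5 nats).

## Sweep orchestration

`run_sweep` fits every (subject, model) pair per condition and window,
assembles evidence matrices, and runs RFX-BMS per window; failed cells are
recorded and their windows marked incomplete rather than dropped.  Results
cache on disk keyed by a content hash of (model document, window data,
priors, settings), making sweeps resumable and reruns reproducible;
everything derives from the dataset seed and the config's master seed, and
a rerun is byte-identical in all TSV/JSON outputs.  Window T = 200 ms is
excluded from both epochs of the early/late summary (the epochs are
defined by strict inequalities around 200 ms).  Conditions are fitted
separately with no shared parameters, and per-window fits are independent
(no parameter sharing across windows) — the simplest reading of a
per-condition, per-window analysis.

## Problem sizes and numerical choices

Desk-scale defaults keep one inversion at ~1–5 s: 63-sample observation
grid, 8 spatial modes, 1 ms integration step, ≤ 15 free parameters.  The
recovery experiments use 12 subjects and the reduced window grid
{50, 100, 150, 200, 250} ms; validation and unit tests use smaller groups.
Ties in BMS inputs are not rounded; free energies are compared as-is.
Degenerate inputs are rejected explicitly (zero-variance data in the
accuracy statistic, all-zero lead-field columns, sources at the sphere
centre, windows off the 10 ms grid, groups smaller than two subjects).

## Known limitations

* The forward model is synthetic; absolute sensitivity percentages and
  absolute free energies have no physical calibration.
* The variational posterior is a Laplace approximation around a local
  optimum; multistart is not implemented (priors start close enough for
  the desk-scale problems here).
* Condition effects are amplitude-only; coupling modulation by condition
  is out of scope.
* The noise-precision model is a single scalar λ per fit (no
  channel-specific or temporally correlated noise).
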