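# Methods

This note documents the models, the synthetic-data generators, the numerical
choices and the known limitations of `spectraldcm`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. Canonical microcircuit

Four populations — spiny stellate (ss), inhibitory interneurons (ii),
superficial pyramidal (sp), deep pyramidal (dp) — with second-order synaptic
dynamics per population (membrane potential `v_p` in mV, current `i_p`):

    dv_p/dt = i_p
    di_p/dt = m_p/τ_p − 2 i_p/τ_p − v_p/τ_p²

`m_p` sums presynaptic firing through signed couplings:
γ1 ss→ii (+), γ2 dp→ii (+), γ3 ss→sp (+), γ4 sp→ss (−), γ5 ii→ss (−),
γ6 ii→dp (−), and self-modulations γ7 (sp), γ8 (ii), γ9 (ss), γ10 (dp), all
inhibitory. The superficial→deep pyramidal projection of some published
microcircuit variants is deliberately absent: the wiring here is exactly the
ten-coupling set listed above, with cross-pair interaction through γ1
(ss→ii) and γ5 (ii→ss). The firing sigmoid is zero-centred,
`S(v) = 1/(1+e^{−σv}) − ½`, so the origin is an exact fixed point and the
linearization there (slope σ/4) requires no fixed-point search. Exogenous
innovations drive the spiny stellate population only; the observed signal is
`obs_gain · (α_sp v_sp + α_dp v_dp)` plus flat measurement noise.

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| τ (ss, ii, sp, dp) | 4, 16, 8, 28 ms | fast superficial pair, slow deep pair |
| γ1…γ10 | +500, +300, +1500, −1500, −10, −550, −100, −150, −100, −80 | see below |
| σ | 1 mV⁻¹ per population (tieable) | unit slope scale; per-population because prior shifts target population subsets |
| α_sp, α_dp | 1.0, 2.0 | both pyramidal resonances visible in the output |
| innovation PSD | a_u f⁻¹ + c_u, a_u = 0.01, c_u = 0.0025 | pink + white drive; amplitudes small enough that the circuit stays in its linear regime |
| a_n | 10⁻⁷ | noise floor well below the signal band |

Coupling magnitudes are in the hundreds because synaptic gain is folded into
γ — a pair of populations with cross-coupling product P and slopes σ/4
resonates at roughly `ω ≈ sqrt(R/2)` with `R = sqrt(P)·(σ/4)/sqrt(τ_a τ_b)`,
and the resonance only emerges from under the `−1/τ` damping when R is of
order 10⁴–10⁵. At order-1 couplings the circuit is overdamped and
spectrally featureless. The defaults were fixed by a one-off design pass:
the linearized circuit is stable with margin ≈ −6 s⁻¹ and the default
spectrum has two peaks, ~9 Hz (deep pair, theta/alpha) and ~29 Hz
(superficial pair, beta/gamma). The innovation spectrum is written as a
function of frequency in Hz; any other convention only rescales a_u.

### Spectral prediction and its oracle

`predict_psd` evaluates `|C(2πif·I − A)⁻¹B|² S_u(f) + a_n` on the frequency
grid (batched linear solves). `simulate_timeseries` integrates the full
nonlinear system by forward Euler driven by frequency-domain-shaped Gaussian
noise with exactly the innovation PSD, on an internal grid 8× finer than the
output rate: at 1 kHz steps plain Euler under-damps the 250 s⁻¹ synaptic
poles enough to bias the spectrum visibly; at 8 kHz internal steps the Welch
log-PSD of a 200 s simulation agrees with the linear prediction to a
fraction of a percent relative MSE (measured against the variance of the
predicted log spectrum over 2–80 Hz — the scale-free form of "relative"
used throughout). The simulator is the package's independent numerical
oracle for the transfer-function algebra.

## 2. Signal metrics

* **RMS** — whole-recording, after mean subtraction; no sliding window.
* **Event detection** — samples deviating more than `threshold_factor` (4)
  × RMS from the mean; contiguous suprathreshold runs collapse to their
  absolute-peak sample (the rule does not define event extent, so the peak
  is the event); events closer than `min_iei` (15 ms) to the previously
  *kept* event are dropped — the earlier event always wins, making the scan
  order-stable and deterministic.
* **Coastline** — Σ|x[i+1] − x[i]| per non-overlapping window (1 s default).
* **Band power** — Welch (2 s Hann, 50% overlap) integrated over the eight
  standard bands 1–4, 4–8, 8–12, 12–30, 30–50, 50–70, 70–120, 120–180 Hz.
  Welch settings are fixed so the Parseval and concentration tests are
  reproducible.
* **Segment metrics** — six per-second scalars (power, coastline,
  intermittency, coherence, asymmetry, spikiness). These formulas are
  *reconstructions*: the original classifier lives in external acquisition
  software whose definitions are not published. The definitions used here:
  power = mean squared mean-subtracted amplitude; intermittency = fraction
  of 100 ms sub-windows whose coastline exceeds 2× the median; coherence =
  peak normalized autocorrelation at 10–500 ms lags; asymmetry = sample
  skewness; spikiness = max |x − mean| / RMS. Classification is
  nearest-neighbour in library-z-scored 6-metric space; zero-variance
  metrics are dropped from the distance.
* **Synaptic features** — polarity-constrained event detection; amplitude
  relative to a local baseline (median of a 5 ms window ending 2 ms before
  the peak); mono-exponential decay fit of the peak-aligned average event
  from the peak down to 10% of the peak (the tail beyond is
  noise-dominated; the fit window is a documented package choice — the
  empirical "decay time" is reported without a defined window); half-life
  = τ·ln 2; homogeneity = midpoint slope of a logistic fit to the empirical
  amplitude CDF, capped at 10⁶ pA⁻¹ for degenerate (step-like) CDFs and
  flagged.

## 3. Variational Laplace inversion

Data feature: log Welch PSD on the fit grid, default 1–100 Hz at 0.5 Hz
(spanning the named analysis bands below hardware filtering). Observation
model: independent Gaussian error per frequency with one log-precision
hyperparameter h, hyperprior N(0, 1). Parameter prior: λ ~ N(0, 1/16)
diagonal (sd 0.25 per log-scaling parameter) — wide enough to express the
condition effects, tight enough to regularize the four exactly flat
directions of the spectral model (the linearized dynamics depend on γ and σ
only through the products γ_{q→p}·σ_q, so one combination per source
population is data-unidentifiable; the prior resolves it).

One outer iteration: (i) Gauss–Newton step on λ from a central
finite-difference Jacobian (step 10⁻³), damped Levenberg–Marquardt;
(ii) closed-coordinate updates of q(h) (Newton on the concave mh-gradient,
fixed-point for vh); (iii) full free-energy evaluation at the candidate —
F = E_q[log-likelihood] − KL(q(λ)‖p(λ)) − KL(q(h)‖p(h)). A step is accepted
only if F does not decrease (damping ×0.7), otherwise rejected (damping
×2); the accepted-step trajectory is therefore monotone by construction.
Convergence: |ΔF| < 0.01 on 4 consecutive accepted steps, cap 128
iterations, or damping beyond 10¹² (step size collapsed). Unstable proposed
parameterizations (max Re eig ≥ 0) are invalid candidates — rejected with
increased damping, never an exception. If a model's *prior mean* is itself
unstable, the optimizer starts from the nearest feasible point on the
segment toward the origin of λ-space. With the noise precision fixed, the
scheme reproduces the conjugate closed-form log evidence of a
linear-Gaussian model to machine precision (tested to 10⁻³).

Model comparison is fixed-effects: Bayes factors `exp(F_i − F_best)` and
posterior model probabilities as the softmax of F under uniform model
priors. Empirical priors chain *means only* — the next condition's prior
takes the previous posterior's expectations with the base prior's
covariance, so every stage is shrunk by the same amount around the previous
estimate.

## 4. Microscale priors and the 22-model space

Feature contrasts (NMDAR-antibody ÷ control) map to log prior shifts:
amplitude ratio → γ, half-life ratio → τ, CDF-slope ratio → σ, each shift
`Δλ = ln(ratio)` — population parameters scale proportionally to the
single-cell features, the simplest quantitative reading of the
feature-to-parameter mapping. A γ coupling belongs to the population whose
synaptic response it scales (its *target*); τ and σ belong to their own
population.

The model space is one reconstruction among several that match its printed
size: 1 null model (no microscale information) + the 7 non-empty subsets of
{γ, τ, σ} × 3 population subsets (superficial pair ss+sp, deep pair ii+dp,
both) = 22, in a deterministic order (null first, then group subsets ×
populations). It contains the three recoverable named members: the null,
the full model ({γ,τ,σ} × both) and the {γ,σ} × deep-pair model.

## 5. Synthetic data: what it emulates and what it does not

**Synaptic traces** — homogeneous Poisson event times, log-normal
amplitudes (positive support, heavy right tail, as PSC amplitude histograms
show; median 15 pA, log-sd 0.35), unit-peak bi-exponential kernels
(0.8 ms rise, 8 ms decay), white Gaussian baseline noise (2 pA), control
event rate 2 s⁻¹. Ground-truth event times refer to kernel *peaks* (what
detectors report). Condition effects are multiplicative:

| condition | rate | amplitude | decay | amplitude log-sd |
|---|---|---|---|---|
| nmdar_48h | ×0.6 | ×0.8 | ×0.7 | ×0.85 |
| nmdar_7d | ×0.45 | ×0.7 | ×0.7 | ×0.8 |
| any IPSC | ×1 | ×1 | ×1 | ×1 |

These magnitudes preserve the observed effect *directions* (sparser,
smaller, faster EPSCs, more so at 7 days; IPSCs unchanged); they are not
fitted to any recording. The dispersion multiplier encodes the reported
increase in amplitude homogeneity; it matters structurally, because for a
purely rescaled log-normal the CDF-slope ratio is exactly the reciprocal of
the amplitude ratio, which would make the implied γ and σ shifts cancel in
the γ·σ products that the spectra identify. A genuine homogeneity change
breaks that degeneracy — and gives the interictal circuit its net
destabilizing product shift (section 6).

**Field traces** — 1/f^β Gaussian background (β = 1.5, RMS 20 µV) shaped in
the frequency domain, bi-exponential interictal transients at
`spike_amp_factor` (8) × background RMS, and ictal epochs in which the
spike rate is multiplied and a 12–30 Hz band-limited oscillation of
configurable RMS is added — an additive construction that elevates broad
power with the maximum in the beta band.

**State spectra** — model log-PSD at a known parameter triplet plus
i.i.d. Gaussian log-domain noise (sd 0.05 by default), the stand-in for the
empirically measured control / interictal / ictal spectra.

Not emulated: intrinsic-excitability (current-step) physiology,
pharmacological rescue conditions, multi-channel recordings, non-stationary
backgrounds, electrode artifacts. Passing tests therefore demonstrate the
pipeline's internal consistency and its behaviour under the stated
generative assumptions — not performance on real recordings.

## 6. The default state triplet and the headline analysis

The documented default triplet (`synth.default_state_lambdas`):

* **control** — λ = 0 (the baseline circuit, margin ≈ −6 s⁻¹);
* **interictal** — deep-pair γ (γ1, γ2, γ6, γ8, γ10) shifted by ln 0.8 and
  deep-pair σ (σ_ii, σ_dp) by ln(1/(0.8·0.85)) ≈ +0.386 — the nominal
  microscale contrast of the nmdar_48h condition applied in the winning
  {γ,σ} × deep placement. The γ·σ product rises by ≈ +0.16 per deep
  coupling: *hypo-excitation with a homogeneity-driven slope increase nets
  out as a destabilized deep oscillator* (margin ≈ −3 s⁻¹);
* **ictal** — interictal plus the ictogenesis shifts γ8 −0.15, γ2 +0.10
  (reduced interneuron self-modulation, stronger deep-pyramidal drive onto
  interneurons: an excitation–inhibition balance shift inside the deep
  pair), leaving the circuit stable but near-critical (margin ≈ −0.6 s⁻¹).

The grid analysis evaluates λ(e, i) = λ_control + e·Δ_epi + i·Δ_icto on a
21×21 lattice over [0,1]², predicts each spectrum, labels unstable points
and excludes them from maps, classifies the rest by smallest mean-squared
difference of *log-amplitude* spectra (½·log PSD; the paper-style ratio map
also uses log amplitudes, >20 Hz over <8 Hz means) against the three
observed spectra, and computes per-row neighbour MSEs on a log₁₀ scale with
a 10⁻¹² floor. Because the ictogenesis direction acts on the deep pair that
the epileptogenesis shift has already sensitized, the seizure-like
territory is reached at a strictly smaller ictogenicity from the interictal
row than from the control row, and the row-maximum sensitivity is largest
at (or immediately adjacent to — the fitted effect vectors are shrunk
slightly toward the prior, which can move the ridge by one 0.05-wide grid
row) the interictal row. These are the two headline readouts recomputed by
the acceptance script.

## 7. Problem sizes and runtimes

The test suite and acceptance script run the pipeline at sizes chosen to
keep a full run in minutes on one CPU: fit grids of 0.5–2 Hz steps over
1–100 Hz depending on the check (finer grids for the end-to-end
state-space analysis, coarser for the 220-inversion model-recovery sweep),
20 seeds for recovery and audit checks, 10 runs for model recovery, 200 s
for the simulation oracle, and 60 s synthetic patch-clamp recordings
(~100 events each). Thresholds are stated with each test and do not depend
on these sizes.

## 8. Known limitations

* The segment-classifier metric formulas and the composition of the
  22-model space are reconstructions (section 2, 4); only the named members
  and the count of the model space are anchored.
* Spectral non-identifiability of γ vs σ (products only) means those
  effects are separated by priors, not data; model comparison margins
  between placements that differ only within a flat direction are
  correspondingly small.
* Fixed-effects model comparison only; no Bayesian model averaging or
  reduction, no random-effects analysis over animals.
* Single-source model: no conduction delays, no multi-region coupling, no
  laminar forward model.
* The Euler simulator targets spectral agreement in the 2–80 Hz band;
  content near the Nyquist frequency is not trustworthy.
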