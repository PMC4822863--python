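# Model and methods

`pitchstdp` models how a population of spiking "pitch neurons" can learn,
without supervision, to extract the pitch of simple and complex sounds from
auditory-nerve activity. The pipeline has two phases: a functional model of
the auditory periphery that produces tonotopic activity maps (the *place
code* of pitch), and a plastic spiking layer whose synapses are shaped by
spike-timing-dependent plasticity (STDP) until its output spike timing
carries the stimulus periodicity (the *temporal code*).

## Stimuli

All built-in stimuli are mono, 16 kHz, 0.5 s, calibrated to 60 dB SPL under
a fixed full-scale convention (a unit-amplitude sinusoid is defined as
94 dB SPL; the absolute anchor is arbitrary and absorbed by the afferent
rate calibration). The set comprises:

* 29 pure tones on an equal-tempered semitone ladder, G2–B4. The ladder is
  generated as `f_low · 2^(k/12)` with `k = 0 … round(12·log2(f_high/f_low))`,
  so the nominal [98, 493] Hz range yields 29 notes (the top note is B4 =
  493.88 Hz; 493 is its truncation).
* two cascade-formant vowels at every ladder pitch: /ɑ/ (formants 710/1150/
  2700 Hz, bandwidths 40/43/105 Hz) and /i/ (230/2000/3000 Hz, bandwidths
  68/63/129 Hz), synthesized as a glottal impulse train through cascaded
  second-order resonators. Only the cascade branch is modelled — no source
  shaping, no amplitude ramp — because the downstream model consumes only
  the resulting spectro-temporal structure.
* "telephone" variants of all vowels: a sharp high-pass FIR (stopband edge
  300 Hz at ≥80 dB attenuation, passband from 350 Hz within ±1 dB) removes
  the fundamental-frequency region, emulating a telephone line. The filter
  is a Kaiser-window design of 1641 taps — a 50 Hz transition with 80 dB
  stopband at 16 kHz requires on the order of 1600 taps; no order-110 FIR
  can meet these band edges. It is applied with its group delay compensated
  so filtered and unfiltered stimuli stay sample-aligned.

A WAV reader (first channel, polyphase resampling to 16 kHz) admits
external recordings, but nothing in the package depends on them.

## Phase I: auditory periphery

A functional three-stage chain replaces a full phenomenological cochlea —
deliberately the simplest front end that preserves what the learning stage
consumes (tonotopy, phase structure, formant peaks, travelling-wave-like
group delays):

1. middle ear: first-order band-pass, 0.1–6 kHz;
2. cochlear filter bank: 200 fourth-order gammatone filters (`scipy.signal.
   gammatone`, ERB-scaled bandwidths) at characteristic frequencies given by
   the Greenwood position–frequency map `CF(d) = 165.4·(10^(2.1·d/34) − 1)`
   over positions 3–22.9 mm from the apex in 0.1 mm steps (CFs ≈ 88 Hz to
   4.1 kHz);
3. inner-hair-cell stage: half-wave rectification followed by a 1 kHz
   second-order low-pass, clipped at zero.

The **place code** is each channel's temporal mean over a 100 ms window,
normalized to its maximum. The first 50 ms are excluded to avoid filter
onset transients (the window placement within the 0.5 s stimulus is
otherwise immaterial for steady stimuli). For the /ɑ/ vowel the dominant
sub-kHz peak falls at ≈660 Hz (the strongest harmonic under the 710 Hz
formant at F0 = 110 Hz); high-pass filtering suppresses the place code
below 300 Hz to under 5% of the maximum.

Known fidelity gaps of this front end: no level-dependent compression, no
two-tone suppression, no adaptation. These are documented as the largest
approximation in the package.

## Phase II: spikes, network, plasticity

**Afferent spikes.** Each channel drives one afferent modelled as an
inhomogeneous Poisson process whose intensity is the channel's IHC
activity, scaled by a single calibration constant and sitting on a
spontaneous floor:

    λ_j(t) = λ_spont + activity_j(t) · (λ_peak − λ_spont) / max(activity)

with `λ_peak = 1300 /s` interpreted as a *population* intensity (all
fibers innervating one cochlear place pooled) — calibrated once so that the
untrained output layer fires at ≈80 spikes/s on a calibrated 60 dB tone —
and `λ_spont = 0.2·λ_peak = 260 /s`, reflecting the spontaneous-to-driven
ratio of high-spontaneous auditory-nerve fibers.
The spontaneous floor matters for learning: it is the unmodulated
background out of which STDP must select phase-consistent synapses, and
without it pre–post correlations dominate the homeostatic term and the
trained rate never settles. Spikes are drawn by thinning at the per-channel
maximum intensity, exact for the sample-resolution piecewise-constant
envelope; no refractoriness is imposed at this stage (it lives in the
output neurons).

**Output layer.** 29 conductance-based leaky integrate-and-fire neurons,
one per pitch category, each receiving all 200 afferents through plastic
weights `w_ij` and a global 10 ms axonal delay:

    τ_m dV/dt = (V_p − V) + Σ_j w_ij (V_rev − V) Σ_f ε(t − t_j^f − Δ)

with τ_m = 10 ms, V_p = V_r = −65 mV, V_th = −50 mV, V_rev = 0 mV,
t_ref = 1 ms (absolute; V clamped at V_r while conductances evolve).
The EPSC kernel is the double exponential
`ε(t) = (e^(−t/τ_B) − e^(−t/τ_A)) / (τ_B − τ_A)` with τ_A = 0.5 ms,
τ_B = 1 ms, normalized to unit area *on the millisecond timescale* (peak
0.5 at 0.693 ms) — the convention of ms-based spiking simulators, and the
only normalization under which the published weight scale (w_0 = 0.0075,
bounds ±0.2) yields subthreshold single EPSPs summing to a dense drive; a
kernel of unit area in seconds makes every single EPSP suprathreshold and
destabilizes the learning rule.

Integration is exponential Euler at dt = 0.1 ms with the conductance
carried by two auxiliary exponential states (exact for step-binned events,
O(1) per step); halving dt moves no spike time by ≥0.1 ms. Stored weights
may become negative (depressed, "silent" synapses that can recover) but by
default only `max(w, 0)` enters the conductance, since all inputs are
excitatory; a literal mode applying negative conductances exists and raises
a numeric error if the total conductance leaves the integrator's domain of
validity.

**Plasticity.** The pair-based STDP window is

    W(s) =  A_p e^(−s/τ_p)   s > 0   (pre before post)
         = −A_d e^(+s/τ_d)   s < 0

with A_p = 15, τ_p = 1 ms, A_d = 10, τ_d = 5 ms, hence
∫W = A_p τ_p − A_d τ_d = −0.035 s (net depressing, wider toward
depression). A weight update over a learning interval accumulates W over
all pre/post spike pairs (truncated at |s| > 7·max(τ_p, τ_d), error
< 10⁻³ of the window mass) minus a homeostatic term b_j·N_pre with
b_j = ν̄·∫W = −1.05, which pins the trained output rate near ν̄ = 30
spikes/s: for independent trains the expected update is
η·T·ν_j·(ν_i·∫W − b_j) = η·T·∫W·ν_j·(ν_i − ν̄), the rate-based rule with
α = η·T·∫W < 0. Pairing uses synaptic arrival times (t_pre + Δ): plasticity
is driven by synaptic, not axonal, events.

**Training.** Each pitch neuron is trained independently on stimuli of its
own category: repeated 0.5 s presentations with fresh Poisson draws, the
learning rate η = 10⁻⁷ and learning time T = 5000 s jointly rescaled as
(η·k, T/k) with η·T fixed ("desk scale"; the out-of-box default is k = 100,
i.e. 100 presentations per category; `--paper-scale` restores the
literal values). Updates are applied every 25 ms of simulated time with
membrane state carried across update boundaries; the summed update equals
the whole-presentation batch rule (pairs are assigned to the episode of
their post-synaptic spike), but at scaled η a 0.5 s batch step overshoots
the homeostatic fixed point, so the cadence is a numerical-integration
choice, not a change of rule. All randomness flows from one master seed
through `numpy.random.SeedSequence` spawning.

Training moves the rate from the high initial regime (~80 spikes/s at
uniform w_0) to ≈30–34 spikes/s within a few seconds-equivalent, then
differentiates the weights: synapses whose (delayed) arrivals consistently
precede output spikes are potentiated, out-of-phase and background synapses
are silenced. On pure tones the winners concentrate at channels with CF
near the category pitch and the trained neuron phase-locks strongly
(vector strength ≈0.8 at its own F0 versus ≈0.05 untrained). Vowel timbre
spreads power over formant channels whose F0 information is an envelope
modulation; the selection signal is weaker, so vowel training uses a finer
desk scale by default in the experiments (k = 10, 1000 presentations per
category) and reaches vector strength ≈0.2–0.35.

## Temporal pitch code and its readouts

* **Vector strength**: Goldberg–Brown resultant `|Σ exp(i·2π·f·t_k)|/N`,
  phases referenced to presentation onset; analysis intervals of 5 s are
  realized as ten 0.5 s presentations with independent Poisson draws whose
  phases pool coherently. Arranged neurons × stimuli (each entry evaluated
  at the stimulus pitch), trained models show diagonal dominance; the
  untrained model has identical rows (identical uniform weights and shared
  input) and exactly zero diagonal gap.
* **Pooled inter-spike-interval histogram (ISIH)**: first-order intervals
  pooled across the population, 1 ms bins centred on integer ms over
  [0, 50] ms, span-3 moving average (reflection padding), normalized to
  maximum; intervals never cross presentation boundaries. An all-order
  variant is available. The histogram of a trained neuron driven by its
  matched tone is a comb at multiples of the stimulus period; the comb
  spacing (median distance between adjacent smoothed peaks) equals the
  period — 9 ms at 110 Hz. Because homeostasis pins the rate near 30
  spikes/s, the *modal* interval sits at a small multiple of the period
  (~33 ms ≈ the mean interval), and for higher pitches the comb lines
  merge under the 1 ms binning: histogram peaks become fewer and stronger
  as pitch rises, while the mode cannot equal one period for pitches whose
  period is far below the mean interval — a direct consequence of the
  published rate target, documented here because readouts that assume
  mode = period will not hold under these parameters.

## Pitch ranking

A single-layer perceptron (two softmax units over the concatenated pair of
smoothed ISIHs; back-propagation on a single layer reduces to the delta
rule) decides which member of a same-type vowel pair (1–12 semitones apart)
has the higher pitch. Per trial, the 540 eligible (type, pitch, pitch)
combinations are split 3:1 into disjoint train/test sets; 1500 training
pairs (10% held out for validation-based early stopping) and 500 test pairs
are drawn from their respective sets, so test pairs are never seen in
training. Scores are averaged over 20 trials. Inputs are standardized with
training-set statistics — the raw design matrix is too ill-conditioned for
plain gradient descent — and the optimizer runs up to 8000 epochs at
learning rate 0.05 with patience 800, settings chosen so the delta rule
reaches the fit quality of a regularized logistic-regression reference on
the same features. With ISIHs from the vowel-trained model (10
presentations per histogram), scores rise from near-chance at 1 semitone to
≈0.8 at 12 semitones, and high-pass-filtered vowels score no worse than the
originals — the missing-fundamental pitch survives in the temporal code via
formant-envelope locking.

## Desk-scale defaults and problem sizes

Out of the box every experiment is scaled to run on a single CPU in
minutes: η×100 training (100 presentations/category) for tones, η×10 for
vowel/ranking experiments, 5 s analysis intervals, 20 ranking trials. The
test-suite fixtures and `scripts/acceptance.py` use these sizes; the
acceptance script additionally averages its stochastic quantities over
three replicate training runs. `--paper-scale` restores η = 10⁻⁷ and
T = 5000 s per category (cluster-scale if run literally).

## What the synthetic conditions do and do not show

The generator reproduces the study's stimulus set exactly (levels,
durations, ladder, formant parameters, telephone filter) and the
periphery's qualitative structure, but not a phenomenological cochlea's
compression, adaptation or spontaneous-rate diversity; afferent intensities
are population rates with an assumed spontaneous fraction. Passing tests
therefore demonstrate the learning mechanism (homeostasis, phase-selective
potentiation, missing-F0 robustness) under an idealized periphery — not
quantitative agreement with auditory-nerve physiology.

## Numerical choices

dt = 0.1 ms (exponential Euler; convergence verified by dt-halving);
plasticity update cadence 25 ms of simulated time; pair-sum truncation at
±35 ms; ISIH smoothing with reflection padding, plateau ties resolved by
raw counts then toward shorter intervals; peak detection at 10% prominence;
weight clipping to [−0.2, 0.2] with clip counts logged in the learning
trace; silent inputs, empty trains and degenerate windows raise ValueError
rather than returning sentinel values (except vector strength of an empty
train, defined as 0).
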