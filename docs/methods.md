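# Model and methods

## The task

A single cortical-like neuron receives spikes from 2000 afferents
(nominally 1000 excitatory, 1000 inhibitory), all firing as homogeneous
Poisson processes at r = 5 Hz on a 0.1 ms grid (each step fires with
probability r·δt). Three disjoint "temporal communities" of ~500 units own
frozen 100 ms spike templates. A trial interleaves template replays
(patterns chosen with equal probability) with fresh-noise gaps drawn
uniformly from [100, 300] ms. Nothing distinguishes a pattern from noise in
firing rate — only the repetition of the same spike arrangement. Every
transmitted spike is deleted independently with probability p_fail = 0.1,
so the received stream differs from the sent stream at each presentation.
The neuron's job is to develop, within a few presentations, a selective
spiking response to one of the repeated patterns.

## Two-compartment neuron

The soma is a leaky integrate-and-fire unit driven by the dendrite through
`g_cds` (35 nS); the dendrite integrates the afferent conductances and the
soma's influence through `g_csd`. Units are mV / ms / nS / pF throughout,
so currents are in pA and `dV/dt = I/C` needs no conversion factors.

* Spike-trace variant: on threshold crossing (−50 mV) the soma resets to
  −70 mV and integration halts for the 2.5 ms refractory period. Because
  the reset potential sits below the dendritic operating range, the
  resting coupling (`g_csdr` = 23 nS) drains the dendrite after every
  spike. This spike-triggered drain is the variant's main rate brake: it
  costs nothing at rest and scales with activity, which is what keeps the
  sparse fluctuation-driven regime from tipping into sustained tonic
  firing.
* Calcium variants: the soma instead jumps to +40 mV and repolarizes
  through an enlarged leak (150 nS) while synaptic/dendritic input to the
  soma is gated off. During this refractory window the coupling is boosted
  by a double-exponential pulse of amplitude `m_csd` (the bAP strength,
  0.2 ms rise / 2.5 ms decay), so the somatic action-potential waveform
  drives a wave of depolarizing current into the dendrite — the
  backpropagating action potential. The dendrite carries an HVA Ca²⁺
  channel with m²h kinetics (printed rate functions; the removable
  singularity of the activation rate at −27 mV is evaluated by its
  analytic limit) and, in the NMDAR variant, a slow NMDA conductance
  (3.3 / 102.38 ms) on a random 75% of excitatory synapses with the
  Jahr–Stevens magnesium block; 5% of the NMDA current counts as calcium.

Synaptic conductances are peak-normalized double exponentials (AMPA-like
0.5/5 ms, GABA-like 1/10 ms) driven by κ-scaled weight magnitudes; reversal
potentials 0 / −80 mV around a −70 mV leak. A small Gaussian membrane
current noise (ρ = 40 pA·√ms) keeps the neuron responsive from trial
start; without it the model can sit silent for many presentations before
the first threshold crossing.

## The plasticity rule

Each synapse carries an eligibility Δw and a PSP trace; the induced
plasticity is the three-factor product

    PI_i(t) = e(t) · PSP_i(t) · ζ(|w_i|)

* `e(t)` is purely postsynaptic: a fast activity trace minus its own
  running average. Spike-trace form: Y jumps by 1 per somatic spike and
  decays with τ_Y = 20 ms; Ȳ low-pass filters Y with τ_Ȳ = 35 ms;
  e = Y − Ȳ. Calcium form: C integrates φ·I_Ca with relaxation to the
  resting level, and e_c = C − C̄. The short averaging constant makes `e`
  a transient detector: an abrupt response burst produces a large positive
  excursion followed by a negative rebound, whereas a slow drift in firing
  rate produces almost nothing. This is the property that stabilizes the
  rule — gradual population-wide rate creep earns no credit, only
  pattern-locked bursts do.
* `PSP_i` low-pass filters the presynaptic impulses of synapse i with
  τ_p = 7 ms, scaled by the weight magnitude |w_i|. Using the magnitude
  (rather than the signed weight) for both classes means a positive
  excitability transient potentiates coincident excitation *and weakens
  coincident inhibition*, while the negative rebound afterwards reverses
  both. A learned response therefore disinhibits its own input window and
  strengthens inhibition onto whatever follows it — typically rival
  patterns and noise — which is exactly the end state in which the tuned
  pattern's inhibitory conductance has collapsed while rival-pattern
  inhibition has grown. With the literal signed product the opposite
  happens (the tuned pattern's own inhibition strengthens and chokes the
  response); we measured that erosion directly and adopted the magnitude
  convention.
* `ζ(x) = (x/τ_ζ)·exp(1 − x/τ_ζ)` (clipped to [0, 1], root at 0, unit
  peak at τ_ζ = 2.2) lets small weights grow readily and saturates large
  ones, shaping the long-tailed final weight distribution and capping the
  positive feedback of Hebbian growth.

PI is low-pass filtered into the eligibility with τ_Δ = 260 ms, and the
weight integrates the eligibility at η = 2.8 ms⁻¹. The slow eligibility
is load-bearing: it spreads a burst's credit over a quarter second, so the
LTP excursion and its LTD rebound largely cancel for inputs that are not
consistently locked to the response, and it prevents weights from
compounding within a single burst. A Dale clamp zeroes any eligibility
whose application would flip a synapse's sign.

Every T_κ = 100 ms a homeostatic scalar κ is renormalized to preserve
κ·Σ|w| across the update (the printed update rule is the first-order
expansion of this conservation law; we implement the exact form). κ
multiplies weights only where they enter the conductances — stored weights
are untouched.

## Tuning detection

The selectivity index of a pattern standardizes the gap between its
community's mean afferent weight and the non-community mean, squashed by
tanh with α = 0.5. Two conventions in the source description are
ambiguous and were resolved as follows (configurable):

* Pooling: statistics run over excitatory afferents. Pooling signed
  weights of both classes is degenerate — the strengthening of
  rival-pattern inhibition cancels the tuned community's signed mean
  almost exactly, so no trajectory would ever cross threshold.
* Threshold scale: the printed dynamic threshold lives on the weight scale
  while the index is tanh-bounded; compared literally the criterion can
  never hold. We interpret the non-pattern dispersion as the standard
  error of its mean (k = 5), compare it against the pattern-mean weight,
  and keep the printed absolute lower bound of 0.15 on the index itself.
  Tuning is declared at the first time both conditions hold continuously
  for 1 s (weight snapshots every 100 ms).

## What the synthetic inputs do and do not capture

The generator reproduces the statistical structure the learning problem
needs: rate-matched frozen templates, equal-probability interleaving,
uniform gaps, per-presentation transmission failure, optional burst units
(each template spike replaced by a 3-spike run at 5 ms) and timing jitter
(uniform displacement with a prescribed mean absolute value). It does not
model rate-coded stimuli, inter-afferent correlations outside the frozen
templates, oscillatory backgrounds, or conduction delays — so passing
tests show pattern-detection capability under idealized Poisson
statistics, not performance on natural spike trains.

## Numerical choices

Forward Euler at δt = 0.1 ms for the nonlinear membrane and gate ODEs;
linear filter states (conductances, bAP pulse, plasticity traces) advance
with exact per-step exponential decay factors, so their impulse responses
match the closed forms to machine precision. Synaptic plasticity state is
updated on a 0.5 ms stride (1 ms and a 10-stride ζ refresh in the
network), which is safe because every plasticity time constant is ≥ 7 ms.
Spike times live on the grid; threshold detection is level-crossing at
step boundaries. Membrane divergence is detected by a per-step bounds
check (±500 mV) and reported as an error naming the trial. The Euler
discretization was verified by step-halving on subthreshold segments.

## Problem sizes used in the shipped checks

Single-neuron batches use the full 2000-afferent, 20 s condition. The
recurrent network ships at a proportionally scaled size (100E/25I units,
10 assemblies of ~9, 1000 afferents, 10 s trials) — the full 400E/100I
size runs, but the scaled network reproduces the within/between assembly
correlation contrast at a fraction of the cost and is what the
reproduction script uses. The variant SNR sweep uses 10 s trials.

## Known limitations

* Convergence speed: tuned trials converge in roughly 5–15 presentations
  (batch means ≈ 10–11), somewhat slower than the 7–8 presentation
  average reported for the original model, and only ~30–50% of 20 s trials
  cross the strict tuning criterion. The bootstrap (first pattern-locked
  responses emerging from initial-weight luck) is the slow step.
* The homeostatic scalar κ drifts below 1 in our trials (minimum ≈ 0.4):
  the Hebbian growth of winning weights outweighs depression, so Σ|w|
  rises and κ compensates downward. The original report has κ staying
  above 1, implying net weight shrinkage under their parameter set.
* The calcium-based variants reproduce the qualitative boost phenomena —
  no learning without the bAP pulse, supralinear burst-evoked calcium,
  the correct STDP pairing signatures, boost-ordered SNR — but their
  in-trial excitability signal has too low a spike-to-background ratio
  for reliable pattern tuning: dendritic-fluctuation calcium dominates
  spike-locked calcium. The strong-boost rescue therefore falls short of
  a majority of trials, and detection-bias effects that depend on robust
  tuning statistics are weak.
* Assemblies are disjoint; conduction delays, multi-compartment dendrites
  and additional channel types are out of scope.
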