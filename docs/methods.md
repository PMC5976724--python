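# Methods

## The scientific question

Does the chaotic or non-chaotic character of *isolated* neural
oscillators shape what their *network* does — the steepness of the
synchronization transition, the waxing and waning of coherence
(metastability), and the tendency to switch between transiently stable
synchronization patterns (multi-stability)?  The package answers this by
simulating small-world networks of electrically coupled conductance-based
neurons whose node dynamics can be dialled between chaos and regularity
with two slow conductances, while the distribution of firing rates is
held fixed across conditions.

## Node model

Each node is a Huber–Braun cold-thermoreceptor neuron extended with a
hyperpolarization-activated cation current (HB + I_h): a parabolic
burster in which fast spike currents (I_d, I_r) ride a slow subthreshold
oscillation generated by a persistent depolarizing current I_sd, a
calcium-activated repolarizing current I_sr and the h-current I_h.

C_m dV/dt = −I_sd − I_sr − I_h − I_d − I_r − I_l + I_syn, with
I_i = ρ(T) g_i a_i (V − E_i) (a_l ≡ 1, a_d instantaneous) and
I_sr = ρ(T) g_sr · a_sr²/(a_sr² + 0.4²) · (V − E_sr).
Gating follows da_i/dt = φ(T)(a_i∞(V) − a_i)/τ_i with sigmoid steady
states a_i∞(V) = 1/(1 + exp(−s_i(V − V_i⁰))); the calcium-like variable
integrates the inward slow current, da_sr/dt = φ(T)(−η I_sd − κ a_sr)/τ_sr,
so inward (negative) I_sd raises a_sr.  Temperature enters through
ρ(T) = 1.3^((T−25)/10) for conductances and φ(T) = 3^((T−25)/10) for
kinetics; all runs use T = 36 °C.  Units are ms, mV, mS/cm², µA/cm²,
µF/cm², making dV/dt mV/ms.  Reference parameters ship as a packaged
text file (`chaosnet/data/hbih_defaults.txt`); the study varies only
g_sd, g_sr and g_h.  With g_h = 0 ("NoIh") the a_h equation decouples
from V, the model is effectively 4-dimensional per node, and no
parameter combination is chaotic.

The sign printed for the gap-junction current would, taken together with
the +I_syn convention of the voltage equation, make electrical coupling
repulsive; we implement the standard diffusive form — node k receives
I_syn,k = g Σ_l C_kl (V_l − V_k) — which is the only sign that produces
a transition to synchrony.  Total coupling current is conserved
(Σ_k I_syn,k = 0) for symmetric C at machine precision.

Initial conditions are V = −60 mV (optionally jittered uniformly by a few
mV per node, seeded), gating at steady state, a_sr = 0.1.  The transient
is discarded, so the choice only needs to land in the attractor's basin.

## Network

Newman–Watts small world: a ring lattice of N nodes each coupled to its
K nearest neighbours per side (degree 2K), plus one shortcut per node
with probability p to a uniformly drawn non-neighbour (redraw on
collision; no lattice edge removed; matrix symmetrized).  Defaults
N = 250, K = 5, p = 0.1; the desk-scale profile uses N = 50.  Gap
conductance is uniform (g_kl = g) and swept over 0 and log-spaced values
in [10⁻⁴, 1] mS/cm².  Topology seeds are shared across populations and
g values so conditions are compared on the same connectivity matrices.

## Integration

Forward Euler with dt = 0.025 ms (numba-compiled kernels).  Spikes are
detected inside the integration loop as linearly interpolated upward
crossings of −20 mV with a 2 ms refractory period (action potentials
overshoot 0 mV; subthreshold activity stays below −40 mV).  Voltage is
recorded at 1 kHz — far above the 50 Hz analysis band.  A run whose
voltage leaves ±500 mV raises a diverged-simulation error naming the
step.  An adaptive-step reference (scipy RK45, rtol 10⁻⁸) exists purely
as a cross-check: at reference parameters Euler and the reference agree
on the firing rate to < 2% over 10 s (interval-based rates; count-based
rates on 10 s are quantized at 0.1 Hz, which would measure the counting
convention rather than the integrator).  Halving dt moves spike times by
O(dt), consistent with first-order convergence.

## Chaos quantification

Maximal Lyapunov exponent (MLE) by the classic two-trajectory scheme in
the full state space: a companion trajectory displaced by d0 = 10⁻⁶
(unweighted Euclidean norm over (V, a_r, a_sd, a_sr, a_h) of all nodes)
is renormalized back to d0 every 1 ms and the mean log stretch per unit
time is accumulated.  Defaults: 5 s transient, 50 s averaging for single
neurons (15–20 s in scans), convergence flagged when the running mean
moves < 5% over the last quarter of the averaging window (scale floored
at the noise band below).  Neuron and network estimates run on the same
Euler scheme as the simulations; benchmark flows (linear contraction,
Lorenz) use an RK4 variant of the estimator.  Calibration: dx/dt = −x
gives −1.0 ± 0.01; Lorenz (10, 28, 8/3) gives 0.906 ± 0.02 against an
independent variational Benettin reference.

Finite averaging leaves a noise floor: estimates on verifiably periodic
orbits scatter up to about +0.6·10⁻³ /ms.  We therefore use a noise band
of 2·10⁻³ /ms: "chaotic" means MLE above the band; "non-chaotic" at or
below it.  A strict MLE > 0 rule would misclassify periodic points whose
finite-average estimate lands marginally positive.  On a coarse 8×8 grid
of the NoIh plane no point exceeds the band — the complete absence of
chaos without I_h.

## Firing patterns and events

Each scanned neuron gets a pattern code: 0 no oscillation, 1
subthreshold oscillation without spikes, 2 spikes with cycle skipping, 3
regular tonic, 4 burst firing, 5 tonic 20–50 spikes/s, 6 > 50 spikes/s.
The slow-oscillation period is estimated from the voltage trace after
clipping at −20 mV (suppressing spike harmonics) and low-passing at
20 Hz; the Welch peak below 20 Hz counts only if it stands ≥ 10× above
the band's median power (a flat spectrum means no slow rhythm).  Spikes
whose ISI is below half the slow period group into one event; an event
with ≥ 2 spikes is a burst, b_k = Nb/Te is a neuron's burst fraction and
MB its network mean.  Decision order: rate bands (6, 5) first, then
bursting (majority of events with ≥ 2 spikes), then skipping (slow
cycles outnumber events by ≥ 20%), else tonic; irregular non-bursting
firing (ISI CV ≥ 0.1) is classed with skipping.  All thresholds are
explicit keyword arguments — the event definition is a modelling choice,
not a measured quantity.  Note the reference parameter point itself is a
skipping oscillator with slowly modulated ISIs (ISI CV ≈ 0.07), not a
strict limit cycle; strict sub-1% periodicity holds at genuinely tonic
points.

## Matched-firing-rate populations

To compare chaotic, non-chaotic and NoIh networks at equal functional
heterogeneity, parameter sets are drawn so all three populations share
the same firing-rate histogram: the 3.0–4.5 spikes/s band is divided
into 0.1 Hz bins and the same number of (g_sd, g_sr) pairs is drawn from
each region per bin (the per-bin count is the sparsest region-bin's
occupancy).  Equality is confirmed by pairwise two-sample
Kolmogorov–Smirnov tests.  The scan grids shipped as defaults were
chosen from our own coarse scans so that every bin is populated in all
three regions: the g_h = 0.4 plane is gridded at 0.0025 mS/cm² over
g_sd ∈ [0.18, 0.355] × g_sr ∈ [0.26, 0.34] (the strip where isolated
rates fall in-band, hugging the firing/silence boundary where chaos
lives), the NoIh plane at 0.005 over [0.175, 0.30] × [0.18, 0.44].  The
MLE is estimated only where the rate is in-band (`mle_policy="band"`);
with 10 s recordings rates are quantized at 0.1 Hz, so matched samples
are bin-for-bin identical and the KS p-values equal 1 by construction.

## Synchrony, metastability, FCD

Voltage traces are zero-phase low-pass filtered at 50 Hz (4th-order
Butterworth, forward–backward), demeaned, and wavelet-transformed
(complex Morlet, ω₀ = 6, 48 log-spaced scales covering 0.5–50 Hz).  The
node's predominant frequency is the scale of maximal time-averaged
wavelet power; its instantaneous phase is the transform's angle at that
single scale.  Three Gaussian sigmas of the largest selected scale are
trimmed from both ends of all phase series (cone of influence), keeping
a common time base.

R(t) is the modulus of the population-mean unit phasor; R its time mean;
metastability χ the temporal variance of R(t) (mean over samples, hence
independent of sampling rate; bounded by 1/4 for a [0,1]-valued series).
Both are zero only in the fully locked case; χ is also zero under full
asynchrony.

Functional connectivity uses 2 s windows with 90% overlap (a 30 s record
gives exactly 141 windows):
FC_kl(T_m) = ⟨|(e^{iφ_k} + e^{iφ_l})/2|⟩_t = ⟨|cos(Δφ/2)|⟩_t.  Each FC
is vectorized over its strict lower triangle excluding the first
sub-diagonal, and the FCD matrix holds Pearson correlations between all
window pairs.  Fully synchronized epochs give constant FC vectors whose
correlation is undefined; two identical constant vectors are assigned
correlation 1 (0 otherwise) and flagged degenerate, matching the all-1
FCD of the locked regime.  The multi-stability summary is the variance
of FCD entries with |i − j| > 9 off-diagonals — exactly the window pairs
that share no samples at 90% overlap, whose correlation would otherwise
be trivially inflated.  The prefix-sum implementation touches each
sample once regardless of overlap.

## Surrogate fixtures

Every analysis stage is validated against generators with closed-form
ground truth: `locked` (R = 1, χ = 0, FCD ≡ 1), `independent`
(E[R] = √π/(2√N) at any instant), `constant_lag`
(FC_kl = |cos((k−l)·lag/2)| exactly, χ = 0), `block_switching` (two
alternating lag patterns; with non-overlapping windows of one block
length the off-diagonal FCD variance is p(1−p)(1−c)², c the
between-state FC correlation), plus voltage-level `spike_train` and
`subthreshold` fixtures amplitude-matched to the model's −90…+40 mV
range so spike-detector thresholds transfer.  The fixtures deliberately
contain no chaos and no conductance dynamics: passing them shows the
*measurement* chain is exact, not that the ODE model is right — the
latter is covered by the analytic-limit, cross-integrator and Lyapunov
benchmark tests.

## Pipeline and problem sizes

A sweep iterates (population, g, seed): build the network (topology seed
shared across populations and g), draw node parameters from the
population with replacement, integrate 5 s transient + 30 s record,
extract phases, compute R, χ, optionally the network MLE and the FCD
variance; aggregate across seeds (never across time) as mean ± SD/SEM.
Per-run failures are logged and excluded, and completed runs are skipped
on resume via `runs.csv`.

The desk-scale profile used throughout the tests and the acceptance
script — N = 50, K = 5, p = 0.1, 2–3 seeds, 30 s records, 10 s scan
recordings, 15 s scan MLE averaging — reproduces the qualitative
transition (R from the uncoupled baseline to > 0.95, interior peaks of χ
and FCD variance) in minutes on one core.  The `paper` profile (N = 250,
10–20 seeds, longer averaging, finer grids) matches the study's scale
and is an overnight run; transitions there shift to somewhat larger g
because synchronizing more oscillators through sparse coupling is
harder.

## Known limitations

- Deterministic dynamics only: no channel noise, no synaptic
  stochasticity; randomness enters solely through topology, parameter
  draws and initial conditions.
- Electrical synapses only; uniform g; undirected graphs.
- The event/burst thresholds and the chaos noise band are explicit
  conventions; the original event-detection criteria are not published.
- The wavelet's predominant frequency is a single global scale per node;
  nodes with strongly drifting rhythms would need a ridge method.
- MLE magnitudes of NoIh networks are not directly comparable to the
  others (250 fewer dimensions), a caveat inherited from the study
  design.
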