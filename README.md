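# chaosnet

Synchronization transitions, metastability and functional-connectivity
dynamics (FCD) in small-world networks of electrically coupled
conductance-based neurons whose isolated dynamics can be chaotic or
non-chaotic.

## The problem

Chaos is widespread in single-neuron dynamics, but does it matter at the
network level?  This package implements a complete simulation-and-analysis
pipeline to ask that question quantitatively.  The nodes are Huber–Braun
thermoreceptor neurons extended with a hyperpolarization-activated current
(HB + I_h) — parabolic bursters whose slow conductances (g_sd, g_sr, g_h)
select tonic, skipping, bursting or chaotic firing, with chaos vanishing
entirely when g_h = 0.  Nodes are coupled by gap junctions
(I_syn,k = g Σ_l C_kl (V_l − V_k)) on a Newman–Watts small-world graph,
and the coupling g is swept from 0 to 1 mS/cm².

Three quantities summarize the network state as g grows:

- **Order parameter** R = ⟨|⟨e^{iφ_k(t)}⟩_N|⟩_t — global phase synchrony,
  0 (incoherent) to 1 (locked); phases come from a 50 Hz low-pass plus
  complex-Morlet wavelet transform at each node's predominant frequency.
- **Metastability** χ = Var_t R(t) — nonzero only when coherence waxes
  and wanes.
- **FCD variance** — windowed functional-connectivity matrices
  (FC_kl = ⟨|cos(Δφ_kl/2)|⟩, 2 s windows, 90% overlap) are compared
  across all window pairs by Pearson correlation; the variance of the
  off-diagonal FCD entries measures multi-stability, the transient
  recurrence of distinct synchronization patterns.

Chaos at the node and network level is quantified by the maximal
Lyapunov exponent (two-trajectory renormalization in the full state
space).  To compare chaotic, non-chaotic and NoIh networks fairly, node
parameters are drawn so that all three populations share the *same
distribution* of isolated firing rates (0.1 Hz bins over 3.0–4.5
spikes/s, per-bin counts matched exactly, verified by pairwise
Kolmogorov–Smirnov tests).

## Layout

```
src/chaosnet/      model, network, simulate, lyapunov, features,
                   synchrony, fcd, surrogates, pipeline
analysis/          numbered drivers reproducing the study step by step
scripts/           acceptance.py (see below)
docs/methods.md    the full methods note
```

## Worked example

Run the analysis chain (each script prints its findings and writes CSVs
under `results/`):

```sh
python analysis/01_single_neuron.py
python analysis/02_scan_parameter_plane.py
python analysis/03_match_populations.py
python analysis/04_sweep_synchrony.py
python analysis/05_fcd_multistability.py
```

Step 01 characterizes representative parameter points:

```
reference          FR=  4.7/s  pattern=2  MLE=+0.00045/ms  -> non_chaotic
tonic              FR=  9.8/s  pattern=3  MLE=+0.00013/ms  -> non_chaotic
chaotic_boundary   FR=  3.7/s  pattern=2  MLE=+0.00254/ms  -> chaotic
bursting           FR= 11.1/s  pattern=4  MLE=+0.00013/ms  -> non_chaotic
noih               FR=  3.9/s  pattern=3  MLE=+0.00013/ms  -> non_chaotic
```

The reference point fires at 4.7 spikes/s with cycle skipping (pattern
code 2) and a near-zero Lyapunov exponent; moving to the firing/silence
boundary (g_sd = 0.25, g_sr = 0.30) makes the neuron chaotic
(MLE ≈ +2.5·10⁻³/ms, above the 2·10⁻³/ms estimator noise band), and
removing I_h abolishes chaos everywhere — step 02 confirms this on full
scans (`scan_noih.csv`: 0 chaotic points out of 1378).

Step 03 draws the matched populations:

```
chaotic      n= 15  rates 3.0-4.4/s
non_chaotic  n= 15  rates 3.0-4.4/s
noih         n= 15  rates 3.0-4.4/s
KS chaotic-non_chaotic: p = 1.000
```

i.e. one parameter set per 0.1 Hz bin and population, with identical
rate histograms (KS p = 1).  Step 04 then sweeps g for N = 50 networks
(3 seeds) from each population; for the chaotic population it prints

```
g=  0.0001  R=0.147+-0.020  chi=0.0047
g=  0.0010  R=0.432+-0.079  chi=0.0314
g=  0.0100  R=0.965+-0.010  chi=0.0012
g=  1.0000  R=1.000+-0.000  chi=0.0000
```

— R rises from the uncoupled baseline (≈ 0.15) to full synchrony, with
metastability peaking mid-transition, and the chaotic population's χ
peak (0.031) exceeds the non-chaotic (0.018) and NoIh (0.015) ones.
Step 05 computes the FCD: near-zero off-diagonal correlations at weak
coupling (patterns never recur), all ≈ 1 at strong coupling (one locked
pattern), and patchy matrices with maximal variance at intermediate g —
the multi-stable regime, dramatically more prominent for chaotic nodes
(FCD variance 0.053 at g = 0.01, vs 0.0005 non-chaotic and 0.0000 NoIh
at the same coupling).

The full-scale configuration (N = 250, 10–20 seeds, network MLE on) is
available via `--profile paper` on steps 02 and 04; it is an overnight
run and is documented, not required, for the desk-scale results above.

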