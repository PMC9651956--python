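# Methods

This note documents the model implemented by `elsm`, the numerical
choices behind the simulator, what the synthetic fixtures do and do not
emulate, and the design decisions taken where the reference design left
the choice open.

## Neuron and synapse model

Neurons are conductance-based leaky integrate-and-fire units on a
shifted voltage scale:

    τ dV/dt = (E_rest − V) + g_e (E_exc − V) + g_i (E_inh − V)

| parameter | default | meaning |
|---|---|---|
| E_rest, E_reset | 13.5 mV | resting and post-spike potential |
| V_th,base | 15 mV | static firing threshold |
| E_exc | 30 mV | excitatory reversal (depolarizing, above threshold) |
| E_inh | 0 mV | inhibitory reversal (hyperpolarizing, below rest) |
| τ (membrane) | 30 ms fixed, or U[5, 55] ms per neuron | leak time constant |
| τ_ge / τ_gi | 3 / 10 ms | conductance decay, excitatory / inhibitory |
| t_ref | 3 ms (E), 2 ms (I) | refractory period |
| SFA increment | 1 mV | threshold jump per spike (excitatory only) |
| τ_sfa | 550 ms fixed, or U[50, 1050] ms | adaptive-threshold decay |

The inhibitory reversal at 0 mV sits 13.5 mV below rest on this scale,
so inhibitory conductance hyperpolarizes; the excitatory reversal must
sit above threshold for excitation to depolarize, and is set to 30 mV
(configurable).  A published parameter table that lists both reversals
at 0 mV would make "excitatory" input hyperpolarizing, which contradicts
the stated sign semantics, so the depolarizing value is the default
here.

Conductances jump instantaneously by the synaptic weight when a
presynaptic spike arrives (weights are non-negative; whether a synapse
excites or inhibits is a property of its type, not a sign).  Initial
membrane potentials are drawn from U[13.5, 15) mV; conductances and the
adaptive threshold start at zero.

## Integration scheme

Time advances in fixed steps of dt (default 1 ms).  Within a step:

1. conductance kicks scheduled for this step are applied;
2. V is advanced by exponential-Euler using the start-of-step
   conductances — treating g as constant over the step makes the update
   V ← V∞ + (V − V∞)·exp(−dt·(1+g_e+g_i)/τ), which is *exact* for the
   leak-only membrane and second-order accurate otherwise;
3. g_e, g_i and θ decay by their exact exponential factors;
4. refractory neurons are clamped at E_reset (their timers decrement;
   conductances still accumulate and decay, so no drive is lost);
5. the threshold test V ≥ V_th,base + θ runs at the step end; spiking
   neurons are reset, made refractory, and (if SFA-enabled) bumped by
   the SFA increment.

Spike delivery: a spike at time t reaches each target at the step
covering t + delay, computed by rounding (t + delay)/dt half-up and
clamped to at least one step ahead.  At dt = 1 ms the 0.8/1.5 ms
recurrent delays therefore act as 1/2 ms; running with dt ≤ 0.1 ms makes
them exact.  The 4 ms input binning used throughout makes sub-millisecond
delay fidelity secondary, which is why 1 ms is the default.

Discretization has one visible consequence: under constant drive the
steady-state inter-spike interval can wobble by ±1 step around its fixed
point, so the adaptation property "successive inter-spike intervals are
non-decreasing" holds up to one dt in the tests.

## Liquid construction

Neurons occupy distinct sites of a 3D integer lattice, filled in raster
order.  The default box for n neurons is the smallest-slack factorization
closest to a 1:1:2 aspect ratio — (10, 10, 20) for n = 2000, which
reproduces the reference sparsity of ≈9.5 recurrent synapses per neuron
(the exact pairwise expectation on that box is 9.499).  Exactly
round(0.8·n) neurons are labeled excitatory, uniformly at random (no
spatial clustering).  Every ordered pair (i ≠ j) is realized
independently as Bernoulli(C_type·exp(−(D/λ)²)); weights are uniform on
[0, upper(type)] and delays are fixed per type.

Each liquid neuron receives exactly 7 input synapses from distinct,
uniformly chosen channels (sampling without replacement — the in-degree
is a per-neuron property, not a Bernoulli mean).  All input synapses act
on g_e.  One published weight list names the IE type twice; the four
entries are read in the conventional EE, EI, IE, II order, giving the
strong 1.2 upper bound to inhibitory→excitatory synapses.  Both readings
remain expressible through `LiquidSpec.recurrent_weight_upper`.

Construction uses independent RNG streams per stage (E/I split,
recurrent topology, recurrent weights, input topology, input weights,
time constants), so changing e.g. the inhibitory weight factor cannot
perturb the realized topology.  `Liquid.with_inhib_factor` rescales only
the input→inhibitory weights, which the balance sweep relies on.

## E/I balance

The sweep rebuilds nothing but the input-inhibitory weight scale
(U[0, factor·0.4]; the reference ratio is factor = 0.5) and, for each
factor, simulates a fixed probe batch of synthetic samples over several
liquid seeds.  The balance statistic is the bare-conductance net drive
g_e − g_i of excitatory neurons, averaged over time per neuron and then
over the network (the driving-force variant g·(E−V) is available as an
option).  The selected factor minimizes |mean net drive|, ties going to
the smaller factor.  The default grid is {0.5, 0.75, 1, 1.5, 2, 2.5, 3}.
On the synthetic probe task the mean net drive decreases monotonically
in the factor, and the demo task is already near balance at the
reference factor 0.5 — denser input regimes shift the balance point to
larger factors.

## Encoding

Step-forward encoding per channel: baseline b starts at the first sample
(default; zero-init available — first-sample avoids a spurious onset
burst), and each frame emits +1/−1 when the signal leaves [b−θ, b+θ],
moving b by ±θ.  The default θ = 0.005 matches the empirical setting
used for normalized cochleograms.  Bipolar trains become unipolar by
channel doubling (positive events first half, negative second half).
Event streams are aligned by cutting/padding to a target duration and
binned half-open into binary occupancy matrices; multiple events per bin
collapse to a single 1, and the simulator re-expands each 1 to one spike
at the bin start.

## Readout

Features are raw integer spike counts of the excitatory neurons over the
whole sample (no normalization — all samples here have equal duration).
The classifier is scikit-learn's multinomial logistic regression with L2
penalty; only C is tuned, by stratified 5-fold cross-validation over
{0.01, 0.1, 1, 10}.

## Quantization

Per synapse type, weights are rounded to the nearest of 2^bits uniform
levels spanning the sampling support [0, upper(type)] — a deterministic,
idempotent scheme with max error upper/(2·(2^bits−1)).  bits ≥ 53
exceeds double precision over these supports and returns the table
unchanged (the "64-bit" path).

## Synthetic fixtures

The template dataset draws one fixed random event template per class
(default: 5 classes, 40 channels, 250 ms, 400 events — about 10 events
per channel, a density comparable to binned cochlear event streams) and
derives samples by Gaussian time jitter (4 ms, one input bin) and
independent event deletion (p = 0.15).  Optional Poisson background
noise is off by default, since encoded audio is deterministic given the
recording.  This emulates the property the pipeline relies on — each
class drives a characteristic channel subset with a characteristic
temporal profile — but *not* the harder aspects of real speech:
speaker variability, correlated spectro-temporal structure, class
overlap, or variable utterance length.  Passing tests therefore certify
the mechanics and relative behavior of the pipeline (e.g. adaptation
reduces spiking; quantization is benign), not absolute benchmark
accuracy; the synthetic task is easy enough that both baseline and
extended configurations can reach ceiling accuracy, where the extensions
show up as a ~3.5× reduction in spikes per neuron rather than an
accuracy gap.

## Problem sizes

Full-scale (2000-neuron) liquids are used wherever only construction is
measured (topology statistics are cheap).  Simulation-heavy studies —
balance sweeps, adaptation comparisons, end-to-end classification — use
the 500-neuron demo liquid on the 5-class task (100 train / 50 test
samples), which exhibits all the qualitative phenomena of interest at
desk scale.

## Known limitations

- The cochlear front end is out of scope; the encoder consumes
  precomputed cochleogram-like matrices, and the float-signal generator
  is a stand-in that does not reproduce cochlear filtering.
- The clock-driven engine rounds sub-dt delays; event-driven exact
  simulation is not provided.
- Whether the membrane leaks or is frozen during refractoriness is not
  observable from outside; this implementation clamps V at E_reset.
- The balance statistic uses bare conductances; with strongly unequal
  reversal-potential distances the driving-force variant can select a
  different factor.
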