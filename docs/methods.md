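# Methods

## Circuit model and scope

The package simulates activity propagation through a layered model of the
fly sweet-taste pathway: labellar sweet GRNs and gustatory interneurons
(GINs, including the feeding command neuron Fdg) converge onto the bilateral
fox pair; fox output diverges to eleven bilateral pairs of ascending neurons
(FDA), premotor neurons, and the peptidergic DSKMP1B pair; FDA-I neurons
synapse directly onto PAM dopaminergic neurons while FDA-II neurons reach
them through one relay layer. Everything upstream of spike generation
(sensory transduction) and downstream of the PAM readout (plasticity,
behavior) is out of scope; so are statistical hypothesis tests, which the
assay module leaves to external tools by exporting tidy tables.

## LIF dynamics and numerics

Membrane and synaptic drive follow two coupled linear ODEs per neuron,

    tau_m dv/dt = (v_rest − v) + g,     tau_s dg/dt = −g,

with v_rest = v_reset = −52 mV, threshold −45 mV, refractory period
2.2 ms (membrane clamped at reset), tau_s = 5 ms, and a 1.8 ms
spike-to-effect delay. A presynaptic spike adds
`sign × W_syn × synapse_count` (mV) to g after the delay, so `W_syn` acts as
mV per synapse. `tau_m` is not constrained by the protocol this package
reproduces; the default is 20 ms, the conventional value for this class of
whole-brain LIF model, and it is freely configurable — the verification
properties fix it explicitly.

The engine integrates on a fixed 0.2 ms grid. Deliveries are quantized to
step boundaries and held in a ring buffer, which makes the two ODEs exactly
solvable within each step; the update uses that closed form, so the only
discretization effects are the quantization of deliveries, threshold
crossings and refractory release to the grid. Neurons crossing threshold in
the same step all spike in that step; within-step delivery order is
irrelevant because deliveries take effect at a later step. Silencing sets a
neuron's effective threshold to infinity while leaving it in the graph —
functionally identical to deletion for downstream flow. Stimulated neurons
are force-spiked from refractory-thinned Poisson trains (realized rate
≈ rate / (1 + rate·t_ref)), which pins the realized input rate and
sidesteps any ambiguity about how a "stimulated" neuron integrates its own
recurrent input.

### Verification oracle

`oracle_simulate` is an intentionally independent implementation: scalar
Heun (explicit trapezoid) integration at dt/10 with a heap-based event
queue, restricted to ≤ 50 neurons. Engine and oracle are compared on the
micro-fixtures (chain, fan-in, diamond, inhibitory pair) under deterministic
input trains. Exact spike-count agreement between a 0.2 ms and a 0.02 ms
integrator is a meaningful requirement only where each postsynaptic spike is
locked to a discrete input event with a robust threshold margin: in
free-running or near-threshold regimes, sub-step quantization differences
accumulate across inter-spike intervals and legitimately shift one spike in
or out at a trial boundary. The verification battery therefore uses clearly
supra-threshold spaced events (one output spike per input event) and clearly
sub-threshold drives (zero spikes), where the discretization argument
guarantees agreement; within it, counts match exactly and spike times agree
within one coarse step. The diamond fixture is checked with one arm
silenced, because with both arms intact its sink neuron receives exactly
twice the single-arm drive and its post-refractory residual is inherently
near-threshold at any weight.

## The synthetic reference connectome

The generator exists because the real whole-brain circuit extract is not
redistributable; it builds a stand-in that embeds the published
synapse-count fractions exactly and preserves the hourglass topology. Key
choices:

- **Exact apportionment.** Synapse totals on constrained connections are
  fixed by the largest-remainder method at configurable scales (default
  1000 synapses of fox input, 1000 of fox output, 500 of DSKMP1B SEZ
  input), so each named fraction rounds to its quoted value at the
  precision it is quoted at (one decimal for 10/4.4/10.5, integer for
  41/22). Randomness is confined to background neurons (300 by default) and
  the 600 seeded background edges among them, which never touch a
  constrained denominator, the PAM readout, or any stimulated population.
- **Inconsistent quoted shares.** The quoted CB0233 shares — 7% of total
  fox output and 41% of fox output to FDA neurons — cannot both hold when
  FDA-I + FDA-II receive 4.4% + 10.5% = 14.9% of output
  (0.41 × 14.9% = 6.1% ≠ 7%). The generator treats the within-FDA share as
  the binding constraint (61 of 149 FDA synapses), so the achieved total
  share is 6.1%.
- **Free parameters.** Only the Fdg share of fox input (10%) is quoted; the
  GRN (30%) and GIN (40%) shares are free parameters of the configuration,
  with the remainder supplied by local SEZ neurons. The split of fox output
  not constrained by quoted fractions (74.1%) goes to premotor neurons.
- **Downstream gain structure.** Unconstrained synapse counts were chosen so
  that (i) no single connection drives a postsynaptic spike from one
  presynaptic spike at the sweep weights (single-spike peak response is
  ≈ 0.16 × W_syn × count mV against a 7 mV threshold gap), which keeps the
  low-rate corner of the sweep quiet instead of shot-noise dominated, and
  (ii) sustained-drive thresholds of the CB0233 → relay → PAM cascade are
  staggered, so PAM recruitment grows gradually with stimulation rate and
  weight. The 20 PAM neurons receive relay input with counts 15…167,
  which is what staggers their recruitment.
- **Laterality.** Bilateral populations are split L/R with per-side
  apportionment; "unilateral stimulation" means the left-side members.

What the generator does **not** emulate: realistic brain scale (~10^5
neurons), morphology, neurotransmitter identity (all deterministic edges are
excitatory except the explicit inhibitory micro-fixture; edges without a
sign default to excitatory with a logged warning), recurrence, or
heavy-tailed degree structure. Consequently, passing the bottleneck and
monotonicity checks shows the *pipeline* reproduces these phenomena on a
circuit built to have them — it does not re-establish the biological claim
on the real connectome, whose loader-compatible tables this package accepts
but does not ship.

## Lesion sweep

The sweep grid defaults to the published protocol: weights
(0.37, 0.38, 0.382, 0.386, 0.39) × rates (20…200 Hz, 12 values), left-side
GRNs + GINs stimulated (a GRN-only flag exists), PAM population as readout,
five trials per cell (the 30-repetition setting is one config field away),
1000 ms trials. Each cell's seed is derived from the base seed and the
cell's own (condition, weight, rate) coordinates via a CRC mix, so grids
are reproducible and invariant to condition execution order. Cells retain
both the per-trial activated counts (whose mean is the heatmap value) and
the any-trial activated set (the activation criterion): the two readings of
"responding" are both exported. The suppression summary reports, per
condition, the mean of (1 − count/baseline) over cells with a non-zero
baseline, excluding and counting zero-baseline cells.

Problem sizes used by the shipped verification runs: the full default
5 × 12 grid at 5 trials/cell for intact vs fox-silenced, and a 2 × 2 grid
for the FDA/CB0233 silencing comparisons; monotonicity is asserted on
trial-averaged counts allowing one inversion of at most one count per row
and column as sampling tolerance.

## Assay statistics

All indices are bounded contrasts of the form (a − b)/(a + b): positional
preference (illuminated vs dark side, frame-averaged over the illumination
window, zero-occupancy frames skipped), closed-loop sip preference (per
fly), and the learning index (CS+ vs CS− quadrants over the 1-min test).
Swapping the roles negates each index exactly. ΔF/F subtracts the per-volume
background ROI and a background-corrected baseline averaged over the 5
volumes preceding each pulse, and divides by that corrected baseline — which
makes it invariant under any common rescaling of signal and background and
undefined when the corrected baseline is non-positive. The dye-consumption
conversion interpolates absorbance on a strictly monotone standard curve and
multiplies by the extraction volume (300 µL carcass, 500 µL excreta),
summing the two per vial; out-of-range absorbances extrapolate from the end
segments with a warning.

The synthetic assay generator draws occupancy/quadrant counts from a
binomial side-choice model (frame-wise placement with probability
(1 + effect)/2), sips from a Poisson total split binomially (exactly
unbiased for the preference conditional on at least one sip), and
fluorescence as pulse-locked exponential transients (peak = effect ×
corrected baseline, decay 5 volumes) with Gaussian noise. These models have
independent frames/flies and no drift, adaptation or tracking error, so
parameter-recovery tests validate the estimators, not the realism of any
particular experiment.
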