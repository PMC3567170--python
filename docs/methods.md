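# Methods

## The model

`wormtaxis` implements a brain-body-environment model of salt
klinotaxis in *C. elegans*: gradient ascent by gradual, continual
reorientation driven by concentration differences sensed during
side-to-side head sweeps.

### Circuit

The circuit is the minimal anatomically grounded klinotaxis network:
chemosensors ASEL/ASER project to the AIY interneuron pair, AIY to AIZ
(one chemical synapse per side), AIZ to the four SMB neck motor
neurons; the left and right members of each interneuron pair are
coupled by a nonrectifying gap junction, and the motor neurons carry
self-connections.  It is recovered from a connectivity table by a
constrained breadth-first search (all simple paths from the sensor root
set to the motor target set, at most 3 synaptic hops, neuron-pair
contact number >= 2), as implemented in `wormtaxis.connectome`.

**Sensors.**  ASEL (ON) and ASER (OFF) compute a rectified differential
of the recent concentration history: the mean over the last `N` seconds
minus the mean over the `M` seconds before that (negated for the OFF
cell), negative values clamped to zero.  A sustained step of size `s`
yields a linear rise to a peak of exactly `s` after `N` seconds and a
linear decay to zero after `N + M` seconds.  The rectified activation
feeds the downstream chemical synapses directly as the presynaptic
output (an option routes it through the logistic instead).

**Interneurons and motor neurons.**  Passive isopotential nodes,

    tau dy/dt = -y + sum_chem w * sigma(y_pre + theta_pre)
                + sum_gap g * (y_other - y_self)
                [+ w_self * sigma(y + theta) + w_osc * osc(t)]

with `sigma` the unit-gain logistic; the bracketed terms exist only on
motor neurons.  `osc(t) = sin(2 pi t / T)` with `T = 4.2 s` (one
locomotion cycle); ventral cells receive it in anti-phase.  The
self-connection is the model's representation of the graded
regenerative inward currents of these cells, and it matters
quantitatively: for `w_self > 4` the steady-state input-output (SSIO)
relation folds (bistability), and slightly below or above that fold the
local gain `sigma' / (1 - w_self * sigma')` is large.  Functional
klinotaxis circuits sit the sensitive branch of the SSIO curve
asymmetrically inside the oscillation's sweep, which is what lets a
small sensory shift modulate the dorsoventral output difference without
the dorsal and ventral responses cancelling.

**Body.**  A point worm moves at `v = 0.022 cm/s`; each step the
heading increments by `phi = w_nmj * ((o_DL + o_DR) - (o_VL + o_VR)) * dt`
(dorsal-minus-ventral output difference, left and right summed), so the
turning bias (the sum of `phi` over one cycle) is invariant to the
integration step.  Pirouettes are Bernoulli events at rate 0.033 Hz
that redraw the heading uniformly; they are enabled during fitness
evaluation and disabled in all analyses.

**Environment.**  Conical gradients `c = baseline + alpha * dist` (used
for evolution, steepness `alpha` drawn from [-0.38, -0.01] per assay)
and Gaussian gradients `c = amp * exp(-dist^2 / 2 sigma^2)` (used for
generalization tests and the behavioral analyses).  The Gaussian
defaults amp = 1.71, sigma = 3 cm place the slope magnitude at the
4.5 cm start circle inside the conical steepness range; the literature
this model follows does not fix these two numbers, so they are
package defaults, not claims.  Because sensing is purely differential,
the baseline offset is behaviorally inert.

### Assays and scores

An assay starts the worm 4.5 cm from the peak with uniform random
heading and uniform random motor activations in [0, 1]; interneurons
start at rest, the concentration history is back-filled with the
starting concentration.  The chemotaxis index is
`CI = 1 - mean_t h(t) / h(0)` (trapezoidal time average of the distance
to the peak, clamped at zero), so CI = 1 means sitting on the peak
throughout and CI = 0 no net approach.  This normalized form is adopted
for the displayed score because it is the only reading of a
"time-averaged distance" index consistent with CI = 1 at the peak and
the reported ~0.87 scale.  Reliability is the fraction of assays
entering a 0.1 cm disk around the peak.

### Genotype and evolution

Twenty genes on [-1, 1] map linearly onto: N, M (shared by both
sensors); the four ASE->AIY weights; AIY biases and gap conductance;
the two AIY->AIZ weights; AIZ biases and gap conductance; the two
AIZ->SMB weights (each shared dorsoventrally); SMB biases and
self-weights (per side, shared dorsoventrally).  Weights and biases
span [-15, 15], conductances [0, 15], N and M [0.1, 4.2] s.  The time
constant (1.5 s), oscillator weight (10) and neuromuscular gain (1) are
fixed map constants: a 20-slot genotype cannot carry every parameter of
the model at once, and these three are the ones whose values the
behavior constrains least (the oscillator weight only sets the scale of
the head sweep that the evolved biases then position against).  The map
is data (serialized with every circuit), so alternative slot
assignments are expressible without code changes.

Fitness is the mean CI over independent 500 s conical-gradient assays.
Within a generation all individuals are evaluated on a common list of
assay seeds (steepness, heading, initialization and pirouettes drawn
per seed); the list is redrawn every generation.  Comparing individuals
under common random conditions removes most of the between-individual
sampling noise from selection while preventing any individual from
retaining a lucky evaluation.  The GA is generational with binary
tournament selection, uniform crossover (probability 0.5), per-gene
Gaussian mutation, and two elites; elitist truncation selection (the
other scheme commonly used with this model family) is available as a
configuration option but collapses the population to a single lineage
within a few generations and performed worse in our pilots.

## Packaged ensemble

The circuits under `wormtaxis/data/ensemble/` were produced by
`scripts/refine_ensemble.py`: perturbed restarts of a Nelder-Mead
refinement of a derandomized chemotaxis objective (mean CI over a
fixed, stratified battery of seeded 800 s conical assays — five
steepness values crossed with six start headings, pirouettes on,
random motor initializations drawn per seed), each result re-tested on
fresh 1000 s assays at the standard integration step.  Seeds, the
objective definition and re-test statistics are embedded in each
file's provenance block, and every analysis of the packaged ensemble
is re-run from the circuit files, not from stored results.

This pipeline, rather than the GA alone, produced the packaged
circuits for a compute reason: at the problem sizes used here, GA runs
from random initializations do not leave the fitness noise floor,
while derandomized refinement from
a designed starting circuit reliably finds genuine klinotaxis —
correct turning-bias/bearing sign opposition, an approximately
sinusoidal phase-response curve, bias linear in the normal gradient
component, and homing to the peak from bearings within roughly +/-1.6
rad.  The packaged circuits' long-assay chemotaxis indices (~0.2, see
each file's provenance) remain well below the ~0.87 that full-scale
evolution attains for this model class; analyses that depend only on
the mechanism (sign structure, phase response, coverage, ablation and
gap-block contrasts) are meaningful on these circuits, while absolute
performance statistics are not representative of fully optimized
ensembles.  The faithful GA pipeline is kept in
`scripts/evolve_ensemble.py`.

## Numerics

* Forward Euler, default `dt = 0.01 s` (all analyses and re-tests).
  Evolution integrates at a coarser step (see each circuit's
  provenance) for throughput; the re-test filter is applied at 0.01 s.
  A convergence test checks that halving dt moves interneuron
  activations after 500 s by < 1e-3 and that the total state error
  shrinks first-order; the driven motor oscillation carries an
  intrinsic O(dt) phase error, so exact step-invariance is not claimed.
* Sensor windows are ring buffers of `round(N/dt)` / `round(M/dt)`
  samples with running sums.
* SSIO fixed points: the map's critical points are located analytically
  (where `w_self * sigma' = 1`), then each monotone branch is bisected;
  stability is the sign of `-1 + w_self * sigma'` at the root.
* Cycle statistics use non-overlapping windows of exactly one period
  starting at phase 0; bearing is measured at the cycle's start point,
  and cycles starting within 0.3 cm of the peak are excluded (bearing
  is ill-conditioned there).  Bearing bins: 18 x 20 degrees.
  Gradient-component bins: equal-count deciles; the linearity of the
  bias/normal-gradient relationship is assessed on binned means (the
  per-cycle scatter is noise-dominated).
* Sensitivity curves: sustained steps on the grid +/-0.02 in 5e-4
  increments injected at phase 0 after 60 settling cycles (some evolved circuits relax to their limit cycle with a ~10-cycle time constant); the response
  is the mean output over the following full cycle minus the no-input
  mean over the same window (the cycle window matches the turning-bias
  timescale).  Coverage counts adjacent grid pairs whose means differ
  by > 1e-4.  Interneuron types: A insensitive; B responsive to one
  step sign; C responsive to both signs with same-direction
  deflections; D responsive to both signs with opposite-direction
  deflections.
* Step-response assays run gradient-free; a drift check on the
  baseline turning bias (tolerance 1e-5 between consecutive settled
  cycles) guards against unsettled transients.
* The dorsal head sweep is the half-cycle where the dorsal oscillator
  drive is positive (phase [0, pi)).

## What the synthetic data does and does not show

The synthetic connectome generator builds layered sensor->inter->motor
graphs with known ground-truth path structure; it validates the search
machinery (including against brute-force enumeration) but does not
emulate the statistics of a real connectome (degree distributions,
reciprocity, contact-number distributions).  The packaged hand-written
table encodes the minimal-circuit topology plus decoy pathways at lower
contact numbers and longer path lengths; mining it exercises every
constraint, but agreement there says nothing about dataset-version
differences in the real connectivity data, which is why fractions
reported for the real connectome are out of scope.  The idealized body
(point worm, constant speed, heading-increment turning) omits
undulatory mechanics, slip and speed modulation, so quantitative
trajectory features beyond the cycle-level statistics analyzed here
should not be read into the model.

## Known limitations

* The evolved ensemble is small compared to a 100-run reproduction;
  distributional statements (coverage gains, gap-strength ratios) are
  correspondingly loose.
* The fixed oscillator weight means head-sweep amplitude is not itself
  evolvable; circuits adapt their biases to it.
* Chemical synapses release tonically; no synaptic dynamics, no
  neuromodulation, no rectifying gap junctions.
* `run_ga` re-samples fitness every generation; reported
  per-generation "best" values are noisy estimates, and the returned
  circuit is the final generation's best (re-tested downstream).
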