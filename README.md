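# wormtaxis

Neuroanatomically grounded models of *C. elegans* salt klinotaxis:
mine a connectome table for the minimal chemosensor-to-neck-motor
circuit, simulate it in an idealized body on a chemical gradient,
evolve its unknown electrophysiological parameters against a
chemotaxis-index fitness, and run the analysis battery (turning-bias
vs. bearing, step responses, steady-state input-output structure,
sensitivity coverage, ablations, gap-junction blocks) over the
resulting model ensemble.

## Who this is for

Systems-neuroscience and computational-biology researchers who want to
connect connectome-level circuit structure to behavior when
electrophysiological parameters are unknown: the package treats the
wiring as a constraint and uses stochastic optimization to fill in
weights, biases and time windows so that the whole brain-body-
environment model performs chemotaxis, then asks which mechanisms the
ensemble of solutions agrees on.

## The model in brief

* **Sensors** (ASEL = ON, ASER = OFF): rectified differential of
  concentration history, `max(0, mean(c, last N s) - mean(c, M s before))`
  (negated for the OFF cell).
* **Neurons**: `tau dy/dt = -y + sum w sigma(y_pre + theta_pre) +
  sum g (y_j - y_i) [+ w_self sigma(y + theta) + w_osc sin(2 pi t / T)]`,
  with `sigma` the logistic and `T = 4.2 s` the head-sweep period
  (motor-only terms in brackets, ventral drive in anti-phase).
* **Body**: point worm at `v = 0.022 cm/s`; heading increments by
  `w_nmj ((o_DL + o_DR) - (o_VL + o_VR)) dt`; pirouettes randomize the
  heading at 0.033 Hz (off during analyses).
* **Score**: chemotaxis index `CI = 1 - <h(t)> / h(0)` over a 500 s
  assay started 4.5 cm from the gradient peak; *reliability* is the
  fraction of assays entering a 0.1 cm disk around the peak.
* **Evolution**: 20 real genes in [-1, 1] map linearly onto the
  circuit parameters (dorsoventrally symmetric); a genetic algorithm
  maximizes mean CI over randomized conical-gradient assays.

See `docs/methods.md` for assumptions, parameter ranges, numerics and
limitations.

## Worked example

Mine the packaged connectivity table for the minimal circuit:

```sh
$ wormtaxis mine --table src/wormtaxis/data/minimal_connectome.csv \
    --roots ASEL,ASER --targets SMBDL,SMBDR,SMBVL,SMBVR \
    --depth 3 --min-contacts 2 --induced
{
  "n_neurons": 10,
  "n_chemical": 14,
  "n_gap": 2,
  "frac_neurons": 0.7142857142857143,
  "frac_chemical": 0.7,
  "frac_gap": 1.0,
  "n_paths": 8,
  "fully_connected": true
}
```

Ten neurons survive the depth-3, contact>=2 search: the two ASE
sensors, the AIY and AIZ pairs (each with its lateral gap junction)
and the four SMB motor neurons; all 8 sensor-to-motor pairs are
connected, so the network is fully connected and this is the minimal
depth at which that holds.

Run a chemotaxis assay with a packaged evolved circuit (exported to a
file first):

```python
from wormtaxis import fixtures
from wormtaxis.assay import AssayConfig, run_assay
from wormtaxis.world import GradientSpec

circuit = fixtures.best_fixture_circuit()
cfg = AssayConfig(duration=500.0, seed=13,
                  gradient=GradientSpec(shape="conical", alpha=-0.2))
res = run_assay(circuit, cfg)
print(round(res.ci, 3), res.reached_peak, round(float(res.h.min()), 2))
```

prints

```
0.494 False 0.31
```

for this seed the worm turns up the gradient and closes from 4.5 cm to
0.31 cm of the peak, spending enough of the assay near it for a
chemotaxis index of 0.49 (CI = 1 would mean sitting on the peak
throughout; 0 means no net approach), without entering the strict
0.1 cm "reached" disk.  Outcomes vary strongly with the seed (starting
heading, motor initialization, pirouette times); the packaged circuits
are partially optimized reference models, not full-scale evolved
solutions — see `docs/methods.md` for what they do and do not
reproduce.

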