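# maskingnet

A spiking attractor-network simulator of **metacontrast backward masking**
in the early visual system.  When a brief visual target is followed within
~100 ms by a nearby mask, target perception is impaired.  `maskingnet`
models this as the interaction of cortical attractor memories spanning LGN,
V1 and V2: a stimulated feature detector — a sparse set of recurrently
wired minicolumns — must *complete* (become fully active through recurrent
excitation) and propagate from V1 through V2 before lateral inhibition from
the mask, or the loss of reinforcing feedback, burns it out.  The package
is for computational neuroscientists studying the feedforward-vs-feedback
debate in masking and, more generally, attractor dynamics in laminar
cortical microcircuits.

## Model

Two patches (V1, V2) of hypercolumns x minicolumns, three laminae (L2/3,
L4, L5), four Hodgkin-Huxley cell classes (adapting pyramidal cells,
fast-spiking basket cells, weakly adapting RSNP interneurons, LGN relay
cells), AMPA/NMDA/GABA_A synapses with short-term depression, 300 Hz
Poisson background, and 10 ms inter-areal latencies:

* **model 1** — 4x4 hypercolumns of 16 minicolumns (39,424 neurons with the
  LGN); 18 random orthogonal attractor memories per area (10 minicolumns in
  10 distinct hypercolumns).  Target: 4 stimulated pattern minicolumns; a
  noise mask stimulates 4-5 minicolumns of *other* memories in the same
  hypercolumns.
* **model 2** — 9x9 hypercolumns of 8 minicolumns (99,792 neurons); 72
  vertical-line feature detectors per area.  Target: one line; mask: the
  two parallel lines 1-3 hypercolumns away, with lateral inhibition
  extending horizontally (100% / 50% / 25% with column distance).

A trial presents target-alone, mask-alone, then target+mask at SOAs of
20-120 ms at one-second spacing (relay cells fire at ~50 Hz for 20 ms
targets and 50-60 ms masks).  A pattern *completes* in an area when >= 7 of
its minicolumns each fire >= 10 layer-2/3 pyramidal spikes; completion in
both V1 and V2 is the proxy for conscious perception.  Masking functions
(completion % vs SOA) are classified *type A* (monotone recovery) or
*type B* (U-shaped).  See `docs/methods.md` for equations, parameters and
the desk-scale subsampling compensation.

## Worked example

Build a desk-scale model-1 individual, run one backward-masking trial and
score completion:

```python
from maskingnet import (ExperimentConfig, build_model, run_trial)

cfg = ExperimentConfig.model1(scale=0.2, n_individuals=1, n_trials=1)
network = build_model(cfg, individual_seed=1)       # 9,216 cortical cells
result = run_trial(network, cfg, trial_seed=7)
print(result[["condition", "soa_ms", "complete_V1", "complete_V2",
              "complete_both"]].to_string(index=False))
```

```
  condition  soa_ms  complete_V1  complete_V2  complete_both
target_only     NaN         True         True           True
  mask_only     NaN        False        False          False
target_mask    20.0        False        False          False
target_mask    40.0        False         True          False
target_mask    60.0         True        False          False
target_mask    80.0         True        False          False
target_mask   100.0         True        False          False
target_mask   120.0         True         True           True
```

The target alone completes regionally (V1 and V2); the mask alone never
completes the target's pattern; with both present, completion fails at
short SOAs and recovers as the SOA grows — backward masking.  Aggregating
many trials (`run_experiment`) yields the masking curve, and
`maskingnet.analysis.classify_masking_type` labels its shape.

The same pipeline is exposed as a CLI
(`maskingnet build | calibrate | run | experiment | analyze | plot`); e.g.

```
maskingnet experiment --model 1 --scale 0.2 --individuals 2 --trials 2 \
    --seed 0 --out results.csv
maskingnet analyze results.csv --out curve.csv
maskingnet plot curve.csv --out curve.png
```

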