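# modsnn — modular spiking neuronal cultures in silico

`modsnn` models how neuronal cultures with a modular ("tracks") architecture
respond to, and recover from, physical damage. It is aimed at computational
neuroscientists studying lesion robustness, self-organized recovery through
synaptic plasticity, and the link between collective activity and
information processing in cultured networks.

The package implements the full in-silico pipeline as a reusable toolkit:

- **Network generation** — neurons scattered over a culture disk; axons
  grown as segment chains with Rayleigh-distributed lengths (⟨ℓ⟩ = 1.1 mm)
  and Gaussian heading noise (σθ = 0.1 rad); parallel crevice/valley bands
  deflect growth (crossing probabilities P_down = 0.5, P_up = 0.05), biasing
  connectivity along tracks into a modular connectome.
- **Spiking dynamics** — Izhikevich neurons
  (dv/dt = 0.04v² + 5v + 140 − u + I, 80% regular-spiking excitatory / 20%
  fast-spiking inhibitory), exponentially decaying synaptic currents
  (τ_E = 5 ms, τ_I = 20 ms), conduction delays, 1 Hz Poisson background.
- **Plasticity** — nearest-neighbour STDP on E→E synapses with soft bounds
  A₊(w) = η₊(1 − w/w_max), A₋(w) = η₋·w/w_max; equilibrium mean weight
  w̄ = w_max·η₊/(η₊−η₋).
- **Lesions** — straight cuts that kill every neuron whose axon they
  transect; intra-/inter-modular orientation, half/full extent; timed
  recovery protocol with matched undamaged controls.
- **Metrics** — network-burst detection (20% of units in 200 ms),
  transfer-entropy effective connectivity (20 ms bins, Markov order 2,
  z ≥ 2), weighted global efficiency (L = w_max/w, Dijkstra), Louvain
  communities and NMI.
- **Reservoir computing** — synthetic 78-channel cochleagrams drive 5% of
  the neurons; a disjoint 5% provides a leaky spike-integration state; a
  ridge readout (λ = 1) classifies three stimulus classes before and after
  damage, with retrained or frozen output weights.

## Worked example

```python
import numpy as np
from modsnn import (desk_preset, generate_network, settle, stage_seed,
                    run_protocol)
from modsnn.experiment import scenario_cuts, replicate_metrics

cfg = desk_preset(master_seed=1)          # 1.5 mm culture, ~700 neurons
net = generate_network(cfg.growth)
net, _ = settle(net, cfg.settle_s, noise=cfg.noise, stdp=cfg.stdp,
                seed=stage_seed(1, "settle"), in_place=True)
print(f"{net.n_neurons} neurons, {net.n_edges} edges, "
      f"mean E->E weight {net.mean_ee_weight():.3f}")

cut = scenario_cuts(cfg.growth.culture_diameter)["intra_half"][1]
result = run_protocol(net, cut, cfg.protocol, noise=cfg.noise,
                      stdp=cfg.stdp, seed=1)
cols = ["timepoint", "n_alive", "n_bursts", "burst_ratio_control"]
print(replicate_metrics(result)[cols].to_string(index=False))
```

prints

```
708 neurons, 11775 edges, mean E->E weight 3.128
timepoint  n_alive  n_bursts  burst_ratio_control
      pre      708        78                  NaN
       t0      540         7             0.076923
      t1m      540        17             0.220779
      t3m      540        40             0.370370
      t6m      540        71             0.470199
```

Read: a half-length cut perpendicular to the tracks kills 168 of 708
neurons; burst frequency collapses to ~8% of the matched undamaged control
immediately after injury and, with STDP running, climbs back towards the
control level over the (scaled) recovery schedule. The settled mean E→E
weight sits at the STDP equilibrium w̄ = 6.8·0.1/0.22 ≈ 3.09.

A command-line interface mirrors the pipeline stages
(`modsnn generate | settle | damage-run | bursts | effconn |
reservoir-eval | report`); `modsnn damage-run --preset desk --out results/`
runs the six-scenario damage batch. Each replicate produces one HDF5 bundle
(`<scenario>_rep<k>.h5`) holding the lesioned network, one raster group per
timepoint (`rasters/pre`, `rasters/t0`, ...) and matching weight/alive
snapshots (`snapshots/<label>`), alongside per-replicate metric CSVs, a
settling weight log, the pooled `burst_ratio_table.csv` and a
`manifest.json` with per-replicate seeds and the config hash.

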