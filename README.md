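# pgcc — Compton-camera prompt-gamma imaging for proton range verification

Proton radiotherapy places its dose maximum (the Bragg peak) at the end of
the proton range; verifying that range *in vivo*, during delivery, is an
open clinical problem.  Prompt gamma (PG) rays emitted along the beam path
can be imaged by a Compton camera (CC): each photon that scatters twice or
three times in the camera constrains its own emission point to a
*cone of origin* — apex at the first interaction, axis through the first
two interactions, half-angle θ from the Compton relation

    cos θ = 1 − mₑc² (1/E′ − 1/E₀),   E′ = E₀ − e₁,

with e₁ the first deposit and E₀ the initial energy (the deposit sum for
double-scatter events; the gamma-ray-tracking estimate
E₀ = e₁ + e₂/2 + sqrt((e₂/2)² + e₂mₑc²/(1 − cos θ₂)) for triples, where θ₂
is the geometric deflection at the middle interaction).  Backprojecting many
kernel-weighted cones onto a voxel grid images the PG emission, whose distal
falloff tracks the beam range.

At clinical dose rates this breaks down: detector pileup records events
whose interactions come from different photons ("false"), in the wrong
order ("mis-ordered"), or as a true double plus an unrelated hit
("double-in-triple").  `pgcc` implements the full chain that addresses
this, for researchers studying CC-based range verification and
machine-learning event processing:

* a seeded synthetic generator for a two-stage CZT camera — analytic
  Klein–Nishina photon transport, module-level trigger/pileup readout with
  anode-order scrambling, and ground-truth event labels;
* a residual fully-connected classifier (scikit-learn estimator API) that
  identifies each event's type and true interaction order over a masked
  16-class scheme, plus a kinematics-only baseline;
* the label-driven cleanup (remove false, re-order true, recover embedded
  doubles) and per-proton detection-rate bookkeeping;
* kernel-weighted cone backprojection with per-event propagated angular
  uncertainties, energy windows, and depth/crossfield profile analysis:
  PGmax/PG80/PG60, contrast-to-noise ratio, and replicated range-shift
  summaries.

## Worked example

```python
from pgcc import (BeamModel, SimulationConfig, simulate, train,
                  predict_labels, process, summarize_rates,
                  ImageGrid, EnergyWindow, reconstruct,
                  depth_profile, range_metrics)

# one high-dose-rate delivery (~4.6e8 protons at the assumed PG yield)
cfg = SimulationConfig(beam=BeamModel(dose_rate_kMU_per_min=180.0),
                       n_emissions=32_000_000, seed=7)
raw = simulate(cfg)

# train the event classifier on an independent, shuffled dataset
train_cfg = SimulationConfig(beam=BeamModel(dose_rate_kMU_per_min=180.0),
                             n_emissions=32_000_000, seed=8,
                             shuffle_training=True)
clf, report = train(simulate(train_cfg), epochs=15, random_state=0)
print(f"validation DS accuracy: {report['validation']['ds_accuracy']:.2f}")

processed = process(raw, predict_labels(raw, clf))
rates = summarize_rates(raw, predict_labels(raw, clf),
                        raw.provenance["protons_simulated"])
print(f"events {len(raw)} raw -> {len(processed)} processed; "
      f"usable fraction {rates.usable_fraction_of_raw:.2f}")

grid = ImageGrid().profile_slab()          # central depth-profile slab
for tag, ds in [("raw", raw), ("processed", processed)]:
    m = range_metrics(depth_profile(reconstruct(ds, grid, EnergyWindow.FULL)))
    print(f"{tag}: PGmax {m.pgmax_depth:.1f} cm, PG60 "
          f"{m.pg60_depth:.1f} cm, CNR {m.cnr:.1f}")
```

Output (seeds as above):

```
validation DS accuracy: 0.85
events 19028 raw -> 12188 processed; usable fraction 0.64
raw: PGmax 7.7 cm, PG60 18.3 cm, CNR 15.6
processed: PGmax 8.9 cm, PG60 18.1 cm, CNR 30.1
```

At the highest clinical dose rate about a third of the recorded events are
pileup; the classifier removes them and restores interaction order, here
roughly doubling the image contrast-to-noise ratio (larger runs give
2–7×).  PG60 sits ~2.5 cm distal to the 15.6 cm beam range because of the
cone-backprojection point spread; range *shifts* are read from the change
in PG60 between deliveries, which tracks imposed millimetre shifts (see
the range-shift study in `scripts/acceptance.py`).

The same chain is scriptable from a shell:

```sh
pgcc simulate --n-emissions 32000000 --dose-rate 180 --seed 7 raw.h5
pgcc simulate --n-emissions 32000000 --dose-rate 180 --seed 8 --shuffle train.h5
pgcc train train.h5 model.npz
pgcc process raw.h5 model.npz processed.h5
pgcc reconstruct processed.h5 img --window full --grid profile
pgcc analyze img
```

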