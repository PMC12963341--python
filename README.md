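# poreflux

Ion-permeation analysis for membrane-pore simulations and single-channel
electrophysiology, built around the characterization of a narrow β-barrel
nanopore — the transmembrane barrel of a trimeric autotransporter adhesin
with its lumen-occluding coiled-coil removed.

The package answers two questions about such a pore, each with a complete,
reusable pipeline plus a matched synthetic-data generator so every step can
be validated end to end without access to raw recordings or trajectories:

1. **How much current do ions carry through the pore, and what slows them
   down?** Given per-ion trajectories, `poreflux` counts complete
   directional translocations with periodic-boundary-aware two-plane
   hysteresis and converts them by

   *I* = (*N*<sub>K</sub> + *N*<sub>Cl</sub>) · *e* / Δ*t*,  *G* = *I* / *V*,

   where *N*<sub>K</sub> counts K⁺ crossings in +Z, *N*<sub>Cl</sub> counts
   Cl⁻ crossings in −Z, and *e* = 1.602 × 10⁻¹⁹ C. Replicates aggregate as
   mean ± SD. Dwell-time analysis quantifies transient anion trapping in
   the constriction formed by two arginine rings, and a two-condition
   comparison contrasts the wild-type-like pore with its constriction-free
   (double-glycine) surrogate. A Brownian-dynamics simulator — ohmic field
   partitioning, hard-wall cylindrical pore, Cl⁻-selective binding
   well + exit barrier — generates the trajectories. Kabsch-superposed
   RMSD series cover structural-stability analysis.

2. **What does the pore look like in planar-bilayer recordings?** A
   trace-idealization pipeline estimates baseline and noise, detects open
   events, segments sub-conductance levels by penalized change-point
   search, classifies events as step-like / multi-level / erratic, and
   summarizes step-like conductances as median (IQR) with the long-event
   (>1 s) fraction compared against liposome-fusion controls by the
   Brunner–Munzel rank test (self-implemented, midrank ties, Satterthwaite
   degrees of freedom). A labelled recording generator emulates the
   acquisition chain (+150 mV, 20 kHz sampling, 4 kHz Bessel low-pass).

See `docs/methods.md` for models, parameter defaults and numerical choices.

## Worked example

```python
from poreflux import pore_sim, permeation, trace_sim, ephys

# --- permeation arm: triplicate 50-ns runs of the trap-free pore ---
cfg = pore_sim.SimConfig(duration_ns=50.0)          # 1 M KCl, +150 mV
trajs = pore_sim.make_replicates(cfg, [1, 2, 3])
agg = permeation.aggregate_replicates(
    [permeation.estimate_conductance(t) for t in trajs])
print(f"I = {agg.mean_current_pA:.2f} +/- {agg.sd_current_pA:.2f} pA")
print(f"G = {agg.mean_conductance_nS:.3f} +/- {agg.sd_conductance_nS:.3f} nS")

# --- electrophysiology arm: a labelled synthetic recording, re-analyzed ---
proto = trace_sim.TraceProtocol(n_events=60, seed=0)
trace = trace_sim.render_trace(trace_sim.generate_events(proto), proto)
found, baseline = ephys.analyze_trace(trace)
summ = ephys.event_conductances(found, proto.voltage_mV)
print(f"step-like G: median {summ.median_nS:.2f} nS, "
      f"IQR {summ.q1_nS:.2f}-{summ.q3_nS:.2f} nS (n={summ.n})")
```

prints

```
I = 81.17 +/- 35.73 pA
G = 0.541 +/- 0.238 nS
step-like G: median 0.18 nS, IQR 0.14-0.34 nS (n=30)
```

The first block is the simulated trap-free pore: ~80 pA at +150 mV, i.e. a
half-nanosiemens conductance, with replicate scatter reported as ± SD. The
second block recovers the step-like single-channel conductance summary from
a noisy synthetic recording; the generator's law has median 0.17 nS and IQR
0.12–0.32 nS, so a 30-event cohort lands within sampling error of it.
Comparing these events' durations against a fusion-control cohort with
`ephys.duration_analysis` gives a >1 s fraction of 57% vs 12% and a
Brunner–Munzel p ≈ 10⁻¹¹.

## Command line

Every pipeline stage is also a `poreflux` subcommand over the same library
code: `simulate-pore`, `simulate-trace`, `permeation`, `rmsd`, `dwell`,
`compare`, `ephys`, `stats bm`, and an end-to-end `report`. Each writes
machine-readable JSON/TSV plus a manifest with config hash and seeds:

```bash
poreflux simulate-pore --seed 1 --out run1
poreflux permeation --traj run1.tsv --out report.json
poreflux simulate-trace --seed 2 --out trace.csv --truth truth.json
poreflux ephys --trace trace.csv --out events.tsv --summary summary.json
```

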