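# cgtkit

Thermodynamic, kinetic and conformational-substate analysis of polymer
**coil–globule transitions** (CGT) from bead-chain trajectory ensembles.

Thermosensitive polymers such as acrylamide 20-mers collapse from an
extended *coil* to a compact *globule* on heating (LCST behaviour).
Characterising that transition from simulation ensembles recorded at
several temperatures requires a chain of estimators, which this package
provides as a composable library:

* **FJC descriptors** — per-frame radius of gyration `Rg`, solvent
  accessible surface area `σ` (Shrake–Rupley), sum of inter-segment
  angles `Ω` and segment contacts `ν` of a freely-jointed-chain
  segmentation (3 monomers per segment), plus backbone torsions.
* **Markov state models** — global standard-scaled k-means
  discretization of the 4D descriptor space, transition-matrix
  estimation (with a reversible variant), implied timescales, PCCA
  two-state splitting, and mean first passage times (MFPT).
* **Hidden Markov models** — discrete-emission Baum–Welch and Viterbi
  for resolving ambiguous macrostate assignments and for
  per-temperature conformational substates.
* **Thermodynamics & kinetics** — `K_eq = p_glob/p_coil`,
  `ΔG = −RT ln K_eq`, van't Hoff decomposition
  `ln K_eq = −ΔH/RT + ΔS/R` with `T* = ΔH/ΔS`, Eyring fits
  `k(T) = cT·exp(−ΔG‡/RT)`, Boltzmann-inverted free-energy profiles
  over `Rg`, and replica leave-one-out uncertainty spreads.
* **Dihedral entropy** — von Mises kernel density estimates of each
  backbone torsion and `ΔS_Pol = S_G − S_C`.
* **Substate catalog** — per-temperature substate models matched across
  temperatures and named by Rg rank (`C0` = most extended coil,
  `G0` = most compact globule), with occupancy tables.
* **Synthetic data** — a Metropolis bead-chain sampler with
  temperature-strengthening attraction, and a hidden-Markov emission
  generator with exact thermodynamic/kinetic ground truth for
  validation.

## Worked example

The whole analysis runs from one config object.  A reduced synthetic
study (6 temperatures × 3 replicas × 2,000 frames; `examples/06_full_pipeline.py`):

```python
from cgtkit.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(n_frames=2_000, n_replicas=3, n_clusters=100,
                     entropy_min_frames=200, seed=0)
res = run_pipeline(cfg)
print(res.vant_hoff.T_star, res.K_eq, res.rates)
```

prints (abridged):

```
transition temperature T*: 283.84 K (true 284.20 K)
dH = 93.9 kJ/mol (true 100.0), dS = 330.6 J/(mol K) (true 351.86)
van't Hoff r^2 (linearised) = 0.9907

  T/K    K_eq (true)      k_fwd (true)       k_bwd (true)   /ns
 277.0   0.336 (0.333)    0.0708 (0.0821)    0.2115 (0.2500)
 283.0   0.902 (0.835)    0.2058 (0.1910)    0.2278 (0.2319)
 292.0   2.950 (3.095)    0.2273 (0.2500)    0.0770 (0.0798)
```

`K_eq` rises through 1 near 284 K — the coil–globule transition
temperature `T* = ΔH/ΔS` — while the forward rate overtakes the
backward rate.  At this reduced size individual `K_eq` and rate values
scatter by 10–20%, yet `T*` (an interpolated zero crossing) is already
pinned to a few tenths of a kelvin; the full study size (4 × 20,000
frames per temperature) brings per-temperature `K_eq` errors under 5%.
The substate catalog recovers the four generating conformational
states and their occupancy trends.

Each script in `examples/` demonstrates one capability (MC sampling,
descriptors, van't Hoff/Eyring fitting, dihedral entropy, MSM/MFPT,
full pipeline) and prints a line explaining the numbers it shows.

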