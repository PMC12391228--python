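# cellflow

Coarse-grained simulation of whole eukaryotic cells in flow, for
mechanobiology studies of how cell stiffness and viscosity shape behavior
in micropipette aspiration and microfluidic devices.

A cell is modeled as two closed triangulated membranes — the cell surface
and the nucleus — whose vertices are dissipative-particle-dynamics (DPD)
particles, joined by a sparse network of Kelvin–Voigt (KV) bonds standing
in for the cytoskeleton. Membrane elasticity combines worm-like-chain
bonds, a per-triangle expansion term, dihedral bending
k_b[1 − cos(θ − θ₀)], and global area/volume constraints; membrane
viscosity is a pairwise dissipative force with matched thermal noise.
Each KV bond carries the stress law

    σ = k_s ε + k_v dε/dt,    ε = (l − l₀)/l₀,

so a handful of parameters (spring k_s, damper k_v, bond density ρ,
wiring width w) controls whole-cell viscoelasticity; the nucleus interior
reuses the same bonds between most-distant vertex pairs at five-fold
spring stiffness (k_s^nuc = 5 k_s^cyt). The package ships virtual
instruments — micropipette aspiration (pressure ramp and constant-pressure
creep) and an obstacle-array microchannel — plus estimators that turn the
traces into moduli via the Theret half-space model,
E = (3Φ/2π)·dΔP/dL_n for the ramp and a standard-linear-solid creep fit
for the apparent viscosity.

See `docs/methods.md` for the full model description, defaults, and
numerical choices.

## Worked example

Build the calibrated cell (k_s = 120, k_v = 10, ρ = 0.8, M2 wiring with
w = 5, nuclear–cytoplasmic volume ratio 0.29), aspirate it with a
quasi-static pressure ramp, and fit the elastic modulus:

```python
from cellflow import build_cell, run_aspiration, theret_elastic
from cellflow.sweeps import RAMP_PROTOCOL

cell = build_cell(6.6, nc_ratio=0.29)   # 6.6 um cell, calibrated defaults
print(f"outer vertices: {cell.n_outer}, nucleus vertices: {cell.n_nucleus}")
print(f"cytoskeleton bonds: {len(cell.cytoskeleton)} "
      f"(rho = {len(cell.cytoskeleton)/cell.n_outer:.2f})")
print(f"nucleus spring stiffness: {cell.nucleus_bonds.k_s[0]:.0f}")

trace = run_aspiration(cell, RAMP_PROTOCOL, mode="ramp", seed=1)
est = theret_elastic(trace, window=None)
print(f"Theret elastic modulus: {est.elastic_modulus:.1f} "
      f"+/- {est.elastic_se:.1f} (simulation pressure units)")
```

Output:

```
outer vertices: 642, nucleus vertices: 252
cytoskeleton bonds: 514 (rho = 0.80)
nucleus spring stiffness: 600
Theret elastic modulus: 472.7 +/- 6.1 (simulation pressure units)
```

The cell meshes to 642 outer and 252 nucleus particles at the default
bond length of 0.5; ρ = 0.8 wires 514 KV bonds between them, and the 5×
nucleus rule turns the cytoskeleton stiffness of 120 into 600 for the
nucleus interior. The fitted modulus is the slope of the suction-pressure
versus normalized-aspiration-length curve scaled by 3Φ/2π; it rises with
k_s and ρ and falls with membrane persistence length (`cellflow.sweeps`
automates those sweeps).

A command-line layer wraps the same library:

```sh
cellflow build --diameter 6.6 --out cell.data   # LAMMPS data + JSON sidecar
cellflow aspirate --mode ramp --out trace.tsv
cellflow analyze trace.tsv --mode ramp
cellflow flow --gap 2.6 --out transit.json
cellflow sweep k_s 60,120,240
```

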