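# fdapsim

Simulation-assisted analysis of actin photoactivation experiments.

## The problem

Pulse-labeling actin with a photoactivatable fluorophore (PA-GFP) and
watching the signal decay out of the activated region (fluorescence decay
after photoactivation, FDAP) mixes two processes: fast diffusion of G-actin
monomers out of the region, and slow release of subunits from immobile
F-actin filaments. Traditional half-time analysis confounds them — and
ignores that a substantial fraction of the signal is already gone before
the first camera frame. `fdapsim` separates the two by forward-simulating
the experiment in a realistic 3-D cell shape and fitting measured decay
curves against a precomputed library of simulated outcomes, recovering the
**G:F ratio** and the **filament depolymerization rate** `K_dep`
simultaneously.

## The model

Two photoactivated species on a voxelized cytoplasm Ω with zero-flux
boundaries:

    ∂g/∂t = D ∇²g − k_pol g + K_dep f        (PA G-actin, diffusing)
    ∂f/∂t =          k_pol g − K_dep f        (PA F-actin, immobile)

with the steady-state (detailed-balance) constraint
`k_pol = K_dep · F₀ / G₀`, `G₀ = A_tot − F₀` (default `A_tot` = 200 µM,
`D` = 3 µm²/s). A 65-ms laser pulse converts dark actin to the PA state
inside a 2-µm-diameter cylinder through the cytoplasm; the ROI-mean PA
concentration is recorded for 25 s and normalized to its value at 0.035 s
(the first frame at 30 frames/s). A library of 380 scenarios
(F₀ = 10…190 µM × K_dep = 0.01…0.20 s⁻¹) is swept once per geometry;
experimental curves are matched to the scenario with the lowest RMSD on a
non-uniform time grid (0.05-s steps to 3 s, 0.2-s steps to 25 s).

Numerics: backward-Euler diffusion on the masked voxel grid (sparse LU,
cached across the library sweep), exact closed-form update of the linear
exchange reaction, half-cell mirror symmetry, and fractional-coverage
weighting of the activation disc. Total PA is conserved to round-off.

## Worked example

```python
import fdapsim as fs

geom = fs.make_round_cell(20.0, 3.5, 0.3)          # radius, height, edge (um)
roi  = fs.ROISpec(center=(10.0, 0.0), radius=1.0)  # 2-um disc, 10 um out
grid = fs.voxelize(geom, 0.5, half_cell=True, spacing_z=0.25, roi=roi)

# small library around G:F = 1
spec = fs.GridSpec(F_values=(80., 90., 100., 110., 120.),
                   K_values=(0.04, 0.05, 0.06, 0.07, 0.08))
lib = fs.generate_library(spec, grid, roi)

# a synthetic "experiment" with known truth, fitted back
truth = lib.curve(100.0, 0.06)
exp = fs.generate_synthetic_curve(truth, {"F0": 100, "K_dep": 0.06},
                                  noise_level=0.02, seed=7)
res = fs.fit_curve(exp.curve, lib)
print(f"F = {res.F:g} uM, K_dep = {res.K_dep:g} 1/s, "
      f"G:F = {res.ratio:g}, RMSD = {res.rmsd:.4f}")
```

prints

```
F = 100 uM, K_dep = 0.06 1/s, G:F = 1, RMSD = 0.0157
```

i.e. the fitter recovers the generating parameters exactly (the best grid
cell), with the RMSD reflecting only the injected 2% frame noise. The same
workflow is available from the shell:

```
fdapsim build-library --out lib.h5
fdapsim synth --library lib.h5 --n 5 --out-dir data/
fdapsim fit --library lib.h5 --curves data/synth_*.csv --out fits.csv
fdapsim delay-loss --D 3 --delays 0.02,0.1
```

## Layout

- `fdapsim.geometry` — analytic cell shapes (rounded cell, axon,
  body-plus-projections), voxelization, ROI placement
- `fdapsim.simulate` — the reaction–diffusion forward model
- `fdapsim.library` — (F × K_dep) sweeps, HDF5 persistence
- `fdapsim.fitting` — RMSD grid search (`DecayCurveFitter`), immobile-
  fraction subtraction, diffusion-only fitting, cohort statistics
- `fdapsim.sensitivity` — finite-difference sensitivity maps
- `fdapsim.synthetic` — synthetic experiments with known ground truth
- `fdapsim.config` / `fdapsim.cli` — YAML config and the `fdapsim` CLI

See `docs/methods.md` for the modeling assumptions, numerical choices and
their limitations.
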