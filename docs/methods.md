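# Methods

## Model

The package simulates fluorescence decay after photoactivation (FDAP) of
actin in a closed cytoplasmic domain. Actin exists as freely diffusing
monomer (G) and immobile filament (F) pools that exchange by
pseudo-first-order polymerization and depolymerization. The cell is assumed
to be at thermodynamic equilibrium over the ~25 s of an experiment: the
bulk concentrations F₀ and G₀ = A_tot − F₀ are constant, which pins the
polymerization rate to `k_pol = K_dep F₀ / G₀` (detailed balance). All
photoactivated (PA) forms carry the same kinetics as dark forms, so the
dark pools never need to be represented explicitly: they are identically
(G₀, F₀) minus the PA fields. During the activation pulse the laser
converts dark actin to PA inside the ROI at rate `laser_rate`, applied to
monomer and filament proportionally; diffusion is active throughout the
pulse, which is what makes the "lost before the first frame" effect
reproducible.

Assumptions inherited from this picture: F-actin is strictly immobile (no
retrograde flow, severing or filament-length dynamics); a single effective
diffusion coefficient covers free G-actin and monomer–protein complexes;
photoactivation efficiency is uniform across the ROI depth (valid for an
open confocal pinhole); bleaching is neglected.

## Parameters (units: µm, s, µM)

| parameter | default | meaning |
|---|---|---|
| `D` | 3 µm²/s | G-actin diffusion coefficient |
| `A_tot` | 200 µM | total actin |
| `F0` | 10–190 µM (library axis) | F-actin concentration; G:F = (A_tot−F₀)/F₀ |
| `K_dep` | 0.01–0.20 s⁻¹ (library axis) | depolymerization rate |
| `t_pulse` | 0.065 s | activation pulse duration |
| `laser_rate` | ln(10³)/0.065 ≈ 106 s⁻¹ | conversion rate; ≥ 99.9% of ROI fluorophores converted by pulse end |
| `t_norm` | 0.035 s | first recorded frame (30 frames/s); curves normalized to 1 here |
| `t_post` | 25 s | recorded decay duration |

Geometries: a rounded spread cell with dome height profile
`h(r) = t_e + (H − t_e)(1 − (r/R)²)^p` (default p = 2, R = 20, H = 3.5,
t_e = 0.3; a second reference 15/7/0.4), an axon-like cylinder
(L = 40, r_a = 0.5) lying on the substrate, and a procedural amoeboid body
with radial narrow projections standing in for image-derived protrusive
shapes. The exact dome expression is a documented stand-in for the
analytic rounded-cell geometry whose published form is not available;
fits are demonstrably insensitive to this choice (the two reference round
geometries select the same library cell within one grid step).

## Numerics

* **Voxelization.** Regular rectangular grid, membership decided at voxel
  centers; default spacing 0.35 µm in-plane and 0.2 µm axially for the
  rounded cell (≈ 3.5 × 10⁴ interior voxels in the half-cell). This size
  was chosen so a full 25-s simulation completes in well under a minute on
  one CPU; the mesh-refinement test bounds its pointwise distance from a
  halved-spacing solution at < 1% of the normalized curve.
* **Half-cell symmetry.** The ROI sits on y = 0; the mirror plane is a
  voxel boundary and the zero-flux condition there makes the half-domain
  solution exactly the symmetric full-cell solution.
* **Time stepping.** Operator splitting: backward-Euler diffusion solve
  (sparse LU on the masked-grid Laplacian, factorizations cached per
  distinct `D·dt` and re-used across an entire library sweep), then the
  exact 2×2 closed-form update of the linear exchange reaction, then the
  exact exponential laser update during the pulse. Steps: 2 ms through the
  pulse and the first 100 ms, 10 ms to 0.5 s, 50 ms to 25 s. Backward
  Euler on an M-matrix preserves positivity; both sub-steps conserve total
  PA exactly (column sums), so conservation holds to round-off.
* **ROI discretization.** The activation/readout disc is represented by
  fractional voxel coverage (4×4 in-plane supersampling): boundary voxels
  are activated at `laser_rate` × coverage and weighted by coverage in the
  ROI mean. This has the same mesh-converged limit as a sharp
  center-membership mask but roughly halves the discretization error of
  the loss fractions at the default spacing (verified against a
  high-resolution 1-D radial finite-volume oracle in the flat-slab limit,
  agreement < 0.2%).
* **Normalization.** Curves are normalized by linear interpolation at
  exactly `t_norm`; degenerate (non-positive) normalizers raise.
* **Fitting.** Exhaustive RMSD scan over the library on the non-uniform
  fit grid (0.05-s steps to 3 s, 0.2-s to 25 s), linear interpolation for
  resampling. Ties break toward smaller `K_dep`, then smaller F —
  deterministic by construction. Curves shorter than 25 s are fitted on
  the overlap (flagged); shorter than 3 s are rejected. Nine runner-up
  fits are reported by default.
* **Immobile-fraction subtraction.** The value at `t_ref` = 2.5 s is
  treated as immobile, subtracted up to `t_ref`, and the result is
  renormalized at `t_norm`; only the first 1.5 s are used for
  diffusion-coefficient fitting.

## Synthetic experiments

The generator emulates the acquisition chain: forward-simulate, sample at
frame times (first frame `first_frame` = 0.035 s, then 1/fps = 1/30 s),
add independent Gaussian noise with s.d. = `noise_level` × first-frame
intensity (default 2%, configurable — the minimal defensible noise model),
renormalize to the first frame. A master seed spawns per-curve seeds
(`numpy.random.SeedSequence`), recorded in metadata; regeneration is
bit-identical. It reproduces the frame-rate artifact: the same decay
sampled at 4.25 fps (first frame 0.235 s) appears substantially slower
than at 30 fps. It does **not** model shot noise, detector gain,
bleaching, or F-actin motion, so passing recovery tests demonstrate the
identifiability of the two parameters under the stated model, not
robustness to every real-world artifact.

## Statistics

Cohort comparisons use the two-tailed two-sample t-test (Welch by default;
pooled variance available), 5/25/50/75/95th percentiles, mean ± 95% CI,
and the within-group Pearson correlation between `K_dep` and the G:F
ratio, all via `scipy.stats`.

## Design choices made where the design was open

* The Methods-consistent 19 × 20 grid (380 scenarios, K_dep from
  0.01 s⁻¹) is the default; a K_dep = 0 row can be enabled in the config.
* Delay loss is defined as the fraction of ROI PA signal lost between
  pulse end and pulse end + delay (the natural reading of "lost before
  imaging begins"); "molecules that left by the first frame" uses the
  pulse-end ROI content as denominator, since the total ever-converted
  pool is inflated ~1.6× by dark monomers diffusing into the ROI during
  the pulse and being converted there.
* Sensitivity differentials are computed on normalized curves (the
  quantities the fitter compares); raw-concentration differentials are
  available by passing raw curves.
* Experimental curves are assumed background-subtracted and first-frame
  normalized; a flag renormalizes at `t_norm` by interpolation.

## Known limitations

* Grid-cell fits only: no interpolation between library cells and no
  continuous-parameter optimization or posterior uncertainty; the top-k
  RMSD ranking is the only fit-quality context.
* The solver is first-order in time; the step schedule was sized so the
  time error is well below the mesh error at default resolution.
* Loss fractions during/just after the pulse carry ~1–2 percentage points
  of residual discretization bias at the default mesh (they converge from
  below; see the mesh-refinement test).
* The procedural projection-cell geometry is a synthetic stand-in, not a
  segmented real cell.
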