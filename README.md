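# rosphere

Diffusional spheres of influence of hydrogen peroxide around marine
phytoplankton and bacterioplankton.

Marine phytoplankton maintain intracellular H₂O₂ well above the seawater
background and leak it outward; heterotrophic bacterioplankton hold it below
background and act as local sinks. Whether one cell can directly alter a
neighbour's H₂O₂ microenvironment — as opposed to merely contributing to the
bulk pool — depends on the competition between two length scales: the radius
of the cell-specific *sphere of influence*, and the mean cell-to-cell spacing
set by the suspension density. `rosphere` computes both, classifies taxon ×
habitat combinations as interacting or not, and renders true-scale community
visualizations in which cell symbols share the scaling of the spatial axes.

The package is for microbial ecologists and biogeochemists who want
quantitative, reproducible versions of these back-of-envelope arguments:
reactive-oxygen microenvironments, phycosphere-scale solute exchange, and the
spatial statistics of plankton suspensions.

## The model in brief

* **Spacing.** For a suspension at density ρ (cells m⁻³), the mean
  nearest-neighbour distance of randomly located cells is
  `⟨d⟩ = c·ρ^(−1/3)` with `c = Γ(4/3)·(4π/3)^(−1/3) ≈ 0.554` — the Poisson
  correction to the naive reciprocal cube root.
* **Gradients.** A static spherical cell of radius R holding intracellular
  concentration C_cell against background C_sea projects a front
  `r(t) = R + √(D·t)` carrying `C = C_cell·(R/r)³·e^(−µt)` (sources, floored
  at C_sea) or `C = C_cell·(r/R)³` (sinks, capped at C_sea).
* **Thresholds.** The sphere of influence ends where C reaches C_sea: without
  decay `r* = R·(C_cell/C_sea)^(1/3)`; with decay, a Lambert-W closed form in
  `Y = 2µt/3` (Newton-refined), cross-checked by a bisection oracle.
* **Classification.** A taxon interacts when `r* ≥ ⟨d⟩` at its density;
  inverting the spacing law gives critical-density threshold lines per
  intracellular:extracellular ratio.

See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

```python
import rosphere as rp

# Mean spacing inside a Phaeocystis colony (2.4e13 cells m⁻³)
rp.mean_cell_spacing(2.4e13).mean_spacing_um      # 19.204730227342562

# Sphere of influence of a 2.2 µm colony cell at ratio 1000
rp.source_threshold_zero_decay(1e-6, 1e-9, 2.2).r_threshold_um   # 22.0

# 19.2 µm spacing < 22.0 µm sphere: colony cells interact directly
phae = rp.load_builtin_table().filter(habitat="colony", taxon="Phaeocystis")
rp.assess_community(phae, source_ratio=1000.0)[0].interacting    # True

# A diatom-sized source cell (10 µm) influences 90 µm beyond its surface
rp.source_threshold_zero_decay(1e-6, 1e-9, 10.0).distance_from_surface_um  # 90.0
```

The same numbers from the shell:

```
$ rosphere threshold --radius 10 --ratio 1000 --direction source
direction  cell_radius_um  ratio  t_threshold_us  r_threshold_um  dist_surface_um                 method
   source            10.0 1000.0             5.4           100.0             90.0 closed_form_zero_decay

$ rosphere assess --habitat colony
      taxon habitat   density_m3  radius_um  ratio  sphere_um  spacing_um  interacting
  Cyanobium  colony 1.000000e+13        1.0 1000.0       10.0   25.712558        False
Phaeocystis  colony 2.400000e+13        2.2 1000.0       22.0   19.204730         True
```

Reading: a 10 µm phytoplankter holding 10⁻⁶ M internally against a 10⁻⁹ M
background elevates local H₂O₂ out to 100 µm from its centre (90 µm from its
surface). Within a Phaeocystis colony the 22 µm spheres exceed the 19.2 µm
mean spacing, so colony cells bathe each other in elevated H₂O₂; the sparser
Cyanobium colony falls short. `rosphere figures --habitat colony --extent 0.1
--outdir out/` renders the corresponding true-scale scene with sidecar CSVs
carrying every plotted number.

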