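# xylokinetics

Quantification and mathematical modelling of the early growth dynamics of
**secondary xylem** in *Arabidopsis thaliana* roots.

Secondary growth — the radial thickening of stems and roots driven by the
cambium — begins in the Arabidopsis root around 7 days after germination
(DAG). During its early stages the secondary xylem occupies an inverted
cone inside the root: its base is the xylem cross-section area *a* at the
root base and its height is the longitudinal extension *h* of secondary
growth down the root. This package provides the full measurement-to-model
chain for that system, aimed at plant developmental biologists who work
from stained histological sections:

* **Automated cell counting** on Toluidine-Blue-style cross-section
  micrographs (dark walls, light lumens): smooth → threshold → size and
  circularity filtering → watershed splitting of touching cells, with a
  relative-count accuracy score against manual or ground-truth counts.
* **Growth-series summarisation** of replicate measurement tables, with
  cone-volume reconstruction `V = a·h/3` and quadrature error
  propagation.
* **Kinetic and allometric fitting.** Each quantity X ∈ {a, N, h, V}
  is modelled as exponential growth, the solution of the simplified
  Lockhart law dX/dt = kX:

  X(t) = X₀·e^(kt)

  fitted by orthogonal distance regression (ODR), Levenberg–Marquardt
  (LM) vertical least squares, or closed-form OLS on logs. The coupling
  of radial and longitudinal growth is the allometric power law

  h = c·aᵖ

  fitted by LM in linear space (free exponent or held at the allometric
  signature p = 2/5) and cross-checked by log–log regression and the
  Pearson correlation.
* **A fully seeded synthetic-data generator** for measurement tables,
  serial-section presence profiles (5 µm sections in 0.5 cm blocks) and
  section micrographs with pixel-level ground truth, so the entire
  chain is testable without microscope time.

## Worked example

```python
import xylokinetics as xk

report = xk.run_pipeline(xk.PipelineConfig(seed=1))
print(report.fits["area"].summary())
```

```
Fit summary — area (odr)
==============================================
nobs: 4    converged: True    R^2: 0.999968
----------------------------------------------
param             estimate         std err
X0             0.000129752     3.47189e-06
k                 0.393311      0.00185079
==============================================
```

The default pipeline draws a synthetic study — 10 replicate roots at
7, 11, 15 and 21 DAG with 10% measurement noise, centred on the group
means reported for this system — and recovers the generative area
log-slope (0.3952 d⁻¹) as k = 0.3933 ± 0.0019 d⁻¹. The same report
carries the other quantities and the allometry:

```python
>>> report.allometry["power_law"].estimates
{'c': 165.49, 'p': 0.5689}          # h = c·a^p on per-day means (mm units)
>>> report.allometry["pearson_r"]
0.9912                              # area-extension coupling
>>> report.fits["volume"].estimates
{'X0': 4.133e-05, 'k': 0.6206}      # cone volume, k ≈ k_a + k_h as expected
```

Counting a synthetic section image:

```python
img, truth = xk.generate_section_image(xk.ImageSpec(seed=5, n_cells=80))
result = xk.count_cells(img)
xk.count_accuracy(result.count, truth.true_count)   # e.g. 0.9875
```

The same operations are available from a shell via
`xylokinetics simulate|count|fit|run` (see `--help` on each subcommand);
`run` writes `report.json`, per-quantity series CSVs, `fits.csv` and
optional plot panels into an output directory.

Measurement CSVs use the header
`dag,replicate,area_um2,cell_count,extension_cm`; internally everything
is converted once to mm / mm² / mm³ / days.

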