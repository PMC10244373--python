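# Methods

## Probe model

The probe is treated as a two-state (dithiol/disulfide) species whose two
excitation channels are linear mixtures of the fully reduced and fully
oxidised endpoint intensities. Under that mixture model the endpoint-
corrected OxD formula

    OxD = (R − R_red) / [ (I490_min/I490_max)(R_ox − R) + (R − R_red) ]

is the exact algebraic inverse of the forward map OxD → R; the test suite
verifies this equivalence numerically over randomized calibrations rather
than assuming it. Potentials follow the two-electron Nernst equation with
R = 8.314 J mol⁻¹ K⁻¹, F = 96485 C mol⁻¹, T = 298 K by default (overridable
per experiment through `PhysicalConstants`). All potentials are handled in
millivolts, signed, negative = reducing.

Reference midpoints: −280 mV for the probe and −320 mV for the NADPH/NADP⁺
couple, both at pH 7. At titration equilibrium the probe and pool
potentials are taken as equal, which is what licenses reading E_NADP(H)
off the probe.

## pH handling

The probe exchanges 2 H⁺ per 2 e⁻, so its midpoint shifts with pH. Two
modes are provided:

* `paper_rounded` (default): exactly −6 mV per 0.1 pH unit (−60 mV/pH),
  the rounded field convention. Every compartment threshold this package
  reports (−338 mV at pH 7.3, −380 mV at pH 8.0, −350/−270 mV at pH 7.5)
  follows from this convention, so it is the default. The rule is extended
  linearly below pH 7 as well; the literature convention below pH 7 is
  unsettled, and users working in acidic compartments should treat those
  numbers with care.
* `exact_nernst`: RT ln10 / F ≈ −59.2 mV/pH, for sensitivity analysis.

The correction is applied to the probe midpoint potential, not to OxD:
OxD is a dimensionless fraction and the shift has units of mV; applying it
to the midpoint reproduces all published compartment thresholds exactly.

The pool standard potential E°′_NADP(H) = −320 mV is used as given,
without a pH correction, matching the convention in which pool potentials
are computed directly from concentration ratios at the stated pH. An
optional proton-corrected mode (−29.6 mV/pH; 1 H⁺ per 2 e⁻) is available
via `e_pool_from_ratio(..., ph_correct_pool=True)` but off by default.

## Detection window

Potentials are considered reliable between 5 % and 95 % probe oxidation.
The Nernst term gives (RT/2F) ln 19 ≈ 37.8 mV per side (75.7 mV full
width); this is rounded to the nearest 10 mV per side (±40 mV, 80 mV
window), because the published compartment thresholds are only reproduced
with the rounded half-window. `detection_window` returns midpoint ± 40 mV
after the pH shift.

## Numerical conventions

* OxD is clipped to [1e-6, 1 − 1e-6] before the logarithm (measured R can
  exceed the calibration endpoints through noise); a strict mode raises
  instead. Clipping events are reported through a warning carrying the
  count.
* Ratio pixels with non-positive corrected long-channel intensity are
  removed from the mask rather than patched with an epsilon, which would
  bias the ratio low.
* Per-cell R defaults to the ratio of background-corrected channel means
  (ratio-of-means), which is robust to photon noise; the mean of pixel
  ratios is available as `statistic="mean_of_ratios"`. The two agree
  exactly on spatially uniform cells.
* Otsu thresholding (between-class variance maximisation) is applied to
  the long-wavelength channel by default — it has the higher signal-to-
  noise ratio in both redox states — with 8-connected components below
  `min_cell_area` removed. A constant image yields an "empty mask" signal
  distinct from an error.
* z-stacks are reduced by maximum-intensity projection before any ratio
  arithmetic.
* Ties in the pseudocolor mapping use floor rounding; the 256-entry
  fire-style LUT ships with the package and rendering is bit-exact
  against it.
* The cycling standard curve is ordinary least squares with a free
  intercept (forcing through the origin is a stricter assumption than the
  assay warrants); an intercept above 10 % of the maximum rate draws a
  warning, as does extrapolation beyond the calibrated 0–400 pmol range.
  Rates are the magnitude of the A600-vs-time slope, since the cycling dye
  is bleached (absorbance falls) as it is reduced.

## Synthetic data

The generator emulates the three input classes the pipeline consumes.

**Scenes.** Cells are non-overlapping axis-aligned ellipses (rejection-
sampled placement) on a low-order background plane; each cell has a true
potential, an expression level, and channel intensities produced by the
same endpoint-mixture forward model the analysis inverts. Noise is Poisson
(photon) followed by additive Gaussian (read, default sd 3 counts).
Defaults mirror the validation conditions used throughout: 50 cells at
256×256 px, E_true ~ U(−340, −280) mV at pH 7.3, expression 2000 counts
(photon-limited SNR ≈ 45), calibration R_red 0.5 / R_ox 1.9 (dynamic range
1.4, the top of the span reported for bacterial imaging) with endpoint
intensity quotient 0.596 taken from the probe's 488-nm extinction
coefficients (13.0/21.8 mM⁻¹ cm⁻¹).

**Titrations.** Nine NADPH/NADP⁺ ratios log-spaced over 10⁻³–10, three
replicates, Gaussian noise of sd 0.02 on R — a plate-reader-scale design
around the probe midpoint (which sits at ratio ≈ 0.044).

**Cycling.** Linear rate model (slope 0.002 AU s⁻¹ pmol⁻¹, zero intercept)
over 0–400 pmol standards with multiplicative rate noise (5 % in the
validation scenario at 200 pmol total, 60 % reduced).

What the generator does **not** model: optical point-spread/diffraction,
photobleaching, chromatic shift, autofluorescence, intra-cell
heterogeneity, cell motion, or dark-current drift. Passing the recovery
tests therefore demonstrates the correctness of the inference chain under
the model's own noise assumptions — not robustness to every artifact of
real microscopy, where background structure and autofluorescence can
dominate the error budget.

## Design choices

* Background ROI is user-supplied (cell-free region); an automatic
  fallback uses the mode of the lowest-decile pixels and is flagged in
  provenance.
* Coordinates are 0-based, row-major; ROIs are (x, y, width, height),
  half-open.
* Time series use fixed per-cell ROIs (no motion tracking); segmentation
  is Otsu + connected components only.
* The zero-noise identity and recovery harness subtracts background from a
  corner ROI; its validation scenes therefore use a flat background so the
  subtraction is exact. Scenes with a tilted plane exercise the same stage
  with a small residual, which the noisy recovery tolerances absorb.
* Run summaries report mean, sample SD (n−1) and n per condition;
  hypothesis testing is deliberately out of scope.
* Full runs are deterministic: identical seed and config produce
  byte-identical CSV/TIFF/PNG/JSON artifacts, and every number in the run
  report is re-derivable from the emitted CSVs.

## Problem sizes

Validation uses 50-cell 256×256 scenes, 10⁴-point grids for oracle
equivalence, and 9×3 titration designs; these sizes make every recovery
experiment sharp (errors well inside tolerance) while keeping the full
suite under a few seconds.

## Known limitations

* The equilibrium assumption (E_probe = E_NADP(H)) holds at titration
  equilibrium and approximately in steady-state cells; transient kinetics
  of probe re-equilibration are not modelled (no rate constants are fitted
  anywhere in the package).
* Outside the 5–95 % oxidation window the potential estimate saturates;
  cells whose truth lies outside are flagged, and their recovery is not
  guaranteed.
* The cycling assay's pool potential is meaningful only for single-
  compartment systems; multi-compartment extracts mix pools with different
  ratios and pH values and cannot be converted to a potential.
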