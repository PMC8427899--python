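# Methods

## FAME data model

A fatty acid is identified by its `Cn:d` code (n acyl carbons, d double
bonds). All property correlations operate on the **methyl ester**: the
molecular weight attached to each species is the formula mass of
C_{n+1}H_{2(n+1)−2d}O₂ from standard atomic weights, and the curated
registry values (C14:0 242.40 … C24:0 382.66 g mol⁻¹) agree with that
formula to < 0.1 g mol⁻¹ (enforced by test). Sources occasionally describe
the Mw in these correlations loosely as "the molecular weight of the fatty
acid"; the per-ester closed forms only reproduce literature values for
pure esters with ester masses, which settles the reading. Codes are
restricted to C4–C24 and to 2d < n (the carboxyl carbon cannot carry a
chain C=C); γ- and α-linolenate are both mapped to C18:3, since positional
isomerism is invisible to every correlation used here.

## Normalization conventions

Microbial GC-FID reports routinely identify less than 100 % of the total
FAME mass. The profile therefore supports two conventions:

* `as_reported` (default): weight-percents enter the equations exactly as
  printed. KV, density and HHV consume the weight *fraction* (wt %/100),
  so a 93 %-identified profile yields proportionally scaled values — this
  open-mass-balance convention is what published tables computed from
  partially identified profiles reproduce (e.g. densities of
  0.65/0.56 g cm⁻³ for ~75/64 % identified totals, i.e. ≈ 0.87 × ΣNᵢ/100).
  SV, IV, DU, OS, LCSF, CP and PP consume raw weight-percent.
* `renormalized`: percentages rescaled to close at 100 %, making every
  property invariant under common scaling of all entries (property-tested).

The report pipeline computes both panels side by side and marks
`as_reported` as primary.

## Fuel-property correlations

KV, density and HHV use the per-ester closed forms of the
Ramírez-Verduzco family, mixed linearly (log-linearly for KV) in the
weight fraction. SV and IV are the classical Σ 560 N/M and Σ 254 D N/M
forms. The cetane correlation is implemented as
**CN = 46.3 + 5458/SV − 0.225 IV**: the numerator is occasionally
misprinted as 5.458, which cannot reproduce any tabulated cetane number,
whereas 5458 reproduces published pairs (SV 142.10, IV 27.85 → 78.44;
SV 127.25, IV 30.52 → 82.32) to two decimals and matches the Krisnangkura
correlation the form derives from. OS uses the inverse-linolenic
correlation 117.9295/(C18:2 + C18:3 + 2.5905), finite for fully saturated
oils. The cold-flow set is LCSF = 0.1 C16:0 + 0.5 C18:0 + 1 C20:0 +
1.5 C22:0 + 2 C24:0 with CFPP = 3.1417 LCSF − 16.477,
CP = 0.526 C16:0 − 4.992 and PP = 0.571 C16:0 − 12.24. Species absent
from a profile contribute zero everywhere rather than raising.

Standards limits ship as a versioned YAML (`data/standards.yaml`).
Saponification value is marked unspecified in all three standards: none of
them regulates SV directly, and limit values occasionally quoted for it
belong to other assays. Cloud/pour-point windows are the common
continental-climate ASTM guidance ranges. HHV is unregulated everywhere.

## Fermentation and wastewater bookkeeping

Lipid content is 100 × lipid/biomass (% of dry cell weight). The yield
coefficient Y_L/C divides lipid produced by substrate consumed
(initial − residual, no maintenance correction) and is reported half-up at
2 decimals, matching fermentation-report convention; removal efficiencies
are 100 × (raw − treated)/raw at 1 decimal. A treated value above raw
yields a negative efficiency with a warning rather than an error (some
parameters legitimately rise during treatment). Per-day summaries flag
days with zero cumulative consumption instead of dividing by zero.

Two yield peaks are reported: the raw per-day maximum of Y_L/C, and the
yield on the day of maximum lipid (`y_lc_at_lipid_peak`). The latter is
the estimator fermentation studies actually quote and is far more stable
under measurement noise — the raw maximum is biased upward by early days
whose consumption is near zero, where the ratio's noise diverges.

## FTIR processing

Second derivatives use moving-mean (boxcar) smoothing — the
"Means-Movement" smoother of Jasco spectral software — of an odd width
(default 25 points, i.e. ≈ 12 cm⁻¹ at the typical 0.5 cm⁻¹ data spacing),
followed by the central three-point second difference scaled by the
squared grid step; stencil-undefined ends are trimmed and the operation is
exact for quadratic baselines. Smoothing is single-pass. Non-uniform grids
are first resampled by linear interpolation to the median step (this
introduces O(h²) interpolation error, tested as approximate rather than
exact). Absorption bands appear as local minima of the second derivative;
`find_bands` accepts a threshold that acts both as a minimum depth below
zero and a minimum prominence, which rejects floating-point-level dips on
flat baseline stretches as well as noise wiggles. Assignment matches
resolved positions to the nearest reference band within ±4 cm⁻¹ (ranged
references such as 1240–1265 cm⁻¹ match anything inside the range).

PCA follows the correlation-matrix convention for spectra: each
wavenumber variable is standardized to zero mean and unit variance
(ddof = 1), the correlation matrix is diagonalized, eigenpairs sorted by
descending eigenvalue, and each eigenvector's sign is fixed so its
largest-magnitude loading is positive (reproducible score orientation).
Scores are projections of the standardized spectra; with all components
retained, scores × loadingsᵀ reconstructs the standardized data to
machine precision. Zero-variance variables are dropped with a warning.
The implementation is cross-checked in tests against an explicit
correlation-matrix eigendecomposition and against scikit-learn PCA on
standardized toy windows.

## Synthetic data: what it emulates, and what it does not

* **FAME profiles** are Dirichlet draws whose concentration vector equals
  a reference composition (default: the stearate-dominant day-6
  wastewater profile; an alternative config mirrors the linolenate-bearing
  synthetic-medium profile), scaled to the reference identified total
  (92.98 %). Mean composition therefore equals the reference; total
  concentration ~93 gives realistic inter-replicate scatter.
* **FTIR series** are sums of Gaussian bands at the canonical lipid
  positions (σ 8–10 cm⁻¹, i.e. FWHM ≈ 19–24 cm⁻¹) on a 400–4000 cm⁻¹ grid
  at 0.5 cm⁻¹ spacing, with lipid-band amplitudes proportional to a
  logistic latent lipid trajectory over days 1–10, a shallow linear
  baseline, a constant 1415 cm⁻¹ protein band, and additive Gaussian
  noise of 2 × 10⁻⁴ AU (scan-averaged ATR level). Not emulated: ATR
  penetration-depth dispersion, atmospheric CO₂/H₂O lines, band-shape
  asymmetry, scattering baselines. Passing tests therefore demonstrate
  correctness of the processing chain, not robustness to every real-world
  artifact.
* **Fermentation curves** use logistic biomass (X₀ 0.15, X_max
  6.93 g L⁻¹, µ 0.9 d⁻¹), substrate consumption proportional to biomass
  formed (23.07 g L⁻¹ of 30 g L⁻¹ consumed by day 10), and lipid formed at
  a fixed true yield (default 0.22 g g⁻¹) from an onset day — so with zero
  noise the summary recovers the true yield exactly, and at 0.05 g L⁻¹
  noise the lipid-peak yield estimator recovers it to ±0.02 over 20
  seeds. Lipid turnover/decline after the peak is not modelled.
* **Wastewater panels** apply known removal fractions to reference raw
  levels; with zero noise the efficiency computation inverts the
  generator exactly.

All generators draw from a single `numpy.random.default_rng(seed)` stream
per call; identical (config, seed) pairs are bitwise reproducible.

## Numerical choices and degenerate inputs

Reported roundings use half-up ties (as printed tables do), with full
precision retained internally. Profile totals may exceed 100 % by at most
0.5 (printed per-species rounding slack); larger totals are rejected.
Empty profiles, zero biomass, zero raw values, non-overlapping windows and
too-short spectra raise typed errors naming the problem; per-property
failures inside `compute_report` are recorded as flags instead of
aborting the report. Report bundles contain no timestamps, so identical
inputs produce byte-identical JSON.

## Known limitations

The fuel-property correlations are empirical fits for C12–C22 ester
mixtures; extrapolation to unusual compositions (very short chains, high
polyunsaturation) inherits their fitting error. The published day-6
fuel-property table for the fungal oils cannot be reproduced exactly here
because the exact input profile behind it was never printed; the
correlations are instead validated against pure-ester closed forms,
published SV/IV→CN and MUFA/PUFA→DU pairs, and monotonicity properties.
Similarly, published PCA variance percentages for instrument spectra are
not reproducible without the raw spectra; the PCA is validated against
dense eigensolver oracles and qualitative day-1 vs day-6/7 separation on
synthetic series. The JCAMP-DX reader covers plain AFFN XYDATA/XYPOINTS
blocks only (no DIF/DUP compression).
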