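# Methods

This note documents the models implemented in `soilrisk`, the default
constants it ships, the design choices that were genuinely open, and what
the synthetic survey generator does and does not emulate.

## Scope and data model

The package analyses a georeferenced farmland soil survey: one row per
sample with planar coordinates and total concentrations (mg/kg) of the
eight heavy metals Pb, Cd, As, Hg, Cr, Zn, Cu, Ni.  Concentrations must be
finite and strictly positive; sample IDs unique; duplicate coordinates are
warned about but allowed (split samples, field duplicates).  Extra
elements are carried through descriptive statistics but flagged.

Coordinates are treated as planar: all distances (IDW) are Euclidean in
the declared plane.  No geodesic correction or CRS reprojection is
performed — survey extents of a few kilometres make the error negligible,
and reprojection belongs upstream of this package.

## Pollution indices

* **Geoaccumulation index** `I_geo = log2(C / (1.5 B))` with `B` the
  regional geochemical background.  The factor 1.5 absorbs natural
  background fluctuation.  Classified on the Müller scale
  (breakpoints 0, 1, 2, 3, 4, 5; seven classes from "uncontaminated" to
  "extremely contaminated"; the 0–1 class is labelled
  "slightly contaminated").
* **Single-factor index** `P_i = C / S` with `S` a screening value.  `S`
  defaults to the background `B` but is a separate registry slot, because
  regulatory applications sometimes screen against risk-control values
  instead.  With `S = B` the identity `I_geo = log2(P_i / 1.5)` holds cell
  for cell and is enforced by test.
* **Nemerow comprehensive index**
  `P_N = sqrt((P_max^2 + P_avg^2) / 2)` over one sample's `P_i` values.
  It satisfies `max(P_max, P_avg)/sqrt(2) <= P_N <= P_max`, weighting the
  worst element heavily.  Classes: 0.7 / 1 / 2 / 3 ("safe", "warning",
  "light pollution", "moderate pollution", "heavy pollution").

Per-element survey means of `I_geo` are computed as means of the
per-sample indices (mean of logs), not the log of the mean concentration;
for right-skewed elements the two differ noticeably (Jensen's
inequality), and the mean-of-logs convention is what survey summary
tables in this field report.

Classification is total and *left-closed downwards*: a value exactly on a
breakpoint resolves to the lower class.  All breakpoints and labels are
config-overridable.

## Potential ecological risk (Hakanson)

`E_r = T_r * C / S` per element and `RI = sum(E_r)` per sample, with the
standard toxic response factors Hg 40, Cd 30, As 10, Pb 5, Ni 5, Cu 5,
Cr 2, Zn 1 (sum 98, so a soil exactly at background scores RI = 98 — kept
as a regression test).  Class scales: `E_r` at 40/80/160/320, `RI` at
150/300/600; both overridable, and overriding the toxic response factors
is allowed but warned.

A caveat for users comparing against published survey tables of this
form: such tables occasionally contain rows inconsistent with
`E_r = T_r * P_i` (e.g. a printed Pb mean `E_r` several times larger than
the printed `T_r * P_i` product).  This package always reproduces the
formula; it never tunes constants to match inconsistent cells.

## Human health risk (USEPA three-pathway model)

Average daily doses for soil ingestion, dermal contact, and inhalation of
resuspended particles:

    ADD_ing = C * IngR * EF * ED / (BW * AT) * 1e-6
    ADD_der = C * SA * AF * ABS * EF * ED / (BW * AT) * 1e-6
    ADD_inh = C * InhR * EF * ED / (PEF * BW * AT)

The inhalation route carries no `1e-6` factor: PEF (m³/kg) converts soil
concentration to an inhaled-air concentration.  Averaging time is
`AT_nc` for non-carcinogenic risk and `AT_ca` for carcinogenic risk.
Then `HQ = ADD / RfD`, `HI = sum(HQ)`, `CR = ADD_ca * SF`,
`TCR = sum(CR)`.  A metal-pathway with no RfD contributes zero to HI with
a logged notice; a carcinogen-pathway with no SF is reported as absent
("—") and excluded from TCR.  Risks are computed on mean concentrations
(the conventional deterministic point estimate); a per-sample HI
distribution is available as an extra via `per_sample_hazard_index`
(exact, because HI is linear in the concentration vector).

### The default exposure/toxicity registry is calibrated

Published farmland studies of this kind typically take exposure
parameters and RfD/SF values from appendices that are not always
reproduced.  The registry shipped here was *back-derived* to be
self-consistent with the published risk tables of the survey this package
is calibrated to, in the same way the default backgrounds are
back-derived (mean concentration ÷ mean single-factor index):

* Standard values were kept wherever they are consistent with the
  published cells: the ingestion RfD column (Pb 3.5e-3, Cd 1e-3, As 3e-4,
  Hg 3e-4, Cr 3e-3, Zn 0.3, Cu 0.04, Ni 0.02 mg/kg/day), As slope factors
  1.5 / 15.1 / 3.66 (ing/inh/der), Cd inhalation SF 6.3, PEF 1.36e9
  m³/kg, adult IngR 100 mg/day, InhR 20 m³/day, ED 24 y, carcinogenic
  averaging over 70 y.
* Where the published cells could not be reproduced with textbook
  values, the registry carries the back-solved ones (adult EF 250 d/y and
  BW 70 kg; child IngR 53 mg/day, InhR 2.1 m³/day, BW 15.9 kg, AT_ca
  6400 d; dermal products SA·AF·ABS of 50.75 and 19.6 cm²·mg/cm²/day for
  adult and child; Cr dermal RfD 2.5e-4; Cd ing/der SF 0.507 / 19.8; Cr
  ing/inh SF 1.46 / 122.5).

With this registry the engine reproduces the calibration study's
published per-cell risks within ~15% and its HI/TCR totals within 2%.
Every constant lives in the editable registry — none is hard-coded in a
computation path — so users with their own guideline tables simply
override them in the config.

Two errata in the calibration tables are worth recording: (1) the printed
adult Zn inhalation HQ of 3.50e-13 is an exponent misprint for 3.50e-8
(the mantissa matches the registry-consistent value exactly, and the
child column confirms an inhalation RfD of 0.3 for Zn); (2) the printed
footnote swapping the inhalation/dermal column descriptions contradicts
the magnitudes (dermal ≫ inhalation under any plausible PEF), so columns
are interpreted by header.

## Source apportionment

* **Pearson screen**: product-moment correlations with two-sided p-values
  from the t-transform on n−2 degrees of freedom; stars at p<0.05 and
  p<0.01.  No multiple-testing correction is applied to the stars (the
  conventional survey display), but a Holm-corrected matrix is returned
  alongside for users who want it.  Constant columns yield missing
  correlations with a warning.
* **PCA** on z-scored concentrations, i.e. an eigen-decomposition of the
  correlation matrix, making the result invariant to per-element affine
  rescaling.  Loadings are eigenvectors scaled by the square root of
  their eigenvalue (squared loadings of a component sum to its
  eigenvalue).  Retention defaults to the Kaiser rule (eigenvalue > 1),
  overridable to a fixed k.  Rotation default is *unrotated*; varimax is
  available as an option, in which case variance contributions are
  recomputed from the rotated loadings (the retained total is
  rotation-invariant).  Sign convention: each component's
  largest-magnitude loading is positive.

The package stops at loadings and contributions.  Naming the factors
(industrial, natural, traffic…) is interpretation and deliberately out of
computational scope.

## Spatial mapping

IDW with default power 2, all-neighbours weighting, and an exactness
radius of 1e-9 × the domain diagonal (a cell coinciding with a sample
returns that sample's value).  Default grid: 100 × 100 over the bounding
box padded 5% per side.  Interpolated values are provably inside the
input value range (convexity); as the power grows the surface converges
to nearest-neighbour assignment.  Interpolation is applied to the
continuous per-sample index values (`P_N`, `RI`, concentrations) and
classification is applied *afterwards* to the interpolated surface, so
class maps show legend breaks cutting a continuous field.  Exports are
plain-text ESRI ASCII grid and XYZ tables; a matplotlib rendering helper
is included.

## Synthetic survey generator

The generator is the stand-in for unreleased per-sample data; it draws
surveys with the statistical structure the analysis assumes:

1. **Locations**: uniform over a 1 km × 1 km domain (48 samples by
   default).
2. **Dependence**: Gaussian copula.  The latent correlation is obtained
   by inverting the exact lognormal Pearson attenuation formula,
   `r = (exp(rho*si*sj) − 1) / sqrt((exp(si²)−1)(exp(sj²)−1))`, so the
   *observed* Pearson correlations target the calibration matrix rather
   than being attenuated by the marginal transform.  The resulting latent
   matrix is projected to the nearest positive semi-definite correlation
   matrix (eigenvalue clipping + renormalization); a shift of more than
   0.2 in any entry triggers an infeasibility warning.
3. **Marginals**: lognormal with `sigma² = ln(1 + cv²)`, calibrated to
   the published per-element means and CVs (Cd 0.29 mg/kg at CV 91%, Hg
   0.05 at 70%, etc.).  Lognormality is the natural model: strictly
   positive support, and CVs of 70–90% are the classic multiplicative
   signature of point-source contamination.
4. **Hotspots**: Cd and Hg each get one localized point source
   (multiplier 4, radius 8% of the domain diagonal) implemented as a
   multiplicative Gaussian bump with decay scale radius/3, so the bump is
   effectively confined inside the stated radius.  Because multiplication
   inflates the column mean, the base lognormal mean is divided by the
   multiplier field's expectation (computed by midpoint quadrature over
   the uniform location distribution); column means therefore match the
   targets exactly in expectation, while the hotspots add a few percent
   of extra CV on top of the lognormal target — the intended point-source
   signature, and well inside the generator's calibration tolerance
   (means within 2%, CVs within 10% relative, verified across replicate
   draws).

What the generator does **not** emulate: the true (unpublished) sampling
coordinates and spatial covariance of the real field — its spatial
structure is illustrative only; any non-lognormal features of the real
concentration distributions (e.g. censoring at detection limits, mixture
structure); and analytical error.  Consequently, passing tests demonstrate
that the *pipeline* reproduces the published summary-level behaviour under
a faithful statistical emulation, not that the real field has been
reconstructed.  Per-sample published results (exact class percentages of
the Nemerow and RI maps) depend on the real spatial field and are checked
only as properties across seeds, not as exact targets.

## Numerical and testing choices

* Sample standard deviations use the n−1 denominator; `CV% = 100·sd/mean`.
* Classification ties resolve to the lower class everywhere.
* The Cholesky factorization of the latent correlation adds a 1e-10
  diagonal jitter for rank-deficient repaired matrices.
* Eri-vs-published consistency is asserted with tolerances propagated
  from the rounding of the printed inputs (both factors printed to two
  decimals), i.e. `|T·P_i − E_r| <= T·0.005 + 0.005`.
* Stochastic test sizes were chosen for tight-but-fast verification:
  300 replicate surveys for generator moment recovery, 200 seeds for the
  pipeline-recovery properties, 2·10⁴ samples for the lognormal moment
  convergence check.  All randomness is seeded; hypothesis-based property
  tests use bounded example counts.

## Known limitations

* Deterministic point-estimate health risk only: no Monte-Carlo exposure
  uncertainty, age-binned integration, or bioaccessibility adjustment.
* No enrichment factor / pollution load index variants, no kriging, no
  receptor models (PMF/UNMIX/APCS-MLR).
* The calibrated exposure registry reproduces one study's published risk
  tables; it is a consistent, editable default, not a recommendation of
  those parameter values for new assessments.
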