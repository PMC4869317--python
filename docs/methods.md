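# Methods

`protonrbe` compares variable proton-RBE schemes against the clinical
constant RBE = 1.1 on voxelised absorbed-dose and dose-averaged-LET
(LET_D) distributions. This note describes the models, the synthetic beam
that stands in for Monte Carlo input, the numerical choices, and what the
package's tests do and do not establish about real treatment plans.

## The linear-quadratic iso-effect framework

A proton absorbed dose D and a photon dose D_x are taken as iso-effective
when

    alpha D + beta D^2 = alpha_x D_x + beta_x D_x^2 .

With RBE = D_x / D this gives a quadratic whose positive root defines the
RBE. Two asymptotic quantities encode the whole dose dependence:

    RBE_max = alpha / alpha_x        (RBE at D -> 0)
    RBE_min = sqrt(beta / beta_x)    (RBE at D -> infinity)

and the RBE as a function of the proton fraction dose D, for a tissue with
photon ratio r = (alpha/beta)_x, is

    RBE(D) = -r/(2D) + (1/D) sqrt( r^2/4 + RBE_max r D + RBE_min^2 D^2 ).

The derivative dRBE/dD is negative exactly when RBE_max > RBE_min; when the
order reverses, the model predicts RBE *rising* with dose — outside the
regime any of these phenomenological fits were built for.

The three models differ only in how their endpoints depend on LET and on r:

* **CAR (Carabe-Fernandez)** — both endpoints linear in LET_D, with slopes
  scaled by 2.686 Gy / r (2.686 Gy is the V79 reference ratio of the
  underlying fit):
  `RBE_max = 0.834 + 0.154 (2.686/r) LET`, `RBE_min = 1.09 + 0.006 (2.686/r) LET`.
  Because the zero-LET intercepts put RBE_max below RBE_min, the model is
  applicable only where `LET/r > 0.62 keV um^-1 Gy^-1` (strictly): LET >
  1.24 keV/um for r = 2 Gy, LET > 6.20 keV/um for r = 10 Gy. The package
  treats the printed 0.62 as authoritative even though the printed endpoint
  coefficients would put the RBE_max/RBE_min crossover at a ratio of about
  0.644; the boundary itself is treated as inapplicable because the dose
  derivative vanishes there. Inapplicable voxels are masked NaN and
  counted, never clamped.
* **WED (Wedenberg)** — `RBE_max = 1 + 0.434 LET / r`, `RBE_min = 1`
  (beta = beta_x). Valid for LET below 30 keV/um; queries beyond emit a
  warning, not an error.
* **LEM (table-driven)** — macroscopic alpha(LET), beta(LET) supplied as an
  external table (the microscopic local-effect computation is out of scope)
  and piecewise-linearly interpolated; out-of-range queries clamp to the
  nearest endpoint with a warning, because linear extrapolation of a
  decreasing beta column would go negative. The transition-dose helper
  `beta_z = (S_max - alpha_z) / (2 D_t)`, with `S_max = alpha_x + 2 beta_x
  D_t`, is provided for table construction; a negative result (alpha_z >
  S_max) is returned flagged, not clamped. `make_synthetic_lem_table`
  builds a stand-in table with the qualitative features of published LEM
  proton tables (alpha rising super-linearly with a vanishing slope at
  LET -> 0, rate scaled by 1/r; beta decreasing via the transition-dose
  construction); it is synthetic and is not a local-effect calculation.

The fixed clinical scheme is the same machinery with
RBE_max = RBE_min = 1.1, for which RBE(D) reduces to 1.1 identically — so
the reference flows through the identical code path.

One unified LET argument is exposed everywhere; whether it receives
unrestricted LET or LET_D is the caller's choice. All grid pipelines feed
LET_D.

### Tissue parameters

Two reference tissues are built in: a late-responding tissue with
(alpha/beta)_x = 2 Gy (alpha_x = 0.123 Gy^-1) and an early-responding
tissue / typical tumour with (alpha/beta)_x = 10 Gy (alpha_x =
0.616 Gy^-1); LEM transition doses D_t of 10 or 40 Gy. The stated ratio is
authoritative: it sets the model slopes and the applicability bounds, so
beta_x is derived as alpha_x / r (0.0615 Gy^-2 for the 2 Gy tissue rather
than an independently rounded 0.0616). `TissueParams.from_ratio` makes this
construction explicit.

## Voxel engine

RBE is evaluated at the **per-fraction** absorbed dose (the models are
dose-dependent, and the fraction dose is the physical argument); totals are
n_fractions multiples. Default plan: 27 fractions of 2 Gy(RBE) at
reference RBE 1.1, i.e. 1.818 Gy absorbed dose per fraction.

Grids are voxel-centre addressed (position = origin + index * spacing);
congruence of dose and LET_D grids (shape, spacing, origin to 1e-6 mm) is
enforced, never silently resampled. Voxels with dose below a configurable
floor (default 1e-3 Gy) take the RBE_max asymptote — the closed form has D
in denominators — and are counted in the compute report.

`lateral_constant_field_mode` reproduces a treatment-planning-system
approximation: each depth slice's LET_D is replaced by the central-axis
value (voxel nearest the field's lateral centroid), removing the off-axis
LET halo. Comparing full and TPS modes isolates the lateral mixed-field
effect: off-axis RBE(full) >= RBE(TPS), equal on axis.

## Plan metrics

* **Volume histograms** are cumulative, V(>= v) in percent of the finite
  masked volume; default bin 0.01 Gy (0.1 keV/um for LET). NaN
  (model-inapplicable) voxels are dropped and counted.
* **Dose-at-volume** (D_95, D_5, ...) evaluates the Hazen-interpolated
  quantile ((k - 0.5)/n plotting positions) of the retained voxel values,
  which matches a sort-based brute-force evaluation exactly; a
  histogram-curve inversion is the fallback for externally supplied
  histograms. (A "largest value with V >= p" step rule was considered and
  rejected: it returns the top of the tied plateau rather than the
  interpolated quantile on discrete data.)
* **Distal fall-off depth R_x**: beam-eye-view profiles are scanned from
  the global maximum toward the exit; the *distal-most* downward crossing
  of x% of the per-fraction prescription is located by linear interpolation
  (exact for piecewise-linear profiles, which is why translated trapezoid
  tests recover sub-voxel shifts to 1e-6 mm). Profiles never reaching a
  level are excluded and counted.
* **Gradient filter**: fall-off shallowness is defined as
  (R_20% - R_80%) / (0.6 d_presc) in mm/Gy, using the already-computed
  crossings; rays above 30 mm/Gy on *either* profile are excluded from
  range-shift statistics (the source analysis does not say which profile
  its filter applies to; requiring both is the conservative choice).
* **Biological range shift**: R_x(varRBE) - R_x(RBE = 1.1) per ray at
  x = 90, 80, 50 %, with 2-D beam-eye-view maps, frequency histograms
  (bin 0.3 mm — resolves sub-millimetre shifts on 1 mm grids), means, and
  explicit exclusion bookkeeping (retained + gradient-excluded +
  level-excluded = total rays).
* **Lateral 80-20 % fall-off**: distance between the 80 % and 20 %
  crossings of the central-axis value on each edge, linearly interpolated;
  the mean over available edges is returned. For an erfc (Gaussian-blurred
  step) edge of width sigma this is 1.6832 sigma.

Thresholds are fractions of the **per-fraction** prescription throughout
(the analyses are of RBE-weighted fraction dose); interpolation is linear
everywhere, no smoothing — deterministic and oracle-friendly.

For opposed two-field plans the combined dose beyond either field's distal
edge only falls to the opposing field's dose bath, so the 20 % crossing
needed by the gradient filter does not exist on the combined grid: range
shifts are a per-field analysis (each component field against 1.1 times
its own dose, at half the prescription), as driven in
`analysis/05_two_field.py`.

## The synthetic beam

The generator replaces Monte Carlo input with closed forms; it defines the
study conditions and is not tuned per experiment.

* **Pristine peak**: entrance plateau (entrance/peak ratio 0.30, slow
  quadratic rise) plus a Gaussian Bragg bump, multiplied by an erfc distal
  edge (range straggling sigma, default 1.8 mm ~ 1.2-1.9 % of a 96 mm
  range). The bump sits 1.45 sigma proximal of the erfc midpoint; the curve
  is normalised by its numerically located maximum, the nominal range is
  the distal-80 % depth, and the realised distal 80-20 % width is ~1.56
  sigma.
* **SOBP**: 16 pristine peaks spanning the 40 mm modulation (deepest
  peak's maximum at the distal box edge), weighted by non-negative least
  squares against a flat plateau on the target interval. Realised
  central-90 % flatness: 1.4 % (contract: <= 2 %).
* **Lateral profile**: Gaussian-blurred box per depth,
  sigma(z) = 4 mm + 0.05 z. This is calibrated so the RBE = 1.1 lateral
  80-20 % fall-off at mid-SOBP depth is ~13.2 mm, matching the ~13.3 mm
  reported for a scanned field at this depth — the observed widening under
  variable RBE is stated relative to that base penumbra, so the base width
  is part of the study conditions.
* **LET_D(z)**: entrance value 1 keV/um, strictly increasing (linear term
  0.01/mm plus an exponential surge of 2 mm sharpness across the distal
  edge), pinned to 10 keV/um at the distal 20 %-dose depth (the reported
  distal range being 8-12 keV/um), and still rising beyond. Off-axis,
  LET_D is enhanced by `1 + (enh - 1)(1 - D/D_axis)` with enh = 1.5 — a
  monotone surrogate for the stopping halo of primary protons and
  higher-LET secondaries. The exponential keeps growing far beyond the
  distal edge where the dose is essentially zero; LET_D there is not
  meaningful (and carries no dose), which is also why LEM tables clamp and
  WED warns in that region.
* **Two-field phantom**: two opposed half-weight fields on a phantom twice
  the box-centre depth long; field B is the mirror of field A. Combined
  dose is the sum; combined LET_D is the dose-weighted average of the
  per-field values (the superposition rule for dose-averaged LET).
* Determinism: identical spec + seed give bit-identical grids; the only
  stochastic option is multiplicative Gaussian dose noise, off by default.

### What the phantom does and does not emulate

It reproduces: a flat 3-D plateau at prescription dose, monotone LET_D
rise with a distal surge, penumbra growth with depth, an off-axis LET
halo, and opposed-field superposition. It does not contain: tissue
heterogeneity, nuclear-fragmentation spectra, realistic entrance/plateau
LET structure, or plan optimisation — in particular the lateral penumbra
is applied at the target-box boundary, so the PTV rim is underdosed
relative to an optimised plan and absolute D_95-type statistics are lower
than patient-plan values. Passing end-to-end tests therefore establishes
the *direction and scale* of variable-RBE effects (D_RBE excess, range
shifts of a few mm, sub-mm-to-mm lateral widening), not patient-specific
values.

## Problem sizes and numerics

The default phantom is 191 x 131 x 122 voxels at 1 mm (the reported
0.65 x 0.65 x 3 mm CT grids round-trip through I/O but are not the default
study grid). A full four-model comparison with range-shift analysis runs
in about a minute on one core. Bisection of the CAR applicability bound
uses an interval tolerance of 1e-9 keV/um. NRRD / MetaImage I/O
(SimpleITK) round-trips values bit-exactly; the quantity tag is stored in
the NRRD header (MetaImage has no free key-value slot, so the tag is
supplied by the caller on read).

## Known limitations

* CAR coefficients are a low-(alpha/beta)_x (V79-based) fit; its
  predictions for the 10 Gy tissue are excluded in practice by the
  applicability bound, and masked voxels simply vanish from statistics.
* The synthetic LEM table is qualitative; real LEM-IV tables (or any
  externally computed alpha/beta vs LET CSV) should be supplied for
  quantitative LEM work.
* The printed tissue table rounds beta_x independently of the ratio; this
  package takes the ratio as exact (see above), a ~0.16 % difference in
  beta_x for the 2 Gy tissue.
* Range-shift means depend on the distal-edge width; the analytic edge
  (sigma 1.8 mm) is steeper than CT-based patient fall-offs, so shifts at
  the 80/50 % levels are smaller than patient-derived means, while the
  90 % level lands in the clinically reported 3-5.4 mm band for the low
  (alpha/beta)_x tissue.
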