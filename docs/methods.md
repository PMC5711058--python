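# Methods

`transitdose` implements the reference-dose side of entrance/exit in-vivo
dosimetry for 6 MV photon beams: reconstructing the dose a detector *should*
read at 1.5 cm inside the beam entry or exit surface, correcting it for the
missing backscatter at the exit, and comparing measured and computed dose
distributions in 1D (relative profiles) and 2D (absolute gamma analysis).

## Dose reconstruction and the backscatter correction factor

The full-backscatter central-axis dose at field size *fs* (square side
defined at 100 cm from the source) and depth *d* is factorized as

    Dose(fs, d) = D_dmax · MU · PDD(fs, d)/100 · OF(fs)

where `D_dmax` is the dose per monitor unit at the depth of maximum for the
10 × 10 cm reference field (1 cGy/MU at calibration), `PDD` the percentage
depth dose and `OF` the field-size output factor. All field-size output
dependence sits in `OF`; `D_dmax` is carried per MU and per reference field.

A point near the beam exit sees less scattered dose than this, because only
a thin slab of material lies beyond it. The backscatter correction factor

    BCF = dose without backscatter / dose with full backscatter,  BCF ≤ 1

restores agreement: `Dose_expected = Dose(fs, d) · BCF`. BCF tables have two
blocks mirroring the slab-phantom measurement geometry: an **entrance**
block at fixed depth 1.5 cm, keyed by the thickness of underlying material
(1.5–31.5 cm), and an **exit** block at fixed 1.5 cm backscatter, keyed by
depth (6.5–31.5 cm). The exit value at depth 1.5 cm equals the entrance
value at thickness 1.5 cm and is stored only once. Entrance-block entries
are strictly partial-backscatter ratios (numerator has *some* backscatter);
they are tabulated anyway because patients present variable thickness, and
the summary labels the block accordingly. Mixed geometries (entrance at a
depth other than 1.5 cm, exit with other than 1.5 cm backscatter) are
rejected rather than guessed.

Two measured reference tables ship with the package (Varian Clinac 21EX,
TPR20,10 = 0.669, and Elekta Synergy, TPR20,10 = 0.687), at their tabulated
3-decimal precision. Values marginally above 1 (up to 1.01) occur in
measured tables through setup noise; they are preserved and flagged with a
warning, never clamped, since the correction is defined as ≤ 1. Ratios
outside (0.9, 1.01] are rejected as physically implausible for these
geometries.

Tabulated BCFs are interpolated bilinearly in (field size, thickness/depth),
exactly at grid nodes, with a hard error instead of extrapolation. The
source tables carry no interpolation prescription; linear interpolation is
this package's choice and is exposed as such. The same table is used for
fixed-SSD and isocentric geometries — the factor is experimentally
SSD-independent (`ssd_invariance_check` quantifies this for derived tables).

## Plane synthesis and gamma analysis

2D absolute dose planes are built from orthogonal 1D scans by
cross-multiplication of the central-axis-normalized profiles, scaled by the
measured central-axis point dose: `plane(x, y) = n_x(x) · n_y(y) · D_cax`.
The construction is exactly separable; real planes deviate from
separability in the corners, which is why the construction is validated
against 2D-array measurements rather than assumed — this limitation is
inherited here and documented rather than corrected. Default grid spacing
is 0.2 cm (the scan resolution); plane extent is 1.6 × the projected field
width, covering penumbra and out-of-field tails used by the gamma ROI.
Diagonal profiles are parameterized by signed radial distance along the
diagonal, the water-tank convention. Resampling for profile comparison is
linear and no smoothing is ever applied to measured-style data.

The gamma index at reference point *r* against evaluated plane *E* is

    γ(r) = min_e sqrt( ((E(e) − R(r))/ΔD)² + (|e − r|/δ)² )

with ΔD the dose criterion as absolute dose and δ the distance criterion
(3%/3 mm by default). Normalization is *global*: ΔD is a percentage of the
reference plane's central-axis dose (the planes are anchored to the CAX
measurement), with global-max as a configurable alternative. The evaluated
plane is bilinearly subsampled on a 0.3 mm lattice (δ/10) and searched to a
radius of 3δ — standard convergence bounds for a discrete gamma search.
Low-dose points are not excluded by default. The implementation enumerates
subsample offsets in order of increasing distance and stops when the
distance term alone exceeds every point's running minimum; this is exact
(the test suite checks equality with a brute-force exhaustive search to
1e-6) but orders of magnitude cheaper on planes that mostly agree. Offsets
falling outside the evaluated grid are excluded from the minimization; the
evaluated grid must cover the reference grid.

Pass rates are reported over two square ROIs centred on the axis: the full
projected field area (edge = fs · (ssd + depth)/100) and the central 80%.
"80% of field area" is implemented as 0.8 *linear* edge scaling (area
factor 0.64); the alternative reading (80% of area, edge factor √0.8) is a
known ambiguity and the linear convention is this package's choice, not a
claim about the source convention.

## The synthetic beam and what it does (not) represent

No deposited dataset exists for this problem, so the `synthetic_data`
module generates analytic stand-ins with known ground truth:

- **Depth dose** `p(d) = (1 − e^{−b(d+s)}) e^{−μd}`, with the shift *s*
  fixed in closed form so the maximum falls exactly at dmax = 1.5 cm, and
  normalized to 100 there. Defaults (μ = 0.0576 cm⁻¹, b = 2.0 cm⁻¹) give
  TPR20,10 = 0.669 via the standard fixed-SSD-to-TPR conversion
  `TPR20,10 = PDD(20)/PDD(10) · ((ssd+20)/(ssd+10))²`; a second preset
  (μ = 0.0549 cm⁻¹) gives 0.687, bracketing the two clinical beams the
  reference BCF tables describe. μ carries a mild field-size slope
  (0.4%/cm around 10 cm) so larger fields fall off more slowly, as phantom
  scatter dictates.
- **Profiles**: flat core × error-function penumbra at the
  divergence-projected field edge `fs·(ssd+d)/(2·ssd)`, surface penumbra
  σ = 0.35 cm growing with depth, 2% horns, 2% out-of-field transmission.
  Symmetric by construction (no beam tilt).
- **Output factors**: `OF(fs) = 1 + 0.009(fs−10) − 0.0002(fs−10)²`,
  strictly increasing over 5–20 cm with OF(10) = 1 — typical 6 MV
  magnitudes (0.95 at 5 cm, 1.07 at 20 cm).
- **Backscatter deficit** (the ground truth BCF surface): entrance
  `1 − A(fs)·e^{−0.35 t}` with A growing linearly in field size; exit
  `B(fs) − 0.0006·(d − 6.5)` with B decreasing in field size. The simplest
  forms matching the observed monotonicities — entrance BCF rising to
  unity with thickness, exit BCF falling with depth, both falling with
  field size — with parameters chosen once so all implied values lie in
  the measured 0.96–1.00 range. No claim is made that they *fit* the
  reference tables.
- **Measurement noise**: multiplicative `1 + ε` with ε a zero-mean normal,
  SD 0.5% (the setup reproducibility of repeat measurements), truncated at
  2 SD. The truncation reflects that reproducibility was characterized as
  a *bound* on observed deviation, and it guarantees that derived BCF
  ratios stay inside the plausibility window for every seed. One seeded
  stream per campaign makes fixtures bit-reproducible.
- **TPS emulation**: `exact` reproduces the truth plane; `full_backscatter`
  omits the exit deficit, overestimating every point by exactly
  1/BCF − 1 (≈ +3.5% at 20 cm field, 31.5 cm depth with the default
  deficit) — the signature of dose engines that assume full backscatter at
  the exit; `shoulder_boost` raises the in-field shoulder band by a set
  fraction at and beyond an onset depth; `center_dip` lowers the central
  region. The shoulder band defaults to 0.80–0.95 of the projected
  half-width: inside the field but outside the central-80% analysis box
  and short of the penumbra (where distance-to-agreement would rescue the
  comparison), so shoulder failures concentrate in the outer 20% of the
  field area, as observed for deterministic-transport engines at depth.
  At small fields and shallow depths the band falls inside the penumbra
  and the effect disappears — consistent with the failure worsening with
  depth and field size.

What passing tests show: that the pipeline's algebra, I/O, interpolation,
search, and closed-loop recovery are correct under controlled conditions.
What they do not show: accuracy on real beams — the synthetic model has no
head scatter, electron contamination, beam tilt, detector volume effects,
or non-separable corner behaviour, and its deficit model is a smooth
two-parameter family, not physics.

## Numerical choices and degenerate inputs

- Interpolation is linear everywhere, exact at nodes, hard error outside
  the tabulated hull.
- BCF serialization rounds to 3 decimals (the tabulated precision); PDD
  percent to 1 decimal; computation is at full precision and rounding
  happens only at write time.
- Gamma subsample step must satisfy step ≤ δ/3 or the criteria object
  rejects it; the flat-offset degenerate case (no gradient) correctly
  yields γ = offset/ΔD everywhere.
- Profile normalization interpolates the central-axis value when 0 cm is
  not sampled and rejects non-positive values there.
- Duplicate measurement cells and incomplete derivation grids are hard
  errors listing the offending cells.
- Report JSON/markdown output is deterministic (sorted keys, fixed float
  formatting); identical config + seed gives byte-identical reports, with
  seed and config hash stamped on every report.

## Problem sizes

Default analyses use the 4 × 7 entrance / 4 × 6 exit measurement grid,
0.2 cm plane spacing (≈ 211 × 211 points for a 20 cm field at 31.5 cm
depth), and gamma comparisons on the (10 cm, 21.5 cm) and (20 cm, 31.5 cm)
cases; oracle equivalence checks use 7 × 7 planes with coarsened criteria,
where exhaustive search is affordable.
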