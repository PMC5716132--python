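# Methods

## The measurement problem

Relative output factors (ROFs) for stereotactic radiosurgery cones relate the
central-axis dose of a cone-collimated field (5–30 mm diameter at isocenter)
to the dose of a 100 × 100 mm² reference field at the same depth
(d_ref = 15 mm, SSD 100 cm):

    ROF(A) = D_w(A, d_ref) / D_w(100×100, d_ref).

No single detector behaves correctly at both ends of this ratio.  Below the
lateral-electron-range diameter D_LEE (~16–20 mm for a 6 MV beam) lateral
electronic equilibrium is lost: an unshielded silicon diode is small enough
to resolve such fields but over-responds there relative to water; an
ionization chamber is water-like but too large.  The pipeline therefore
daisy-chains the two detectors through an intermediate cone A₀ where both
respond reliably,

    ROF(A) = [D_Si(A)/D_Si(A₀)] · [D_w^IC(A₀)/D_w^IC(ref)],

and removes the residual silicon/water response difference with a
field-size-dependent factor normalized at the intermediate cone,
k^A_A₀ = k_w^Si(A)/k_w^Si(A₀):

    ROF_corr(A) = k^A_A₀ · ROF_meas(A).

The intermediate cone is selected as the smallest cone whose diameter meets
its own D_LEE; on the packaged per-cone D_LEE reference constants this is
the 20 mm cone.  The published "rule of thumb"
`D_LEE = 15.124 · ratio − 10.086` is implemented verbatim on a
caller-supplied %dd ratio.  As printed the rule is stated for
%dd(20)/%dd(10), which is < 1 for physical beams and yields negative
diameters; the packaged reference table is consistent with the inverse
ratio (≈1.9).  We do not silently invert: the function evaluates whatever
ratio it is given and raises a documented warning when the result is
non-positive.

## The synthetic dose engine

Because the pipeline's job is to *correct* a perturbation, testing it
requires a world in which the truth is knowable.  The `synthetic_field`
engine supplies that world.  It is not a transport code; it is the simplest
model that reproduces the phenomena that make small-cone dosimetry hard.

Relative dose factorizes as

    D(r, z, d) = N · T(d, z) · L(r, z)

with

* **depth factor** `T(d, z) = (1 − e^{−β d}) e^{−µ d} (SAD/z)²` —
  exponential buildup (β, default 0.3 /mm), quasi-exponential primary
  attenuation (µ, default 0.005 /mm) and inverse square.  The broad-field
  depth of maximum is ln(1 + β/µ)/β = 13.7 mm, in the 6 MV range, and the
  %dd(10)/%dd(20) ratio is ≈1.96, mapping through the D_LEE rule to
  ≈19.5 mm for large cones.
* **lateral factor** `L(r, z)`: the radial convolution, in the transverse
  plane, of the aperture fluence with a two-component Gaussian kernel
  (σ = 2.2 mm, weight 0.88: lateral secondary-electron transport;
  σ = 28 mm, weight 0.12: phantom scatter).  With these defaults the
  synthetic D_LEE computed from the engine's own PDDs spans 16.5–19.5 mm
  across the cone set, inside the published 16–20 mm band, and the 5 mm
  cone's central-axis dose sits ~10% below the 7.5 mm cone's — the loss of
  lateral equilibrium the correction pipeline must handle.

The **fluence** at a point is the visible fraction of the focal spot — a
uniform disc, default 1.5 mm diameter — obtained by ray-testing ≥ 500
quasi-uniform (stratified-radius, golden-angle) spot samples through both
circular cone apertures.  This one primitive produces the geometric
penumbra, the finite-spot field-size inflation, and source occlusion for
sufficiently focused collimation.

**Cone geometry** is invented (no aperture drawings exist for these cones;
the originals were measured with a feeler gauge): apertures at 630/700 mm
from the source; the bottom aperture projects the nominal radius from the
source to the isocenter plane; the top aperture lies on the edge line
converging 4 m *above* the source.  This mirrors the near-cylindrical bore
reported for BrainLAB-type cones, whose back-projected opening (≈9 mm at
the source plane for the 5 mm cone) dwarfs the focal spot, so the occlusion
fraction is exactly zero for the whole packaged set.  `occlusion_fraction`
uses the area-deficit closed form 1 − (d₀/spot)² when the smaller
back-projected aperture diameter d₀ falls below the spot diameter.

**Numerics.**  The radial convolution uses the exact angular integral
(modified Bessel function, `i0e` for stability) and a radial grid of
two-point Gauss–Legendre cells at `grid_step` (default 0.1 mm) resolution,
refined 5× across the geometric penumbra annulus where the fluence varies
fastest.  Against a direct Cartesian double-sum convolution the engine
agrees to ~1×10⁻⁴ relative, an order below the 10⁻³ equivalence bound used
in the tests.  A grid step exceeding the narrowest kernel sigma is rejected
as a configuration error.  Radial fluence profiles are cached per
transverse plane, so scans and footprint averages cost little.

**Tilt.**  "Gantry tilt" with the phantom surface at isocenter pivots the
beam about the point where the untilted axis meets the surface, while the
detector moves along the fixed vertical line; this reproduces both a gantry
readout error and a non-vertical scan axis with a single parameter.  A
detector at line depth d then sits d·sinθ off-axis in the beam frame, with
depth measured from the (now obliquely crossed) surface along the
source-to-detector ray.

## Detectors

A reading is the dose averaged over ≥ 100 stratified sample points on the
active footprint disc, multiplied by a phenomenological material response

    RF(A) = 1 + c · e^{−A/λ},

the generator's ground truth for the silicon over-response (not a
cavity-theory computation — parameter recovery requires a knowable truth).
The packaged diode matches an unshielded SRS diode chip (0.6 mm² disc,
0.06 mm thick, bare) with c = 0.10, λ = 6 mm, giving
RF(5)/RF(20) ≈ 1.040 — the ~4% 5 mm-cone over-response reported for this
detector class, so the synthetic k^5_20 lands near the published 0.961.
The Markus-type chamber is a 5 mm disc with RF ≡ 1 (it is only used at and
above the intermediate cone).  k factors are generated exactly as a
detector-simulation would: paired doses at the reference point with and
without the cavity, k_w^Si(A) = D_w/D_Si, normalized to the 20 mm entry.
These fold in both RF and the (sub-percent) footprint-averaging
perturbation, which is precisely why applying them recovers the point-dose
truth.

## Uncertainties, rounding, fixtures

`UncertainValue` carries value ± 1σ; products and ratios combine relative
sigmas in uncorrelated quadrature (verified against Monte-Carlo propagation
with 10⁵ draws).  On the published 5 mm inputs quadrature gives σ ≈ 0.010
versus the printed 0.011 — retained as a documented discrepancy, never
matched silently.  Deviation columns use
100·(reference − corrected)/corrected on the 3-decimal half-up-rounded
table entries, reported to 2 decimals: the only convention that reproduces
the published cells (two of seven printed cells are off by one final digit
under *any* single convention and are excluded from exact checks).
Rounding is presentation-layer only; full precision is kept internally.

The fixture generator emits, deterministically per (config, seed): PDD
(0–150 mm, 1 mm) and OAR (SSD 92.5 cm, depth 7.5 cm) scans per cone, a
reading table at the reference point, noise-free k factors, and ground-truth
ROF/RF tables.  Each tabulated reading is the mean of 10 repeat
acquisitions with 0.3% 1σ multiplicative noise (σ = standard error), the
protocol a scanning system's repeat-and-average acquisition mimics.  Under
these conditions the corrected ROFs recover truth within ~0.3% while the
uncorrected 5 mm diode ROF is biased high by ~3.4%.

All randomness flows from one config seed through named, hash-derived
sub-streams (spot sampling, footprint sampling, reading noise), so every
output is reproducible bit-for-bit.

## What the synthetic world does and does not show

The generator reproduces: buildup-then-falloff PDDs whose %dd ratios map
into the published D_LEE band; penumbra broadening from spot size plus
electron transport; equilibrium loss below ~18 mm; a diode that over-reads
small cones; volume averaging; occlusion-free near-cylindrical bores; and
tilt-induced PDD distortion growing with depth and angle.  It omits
spectral changes, electron contamination, detector stem/cable and
directional effects, and any accelerator-head specifics.  Passing the
recovery tests therefore demonstrates that the *pipeline arithmetic and its
correction logic* are right, not that the engine predicts any particular
machine; conversely the worked-example tests pin the pipeline to the
published table of a real Trilogy/BrainLAB commissioning exactly.

Known limitations worth stating:

* The 5 mm cone's simulated OAR FWHM is 6.1 mm — 22% above the geometric
  projection — because the σ = 2.2 mm transport kernel dominates at that
  size (measured small-field FWHMs show the same inflation).  For
  ≥ 7.5 mm cones FWHM tracks the projection within a few percent.
* With the same kernel, a 1.0° tilt already perturbs the 5 mm PDD by ~5%
  at 50 mm depth (2% is crossed at 64/46/37/34 mm for
  0.5/0.7/0.9/1.0°).  A claim that ≤ 1.0° misalignment leaves depths
  ≤ 50 mm within 2% holds in this synthetic world only for angles up to
  ~0.5°; the corresponding test is left failing rather than relaxed,
  because the profile flatness that claim needs is inconsistent with the
  kernel width that places D_LEE in the published band.
* The reference field is modelled as the equal-area circle (112.84 mm
  diameter); at that size the lateral factor is saturated to < 0.1%, so
  the circle/square distinction is immaterial for central-axis dose.
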