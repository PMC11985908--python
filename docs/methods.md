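# Methods

This note documents the models behind `multiscint`, the assumptions they
make, the parameters that matter, and what the packaged surrogate study
conditions do and do not demonstrate about real detectors.

## Physical setting

A stack of scintillating layers sits on an RGB detector. X-rays in the
16–67 keV band enter from the top; each absorbed X-ray deposits its energy
at one point and the layer converts it to a burst of optical photons in that
layer's emission channel. The energy band is divided into three bins at 33
and 50 keV — the K-edge energies of iodine and gadolinium, the two standard
contrast-agent elements — so that a detector which can tell the bins apart
can discriminate the agents from tissue and bone.

The design idea is that the three bins can be steered into three different
layers: a top layer with a large, monotonically decreasing attenuation and
no K-edge in band captures 16–33 keV; a middle layer with a K-edge at
50 keV captures 50–67 keV while passing 33–50 keV; a bottom layer with a
K-edge at 33 keV absorbs the remaining intermediate bin. Emission colors
blueshift from top to bottom so light from deeper layers is not re-absorbed
above. What the detector then sees per X-ray is one colored spot whose
**color** names the absorbing layer and whose **effective radius** (mean
distance of the spot's photons to their centroid) is a proxy for the
emission height above the detector.

## Analytic absorption model (`absorption`)

Beer–Lambert attenuation gives the absorption per unit length
`A(z, E) = mu(z, E) exp(-∫_0^z mu dz')`, with the optical depth summed
exactly layer by layer. Three normalizations of `A` drive everything:

* `p_abs(z | E_inc)` — where an X-ray of a given energy is absorbed;
* `p_det(E_det | z)` — what energies are plausible given an absorption
  depth, under a uniform incident measure over the band;
* the joint `N(E_inc) ∫ p_abs p_det dz`, normalized globally, integrated
  over bin rectangles to the 3×3 proportion matrix `p^(mn)`.

The accuracy `eta = Σ_m p^(mm)` is the spectrum-weighted probability that
the probabilistic depth→energy assignment lands in the true bin: 1/3 for
three equal bins with no depth information, 1 for perfect isolation. Note
that `p^(mn)` is normalized so each incident energy contributes through
`N(E)` only — an incident bin's weight does not depend on how often it is
absorbed. The empirical confusion matrix in `reconstruction.empirical_eta`
is normalized the same way (rows conditioned on their own counts, then
scaled by the bin prior); normalizing by detected counts instead would
reward stacks that simply refuse to absorb hard X-rays.

Quadrature: composite Simpson in depth on a per-layer grid (default
`dz = L/2000`) and trapezoid in energy (default 0.25 keV) on per-bin grids.
Layer boundaries and K-edges are carried as double points so no panel
straddles a discontinuity; the K-edge energy itself belongs to the
post-edge branch (`H(0) = 1`), matching the convention that an edge energy
starts the upper bin. Refining both grids twice moves `eta` by less than
1e-3.

## Materials (`materials`)

Two attenuation representations: tabulated mass-attenuation curves
(log–log interpolation, never across a K-edge, user-supplied densities) and
the photoelectric-like parametric form
`mu(E) = E^a exp[b + c H(E - E_K)]` with `a < 0`. Mixtures combine by the
mass-weighted sum of component mass-attenuation curves, with the edge list
of a mixture the union of component edges. Units are fixed package-wide:
keV, mm, g/cm³, `mu` in 1/mm.

Real scintillator and tissue tables are deliberately not bundled
(licensing and versioning of external physical databases); the package
ships **parametric surrogates** instead, chosen once to satisfy the design
rules above: an edge-free top layer anchored near ZnSe-class magnitudes
(`a = -2.55`, `mu(20 keV) ≈ 10.6/mm`), a middle layer with a 50 keV edge
and ~4.5× jump (Gadox-class), a bottom layer with a 33 keV edge and ~5.5×
jump (NaI-class). Light yields (55/60/38 photons per keV, top to bottom)
and decay times follow the same material classes. Surrogate tissues for
the phantom (adipose, muscle, bone, 1% iodinated and gadolinated blood)
are anchored at 30 keV to typical published magnitudes with edge jumps
sized for a 1% agent mass fraction.

## Monte Carlo simulator (`montecarlo`)

The event-level simulator replaces a full particle-transport code at desk
scale. Simplifications, in order of physical importance:

* **Photoelectric-style total absorption at one point.** No Compton
  scattering, no K-fluorescence escape: the deposited energy equals the
  incident energy. This overstates how cleanly energy maps to depth.
* **Straight-ray optics with a hard angular acceptance.** Emission is
  isotropic; only downward photons within the total-internal-reflection
  cutoff (25°) can reach the detector, and a photon emitted a height `h`
  above the detector lands at offset `h tan(theta)`. No refraction at
  interfaces, no optical self-absorption (the blueshift ordering is the
  design argument for neglecting it).
* **Poisson photon statistics with thinning.** The photon budget is
  Poisson(yield × E × efficiency); survivors of the angular cap are sampled
  directly from the cap (statistically identical to emitting everything
  and discarding). The detection-efficiency scalar (default 1) absorbs all
  unmodeled losses.
* **Idealized nanophotonic angular filter**: a hard cutoff (default 15°)
  on photons born above the bottom layer. The removed fraction of
  detector-bound light has the closed form
  `1 - (1 - cos θ_c)/(1 - cos θ_TIR)` — about 64% at 15°/25°.

The absorption-depth sampler is exact inverse-CDF on the piecewise
exponential survival law; its histograms are tested against the analytic
`p_abs` by chi-squared at n = 50,000. Detector default: 12.8 mm square,
25 µm pitch (512×512 — chosen so single-photon spots span several pixels;
the pitch is a rendering choice, all clustering runs on raw hit
coordinates). Out-of-bounds hits are dropped. All randomness flows through
one seeded generator; a frame is bit-reproducible from its seed.

## Spot finding and scoring (`clustering`)

Spots are found by a G-means-style loop: k-means refinement (two-step
iteration to a 1e-6 mm tolerance, 100 iteration cap), then a unimodality
test of each cluster's projection onto its first principal axis; rejected
clusters split along that axis at ±sqrt(2λ/π). The unimodality test is the
Hartigan dip statistic — the minimal sup-distance from the empirical CDF
to the class of unimodal CDFs — implemented in-package with the classic
convex-minorant/concave-majorant algorithm and validated against an exact
linear-programming oracle. P-values come from seeded bootstrap against the
uniform null (the least-favorable unimodal case); the split decision uses
cached null critical values at significance `alpha = 0.001` (the usual
G-means setting; exposed). Clusters under 4 points are unimodal by
decision.

Clusterings are scored against the ground-truth event assignment by the
Fowlkes–Mallows index computed from the label contingency table, checked
against pair enumeration and an independent library implementation.

## Energy reconstruction (`reconstruction`)

Calibration sweeps the band in 1 keV steps with single-X-ray simulations
(desk default 2,000 per energy; the acceptance script uses 10,000) and
accumulates counts over (channel, radius bin, energy). Radii are binned
into 32 equal-width bins spanning [0, 99th percentile] of calibration
radii with overflow clamped into the last bin; counts get +0.5 additive
smoothing before normalization. A measured spot's bin posterior is the
bin-aggregated conditional at its (channel, radius bin); classification is
MAP with ties to the lower bin, and empty cells fall back to the channel
marginal with a logged warning. Events with no surviving photon are
invisible; they are excluded from calibration and reported separately as
unclassifiable. Both the MAP accuracy and the average posterior mass on
the true bin (the soft analog of the analytic `eta`) are reported; MAP is
the headline. The calibration table serializes to a single versioned JSON
file — the count array is small (3×32×52) and a plain-text container keeps
it portable and diffable.

A note on convergence: with desk-scale calibrations the per-cell
conditional over 52 energies is intrinsically noisy — a cell holding
`n` events spread over `K` energies moves by a total-variation distance of
roughly `sqrt(2K/(pi n))` between independent runs, about 0.06–0.10 at
2,000 events/keV. The three-bin posteriors the classifier actually uses
average over that noise and are stable (TV < 0.05 per well-occupied cell
at the same scale); matching per-energy conditionals to the same tolerance
requires calibration sizes of order 10^5 per keV.

## Bounds (`bounds`)

The floor is uniform guessing, 1/M. The ceiling optimizes the analytic
`eta` over hypothetical three-layer stacks in the parametric form with
K-edges fixed at 33 keV (bottom) and 50 keV (middle) and nine free
parameters (a, b, c per layer), multi-start bounded quasi-Newton per shared
layer thickness over a 0.01–3.5 mm sweep. The landscape is smooth in the
parameters (edges live on the energy axis). Default parameter boxes are
generous neighborhoods of the surrogate materials' parameters and are
fully user-configurable; bounds for real material families require boxes
fitted to measured data. The bound applies to the spectrum-weighted soft
accuracy, which is what the analytic `eta` measures; MAP accuracies are
compared against it in that metric.

## Phantom imaging (`phantom`)

The forward model works at the spectrum level: per region, the incident
spectrum is attenuated through the pixel's material mix (path thicknesses
summing to the 1 cm phantom thickness; depth order is irrelevant to
transmission), binned, and pushed through the detector's row-conditional
map `p(n|m)`. Gaussian noise with sigma = epsilon × (mean bin intensity)
emulates detector noise at epsilon ≈ 0.001–0.004; negatives clip to zero
with a logged count. The default phantom embeds four cylinders (muscle,
bone, 1% iodinated blood, 1% gadolinated blood) in adipose background,
with region fractions solved by root finding so all regions transmit
identically to an energy-integrating detector — the phantom is featureless
without energy resolution by construction.

Identification inverts per-bin effective attenuations
`mu_eff = -ln(I/I_flat)/L` (ratios floored at 1e-6 with a logged count) and
clusters pixels in the 3-D attenuation space with the same G-means
machinery. The background cluster is the one holding the most border
pixels. Pixel accuracy `eta_img` is the confusion-matrix trace after the
optimal label permutation, found by assignment optimization and verified
against exhaustive permutation search for small label counts.

## Study conditions, sizes, and what they show

The packaged study conditions are: 0.1 mm layers (0.3 mm total) for the
headline accuracy comparison, a 12.8 × 12.8 mm² detector, uniform incident
energies and positions, desk-scale calibrations (2,000–10,000 events/keV),
10,000-event accuracy estimates, two frames per flux point, and a 96–128
pixel phantom grid. These sizes keep the full suite and the acceptance
script at the minutes scale on one core while leaving every Monte Carlo
margin several standard errors wide.

On these surrogates the framework reproduces the qualitative structure of
a real multicolor design: three-layer accuracy around 0.52–0.54, beating
every same-thickness single layer (an edge-free single layer lands near
0.36; a single layer with an in-band K-edge is worst, pinned at the 1/3
floor); accuracy grows with total thickness; clustering degrades with
flux; thinner stacks and the angular filter both shift the spot-radius
distribution down and buy roughly a factor two in usable flux at FM = 0.8.
Passing these tests shows the machinery is self-consistent and that the
design logic works on materials obeying the stated attenuation structure.
It does not validate real-detector accuracy values: those depend on
measured attenuation tables, Compton and fluorescence transport, and
optical interfaces that the desk simulator deliberately omits. Supplying
measured tables through the documented YAML/ASCII interfaces reruns the
identical pipeline on real materials.

## Known limitations

* No Compton scattering, fluorescence escape, or optical refraction /
  self-absorption; deposited energy equals incident energy.
* The angular filter is an ideal hard cutoff, not a wavelength- and
  angle-dependent transmittance map.
* The spectrum-level phantom model ignores event-level shot noise within
  a pixel (detector noise is modeled as additive Gaussian only).
* Surrogate materials are parametric stand-ins; their parameters are fixed
  package constants, not fits to any specific measured dataset.
* The parametric upper bound is a multi-start local optimum; no global
  optimality claim is made.
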