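# Methods

## Physics model

`brachymc` is a *kerma-approximation* photon Monte Carlo: charged
particles are never transported.  The interaction model is

* **Incoherent (Compton) scattering** on free electrons with the exact
  Klein-Nishina differential cross-section, sampled by the standard
  composition-rejection scheme.  Binding effects and Doppler broadening
  are ignored; the Compton electron's energy is deposited at the
  interaction site.
* **Photoelectric absorption** depositing the full photon energy
  locally; no fluorescence or characteristic X-ray production.
* **Coherent (Rayleigh) scattering off** by default (it changes no
  energy and, for the media and the 10 keV-1.4 MeV range involved, is a
  second-order effect on the quantities this package reports).
* **No pair production** (the spectrum tops out at 1.378 MeV, barely
  above threshold, where the cross-section is negligible).
* **Energy cut 10 keV**: photons below the cut are terminated with
  local deposition; spectrum lines under the cut are dropped at
  sampling time but still counted as histories, so per-history
  normalization matches a full-spectrum definition.

Dose is scored two ways.  *Analog* scoring tallies locally imparted
energy per voxel mass.  *Track-length estimation* (TLE) credits every
photon flight segment with E·(&mu;_en/&rho;)(E, material)·chord per voxel
volume — collisional kerma, reported as dose to medium under the
charged-particle-equilibrium (CPE) assumption.  CPE fails within a few
millimetres of the source and at interfaces of very different density;
the package reports kerma there anyway (flagging |y| &le; 0.2 cm in
profile comparisons), which reproduces the standard workflow this
engine mirrors rather than "fixing" it.

### Interaction coefficients

The per-element tables bundled under `brachymc/data/coefficients/` are
generated by `scripts/make_coefficient_tables.py` from the package's own
physics model, not from an external compilation:

* &mu;/&rho; = (N_A/A)·(Z·&sigma;_KN + &sigma;_pe), and
  &mu;_en/&rho; = (N_A/A)·(Z·&sigma;_KN,tr + &sigma;_pe), with the exact
  closed-form Klein-Nishina total and energy-transfer cross-sections
  (verified against quadrature of the differential form in the tests);
* &sigma;_pe is a smooth five-parameter fit,
  ln &sigma; = a0 + a1·lnZ + (a2 + a3·lnZ)·x + a4·x² with
  x = ln(E/100 keV), anchored on standard attenuation values for O, Al,
  Fe and Pb between 10 keV and 1 MeV, with a constant jump ratio of 5.5
  at the K edge for Mo and Ir (the only bundled elements with a K edge
  above 10 keV).

Element-wise photoelectric accuracy is of order &plusmn;30%.  What the
package's headline numbers actually depend on is much better behaved:
above ~50 keV in low-Z media the coefficients are Compton-dominated and
good to a few percent against standard tables (water &mu;_en/&rho; within
~2.5% over 50 keV-1 MeV), and the water/air mass energy-absorption
*ratio* — which the dose-rate constant is mostly made of — is set by
Z/A ratios and reproduced to ~0.1%.  Crucially the tables are
*self-consistent with transport*: TLE kerma and analog energy
deposition share the same cross-sections, so the two estimators agree
in expectation exactly, a property the tests exercise.  Radiative
losses of secondaries (&lt;0.5% in these media below 1.4 MeV) are
neglected in &mu;_en.

The generated grid is 65 log-spaced points over 10 keV-1.4 MeV plus
K-edge bracketing points; interpolation is linear in log-log, with no
extrapolation allowed.

### Source model

The GammaMed Plus geometry uses the published dimensions: active core
L = 3.5 mm, diameter 0.6 mm, pure iridium at 22.42 g/cm³; 316L capsule
(8.03 g/cm³) 0.9 mm outer / 0.7 mm inner diameter; 304 wire
(5.6 g/cm³) 0.9 mm diameter, modelled over 2 mm.  Details the published
drawing does not fix numerically were chosen once: a 0.05 mm radial and
axial clearance between core and capsule cavity (air-filled), 0.5 mm
solid capsule ends, and a truncated-cone tip of height 0.5 mm tapering
to 0.25 mm radius (configurable; dose points of interest sit &ge; 2 mm
off the tip axis where this detail is second order).  Ir-192 activity
is uniform through the core; emission is isotropic; the source local
frame has z along the long axis, origin at the core centre (TG43
convention).

The bundled spectrum is the NNDC-style Ir-192 line table: evaluated
gamma lines plus Pt/Os K X-ray lines and grouped L X-ray lines,
2.35 photons/decay, 7.82 keV-1.378 MeV, intensity-weighted mean
0.347 MeV.  The L-group intensities (all under or near the 10 keV cut)
are approximate; they are absorbed in the capsule, and because both the
reference dose and the air-kerma strength are per history their
normalization cancels exactly in the dose-rate constant.

## Transport engines

**Voxel engine** (slab phantoms): exact Amanatides-Woo grid traversal
with chord-wise optical-depth accumulation, so the flight distance is
sampled from the exact heterogeneous exponential.  Woodcock delta
tracking is available as an analog-mode option with identical
expectation (cross-validated in the tests).  Voids (the "vacuum"
material) have zero attenuation; analog deposition that would land in a
void is banked to a separate tally and warned about.  The source
hardware is carved onto the 1 mm grid by 10&sup3; sub-voxel sampling per
voxel; a voxel majority-filled by hardware takes its dominant hardware
material (a plain plurality would always lose to the surrounding
medium, erasing 0.9 mm hardware from a 1 mm grid).

**Sphere engine** (TG43 runs): the encapsulated source is tracked over
its analytic geometry by 20 &mu;m ray-marching inside a tight bounding
cylinder, and analytically in the surrounding homogeneous medium (water
sphere of 40 cm radius, or void for air-kerma-strength runs).  Kerma is
scored by track-length estimation on (r, &theta;) shells via exact
two-sphere chord clipping, with &theta; assigned at the chord midpoint
— shell scoring avoids the dose-gradient-over-voxel bias of Cartesian
scoring near a source.  Shell-averaged kerma is converted to the point
value at the nominal (r, &theta;) with the line-source geometry factor
averaged over the bin (the same D&times;G0/G idea used for profile
presentation).  Default bins: 1 mm thick shells, 10&deg; polar bands
with a narrow 88-92&deg; transverse band.

**Air-kerma strength**: S_K = K_air(d)·d² scored in vacuo at
d = 100 cm (default) in an 85-95&deg; transverse band.  In vacuo kerma
falls exactly as 1/r², so the shell-volume average maps to K·d² without
thin-shell bias, and S_K is independent of d (tested at 10-200 cm).
Per-history S_K in Gy·cm² divided into per-history dose in Gy gives the
dose-rate constant directly in cGy·h&#8315;&sup1;·U&#8315;&sup1;, since
1 U = 1 &mu;Gy·m²/h = 1 cGy·cm²/h.

**Randomness and replay**: Python-level sampling uses a named, seeded
`RandomStream` (MT19937 by default); the compiled kernels seed numba's
internal Mersenne Twister state once per run.  The contract, enforced
by tests, is bit-exact replay under a fixed (seed, configuration,
phantom) — not a particular stream shared across engines.

**Uncertainty** is accumulated history by history (first and second
moments of the per-history voxel/bin score, Sempau-style last-history
flush), which is unbiased for within-history correlated scores;
reported as k=1 relative standard error, NaN-flagged for unscored
voxels, undefined for n &lt; 2.

## TG43 engine

The subtended angle &beta; is computed as a difference of `atan2` terms,
stable through &theta; &rarr; 0/180 where G_L passes smoothly into the
on-axis closed form 1/(r² &minus; L²/4); the implementation agrees with
direct quadrature of the defining line integral to 1e-10.  g_L is
interpolated linearly in r, F bilinearly in (r, &theta;); both are
normalized exactly at r0 = 1 cm, &theta;0 = 90&deg;, and the reference
node must be present in the table (no silent interpolation at the
normalization point).  Evaluation outside the tables raises unless
nearest-edge evaluation is explicitly allowed.  The uncertainty budget
carried through `dose_rate_constant` combines, in quadrature, the
type-A statistics of the reference-point dose and of S_K; bundled
alongside are the published consensus value 1.117 &plusmn; 0.004 and
the two source estimates (1.118 &plusmn; 0.003, 1.115 &plusmn; 0.003)
whose half-up-rounded mean defines it.

## Gamma analysis

The 1D gamma index uses local normalization by default (denominator:
the reference dose at the point under test; global mode available).
The evaluated profile is treated as piecewise linear, and gamma² —
quadratic in position on each linear segment — is minimized in closed
form per segment within the finite search window, so the reported value
is exact rather than a dense-search approximation; the tests confirm it
lower-bounds and agrees with an independent bounded-Brent numerical
oracle to 1e-6.  The window (&plusmn;cap&times;distance-criterion,
default &plusmn;2 mm) also caps the maximum obtainable gamma at 2,
mirroring the search-limit behaviour of the widely used MATLAB
implementation of this test.  Where the local reference dose is zero
(possible in sparsely sampled Monte Carlo profiles) the denominator
falls back to the global reference maximum — identically zero profiles
agree trivially.  Reference-side statistical uncertainty is *not*
folded into gamma; it is reported separately with the point-to-point
differences.  Pass rates are computed over non-excluded points
(|y| &gt; 0.2 cm) and rounded half-up to two decimals in tables, with
point counts reported alongside because a percentage over an
unstated denominator is uninterpretable.

## Synthetic data

The six slab phantoms reproduce the published material combinations
(water backscatter; PEEK/air, cartilage/bone, titanium/lung,
adipose/muscle media; stainless-steel and PMMA source slabs, the PMMA
phantom having no second backscatter slab).  Voxel centres sit at
(i+&frac12;) mm, so 101 mm and 11 mm slabs map to whole voxel counts
exactly, an identity the tests assert for all six phantoms.  Profiles
are taken along the stacking axis through the source centre (the
drawing leaves the lateral offset unstated; through-centre is the
recorded default).  The profile-pair generator applies a known shift,
scale and multiplicative Gaussian noise to a declared positive shape on
a 1 mm grid; its metadata is the ground truth recovered in the tests
(best-match shift to within half a search step).  The generated TG43
grid (`generate_tg43_grid`) is the stand-in for an external
planning-system export in end-to-end tests; real TPS grids are imported
via the flat-binary/CSV + JSON-sidecar path instead.

What the synthetic stage does *not* emulate: CT-derived anatomy,
applicator/shield hardware, DICOM transfer, and the vendor dose engine
itself.  A passing gamma stage on synthetic pairs demonstrates the
comparison machinery, not the accuracy of any clinical system.

## Problem sizes and numerical choices

The reference workflow this package mirrors ran ~2.1e9 histories per
configuration over days; `brachymc` exposes `n_histories` and reports
statistical uncertainty instead of claiming that precision.  The
defaults used by `scripts/acceptance.py` — 1e7 histories for the
water-sphere dose (k=1 relative statistics ~0.4% at 1 cm) and 1e6 for
in-vacuo S_K (~0.3%) — were chosen as the point where the statistical
term is small against the published &plusmn;0.033 uncertainty of the
dose-rate constant being compared to; the whole script is a few minutes
on one core.  Histories beyond the 2.1e9 single-run ceiling trigger a
soft warning (shard by seed instead).  Other fixed choices: 20 &mu;m
march step inside the source (optical-depth error per crossing
&lt; 1e-3, sign-averaging over emission angles), 256-point log-energy
lookup grids in the kernels, 1e-9 cm tolerance on ray-grid chord
partitions, and a numba threading-free (single-thread) kernel design so
that replay is exact on any machine.

## Known limitations

* Kerma &ne; dose within ~0.6 cm of the source and in low-density media
  (electron ranges exceed the voxel size); values there are collisional
  kerma by construction.
* Free-electron Compton and the parameterized photoelectric fit limit
  element-wise coefficient accuracy (~&plusmn;30% worst case on
  &sigma;_pe, ~1% on Compton-dominated mixtures); fine for the ratios
  and comparisons computed here, not a replacement for evaluated
  cross-section libraries in absolute heavy-element dosimetry.
* No fluorescence: characteristic X-ray escape from steel/titanium is
  absent, slightly hardening dose just outside high-Z slabs.
* The anisotropy function very near the wire axis (&theta; &gt; ~170&deg;)
  reflects the 2 mm modelled wire; engines modelling longer wires report
  systematically lower F there.
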