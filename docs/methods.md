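# Methods

## Electromagnetic model

The simulator solves Maxwell's equations on a 2D Yee lattice in the
transverse-magnetic mode: one out-of-plane electric component `E` on cell
corners and two in-plane magnetic components `H1` (y-staggered) and `H2`
(x-staggered). Spatial and temporal derivatives are second-order central
differences; the leapfrog update advances H half a step from the curl of E,
then E from the curl of H scaled by `1/n(x,y)^2`. This single-E-component
mode was chosen because the scalar post-processing (one field amplitude per
probe) only uses one electric component; polarisation-resolved tissue
response is out of scope.

All media are non-dispersive: each cell carries a constant refractive index
`n >= 1` over the whole source band. The only dispersion in a run is the
numerical dispersion of the grid. Units are SI throughout, with
`c = 299792458 m/s` (and `eps0`, `mu0`) taken from `scipy.constants`.

**Stability and resolution.** The time step is `dt = Sc * dx / c` with the
Courant number capped at `1/sqrt(2)` in 2D (used as the default). Grids
coarser than 20 cells per carrier wavelength are rejected; the canonical
configuration uses 100 (850 nm carrier on 8.5 nm cells, `dt ~ 2.0e-17 s`).
Field finiteness is checked every 200 steps and a blow-up raises an error
carrying the step index.

**Boundaries.** The outermost E nodes are a perfect electric conductor; a
convolutional PML (unit stretching, zero frequency shift) occupies the
cells just inside it. The conductivity is graded polynomially,
`sigma(d) = sigma_max (d/L)^m`, with `sigma_max` set from a design
round-trip reflection `R0`: defaults 10 cells, order `m = 3`, `R0 = 1e-6` —
community-standard values for pulsed 2D work. Measured reflected energy
against a double-length-domain oracle is ~1e-9 at the default, with a
discretisation floor near `R0 ~ 1e-4`. The transverse (y) boundary can be
made periodic; a line source then radiates an exact plane wave, which is
how the Fresnel and slab validation runs avoid edge diffraction.

**Source and probes.** The source is a soft (additive) line spanning the
transverse interior — approximating a plane wave along the long axis — or a
single-node soft source for unit tests. Its waveform is a Gaussian-enveloped
carrier `cos(2 pi c (t - t0)/lambda0) exp(-(t - t0)^2 / 2 sigma_t^2)`. The
printed pulse "length" `W` is calibrated as five temporal standard
deviations (`sigma_t = W/5`): this is the unique simple ratio that
reproduces both quoted spectral widths (25 fs -> ~76 nm, 150 fs -> ~13 nm)
when the *amplitude* spectrum is Gaussian-fitted in wavelength. The power
spectrum is narrower by sqrt(2) and would give ~54 nm; bandwidth fits
therefore use the amplitude spectrum, while `power_spectrum` defaults to
true power (it satisfies Parseval to 1e-9). Probes record the E amplitude
at a fixed node every 10 time steps (configurable), matching the cadence
the post-processing assumes.

## Phantoms

**Glass rod.** Three layers along the propagation axis: water
(`n = 1.3272`), glass (`1.5098`), water-sucrose solution. The solution
index follows the degree-Brix scale translated rigidly to 850 nm:
`n = 0.00145 * Bx + 1.3290`. The two printed water values (1.3272 in the
layer stack, 1.3290 as the Brix intercept) are deliberately kept distinct —
each model uses its own published value and they are never unified.

**Nerve.** Half the domain is Ringer's solution (treated as water, 1.3290);
then an epineurium band (1.4, from a 40% fluid / 60% dry-mass mixture with
70/30 fibres-to-lipids) containing circular elastic fibres (1.41, scleral
fibrils); then endoneurial fluid (1.335, as cerebrospinal fluid) packed
with myelinated axons — axoplasm core 1.338 and a myelin annulus 1.4 (40%
water plus a 70/30 lipid/protein dry mass). Axon diameters, counts and
packing are not published for this preparation; the defaults (2 um core,
0.3 um sheath, 0.3 um clearance, jittered hexagonal lattice seeded by the
experiment seed, centres clamped into the feasible box and overlapping
candidates skipped) were chosen once to resemble micrograph scale and are
fully configurable. Three elastic fibres sit at staggered depths across the
band by default. A cell takes the index of the region containing its E-node
centre; no sub-cell averaging is applied.

**Active nerve.** Activity is emulated by a discrete shift of the axoplasm
index only, default `+1.45e-5` — the index change of a 0.01 degree-Brix
sucrose solution relative to water, which makes the dilute-sucrose rod a
bench-verifiable stand-in for the active nerve. The ray-tracing argument
that originally motivated the magnitude is not reimplemented; the shift is
a configuration parameter.

## Post-processing

The reference arm is a separate run in which the phantom is replaced by its
front medium and a perfect-mirror plane, by default at the sample's front
interface so zero optical delay aligns there. Sample and reference traces
are summed and squared to form the interference intensity; the A-scan is
the magnitude of the analytic signal (Hilbert transform) of that intensity
after baseline removal. The default baseline is the global mean — the echo
train carried by the squared-sample term then stays in the envelope, which
is what makes every interface visible in a fixed-mirror two-run design.
Subtracting the self terms (`ref^2 + sample^2`) instead is available as an
option but retains only the cross term, which a fixed mirror confines to
one delay. When two scans will be differenced, both arms share one baseline
(the inactive arm's mean): a per-arm mean would differ by a constant and
couple the arms everywhere.

**Depth mapping.** Each detected instant corresponds to a round-trip
optical path; depth advances by `c dt / (2 n(z))` using the axial index
profile of the phantom (layer-aware mode, the default — it makes geometric
layer thicknesses recoverable), or by a single global index in uniform
mode. Depth zero is placed at a named interface (water/glass for the rod,
Ringer/epineurium for the nerve). The reported scan is cropped from
halfway between the probe and the zero interface, which removes the
incident pulse passing the probe (it maps to depth `x_probe - x_interface`)
while keeping the full echo train.

**Differential scans and noise.** The differential is
`(inactive - active) / I_in`, where the incoming intensity `I_in` is the
squared peak of the analytic signal of the reference trace. The shot-noise
band is the relative Poisson standard deviation
`sqrt(envelope / I_in / N_photons)` at a configurable photon budget,
default 1e6 photons per A-scan (the absolute budget of a real detector is
setup-dependent; the band scales as `1/sqrt(N)`).

Two identical pipelines produce bit-identical scans, so a zero perturbation
cancels exactly. With a non-zero perturbation the localisation of the
differential is limited by the coherence gate and the analytic-signal
tails: at fixture scale ~98% of the differential energy lies past the
axon-region onset (minus one coherence length) and pre-onset residuals stay
roughly an order of magnitude below the peak — the numerical meaning of
"only the axon region changes".

## Validation

- **Propagation**: envelope-peak timing between two vacuum probes matches
  `d/c` within 1% at 100 cells/wavelength; the error shrinks as resolution
  grows from 20 to 100 cells/wavelength.
- **Fresnel**: per-wavelength intensity transmission across a water-glass
  interface, `(n2/n1) |E_t(lambda)/E_i(lambda)|^2` with the incident pulse
  isolated by time gating, matches `4 n1 n2/(n1+n2)^2 = 0.99586` within 1%
  (measured ~0.04% at 100 cells/wavelength) and is wavelength-flat; the
  impedance factor `n2/n1` is required for energy consistency, and
  reflected plus transmitted intensity closes to 1 within 0.5%. Spectral
  ratios use only bins above 1% of the incident peak power.
- **Geometry**: a mirror echo returns after `2d/c` within one subsampled
  step; a 4 um slab's two interface peaks sit 4 um apart on the depth axis
  within one coherence length.

## Problem sizes

Test and validation runs use reduced-scale fixtures: the same physics code
path on 20 x 4 um^2 (or quasi-1D) domains at 100 or 50 cells per
wavelength, sizes chosen so the whole suite completes in minutes on one
core. The full-scale configuration (100 x 17 um^2 at 8.5 nm cells) remains
a valid input and is exposed as `canonical_nerve_config()`. The stepping
loop is numba-compiled when numba is importable, with an equivalent
vectorised numpy fallback.

## Known limitations

- 2D only; cylindrical symmetry of the samples is assumed, and speckle
  statistics of a 3D medium are not reproduced.
- Non-dispersive, isotropic, lossless media; no birefringence, so
  polarisation-sensitive contrast mechanisms are absent.
- The reduced fixtures shrink domain and resolution, not physics: they
  preserve layer topology and index values but not absolute echo amplitudes
  or the full-scale speckle texture, so passing tests demonstrate correct
  mechanics and scaling laws, not instrument-level signal levels.
- The Poisson band's absolute scale depends on the assumed photon budget;
  other detector noise sources are intentionally excluded.
- B-scan assembly from tiled domains is not implemented.
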