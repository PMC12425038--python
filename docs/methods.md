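# Methods

`smsepi` implements a vendor-neutral BOLD SMS-EPI fMRI protocol end to
end: sequence generation in the Pulseq block model, design-phase safety
prediction, a discrete forward simulator that plays the role of the
scanner, the harmonized reconstruction chain, and the fBIRN/ABCD phantom
QA battery.  This note records the models, the defaults that matter, and
the design choices made where the design was genuinely open.

## Sequence model and .seq serialization

A sequence is an ordered list of non-overlapping blocks; each block holds
at most one RF pulse, one gradient per axis, and one ADC window, and block
order is execution order.  Gradients are gamma-normalized (Hz/m,
conversions assume gamma/2pi = 42.576 MHz/T), so the data model is
nuclide-unambiguous and matches the public Pulseq convention.  Gradient
waveforms must be continuous across block boundaries; the tolerance is
1e-6 of the profile's maximum gradient (the continuity requirement itself
carries no published tolerance).

Serialization targets Pulseq v1.4 sections ([VERSION], [DEFINITIONS],
[BLOCKS], [RF], [GRADIENTS], [TRAP], [ADC], [SHAPES]) with derivative
run-length shape compression.  Event IDs are content-hashed so the many
repeated echo blocks of a multi-volume EPI file share single library
entries; writing is deterministic (byte-identical for the same object).
Two dialect notes: delays are written in (possibly fractional)
microseconds, and arbitrary-gradient lines carry two trailing columns with
their boundary values.  Unknown sections (e.g. [SIGNATURE]) are preserved
verbatim.  Default rasters: RF 1 us, gradient 10 us, ADC 100 ns, block
duration 10 us.

k-space trajectories integrate the gradient waveforms analytically
(piecewise-quadratic for trapezoids), with k reset at each RF pulse's
effective center (time of peak amplitude).

## RF design

Excitation and fat-saturation pulses are designed with the Shinnar-Le Roux
transform.  The beta polynomial is a Parks-McClellan equiripple filter
(least-squares fallback); minimum-phase variants design the
magnitude-squared response on 2n-1 taps and spectral-factorize via the
cepstral method; alpha is the minimum-phase factor of 1 - |B|^2; the
hard-pulse recursion is then inverted.  The recursion pair is validated by
an exact forward/inverse round trip, and every designed pulse is checked
through the package's Bloch simulator (rotation-operator integration, no
relaxation, |M| conserved to 1e-9) - the simulator, not the filter
algebra, is the oracle of record.

The slice-select gradient amplitude is calibrated to the *delivered*
profile: after design, the frequency-domain FWHM of the Bloch-simulated
excitation is measured and g = FWHM/thickness.  This removes the small
(few-percent) bias between a recipe's nominal time-bandwidth and its
half-maximum width, so the slice width equals the nominal thickness for
both filter types.

Multiband pulses sum frequency-shifted copies of the single-band pulse,
one per slice position, with per-band phase offsets chosen by a seeded
random-restart Nelder-Mead minimization of the synthesized peak amplitude
(a Wong-style schedule; for six bands the optimized peak is ~30% lower
than the zero-phase sum).  The comb is synthesized symmetric about z = 0
and shifted to each shot's slice group with an RF frequency offset.

Fat saturation uses a minimum-phase 90 degree pulse played at -3.45 ppm
(-440.7 Hz at 3 T) with bandwidth 35% of the fat-water separation
(TBW 2, ~13 ms); water retains >= 95% Mz, fat Mz is driven below 10%.
RF spoiling uses the community-standard 117 degree quadratic schedule,
phi_n = 117 deg * n(n+1)/2, applied to both the excitation phase and the
receiver phase of each shot.

## Protocol assembly

Defaults follow the ABCD-matched acquisition: 2.4 mm isotropic, 90 x 90
matrix, 60 slices without gaps, SMS factor 6, TR 0.8 s, partial Fourier
0.8, FOV 21.6 x 21.6 x 14.4 cm, blipped-CAIPI FOV/3 shift.  Values the
protocol description does not print are package defaults, reported (not
asserted) by `protocol_report`: flip angle 52 degrees, excitation SLR
TBW 4 / 3.2 ms, TE = minimum achievable (~25.5 ms as built), echo spacing
as designed (~0.75 ms), three navigator echoes, two dummy volumes.

One shot = fat sat (with a >= 4 pi z spoiler), multiband excitation with
slice rephaser, readout prewinder, three ky = 0 navigators of alternating
polarity, ky prewinder, then the CAIPI-blipped ramp-sampled EPI train over
the *late* 80% of ky (asymmetric echo; the early lines are omitted).  Each
echo is one block: the readout trapezoid (alternating sign, zeroth moment
exactly nx/fov_x) with a symmetric ADC window sampling ramps and flat top
at ~2x flat-top oversampling, followed by a short gap holding the y blip
and the CAIPI z blip, so every ADC sample sees a constant, exactly
Cartesian ky.  Per-volume timing is exact: delay blocks pad every shot to
TR / (n_slices/SMS), so one volume sums to one TR to the raster.

Slice ordering: shot s excites slices {s, s+n_shots, ...} (maximum band
separation) with even shots before odd ones.  The CAIPI blips step kz
through the cycle c_e = (ky_e mod S) - (ky_0 mod S) in units of
1/(S * band_separation); referenced to the lowest band of the group, band
b acquires exp(2 pi i b c_e / S) - an exact in-plane shift of b*ny/S
voxels.  One function (`caipi_phase_table`) defines this encoding for the
sequence, the simulator, and the reconstruction.

A single-band reference segment (one 2D-EPI shot per slice, same readout)
precedes the time series; it provides the slice-GRAPPA calibration, the
SENSE coil maps, and the ghost-correction navigators.

## Safety

Two PNS predictors act on the per-axis slew rate at the gradient raster,
combined across axes by root-sum-of-squares:

* impulse-response model: convolution with the normalized nerve impulse
  response h(t) = c/(c+t)^2, scaled by an effective coil length and
  expressed as % of the rheobase.  Defaults are the published GE
  whole-body constants: rheobase 23.4 T/s, chronaxie 334 us, effective
  length 0.333 m (an effective slew rheobase of ~70 T/m/s).  All
  constants are configurable.
* SAFE-style cascade: three first-order low-pass stages; the fastest
  filters the rectified slew, the two slower stages filter the signed slew
  and contribute their magnitude (preserving bipolar cancellation).  The
  stage weights/time constants (0.153/0.109 ms, 0.453/0.336 ms,
  0.340/1.472 ms) are the 3-exponential least-squares approximation of
  h(t), so both predictors share one physiological scale; on the
  protocol's EPI train they agree within ~3%.

The builder derates iteratively: the EPI readout slew is reduced 5% at a
time until the train's impulse-response prediction is below 80% of the
stimulation limit, and an outer loop re-checks one full TR (periodic wrap,
steady-state train) including spoilers, rephasers and prewinders, which
are themselves designed at half the readout slew budget so simultaneous
multi-axis ramps cannot dominate the root-sum-of-squares.  The shipped
protocol lands at ~77% of the limit.  Relative RF energy integrates
|b1|^2 dt per TR against a 1 ms, 180 degree hard pulse.

## Forward simulator

The simulator is a discrete-voxel DFT evaluated at the exact ADC sample
positions of the designed readout - no continuous-object transform - so
the noiseless reconstruction oracle is exact by construction.  Within an
echo ky is constant and integer, so encoding factors into a unitary FFT
along y and a small dense DFT along x at the measured (ramp-sampled) kx
positions; SMS shots are the CAIPI-phase-weighted band sums.  Phantom: a
uniform ball with anti-aliased boundary, default radius 0.4 of the
in-plane FOV (the 17 cm QA ball / 21.6 cm FOV proportion; it may extend
past the slab in z, where selective excitation prevents aliasing).  Coil
maps: Gaussian lobes on a ring with low-order polynomial phase, unit
root-sum-of-squares.  Imperfections, all seeded: per-coil complex Gaussian
noise; an odd-echo phase error exp(i(theta0 + theta1*n)) applied to
negative-polarity echoes in acquisition sample order; a linear
multiplicative drift across volumes.  T2* decay along the echo train,
motion, and B0 inhomogeneity are deliberately absent (extension points) -
passing tests therefore validate the encoding/decoding chain, not
robustness to physiologic or off-resonance effects in real data.

## Reconstruction

Fixed order per volume: odd/even phase correction -> ramp regridding ->
SMS unaliasing -> partial-Fourier zero-fill -> unitary centered inverse
FFT -> root-sum-of-squares coil combination; dummy volumes dropped; output
written as 4D NIfTI (RAS-diagonal affine from the FOV, TR in the header).

* Phase correction: theta0/theta1 are fit once from the reference
  segment's navigators, pairing negative- and positive-polarity samples
  *by kx position* (the Cartesian grid is not mirror-symmetric, so naive
  sample reversal would bias the fit by one k step); magnitude-weighted
  linear fit of the cross-correlation phase.  Injected errors are
  recovered to well under 1%.
* Regridding: the sampled signal is modeled as the DFT of an nx-voxel
  object row at the measured kx positions; the Cartesian line is the DFT
  of the least-squares object estimate (precomputed matrix per polarity).
  For flat-top sampling on the grid this is the identity; for the
  simulator's data it is exact.
* Slice GRAPPA (default): per (shot-group, band) kernels, default 7 x 7
  taps, fit from the CAIPI-phase-weighted collapsed calibration by ridge
  least squares on zero-padded patches - the same patch geometry used at
  application time - with border rows down-weighted (0.25) so the physical
  interior dominates.  A 5 x 5 kernel leaves ~2e-3 interior residual at
  the shipped 6-coil geometry, 7 x 7 reaches ~1e-4, hence the default.
  Interior calibration residual is reported per kernel.
* SENSE: per-voxel least squares over the coil-by-band system built from
  CAIPI-shifted coil maps (ratio-to-RSS maps from the reference segment);
  bands with zero sensitivity at a voxel are excluded and the reduced
  system solved exactly, grouped by support pattern; unresolvable voxels
  are flagged (zeroed); the g-factor map is emitted.  Integer-voxel CAIPI
  shifts are required (matrix divisible by the CAIPI shift).
* Partial Fourier is explicit zero-fill of the missing early ky lines - no
  homodyne, no phase estimation - matching the harmonized workflow this
  package reproduces.

Noiseless end-to-end recovery at the reduced geometry is < 2.5% in-mask
NRMSE for both methods (limited by partial-Fourier truncation of the ball
edge), < 1e-3 for the single-band full-Fourier case, and both methods
agree within 2%.

## QA battery

fBIRN conventions: 2nd-order Legendre detrend per voxel; 21 x 21
center-slice signal ROI (center of mass); SFNR = ROI mean of mean/SD of
residuals; SNR from the odd/even volume-sum difference image; Weisskoff
F(N) for N = 1..21 with RDC = F(1)/F(21) clipped to [1, 21] and flagged at
the bounds; per-axis Gaussian-equivalent FWHM from lag-1 autocorrelation
of detrended residuals, FWHM = dx*sqrt(-2 ln 2 / ln r1), with a sub-voxel
floor flag for r1 <= 0.  Constant series cap SFNR at 1e6 with a flag
rather than returning infinity.

The ghost-to-signal ratio uses mask-based regions: the ghost region is the
object support translated by FOV/2 along PE minus a dilated copy of the
object (a QA ball wider than half the PE FOV leaves no room for fixed
boxes), and background corner boxes shrink adaptively until clear of both
object and ghost.  Because zero-fill partial Fourier leaves truncation
tails in the PE gap (a GSR floor of a few percent at coarse test
resolutions), the ghost-specific validations run on full-Fourier
acquisitions, where an injected pi/20 odd-echo phase produces GSR ~ 0.08
and navigator correction reduces it by more than an order of magnitude.

## Problem sizes

The protocol-conformance checks (sequence generation, trajectory, PNS,
full-geometry simulation and reconstruction of 5 volumes at 90 x 90 x 60,
SMS 6, 8 coils) run at the full printed geometry.  The remaining test
batteries use a reduced geometry of 36 x 36, 12 slices, SMS 3, 6 coils -
36 rather than 32 so the CAIPI FOV/3 shift stays an integer voxel count,
as in the full protocol (90/3 = 30).

## Known limitations

* The simulator excites perfect box profiles implicitly (band membership
  is discrete); the Bloch oracle is used for pulse validation only.
* No in-plane ky acceleration beyond partial Fourier; no non-Cartesian
  readouts; no distortion/motion correction; no absolute SAR (W/kg).
* PNS percentages depend on the model constants; the shipped bound is
  stated for the documented defaults and both models are configurable.
* The .seq writer emits a v1.4-compatible dialect; files produced by other
  writers parse as long as they use the core v1.4 sections.
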