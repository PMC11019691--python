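# Methods

## Forward model

**Optics.** The point-spread function is a scalar angular-spectrum model: a
uniform circular pupil of radius NA/λ_em in lateral spatial frequency,
propagated to each defocus z with the phase factor
exp(2πi·z·√((n/λ_em)² − k²)) and squared in real space. No vector effects,
polarization, or index-mismatch aberration are modelled; the measured
modulation contrast absorbs polarization effects as a single
orientation-independent factor, which is adequate at the moderate pattern
frequency used (237 nm ≈ 0.79 of the emission cutoff). PSF volumes are
normalized to unit total intensity; for image formation each defocus slice
is renormalized to the focal-slice energy, because defocus redistributes
light laterally but does not absorb it — an emitter then contributes its
full brightness to every focal plane's image, up to lateral truncation of
far-defocus kernels.

**Illumination.** Interference of two (±1 orders) or three (0, ±1 orders)
plane waves. With fine fringe period p (237 nm default), the ±1 beams carry
lateral field frequency 1/(2p); the three-beam intensity contains harmonics
at 0, ±1/(2p) and ±1/p. The coarse harmonic beats axially as cos(Δk_z·z)
with Δk_z = 2πn/λ_ex·(1 − cos θ), sin θ = λ_ex/(2np) (beat period ≈ 1.2 µm
here); the fine harmonic is z-independent. Default beam balance gives all
three beams equal intensity, so the intensity harmonics are 3 : 2 : 1 and
the relative modulation depths are m₁ = 4/3, m₂ = 2/3. Two-beam mode blocks
the 0 order (a₀ = 0, fringes fully modulated, z-independent). Illumination
maps are normalized to unit spatial mean inside the simulator so widefield
and structured exposures carry equal power.

**Multifocus detection and camera.** Seven plane images (z offsets −3…+3 ×
264 nm) are each scaled by an 11 % transmission efficiency (the remaining
~23 % of the light is treated as lost to stray grating orders, not imaged),
placed on a 3×3 tile grid with guard gaps inside the sensor crop (the
in-focus plane at the centre cell, two corner cells unused), and offset by
per-plane integer "jitter" — the calibration ground truth. Poisson shot
noise, Gaussian read noise (1.6 e⁻ RMS), gain, offset and bit-depth
clipping follow; noiseless mode keeps exact expectations for conservation
tests. Acquisition sequencing is phase-fastest (5 phases × 3 orientations),
with optional interleaved piezo z-steps of 132 nm; the timing model charges
exposure + 8.5 ms readout per frame and 170 ms per piezo translation (one
per z-step when stepping; none for single-position volumes). Times are
rounded half-up to 1 ms and rates to 0.1 volumes/s — e.g. 142.5 ms → 7.0
volumes/s at 1 ms exposure, 427.5 ms → 428 ms and 2.3 volumes/s at 20 ms.

## Phantoms

All generators are pure functions of (parameters, seed); coordinates are
sample-space nm with the origin at the volume corner and z away from the
coverslip. Bead fields are dart-thrown uniform positions with a hard
minimum separation; emitters rasterize by trilinear splatting (exact
brightness conservation; the 100 nm diameter is sub-voxel and kept as
metadata). Filaments are worm-like-chain random walks rendered as Gaussian
tubes with a deterministic crossing pair (≤ 200 nm lateral approach) so
sub-diffraction crossings always exist; integrated density equals linear
density × arc length. The ER-like phantom grows a random spanning tree of
tubules with perforated sheet patches at a fraction of nodes, then
saturates the rendered intensity (membrane fluorescence is roughly uniform
per area), which also makes the half-max support a single 26-connected
component. Perforated-sheet phantoms at chosen z planes serve the
axial-contrast comparisons.

What the phantoms do *not* emulate: temporal dynamics, photobleaching,
spectral variation, aberrated or depth-dependent PSFs, and cytosolic
background. Passing tests therefore demonstrate the correctness of the
processing chain under the stated optical model, not performance on real
tissue-like data.

## Reconstruction

Plane-by-plane generalized Wiener, applied per orientation and focal plane:

1. **Band separation.** Per-pixel inversion of M_jm = exp(i·m·φ_j),
   φ_j = 2πj/n_phases; exact for 5 phases / 5 orders (3/3 two-beam),
   least-squares when overdetermined. A condition-number gate rejects
   duplicate phases.
2. **Parameter estimation.** The order-1 band is cross-correlated with
   order 0. Two measures make the carrier peak robust against
   object-speckle sidelobes (sparse bead fields are the hard case): both
   bands are flattened by regularized OTF compensation before correlating,
   and the correlations of all seven focal planes are pooled coherently —
   they share one illumination pattern. The integer-bin peak (restricted to
   ±25 % of the nominal frequency) is refined by zoomed local DFT stages to
   ~0.005 bins under a Hann window that suppresses leakage tails; the top 8
   candidate bins are refined and the best kept, since scalloping can drop
   a half-bin-offset peak below a sidelobe. Starting phase and complex
   modulation amplitudes come from OTF-weighted least squares; per plane,
   amplitudes are re-estimated (the coarse harmonic beats axially), while
   the wave vector and phase are anchored globally. Failure raises, with an
   optional fallback to nominal parameters.
3. **Wiener combination.** Each band is zero-pad upsampled 2×, shifted to
   its true position by a real-space phase ramp, and merged with
   conj(c_m·O_m) weighting over Σ|c_m·O_m|² + w², w = 0.05 relative to the
   unit OTF peak. Orders with |c_m| < 0.02 are dropped. A raised-cosine
   notch of depth 0.95 and width 0.5× the pattern frequency attenuates the
   order-0 low-frequency core — the optical-sectioning step: out-of-focus
   haze is concentrated there, and the modulated bands carry the same
   in-focus information. Triangle apodization reaches zero at
   2NA/λ_em + 1/p. Axial resolution extension is deliberately not
   attempted: planes are independent, matching an acquisition in which the
   sample never moves relative to the grating.
4. **Assembly.** Interleaved z-steps merge by plane interleaving (no
   interpolation); the stack is then aligned translation-only by upsampled
   phase correlation (factor 100) against the central plane and clamped
   nonnegative. Registration runs *after* reconstruction so it cannot
   disturb sample–pattern frequency interactions. Widefield volumes are the
   per-plane mean over all 15 (or 9) raw frames, which cancels the
   modulation exactly over full phase cycles.

Tile-map calibration reproduces the instrument procedure: a bead field is
scanned through focus in multifocus widefield mode, each tile's maximum
intensity projection is cross-correlated (normalized, integer peak) against
the in-focus reference tile, and the recovered offsets become the per-plane
crop origins. Offsets are relative to the reference tile, exactly as in the
overlay procedure; the strongest correlation peak wins when several beads
produce multiple candidates.

## Parameter defaults

| parameter | default | why |
| --- | --- | --- |
| NA / n / λ_ex / λ_em | 1.4 / 1.515 / 491 / 525 nm | 63×/1.4 oil objective, 491 nm laser, GFP-range emission |
| magnification | 63 × 1.6 = 100.8× | objective × auxiliary tube lens |
| sample pixel | 6.5 µm / 100.8 = 64.5 nm | sCMOS pitch divided by magnification (derived, never set) |
| pattern | 237 nm at 41°/101°/161°, 5 phases | orientations 60° apart; 1.74× lateral improvement |
| planes | 7 × 264 nm, 11 %/plane | light efficiency vs axial coverage (1.8 µm) |
| camera | 1600² crop, 1.6 e⁻ read noise, offset 100 | sCMOS-like detection |
| timing | 8.5 ms readout, 170 ms/piezo step | rolling-shutter readout bound; stage settling |
| Wiener w / notch depth / notch width | 0.05 / 0.95 / 0.5·(1/p) | regularization vs ringing; haze rejection vs DC fidelity |

Desk-scale runs (tests, demos) shrink only the field of view — 128 px tiles
in a 424 px frame, 9–17 phantom z-slices at 132 nm — never the instrument
parameters, so every per-pixel and per-frame quantity matches the
full-scale configuration.

## Numerical choices

Spectra use the plain FFT layout (DC at bin 0) with frequencies in
cycles/nm and corner-origin real-space coordinates, centralized in one
helper module; arrays are only fftshift-ed transiently. The radial OTF
interpolant is anchored at OTF(0) = 1 (bin-averaged profiles start at a
half-bin radius). FWHM measurement fits a Gaussian plus offset within ±1.5
estimated FWHM of the peak — diffraction tails are not Gaussian and bias a
full-profile fit low — and falls back to the full profile for short (axial,
7-sample) traces; a half-maximum crossing oracle guards the fit in the
tests. Reported times/rates round half-up. Degenerate inputs fail loudly:
undersampled PSF grids, patterns below the excitation diffraction limit,
infeasible bead packing, overflowing tile layouts, duplicate phases,
featureless planes in registration (warn, shift 0).

## Known limitations

* The scalar, unaberrated PSF makes widefield FWHMs (~194 nm lateral,
  ~500 nm axial at these samplings) smaller than a real instrument
  measures; ratios between reconstruction and widefield are the meaningful
  desk-scale quantities.
* On the two-sheet axial-contrast comparison, both SIM modes far exceed
  widefield (gaps ≈ +0.6 of contrast), but three-beam does not clearly beat
  two-beam in this model (differences within ±0.03): at this pattern
  frequency the detection OTF already suppresses the two-beam fine-band
  defocus leak, while the three-beam coarse band admits extra leak from
  structure near the illumination focus, where its axial beat provides no
  suppression. The experimentally reported three-beam advantage involves
  aberrated PSFs, spectrum-optimized reconstruction filters and thick
  samples that this model deliberately omits. A per-plane gain-equalization
  option exists (`ReconOptions.equalize_gain`) and shows that naive
  notch-based sectioning can masquerade as a three-beam advantage through
  axial gain ripple; it is off by default.
* The coarse-band treatment near its axial zero crossings relies on
  per-plane amplitude re-estimation; very dim planes fall back to dropping
  the band (min_mod), trading resolution bridging for robustness.
* The light not delivered to the seven tiles is discarded, not imaged as
  stray background; fixed-pattern and rolling-shutter effects are not
  simulated (the readout constraint enters only the timing model).
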