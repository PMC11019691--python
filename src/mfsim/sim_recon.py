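"""Plane-by-plane SIM reconstruction.

The classic generalized-Wiener scheme: per orientation the phase-stepped raw
images are separated into complex Fourier orders (bands) by inverting the
phase-mixing matrix; the illumination wave vector, starting phase and
modulation depths are estimated from the bands by cross-correlation with
sub-bin refinement; each band is shifted to its true frequency position on a
2x upsampled grid and all bands are merged by OTF-weighted regularized
division, followed by apodization.

Optical sectioning: the order-0 band's low-frequency core (where the
modulated bands carry the same object information) is attenuated by a
raised-cosine notch.  Out-of-focus structure enters the modulated bands only
through the defocused OTF at the pattern frequency — and, in three-beam
mode, through the axially beating coarse component — so down-weighting the
order-0 core rejects out-of-focus light.  Axial resolution is deliberately
not extended: planes are reconstructed independently, matching a multifocus
acquisition in which the sample never moves relative to the grating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import interp1d

from ._fft import freq_grids, pad_spectrum, refine_peak
from .errors import DimensionError, EstimationError, ReconstructionError
from .mf_simulator import RawAcquisition
from .optics_core import (
    THREE_BEAM,
    TWO_BEAM,
    IlluminationPattern,
    OpticalConfig,
    PSFVolume,
    axial_beat_wavevector,
    pattern_wavevector,
)
from .registration import TileMap, extract_planes, subpixel_align_stack

__all__ = [
    "BandSet",
    "PatternEstimate",
    "ReconOptions",
    "ReconVolume",
    "separate_bands",
    "estimate_pattern",
    "wiener_combine",
    "reconstruct_volume",
    "widefield_average",
    "rl_deconvolve",
    "radial_otf",
]


def separate_bands(
    frames: np.ndarray,
    n_orders: int,
    phases: np.ndarray | None = None,
) -> dict[int, np.ndarray]:
    """Invert the phase-mixing matrix for one orientation.

    ``frames`` holds the ``n_phases`` raw images (phase index first); the
    j-th frame is modelled as ``sum_m B_m(x) * exp(i m phi_j)`` with phases
    ``phi_j = 2 pi j / n_phases`` on the fundamental harmonic.  Returns the
    complex band spectra keyed by order m in ``-(n_orders//2) ..
    +(n_orders//2)`` (FFT layout).  Exact inversion when ``n_phases ==
    n_orders``; least-squares otherwise.
    """
    n_phases = frames.shape[0]
    if phases is None:
        phases = 2.0 * np.pi * np.arange(n_phases) / n_phases
    if n_phases < n_orders:
        raise DimensionError(f"{n_phases} phases cannot determine {n_orders} orders")
    ms = np.arange(n_orders) - n_orders // 2
    mix = np.exp(1j * np.outer(phases, ms))
    if np.linalg.cond(mix) > 1e8:
        raise ReconstructionError("phase-mixing matrix is singular (duplicate phases?)")
    inv = np.linalg.pinv(mix)
    spectra = np.fft.fft2(np.asarray(frames, dtype=float), axes=(-2, -1))
    flat = spectra.reshape(n_phases, -1)
    bands = (inv @ flat).reshape((n_orders,) + frames.shape[1:])
    return {int(m): bands[i] for i, m in enumerate(ms)}


@dataclass
class PatternEstimate:
    """Estimated illumination parameters for one orientation.

    ``k_fine`` is the fine-harmonic wave vector (kx, ky) in cycles/nm (the
    reciprocal pattern period); ``phase`` the starting phase on the
    fundamental harmonic; ``m1``/``m2`` the modulation depths of orders 1
    and 2 (``m2`` is None in two-beam mode, where order 1 is the fine
    harmonic).  ``amps`` holds the complex order amplitudes relative to
    order 0, including the starting-phase factor.
    """

    k_fine: np.ndarray
    phase: float
    m1: float
    m2: float | None = None
    amps: dict[int, complex] = field(default_factory=dict)

    @property
    def angle_deg(self) -> float:
        return float(np.rad2deg(np.arctan2(self.k_fine[1], self.k_fine[0])) % 180.0)

    @property
    def period(self) -> float:
        return float(1.0 / np.linalg.norm(self.k_fine))


def _band_ratio(
    i0: np.ndarray,
    im: np.ndarray,
    k: np.ndarray,
    spacing: float,
    otf=None,
) -> complex:
    """Least-squares complex amplitude of band m relative to band 0.

    Shifts band m's content back onto band 0 by a real-space phase ramp at
    the (sub-bin) wave vector ``k`` and projects onto band 0.  When an OTF
    interpolant is supplied, both bands are weighted by the *other* band's
    shifted OTF first, which makes the ratio an unbiased estimate of the
    pure illumination coefficient (the transfer-function attenuation
    cancels); without it the ratio measures the modulation present in the
    data, OTF attenuation included.
    """
    ny, nx = i0.shape
    y = np.arange(ny)[:, None] * spacing
    x = np.arange(nx)[None, :] * spacing
    ramp = np.exp(-2j * np.pi * (k[0] * x + k[1] * y))
    if otf is None:
        num = np.vdot(i0, im * ramp)
        den = np.vdot(i0, i0).real
        return complex(num / den)
    b0 = np.fft.fft2(i0)
    bms = np.fft.fft2(im * ramp)
    ky, kx = freq_grids((ny, nx), spacing)
    o0 = otf(np.hypot(ky, kx))
    om = otf(np.hypot(ky + k[1], kx + k[0]))
    num = np.vdot(b0 * om, bms * o0)
    den = np.vdot(b0 * om, b0 * om).real
    return complex(num / max(den, 1e-300))


def estimate_pattern(
    bands: dict[int, np.ndarray] | list[dict[int, np.ndarray]],
    otf=None,
    spacing: float = 64.5,
    k_prior: np.ndarray | None = None,
    beam_mode: str = THREE_BEAM,
    min_peak_snr: float = 2.0,
) -> PatternEstimate:
    """Estimate wave vector, starting phase and modulation depths from bands.

    The order-1 band is cross-correlated against order 0 over their spectral
    overlap; the correlation peak (restricted to within 25 % of the prior
    when one is given) is refined by zoomed local DFT stages to ~0.005
    frequency bins.  Two measures make the peak stand out over the
    object-speckle background: both bands are flattened by regularized OTF
    compensation (so the object's spectral envelope does not bury the
    carrier), and when ``bands`` is a *list* of band sets (e.g. the seven
    focal planes of one multifocus frame group, which share one
    illumination pattern) their correlations are pooled coherently.  The
    starting phase and the complex modulation amplitudes come from
    OTF-weighted least squares on the first band set.  Raises
    :class:`EstimationError` when no peak stands above the correlation
    noise floor.
    """
    band_list = bands if isinstance(bands, list) else [bands]
    ny, nx = band_list[0][0].shape
    ky, kx = freq_grids((ny, nx), spacing)
    kmag = np.hypot(ky, kx)
    if otf is not None:
        o_grid = otf(kmag)
        flat = np.where(o_grid > 0.02, 1.0 / (o_grid + 0.05), 0.0)
    else:
        flat = 1.0
    # Hann window: spectral-leakage tails otherwise bias the peak position
    win = np.outer(np.hanning(ny), np.hanning(nx))
    prod = np.zeros((ny, nx), dtype=complex)
    for bset in band_list:
        prod += np.conj(np.fft.ifft2(bset[0] * flat)) * np.fft.ifft2(bset[1] * flat)
    prod *= win
    spec = np.fft.fft2(prod)

    # order-1 sits at the coarse harmonic (three-beam) or the fine one (two-beam)
    if k_prior is not None:
        k1_prior = np.asarray(k_prior, float) / (2.0 if beam_mode == THREE_BEAM else 1.0)
        pm = np.linalg.norm(k1_prior)
        mask = np.abs(kmag - pm) <= 0.25 * pm
    else:
        mask = kmag > 2.0 / (ny * spacing)  # exclude the DC neighbourhood
    mag = np.abs(spec) * mask
    floor = np.median(np.abs(spec)[mask]) + 1e-300
    if mag.max() / floor < min_peak_snr:
        raise EstimationError(
            f"order-1 correlation peak SNR {mag.max() / floor:.2f} below {min_peak_snr}"
        )
    # integer-bin peaks suffer scalloping (a half-bin offset loses ~60 % of the
    # peak), so refine the strongest candidate bins sub-bin and keep the best
    bin_size = 1.0 / (ny * spacing)
    n_cand = 8
    cand = np.argsort(mag.ravel())[::-1][:n_cand]
    best = None
    for flat_idx in cand:
        iy, ix = np.unravel_index(flat_idx, mag.shape)
        k0 = np.array([kx[0, ix], ky[iy, 0]])
        kc, vc = refine_peak(prod, k0, spacing, bin_size, stages=((0.6, 0.15),))
        if best is None or abs(vc) > abs(best[1]):
            best = (kc, vc)
    k1, val = refine_peak(prod, best[0], spacing, bin_size,
                          stages=((0.15, 0.02), (0.025, 0.002)))
    if k_prior is not None and np.dot(k1, k1_prior) < 0:
        # resolve the +/- ambiguity consistently with the prior direction
        k1 = -k1
        val = np.conj(val)
    bands = band_list[0]
    i0 = np.fft.ifft2(bands[0])
    i1 = np.fft.ifft2(bands[1])

    a1 = _band_ratio(i0, i1, k1, spacing, otf=otf)
    phase = float(np.angle(a1))
    amps = {0: 1.0 + 0.0j, 1: a1, -1: np.conj(a1)}
    if beam_mode == THREE_BEAM:
        i2 = np.fft.ifft2(bands[2])
        a2 = _band_ratio(i0, i2, 2.0 * k1, spacing, otf=otf)
        amps[2] = a2
        amps[-2] = np.conj(a2)
        k_fine = 2.0 * k1
        m1, m2 = 2.0 * abs(a1), 2.0 * abs(a2)
    else:
        k_fine = k1
        m1, m2 = 2.0 * abs(a1), None
    return PatternEstimate(k_fine=np.asarray(k_fine), phase=phase, m1=float(m1),
                           m2=None if m2 is None else float(m2), amps=amps)


def radial_otf(psf: PSFVolume):
    """Radial interpolant of the in-focus 2-D OTF, normalized to OTF(0) = 1.

    Returns ``f(k_magnitude) -> OTF`` usable on arbitrary frequency grids.
    """
    sl = psf.data[psf.data.shape[0] // 2]
    sl = sl / sl.sum()
    otf = np.abs(np.fft.fft2(np.fft.ifftshift(sl)))
    ky, kx = freq_grids(sl.shape, psf.voxel[1])
    kmag = np.hypot(ky, kx).ravel()
    order = np.argsort(kmag)
    k_sorted = kmag[order]
    o_sorted = otf.ravel()[order]
    # collapse to a monotone radial profile by bin-averaging
    nbins = sl.shape[0]
    edges = np.linspace(0, k_sorted[-1], nbins + 1)
    idx = np.clip(np.searchsorted(edges, k_sorted) - 1, 0, nbins - 1)
    prof = np.bincount(idx, weights=o_sorted, minlength=nbins)
    cnt = np.maximum(np.bincount(idx, minlength=nbins), 1)
    prof = prof / cnt
    centers = (edges[:-1] + edges[1:]) / 2
    # anchor the profile at DC (OTF(0) = 1 by normalization)
    centers = np.concatenate(([0.0], centers))
    prof = np.concatenate(([1.0], prof))
    f = interp1d(centers, prof, bounds_error=False, fill_value=0.0)
    return lambda k: np.clip(f(k), 0.0, None)


@dataclass(frozen=True)
class ReconOptions:
    """Reconstruction knobs.

    ``wiener_w`` is the regularizer relative to the peak OTF^2.  The
    sectioning notch attenuates the order-0 band by ``notch_depth`` at DC,
    relaxing as a raised cosine out to ``notch_width_frac`` times the fine
    pattern frequency (the region where the modulated bands overlap order
    0).  Orders whose estimated relative amplitude falls below ``min_mod``
    are dropped for that plane (e.g. the three-beam coarse band near its
    axial zero crossing).
    """

    wiener_w: float = 0.05
    notch_depth: float = 0.95
    notch_width_frac: float = 0.5
    apodization: str = "triangle"
    upsample: int = 2
    min_mod: float = 0.02
    equalize_gain: bool = False
    align: bool = True
    fallback_nominal: bool = True

    def __post_init__(self) -> None:
        if self.wiener_w <= 0:
            raise ReconstructionError("Wiener parameter w must be positive")


@dataclass
class ReconVolume:
    """Reconstructed super-resolution volume.

    ``data`` has axes (z, y, x) on a laterally 2x upsampled grid;
    ``voxel`` is (dz, dy, dx) nm; ``z_offsets`` the plane positions
    relative to the nominal focus; ``estimates`` maps plane index ->
    orientation -> :class:`PatternEstimate`.
    """

    data: np.ndarray
    voxel: tuple[float, float, float]
    z_offsets: np.ndarray
    estimates: dict[int, dict[int, PatternEstimate]] = field(default_factory=dict)
    options: ReconOptions | None = None
    shifts: object = None


def wiener_combine(
    bands_by_orientation: dict[int, dict[int, np.ndarray]],
    estimates: dict[int, PatternEstimate],
    otf,
    cfg: OpticalConfig,
    pat: IlluminationPattern,
    opts: ReconOptions | None = None,
    spacing: float | None = None,
) -> np.ndarray:
    """Generalized Wiener combination of all orientations for one plane.

    Every band m is moved to its true position (a shift of ``m`` times the
    orientation's fundamental wave vector) on an upsampled grid, weighted by
    its shifted OTF and complex modulation amplitude, and merged as
    ``sum conj(c O) B / (sum |c O|^2 + w^2)`` followed by apodization
    reaching zero at the extended cutoff (widefield cutoff + pattern
    frequency).  Returns the real part of the inverse transform.
    """
    opts = opts or ReconOptions()
    if spacing is None:
        spacing = cfg.px_sample
    any_band = next(iter(next(iter(bands_by_orientation.values())).values()))
    n = any_band.shape[0]
    m_out = opts.upsample * n
    out_spacing = spacing / opts.upsample
    ky, kx = freq_grids((m_out, m_out), out_spacing)
    y = np.arange(m_out)[:, None] * out_spacing
    x = np.arange(m_out)[None, :] * out_spacing

    k_wf = cfg.cutoff_em
    k_pat = 1.0 / pat.period
    notch_k = opts.notch_width_frac * k_pat

    num = np.zeros((m_out, m_out), dtype=complex)
    den = np.zeros((m_out, m_out), dtype=float)
    for o, bands in bands_by_orientation.items():
        est = estimates[o]
        k_fund = est.k_fine / (2.0 if pat.beam_mode == THREE_BEAM else 1.0)
        for m, band in bands.items():
            c = est.amps.get(m, 0.0)
            if m != 0 and abs(c) < opts.min_mod:
                continue
            shift = m * k_fund
            big = np.fft.ifft2(pad_spectrum(band, (m_out, m_out)))
            big *= np.exp(-2j * np.pi * (shift[0] * x + shift[1] * y))
            spec = np.fft.fft2(big)
            o_m = otf(np.hypot(ky + shift[1], kx + shift[0]))
            w = np.conj(c) * o_m
            if m == 0 and opts.notch_depth > 0:
                kmag0 = np.hypot(ky, kx)
                g = np.ones_like(kmag0)
                core = kmag0 <= notch_k
                g[core] = 1.0 - opts.notch_depth * 0.5 * (
                    1.0 + np.cos(np.pi * kmag0[core] / notch_k)
                )
                w = w * g
            num += w * spec
            den += np.abs(c * o_m) ** 2
    wparam = opts.wiener_w**2  # OTF is normalized to peak 1
    combined = num / (den + wparam)
    if opts.equalize_gain:
        # flat-field gain: response of the plane to a uniform in-focus object.
        # Dividing it out keeps axial photometry uniform even where the
        # three-beam coarse modulation (and with it the band weighting) beats.
        g_dc = 0.0
        for o, bands in bands_by_orientation.items():
            est = estimates[o]
            for m in bands:
                c = est.amps.get(m, 0.0)
                if m != 0 and abs(c) < opts.min_mod:
                    continue
                k_fund = est.k_fine / (2.0 if pat.beam_mode == THREE_BEAM else 1.0)
                o_dc = float(otf(np.linalg.norm(m * k_fund)))
                w_dc = abs(c) ** 2 * o_dc**2
                if m == 0:
                    w_dc *= 1.0 - opts.notch_depth
                g_dc += w_dc
        g_dc /= den[0, 0] + wparam if den[0, 0] > 0 else 1.0
        if g_dc > 1e-6:
            combined = combined / g_dc

    kmag = np.hypot(ky, kx)
    k_ext = k_wf + k_pat
    if opts.apodization == "triangle":
        apod = np.clip(1.0 - kmag / k_ext, 0.0, None)
    elif opts.apodization == "none":
        apod = (kmag <= k_ext).astype(float)
    else:
        raise ReconstructionError(f"unknown apodization {opts.apodization!r}")
    return np.fft.ifft2(combined * apod).real


def _group_planes(raw: RawAcquisition, tile_map: TileMap, timepoint: int, zstep: int):
    """Extract tiles of every frame and regroup as plane -> orientation -> phase stack."""
    n_orient = raw.frames.shape[2]
    n_phase = raw.frames.shape[3]
    n_planes = raw.multifocus.n_planes
    t = tile_map.tile_px
    grouped = np.empty((n_planes, n_orient, n_phase, t, t), dtype=float)
    offset = raw.camera.offset
    for o in range(n_orient):
        for j in range(n_phase):
            stack = extract_planes(raw.frames[timepoint, zstep, o, j], tile_map)
            grouped[:, o, j] = stack - offset
    return grouped


def reconstruct_volume(
    raw: RawAcquisition,
    tile_map: TileMap,
    opts: ReconOptions | None = None,
    psf: PSFVolume | None = None,
    timepoint: int = 0,
) -> ReconVolume:
    """Reconstruct one timepoint of a raw acquisition plane by plane.

    Pipeline: extract tiles -> regroup per plane into (orientation, phase)
    sets -> separate bands -> estimate pattern parameters (wave vector and
    phase on the in-focus reference plane, where modulation is strongest;
    per-plane complex amplitudes) -> generalized Wiener combination per
    plane -> interleave piezo z-steps into a single stack -> sub-pixel
    alignment.  Laterally the output grid is 2x the raw sampling.
    """
    opts = opts or ReconOptions()
    if raw.ground_truth.get("widefield"):
        raise ReconstructionError("cannot SIM-reconstruct a widefield acquisition")
    pat = raw.pattern
    cfg = raw.optics
    n_orient, n_phase = raw.frames.shape[2], raw.frames.shape[3]
    if n_orient != pat.n_orientations or n_phase != pat.n_phases:
        raise ReconstructionError("incomplete orientation/phase groups in acquisition")
    if psf is None:
        from .mf_simulator import default_psf_for

        psf = default_psf_for(cfg, raw.ground_truth["phantom"], raw.multifocus) \
            if "phantom" in raw.ground_truth else None
    if psf is None:
        raise ReconstructionError("a PSF (or ground-truth phantom) is required")
    otf = radial_otf(psf)
    spacing = cfg.px_sample
    mf = raw.multifocus
    offsets = mf.plane_offsets()
    ref_plane = int(np.argmin(np.abs(offsets)))
    nominal_k = {o: pattern_wavevector(pat, o) for o in range(n_orient)}
    dkz = axial_beat_wavevector(pat, cfg) if pat.beam_mode == THREE_BEAM else 0.0

    planes_out: list[tuple[float, np.ndarray]] = []
    estimates_all: dict[int, dict[int, PatternEstimate]] = {}
    n_zsteps = raw.frames.shape[1]
    for k in range(n_zsteps):
        grouped = _group_planes(raw, tile_map, timepoint, k)
        all_bands = {
            o: [separate_bands(grouped[p, o], pat.n_orders) for p in range(mf.n_planes)]
            for o in range(n_orient)
        }
        # wave vector and phase are anchored on the in-focus reference plane,
        # pooling every plane's band correlation (one shared pattern)
        ref_est: dict[int, PatternEstimate] = {}
        for o in range(n_orient):
            pooled = [all_bands[o][ref_plane]] + [
                all_bands[o][p] for p in range(mf.n_planes) if p != ref_plane
            ]
            try:
                ref_est[o] = estimate_pattern(
                    pooled, otf=otf, spacing=spacing, k_prior=nominal_k[o],
                    beam_mode=pat.beam_mode,
                )
            except EstimationError:
                if not opts.fallback_nominal:
                    raise
                warnings.warn(f"pattern estimation failed for orientation {o}; "
                              "falling back to nominal parameters")
                amps = {m: (1.0 if m == 0 else 0.25) + 0j for m in
                        range(-(pat.n_orders // 2), pat.n_orders // 2 + 1)}
                ref_est[o] = PatternEstimate(
                    k_fine=nominal_k[o], phase=0.0, m1=0.5,
                    m2=0.5 if pat.beam_mode == THREE_BEAM else None, amps=amps,
                )
        for p in range(mf.n_planes):
            per_orient_bands = {}
            ests = {}
            for o in range(n_orient):
                bands = all_bands[o][p]
                per_orient_bands[o] = bands
                if p == ref_plane:
                    ests[o] = ref_est[o]
                else:
                    # the wave vector and starting phase are global (one
                    # illumination pattern for all planes); the complex band
                    # amplitudes are re-estimated per plane, since the
                    # three-beam coarse harmonic beats axially as
                    # cos(dk_z * z_p) and each plane sees its own modulation
                    base = ref_est[o]
                    kf = base.k_fine / (2.0 if pat.beam_mode == THREE_BEAM else 1.0)
                    i0 = np.fft.ifft2(bands[0])
                    amps = {0: 1.0 + 0j}
                    a1 = _band_ratio(i0, np.fft.ifft2(bands[1]), kf, spacing, otf=otf)
                    amps[1], amps[-1] = a1, np.conj(a1)
                    m2 = None
                    if pat.beam_mode == THREE_BEAM:
                        a2 = _band_ratio(i0, np.fft.ifft2(bands[2]), 2 * kf, spacing, otf=otf)
                        amps[2], amps[-2] = a2, np.conj(a2)
                        m2 = 2.0 * abs(a2)
                    ests[o] = replace(base, amps=amps, m1=2.0 * abs(a1), m2=m2)
            plane_img = wiener_combine(
                per_orient_bands, ests, otf, cfg, pat, opts=opts, spacing=spacing
            )
            z = float(offsets[p] + k * raw.timing.zstep_nm)
            planes_out.append((z, plane_img))
            estimates_all.setdefault(len(planes_out) - 1, ests)

    planes_out.sort(key=lambda zp: zp[0])
    data = np.stack([img for _, img in planes_out])
    zs = np.array([z for z, _ in planes_out])
    dz_eff = float(np.min(np.diff(zs))) if len(zs) > 1 else mf.dz

    shift_set = None
    if opts.align and data.shape[0] >= 2:
        data, shift_set = subpixel_align_stack(data, reference=None)
    data = np.clip(data, 0.0, None)
    return ReconVolume(
        data=data,
        voxel=(dz_eff, spacing / opts.upsample, spacing / opts.upsample),
        z_offsets=zs,
        estimates=estimates_all,
        options=opts,
        shifts=shift_set,
    )


def widefield_average(
    raw: RawAcquisition,
    tile_map: TileMap,
    timepoint: int = 0,
) -> ReconVolume:
    """Widefield volume: per plane, the pixelwise mean over all raw frames.

    Averaging over full phase cycles cancels the illumination modulation
    exactly, leaving the uniform-illumination (widefield) image of each
    focal plane.  Piezo z-steps are interleaved into a single stack.
    """
    if raw.frames.shape[2] * raw.frames.shape[3] < 1:
        raise ReconstructionError("no frames to average")
    mf = raw.multifocus
    offsets = mf.plane_offsets()
    planes: list[tuple[float, np.ndarray]] = []
    for k in range(raw.frames.shape[1]):
        grouped = _group_planes(raw, tile_map, timepoint, k)
        mean = grouped.mean(axis=(1, 2))
        for p in range(mf.n_planes):
            planes.append((float(offsets[p] + k * raw.timing.zstep_nm), mean[p]))
    planes.sort(key=lambda zp: zp[0])
    zs = np.array([z for z, _ in planes])
    data = np.stack([img for _, img in planes])
    dz_eff = float(np.min(np.diff(zs))) if len(zs) > 1 else mf.dz
    return ReconVolume(
        data=data,
        voxel=(dz_eff, raw.optics.px_sample, raw.optics.px_sample),
        z_offsets=zs,
    )


def rl_deconvolve(volume: np.ndarray, psf: np.ndarray, iterations: int = 20) -> np.ndarray:
    """Richardson-Lucy deconvolution (multiplicative updates, flux conserving).

    A basic stand-in for commercial deconvolution packages.  ``psf`` must
    be normalized to unit sum and share the volume's grid spacing; negative
    input values are clamped to zero with a warning.
    """
    from scipy.signal import fftconvolve

    if iterations < 1:
        raise DimensionError("need at least one iteration")
    vol = np.asarray(volume, dtype=float)
    if vol.min() < 0:
        warnings.warn("negative input values clamped to zero for RL deconvolution")
        vol = np.clip(vol, 0.0, None)
    kern = np.asarray(psf, dtype=float)
    kern = kern / kern.sum()
    kern_t = kern[::-1, ::-1, ::-1] if kern.ndim == 3 else kern[::-1, ::-1]
    est = np.full_like(vol, vol.mean() if vol.mean() > 0 else 1.0)
    eps = 1e-12
    for _ in range(iterations):
        blurred = fftconvolve(est, kern, mode="same")
        ratio = vol / np.maximum(blurred, eps)
        est = est * fftconvolve(ratio, kern_t, mode="same")
    return est
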