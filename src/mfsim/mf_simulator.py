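"""Forward model: phantom -> raw multifocus SIM camera frames.

A raw frame is a single camera exposure containing all focal-plane images
tiled side by side: the multifocus grating splits the emission into
``n_planes`` copies focused at offsets ``{-3 dz ... +3 dz}`` (7 planes,
dz = 264 nm by default), each receiving ~11 % of the collected light and
landing on its own tile of the (nominally 1600 x 1600 px) sensor crop.
An acquisition sequences such frames over pattern orientations and phases
(15 frames three-beam, 9 two-beam per volume), optionally interleaving
piezo z-steps of half the plane spacing (132 nm) for denser axial sampling.

The timing model reproduces the instrument arithmetic: each frame costs
exposure + readout (8.5 ms rolling-shutter readout, no overlap during SIM
sequences), and each piezo translation adds 170 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable

import numpy as np
from scipy.signal import fftconvolve

from .errors import ConfigError, DimensionError, LayoutError, VoxelMismatchError
from .optics_core import (
    THREE_BEAM,
    IlluminationPattern,
    OpticalConfig,
    PSFVolume,
    generate_psf,
    illumination_field,
)
from .phantoms import DensityPhantom

__all__ = [
    "MultifocusConfig",
    "CameraConfig",
    "AcquisitionTiming",
    "TimingReport",
    "RawAcquisition",
    "render_plane_image",
    "compose_camera_frame",
    "simulate_acquisition",
    "simulate_widefield_zscan",
    "acquisition_time_ms",
    "default_psf_for",
]

_DEFAULT_LAYOUT = {0: (0, 0), 1: (0, 1), 2: (0, 2), 3: (1, 1), 4: (1, 0), 5: (1, 2), 6: (2, 0)}


@dataclass(frozen=True)
class MultifocusConfig:
    """Multifocus grating and tile geometry.

    ``tile_layout`` maps plane index (ascending z) to a (row, col) cell of a
    3x3 grid; the default puts the in-focus plane (z = 0) at the centre cell
    and leaves two corner cells unused.  ``jitter`` holds per-plane true tile
    offsets in px, the ground truth that tile-map calibration must recover.
    """

    n_planes: int = 7
    dz: float = 264.0
    plane_efficiency: tuple[float, ...] | float = 0.11
    tile_px: int = 464
    tile_layout: dict[int, tuple[int, int]] | None = None
    jitter: dict[int, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.n_planes < 1:
            raise ConfigError("need at least one focal plane")
        eff = self.efficiencies
        if len(eff) != self.n_planes or np.sum(eff) > 1.0 + 1e-9:
            raise ConfigError("plane efficiencies must have one entry per plane, summing to <= 1")
        if len(self.layout) != self.n_planes:
            raise ConfigError("tile layout must assign every plane")
        if len(set(self.layout.values())) != self.n_planes:
            raise LayoutError("tile layout assigns two planes to the same cell")

    @property
    def efficiencies(self) -> np.ndarray:
        if np.isscalar(self.plane_efficiency):
            return np.full(self.n_planes, float(self.plane_efficiency))
        return np.asarray(self.plane_efficiency, dtype=float)

    @property
    def layout(self) -> dict[int, tuple[int, int]]:
        if self.tile_layout is not None:
            return self.tile_layout
        if self.n_planes == 7:
            return _DEFAULT_LAYOUT
        return {i: divmod(i, 3) for i in range(self.n_planes)}

    def plane_offsets(self) -> np.ndarray:
        """Focal-plane z offsets (nm), symmetric about 0 and ascending."""
        return (np.arange(self.n_planes) - (self.n_planes - 1) / 2.0) * self.dz

    def jitter_of(self, plane: int) -> tuple[int, int]:
        if self.jitter is None:
            return (0, 0)
        return tuple(int(v) for v in self.jitter.get(plane, (0, 0)))

    def tile_origin(self, plane: int, frame_shape: tuple[int, int]) -> tuple[int, int]:
        """Nominal (row, col) origin of a plane's tile, guard gaps included."""
        r, c = self.layout[plane]
        gap_y = (frame_shape[0] - 3 * self.tile_px) // 4
        gap_x = (frame_shape[1] - 3 * self.tile_px) // 4
        if gap_y < 0 or gap_x < 0:
            raise LayoutError(
                f"3x3 grid of {self.tile_px} px tiles does not fit a {frame_shape} frame"
            )
        return (gap_y + r * (self.tile_px + gap_y), gap_x + c * (self.tile_px + gap_x))


@dataclass(frozen=True)
class CameraConfig:
    """sCMOS detection: sensor crop, read noise (e- RMS), gain (e-/DU), offset (DU)."""

    frame_px: tuple[int, int] = (1600, 1600)
    read_noise: float = 1.6
    gain: float = 1.0
    offset: float = 100.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.read_noise < 0 or self.gain <= 0:
            raise ConfigError("read noise must be >= 0 and gain > 0")

    @property
    def shape(self) -> tuple[int, int]:
        if np.isscalar(self.frame_px):
            return (int(self.frame_px), int(self.frame_px))
        return tuple(int(v) for v in self.frame_px)

    @property
    def max_du(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class AcquisitionTiming:
    """Per-volume acquisition timing parameters (all times in ms)."""

    exposure_ms: float = 20.0
    readout_ms: float = 8.5
    n_frames_per_volume: int = 15
    piezo_step_ms: float = 170.0
    n_zsteps: int = 1
    zstep_nm: float = 132.0

    def __post_init__(self) -> None:
        if min(self.exposure_ms, self.readout_ms, self.piezo_step_ms) < 0:
            raise ConfigError("times must be nonnegative")
        if self.n_zsteps < 1 or self.n_frames_per_volume < 1:
            raise ConfigError("frame and z-step counts must be positive")


@dataclass(frozen=True)
class TimingReport:
    """Exact per-volume time plus the values as the instrument reports them."""

    time_ms: float
    time_ms_rounded: int
    rate_hz: float


def _round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def acquisition_time_ms(t: AcquisitionTiming) -> TimingReport:
    """Per-volume acquisition time and volumetric rate.

    ``time = n_zsteps * n_frames * (exposure + readout) + piezo penalty``;
    with a single z position no piezo translation occurs.  Times are
    reported rounded to the nearest ms and rates to one decimal (half-up).
    """
    frame_time = t.exposure_ms + t.readout_ms
    time = t.n_zsteps * t.n_frames_per_volume * frame_time
    if t.n_zsteps > 1:
        time += t.n_zsteps * t.piezo_step_ms
    if time <= 0:
        raise ConfigError("degenerate timing: zero total acquisition time")
    return TimingReport(
        time_ms=time,
        time_ms_rounded=int(_round_half_up(time)),
        rate_hz=_round_half_up(1000.0 / time, 1),
    )


@dataclass
class RawAcquisition:
    """Raw camera frames indexed (timepoint, z-step, orientation, phase).

    ``frames`` has shape (T, n_zsteps, n_orient, n_phases, H, W); the
    flattened page order used on disk is phase-fastest.  ``ground_truth``
    carries the phantom, tile jitter, true pattern parameters and plane z
    offsets so downstream estimators can be validated against it.
    """

    frames: np.ndarray
    timing: AcquisitionTiming
    optics: OpticalConfig
    pattern: IlluminationPattern
    multifocus: MultifocusConfig
    camera: CameraConfig
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_timepoints(self) -> int:
        return self.frames.shape[0]

    def frame(self, t: int = 0, zstep: int = 0, orientation: int = 0, phase: int = 0):
        return self.frames[t, zstep, orientation, phase]


def render_plane_image(
    phantom: DensityPhantom,
    psf: PSFVolume,
    illum: np.ndarray | Callable[[float], np.ndarray] | float,
    plane_z: float,
    focus_z: float | None = None,
) -> np.ndarray:
    """Expected-photon image of one focal plane.

    For each phantom slice at sample height ``z_s`` the emitted density
    ``phantom * illum(z_s - focus_z)`` is convolved laterally with the PSF
    slice at defocus ``z_s - focus_z - plane_z`` and accumulated.  ``illum``
    may be a constant, a single 2-D map (applied at every z) or a callable
    of the defocus relative to the illumination focus, which is how the
    z-dependent three-beam coarse component enters.  Linear in the phantom.
    """
    if not np.allclose(phantom.voxel, psf.voxel, rtol=1e-6):
        raise VoxelMismatchError(
            f"phantom voxel {phantom.voxel} != psf voxel {psf.voxel}"
        )
    nz = phantom.volume.shape[0]
    dz = phantom.voxel[0]
    if focus_z is None:
        focus_z = (nz - 1) / 2.0 * dz
    out = np.zeros(phantom.volume.shape[1:], dtype=float)
    for s in range(nz):
        sl = phantom.volume[s]
        if not sl.any():
            continue
        z_rel = s * dz - focus_z  # height relative to the illumination focus
        if callable(illum):
            pattern = illum(z_rel)
        else:
            pattern = illum
        kernel = psf.render_kernel(z_rel - plane_z)
        out += fftconvolve(sl * pattern, kernel, mode="same")
    return out


def compose_camera_frame(
    plane_images: list[np.ndarray],
    mf: MultifocusConfig,
    cam: CameraConfig,
    seed: int | np.random.Generator | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Multiplex per-plane expected-photon images onto one camera frame.

    Each plane image is scaled by its transmission efficiency and placed at
    its nominal tile origin plus the true jitter.  With ``noise=True``,
    Poisson shot noise, Gaussian read noise, gain, offset and bit-depth
    clipping are applied and an integer frame is returned; noiseless mode
    returns the exact expected frame in float (photon bookkeeping holds
    exactly).
    """
    if len(plane_images) != mf.n_planes:
        raise DimensionError(f"expected {mf.n_planes} plane images, got {len(plane_images)}")
    shape = cam.shape
    eff = mf.efficiencies
    photons = np.zeros(shape, dtype=float)
    for p, img in enumerate(plane_images):
        if img.shape != (mf.tile_px, mf.tile_px):
            raise DimensionError(
                f"plane image {p} is {img.shape}, expected {(mf.tile_px,) * 2}"
            )
        r0, c0 = mf.tile_origin(p, shape)
        jy, jx = mf.jitter_of(p)
        r0, c0 = r0 + jy, c0 + jx
        if r0 < 0 or c0 < 0 or r0 + mf.tile_px > shape[0] or c0 + mf.tile_px > shape[1]:
            raise LayoutError(f"tile for plane {p} falls outside the camera frame")
        photons[r0 : r0 + mf.tile_px, c0 : c0 + mf.tile_px] += eff[p] * img
    if not noise:
        return photons / cam.gain + cam.offset
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    electrons = rng.poisson(photons).astype(float)
    if cam.read_noise > 0:
        electrons += rng.normal(0.0, cam.read_noise, size=shape)
    du = np.rint(electrons / cam.gain + cam.offset)
    return np.clip(du, 0, cam.max_du).astype(np.uint16)


def default_psf_for(
    cfg: OpticalConfig,
    phantom: DensityPhantom,
    mf: MultifocusConfig,
    extra_z_nm: float = 0.0,
    lateral_px: int = 97,
) -> PSFVolume:
    """PSF grid matching the phantom voxel and covering every defocus the
    acquisition can request (phantom extent + outermost plane + z-stepping)."""
    dz = phantom.voxel[0]
    half_phantom = (phantom.volume.shape[0] - 1) / 2.0 * dz
    max_def = half_phantom + abs(mf.plane_offsets()).max() + abs(extra_z_nm)
    nz = 2 * int(np.ceil(max_def / dz)) + 3
    return generate_psf(cfg, (nz, lateral_px, lateral_px),
                        (dz, phantom.voxel[1], phantom.voxel[2]))


def simulate_acquisition(
    phantom: DensityPhantom,
    pat: IlluminationPattern,
    cfg: OpticalConfig,
    mf: MultifocusConfig,
    cam: CameraConfig,
    timing: AcquisitionTiming | None = None,
    timepoints: int = 1,
    seed: int | None = 0,
    noise: bool = True,
    widefield: bool = False,
    focus_z: float | None = None,
    psf: PSFVolume | None = None,
    exposure_scale: float = 1.0,
) -> RawAcquisition:
    """Simulate a full MF-SIM acquisition.

    For every timepoint and piezo z-step the orientation/phase sequence is
    played out (phase fastest); each frame renders all focal planes with the
    illumination evaluated at each sample height, then composes the camera
    frame.  Piezo step ``k`` raises the objective focus (and with it every
    plane and the illumination) by ``k * zstep_nm`` in sample coordinates.
    With ``widefield=True`` the pattern is replaced by uniform illumination
    of equal mean power and a single frame per (timepoint, z-step) is taken.
    Same seed implies a bit-identical result.
    """
    if timing is None:
        n_frames = 1 if widefield else pat.n_orientations * pat.n_phases
        timing = AcquisitionTiming(n_frames_per_volume=n_frames)
    if not np.isclose(phantom.voxel[1], cfg.px_sample, rtol=1e-3):
        raise VoxelMismatchError(
            f"phantom lateral voxel {phantom.voxel[1]:g} nm != sample pixel "
            f"{cfg.px_sample:g} nm"
        )
    n_orient = 1 if widefield else pat.n_orientations
    n_phase = 1 if widefield else pat.n_phases
    nzs = timing.n_zsteps
    if psf is None:
        psf = default_psf_for(cfg, phantom, mf, extra_z_nm=(nzs - 1) * timing.zstep_nm)
    nz_ph = phantom.volume.shape[0]
    base_focus = (nz_ph - 1) / 2.0 * phantom.voxel[0] if focus_z is None else focus_z
    offsets = mf.plane_offsets()
    rng = np.random.default_rng(seed)

    shape = cam.shape
    dtype = np.uint16 if noise else float
    frames = np.zeros((timepoints, nzs, n_orient, n_phase) + shape, dtype=dtype)
    for t in range(timepoints):
        for k in range(nzs):
            fz = base_focus + k * timing.zstep_nm
            for o in range(n_orient):
                for j in range(n_phase):
                    if widefield:
                        illum = 1.0
                    else:
                        def illum(z_rel, o=o, j=j):
                            return illumination_field(
                                pat, cfg, o, j, z=z_rel,
                                grid=(mf.tile_px, mf.tile_px),
                                spacing=phantom.voxel[1], normalize=True,
                            )
                    planes = [
                        exposure_scale
                        * render_plane_image(phantom, psf, illum, zp, focus_z=fz)
                        for zp in offsets
                    ]
                    frames[t, k, o, j] = compose_camera_frame(
                        planes, mf, cam, seed=rng, noise=noise
                    )

    gt = {
        "phantom": phantom,
        "jitter": {p: mf.jitter_of(p) for p in range(mf.n_planes)},
        "pattern": pat,
        "focus_z": base_focus,
        "plane_z": {
            k: (base_focus + k * timing.zstep_nm + offsets).tolist() for k in range(nzs)
        },
        "widefield": widefield,
    }
    return RawAcquisition(
        frames=frames, timing=timing, optics=cfg, pattern=pat,
        multifocus=mf, camera=cam, ground_truth=gt,
    )


def simulate_widefield_zscan(
    phantom: DensityPhantom,
    cfg: OpticalConfig,
    mf: MultifocusConfig,
    cam: CameraConfig,
    n_steps: int = 9,
    zstep_nm: float = 132.0,
    seed: int | None = 0,
    noise: bool = True,
    exposure_scale: float = 1.0,
) -> RawAcquisition:
    """Multifocus widefield bead z-scan, the input to tile-map calibration.

    The focus is stepped symmetrically through the phantom so every tile
    sees the beads sharply at some scan position.
    """
    timing = AcquisitionTiming(n_frames_per_volume=1, n_zsteps=n_steps, zstep_nm=zstep_nm)
    centre = (phantom.volume.shape[0] - 1) / 2.0 * phantom.voxel[0]
    start = centre - (n_steps - 1) / 2.0 * zstep_nm
    return simulate_acquisition(
        phantom, IlluminationPattern(), cfg, mf, cam, timing=timing,
        seed=seed, noise=noise, widefield=True, focus_z=start,
        exposure_scale=exposure_scale,
    )
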