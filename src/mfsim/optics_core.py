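"""Physical optics building blocks: PSF, OTF and structured-illumination fields.

The point-spread function uses a scalar angular-spectrum model: a uniform
circular pupil of radius NA/lambda_em (in lateral spatial frequency) is
propagated to each defocus plane with the phase factor
``exp(2*pi*i * z * sqrt((n/lambda)^2 - k^2))`` and transformed back to real
space; the intensity PSF is the squared modulus of the amplitude.  No vector
effects or index-mismatch aberrations are modelled.

Structured illumination is the interference of two (+/-1 orders) or three
(0, +/-1 orders) plane waves.  With pattern period ``p`` (the period of the
fine intensity fringe in the sample), the +/-1 beams carry lateral field
frequency ``1/(2p)``, so the intensity contains harmonics at 0 and
``+/-1/p`` (two-beam) or 0, ``+/-1/(2p)`` and ``+/-1/p`` (three-beam).
The three-beam coarse harmonic at ``1/(2p)`` beats axially with period
``2*pi/dk_z`` where ``dk_z = 2*pi*n/lambda_ex * (1 - cos(theta))`` and
``sin(theta) = lambda_ex/(2*n*p)``; this axial modulation is what gives
three-beam SIM its optical-sectioning advantage.

Fourier conventions are centralised in :mod:`mfsim._fft`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._fft import corner_coords, freq_grids
from .errors import ConfigError, DimensionError, SamplingError

__all__ = [
    "TWO_BEAM",
    "THREE_BEAM",
    "OpticalConfig",
    "IlluminationPattern",
    "PSFVolume",
    "generate_psf",
    "psf_to_otf",
    "illumination_field",
    "pattern_wavevector",
    "axial_beat_wavevector",
]

TWO_BEAM = "two_beam"
THREE_BEAM = "three_beam"


@dataclass(frozen=True)
class OpticalConfig:
    """Microscope optics shared by the simulator and the reconstruction.

    Defaults describe a 63x/1.4 oil objective with a 1.6x auxiliary tube
    lens (100.8x total emission magnification), 491 nm excitation, 525 nm
    emission and a 6.5 um camera pixel pitch, giving a sample-space pixel
    of ~64.5 nm.
    """

    na: float = 1.4
    lambda_ex: float = 491.0
    lambda_em: float = 525.0
    n_imm: float = 1.515
    mag_objective: float = 63.0
    mag_tube: float = 1.6
    camera_pitch: float = 6.5  # um

    def __post_init__(self) -> None:
        if not 0 < self.na < self.n_imm:
            raise ConfigError(f"need 0 < NA < n_imm, got NA={self.na}, n={self.n_imm}")
        if not self.lambda_ex < self.lambda_em:
            raise ConfigError("excitation wavelength must be below emission (Stokes shift)")
        if min(self.mag_objective, self.mag_tube, self.camera_pitch) <= 0:
            raise ConfigError("magnifications and pixel pitch must be positive")

    @property
    def px_sample(self) -> float:
        """Sample-space pixel size in nm (derived, never set independently)."""
        return self.camera_pitch * 1000.0 / (self.mag_objective * self.mag_tube)

    @property
    def cutoff_em(self) -> float:
        """Incoherent lateral detection cutoff 2*NA/lambda_em (cycles/nm)."""
        return 2.0 * self.na / self.lambda_em


@dataclass(frozen=True)
class IlluminationPattern:
    """SIM illumination parameters.

    ``a0``/``a1`` are the relative field amplitudes of the 0 and +/-1 order
    beams.  The defaults balance all three beams to equal intensity and use
    the instrument's pattern: 237 nm period at orientations 41/101/161 deg,
    five phase steps.
    """

    period: float = 237.0
    orientations: tuple[float, ...] = (41.0, 101.0, 161.0)
    n_phases: int = 5
    beam_mode: str = THREE_BEAM
    a0: float = 1.0
    a1: float = 1.0

    def __post_init__(self) -> None:
        if self.beam_mode not in (TWO_BEAM, THREE_BEAM):
            raise ConfigError(f"unknown beam mode {self.beam_mode!r}")
        if self.beam_mode == THREE_BEAM and self.n_phases != 5:
            raise ConfigError("three-beam SIM uses exactly 5 phase steps")
        if self.beam_mode == TWO_BEAM:
            if self.n_phases < 3:
                raise ConfigError("two-beam SIM needs at least 3 phase steps")
            if self.a0 != 0.0:
                raise ConfigError("two-beam mode blocks the 0th-order beam (a0 must be 0)")
        if self.period <= 0:
            raise ConfigError("pattern period must be positive")

    @classmethod
    def two_beam(
        cls,
        period: float = 237.0,
        orientations: tuple[float, ...] = (41.0, 101.0, 161.0),
        n_phases: int = 3,
        a1: float = 1.0,
    ) -> "IlluminationPattern":
        return cls(period=period, orientations=orientations, n_phases=n_phases,
                   beam_mode=TWO_BEAM, a0=0.0, a1=a1)

    @property
    def n_orientations(self) -> int:
        return len(self.orientations)

    @property
    def n_orders(self) -> int:
        """Number of lateral intensity harmonics (5 three-beam, 3 two-beam)."""
        return 5 if self.beam_mode == THREE_BEAM else 3

    @property
    def mean_power(self) -> float:
        """Spatial mean of the interference intensity (any phase, any z)."""
        return self.a0**2 + 2.0 * self.a1**2

    def phase(self, phase_idx: int) -> float:
        """Pattern phase step in rad on the fundamental harmonic."""
        return 2.0 * np.pi * phase_idx / self.n_phases


@dataclass
class PSFVolume:
    """3-D intensity point-spread function on a regular grid.

    ``data`` has axes (z, y, x) and sums to 1; ``voxel`` is (dz, dy, dx) nm.
    The focal plane is the central z slice.
    """

    data: np.ndarray
    voxel: tuple[float, float, float]

    @property
    def z_coords(self) -> np.ndarray:
        nz = self.data.shape[0]
        return (np.arange(nz) - nz // 2) * self.voxel[0]

    def render_kernel(self, defocus: float, strict: bool = True) -> np.ndarray:
        """Imaging kernel at a defocus, normalized to unit energy at focus.

        Defocus spreads light laterally but does not absorb it, so every
        slice of an untruncated widefield PSF carries equal energy; dividing
        by the focal-slice sum gives kernels whose in-focus image of a point
        integrates to the emitter brightness, while lateral truncation of
        far-defocus slices still loses the light that falls outside the grid.
        """
        nz = self.data.shape[0]
        return self.slice_at(defocus, strict=strict) / self.data[nz // 2].sum()

    def slice_at(self, defocus: float, strict: bool = True) -> np.ndarray:
        """Nearest PSF xy slice at the given defocus (nm)."""
        nz = self.data.shape[0]
        idx = int(round(defocus / self.voxel[0])) + nz // 2
        if idx < 0 or idx >= nz:
            if strict:
                raise DimensionError(
                    f"defocus {defocus:g} nm outside PSF z-range "
                    f"[{self.z_coords[0]:g}, {self.z_coords[-1]:g}] nm"
                )
            idx = min(max(idx, 0), nz - 1)
        return self.data[idx]


def generate_psf(
    cfg: OpticalConfig,
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
) -> PSFVolume:
    """Scalar angular-spectrum PSF on a (z, y, x) grid.

    Parameters
    ----------
    shape : (nz, ny, nx) grid dimensions, each >= 3; odd sizes keep the
        focus and optical axis at the grid centre.
    voxel : (dz, dy, dx) spacings in nm.  Lateral spacing must satisfy
        lambda_em/(4*NA) (Nyquist for the widefield OTF).
    """
    nz, ny, nx = shape
    dz, dy, dx = voxel
    if min(shape) < 3:
        raise DimensionError(f"PSF grid must be at least 3 in every axis, got {shape}")
    nyq = cfg.lambda_em / (4.0 * cfg.na)
    if max(dy, dx) > nyq + 1e-9:
        raise SamplingError(
            f"lateral voxel {max(dy, dx):g} nm undersamples the OTF "
            f"(need <= lambda_em/(4 NA) = {nyq:.2f} nm)"
        )
    if dy != dx:
        raise SamplingError("lateral voxel must be isotropic (dy == dx)")

    ky, kx = freq_grids((ny, nx), dx)
    k2 = ky**2 + kx**2
    kmax = cfg.na / cfg.lambda_em  # coherent pupil radius, cycles/nm
    pupil = (k2 <= kmax**2).astype(float)
    kz = np.sqrt(np.maximum((cfg.n_imm / cfg.lambda_em) ** 2 - k2, 0.0))

    data = np.empty(shape, dtype=float)
    zs = (np.arange(nz) - nz // 2) * dz
    for i, z in enumerate(zs):
        field = np.fft.ifft2(pupil * np.exp(2j * np.pi * kz * z))
        data[i] = np.abs(np.fft.fftshift(field)) ** 2
    data /= data.sum()
    return PSFVolume(data=data, voxel=(float(dz), float(dy), float(dx)))


def psf_to_otf(psf: PSFVolume) -> np.ndarray:
    """3-D complex OTF of a PSF, DC at the array centre, OTF(0) = 1."""
    total = psf.data.sum()
    data = psf.data
    if not np.isclose(total, 1.0, rtol=1e-6):
        warnings.warn("PSF not normalized; normalizing before OTF computation")
        data = data / total
    otf = np.fft.fftn(np.fft.ifftshift(data))
    return np.fft.fftshift(otf)


def pattern_wavevector(pat: IlluminationPattern, orientation_idx: int) -> np.ndarray:
    """Fine-harmonic wave vector (kx, ky) in cycles/nm for one orientation."""
    th = np.deg2rad(pat.orientations[orientation_idx])
    return (1.0 / pat.period) * np.array([np.cos(th), np.sin(th)])


def axial_beat_wavevector(pat: IlluminationPattern, cfg: OpticalConfig) -> float:
    """Axial beat dk_z (rad/nm) between the 0 and +/-1 order beams."""
    kf = 1.0 / pat.period
    sin_t = cfg.lambda_ex * kf / (2.0 * cfg.n_imm)
    if sin_t >= 1.0:
        raise SamplingError("pattern period too small for propagating +/-1 beams")
    cos_t = np.sqrt(1.0 - sin_t**2)
    return 2.0 * np.pi * cfg.n_imm / cfg.lambda_ex * (1.0 - cos_t)


def illumination_field(
    pat: IlluminationPattern,
    cfg: OpticalConfig,
    orientation_idx: int,
    phase_idx: int,
    z: float = 0.0,
    grid: tuple[int, int] = (256, 256),
    spacing: float | None = None,
    normalize: bool = False,
) -> np.ndarray:
    """Interference intensity of the SIM beams on a 2-D grid at defocus ``z``.

    Coordinates use the corner-origin convention; ``spacing`` defaults to the
    sample-space pixel size.  With ``normalize=True`` the map is divided by
    its analytic spatial mean, so a widefield exposure of equal mean power
    is the constant 1.
    """
    if not 0 <= orientation_idx < pat.n_orientations:
        raise ConfigError(f"orientation index {orientation_idx} out of range")
    if not 0 <= phase_idx < pat.n_phases:
        raise ConfigError(f"phase index {phase_idx} out of range")
    if pat.period < cfg.lambda_ex / (2.0 * cfg.na) - 1e-9:
        raise SamplingError(
            f"pattern period {pat.period:g} nm below the excitation diffraction "
            f"limit {cfg.lambda_ex / (2 * cfg.na):.2f} nm"
        )
    if spacing is None:
        spacing = cfg.px_sample

    y, x = corner_coords(grid, spacing)
    th = np.deg2rad(pat.orientations[orientation_idx])
    kf = 1.0 / pat.period
    u = x * np.cos(th) + y * np.sin(th)
    phi = pat.phase(phase_idx)

    if pat.beam_mode == TWO_BEAM:
        # fundamental = fine fringe at 1/p; fringes are z-independent
        intensity = 2.0 * pat.a1**2 * (1.0 + np.cos(2.0 * np.pi * kf * u + phi))
    else:
        # fundamental = coarse harmonic at 1/(2p)
        psi = 2.0 * np.pi * (kf / 2.0) * u + phi
        dkz = axial_beat_wavevector(pat, cfg)
        intensity = (
            pat.a0**2
            + 2.0 * pat.a1**2
            + 2.0 * pat.a1**2 * np.cos(2.0 * psi)
            + 4.0 * pat.a0 * pat.a1 * np.cos(dkz * z) * np.cos(psi)
        )
    if normalize:
        intensity = intensity / pat.mean_power
    return intensity
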