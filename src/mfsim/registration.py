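"""Tile-map calibration and image registration.

Two registration steps frame the reconstruction:

1. *Tile-map calibration*: a 100 nm bead field is recorded in multifocus
   widefield mode while stepping through focus; per tile, the maximum
   intensity projection along the scan is cross-correlated (normalized,
   integer peak) against the reference tile to recover the true crop
   origin of every focal plane on the camera frame.
2. *Sub-pixel alignment*: after plane-by-plane SIM reconstruction, the
   plane stack is registered to the reference plane by upsampled phase
   correlation (translation-only) and shifted in the Fourier domain.
   Alignment deliberately happens after reconstruction so it cannot
   interfere with the sample-pattern frequency content of the raw data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .errors import CalibrationError, DimensionError
from .mf_simulator import MultifocusConfig, RawAcquisition

__all__ = ["TileMap", "ShiftSet", "calibrate_tile_map", "extract_planes", "subpixel_align_stack"]


@dataclass
class TileMap:
    """Per-plane crop origins on the camera frame (the registration matrix).

    ``origins[p]`` is the calibrated (row, col) crop origin for plane ``p``;
    ``offsets[p]`` is the recovered deviation from the nominal layout.
    Planes are indexed by ascending z offset.
    """

    origins: dict[int, tuple[int, int]]
    tile_px: int
    z_offsets: dict[int, float]
    reference_plane: int
    offsets: dict[int, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        z = [self.z_offsets[p] for p in sorted(self.z_offsets)]
        if any(b <= a for a, b in zip(z, z[1:])):
            raise DimensionError("plane z offsets must be strictly increasing")

    def to_json(self, path) -> None:
        doc = {
            "tile_px": self.tile_px,
            "reference_plane": self.reference_plane,
            "origins": {str(p): list(v) for p, v in self.origins.items()},
            "offsets": {str(p): list(v) for p, v in self.offsets.items()},
            "z_offsets": {str(p): v for p, v in self.z_offsets.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TileMap":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            origins={int(p): tuple(v) for p, v in doc["origins"].items()},
            tile_px=int(doc["tile_px"]),
            z_offsets={int(p): float(v) for p, v in doc["z_offsets"].items()},
            reference_plane=int(doc["reference_plane"]),
            offsets={int(p): tuple(v) for p, v in doc.get("offsets", {}).items()},
        )


@dataclass
class ShiftSet:
    """Per-plane sub-pixel (dy, dx) shifts relative to the reference plane."""

    shifts: dict[int, tuple[float, float]]
    reference_plane: int

    def __post_init__(self) -> None:
        ref = self.shifts.get(self.reference_plane)
        if ref is not None and any(abs(v) > 1e-12 for v in ref):
            raise DimensionError("reference plane shift must be (0, 0)")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "reference_plane": self.reference_plane,
                    "shifts": {str(p): list(v) for p, v in self.shifts.items()},
                },
                fh,
                indent=2,
            )


def _norm_xcorr_peak(ref: np.ndarray, img: np.ndarray, max_shift: int):
    """Integer-peak normalized cross-correlation between equal-size tiles.

    Returns ((dy, dx), peak_coefficient): ``img`` shifted by (dy, dx) best
    matches ``ref``.  The search is restricted to |shift| <= max_shift.
    """
    a = ref - ref.mean()
    b = img - img.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return (0, 0), 0.0
    corr = np.fft.ifft2(np.conj(np.fft.fft2(a)) * np.fft.fft2(b)).real / denom
    # corr[s] = sum_x a(x) b(x + s): when b's content is a displaced by +t
    # (b(x) = a(x - t)) the peak sits at s = +t
    wy = np.r_[np.arange(0, max_shift + 1), np.arange(-max_shift, 0)]
    window = corr[np.ix_(wy % ref.shape[0], wy % ref.shape[1])]
    iy, ix = np.unravel_index(np.argmax(window), window.shape)
    return (int(wy[iy]), int(wy[ix])), float(window[iy, ix])


def calibrate_tile_map(
    bead_stack: RawAcquisition,
    mf: MultifocusConfig | None = None,
    max_shift: int = 16,
    min_peak: float = 0.2,
) -> TileMap:
    """Recover per-plane tile origins from a multifocus widefield bead z-scan.

    Per plane the nominal tile is cropped from the z-scan maximum intensity
    projection and cross-correlated against the reference (in-focus) tile;
    the integer correlation peak gives the tile's offset from the nominal
    layout.  Calibration is invariant to global intensity scaling.  A peak
    coefficient below ``min_peak`` raises :class:`CalibrationError` naming
    the plane.
    """
    if mf is None:
        mf = bead_stack.multifocus
    frames = bead_stack.frames.reshape((-1,) + bead_stack.frames.shape[-2:])
    mip = frames.max(axis=0).astype(float)
    mip -= np.median(mip)  # remove the camera offset pedestal
    shape = mip.shape
    offsets = mf.plane_offsets()
    ref_plane = int(np.argmin(np.abs(offsets)))

    tiles = {}
    for p in range(mf.n_planes):
        r0, c0 = mf.tile_origin(p, shape)
        tiles[p] = mip[r0 : r0 + mf.tile_px, c0 : c0 + mf.tile_px]

    found: dict[int, tuple[int, int]] = {}
    for p in range(mf.n_planes):
        if p == ref_plane:
            found[p] = (0, 0)
            continue
        shift, peak = _norm_xcorr_peak(tiles[ref_plane], tiles[p], max_shift)
        if peak < min_peak:
            raise CalibrationError(
                f"correlation peak {peak:.3f} below {min_peak} for plane {p}"
            )
        # tile content shifted by +s relative to reference => true origin moved by +s
        found[p] = (shift[0], shift[1])

    origins = {}
    for p in range(mf.n_planes):
        r0, c0 = mf.tile_origin(p, shape)
        origins[p] = (r0 + found[p][0], c0 + found[p][1])
    return TileMap(
        origins=origins,
        tile_px=mf.tile_px,
        z_offsets={p: float(offsets[p]) for p in range(mf.n_planes)},
        reference_plane=ref_plane,
        offsets=found,
    )


def extract_planes(frame: np.ndarray, tile_map: TileMap) -> np.ndarray:
    """Crop all focal-plane tiles from one camera frame into a (z, y, x) stack.

    Pure crop at the calibrated origins, ordered by ascending z offset; no
    interpolation.
    """
    order = sorted(tile_map.z_offsets, key=tile_map.z_offsets.get)
    t = tile_map.tile_px
    stack = np.empty((len(order), t, t), dtype=float)
    for i, p in enumerate(order):
        r0, c0 = tile_map.origins[p]
        if r0 < 0 or c0 < 0 or r0 + t > frame.shape[0] or c0 + t > frame.shape[1]:
            raise DimensionError(f"crop for plane {p} at {(r0, c0)} outside the frame")
        stack[i] = frame[r0 : r0 + t, c0 : c0 + t]
    return stack


def subpixel_align_stack(
    stack: np.ndarray,
    reference: int | None = None,
    upsample_factor: int = 100,
) -> tuple[np.ndarray, ShiftSet]:
    """Translation-only sub-pixel registration of a plane stack.

    Each plane is registered to the reference plane by phase correlation
    with Fourier-domain upsampling and shifted with a Fourier phase ramp.
    Featureless (zero-variance) planes get shift (0, 0) with a warning.
    """
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise DimensionError("need a stack of at least two planes")
    if reference is None:
        reference = stack.shape[0] // 2
    ref = stack[reference]
    aligned = np.empty_like(stack, dtype=float)
    shifts: dict[int, tuple[float, float]] = {}
    for p in range(stack.shape[0]):
        if p == reference:
            aligned[p] = stack[p]
            shifts[p] = (0.0, 0.0)
            continue
        if np.ptp(stack[p]) == 0:
            warnings.warn(f"plane {p} is featureless; shift set to (0, 0)")
            aligned[p] = stack[p]
            shifts[p] = (0.0, 0.0)
            continue
        shift, _, _ = phase_cross_correlation(
            ref, stack[p], upsample_factor=upsample_factor, normalization=None
        )
        aligned[p] = np.fft.ifft2(
            ndimage.fourier_shift(np.fft.fft2(stack[p]), shift)
        ).real
        shifts[p] = (float(shift[0]), float(shift[1]))
    return aligned, ShiftSet(shifts=shifts, reference_plane=reference)
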