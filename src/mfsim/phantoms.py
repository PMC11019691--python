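"""Synthetic ground-truth samples.

Emulates the specimen classes used to characterise the instrument: fields of
100 nm fluorescent beads on a coverslip, microtubule-like filament networks,
and endoplasmic-reticulum-like networks of interconnected tubules and
perforated sheets.

Coordinate convention: sample space, nm, origin at the volume corner,
z increasing away from the coverslip.  Density grids have axes (z, y, x).
All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DimensionError, PackingError

__all__ = [
    "EmitterSet",
    "DensityPhantom",
    "make_bead_field",
    "make_filament_network",
    "make_er_network",
    "make_sheet_phantom",
    "rasterize_emitters",
    "uniform_phantom",
]


@dataclass
class EmitterSet:
    """Point-like fluorescent emitters (e.g. 100 nm beads).

    ``positions`` is an (n, 3) array of (x, y, z) nm; ``brightness`` is the
    expected photon yield per emitter per unit exposure at unit illumination.
    """

    positions: np.ndarray
    brightness: float = 1.0
    diameter: float = 100.0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.brightness <= 0:
            raise DimensionError("emitter brightness must be positive")


@dataclass
class DensityPhantom:
    """Fluorophore density on a regular grid; axes (z, y, x), voxel (dz, dy, dx) nm."""

    volume: np.ndarray
    voxel: tuple[float, float, float]
    label: str = "beads"

    def __post_init__(self) -> None:
        v = np.asarray(self.volume, dtype=float)
        if not np.all(np.isfinite(v)) or v.min() < 0:
            raise DimensionError("phantom density must be finite and nonnegative")
        self.volume = v

    @property
    def z_coords(self) -> np.ndarray:
        return np.arange(self.volume.shape[0]) * self.voxel[0]


def _check_bounds(bounds) -> np.ndarray:
    b = np.asarray(bounds, dtype=float)
    if b.shape != (3,) or np.any(b <= 0):
        raise DimensionError(f"bounds must be three positive extents (x, y, z) nm, got {bounds}")
    return b


def make_bead_field(
    n: int,
    bounds,
    min_sep: float = 0.0,
    seed: int | None = None,
    brightness: float = 1.0,
    max_tries: int = 10_000,
) -> EmitterSet:
    """Uniform random bead positions with a hard minimum pairwise separation.

    ``bounds`` are the (x, y, z) extents in nm.  Dart throwing with bounded
    retries; raises :class:`PackingError` if the requested density is
    infeasible.
    """
    if n < 1:
        raise DimensionError("need at least one bead")
    b = _check_bounds(bounds)
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        if tries > max_tries * n:
            raise PackingError(
                f"could not place {n} beads with min_sep={min_sep} nm in {tuple(b)}"
            )
        tries += 1
        p = rng.uniform(0.0, b)
        if min_sep > 0 and pts:
            d2 = np.sum((np.asarray(pts) - p) ** 2, axis=1)
            if d2.min() < min_sep**2:
                continue
        pts.append(p)
    return EmitterSet(positions=np.asarray(pts), brightness=brightness)


def rasterize_emitters(
    emitters: EmitterSet,
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
    label: str = "beads",
) -> DensityPhantom:
    """Trilinear splat of emitters onto a density grid.

    Each emitter deposits its full brightness onto the eight surrounding
    voxels, so total brightness is conserved exactly.  Beads are treated as
    sub-voxel points; the physical diameter is kept as metadata only.
    """
    nz, ny, nx = shape
    dz, dy, dx = voxel
    vol = np.zeros(shape, dtype=float)
    for x, y, z in emitters.positions:
        fz, fy, fx = z / dz, y / dy, x / dx
        iz, iy, ix = int(np.floor(fz)), int(np.floor(fy)), int(np.floor(fx))
        wz, wy, wx = fz - iz, fy - iy, fx - ix
        for oz, az in ((0, 1 - wz), (1, wz)):
            for oy, ay in ((0, 1 - wy), (1, wy)):
                for ox, ax in ((0, 1 - wx), (1, wx)):
                    zz, yy, xx = iz + oz, iy + oy, ix + ox
                    if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                        vol[zz, yy, xx] += emitters.brightness * az * ay * ax
    return DensityPhantom(volume=vol, voxel=voxel, label=label)


def _splat_segment(vol, p0, p1, voxel, linear_density, step=25.0):
    """Deposit density along a line segment by dense trilinear point splats."""
    length = float(np.linalg.norm(p1 - p0))
    n = max(int(np.ceil(length / step)), 1)
    ds = length / n
    ts = (np.arange(n) + 0.5) / n
    nz, ny, nx = vol.shape
    dz, dy, dx = voxel
    for t in ts:
        x, y, z = p0 + t * (p1 - p0)
        fz, fy, fx = z / dz, y / dy, x / dx
        iz, iy, ix = int(np.floor(fz)), int(np.floor(fy)), int(np.floor(fx))
        wz, wy, wx = fz - iz, fy - iy, fx - ix
        amt = linear_density * ds
        for oz, az in ((0, 1 - wz), (1, wz)):
            for oy, ay in ((0, 1 - wy), (1, wy)):
                for ox, ax in ((0, 1 - wx), (1, wx)):
                    zz, yy, xx = iz + oz, iy + oy, ix + ox
                    if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                        vol[zz, yy, xx] += amt * az * ay * ax


def make_filament_network(
    n_filaments: int,
    bounds,
    persistence_len: float = 5000.0,
    seed: int | None = None,
    shape: tuple[int, int, int] | None = None,
    voxel: tuple[float, float, float] = (132.0, 64.5, 64.5),
    linear_density: float = 1.0,
    tube_sigma: float = 60.0,
    step: float = 50.0,
    return_paths: bool = False,
):
    """Worm-like-chain style random filaments rasterized as Gaussian tubes.

    When ``n_filaments >= 2`` the first two filaments are a deterministic
    crossing pair passing within 200 nm of each other laterally near the
    volume centre, so sub-diffraction crossings are always present.
    Total integrated density is n_filaments * arc length * linear density
    (conserved by construction; Gaussian smoothing is renormalised).
    """
    if persistence_len <= 0:
        raise DimensionError("persistence length must be positive")
    b = _check_bounds(bounds)
    if shape is None:
        shape = tuple(int(round(b[2 - i] / voxel[i])) for i in range(3))  # (nz, ny, nx)
    vol = np.zeros(shape, dtype=float)
    if n_filaments == 0:
        ph = DensityPhantom(volume=vol, voxel=voxel, label="filaments")
        return (ph, []) if return_paths else ph
    rng = np.random.default_rng(seed)
    margin = 4.0 * tube_sigma
    lo = np.array([margin, margin, min(margin, 0.25 * b[2])])
    hi = b - lo
    arc_target = 1.2 * float(np.hypot(b[0], b[1]))

    def walk(start, direction):
        pts = [np.asarray(start, dtype=float)]
        d = np.asarray(direction, dtype=float)
        d /= np.linalg.norm(d)
        sigma = np.sqrt(step / persistence_len)
        total = 0.0
        while total < arc_target:
            perp = rng.normal(scale=sigma, size=3)
            perp[2] *= 0.3  # filaments stay mostly in-plane, like cells on a coverslip
            d = d + perp
            d /= np.linalg.norm(d)
            p = pts[-1] + d * step
            for ax in range(3):
                if p[ax] < lo[ax] or p[ax] > hi[ax]:
                    d[ax] = -d[ax]
                    p[ax] = np.clip(p[ax], lo[ax], hi[ax])
            pts.append(p)
            total += step
        return np.asarray(pts)

    paths = []
    centre = b / 2.0
    if n_filaments >= 2:
        # crossing pair: straight filaments through the centre, 150 nm apart laterally
        for sign, ang in ((1.0, 0.35), (-1.0, -0.35)):
            d = np.array([np.cos(ang), np.sin(ang), 0.0])
            off = np.array([0.0, sign * 75.0, 0.0])
            half = 0.45 * min(b[0], b[1])
            p0 = np.clip(centre + off - d * half, lo, hi)
            p1 = np.clip(centre + off + d * half, lo, hi)
            n_pts = max(int(np.linalg.norm(p1 - p0) / step), 2)
            ts = np.linspace(0, 1, n_pts + 1)[:, None]
            paths.append(p0[None, :] + ts * (p1 - p0)[None, :])
    while len(paths) < n_filaments:
        start = rng.uniform(lo, hi)
        ang = rng.uniform(0, 2 * np.pi)
        paths.append(walk(start, [np.cos(ang), np.sin(ang), 0.05 * rng.standard_normal()]))

    for path in paths:
        for p0, p1 in zip(path[:-1], path[1:]):
            _splat_segment(vol, p0, p1, voxel, linear_density, step=min(step / 2, 25.0))

    total = vol.sum()
    sig = (0.3 * tube_sigma / voxel[0], tube_sigma / voxel[1], tube_sigma / voxel[2])
    vol = ndimage.gaussian_filter(vol, sigma=sig, mode="constant")
    if vol.sum() > 0:
        vol *= total / vol.sum()  # tube profile must not change integrated density
    ph = DensityPhantom(volume=vol, voxel=voxel, label="filaments")
    return (ph, paths) if return_paths else ph


def make_er_network(
    bounds,
    tubule_radius: float = 60.0,
    sheet_fraction: float = 0.3,
    seed: int | None = None,
    shape: tuple[int, int, int] | None = None,
    voxel: tuple[float, float, float] = (132.0, 64.5, 64.5),
    n_nodes: int = 40,
) -> DensityPhantom:
    """ER-like phantom: perforated sheet patches joined by a tubule tree.

    The tubule graph is grown as a random spanning tree (each new node
    connects to its nearest already-placed node), so the rendered network is
    a single connected component by construction.  ``sheet_fraction``
    controls the share of nodes that carry a sheet patch.
    """
    if not 0.0 <= sheet_fraction <= 1.0:
        raise DimensionError("sheet_fraction must be in [0, 1]")
    b = _check_bounds(bounds)
    if shape is None:
        shape = tuple(int(round(b[2 - i] / voxel[i])) for i in range(3))
    rng = np.random.default_rng(seed)
    vol = np.zeros(shape, dtype=float)
    margin = 4.0 * tubule_radius
    lo = np.array([margin, margin, min(margin, 0.2 * b[2])])
    hi = b - lo

    nodes = [rng.uniform(lo, hi)]
    for _ in range(n_nodes - 1):
        p = rng.uniform(lo, hi)
        q = nodes[int(np.argmin([np.linalg.norm(p - m) for m in nodes]))]
        _splat_segment(vol, q, p, voxel, linear_density=1.0)
        nodes.append(p)

    n_sheets = int(round(sheet_fraction * len(nodes)))
    dz, dy, dx = voxel
    for node in nodes[:n_sheets]:
        radius = rng.uniform(800.0, 1600.0)
        iz = int(np.clip(round(node[2] / dz), 0, shape[0] - 1))
        yy, xx = np.mgrid[0 : shape[1], 0 : shape[2]]
        r2 = ((yy * dy - node[1]) ** 2 + (xx * dx - node[0]) ** 2)
        disc = r2 <= radius**2
        # punch holes: ER sheets are fenestrated
        for _ in range(6):
            hc = node[:2] + rng.uniform(-radius, radius, size=2)
            hr = rng.uniform(150.0, 400.0)
            hole = ((yy * dy - hc[1]) ** 2 + (xx * dx - hc[0]) ** 2) <= hr**2
            disc &= ~hole
        vol[iz][disc] += 0.35

    sig = (0.4 * tubule_radius / dz, tubule_radius / dy, tubule_radius / dx)
    vol = ndimage.gaussian_filter(vol, sigma=sig, mode="constant")
    # membrane fluorescence is roughly uniform per unit area: saturate the
    # rendered intensity so tubules and sheets reach comparable levels
    if vol.any():
        level = np.percentile(vol[vol > 0.1 * vol.max()], 50)
        vol = level * np.tanh(vol / level)
    return DensityPhantom(volume=vol, voxel=voxel, label="er_network")


def make_sheet_phantom(
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
    z_planes_nm: tuple[float, ...],
    hole_pitch: float = 1200.0,
    hole_radius: float = 350.0,
    seed: int | None = None,
) -> DensityPhantom:
    """Flat fluorescent sheets with punched holes at the given z positions.

    Used for axial-contrast comparisons: the holes give each sheet lateral
    structure so out-of-focus leakage is measurable.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    dz, dy, dx = voxel
    vol = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for z_nm in z_planes_nm:
        iz = int(round(z_nm / dz))
        if not 0 <= iz < nz:
            raise DimensionError(f"sheet z={z_nm} nm outside the volume")
        sheet = np.ones((ny, nx), dtype=float)
        for cy in np.arange(hole_pitch / 2, ny * dy, hole_pitch):
            for cx in np.arange(hole_pitch / 2, nx * dx, hole_pitch):
                jitter = rng.uniform(-hole_pitch / 4, hole_pitch / 4, size=2)
                r2 = (yy * dy - cy - jitter[0]) ** 2 + (xx * dx - cx - jitter[1]) ** 2
                sheet[r2 <= hole_radius**2] = 0.0
        vol[iz] += sheet
    return DensityPhantom(volume=vol, voxel=voxel, label="sheets")


def uniform_phantom(
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
    value: float = 1.0,
) -> DensityPhantom:
    """Spatially constant density (flat-field test object)."""
    return DensityPhantom(volume=np.full(shape, float(value)), voxel=voxel, label="sheets")
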