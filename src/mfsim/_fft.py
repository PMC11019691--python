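"""Shared Fourier conventions.

All spectra in this package use the plain numpy FFT layout (DC at index
``[0, 0]``), with spatial frequencies in cycles/nm obtained from
:func:`numpy.fft.fftfreq` with the sample-space pixel size as spacing.
Real-space coordinates are measured from the array corner (index ``[0, 0]``),
in nm, matching the phantom coordinate convention.  Arrays are only
``fftshift``-ed transiently for presentation or zero-padding, never for
storage.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "freq_grids",
    "pad_spectrum",
    "corner_coords",
    "local_dft",
    "refine_peak",
]


def freq_grids(shape: tuple[int, int], spacing: float):
    """Return (ky, kx) broadcastable frequency grids in cycles/nm."""
    ky = np.fft.fftfreq(shape[0], d=spacing)[:, None]
    kx = np.fft.fftfreq(shape[1], d=spacing)[None, :]
    return ky, kx


def corner_coords(shape: tuple[int, int], spacing: float):
    """Return (y, x) coordinate grids in nm with origin at the array corner."""
    y = np.arange(shape[0])[:, None] * spacing
    x = np.arange(shape[1])[None, :] * spacing
    return y, x


def pad_spectrum(spec: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Zero-pad an FFT-layout spectrum to a larger grid (band-limited upsampling).

    The padded spectrum keeps the same frequency content; the corresponding
    real-space image is the input sampled on a finer grid.
    """
    ny, nx = spec.shape
    my, mx = out_shape
    if my < ny or mx < nx:
        raise ValueError("pad_spectrum target must not be smaller than input")
    s = np.fft.fftshift(spec)
    out = np.zeros(out_shape, dtype=complex)
    oy, ox = (my - ny) // 2, (mx - nx) // 2
    out[oy : oy + ny, ox : ox + nx] = s
    # preserve per-pixel amplitudes in real space
    return np.fft.ifftshift(out) * (my * mx) / (ny * nx)


def local_dft(img: np.ndarray, ky: np.ndarray, kx: np.ndarray, spacing: float) -> np.ndarray:
    """Evaluate ``C(k) = sum_x img(x) * exp(-2*pi*i k.x)`` on a small k-grid.

    ``ky``/``kx`` are 1-D arrays of frequencies (cycles/nm); coordinates use
    the corner-origin convention.  Returns an array of shape (len(ky), len(kx)).
    """
    y = np.arange(img.shape[0]) * spacing
    x = np.arange(img.shape[1]) * spacing
    ey = np.exp(-2j * np.pi * np.outer(ky, y))
    ex = np.exp(-2j * np.pi * np.outer(x, kx))
    return ey @ img @ ex


def refine_peak(
    img: np.ndarray,
    k0: np.ndarray,
    spacing: float,
    bin_size: float,
    stages: tuple[tuple[float, float], ...] = ((1.2, 0.1), (0.12, 0.005)),
) -> tuple[np.ndarray, complex]:
    """Refine a correlation peak of ``C(k)`` around ``k0`` by zoomed local DFTs.

    ``stages`` lists (half-width, step) pairs in units of frequency bins.
    Returns the refined wave vector (cycles/nm) and the complex peak value.
    """
    k = np.asarray(k0, dtype=float)
    val = None
    for half, step in stages:
        off = np.arange(-half, half + step / 2, step) * bin_size
        ky = k[1] + off
        kx = k[0] + off
        c = local_dft(img, ky, kx, spacing)
        iy, ix = np.unravel_index(np.argmax(np.abs(c)), c.shape)
        k = np.array([kx[ix], ky[iy]])
        val = c[iy, ix]
    return k, val
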