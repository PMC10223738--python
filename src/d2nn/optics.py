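"""Scalar free-space wave propagation.

Two routes between parallel planes are provided:

* :func:`propagate_asm` — band-limited angular spectrum method (ASM).  The
  field's 2-D spectrum is multiplied by ``exp(j 2π γ Δz)`` with
  ``γ = sqrt(1/λ² − u² − v²)``; spatial frequencies beyond the propagating
  band (``u² + v² > 1/λ²``) are zeroed rather than allowed to blow up
  exponentially.  This is the fast route used everywhere in the network.

* :func:`propagate_rs_direct` — literal superposition of Rayleigh–Sommerfeld
  secondary waves (first Rayleigh–Sommerfeld solution), an O(n⁴) brute force
  intended as an independent oracle on small grids.

Conventions (fixed so that tests are portable):

* forward Fourier kernel ``exp(−j2π(ux+vy))`` (numpy's default ``fft2``);
  round-trip ``ifft2(fft2(x))`` is identity;
* time convention ``exp(+jkr)`` for outgoing waves, hence ``+j`` in the
  transfer-function exponent;
* arrays are indexed (row, col) = (y, x) with the physical origin at the
  array centre; frequency samples lie at multiples of ``1/(pad_factor·n·pitch)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "ComplexField",
    "TransferFunction",
    "RSKernel",
    "transfer_function",
    "propagate_asm",
    "rs_kernel",
    "propagate_rs_direct",
    "matched_pitch",
    "bandlimited_random_field",
]

#: He-Ne laser line, the default source wavelength (metres).
HENE_WAVELENGTH = 632.8e-9

#: Default sample pitch (metres): a 0.8 mm aperture sampled at 200 px,
#: equivalently 1.6 mm at 400 px.
DEFAULT_PITCH = 4e-6


@dataclass(frozen=True)
class GridSpec:
    """Uniform square sampling grid for a scalar optical field.

    Parameters
    ----------
    n : int
        Samples per side.
    pitch : float
        Physical sample spacing in metres.
    wavelength : float
        Vacuum wavelength λ in metres.
    """

    n: int
    pitch: float = DEFAULT_PITCH
    wavelength: float = HENE_WAVELENGTH

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n <= 0:
            raise ValueError(f"grid size must be a positive integer, got {self.n}")
        if not (self.pitch > 0):
            raise ValueError(f"pitch must be positive, got {self.pitch}")
        if not (self.wavelength > 0):
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")

    @property
    def side(self) -> float:
        """Physical side length n·pitch (m)."""
        return self.n * self.pitch

    @property
    def k(self) -> float:
        """Wave number k = 2π/λ (rad/m); derived, never stored."""
        return 2.0 * np.pi / self.wavelength

    def coords(self) -> np.ndarray:
        """Centred physical sample coordinates along one axis (m)."""
        return (np.arange(self.n) - self.n // 2) * self.pitch


@dataclass
class ComplexField:
    """Complex scalar field sampled on a :class:`GridSpec`."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != (self.grid.n, self.grid.n):
            raise ValueError(
                f"field shape {self.values.shape} does not match grid n={self.grid.n}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite samples")

    @property
    def power(self) -> float:
        """Total power Σ|u|²·pitch² (W, up to a constant impedance factor)."""
        return float(np.sum(np.abs(self.values) ** 2) * self.grid.pitch**2)


@dataclass
class TransferFunction:
    """Angular-spectrum transfer function on the (padded) frequency grid."""

    values: np.ndarray
    dz: float
    grid: GridSpec
    pad_factor: int = 1


@dataclass
class RSKernel:
    """Rayleigh–Sommerfeld impulse response sampled on lateral offsets.

    ``values[i, j]`` is the response at lateral offset
    ``((i−(n−1))·pitch, (j−(n−1))·pitch)``; the zero offset sits at the
    centre of the (2n−1)×(2n−1) array.
    """

    values: np.ndarray
    dz: float
    grid: GridSpec


def _freq_grid(grid: GridSpec, pad_factor: int) -> tuple[np.ndarray, np.ndarray]:
    m = pad_factor * grid.n
    f = np.fft.fftfreq(m, d=grid.pitch)
    return np.meshgrid(f, f, indexing="ij")


def transfer_function(grid: GridSpec, dz: float, pad_factor: int = 1) -> TransferFunction:
    """Band-limited ASM transfer function H(u,v) = exp(j·2π·γ·dz).

    γ = sqrt(1/λ² − u² − v²) on the propagating band; evanescent components
    (negative radicand) are hard-zeroed.  ``dz`` may be negative, which gives
    the conjugate (back-propagating) transfer function.
    """
    if pad_factor < 1 or int(pad_factor) != pad_factor:
        raise ValueError(f"pad_factor must be an integer >= 1, got {pad_factor}")
    fv, fu = _freq_grid(grid, pad_factor)
    radicand = 1.0 / grid.wavelength**2 - fu**2 - fv**2
    band = radicand >= 0.0
    gamma = np.sqrt(np.where(band, radicand, 0.0))
    values = np.where(band, np.exp(2j * np.pi * gamma * dz), 0.0 + 0.0j)
    return TransferFunction(values=values, dz=dz, grid=grid, pad_factor=pad_factor)


def _pad_slices(n: int, pad_factor: int) -> slice:
    m = pad_factor * n
    lo = (m - n) // 2
    return slice(lo, lo + n)


def _propagate_values(values: np.ndarray, H: np.ndarray, n: int, pad_factor: int) -> np.ndarray:
    """Propagate an (..., n, n) stack through transfer function ``H``.

    Zero-pads each field to pad_factor·n per side (centred), transforms,
    multiplies by H, inverse-transforms and crops back.  Linear in the input;
    shared by the public API and the batched network forward/backward passes.
    """
    if pad_factor == 1:
        spec = np.fft.fft2(values)
        return np.fft.ifft2(spec * H)
    m = pad_factor * n
    s = _pad_slices(n, pad_factor)
    padded = np.zeros(values.shape[:-2] + (m, m), dtype=np.complex128)
    padded[..., s, s] = values
    out = np.fft.ifft2(np.fft.fft2(padded) * H)
    return np.ascontiguousarray(out[..., s, s])


def propagate_asm(
    field: ComplexField,
    dz: float,
    pad_factor: int = 2,
    H: TransferFunction | None = None,
) -> ComplexField:
    """Propagate a field over axial distance ``dz`` with band-limited ASM.

    Parameters
    ----------
    field : ComplexField
        Input field.
    dz : float
        Axial distance in metres (negative back-propagates).
    pad_factor : int
        Zero-padding factor; 2 suppresses circular-wraparound artifacts,
        1 gives the exactly unitary cyclic transform.
    H : TransferFunction, optional
        Precomputed transfer function (must match grid, dz and pad_factor).
    """
    if H is None:
        H = transfer_function(field.grid, dz, pad_factor)
    else:
        if H.grid != field.grid or H.pad_factor != pad_factor or H.dz != dz:
            raise ValueError("precomputed transfer function does not match the request")
    out = _propagate_values(field.values, H.values, field.grid.n, pad_factor)
    return ComplexField(values=out, grid=field.grid)


def rs_kernel(grid: GridSpec, dz: float) -> RSKernel:
    """Rayleigh–Sommerfeld impulse response between planes ``dz`` apart.

    w(Δx, Δy) = (1/2π)·(dz/r)·(1/r − jk)·exp(jkr)/r,
    r = sqrt(Δx² + Δy² + dz²), evaluated on every lateral offset reachable
    between two n×n grids (a (2n−1)×(2n−1) array).
    """
    if not (dz > 0):
        raise ValueError(f"rs_kernel requires dz > 0 (singular at dz = 0), got {dz}")
    offs = (np.arange(2 * grid.n - 1) - (grid.n - 1)) * grid.pitch
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    r = np.sqrt(dx**2 + dy**2 + dz**2)
    k = grid.k
    w = (1.0 / (2.0 * np.pi)) * (dz / r) * (1.0 / r - 1j * k) * np.exp(1j * k * r) / r
    return RSKernel(values=w, dz=dz, grid=grid)


def propagate_rs_direct(field: ComplexField, dz: float) -> ComplexField:
    """Brute-force Rayleigh–Sommerfeld superposition (oracle route).

    output(x) = Σ_k input(k) · w(x − k) · pitch², the exact discrete
    secondary-wave sum.  O(n⁴): intended for n ≤ 64 cross-checks of
    :func:`propagate_asm`, not for production propagation.
    """
    n = field.grid.n
    K = rs_kernel(field.grid, dz).values
    src = field.values
    out = np.empty((n, n), dtype=np.complex128)
    # out[i, j] = sum_k src[k] * K[i - k + (n-1)]; the flipped kernel window
    # K[i:i+n, j:j+n][::-1, ::-1] realises the offset indexing exactly.
    for i in range(n):
        win_i = K[i : i + n][::-1]
        for j in range(n):
            out[i, j] = np.sum(src * win_i[:, j : j + n][:, ::-1])
    out *= field.grid.pitch**2
    return ComplexField(values=out, grid=field.grid)


def matched_pitch(n: int, dz: float, wavelength: float = HENE_WAVELENGTH) -> float:
    """Largest pitch sampling the impulse response alias-free over an n×n window.

    The kernel's local spatial frequency at the farthest lateral offset
    2(n−1)·pitch must stay below Nyquist 1/(2·pitch), giving
    pitch = sqrt(λ·dz / (4(n−1))).  Used to put small oracle grids in a
    regime where the ASM and direct-sum routes describe the same physics.
    """
    return float(np.sqrt(wavelength * dz / (4.0 * (n - 1))))


def bandlimited_random_field(
    grid: GridSpec,
    rng: np.random.Generator,
    band_fraction: float = 0.5,
    envelope_div: float = 4.0,
) -> ComplexField:
    """Random complex field, band-limited and apodized, for propagation checks.

    Draws an i.i.d. complex spectrum restricted to |u|,|v| ≤
    band_fraction·Nyquist, inverse-transforms, and applies a Gaussian
    envelope (σ = n/envelope_div pixels) so the field vanishes toward the
    window edge.  Such fields are representable by both the angular-spectrum
    and direct-summation routes, unlike white noise whose near-Nyquist
    content walks off the sampled window over mm-scale distances.
    """
    n = grid.n
    f1 = np.fft.fftfreq(n, d=grid.pitch)
    fv, fu = np.meshgrid(f1, f1, indexing="ij")
    nyq = 0.5 / grid.pitch
    mask = (np.abs(fu) <= band_fraction * nyq) & (np.abs(fv) <= band_fraction * nyq)
    spec = (rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))) * mask
    values = np.fft.ifft2(spec)
    x = np.arange(n) - n // 2
    env = np.exp(-0.5 * (x / (n / envelope_div)) ** 2)
    return ComplexField(values=values * np.outer(env, env), grid=grid)
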