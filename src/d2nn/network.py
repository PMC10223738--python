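"""The diffractive deep neural network (D2NN) model.

A D2NN is a stack of passive diffractive layers separated by free-space
propagation.  Each layer applies a per-pixel complex modulation
``t = a·exp(jφ)`` (|t| ≤ 1) to the incident field; the phases (and optionally
the amplitudes) are the trainable parameters.  Inference is one coherent
forward pass: the input image amplitude-modulates a plane wave, the field
propagates through the layers, and per-class detector regions on the output
plane integrate the arriving light; the predicted class is the region with
the maximum readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import ComplexField, GridSpec, transfer_function, _propagate_values
from .synthetic import resize_nearest

__all__ = [
    "DiffractiveLayer",
    "DetectorLayout",
    "NetworkConfig",
    "DiffractiveNetwork",
    "encode_input",
    "apply_layer",
    "read_detectors",
    "predict",
]


@dataclass
class DiffractiveLayer:
    """One trainable modulation layer: t = amplitude · exp(j·phase)."""

    phase: np.ndarray  # radians, n×n
    amplitude: np.ndarray  # [0, 1], n×n
    phase_trainable: bool = True
    amplitude_trainable: bool = False

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64)
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        if self.phase.shape != self.amplitude.shape:
            raise ValueError("phase and amplitude shapes differ")
        if np.any(self.amplitude < 0) or np.any(self.amplitude > 1):
            raise ValueError("amplitude must lie in [0, 1] (passive layer)")

    @property
    def transmission(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)


@dataclass(frozen=True)
class DetectorLayout:
    """Per-class rectangular detector regions on the output plane.

    Each region is (row0, row1, col0, col1), half-open, in class order.
    ``readout_mode`` is "magnitude" (A_i = Σ|u|) or "intensity" (A_i = Σ|u|²).
    """

    regions: tuple
    readout_mode: str = "magnitude"

    def __post_init__(self) -> None:
        regions = tuple(tuple(int(v) for v in r) for r in self.regions)
        object.__setattr__(self, "regions", regions)
        if len(regions) < 2:
            raise ValueError("need at least 2 detector regions")
        if self.readout_mode not in ("magnitude", "intensity"):
            raise ValueError(f"unknown readout mode {self.readout_mode!r}")
        for r in regions:
            r0, r1, c0, c1 = r
            if not (0 <= r0 < r1 and 0 <= c0 < c1):
                raise ValueError(f"degenerate region {r}")
        for i, a in enumerate(regions):
            for b in regions[i + 1 :]:
                if a[0] < b[1] and b[0] < a[1] and a[2] < b[3] and b[2] < a[3]:
                    raise ValueError(f"detector regions overlap: {a} and {b}")

    @classmethod
    def default(cls, n: int, readout_mode: str = "magnitude") -> "DetectorLayout":
        """Two square regions, each 20% of the side, vertically centred,
        horizontally centred at 25% (class 0) and 75% (class 1) of the width."""
        s = max(1, round(0.2 * n))
        r0 = n // 2 - s // 2
        regions = []
        for fx in (0.25, 0.75):
            c0 = round(fx * n) - s // 2
            regions.append((r0, r0 + s, c0, c0 + s))
        return cls(regions=tuple(regions), readout_mode=readout_mode)

    def validate_grid(self, n: int) -> None:
        for r in self.regions:
            if r[1] > n or r[3] > n:
                raise ValueError(f"region {r} exceeds the {n}×{n} grid")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and physical configuration of a D2NN."""

    grid: GridSpec
    num_layers: int = 5
    dz: float = 10e-3
    detector: DetectorLayout = None  # type: ignore[assignment]
    input_size: int = 50
    modulation_mode: str = "phase"  # "phase" or "phase+amplitude"
    pad_factor: int = 2

    def __post_init__(self) -> None:
        if self.detector is None:
            object.__setattr__(self, "detector", DetectorLayout.default(self.grid.n))
        if self.num_layers < 0:
            raise ValueError("num_layers must be >= 0")
        if self.grid.n % self.input_size != 0:
            raise ValueError(
                f"network size {self.grid.n} must be divisible by input size {self.input_size}"
            )
        if self.modulation_mode not in ("phase", "phase+amplitude"):
            raise ValueError(f"unknown modulation mode {self.modulation_mode!r}")
        self.detector.validate_grid(self.grid.n)

    def to_dict(self) -> dict:
        return {
            "grid": {"n": self.grid.n, "pitch": self.grid.pitch, "wavelength": self.grid.wavelength},
            "num_layers": self.num_layers,
            "dz": self.dz,
            "detector": {"regions": list(self.detector.regions), "readout_mode": self.detector.readout_mode},
            "input_size": self.input_size,
            "modulation_mode": self.modulation_mode,
            "pad_factor": self.pad_factor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(
            grid=GridSpec(**d["grid"]),
            num_layers=d["num_layers"],
            dz=d["dz"],
            detector=DetectorLayout(
                regions=tuple(tuple(r) for r in d["detector"]["regions"]),
                readout_mode=d["detector"]["readout_mode"],
            ),
            input_size=d["input_size"],
            modulation_mode=d["modulation_mode"],
            pad_factor=d["pad_factor"],
        )


def encode_input(image: np.ndarray, grid: GridSpec) -> ComplexField:
    """Encode an image as the amplitude of a zero-phase field.

    Pixel values must already be normalised to [0, 1]; the image must match
    the grid size (upsample 50×50 patches with nearest interpolation first).
    """
    image = np.asarray(image, dtype=np.float64)
    if np.any(image < 0) or np.any(image > 1):
        raise ValueError("input image values must lie in [0, 1]")
    return ComplexField(values=image.astype(np.complex128), grid=grid)


def apply_layer(field: ComplexField, layer: DiffractiveLayer) -> ComplexField:
    """Elementwise modulation: output = t ⊙ field."""
    if layer.phase.shape != field.values.shape:
        raise ValueError("layer/field shape mismatch")
    return ComplexField(values=layer.transmission * field.values, grid=field.grid)


def read_detectors(field: ComplexField | np.ndarray, layout: DetectorLayout) -> np.ndarray:
    """Per-class readouts A_i from the detector-plane field.

    magnitude mode: A_i = Σ_{p∈region_i} |u(p)|; intensity: Σ |u(p)|².
    Accepts a ComplexField or a raw (..., n, n) array (batched).
    """
    values = field.values if isinstance(field, ComplexField) else np.asarray(field)
    mag = np.abs(values)
    if layout.readout_mode == "intensity":
        mag = mag**2
    A = [mag[..., r0:r1, c0:c1].sum(axis=(-2, -1)) for r0, r1, c0, c1 in layout.regions]
    return np.stack(A, axis=-1)


def predict(readout: np.ndarray) -> int | np.ndarray:
    """Class index with the maximum readout; ties break to the lowest index."""
    readout = np.asarray(readout)
    idx = np.argmax(readout, axis=-1)
    return int(idx) if idx.ndim == 0 else idx


class DiffractiveNetwork:
    """A configured stack of diffractive layers with cached propagators."""

    def __init__(self, config: NetworkConfig, layers: list[DiffractiveLayer]):
        if len(layers) != config.num_layers:
            raise ValueError("layer count does not match config")
        n = config.grid.n
        for layer in layers:
            if layer.phase.shape != (n, n):
                raise ValueError("layer shape does not match network grid")
        self.config = config
        self.layers = layers
        self._H = transfer_function(config.grid, config.dz, config.pad_factor).values
        self._H_adj = np.conj(self._H)

    # -- construction -------------------------------------------------------

    @classmethod
    def initialize(cls, config: NetworkConfig, seed: int = 0) -> "DiffractiveNetwork":
        """Fresh network: phases i.i.d. uniform on [0, 2π), amplitudes 1."""
        rng = np.random.default_rng(seed)
        n = config.grid.n
        amp_trainable = config.modulation_mode == "phase+amplitude"
        layers = [
            DiffractiveLayer(
                phase=rng.uniform(0.0, 2.0 * np.pi, size=(n, n)),
                amplitude=np.ones((n, n)),
                phase_trainable=True,
                amplitude_trainable=amp_trainable,
            )
            for _ in range(config.num_layers)
        ]
        return cls(config, layers)

    # -- forward ------------------------------------------------------------

    def _prepare_batch(self, images: np.ndarray) -> np.ndarray:
        """Upsample (if needed) and validate a (B, s, s) image batch."""
        images = np.asarray(images, dtype=np.float64)
        single = images.ndim == 2
        if single:
            images = images[None]
        n = self.config.grid.n
        if images.shape[-1] == self.config.input_size and self.config.input_size != n:
            images = np.stack([resize_nearest(im, n) for im in images])
        if images.shape[-2:] != (n, n):
            raise ValueError(f"images must be {self.config.input_size}² or {n}², got {images.shape[-2:]}")
        if np.any(images < 0) or np.any(images > 1):
            raise ValueError("input image values must lie in [0, 1]")
        return images

    def forward_batch(self, images: np.ndarray, cache: bool = False):
        """Propagate a batch of images to the detector plane.

        Returns the (B, n, n) detector-plane field; with ``cache=True`` also
        returns the per-layer intermediate fields needed for the adjoint
        (backward) pass: ``pre[l]`` is the field arriving at layer l and
        ``post[l]`` the field just after its modulation.
        """
        images = self._prepare_batch(images)
        n, pf = self.config.grid.n, self.config.pad_factor
        u = images.astype(np.complex128)
        pre, post = [], []
        for layer in self.layers:
            v = _propagate_values(u, self._H, n, pf)
            u = layer.transmission * v
            if cache:
                pre.append(v)
                post.append(u)
        u_out = _propagate_values(u, self._H, n, pf)
        if cache:
            return u_out, pre, post
        return u_out

    def backpropagate(self, g: np.ndarray, pre: list, post: list):
        """Adjoint pass: pull a detector-plane cotangent back through the net.

        ``g`` holds 2·∂L/∂u* of the batch loss w.r.t. the output field.
        Returns (phase_grads, amplitude_grads) summed over the batch.
        """
        n, pf = self.config.grid.n, self.config.pad_factor
        phase_grads, amp_grads = [], []
        g = _propagate_values(g, self._H_adj, n, pf)
        for layer, v, u in zip(reversed(self.layers), reversed(pre), reversed(post)):
            # u = a e^{jφ} v ⇒ dL/dφ = −Im(u·conj(g)), dL/da = Re(conj(g)·e^{jφ}v)
            phase_grads.append(-np.imag(u * np.conj(g)).sum(axis=0))
            amp_grads.append(np.real(np.conj(g) * np.exp(1j * layer.phase) * v).sum(axis=0))
            g = np.conj(layer.transmission) * g
            g = _propagate_values(g, self._H_adj, n, pf)
        return phase_grads[::-1], amp_grads[::-1]

    def forward(self, image: np.ndarray) -> ComplexField:
        """Single-image forward pass to the detector-plane field."""
        out = self.forward_batch(image[None] if image.ndim == 2 else image)
        return ComplexField(values=out[0], grid=self.config.grid)

    def readouts(self, images: np.ndarray) -> np.ndarray:
        """Batched detector readouts A (B, num_classes)."""
        return read_detectors(self.forward_batch(images), self.config.detector)

    # -- export -------------------------------------------------------------

    def wrapped_phases(self) -> list[np.ndarray]:
        """Phases wrapped to [0, 2π) for fabrication-style export."""
        return [np.mod(layer.phase, 2.0 * np.pi) for layer in self.layers]

    def copy(self) -> "DiffractiveNetwork":
        return DiffractiveNetwork(
            self.config,
            [
                DiffractiveLayer(
                    phase=layer.phase.copy(),
                    amplitude=layer.amplitude.copy(),
                    phase_trainable=layer.phase_trainable,
                    amplitude_trainable=layer.amplitude_trainable,
                )
                for layer in self.layers
            ],
        )
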