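"""Run configuration: one YAML document describing a full reproducible run.

Every physically meaningful default is pre-filled (632.8 nm source, 4 µm
pitch, 5 layers, 10 mm spacing, 200²/400² neurons, batch 64, learning rates
0.005/0.001, 120 epochs, 8:17:75 split, scan threshold 0.5) so a minimal
config only names a task and paths.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .detection import ScanConfig
from .network import DetectorLayout, NetworkConfig
from .optics import GridSpec
from .synthetic import PatchParams
from .training import Hyperparams, SplitSpec

__all__ = ["RunConfig", "load_config", "dump_config"]

TASKS = ("gen-data", "detect-train", "classify-train", "scan", "eval", "crossval")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run bit-for-bit on one thread."""

    task: str = "detect-train"
    seed: int = 0
    network_size: int | None = None  # default 200 (detection) / 400 (classification)
    num_layers: int = 5
    dz: float = 10e-3
    wavelength: float = 632.8e-9
    pitch: float = 4e-6
    input_size: int = 50
    readout_mode: str = "magnitude"
    modulation_mode: str = "phase"
    pad_factor: int = 2
    hyper: dict = field(default_factory=dict)  # Hyperparams overrides
    split: tuple[float, float, float] = (8.0, 17.0, 75.0)
    scan: dict = field(default_factory=dict)  # ScanConfig overrides
    patch: dict = field(default_factory=dict)  # PatchParams overrides
    ratio: tuple[int, int] | None = None  # class rebalance, e.g. [1, 4]
    augment: bool = False
    classification_data: bool = False  # gen-data: benign/malignant instead of nodule/background
    n_folds: int = 10
    # gen-data sizing
    n_patches: int = 400
    slice_size: int = 300
    n_slices: int = 1
    n_nodules: int = 5
    paths: dict = field(default_factory=dict)  # data / checkpoint / out

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")

    @property
    def classification(self) -> bool:
        return self.task == "classify-train"

    def network_config(self) -> NetworkConfig:
        n = self.network_size or (400 if self.classification else 200)
        return NetworkConfig(
            grid=GridSpec(n=n, pitch=self.pitch, wavelength=self.wavelength),
            num_layers=self.num_layers,
            dz=self.dz,
            detector=DetectorLayout.default(n, readout_mode=self.readout_mode),
            input_size=self.input_size,
            modulation_mode=self.modulation_mode,
            pad_factor=self.pad_factor,
        )

    def hyperparams(self, task: str) -> Hyperparams:
        return Hyperparams.for_task(task, seed=self.seed, **self.hyper)

    def scan_config(self) -> ScanConfig:
        return ScanConfig(**self.scan)

    def patch_params(self) -> PatchParams:
        overrides = dict(self.patch)
        if "nodule_radius" in overrides:
            overrides["nodule_radius"] = tuple(overrides["nodule_radius"])
        return PatchParams(**overrides)

    def split_spec(self) -> SplitSpec:
        return SplitSpec(ratios=tuple(self.split), seed=self.seed)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "split" in raw:
        raw["split"] = tuple(raw["split"])
    if raw.get("ratio") is not None:
        raw["ratio"] = tuple(raw["ratio"])
    return RunConfig(**raw)


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
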