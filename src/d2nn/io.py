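"""Checkpoint and manifest I/O.

Networks serialize to a single ``.npz`` archive holding every layer's phase
and amplitude plus the JSON-encoded :class:`~d2nn.network.NetworkConfig`;
save → load → save is bit-exact.  Run manifests are versioned JSON recording
every stochastic choice (seeds, splits, rebalance selections, defaulted
modes) so a run is recoverable from the manifest alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .network import DiffractiveLayer, DiffractiveNetwork, NetworkConfig
from .optics import ComplexField, GridSpec

__all__ = [
    "save_network",
    "load_network",
    "save_field",
    "load_field",
    "write_manifest",
    "read_manifest",
    "CHECKPOINT_VERSION",
]

CHECKPOINT_VERSION = 1
MANIFEST_VERSION = 1


def save_network(network: DiffractiveNetwork, path: str | Path, aux: dict | None = None) -> None:
    """Write a network checkpoint (phases, amplitudes, config, aux scalars)."""
    meta = {
        "format_version": CHECKPOINT_VERSION,
        "config": network.config.to_dict(),
        "trainable": [
            [layer.phase_trainable, layer.amplitude_trainable] for layer in network.layers
        ],
        "aux": aux or {},
    }
    arrays = {"_meta": np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)}
    for i, layer in enumerate(network.layers):
        arrays[f"phase_{i}"] = layer.phase
        arrays[f"amplitude_{i}"] = layer.amplitude
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_network(path: str | Path) -> tuple[DiffractiveNetwork, dict]:
    """Read a checkpoint back; returns (network, aux dict)."""
    with np.load(path) as data:
        try:
            meta = json.loads(bytes(data["_meta"]).decode())
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"not a network checkpoint: {path}") from exc
        if meta.get("format_version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"checkpoint format version {meta.get('format_version')} "
                f"not supported (expected {CHECKPOINT_VERSION})"
            )
        config = NetworkConfig.from_dict(meta["config"])
        layers = []
        for i in range(config.num_layers):
            pt, at = meta["trainable"][i]
            layers.append(
                DiffractiveLayer(
                    phase=data[f"phase_{i}"].copy(),
                    amplitude=data[f"amplitude_{i}"].copy(),
                    phase_trainable=pt,
                    amplitude_trainable=at,
                )
            )
    return DiffractiveNetwork(config, layers), meta.get("aux", {})


def save_field(field: ComplexField, path: str | Path, dz: float | None = None) -> None:
    """Write a complex field with its physical metadata (lossless)."""
    meta = {
        "n": field.grid.n,
        "pitch": field.grid.pitch,
        "wavelength": field.grid.wavelength,
        "dz": dz,
    }
    with open(path, "wb") as fh:
        np.savez(
            fh,
            values=field.values,
            _meta=np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8),
        )


def load_field(path: str | Path) -> tuple[ComplexField, dict]:
    """Read a field back; returns (field, metadata dict)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        grid = GridSpec(n=meta["n"], pitch=meta["pitch"], wavelength=meta["wavelength"])
        field = ComplexField(values=data["values"].copy(), grid=grid)
    return field, meta


def write_manifest(path: str | Path, payload: dict) -> None:
    doc = {"manifest_version": MANIFEST_VERSION, **payload}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=_jsonify) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
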