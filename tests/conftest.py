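"""Shared fixtures.

The expensive seeded training runs (reduced-scale detection network and the
translation-robust scan network) are session-scoped so the acceptance tests
and pipeline-invariant tests share one run each.
"""

from dataclasses import replace

import numpy as np
import pytest

from d2nn.detection import ScanConfig, scan_slice
from d2nn.network import DetectorLayout, DiffractiveNetwork, NetworkConfig
from d2nn.optics import GridSpec
from d2nn.synthetic import PatchParams, gen_patch, gen_slice
from d2nn.training import Hyperparams, train

# reduced-scale study conditions: 100x100 neuron grid, 3 layers, 200/100
# train/val patches, seed 0
REDUCED_N = 100
REDUCED_LAYERS = 3
N_TRAIN, N_VAL = 200, 100


def make_patch_set(params: PatchParams, n: int, seed: int):
    rng = np.random.default_rng(seed)
    patches = [gen_patch(params, i % 2, rng) for i in range(n)]
    return (
        np.stack([p.image for p in patches]),
        np.array([p.label for p in patches]),
    )


def reduced_config(n: int = REDUCED_N, layers: int = REDUCED_LAYERS) -> NetworkConfig:
    return NetworkConfig(
        grid=GridSpec(n=n),
        num_layers=layers,
        detector=DetectorLayout.default(n),
        input_size=50,
    )


@pytest.fixture(scope="session")
def detection_data():
    """200 training / 100 validation patches, defaults, seed 0."""
    params = PatchParams()
    tr = make_patch_set(params, N_TRAIN, seed=0)
    va = make_patch_set(params, N_VAL, seed=1)
    return tr, va


@pytest.fixture(scope="session")
def reduced_training_run(detection_data):
    """10-epoch seeded training of the reduced detection network."""
    (tr_imgs, tr_lab), (va_imgs, va_lab) = detection_data
    net = DiffractiveNetwork.initialize(reduced_config(), seed=0)
    net, history, aux = train(
        net, tr_imgs, tr_lab, va_imgs, va_lab,
        Hyperparams.for_task("detection", epochs=10, seed=0),
        "detection",
    )
    return net, history, aux


@pytest.fixture(scope="session")
def scan_run():
    """Scan-trained network (translation-jittered patches) + scanned slice.

    Training patches use centre jitter of stride/2 so windows on the scan
    lattice, where nodules sit up to ~7 px off-centre, are in-distribution.
    """
    params = replace(PatchParams(), center_jitter=5.0)
    tr_imgs, tr_lab = make_patch_set(params, N_TRAIN, seed=0)
    net = DiffractiveNetwork.initialize(reduced_config(), seed=0)
    net, _, aux = train(
        net, tr_imgs, tr_lab, None, None,
        Hyperparams.for_task("detection", epochs=30, seed=0),
        "detection",
    )
    sl = gen_slice(PatchParams(), 300, 300, 5, np.random.default_rng(7))
    config = ScanConfig(window=50, stride=10, threshold=0.5, b0=aux["b0"], b1=aux["b1"])
    cmap = scan_slice(net, sl.image, config)
    return net, aux, sl, cmap


@pytest.fixture
def tiny_net():
    """Small 2-layer network on a 32×32 grid for fast unit checks."""
    cfg = NetworkConfig(
        grid=GridSpec(n=32), num_layers=2,
        detector=DetectorLayout.default(32), input_size=32,
    )
    return DiffractiveNetwork.initialize(cfg, seed=3)
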