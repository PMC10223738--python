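"""Seeded generators for CT-like synthetic patches and slices.

Real thoracic-CT patch data (cropped around annotated nodule centres, with
radiologist malignancy ratings) is not bundled; these generators emulate its
geometry at 50×50-pixel scale so the whole pipeline is exercisable offline:

* nodule vs. background patches — a soft-edged, roughly round bright blob on
  band-limited lung-like texture;
* benign vs. malignant patch pairs — the malignant class is larger, has an
  irregular (harmonically perturbed) boundary, and grows radial spicules;
* full slices with nodules planted at known centres for sliding-window scans.

Every generator is a pure function of (parameters, rng seed).  All images are
float64 in [0, 1].
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "PatchParams",
    "LabeledPatch",
    "SyntheticSlice",
    "gen_patch",
    "gen_benign_malignant",
    "gen_slice",
    "augment",
    "resize_nearest",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class PatchParams:
    """Generative parameters for one patch family.

    Background is a mean grey level plus band-limited (low-pass filtered
    white) noise; the nodule is an additive radially-soft blob.  Defaults are
    chosen so the two classes are separable but textured: nodule contrast
    (0.5) comfortably exceeds texture amplitude (0.08).
    """

    size: int = 50
    background_mean: float = 0.20
    background_jitter: float = 0.10  # per-patch uniform level draw around the mean
    texture_amplitude: float = 0.08
    texture_corr_length: float = 4.0  # px, Gaussian correlation length
    shading_amplitude: float = 0.06  # coarse dark lung-field shading (slices)
    shading_corr_length: float = 25.0  # px
    streak_amplitude: float = 0.12  # bright vessel/rib-like ridges (slices)
    nodule_radius: tuple[float, float] = (5.0, 9.0)  # px, uniform draw
    nodule_contrast: float = 0.5
    edge_softness: float = 2.5  # px, smoothstep shoulder width
    center_jitter: float = 0.0  # px, uniform blob offset; set to stride/2 for scan training
    # malignant styling (relative to the benign blob above)
    malignant_radius_multiplier: float = 1.6
    boundary_irregularity: float = 0.25  # radial perturbation amplitude (fraction of R)
    spicule_count: int = 6
    spicule_length: float = 4.0  # px of extra radius at a spicule peak

    def __post_init__(self) -> None:
        lo, hi = self.nodule_radius
        if not (0 < lo <= hi < self.size / 2):
            raise ValueError(f"nodule radius range {self.nodule_radius} must fit the patch")
        if self.nodule_contrast <= self.texture_amplitude:
            raise ValueError("nodule contrast must exceed texture amplitude for separable classes")
        if not (0 <= self.background_mean <= 1):
            raise ValueError("background mean must lie in [0, 1]")


@dataclass
class LabeledPatch:
    """A size×size image in [0,1] with a binary label and its provenance."""

    image: np.ndarray
    label: int
    provenance: dict = field(default_factory=dict)


@dataclass
class SyntheticSlice:
    """Full slice image plus ground-truth nodule centres (row, col)."""

    image: np.ndarray
    truth_centers: list[tuple[int, int]]


def _correlated_noise(shape, corr_length, amplitude, rng) -> np.ndarray:
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), corr_length, mode="wrap")
    sd = noise.std()
    return noise * (amplitude / sd) if sd > 0 else noise


def _streak(shape, col, width, amp) -> np.ndarray:
    cc = np.arange(shape[1])
    return amp * np.exp(-0.5 * ((cc - col) / width) ** 2)[None, :]


def _background(params: PatchParams, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Patch background: a per-patch grey level plus band-limited texture.

    The level jitter emulates the heterogeneous local brightness of lung
    parenchyma (patches are notionally clipped from anywhere in a slice).
    """
    level = params.background_mean
    if params.background_jitter > 0:
        level = level + rng.uniform(-params.background_jitter, params.background_jitter)
    base = np.full(shape, level)
    if params.texture_amplitude > 0:
        base = base + _correlated_noise(shape, params.texture_corr_length, params.texture_amplitude, rng)
    return base


def _slice_background(params: PatchParams, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Slice background: patch texture plus large-scale dark lung regions
    and a few bright vessel/rib-like streaks."""
    base = np.full(shape, params.background_mean)
    if params.texture_amplitude > 0:
        base = base + _correlated_noise(shape, params.texture_corr_length, params.texture_amplitude, rng)
    if params.shading_amplitude > 0:
        coarse = _correlated_noise(shape, params.shading_corr_length, 1.0, rng)
        base = base - params.shading_amplitude * np.clip(coarse, 0.0, None)
    if params.streak_amplitude > 0:
        for _ in range(max(2, (shape[0] * shape[1]) // 40000)):
            base = base + _streak(
                shape,
                col=rng.uniform(0, shape[1]),
                width=rng.uniform(4, 10),
                amp=rng.uniform(0.4, 1.0) * params.streak_amplitude,
            )
    return base


def _smoothstep(s: np.ndarray) -> np.ndarray:
    s = np.clip(s, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def _blob(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius_of_theta,
    contrast: float,
    softness: float,
) -> np.ndarray:
    """Additive blob whose boundary radius may depend on polar angle."""
    rr, cc = np.indices(shape)
    dy = rr - center[0]
    dx = cc - center[1]
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    radius = radius_of_theta(theta) if callable(radius_of_theta) else radius_of_theta
    return contrast * _smoothstep((radius - r) / max(softness, 1e-9))


def gen_patch(params: PatchParams, label: int, rng: np.random.Generator) -> LabeledPatch:
    """Generate one detection-task patch.

    ``label`` 1 = nodule (central soft-edged round blob on texture),
    0 = background texture only.
    """
    n = params.size
    img = _background(params, (n, n), rng)
    radius = rng.uniform(*params.nodule_radius)
    jitter = rng.uniform(-params.center_jitter, params.center_jitter, size=2)
    if label == 1:
        c = ((n - 1) / 2.0 + jitter[0], (n - 1) / 2.0 + jitter[1])
        img = img + _blob((n, n), c, radius, params.nodule_contrast, params.edge_softness)
    elif label != 0:
        raise ValueError(f"label must be 0 (background) or 1 (nodule), got {label}")
    img = np.clip(img, 0.0, 1.0)
    return LabeledPatch(image=img, label=int(label), provenance={"task": "detection", **asdict(params)})


def gen_benign_malignant(params: PatchParams, label: int, rng: np.random.Generator) -> LabeledPatch:
    """Generate one classification-task patch.

    ``label`` 0 = benign (small smooth round blob), 1 = malignant (radius
    scaled by the multiplier, boundary perturbed by low-order harmonics,
    radial spicules added).  Both classes sit on the same background family.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 (benign) or 1 (malignant), got {label}")
    n = params.size
    img = _background(params, (n, n), rng)
    base_radius = rng.uniform(*params.nodule_radius)
    c = ((n - 1) / 2.0, (n - 1) / 2.0)
    if label == 0:
        radius = base_radius
    else:
        R = base_radius * params.malignant_radius_multiplier
        # low-order harmonic boundary perturbation
        amps = rng.uniform(0.5, 1.0, size=3) * params.boundary_irregularity / 3.0
        phases = rng.uniform(0, 2 * np.pi, size=3)
        # spicules: narrow angular bumps of extra radius
        sp_theta = rng.uniform(0, 2 * np.pi, size=params.spicule_count)
        sp_width = 0.18  # rad

        def radius_fn(theta: np.ndarray) -> np.ndarray:
            rad = R * (
                1.0
                + sum(a * np.cos((m + 2) * theta + p) for m, (a, p) in enumerate(zip(amps, phases)))
            )
            for t0 in sp_theta:
                d = np.angle(np.exp(1j * (theta - t0)))
                rad = rad + params.spicule_length * np.exp(-0.5 * (d / sp_width) ** 2)
            return rad

        radius = radius_fn
    img = img + _blob((n, n), c, radius, params.nodule_contrast, params.edge_softness)
    img = np.clip(img, 0.0, 1.0)
    return LabeledPatch(
        image=img, label=int(label), provenance={"task": "classification", **asdict(params)}
    )


def gen_slice(
    params: PatchParams,
    H: int,
    W: int,
    n_nodules: int,
    rng: np.random.Generator,
    window: int = 50,
) -> SyntheticSlice:
    """Generate a full slice with ``n_nodules`` planted at known centres.

    Background emulates a lung field: large-scale dark regions with a few
    bright streaks (vessel/rib-like ridges).  Centres are rejection-sampled
    at least ``window/2`` px from every border and pairwise at least
    ``window`` px apart.
    """
    if n_nodules < 0:
        raise ValueError("n_nodules must be >= 0")
    margin = window // 2
    if H < window or W < window:
        raise ValueError("slice must be at least one window on each side")

    img = _slice_background(params, (H, W), rng)

    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < n_nodules:
        tries += 1
        if tries > 10000:
            raise RuntimeError("could not place nodules with the required spacing")
        r = int(rng.integers(margin, H - margin))
        c = int(rng.integers(margin, W - margin))
        if all(np.hypot(r - r0, c - c0) >= window for r0, c0 in centers):
            centers.append((r, c))
    for r, c in centers:
        radius = rng.uniform(*params.nodule_radius)
        img = img + _blob((H, W), (r, c), radius, params.nodule_contrast, params.edge_softness)

    return SyntheticSlice(image=np.clip(img, 0.0, 1.0), truth_centers=centers)


def augment(patch: LabeledPatch | np.ndarray) -> list:
    """The 8 dihedral-group variants of a square patch, original first.

    4 right-angle rotations × optional horizontal flip; labels preserved.
    """
    if isinstance(patch, LabeledPatch):
        imgs = augment(patch.image)
        return [LabeledPatch(image=im, label=patch.label, provenance=dict(patch.provenance)) for im in imgs]
    img = np.asarray(patch)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("augment requires a square 2-D patch")
    rots = [np.rot90(img, k) for k in range(4)]
    return [r.copy() for r in rots] + [np.fliplr(r).copy() for r in rots]


def resize_nearest(image: np.ndarray, target_n: int) -> np.ndarray:
    """Nearest-neighbour upsampling by integer pixel replication.

    ``target_n`` must be an integer multiple of the source side; each source
    pixel fills a k×k block, so the value set is preserved exactly.
    """
    image = np.asarray(image)
    n = image.shape[0]
    if image.ndim != 2 or image.shape[1] != n:
        raise ValueError("resize_nearest expects a square 2-D image")
    if target_n % n != 0:
        raise ValueError(f"target size {target_n} is not an integer multiple of source size {n}")
    k = target_n // n
    return np.repeat(np.repeat(image, k, axis=0), k, axis=1)


# ---------------------------------------------------------------------------
# dataset directory format: images/*.png (16-bit grayscale) + labels.csv
# ---------------------------------------------------------------------------

def save_dataset(directory: str | Path, patches: list[LabeledPatch], case_ids=None) -> None:
    """Write patches as ``images/NNNNN.png`` (16-bit) plus ``labels.csv``.

    ``labels.csv`` columns: filename, label, case_id.  This directory layout
    is also the adapter surface for user-prepared real patch data.
    """
    from PIL import Image

    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    if case_ids is None:
        case_ids = [str(i) for i in range(len(patches))]
    rows = []
    for i, (p, cid) in enumerate(zip(patches, case_ids)):
        fname = f"{i:05d}.png"
        arr = np.clip(np.round(p.image * 65535.0), 0, 65535).astype(np.uint16)
        Image.fromarray(arr).save(directory / "images" / fname)
        rows.append((fname, p.label, cid))
    with open(directory / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "label", "case_id"])
        w.writerows(rows)


def load_dataset(directory: str | Path):
    """Read a dataset directory back as (images (N,s,s) float, labels, case_ids)."""
    from PIL import Image

    directory = Path(directory)
    images, labels, case_ids = [], [], []
    with open(directory / "labels.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            arr = np.asarray(Image.open(directory / "images" / row["filename"]), dtype=np.float64)
            images.append(arr / 65535.0)
            labels.append(int(row["label"]))
            case_ids.append(row["case_id"])
    return np.stack(images), np.asarray(labels, dtype=np.int64), case_ids
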