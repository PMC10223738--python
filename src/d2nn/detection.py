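"""Sliding-window nodule detection on full slices.

A trained detection network classifies one 50×50 window at a time; scanning
the window across a slice on a stride lattice yields a per-position nodule
score (the normalized positive-detector readout), from which candidate
nodule centres are thresholded and compared against ground-truth centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import DiffractiveNetwork
from .synthetic import resize_nearest

__all__ = [
    "ScanConfig",
    "CandidateMap",
    "nodule_score",
    "scan_positions",
    "scan_slice",
    "evaluate_scan",
    "rebalance",
    "normalize_hu",
]


@dataclass(frozen=True)
class ScanConfig:
    """Sliding-window scan settings."""

    window: int = 50
    stride: int = 10
    threshold: float = 0.5
    batch_size: int = 256
    b0: float = 0.0
    b1: float = 0.0

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not (1 <= self.stride <= self.window):
            raise ValueError("stride must satisfy 1 <= stride <= window")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")


@dataclass
class CandidateMap:
    """Scan output: score map, binary mask and sorted candidate list.

    ``score_map`` is NaN where no window was evaluated; scores are written at
    window centres.  ``candidates`` are (row, col, score) sorted by
    descending score; the mask is True where score strictly exceeds the
    threshold.
    """

    score_map: np.ndarray
    threshold: float
    candidates: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def mask(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.score_map, nan=-np.inf) > self.threshold

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["row", "col", "score"])
            w.writerows(self.candidates)

    def save_images(self, score_path, mask_path) -> None:
        """Export the score map and binary mask as grayscale PNGs."""
        from PIL import Image

        score = np.nan_to_num(self.score_map, nan=0.0)
        Image.fromarray(np.clip(score * 255, 0, 255).astype(np.uint8)).save(score_path)
        Image.fromarray((self.mask * 255).astype(np.uint8)).save(mask_path)


def nodule_score(normalized) -> np.ndarray:
    """Per-class existence scores: score_i = A'_i / (A'_0 + A'_1).

    Accepts a :class:`~d2nn.training.NormalizedReadout` or a raw array
    (batched along leading axes); scores are nonnegative and sum to 1.
    """
    A = getattr(normalized, "A_prime", normalized)
    A = np.asarray(A, dtype=np.float64)
    s = A.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("degenerate normalized readout: scores need A'_0 + A'_1 > 0")
    return A / s


def scan_positions(side: int, window: int, stride: int) -> np.ndarray:
    """Window top-left offsets along one axis; out-of-bounds windows skipped."""
    if side < window:
        raise ValueError(f"slice side {side} smaller than window {window}")
    return np.arange(0, side - window + 1, stride)


def scan_slice(network: DiffractiveNetwork, slice_image: np.ndarray, config: ScanConfig) -> CandidateMap:
    """Scan a slice with a trained detection network.

    Every window on the stride lattice is clipped, upsampled by nearest
    interpolation to the network grid, run through the network, and its
    positive-class score (class 1 = nodule) is written at the window centre.
    """
    img = np.asarray(slice_image, dtype=np.float64)
    H, W = img.shape
    w = config.window
    rows = scan_positions(H, w, config.stride)
    cols = scan_positions(W, w, config.stride)
    n = network.config.grid.n

    score_map = np.full((H, W), np.nan)
    centers, windows = [], []
    for r in rows:
        for c in cols:
            centers.append((r + w // 2, c + w // 2))
            windows.append(resize_nearest(img[r : r + w, c : c + w], n))

    b = np.array([config.b0, config.b1])
    scores = np.empty(len(windows))
    for i in range(0, len(windows), config.batch_size):
        batch = np.stack(windows[i : i + config.batch_size])
        A = network.readouts(batch)
        Ap = A / (A.sum(axis=1, keepdims=True) + b.sum())
        scores[i : i + len(batch)] = nodule_score(Ap)[:, 1]

    candidates = []
    for (rc, cc), s in zip(centers, scores):
        score_map[rc, cc] = s
        if s > config.threshold:
            candidates.append((rc, cc, float(s)))
    candidates.sort(key=lambda t: -t[2])
    return CandidateMap(score_map=score_map, threshold=config.threshold, candidates=candidates)


def evaluate_scan(candidates, truth_centers, match_radius: float = 25.0):
    """Scan recall and false-positive count against ground-truth centres.

    A truth centre counts as detected if any candidate lies within
    ``match_radius`` (Euclidean, inclusive); every candidate that is not
    within the radius of any truth centre counts as one false positive.
    Returns (recall, fp_count); recall is NaN with no truth centres.
    """
    if not (match_radius > 0):
        raise ValueError("match_radius must be positive")
    cand = [(r, c) for r, c, *_ in candidates]
    detected = 0
    for tr, tc in truth_centers:
        if any(np.hypot(tr - r, tc - c) <= match_radius for r, c in cand):
            detected += 1
    fp = sum(
        1
        for r, c in cand
        if not any(np.hypot(tr - r, tc - c) <= match_radius for tr, tc in truth_centers)
    )
    recall = detected / len(truth_centers) if truth_centers else float("nan")
    return recall, fp


def rebalance(images: np.ndarray, labels: np.ndarray, ratio: tuple[int, int], seed: int = 0):
    """Subsample the over-represented class to a positive:negative ratio.

    Seeded, without replacement, never duplicating items; the achieved ratio
    is exact within ±1 by integer rounding.  Raises if the ratio would
    require oversampling either class.
    """
    p, q = ratio
    if p <= 0 or q <= 0:
        raise ValueError("ratio parts must be positive")
    labels = np.asarray(labels)
    pos_idx = np.nonzero(labels == 1)[0]
    neg_idx = np.nonzero(labels == 0)[0]
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("both classes must be nonempty")
    rng = np.random.default_rng(seed)

    want_pos = round(len(neg_idx) * p / q)
    if want_pos <= len(pos_idx):
        # positives over-represented: shrink them, keep all negatives
        if want_pos == 0:
            raise ValueError(
                f"ratio {p}:{q} unreachable without oversampling: "
                f"{len(neg_idx)} negatives would require 0 positives"
            )
        pos_keep = np.sort(rng.choice(pos_idx, size=want_pos, replace=False))
        neg_keep = neg_idx
    else:
        want_neg = round(len(pos_idx) * q / p)
        if want_neg == 0 or want_neg > len(neg_idx):
            short = max(want_neg - len(neg_idx), want_pos - len(pos_idx))
            raise ValueError(
                f"ratio {p}:{q} unreachable without oversampling: short by {short}"
            )
        pos_keep = pos_idx
        neg_keep = np.sort(rng.choice(neg_idx, size=want_neg, replace=False))
    keep = np.sort(np.concatenate([pos_keep, neg_keep]))
    return images[keep], labels[keep], keep


def normalize_hu(image_hu: np.ndarray, lo: float = -1000.0, hi: float = 400.0) -> np.ndarray:
    """Map CT Hounsfield units to [0, 1] with a fixed lung window."""
    return np.clip((np.asarray(image_hu, dtype=np.float64) - lo) / (hi - lo), 0.0, 1.0)
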