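"""Training: readout normalizations, losses, optimization and data splits.

Two task-specific readout normalizations are used:

* detection — A'_i = A_i / (A_0 + A_1 + b_0 + b_1), with nonnegative bias
  scalars b_0, b_1 guarding against near-dark detector planes (background
  windows can carry almost no light); loss is softmax cross-entropy on A'.
* classification — A'_i = α·A_i / max(A_0, A_1); loss is mean squared error
  against the α-scaled one-hot target.

Gradients with respect to layer phases/amplitudes and the (softplus-
parameterized) biases are computed by a reverse-mode adjoint pass through the
angular-spectrum propagation chain; optimization uses Adam by default with
plain gradient descent available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import DiffractiveNetwork, read_detectors

__all__ = [
    "NormalizedReadout",
    "Hyperparams",
    "SplitSpec",
    "TrainingHistory",
    "normalize_detection",
    "loss_softmax_ce",
    "normalize_classification",
    "loss_mse",
    "train",
    "split_cases",
    "kfold_cases",
]


@dataclass
class NormalizedReadout:
    """Normalized per-class readouts A' plus the scheme that produced them."""

    A_prime: np.ndarray
    scheme: str  # "detection" | "classification"
    b0: float = 0.0
    b1: float = 0.0
    alpha: float = 1.0


@dataclass
class Hyperparams:
    """Optimization hyperparameters.

    Defaults follow the published training recipe: batch 64, 120 epochs,
    learning rate 0.005 for detection and 0.001 for classification.
    """

    batch_size: int = 64
    learning_rate: float = 0.005
    epochs: int = 120
    seed: int = 0
    optimizer: str = "adam"  # "adam" | "sgd"
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    alpha: float = 1.0  # classification target scale
    train_biases: bool = True  # detection b0, b1

    def __post_init__(self) -> None:
        if self.batch_size <= 0 or self.epochs < 0 or self.learning_rate < 0:
            raise ValueError("batch size and epochs must be positive, learning rate nonnegative")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    @classmethod
    def for_task(cls, task: str, **overrides) -> "Hyperparams":
        lr = {"detection": 0.005, "classification": 0.001}[task]
        return cls(**{"learning_rate": lr, **overrides})


@dataclass(frozen=True)
class SplitSpec:
    """Validation : test : training ratio split over case identifiers."""

    ratios: tuple[float, float, float] = (8.0, 17.0, 75.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must be positive")


@dataclass
class TrainingHistory:
    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# normalizations and losses (value APIs, spec-level single readout)
# ---------------------------------------------------------------------------

def normalize_detection(readout: np.ndarray, b0: float, b1: float) -> NormalizedReadout:
    """A'_i = A_i / (A_0 + A_1 + b_0 + b_1)."""
    A = np.asarray(readout, dtype=np.float64)
    if np.any(A < 0) or b0 < 0 or b1 < 0:
        raise ValueError("readouts and biases must be nonnegative")
    denom = A.sum() + b0 + b1
    if denom <= 0:
        raise ValueError("degenerate readout: all readouts and biases are zero")
    return NormalizedReadout(A_prime=A / denom, scheme="detection", b0=b0, b1=b1)


def loss_softmax_ce(normalized: NormalizedReadout | np.ndarray, label: np.ndarray) -> float:
    """Softmax cross-entropy on normalized readouts with a one-hot label."""
    A = normalized.A_prime if isinstance(normalized, NormalizedReadout) else np.asarray(normalized)
    label = np.asarray(label, dtype=np.float64)
    if label.shape != A.shape or not (np.all((label == 0) | (label == 1)) and label.sum() == 1):
        raise ValueError("label must be one-hot over the classes")
    z = A - A.max()
    log_softmax = z - np.log(np.sum(np.exp(z)))
    return float(-np.sum(label * log_softmax))


def normalize_classification(readout: np.ndarray, alpha: float) -> NormalizedReadout:
    """A'_i = α·A_i / max(A_0, A_1); the largest readout maps exactly to α."""
    A = np.asarray(readout, dtype=np.float64)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    m = A.max()
    if m <= 0:
        raise ValueError("degenerate readout: max(A) must be positive")
    return NormalizedReadout(A_prime=alpha * A / m, scheme="classification", alpha=alpha)


def loss_mse(normalized: NormalizedReadout | np.ndarray, label: np.ndarray, alpha: float) -> float:
    """Σ_i (A'_i − α·label_i)²; zero iff A' equals the α-scaled one-hot."""
    A = normalized.A_prime if isinstance(normalized, NormalizedReadout) else np.asarray(normalized)
    label = np.asarray(label, dtype=np.float64)
    if label.shape != A.shape or not (np.all((label == 0) | (label == 1)) and label.sum() == 1):
        raise ValueError("label must be one-hot over the classes")
    return float(np.sum((A - alpha * label) ** 2))


# ---------------------------------------------------------------------------
# batched loss + gradient w.r.t. raw readouts (training internals)
# ---------------------------------------------------------------------------

def _onehot(labels: np.ndarray, num_classes: int = 2) -> np.ndarray:
    return np.eye(num_classes)[np.asarray(labels, dtype=np.int64)]


def _detection_loss_grad(A: np.ndarray, labels: np.ndarray, b: np.ndarray):
    """Mean softmax-CE loss over a batch; returns (loss, dL/dA, dL/db)."""
    B = A.shape[0]
    onehot = _onehot(labels, A.shape[1])
    S = A.sum(axis=1, keepdims=True) + b.sum()
    Ap = A / S
    z = Ap - Ap.max(axis=1, keepdims=True)
    log_softmax = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = float(-(onehot * log_softmax).sum() / B)
    dAp = (np.exp(log_softmax) - onehot) / B  # softmax − label
    # A'_i = A_i/S ⇒ ∂A'_i/∂A_j = δ_ij/S − A_i/S², ∂A'_i/∂b_k = −A_i/S²
    common = (dAp * A).sum(axis=1, keepdims=True) / S**2
    dA = dAp / S - common
    db = np.full_like(b, -float(common.sum()))
    return loss, dA, db


def _classification_loss_grad(A: np.ndarray, labels: np.ndarray, alpha: float):
    """Mean MSE loss over a batch; returns (loss, dL/dA)."""
    B = A.shape[0]
    onehot = _onehot(labels, A.shape[1])
    m_idx = np.argmax(A, axis=1)
    M = A[np.arange(B), m_idx][:, None]
    if np.any(M <= 0):
        raise ValueError("degenerate readout: max(A) must be positive for every item")
    Ap = alpha * A / M
    resid = Ap - alpha * onehot
    loss = float((resid**2).sum() / B)
    dAp = 2.0 * resid / B
    dA = alpha * dAp / M
    # subgradient through M = A_m (argmax; ties take the lowest index)
    dA[np.arange(B), m_idx] -= (dAp * alpha * A / M**2).sum(axis=1)
    return loss, dA


def _readout_field_cotangent(u_out: np.ndarray, dA: np.ndarray, layout) -> np.ndarray:
    """Seed cotangent g = 2·∂L/∂u* on the detector plane from dL/dA."""
    g = np.zeros_like(u_out)
    mag = np.abs(u_out)
    for i, (r0, r1, c0, c1) in enumerate(layout.regions):
        u = u_out[:, r0:r1, c0:c1]
        if layout.readout_mode == "magnitude":
            m = mag[:, r0:r1, c0:c1]
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = np.where(m > 0, u / np.where(m > 0, m, 1.0), 0.0)
            g[:, r0:r1, c0:c1] = dA[:, i, None, None] * unit
        else:  # intensity: A = Σ|u|² ⇒ g = 2u·dL/dA
            g[:, r0:r1, c0:c1] = dA[:, i, None, None] * 2.0 * u
    return g


def batch_loss_and_grads(
    network: DiffractiveNetwork,
    images: np.ndarray,
    labels: np.ndarray,
    task: str,
    b: np.ndarray | None = None,
    alpha: float = 1.0,
):
    """Mean batch loss and gradients w.r.t. phases, amplitudes and biases.

    The workhorse behind :func:`train`; also used directly by the
    finite-difference gradient checks.
    """
    u_out, pre, post = network.forward_batch(images, cache=True)
    A = read_detectors(u_out, network.config.detector)
    if task == "detection":
        if b is None:
            b = np.zeros(2)
        loss, dA, db = _detection_loss_grad(A, labels, b)
    elif task == "classification":
        loss, dA = _classification_loss_grad(A, labels, alpha)
        db = np.zeros(2)
    else:
        raise ValueError(f"unknown task {task!r}")
    g = _readout_field_cotangent(u_out, dA, network.config.detector)
    phase_grads, amp_grads = network.backpropagate(g, pre, post)
    return loss, phase_grads, amp_grads, db


def batch_loss(
    network: DiffractiveNetwork,
    images: np.ndarray,
    labels: np.ndarray,
    task: str,
    b: np.ndarray | None = None,
    alpha: float = 1.0,
) -> float:
    """Mean batch loss only (no gradients); used by finite-difference checks."""
    A = network.readouts(images)
    if task == "detection":
        if b is None:
            b = np.zeros(2)
        loss, _, _ = _detection_loss_grad(A, labels, b)
    else:
        loss, _ = _classification_loss_grad(A, labels, alpha)
    return loss


# ---------------------------------------------------------------------------
# optimizer and training loop
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, shapes, lr, beta1, beta2, eps):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, grads):
        self.t += 1
        out = []
        for i, g in enumerate(grads):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            out.append(self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    return float(np.log(np.expm1(y)))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def evaluate_accuracy(
    network: DiffractiveNetwork, images: np.ndarray, labels: np.ndarray, batch_size: int = 256
) -> float:
    """Fraction of argmax-readout predictions matching the labels."""
    preds = predict_batched(network, images, batch_size)
    return float(np.mean(preds == np.asarray(labels)))


def predict_batched(network: DiffractiveNetwork, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
    preds = []
    for i in range(0, len(images), batch_size):
        A = network.readouts(images[i : i + batch_size])
        preds.append(np.argmax(A, axis=1))
    return np.concatenate(preds) if preds else np.empty(0, dtype=np.int64)


def train(
    network: DiffractiveNetwork,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    val_images: np.ndarray | None,
    val_labels: np.ndarray | None,
    hyper: Hyperparams,
    task: str,
) -> tuple[DiffractiveNetwork, TrainingHistory, dict]:
    """Minibatch gradient optimization of the task loss.

    Detection uses softmax cross-entropy on bias-normalized readouts (b0, b1
    trainable through a softplus map, initialized at 0.01); classification
    uses MSE against the α-scaled one-hot target.  Returns the trained
    network (modified in place), the per-epoch history and a dict of final
    auxiliary parameters ({"b0", "b1"} for detection).

    Fully reproducible given ``hyper.seed`` on a single thread.
    """
    if task not in ("detection", "classification"):
        raise ValueError(f"unknown task {task!r}")
    n_train = len(train_images)
    if n_train == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(hyper.seed)

    beta = np.full(2, _softplus_inv(0.01))  # b = softplus(beta), b(0) = 0.01
    train_b = task == "detection" and hyper.train_biases

    param_shapes = [l.phase.shape for l in network.layers]
    amp_shapes = [l.amplitude.shape for l in network.layers if l.amplitude_trainable]
    shapes = param_shapes + amp_shapes + ([beta.shape] if train_b else [])
    if hyper.optimizer == "adam":
        opt = _Adam(shapes, hyper.learning_rate, hyper.beta1, hyper.beta2, hyper.eps)
    else:
        opt = None

    history = TrainingHistory()
    for epoch in range(hyper.epochs):
        order = rng.permutation(n_train)
        losses = []
        for start in range(0, n_train, hyper.batch_size):
            idx = order[start : start + hyper.batch_size]
            b = _softplus(beta) if task == "detection" else None
            loss, pg, ag, db = batch_loss_and_grads(
                network, train_images[idx], train_labels[idx], task, b=b, alpha=hyper.alpha
            )
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}: {loss}")
            losses.append(loss)

            # frozen-phase layers keep their optimizer slot but see zero gradient
            pg = [g if l.phase_trainable else np.zeros_like(g) for g, l in zip(pg, network.layers)]
            amp_grads = [g for g, l in zip(ag, network.layers) if l.amplitude_trainable]
            all_grads = list(pg) + amp_grads
            if train_b:
                all_grads.append(db * _sigmoid(beta))  # chain through softplus
            if opt is not None:
                updates = opt.step(all_grads)
            else:
                updates = [hyper.learning_rate * g for g in all_grads]

            for layer, upd in zip(network.layers, updates[: len(network.layers)]):
                if layer.phase_trainable:
                    layer.phase -= upd
            k = len(network.layers)
            for layer in network.layers:
                if layer.amplitude_trainable:
                    # amplitude lives in [0,1]; project after the step
                    layer.amplitude = np.clip(layer.amplitude - updates[k], 0.0, 1.0)
                    k += 1
            if train_b:
                beta -= updates[-1]

        val_acc = (
            evaluate_accuracy(network, val_images, val_labels)
            if val_images is not None and len(val_images)
            else float("nan")
        )
        history.epoch.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.val_accuracy.append(val_acc)

    aux = {}
    if task == "detection":
        b = _softplus(beta)
        aux = {"b0": float(b[0]), "b1": float(b[1])}
    return network, history, aux


# ---------------------------------------------------------------------------
# case-level splitting
# ---------------------------------------------------------------------------

def _largest_remainder(total: int, ratios) -> list[int]:
    ratios = np.asarray(ratios, dtype=np.float64)
    quota = total * ratios / ratios.sum()
    base = np.floor(quota).astype(int)
    rem = quota - base
    for i in np.argsort(-rem)[: total - base.sum()]:
        base[i] += 1
    return base.tolist()


def split_cases(case_ids, spec: SplitSpec = SplitSpec()):
    """Seeded split of case identifiers into (validation, test, training).

    Shuffles once, then assigns contiguous blocks sized by largest-remainder
    rounding of the ratio (default 8:17:75).  Splitting at case level keeps
    all patches from one case in a single split (leakage control).
    """
    case_ids = list(case_ids)
    if len(set(case_ids)) != len(case_ids):
        raise ValueError("case ids must be unique")
    if len(case_ids) < 3:
        raise ValueError("need at least one case per split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(case_ids))
    shuffled = [case_ids[i] for i in order]
    sizes = _largest_remainder(len(case_ids), spec.ratios)
    val = shuffled[: sizes[0]]
    test = shuffled[sizes[0] : sizes[0] + sizes[1]]
    tr = shuffled[sizes[0] + sizes[1] :]
    return val, test, tr


def kfold_cases(case_ids, k: int, seed: int = 0):
    """Seeded near-equal partition of case ids into k disjoint folds."""
    case_ids = list(case_ids)
    if k < 2 or k > len(case_ids):
        raise ValueError("need 2 <= k <= number of cases")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(case_ids))
    shuffled = [case_ids[i] for i in order]
    return [list(fold) for fold in np.array_split(np.asarray(shuffled, dtype=object), k)]
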