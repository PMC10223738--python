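"""Model-level API: a classifier object built from data whose ``fit()``
returns a results object.

:class:`DiffractiveClassifier` wraps the full workflow — case-level
splitting, optional class rebalancing and augmentation, training, held-out
evaluation — around a :class:`~d2nn.network.DiffractiveNetwork`, in the
style of a statsmodels model.  :class:`DiffractiveResults` carries the
trained parameters, per-epoch history, test-set metrics and ROC, and renders
a ``summary()`` table.

Example
-------
>>> from d2nn.model import DiffractiveClassifier
>>> model = DiffractiveClassifier(images, labels, task="detection")
>>> res = model.fit(seed=0, epochs=10)
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import nodule_score, rebalance
from .metrics import BinaryMetrics, confusion_and_metrics, roc_auc
from .network import DetectorLayout, DiffractiveNetwork, NetworkConfig
from .optics import GridSpec
from .synthetic import augment
from .training import (
    Hyperparams,
    SplitSpec,
    TrainingHistory,
    predict_batched,
    split_cases,
    train,
)

__all__ = ["DiffractiveClassifier", "DiffractiveResults"]


def _default_config(task: str, network_size: int | None = None) -> NetworkConfig:
    # published architecture: 200×200 neurons for detection, 400×400 for
    # classification, 5 layers, 10 mm spacing, 632.8 nm, 4 µm pitch
    n = network_size or {"detection": 200, "classification": 400}[task]
    return NetworkConfig(grid=GridSpec(n=n), num_layers=5, detector=DetectorLayout.default(n))


class DiffractiveClassifier:
    """A trainable diffractive optical classifier built from labeled patches.

    Parameters
    ----------
    images : (N, s, s) array
        Patches in [0, 1] (s = 50 by default; upsampled internally).
    labels : (N,) array of {0, 1}
        Class 1 is the positive class (nodule / malignant).
    task : "detection" | "classification"
        Selects the readout normalization and loss (softmax cross-entropy on
        bias-normalized readouts vs. MSE on max-normalized readouts).
    case_ids : sequence, optional
        Case identifier per patch; splits are made at case level so patches
        from one case never straddle splits.  Defaults to one case per patch.
    config : NetworkConfig, optional
        Architecture; defaults to the published geometry for the task.
    """

    def __init__(self, images, labels, task: str = "detection", case_ids=None,
                 config: NetworkConfig | None = None):
        self.images = np.asarray(images, dtype=np.float64)
        self.labels = np.asarray(labels, dtype=np.int64)
        if self.images.ndim != 3 or len(self.images) != len(self.labels):
            raise ValueError("need (N, s, s) images and N labels")
        if task not in ("detection", "classification"):
            raise ValueError(f"unknown task {task!r}")
        self.task = task
        self.case_ids = list(case_ids) if case_ids is not None else [str(i) for i in range(len(labels))]
        if len(self.case_ids) != len(self.labels):
            raise ValueError("need one case id per patch")
        self.config = config if config is not None else _default_config(task)

    @classmethod
    def from_directory(cls, path, task: str = "detection", config: NetworkConfig | None = None):
        """Build from a dataset directory (``images/*.png`` + ``labels.csv``)."""
        from .synthetic import load_dataset

        images, labels, case_ids = load_dataset(path)
        return cls(images, labels, task=task, case_ids=case_ids, config=config)

    def fit(
        self,
        seed: int = 0,
        split: SplitSpec | None = None,
        ratio: tuple[int, int] | None = None,
        augment_training: bool = False,
        network: DiffractiveNetwork | None = None,
        **hyper_overrides,
    ) -> "DiffractiveResults":
        """Split by case, optionally rebalance/augment, train, evaluate.

        Returns a :class:`DiffractiveResults` with the trained network, the
        per-epoch history, and metrics on the held-out test split.
        """
        split = split if split is not None else SplitSpec(seed=seed)
        hyper = Hyperparams.for_task(self.task, seed=seed, **hyper_overrides)

        unique_cases = list(dict.fromkeys(self.case_ids))
        val_c, test_c, train_c = split_cases(unique_cases, split)
        cid = np.asarray(self.case_ids, dtype=object)
        masks = {name: np.isin(cid, list(cs)) for name, cs in
                 [("val", val_c), ("test", test_c), ("train", train_c)]}

        tr_imgs, tr_labels = self.images[masks["train"]], self.labels[masks["train"]]
        rebalance_keep = None
        if ratio is not None:
            tr_imgs, tr_labels, rebalance_keep = rebalance(tr_imgs, tr_labels, ratio, seed=seed)
        if augment_training:
            tr_imgs = np.concatenate([np.stack(augment(im)) for im in tr_imgs])
            tr_labels = np.repeat(tr_labels, 8)

        if network is None:
            network = DiffractiveNetwork.initialize(self.config, seed=seed)
        network, history, aux = train(
            network,
            tr_imgs,
            tr_labels,
            self.images[masks["val"]],
            self.labels[masks["val"]],
            hyper,
            self.task,
        )
        return DiffractiveResults(
            model=self,
            network=network,
            history=history,
            hyper=hyper,
            aux=aux,
            split={"validation": val_c, "test": test_c, "training": train_c},
            rebalance_keep=rebalance_keep,
        )


@dataclass
class DiffractiveResults:
    """Fitted-network results: parameters, history, held-out metrics."""

    model: DiffractiveClassifier
    network: DiffractiveNetwork
    history: TrainingHistory
    hyper: Hyperparams
    aux: dict
    split: dict
    rebalance_keep: np.ndarray | None = None
    _test_cache: tuple | None = field(default=None, repr=False)

    # -- inference ----------------------------------------------------------

    def predict(self, images) -> np.ndarray:
        """Argmax-readout class predictions for a batch of patches."""
        return predict_batched(self.network, np.asarray(images, dtype=np.float64))

    def scores(self, images) -> np.ndarray:
        """Positive-class scores in [0, 1] for a batch of patches."""
        A = self.network.readouts(np.asarray(images, dtype=np.float64))
        if self.model.task == "detection":
            b = self.aux.get("b0", 0.0) + self.aux.get("b1", 0.0)
            Ap = A / (A.sum(axis=1, keepdims=True) + b)
        else:
            Ap = self.hyper.alpha * A / A.max(axis=1, keepdims=True)
        return nodule_score(Ap)[:, 1]

    # -- evaluation ---------------------------------------------------------

    def _test_arrays(self):
        mask = np.isin(np.asarray(self.model.case_ids, dtype=object), list(self.split["test"]))
        return self.model.images[mask], self.model.labels[mask]

    def test_metrics(self) -> BinaryMetrics:
        imgs, labels = self._test_arrays()
        return confusion_and_metrics(self.predict(imgs), labels)

    def test_roc(self):
        imgs, labels = self._test_arrays()
        return roc_auc(self.scores(imgs), labels)

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch": self.history.epoch, "train_loss": self.history.train_loss,
             "val_accuracy": self.history.val_accuracy}
        )

    def metrics_table(self) -> pd.DataFrame:
        """One-row table with the standard column set for the test split."""
        return pd.DataFrame([self.test_metrics().to_row()])

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        m = self.test_metrics()
        cfg = self.network.config
        _, _, auc = self.test_roc()
        lines = [
            "Diffractive optical classifier results",
            "=" * 54,
            f"Task:               {self.model.task}",
            f"Layers:             {cfg.num_layers} ({cfg.grid.n}x{cfg.grid.n} neurons, "
            f"dz = {cfg.dz * 1e3:g} mm, lambda = {cfg.grid.wavelength * 1e9:g} nm)",
            f"Readout:            {cfg.detector.readout_mode}-sum, "
            f"{len(cfg.detector.regions)} detector regions",
            f"Epochs / batch:     {self.hyper.epochs} / {self.hyper.batch_size}"
            f"   (lr = {self.hyper.learning_rate}, seed = {self.hyper.seed})",
            f"Final train loss:   {self.history.train_loss[-1]:.6f}" if self.history.train_loss else
            "Final train loss:   n/a",
            f"Final val accuracy: {self.history.val_accuracy[-1]:.4f}" if self.history.val_accuracy else
            "Final val accuracy: n/a",
            "-" * 54,
            f"Test confusion:     TP={m.tp}  FP={m.fp}  TN={m.tn}  FN={m.fn}",
            f"Accuracy:           {100 * m.accuracy:.2f} %",
            f"Recall:             {100 * m.recall:.2f} %",
            f"Precision:          {100 * m.precision:.2f} %",
            f"Specificity:        {100 * m.specificity:.2f} %",
            f"F1 score:           {m.f1:.4f}",
            f"MCC:                {m.mcc:.4f}",
            f"ROC AUC:            {auc:.4f}",
        ]
        if self.aux:
            lines.append(
                "Learned biases:     " + ", ".join(f"{k}={v:.4g}" for k, v in self.aux.items())
            )
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Training loss and validation accuracy per epoch."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history.epoch, self.history.train_loss, label="train loss")
        ax2 = ax.twinx()
        ax2.plot(self.history.epoch, self.history.val_accuracy, "C1", label="val accuracy")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax2.set_ylabel("validation accuracy")
        return ax

    def save(self, path) -> None:
        from .io import save_network

        save_network(self.network, path, aux=self.aux)
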