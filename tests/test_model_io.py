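"""Model/results API, checkpoint round-trips and the command-line surface."""

import hashlib

import numpy as np
import pytest
from click.testing import CliRunner

from d2nn.cli import main
from d2nn.io import load_network, save_network
from d2nn.model import DiffractiveClassifier
from d2nn.network import DetectorLayout, DiffractiveNetwork, NetworkConfig
from d2nn.optics import GridSpec
from d2nn.synthetic import PatchParams, gen_patch


def small_config(n=50, layers=2):
    return NetworkConfig(grid=GridSpec(n=n), num_layers=layers,
                         detector=DetectorLayout.default(n), input_size=50)


@pytest.fixture(scope="module")
def small_fit():
    rng = np.random.default_rng(0)
    patches = [gen_patch(PatchParams(), i % 2, rng) for i in range(60)]
    imgs = np.stack([p.image for p in patches])
    labels = np.array([p.label for p in patches])
    model = DiffractiveClassifier(imgs, labels, task="detection", config=small_config())
    return model.fit(seed=0, epochs=4, batch_size=16)


class TestModelAPI:
    def test_fit_produces_history_and_metrics(self, small_fit):
        frame = small_fit.history_frame()
        assert list(frame.columns) == ["epoch", "train_loss", "val_accuracy"]
        assert len(frame) == 4
        m = small_fit.test_metrics()
        assert m.tp + m.fp + m.tn + m.fn == len(small_fit._test_arrays()[0])

    def test_split_covers_all_cases_disjointly(self, small_fit):
        s = small_fit.split
        allc = s["validation"] + s["test"] + s["training"]
        assert len(allc) == len(set(allc)) == 60

    def test_summary_renders(self, small_fit):
        text = small_fit.summary()
        for token in ("Task:", "detection", "Accuracy:", "MCC:", "ROC AUC:"):
            assert token in text

    def test_predict_and_scores_shapes(self, small_fit):
        imgs, _ = small_fit._test_arrays()
        preds = small_fit.predict(imgs)
        scores = small_fit.scores(imgs)
        assert preds.shape == scores.shape == (len(imgs),)
        assert set(np.unique(preds)) <= {0, 1}
        assert np.all((scores >= 0) & (scores <= 1))
        # argmax prediction consistent with thresholding the score at 0.5
        assert np.array_equal(preds, (scores > 0.5).astype(preds.dtype))

    def test_metrics_table_column_order(self, small_fit):
        cols = list(small_fit.metrics_table().columns)
        assert cols == ["Accuracy (%)", "Recall(Sensitivity) (%)", "Precision (%)",
                        "F1 Score", "MMC"]

    def test_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            DiffractiveClassifier(np.zeros((4, 50, 50)), np.zeros(3))


class TestCheckpointIO:
    def test_save_load_save_bit_exact(self, tmp_path):
        net = DiffractiveNetwork.initialize(small_config(), seed=1)
        p1, p2 = tmp_path / "a.npz", tmp_path / "b.npz"
        save_network(net, p1, aux={"b0": 0.01, "b1": 0.02})
        net2, aux = load_network(p1)
        save_network(net2, p2, aux=aux)
        assert hashlib.sha256(p1.read_bytes()).digest() == hashlib.sha256(p2.read_bytes()).digest()

    def test_forward_identical_after_reload(self, tmp_path):
        net = DiffractiveNetwork.initialize(small_config(), seed=2)
        save_network(net, tmp_path / "net.npz")
        net2, _ = load_network(tmp_path / "net.npz")
        img = np.random.default_rng(0).uniform(0, 1, (50, 50))
        assert np.array_equal(net.forward(img).values, net2.forward(img).values)

    def test_field_serialization_lossless(self, tmp_path):
        from d2nn.io import load_field, save_field
        from d2nn.optics import ComplexField

        grid = GridSpec(n=16, pitch=3e-6, wavelength=500e-9)
        rng = np.random.default_rng(0)
        field = ComplexField(rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16)), grid)
        save_field(field, tmp_path / "f.npz", dz=5e-3)
        loaded, meta = load_field(tmp_path / "f.npz")
        assert np.array_equal(loaded.values, field.values)
        assert loaded.grid == grid
        assert meta["dz"] == 5e-3

    def test_non_checkpoint_rejected(self, tmp_path):
        path = tmp_path / "junk.npz"
        np.savez(path, a=np.zeros(3))
        with pytest.raises((ValueError, KeyError)):
            load_network(path)


class TestCLI:
    def _gen(self, runner, tmp_path, seed=3, out="data"):
        cfg = tmp_path / "gen.yaml"
        cfg.write_text(
            "task: gen-data\nn_patches: 40\nn_slices: 1\nslice_size: 120\nn_nodules: 1\n"
        )
        res = runner.invoke(main, ["gen-data", "--config", str(cfg), "--seed", str(seed),
                                   "--out", str(tmp_path / out)])
        assert res.exit_code == 0, res.output
        return tmp_path / out

    def test_gen_data_deterministic(self, tmp_path):
        runner = CliRunner()
        d1 = self._gen(runner, tmp_path, out="d1")
        d2 = self._gen(runner, tmp_path, out="d2")
        for rel in sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file()):
            if rel.name == "manifest.json":
                continue  # records the differing output path
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_train_eval_scan_workflow(self, tmp_path):
        runner = CliRunner()
        data = self._gen(runner, tmp_path)
        train_cfg = tmp_path / "train.yaml"
        train_cfg.write_text(
            "task: detect-train\nnetwork_size: 50\nnum_layers: 2\n"
            "hyper: {epochs: 2, batch_size: 16}\n"
            f"paths: {{data: {data / 'patches'}}}\n"
        )
        res = runner.invoke(main, ["detect-train", "--config", str(train_cfg),
                                   "--seed", "0", "--out", str(tmp_path / "run")])
        assert res.exit_code == 0, res.output
        run = tmp_path / "run"
        assert (run / "checkpoint.npz").exists()
        assert (run / "history.csv").exists()
        assert (run / "manifest.json").exists()
        # metrics CSV confusion counts sum to the test-set size
        import json
        import pandas as pd

        manifest = json.loads((run / "manifest.json").read_text())
        n_test_cases = len(manifest["split"]["test"])
        metrics = pd.read_csv(run / "metrics.csv")
        assert metrics.shape[0] == 1

        # scan with threshold 1.0 → header-only candidates CSV
        scan_cfg = tmp_path / "scan.yaml"
        scan_cfg.write_text(
            "task: scan\nscan: {threshold: 1.0, stride: 25}\n"
            f"paths: {{checkpoint: {run / 'checkpoint.npz'}, "
            f"slice: {data / 'slice_000.csv'}, truth: {data / 'slice_000_truth.csv'}}}\n"
        )
        res = runner.invoke(main, ["scan", "--config", str(scan_cfg),
                                   "--seed", "0", "--out", str(tmp_path / "scanout")])
        assert res.exit_code == 0, res.output
        lines = (tmp_path / "scanout" / "candidates.csv").read_text().strip().splitlines()
        assert lines == ["row,col,score"]

        # eval reuses the checkpoint on the same dataset
        eval_cfg = tmp_path / "eval.yaml"
        eval_cfg.write_text(
            f"task: eval\npaths: {{checkpoint: {run / 'checkpoint.npz'}, "
            f"data: {data / 'patches'}}}\n"
        )
        res = runner.invoke(main, ["eval", "--config", str(eval_cfg),
                                   "--seed", "0", "--out", str(tmp_path / "evalout")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "evalout" / "metrics.csv").exists()

    def test_crossval_folds_cover_all_cases(self, tmp_path):
        runner = CliRunner()
        data = self._gen(runner, tmp_path)
        cv_cfg = tmp_path / "cv.yaml"
        cv_cfg.write_text(
            "task: crossval\nnetwork_size: 50\nnum_layers: 1\nn_folds: 3\n"
            "hyper: {epochs: 1, batch_size: 16}\n"
            f"paths: {{data: {data / 'patches'}}}\n"
        )
        res = runner.invoke(main, ["crossval", "--config", str(cv_cfg),
                                   "--seed", "0", "--out", str(tmp_path / "cv")])
        assert res.exit_code == 0, res.output
        import json
        import pandas as pd

        frame = pd.read_csv(tmp_path / "cv" / "crossval.csv")
        assert len(frame) == 3
        manifest = json.loads((tmp_path / "cv" / "manifest.json").read_text())
        assert sum(len(f) for f in manifest["folds"]) == 40

    def test_missing_config_path_fails(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(main, ["detect-train", "--config", str(tmp_path / "nope.yaml")])
        assert res.exit_code != 0
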