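"""End-to-end training/evaluation/prediction pipeline on a miniature
setup (tiny architecture, 32x32 phantoms, a few epochs)."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from lkmu import ArchConfig, PhantomSpec, generate_dataset, poly_lr
from lkmu.estimator import LKMULiteSegmenter
from lkmu.train import TrainConfig, evaluate, load_checkpoint, predict, train

TINY_ARCH = dict(num_classes=1, stage_channels=(16, 16, 16, 16, 16))
TINY_SPEC = PhantomSpec(height=32, width=32, n_classes=1, n_layers=6,
                        axis_range=(3, 8), curvature_amplitude=1.0,
                        blobs_per_class=(1, 2))


@pytest.fixture(scope="module")
def tiny_run(tmp_path_factory):
    """One shared 3-epoch training run over 6 phantom images."""
    root = tmp_path_factory.mktemp("run")
    data = root / "data"
    manifest = generate_dataset(TINY_SPEC, n=6, seed=2, out_dir=data)
    train_df = manifest.iloc[:4]
    val_df = manifest.iloc[4:]
    train_df.to_csv(data / "train.csv", index=False)
    val_df.to_csv(data / "val.csv", index=False)
    cfg = TrainConfig(arch=ArchConfig(**TINY_ARCH), epochs=3, batch_size=2,
                      seed=0, augment=True,
                      train_manifest=str(data / "train.csv"),
                      val_manifest=str(data / "val.csv"),
                      out_dir=str(root / "out"))
    result = train(cfg)
    return cfg, result, data


def test_logged_lr_follows_poly_schedule(tiny_run):
    cfg, result, _ = tiny_run
    log = result["log"]
    for _, row in log.iterrows():
        expected = poly_lr(int(row["epoch"]), initial_lr=cfg.lr,
                           num_epochs=cfg.epochs, power=cfg.lr_power)
        assert row["lr"] == pytest.approx(expected)


def test_best_checkpoint_is_argmin_val_loss(tiny_run):
    _, result, _ = tiny_run
    log = result["log"]
    assert result["best_epoch"] == int(log["val_loss"].idxmin())
    assert result["best_val_loss"] == pytest.approx(log["val_loss"].min())
    assert log["val_loss"].iloc[result["best_epoch"]] <= log["val_loss"].iloc[0]


def test_training_is_reproducible(tmp_path):
    data = tmp_path / "d"
    manifest = generate_dataset(TINY_SPEC, n=4, seed=3, out_dir=data)
    manifest.to_csv(data / "all.csv", index=False)

    def run(out):
        cfg = TrainConfig(arch=ArchConfig(**TINY_ARCH), epochs=2,
                          batch_size=2, seed=7, augment=True,
                          train_manifest=str(data / "all.csv"),
                          val_manifest=str(data / "all.csv"),
                          out_dir=str(tmp_path / out))
        return train(cfg)["log"]

    log1 = run("r1")
    log2 = run("r2")
    pd.testing.assert_frame_equal(log1, log2)


def test_one_step_moves_every_parameter(tmp_path):
    from lkmu import build_model, generate_phantom
    from lkmu.train import fit_arrays

    model = build_model(ArchConfig(**TINY_ARCH), seed=5)
    init = {n: p.data.copy() for n, p in model.named_parameters()}
    samples = [generate_phantom(TINY_SPEC, s) for s in range(2)]
    fit_arrays(model, samples, samples, epochs=1, batch_size=2, lr=1e-3,
               weight_decay=1e-4, lr_power=0.9, seed=0, augment_train=False)
    unchanged = [n for n, p in model.named_parameters()
                 if np.array_equal(p.data, init[n])]
    assert unchanged == []


def test_checkpoint_roundtrip_preserves_predictions(tiny_run, rng):
    _, result, _ = tiny_run
    from lkmu.nn import autograd as ag

    model = result["model"]
    model.eval()
    loaded, sidecar = load_checkpoint(result["last_checkpoint"])
    assert sidecar["arch"]["num_classes"] == 1
    x = rng.standard_normal((1, 3, 32, 32)).astype(np.float32)
    with ag.no_grad():
        np.testing.assert_array_equal(model(x).data, loaded(x).data)


def test_evaluate_deterministic_and_mean_rows(tiny_run, tmp_path):
    _, result, data = tiny_run
    df1 = evaluate(result["best_checkpoint"], data / "val.csv",
                   out_csv=tmp_path / "m.csv")
    df2 = evaluate(result["best_checkpoint"], data / "val.csv")
    pd.testing.assert_frame_equal(df1, df2)
    assert (tmp_path / "m.csv").exists()
    # each sample's mean row equals the arithmetic mean of its class rows
    for sample in df1[df1["sample"] != "ALL"]["sample"].unique():
        sub = df1[df1["sample"] == sample]
        mean_row = sub[sub["class"] == "mean"].iloc[0]
        class_rows = sub[sub["class"] != "mean"]
        assert mean_row["dsc"] == pytest.approx(class_rows["dsc"].mean())


def test_evaluating_ground_truth_scores_perfectly(tmp_path):
    """Feeding the ground-truth masks through the metric path yields
    IoU = DSC = 1 and HD95 = 0 — the oracle-input sanity check."""
    from lkmu import seg_metrics, generate_phantom

    sample = generate_phantom(TINY_SPEC, 1)
    rep = seg_metrics(sample.mask, sample.mask, n_classes=1)
    assert rep.mean["iou"] == 1.0
    assert rep.mean["dsc"] == 1.0
    assert rep.mean["hd95"] == 0.0


def test_predict_writes_masks_and_overlays(tiny_run, tmp_path):
    _, result, data = tiny_run
    images = sorted(str(p) for p in data.glob("phantom_*[0-9].png"))[:2]
    written = predict(result["best_checkpoint"], images, tmp_path / "preds")
    assert len(written) == 2
    for mask_path, overlay_path in written:
        mask = np.asarray(Image.open(mask_path))
        overlay = np.asarray(Image.open(overlay_path))
        original = np.asarray(Image.open(images[0] if "0000" in mask_path
                                         else images[1]).convert("L"))
        assert mask.shape == original.shape
        assert overlay.shape == original.shape + (3,)
        # untouched wherever background
        bg = mask == 0
        for ch in range(3):
            np.testing.assert_array_equal(overlay[..., ch][bg], original[bg])
        # painted pixels use only the configured palette
        from lkmu.train import OVERLAY_PALETTE
        fg = ~bg
        if fg.any():
            colours = {tuple(c) for c in overlay[fg].reshape(-1, 3)}
            assert colours <= set(map(tuple, OVERLAY_PALETTE.values()))


def test_predict_warns_and_fails_gracefully(tiny_run, tmp_path):
    _, result, _ = tiny_run
    bogus = tmp_path / "nope.png"
    with pytest.raises(RuntimeError, match="no input image"):
        with pytest.warns(UserWarning, match="skipping"):
            predict(result["best_checkpoint"], [bogus], tmp_path / "p2")


def test_train_rejects_empty_manifest(tmp_path):
    empty = tmp_path / "empty.csv"
    pd.DataFrame(columns=["image", "mask"]).to_csv(empty, index=False)
    cfg = TrainConfig(arch=ArchConfig(**TINY_ARCH), epochs=1,
                      train_manifest=str(empty), val_manifest=str(empty),
                      out_dir=str(tmp_path / "o"))
    with pytest.raises(ValueError, match="empty manifest"):
        train(cfg)


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

def test_estimator_fit_predict_score():
    from lkmu import generate_phantom

    samples = [generate_phantom(TINY_SPEC, s) for s in range(3)]
    X = np.stack([s.image for s in samples])
    y = np.stack([s.mask for s in samples])
    est = LKMULiteSegmenter(stage_channels=(16,) * 5, epochs=2, batch_size=2,
                            seed=0)
    est.fit(X, y)
    preds = est.predict(X)
    assert preds.shape == y.shape
    proba = est.predict_proba(X)
    assert proba.shape == (3, 1, 32, 32)
    assert 0.0 <= est.score(X, y) <= 1.0
    assert est.best_epoch_ in est.history_["epoch"].values


def test_estimator_sklearn_protocol():
    from sklearn.base import clone

    est = LKMULiteSegmenter(epochs=5, lr=2e-3)
    params = est.get_params()
    assert params["epochs"] == 5
    est2 = clone(est)
    assert est2.get_params() == params
    est2.set_params(epochs=7)
    assert est2.epochs == 7
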