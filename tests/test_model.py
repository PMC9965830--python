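"""Model/Results pipeline: preprocessing, a training smoke run, evaluation,
persistence, and the CLI surface."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from irisloc.cli import main as cli_main
from irisloc.core import Circle
from irisloc.model import (IrisLocalizationModel, IrisLocalizationResults,
                           TrainConfig, preprocess, preprocess_sample)
from irisloc.net import NetConfig
from irisloc.simdata import SimConfig, generate_samples, make_dataset

SMOKE_SIZE = (64, 64)


@pytest.fixture(scope="module")
def smoke_results():
    """A short seeded training run shared by the pipeline tests."""
    cfg = SimConfig(image_size=SMOKE_SIZE, seed=31)
    samples = generate_samples(50, cfg)
    model = IrisLocalizationModel(
        samples, net_config=NetConfig.tiny_preset(),
        train_config=TrainConfig(epochs=5, seed=2))
    return model, model.fit()


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def test_preprocess_pads_to_standard_sizes():
    """A 400x300 frame becomes 448x320 via symmetric padding of 24 rows and
    10 columns per side."""
    image = np.full((400, 300, 3), 50, dtype=np.uint8)
    out, (dx, dy) = preprocess(image, (448, 320))
    assert out.shape == (448, 320, 3)
    assert (dx, dy) == (10, 24)
    assert (out[24:-24, 10:-10] == 50).all()
    assert (out[:24] == 0).all() and (out[:, :10] == 0).all()


def test_preprocess_identity():
    image = np.arange(96 * 96 * 3, dtype=np.uint8).reshape(96, 96, 3)
    out, (dx, dy) = preprocess(image, (96, 96))
    assert (dx, dy) == (0, 0)
    assert np.array_equal(out, image)


def test_preprocess_crops_larger_sources():
    image = np.zeros((200, 200), dtype=np.uint8)
    image[100, 100] = 7
    out, (dx, dy) = preprocess(image, (128, 128))
    assert out.shape == (128, 128)
    assert out[100 + dy, 100 + dx] == 7


def test_preprocess_sample_translates_circles(clean_sample):
    target = (128, 160)
    moved = preprocess_sample(clean_sample, target)
    dy = (target[0] - clean_sample.shape[0]) // 2
    dx = (target[1] - clean_sample.shape[1]) // 2
    assert moved.inner.x == clean_sample.inner.x + dx
    assert moved.inner.y == clean_sample.inner.y + dy
    assert moved.mask.sum() == clean_sample.mask.sum()


def test_preprocess_rejects_bad_target():
    with pytest.raises(ValueError):
        preprocess(np.zeros((64, 64, 3), dtype=np.uint8), (60, 64))


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------

def test_smoke_training_reduces_loss(smoke_results):
    _, res = smoke_results
    hist = res.history
    assert hist.iloc[-1]["total"] < hist.iloc[0]["total"]
    assert np.isfinite(hist["total"]).all()


def test_summary_reports_fit(smoke_results):
    _, res = smoke_results
    text = res.summary()
    assert "parameters" in text and "best epoch" in text


def test_predict_returns_valid_results(smoke_results):
    model, res = smoke_results
    out = res.predict([model.samples[0].image])[0]
    assert out.inner.r >= 1.0 and out.outer.r >= 1.0
    assert 0.0 < out.score_inner < 1.0
    assert out.mask.shape == model.samples[0].shape
    d = out.to_dict()
    assert set(d) == {"inner", "outer"}
    assert set(d["inner"]) == {"x", "y", "r", "score"}


def test_oracle_evaluation_is_perfect(smoke_results):
    model, res = smoke_results
    report, per_image = res.evaluate(model.samples[:6], oracle=True)
    assert report.miou_box_inner == report.miou_box_outer == 1.0
    assert report.miou_mask == 1.0
    assert report.e1_mask == report.e1_norm == 0.0
    assert report.mhdist_inner == report.mhdist_outer == 0.0
    assert report.n_images == 6
    assert len(per_image) == 6


def test_eval_report_has_expected_columns(smoke_results):
    model, res = smoke_results
    report, _ = res.evaluate(model.samples[:2])
    d = report.to_dict()
    assert set(d) == {
        "miou_box_inner", "miou_box_outer", "miou_box_avg", "mhdist_inner",
        "mhdist_outer", "e1_mask", "miou_mask", "e1_norm", "n_images"}


def test_evaluation_is_deterministic(smoke_results):
    model, res = smoke_results
    r1, _ = res.evaluate(model.samples[:4])
    r2, _ = res.evaluate(model.samples[:4])
    assert r1.to_dict() == r2.to_dict()


def test_checkpoint_roundtrip_reproduces_predictions(tmp_path, smoke_results):
    model, res = smoke_results
    path = tmp_path / "ckpt.npz"
    res.save(path)
    loaded = IrisLocalizationResults.load(path)
    assert loaded.val_miou_box_avg == pytest.approx(res.val_miou_box_avg)
    assert loaded.best_epoch == res.best_epoch
    img = model.samples[1].image
    a = res.predict_one(img)
    b = loaded.predict_one(img)
    assert (a.inner.x, a.inner.y, a.inner.r) == (b.inner.x, b.inner.y, b.inner.r)
    assert np.array_equal(a.mask, b.mask)
    # the stored validation metric is reproduced by re-evaluating the split
    if res.val_indices:
        val = [model.samples[i] for i in res.val_indices]
        report, _ = loaded.evaluate(val)
        assert report.miou_box_avg == pytest.approx(res.val_miou_box_avg, abs=1e-6)


def test_use_cgr_flag_changes_targets_only():
    from irisloc.encode import EncodeConfig, encode_sample
    s = generate_samples(1, SimConfig(seed=41))[0]
    on = encode_sample(s.inner, s.outer, s.shape, EncodeConfig(use_cgr=True))
    off = encode_sample(s.inner, s.outer, s.shape, EncodeConfig(use_cgr=False))
    assert not np.array_equal(on.heat, off.heat)
    assert np.array_equal(on.offset, off.offset)
    assert np.array_equal(on.center_mask, off.center_mask)


def test_nan_loss_aborts_with_diagnostic():
    samples = generate_samples(8, SimConfig(image_size=SMOKE_SIZE, seed=55))
    model = IrisLocalizationModel(
        samples, net_config=NetConfig.tiny_preset(),
        train_config=TrainConfig(epochs=1, lr=1e18, seed=0, val_fraction=0.0))
    with pytest.raises(RuntimeError, match="epoch 0"):
        model.fit()


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def test_cli_simdata_and_eval_oracle(tmp_path, smoke_results):
    _, res = smoke_results
    runner = CliRunner()
    data_dir = tmp_path / "data"
    out = runner.invoke(cli_main, ["simdata", "--n", "3", "--seed", "12",
                                   "--out", str(data_dir), "--size", "64", "64"])
    assert out.exit_code == 0, out.output
    ckpt = tmp_path / "ckpt.npz"
    res.save(ckpt)
    out = runner.invoke(cli_main, ["eval", "--ckpt", str(ckpt),
                                   "--data", str(data_dir / "manifest.csv"),
                                   "--oracle", "--out", str(tmp_path / "rep")])
    assert out.exit_code == 0, out.output
    assert "miou_box_inner" in out.output
    report = json.loads((tmp_path / "rep" / "eval_report.json").read_text())
    assert report["miou_box_avg"] == 1.0
    assert (tmp_path / "rep" / "eval_report.csv").exists()
    assert (tmp_path / "rep" / "per_image_metrics.csv").exists()


def test_cli_infer_writes_schema_conformant_json(tmp_path, smoke_results):
    _, res = smoke_results
    ckpt = tmp_path / "ckpt.npz"
    res.save(ckpt)
    data_dir = tmp_path / "imgs"
    make_dataset(2, SimConfig(image_size=SMOKE_SIZE, seed=61), data_dir)
    runner = CliRunner()
    out = runner.invoke(cli_main, [
        "infer", "--ckpt", str(ckpt), "--out", str(tmp_path / "res"),
        str(data_dir / "sim_0000.png"), str(data_dir / "sim_0001.png")])
    assert out.exit_code == 0, out.output
    files = sorted((tmp_path / "res").glob("*.json"))
    assert len(files) == 2
    rec = json.loads(files[0].read_text())
    for key in ("inner", "outer"):
        assert {"x", "y", "r", "score"} <= set(rec[key])
    assert (tmp_path / "res" / "sim_0000_mask.png").exists()


def test_cli_infer_nonzero_exit_on_unreadable(tmp_path, smoke_results):
    _, res = smoke_results
    ckpt = tmp_path / "ckpt.npz"
    res.save(ckpt)
    bad = tmp_path / "missing.png"
    runner = CliRunner()
    out = runner.invoke(cli_main, ["infer", "--ckpt", str(ckpt),
                                   "--out", str(tmp_path / "res"), str(bad)])
    assert out.exit_code == 1
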