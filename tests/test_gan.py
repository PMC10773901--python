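"""Conditional WGAN-GP: gradient penalty, training contracts, sampling."""

import numpy as np
import pytest

from craniosynth import gan
from craniosynth.distmap import DistanceMap
from craniosynth.headgen import CLASSES, synth_head
from craniosynth.distmap import encode_distance_map
from craniosynth.nn.tensor import Tensor, matmul, reshape
from craniosynth.simmetric import ssim, ssim_cc


def _linear_critic(u):
    w = Tensor(np.asarray(u).reshape(-1, 1), requires_grad=True)

    def critic(x, labels):
        return matmul(reshape(x, (x.shape[0], -1)), w)

    return critic


class TestGradientPenalty:
    @pytest.fixture()
    def batches(self, rng):
        xr = rng.random((6, 1, 28, 28))
        xf = rng.random((6, 1, 28, 28))
        y = rng.integers(0, 4, 6)
        return (xr, y), (xf, y)

    def test_unit_gradient_critic_has_zero_penalty(self, rng, batches):
        u = rng.normal(size=784)
        u /= np.linalg.norm(u)
        gp = gan.gradient_penalty(_linear_critic(u), *batches)
        assert gp.item() == pytest.approx(0.0, abs=1e-9)

    def test_doubled_gradient_critic_has_unit_penalty(self, rng, batches):
        u = rng.normal(size=784)
        u /= np.linalg.norm(u)
        gp = gan.gradient_penalty(_linear_critic(2 * u), *batches)
        assert gp.item() == pytest.approx(1.0, abs=1e-5)

    def test_lambda_scaling_is_linear(self, rng, batches):
        u = rng.normal(size=784)
        u /= np.linalg.norm(u)
        gp = gan.gradient_penalty(_linear_critic(3 * u), *batches).item()
        assert 2 * gp == pytest.approx((Tensor(2.0) * gan.gradient_penalty(_linear_critic(3 * u), *batches)).item(), rel=1e-6)

    def test_mismatched_batches_rejected(self, rng):
        xr = rng.random((4, 1, 28, 28))
        xf = rng.random((3, 1, 28, 28))
        with pytest.raises(ValueError, match="equal shape"):
            gan.gradient_penalty(_linear_critic(np.ones(784)), (xr, np.zeros(4)), (xf, np.zeros(3)))


def test_generator_mixes_upsampling_kinds():
    """The image-forming path alternates interpolation-upsample+conv with a
    transposed convolution (the anti-checkerboard design)."""
    model = gan.Generator(gan.GANConfig(seed=0), np.random.default_rng(0))
    kinds = [k for k in model.upsampling_kinds if k in ("upsample", "conv", "convtranspose")]
    assert kinds == ["upsample", "conv", "convtranspose", "conv"]


@pytest.fixture(scope="module")
def smoke_maps():
    maps = []
    for label in CLASSES:
        for s in range(12):
            maps.append(encode_distance_map(synth_head(label, 300 + s)))
    return maps


@pytest.fixture(scope="module")
def smoke_model(smoke_maps, tmp_path_factory):
    snap = tmp_path_factory.mktemp("snapshots")
    model = gan.train_cgan(
        smoke_maps,
        gan.GANConfig(epochs=40, seed=3, learning_rate=7e-4, n_critic=5, snapshot_every=20),
        snapshot_dir=snap,
    )
    model.meta_snapshot_dir = snap  # stashed for the export test
    return model


class TestTraining:
    def test_losses_finite_and_logged(self, smoke_model):
        log = smoke_model.train_log
        assert len(log["epoch"]) == 40
        assert np.all(np.isfinite(log["critic_loss"]))
        assert np.all(np.isfinite(log["grad_penalty"]))

    def test_critic_generator_update_accounting(self, smoke_model):
        log = smoke_model.train_log
        assert log["total_gen_steps"] == log["total_critic_steps"] // 5

    def test_snapshot_grids_exported(self, smoke_model):
        snaps = sorted(smoke_model.meta_snapshot_dir.glob("epoch_*.png"))
        assert len(snaps) == 2  # every 20 of 40 epochs

    def test_missing_class_rejected(self, smoke_maps):
        partial = [m for m in smoke_maps if m.label != "coronal"]
        with pytest.raises(ValueError, match="missing"):
            gan.train_cgan(partial, gan.GANConfig(epochs=1))

    def test_wasserstein_gap_declines_from_peak(self, benchmark_report):
        """As the generator catches up, the critic's real-fake score gap
        falls well below its training-time peak."""
        log = benchmark_report.artifacts[0]["models"]["gan"].train_log
        gaps = np.asarray(log["score_gap"])
        peak = gaps.max()
        assert gaps[-1] < 0.5 * peak


class TestSampling:
    def test_shape_range_and_determinism(self, smoke_model):
        a = gan.sample_cgan(smoke_model, "sagittal", 4, seed=5)
        b = gan.sample_cgan(smoke_model, "sagittal", 4, seed=5)
        assert all(x.pixels.shape == (28, 28) for x in a)
        assert all((x.pixels >= 0).all() and (x.pixels <= 1).all() for x in a)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))

    def test_unknown_label_rejected(self, smoke_model):
        with pytest.raises(ValueError, match="unknown class"):
            gan.sample_cgan(smoke_model, "lambdoid", 1)

    def test_checkpoint_roundtrip_preserves_samples(self, smoke_model, tmp_path):
        path = tmp_path / "gan.ckpt"
        smoke_model.save(path)
        back = gan.GANModel.load(path)
        a = gan.sample_cgan(smoke_model, "metopic", 3, seed=9)
        b = gan.sample_cgan(back, "metopic", 3, seed=9)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))

    def test_conditioning_matches_requested_class(self, benchmark_report):
        """Sagittal samples of the trained conditional model are closer to
        sagittal training images than to coronal ones (SSIM_cc)."""
        art = benchmark_report.artifacts[0]
        model = art["models"]["gan"]
        train_imgs = art["model_images"]
        sagittal = [m for m in train_imgs if m.label == "sagittal"]
        coronal = [m for m in train_imgs if m.label == "coronal"]
        samples = gan.sample_cgan(model, "sagittal", 50, seed=2)
        same = np.mean([ssim_cc(s, sagittal) for s in samples])
        cross = np.mean([max(ssim(s, c) for c in coronal) for s in samples])
        assert same > cross
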