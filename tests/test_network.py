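"""Network architecture contracts: feature sizes, cumulative risk algebra,
masking/permutation invariances, time embedding, and Grad-CAM."""

import numpy as np
import pytest

from mammorisk import autodiff as ad
from mammorisk.autodiff import Tensor
from mammorisk.cohort import riskf_encoding_dim
from mammorisk.network import (
    Batch,
    ModelConfig,
    RiskModel,
    cumulative_risk,
    cumulative_risk_tensor,
    gradcam_heatmaps,
    load_checkpoint,
    risk_curve,
    save_checkpoint,
    tiny_config,
)

RNG = np.random.default_rng(11)


def random_batch(cfg, b=2, n_priors=(2, 0), seed=3):
    rng = np.random.default_rng(seed)
    t = cfg.max_timepoints
    h, w = cfg.image_size
    images = rng.random((b, t, 4, h, w))
    slot_mask = np.zeros((b, t), dtype=bool)
    intervals = np.zeros((b, t))
    for i, k in enumerate(n_priors):
        slot_mask[i, : k + 1] = True
        intervals[i, 1: k + 1] = np.sort(rng.uniform(10, 80, size=k))
    images *= slot_mask[:, :, None, None, None]
    return Batch(
        images=images, slot_mask=slot_mask, intervals=intervals,
        riskf=rng.normal(size=(b, riskf_encoding_dim())),
        tumor=np.full((b, 2, cfg.tumor_dim), -1.0),
    )


@pytest.fixture(scope="module")
def tiny_model():
    cfg = tiny_config()
    return RiskModel(cfg, seed=0).eval(), cfg


# ---------------------------------------------------------------------------
# cumulative risk head
# ---------------------------------------------------------------------------

class TestCumulativeRisk:
    def test_uniform_logits(self):
        logits = np.zeros(16)
        assert cumulative_risk(logits, 1) == pytest.approx(1 / 16)
        assert cumulative_risk(logits, 10) == pytest.approx(10 / 16)

    def test_healthy_limit(self):
        logits = np.full(16, -30.0)
        logits[0] = 30.0
        for j in (1, 5, 15):
            assert cumulative_risk(logits, j) == pytest.approx(0.0, abs=1e-12)

    def test_matches_prefix_sum_oracle_and_invariants(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(scale=3.0, size=(10_000, 16))
        # independent oracle: plain softmax + prefix sum
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        p = e / e.sum(axis=1, keepdims=True)
        prefix = np.cumsum(p[:, 1:], axis=1)
        curve = risk_curve(logits)
        np.testing.assert_allclose(curve, prefix, atol=1e-12)
        for j in (1, 7, 15):
            np.testing.assert_allclose(cumulative_risk(logits, j),
                                       prefix[:, j - 1], atol=1e-12)
        # probability conservation and monotonicity
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(curve[:, -1], 1.0 - p[:, 0], atol=1e-9)
        assert np.all(np.diff(curve, axis=1) >= -1e-15)

    def test_horizon_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cumulative_risk(np.zeros(16), 0)
        with pytest.raises(ValueError):
            cumulative_risk(np.zeros(16), 16)

    def test_tensor_version_matches_numpy(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(7, 16))
        t = cumulative_risk_tensor(Tensor(logits))
        np.testing.assert_allclose(t.data, risk_curve(logits), atol=1e-12)


# ---------------------------------------------------------------------------
# architectural contracts
# ---------------------------------------------------------------------------

class TestArchitecture:
    def test_paper_scale_dimensions(self):
        """Full-scale config: 512-wide features, 1152 side-MLP input, 640 fused."""
        cfg = ModelConfig()
        assert cfg.feature_dim == 512
        assert 2 * cfg.feature_dim + cfg.tumor_dim == 1152
        assert cfg.fused_dim == 640
        model = RiskModel(cfg, seed=0)
        assert model.side_mlp.fc1.weight.shape == (1152, 512)
        assert model.exam_mlp.fc1.weight.shape == (1024, 512)
        assert model.patient_head.weight.shape == (640, 16)

    def test_output_shapes_and_determinism(self, tiny_model):
        model, cfg = tiny_model
        batch = random_batch(cfg)
        with ad.no_grad():
            o1 = model(batch)
            o2 = model(batch)
        assert o1.tau.shape == (2, cfg.fused_dim)
        assert o1.patient_logits.shape == (2, 16)
        assert o1.breast_logits.shape == (2, 2, 16)
        assert o1.side_risk_logits.shape == (2, 2, 16)
        np.testing.assert_array_equal(o1.tau.data, o2.tau.data)
        np.testing.assert_array_equal(o1.patient_logits.data, o2.patient_logits.data)

    def test_shared_encoder_identical_images_identical_features(self, tiny_model):
        model, cfg = tiny_model
        img = np.random.default_rng(0).random((1, 1, *cfg.image_size))
        with ad.no_grad():
            f1 = model.backbone(Tensor(img)).data
            f2 = model.backbone(Tensor(img.copy())).data
        np.testing.assert_array_equal(f1, f2)
        assert f1.shape == (1, cfg.feature_dim)
        assert np.all(np.isfinite(f1))

    def test_zero_image_gives_finite_features(self, tiny_model):
        model, cfg = tiny_model
        with ad.no_grad():
            f = model.backbone(Tensor(np.zeros((1, 1, *cfg.image_size)))).data
        assert np.all(np.isfinite(f))

    def test_batching_equivariance(self, tiny_model):
        model, cfg = tiny_model
        rng = np.random.default_rng(2)
        imgs = rng.random((8, 1, *cfg.image_size))
        with ad.no_grad():
            full = model.backbone(Tensor(imgs)).data
            one = model.backbone(Tensor(imgs[3:4])).data
        np.testing.assert_allclose(one[0], full[3], atol=1e-5)

    def test_swapping_cc_mlo_changes_output(self, tiny_model):
        model, cfg = tiny_model
        batch = random_batch(cfg)
        swapped = Batch(images=batch.images[:, :, [1, 0, 3, 2]].copy(),
                        slot_mask=batch.slot_mask, intervals=batch.intervals,
                        riskf=batch.riskf, tumor=batch.tumor)
        with ad.no_grad():
            a = model(batch).side_risk_logits.data
            b = model(swapped).side_risk_logits.data
        assert np.abs(a - b).max() > 1e-8

    def test_gradients_reach_every_head(self, tiny_model):
        model, cfg = tiny_model
        from mammorisk import nn
        model2 = RiskModel(cfg, seed=1)  # fresh model, training mode
        nn.seed_dropout(model2, np.random.default_rng(0))
        batch = random_batch(cfg)
        out = model2(batch)
        total = out.patient_logits.sum() + out.breast_logits.sum() \
            + out.side_risk_logits.sum() + out.exam_risk_logits.sum()
        for d in (out.side_aux, out.exam_aux, out.fused_aux):
            for v in d.values():
                total = total + v.sum()
        total.backward()
        for name, p in model2.named_parameters():
            assert p.grad is not None, f"no gradient reached {name}"
            assert np.all(np.isfinite(p.grad)), f"non-finite gradient at {name}"


# ---------------------------------------------------------------------------
# time embedding
# ---------------------------------------------------------------------------

class TestTimeEmbedding:
    def test_zero_interval_is_fixed_reference(self, tiny_model):
        model, _ = tiny_model
        with ad.no_grad():
            a = model.time_embed(np.zeros((1, 3))).data
        assert np.allclose(a[0, 0], a[0, 1]) and np.allclose(a[0, 0], a[0, 2])

    def test_identical_intervals_identical_embeddings(self, tiny_model):
        model, _ = tiny_model
        with ad.no_grad():
            e = model.time_embed(np.array([[12.0, 12.0]])).data
        np.testing.assert_array_equal(e[0, 0], e[0, 1])

    def test_continuity_nearby_intervals_are_closer(self, tiny_model):
        model, _ = tiny_model
        with ad.no_grad():
            e = model.time_embed(np.array([[12.0, 12.1, 60.0]])).data[0]
        assert np.linalg.norm(e[0] - e[1]) < np.linalg.norm(e[0] - e[2])

    def test_lipschitz_on_screening_range(self, tiny_model):
        model, _ = tiny_model
        grid = np.linspace(0, 240, 2401)[None, :]
        with ad.no_grad():
            e = model.time_embed(grid).data[0]
        diffs = np.linalg.norm(np.diff(e, axis=0), axis=1) / 0.1
        assert diffs.max() < 50.0  # bounded empirical Lipschitz constant

    def test_negative_interval_rejected(self, tiny_model):
        model, _ = tiny_model
        with pytest.raises(ValueError):
            model.time_embed(np.array([[-1.0]]))


# ---------------------------------------------------------------------------
# masking and permutation invariance
# ---------------------------------------------------------------------------

class TestMaskingInvariance:
    def test_appending_masked_slot_leaves_outputs_unchanged(self, tiny_model):
        model, cfg = tiny_model
        batch = random_batch(cfg, b=1, n_priors=(2,))
        altered = Batch(images=batch.images.copy(), slot_mask=batch.slot_mask.copy(),
                        intervals=batch.intervals.copy(), riskf=batch.riskf,
                        tumor=batch.tumor)
        # put garbage in a masked slot; the model must zero + ignore it
        altered.images[0, 4] = 7.7
        altered.intervals[0, 4] = 0.0
        with ad.no_grad():
            a = model(batch)
            b = model(altered)
        assert np.abs(a.tau.data - b.tau.data).max() < 1e-6
        assert np.abs(a.patient_logits.data - b.patient_logits.data).max() < 1e-6
        assert np.abs(a.breast_logits.data - b.breast_logits.data).max() < 1e-6

    def test_permuting_priors_with_their_time_embeddings(self, tiny_model):
        """Exam order is carried only by the interval embedding, so permuting
        prior slots together with their intervals is a no-op."""
        model, cfg = tiny_model
        batch = random_batch(cfg, b=1, n_priors=(3,), seed=9)
        perm = [0, 2, 1, 3, 4, 5]  # swap the first two priors
        permuted = Batch(images=batch.images[:, perm].copy(),
                         slot_mask=batch.slot_mask[:, perm].copy(),
                         intervals=batch.intervals[:, perm].copy(),
                         riskf=batch.riskf, tumor=batch.tumor)
        with ad.no_grad():
            a = model(batch)
            b = model(permuted)
        assert np.abs(a.tau.data - b.tau.data).max() < 1e-6
        assert np.abs(a.patient_logits.data - b.patient_logits.data).max() < 1e-6

    def test_stp_reduction_masks_equal_flag(self, tiny_model):
        """use_multitimepoint=False must equal explicitly masking all priors."""
        _, cfg = tiny_model
        import dataclasses
        batch = random_batch(cfg, b=2, n_priors=(3, 1), seed=5)
        masked = Batch(images=batch.images.copy(), slot_mask=batch.slot_mask.copy(),
                       intervals=batch.intervals.copy(), riskf=batch.riskf,
                       tumor=batch.tumor)
        masked.slot_mask[:, 1:] = False
        masked.images[:, 1:] = 0.0
        masked.intervals[:, 1:] = 0.0
        cfg_stp = dataclasses.replace(cfg, use_multitimepoint=False)
        m_full = RiskModel(cfg, seed=7).eval()
        m_stp = RiskModel(cfg_stp, seed=7).eval()   # same seed -> same weights
        with ad.no_grad():
            a = m_full(masked)
            b = m_stp(batch)
        np.testing.assert_array_equal(a.patient_logits.data, b.patient_logits.data)
        np.testing.assert_array_equal(a.tau.data, b.tau.data)


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

class TestGradCam:
    def test_maps_normalised_and_aligned(self, tiny_model):
        model, cfg = tiny_model
        batch = random_batch(cfg, b=1, n_priors=(2,))
        maps = gradcam_heatmaps(model, batch, target="patient", horizon=10)
        t = cfg.max_timepoints
        assert maps.shape == (t, 4, *cfg.image_size)
        assert maps.min() >= 0.0
        for slot in range(3):  # valid slots: target + 2 priors
            for v in range(4):
                m = maps[slot, v]
                assert m.max() == pytest.approx(1.0) or m.max() == 0.0
        assert np.all(maps[3:] == 0)  # masked slots stay empty

    def test_breast_target_accepted(self, tiny_model):
        model, cfg = tiny_model
        batch = random_batch(cfg, b=1, n_priors=(0,))
        maps = gradcam_heatmaps(model, batch, target="breast", side=1, horizon=5)
        assert maps.shape == (cfg.max_timepoints, 4, *cfg.image_size)

    def test_batch_of_two_rejected(self, tiny_model):
        model, cfg = tiny_model
        with pytest.raises(ValueError):
            gradcam_heatmaps(model, random_batch(cfg, b=2))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

class TestCheckpoint:
    def test_round_trip_and_config_guard(self, tiny_model, tmp_path):
        model, cfg = tiny_model
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path, config=cfg)
        batch = random_batch(cfg)
        with ad.no_grad():
            a = model(batch).patient_logits.data
            b = restored.eval()(batch).patient_logits.data
        np.testing.assert_array_equal(a, b)
        other = tiny_config(feature_dim=32, tumor_dim=32)
        with pytest.raises(ValueError):
            load_checkpoint(path, config=other)
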