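import numpy as np
import pytest

from conftest import tiny_cnn
from oracles import finite_difference_alphas
from usconf import nn
from usconf.gradcam import align_map, gradcam_raw, normalize_map
from usconf.roi import RoiResult


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_alphas_match_finite_differences(seed):
    """Channel importances from backprop agree with a central-difference
    oracle on seeded tiny CNNs, and so does the assembled map."""
    model = tiny_cnn(seed)
    rng = np.random.default_rng(100 + seed)
    x = rng.normal(size=(1, 1, 8, 8))
    layer_idx = 3  # last spatial (second ReLU)
    cam = gradcam_raw(model, x, target_class=1, layer_id=layer_idx)

    alpha_fd = np.array(finite_difference_alphas(model, x, 1, layer_idx))
    model.forward(x)
    A = model.activations[layer_idx + 1][0]
    seed_grad = np.zeros((1, 3))
    seed_grad[0, 1] = 1.0
    dA = model.grad_wrt_activation(layer_idx, seed_grad)
    Z = A.shape[1] * A.shape[2]
    alpha_ad = dA[0].sum(axis=(1, 2)) / Z

    np.testing.assert_allclose(alpha_ad, alpha_fd, rtol=1e-3, atol=1e-8)
    raw_fd = np.maximum((alpha_fd[:, None, None] * A).sum(axis=0), 0.0)
    np.testing.assert_allclose(cam.raw, raw_fd, rtol=1e-3, atol=1e-8)


def test_default_layer_and_class_selection():
    model = tiny_cnn(0)
    x = np.random.default_rng(0).normal(size=(1, 1, 8, 8))
    cam = gradcam_raw(model, x)
    assert cam.layer_id == model.last_spatial_index()
    logits = model.forward(x)
    assert cam.target_class == int(np.argmax(logits[0]))
    assert (cam.raw >= 0).all()


def test_mean_score_model_gives_map_proportional_to_feature():
    """If the class score is the mean of a single feature map, the raw map
    is ReLU(A)/Z up to the constant alpha = 1/Z."""
    rng = np.random.default_rng(3)
    model = nn.Sequential([
        nn.Conv2D(1, 1, 3, rng), nn.GlobalAvgPool(), nn.Linear(1, 1, rng),
    ])
    model.layers[2].W[...] = 1.0
    model.layers[2].b[...] = 0.0
    x = rng.normal(size=(1, 1, 6, 6))
    model.forward(x)
    A = model.activations[1][0, 0]
    cam = gradcam_raw(model, x, target_class=0, layer_id=0)
    np.testing.assert_allclose(cam.raw, np.maximum(A, 0.0) / A.size, atol=1e-12)


def test_joint_alpha_feature_scaling_squares_raw_map():
    """When the importance weights and the feature maps each pick up a
    factor s, the assembled map scales by s^2 (numeric check on a real
    model's activations and gradients)."""
    model = tiny_cnn(1)
    x = np.random.default_rng(7).normal(size=(1, 1, 8, 8))
    layer_idx = 3
    model.forward(x)
    A = model.activations[layer_idx + 1]
    seed_grad = np.zeros((1, 3))
    seed_grad[0, 0] = 1.0
    dA = model.grad_wrt_activation(layer_idx, seed_grad)
    alpha = dA[0].sum(axis=(1, 2)) / (A.shape[2] * A.shape[3])
    raw = np.maximum((alpha[:, None, None] * A[0]).sum(axis=0), 0.0)
    s = 3.0
    scaled = np.maximum(((s * alpha)[:, None, None] * (s * A[0])).sum(axis=0), 0.0)
    np.testing.assert_allclose(scaled, s**2 * raw, atol=1e-12)


def test_normalize_examples():
    np.testing.assert_allclose(
        normalize_map(np.array([[0.0, 2.0], [4.0, 8.0]])),
        np.array([[0.0, 0.25], [0.5, 1.0]]),
    )
    assert (normalize_map(np.full((3, 3), 5.0)) == 0.0).all()
    already = np.array([[0.0, 0.5], [0.25, 1.0]])
    np.testing.assert_allclose(normalize_map(already), already)
    with pytest.raises(ValueError):
        normalize_map(np.array([[-1.0, 0.0]]))


def test_align_identity_and_zero():
    m = np.random.default_rng(0).random((10, 6))
    roi = RoiResult(image_roi=m, row_offset=0, rows_kept=10)
    np.testing.assert_allclose(align_map(m, (10, 6), roi), m, atol=1e-12)
    assert (align_map(np.zeros((4, 4)), (10, 6), roi) == 0.0).all()


def test_align_bilinear_upsample_closed_form():
    """2x2 -> 4x4 bilinear: corners preserved, interior follows the
    closed-form bilinear weights at half-pixel sample centers."""
    small = np.array([[0.0, 1.0], [1.0, 0.0]])
    up = align_map(small, (4, 4), RoiResult(None, 0, 4))
    # sample centers map to source coords (-0.25, 0.25, 0.75, 1.25), clamped
    src = np.clip(np.array([-0.25, 0.25, 0.75, 1.25]), 0, 1)
    expected = np.empty((4, 4))
    for i, y in enumerate(src):
        for j, x in enumerate(src):
            expected[i, j] = (small[0, 0] * (1 - y) * (1 - x)
                              + small[0, 1] * (1 - y) * x
                              + small[1, 0] * y * (1 - x)
                              + small[1, 1] * y * x)
    np.testing.assert_allclose(up, expected, atol=1e-12)


def test_align_places_strip_at_offset():
    m = np.ones((2, 3))
    roi = RoiResult(None, row_offset=4, rows_kept=4)
    out = align_map(m, (10, 3), roi)
    assert (out[4:8] == 1.0).all()
    assert (out[:4] == 0.0).all() and (out[8:] == 0.0).all()


def test_align_argmax_preserved_on_peaked_map():
    m = np.zeros((5, 5))
    m[3, 1] = 1.0
    out = align_map(m, (20, 20), RoiResult(None, 0, 20))
    i, j = np.unravel_index(np.argmax(out), out.shape)
    assert abs(i / 4 - 3) <= 0.6 and abs(j / 4 - 1) <= 0.6


def test_align_rejects_inconsistent_offsets():
    with pytest.raises(ValueError):
        align_map(np.ones((2, 2)), (5, 5), RoiResult(None, 4, 4))


def test_gradcam_requires_spatial_layer():
    model = tiny_cnn(0)
    x = np.zeros((1, 1, 8, 8))
    with pytest.raises(ValueError, match="spatial"):
        gradcam_raw(model, x, target_class=0, layer_id=5)  # Linear head
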