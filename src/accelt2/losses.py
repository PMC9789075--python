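"""Multi-component, ROI-specific training losses.

The training objective is a weighted sum of four terms computed between a
predicted and a ground-truth T2 map::

    L = lam_l1 * L_l1 + lam_l1_roi * L_l1_roi + lam_ssim * L_ssim
        + lam_feature * L_feature

* ``L_l1`` / ``L_l1_roi``: mean absolute difference of sigmoid-scaled maps,
  globally and over the tissue-of-interest pixels.  The sigmoid operator
  re-weights the T2 axis so errors at high T2 (where sharp, clinically
  relevant contrasts live) cost more than errors in low-T2 background.
* ``L_ssim``: 1 - SSIM on maps clipped to a declared dynamic range.
* ``L_feature``: mean absolute difference of deep convolutional features of
  the two maps (a perceptual loss); the feature extractor is injected so a
  pretrained 19-layer VGG-style stack can be used when its weights are
  available, and a fixed-seed random stack with the same interface
  otherwise.

All terms are differentiable through the package autograd engine; numpy
arrays are accepted and evaluated without a tape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor
from .nn.layers import Conv2d, Module, ReLU, Sequential

__all__ = ["SigmoidParams", "LossWeights", "AnatomyPreset", "PRESETS",
           "sigmoid_scale", "l1_scaled", "l1_scaled_roi", "ssim_loss",
           "feature_loss", "network_loss", "RandomConvFeatures"]


@dataclass(frozen=True)
class SigmoidParams:
    """Translated/scaled sigmoid: S maps T2 (ms) into (y_l, y_h)."""

    x_l: float
    x_h: float
    y_l: float
    y_h: float

    def __post_init__(self):
        if not self.x_l < self.x_h:
            raise ValueError("require x_l < x_h")
        if not (0 < self.y_l <= self.y_h):
            raise ValueError("require 0 < y_l <= y_h")


@dataclass(frozen=True)
class LossWeights:
    lam_l1: float = 1.0
    lam_l1_roi: float = 100.0
    lam_ssim: float = 1.0
    lam_feature: float = 0.0

    def __post_init__(self):
        vals = (self.lam_l1, self.lam_l1_roi, self.lam_ssim, self.lam_feature)
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be >= 0")
        if all(v == 0 for v in vals):
            raise ValueError("at least one loss weight must be positive")


@dataclass(frozen=True)
class AnatomyPreset:
    anatomy: str
    sigmoid: SigmoidParams
    # random-search ranges (lo, hi) per weight
    lam_l1_range: tuple
    lam_l1_roi_range: tuple
    lam_ssim_range: tuple
    lam_feature_range: tuple
    signal_scale_target: float  # upper end of per-slice signal scaling


PRESETS = {
    "knee": AnatomyPreset(
        "knee", SigmoidParams(0.0, 100.0, 0.1, 1.0),
        (1.0, 1.0), (50.0, 150.0), (0.0, 2.0), (0.0, 0.5), 500.0),
    "hip": AnatomyPreset(
        "hip", SigmoidParams(0.0, 60.0, 0.5, 1.0),
        (1.0, 1.0), (0.0, 3.0), (0.0, 2.0), (0.0, 1.0), 100.0),
    "spine": AnatomyPreset(
        "spine", SigmoidParams(0.0, 150.0, 0.25, 1.0),
        (1.0, 1.0), (1.0, 10.0), (10.0, 100.0), (5.0, 55.0), 500.0),
}


def _is_tensor(x):
    return isinstance(x, Tensor)


def sigmoid_scale(x, p: SigmoidParams):
    """S(x) = y_l + (y_h - y_l) / (1 + exp(-(10/(x_h-x_l)) (x - (x_l+x_h)/2))).

    Strictly increasing with open range (y_l, y_h); works on floats, numpy
    arrays and autograd tensors.
    """
    k = 10.0 / (p.x_h - p.x_l)
    mid = 0.5 * (p.x_l + p.x_h)
    if _is_tensor(x):
        z = ((x - mid) * (-k)).exp()
        return p.y_l + (p.y_h - p.y_l) / (1.0 + z)
    z = np.exp(-k * (np.asarray(x, dtype=float) - mid))
    out = p.y_l + (p.y_h - p.y_l) / (1.0 + z)
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def l1_scaled(t2_true, t2_pred, p: SigmoidParams):
    """Mean |S(T2) - S(T2_hat)| over all pixels."""
    st = sigmoid_scale(_as_const(t2_true), p)
    sp = sigmoid_scale(t2_pred, p)
    diff = (sp - st) if _is_tensor(sp) else np.asarray(sp) - np.asarray(st)
    return diff.abs().mean() if _is_tensor(diff) else float(np.abs(diff).mean())


def l1_scaled_roi(t2_true, t2_pred, roi, p: SigmoidParams):
    """Mean |S(T2) - S(T2_hat)| over tissue-of-interest pixels."""
    roi = np.asarray(roi) > 0
    n = int(roi.sum())
    if n == 0:
        raise ValueError("empty ROI: tissue segmentation missing")
    st = sigmoid_scale(_as_const(t2_true), p)
    sp = sigmoid_scale(t2_pred, p)
    if _is_tensor(sp):
        w = roi.astype(sp.dtype)
        return ((sp - st) * w).abs().sum() / float(n)
    return float(np.abs(np.asarray(sp) - np.asarray(st))[roi].mean())


def _as_const(x):
    return x.data if _is_tensor(x) else np.asarray(x, dtype=float)


def _uniform_filter_valid(x: Tensor, win: int) -> Tensor:
    """Mean filter with a win x win window, valid region only (N,1,H,W)."""
    kernel = Tensor(np.full((1, 1, win, win), 1.0 / win**2, dtype=x.dtype))
    return x.conv2d(kernel, None, stride=1, padding=0)


def ssim_loss(t2_true, t2_pred, data_range: float | None = None,
              win: int = 7, k1: float = 0.01, k2: float = 0.03):
    """1 - SSIM between two maps.

    Maps are clipped to [0, data_range] and rescaled to [0, 1]; SSIM uses a
    uniform win x win window (matching the common library default) with
    stabilisation constants C1 = (k1)^2, C2 = (k2)^2 on the unit range, and
    is averaged over the valid (fully covered) window positions.
    """
    xt = _as_const(t2_true)
    tensor_mode = _is_tensor(t2_pred)
    if data_range is None:
        data_range = float(max(xt.max(), float(
            t2_pred.data.max() if tensor_mode else np.max(t2_pred)), 1e-6))
    xp = t2_pred if tensor_mode else Tensor(np.asarray(t2_pred, dtype=float))
    xt = np.clip(xt, 0, data_range) / data_range
    xp = xp.clip(0.0, data_range) / data_range

    a = Tensor(xt.reshape(1, 1, *xt.shape[-2:]))
    b = xp.reshape(1, 1, *xp.data.shape[-2:])
    c1, c2 = k1**2, k2**2
    mu_a = _uniform_filter_valid(a, win)
    mu_b = _uniform_filter_valid(b, win)
    # sample (unbiased) variances/covariance, as in the standard formulation
    npix = win * win
    corr = npix / (npix - 1.0)
    var_a = (_uniform_filter_valid(a * a, win) - mu_a * mu_a) * corr
    var_b = (_uniform_filter_valid(b * b, win) - mu_b * mu_b) * corr
    cov = (_uniform_filter_valid(a * b, win) - mu_a * mu_b) * corr
    num = (mu_a * mu_b * 2.0 + c1) * (cov * 2.0 + c2)
    den = (mu_a * mu_a + mu_b * mu_b + c1) * (var_a + var_b + c2)
    ssim = (num / den).mean()
    loss = 1.0 - ssim
    return loss if tensor_mode else float(loss.data)


class RandomConvFeatures(Module):
    """Fixed-seed random convolutional feature stack.

    Drop-in extractor with the same interface as a pretrained deep feature
    network: maps (N, 3, 224, 224) inputs to a mid-depth feature volume.
    Weights are frozen; the stack is reproducible bit-exactly from its seed.
    """

    def __init__(self, seed: int = 0, depths=(16, 32, 64), dtype=np.float64):
        super().__init__()
        rng = np.random.default_rng(seed)
        mods = []
        ci = 3
        for co in depths:
            conv = Conv2d(ci, co, kernel=3, stride=2, padding=1, rng=rng,
                          dtype=dtype)
            conv.weight.requires_grad = False
            conv.bias.requires_grad = False
            mods += [conv, ReLU()]
            ci = co
        self.stack = Sequential(*mods)

    def forward(self, x: Tensor) -> Tensor:
        return self.stack(x)


_IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
_IMAGENET_STD = np.array([0.229, 0.224, 0.225])


def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Linear-interpolation matrix mapping length n_in to n_out
    (align-corners-false convention)."""
    m = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for i in range(n_out):
        pos = (i + 0.5) * scale - 0.5
        lo = int(np.floor(pos))
        w = pos - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        m[i, lo_c] += 1 - w
        m[i, hi_c] += w
    return m


def feature_loss(t2_true, t2_pred, extractor, data_range: float = 150.0,
                 size: int = 224):
    """Mean absolute difference of deep features of the two maps.

    Maps are linearly resized to ``size x size``, scaled to [0, 1] by
    ``data_range``, tripled along the channel axis and normalized with the
    standard per-channel means/s.d. (0.485/0.456/0.406, 0.229/0.224/0.225)
    before feature extraction.
    """
    if extractor is None:
        raise ValueError("no feature extractor supplied and no fallback")
    xt = _as_const(t2_true)
    tensor_mode = _is_tensor(t2_pred)
    xp = t2_pred if tensor_mode else Tensor(np.asarray(t2_pred, dtype=float))

    h, w = xt.shape[-2:]
    my = _resize_matrix(h, size)
    mx = _resize_matrix(w, size)

    def prep(img):
        t = img if _is_tensor(img) else Tensor(img)
        t = t.reshape(1, 1, h, w).resample(my, mx).clip(0.0, data_range) \
            / data_range
        from .nn.autograd import concat
        t3 = concat([t, t, t], axis=1)
        mean = _IMAGENET_MEAN.reshape(1, 3, 1, 1)
        std = _IMAGENET_STD.reshape(1, 3, 1, 1)
        return (t3 - Tensor(mean)) / Tensor(std)

    fa = extractor(prep(xt))
    fb = extractor(prep(xp))
    loss = (fb - fa).abs().mean()
    return loss if tensor_mode else float(loss.data)


def network_loss(t2_true, t2_pred, roi, weights: LossWeights,
                 sigmoid: SigmoidParams, extractor=None,
                 ssim_range: float | None = None):
    """Weighted multi-component objective with per-component breakdown.

    Any subset of weights may be zero (ablation configurations); zero-weight
    components are skipped entirely.  Returns ``(total, components)`` where
    components maps names to floats.
    """
    tensor_mode = _is_tensor(t2_pred)
    total = Tensor(np.asarray(0.0)) if tensor_mode else 0.0
    comps = {}
    if ssim_range is None:
        ssim_range = 1.5 * sigmoid.x_h
    if weights.lam_l1 > 0:
        c = l1_scaled(t2_true, t2_pred, sigmoid)
        comps["l1"] = float(c.data) if tensor_mode else c
        total = total + weights.lam_l1 * c
    if weights.lam_l1_roi > 0:
        c = l1_scaled_roi(t2_true, t2_pred, roi, sigmoid)
        comps["l1_roi"] = float(c.data) if tensor_mode else c
        total = total + weights.lam_l1_roi * c
    if weights.lam_ssim > 0:
        c = ssim_loss(t2_true, t2_pred, data_range=ssim_range)
        comps["ssim"] = float(c.data) if tensor_mode else c
        total = total + weights.lam_ssim * c
    if weights.lam_feature > 0:
        c = feature_loss(t2_true, t2_pred, extractor, data_range=ssim_range)
        comps["feature"] = float(c.data) if tensor_mode else c
        total = total + weights.lam_feature * c
    return total, comps
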