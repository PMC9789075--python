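"""Desk-scale training of the reconstruction network.

Implements the optimisation protocol used for the reconstruction
pipelines: per-slice signal scaling, paired spatial augmentation
(translation and rotation applied identically to all echo images, the
target map and the ROI mask), Adam at learning rate 1e-3 with batch size
1, early stopping on validation loss with a 10-epoch patience, and the
constrained random hyperparameter search over the loss-component weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .losses import PRESETS, AnatomyPreset, LossWeights, network_loss
from .metrics import pearson_roi, roi_nrmse
from .nn.autograd import Tensor, no_grad
from .nn.optim import Adam
from .phantom import EchoSeries

__all__ = ["TrainConfig", "TrainSample", "TrainResults", "scale_signals",
           "augment_sample", "train", "hyperparameter_search"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 1
    max_epochs: int = 100
    patience: int = 10                 # early-stop epochs without improvement
    translate_px: float = 10.0         # +/- in-plane translation
    rotate_deg: float = 5.0            # +/- rotation about the slice axis
    augment: bool = True
    anatomy: str = "knee"
    seed: int = 0
    search_iterations: int = 15
    search_epochs: int = 10

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.translate_px < 0 or self.rotate_deg < 0:
            raise ValueError("augmentation bounds must be non-negative")


@dataclass
class TrainSample:
    """One training slice: scaled echo images, target map, ROI mask."""

    echoes: np.ndarray   # (n_echoes, n_y, n_x)
    target: np.ndarray   # (n_y, n_x) ground-truth T2 (ms)
    roi: np.ndarray      # (n_y, n_x) boolean / labels


def scale_signals(echo_series: EchoSeries, anatomy: str = "knee",
                  preset: AnatomyPreset | None = None) -> EchoSeries:
    """Per-slice linear scaling of signal intensities.

    The middle 95% of pixel values of a slice (2.5th..97.5th percentile,
    computed jointly over its echo images so the relative decay is
    untouched) is mapped onto [0, target], target = 500 for knee and spine,
    100 for the hip.
    """
    preset = preset or PRESETS[anatomy]
    target = preset.signal_scale_target
    data = echo_series.data.astype(float).copy()
    for z in range(data.shape[3]):
        sl = data[:, :, :, z]
        lo, hi = np.percentile(sl, [2.5, 97.5])
        if hi <= lo:
            import warnings
            warnings.warn(f"slice {z} is constant; left unscaled")
            continue
        data[:, :, :, z] = (sl - lo) * (target / (hi - lo))
    return EchoSeries(data=data, echo_times=echo_series.echo_times)


def augment_sample(sample: TrainSample, rng: np.random.Generator,
                   translate_px: float, rotate_deg: float) -> TrainSample:
    """Random rigid in-plane transform, identical for every channel.

    Images and target are resampled bilinearly, the ROI mask with nearest
    neighbour; out-of-frame pixels are zero-filled.
    """
    ty = rng.uniform(-translate_px, translate_px)
    tx = rng.uniform(-translate_px, translate_px)
    ang = rng.uniform(-rotate_deg, rotate_deg)

    def xform(img, order):
        out = ndimage.rotate(img, ang, reshape=False, order=order, cval=0.0)
        return ndimage.shift(out, (ty, tx), order=order, cval=0.0)

    echoes = np.stack([xform(e, 1) for e in sample.echoes])
    target = xform(sample.target, 1)
    roi = xform(sample.roi.astype(float), 0).astype(sample.roi.dtype)
    return TrainSample(echoes=echoes, target=target, roi=roi)


@dataclass
class TrainResults:
    """Best-validation checkpoint plus per-epoch history."""

    model: object
    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float
    best_state: dict = field(repr=False, default=None)


def _epoch_pass(model, samples, weights, preset, extractor, optimizer, rng,
                cfg):
    """One pass over ``samples``; trains when ``optimizer`` is given."""
    training = optimizer is not None
    order = rng.permutation(len(samples)) if training else range(len(samples))
    total, comps_acc = 0.0, {}
    for i in order:
        s = samples[i]
        if training and cfg.augment:
            s = augment_sample(s, rng, cfg.translate_px, cfg.rotate_deg)
        x = Tensor(s.echoes[None].astype(np.float32))
        if training:
            model.train()
            pred = model(x)
            loss, comps = network_loss(s.target.astype(np.float32),
                                       pred.reshape(*s.target.shape),
                                       s.roi, weights, preset.sigmoid,
                                       extractor=extractor)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            val = float(loss.data)
        else:
            model.eval()
            with no_grad():
                pred = model(x)
            loss, comps = network_loss(s.target.astype(np.float32),
                                       pred.data.reshape(s.target.shape),
                                       s.roi, weights, preset.sigmoid,
                                       extractor=extractor)
            val = float(loss)
        total += val
        for k, v in comps.items():
            comps_acc[k] = comps_acc.get(k, 0.0) + v
    n = len(samples)
    return total / n, {k: v / n for k, v in comps_acc.items()}


def train(model, train_samples, val_samples, config: TrainConfig,
          weights: LossWeights | None = None, extractor=None) -> TrainResults:
    """Train with Adam, batch 1, per-step augmentation and early stopping.

    Returns the checkpoint with the minimum validation loss (not the last
    epoch).  Fully seeded: identical seeds give identical loss curves.
    """
    if not train_samples:
        raise ValueError("empty training set")
    if not val_samples:
        raise ValueError("empty validation set")
    preset = PRESETS[config.anatomy]
    weights = weights or LossWeights()
    if extractor is None and weights.lam_feature > 0:
        from .losses import RandomConvFeatures
        extractor = RandomConvFeatures(seed=config.seed)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)

    rows = []
    best = (np.inf, -1, None)
    for epoch in range(config.max_epochs):
        tr_loss, tr_comps = _epoch_pass(model, train_samples, weights, preset,
                                        extractor, opt, rng, config)
        va_loss, _ = _epoch_pass(model, val_samples, weights, preset,
                                 extractor, None, rng, config)
        rows.append({"epoch": epoch, "train_loss": tr_loss,
                     "val_loss": va_loss,
                     **{f"train_{k}": v for k, v in tr_comps.items()}})
        if va_loss < best[0]:
            best = (va_loss, epoch, model.state_dict())
        elif epoch - best[1] >= config.patience:
            break
    if best[2] is not None:
        model.load_state_dict(best[2])
    return TrainResults(model=model, history=pd.DataFrame(rows),
                        best_epoch=best[1], best_val_loss=best[0],
                        best_state=best[2])


def _sample_weights(rng, preset: AnatomyPreset) -> LossWeights:
    def draw(rg):
        lo, hi = rg
        return lo if hi == lo else float(rng.uniform(lo, hi))

    return LossWeights(lam_l1=draw(preset.lam_l1_range),
                       lam_l1_roi=draw(preset.lam_l1_roi_range),
                       lam_ssim=draw(preset.lam_ssim_range),
                       lam_feature=draw(preset.lam_feature_range))


def hyperparameter_search(model_factory, train_samples, val_samples,
                          config: TrainConfig, extractor=None):
    """Constrained random search over loss-component weights.

    Weights are drawn uniformly within the anatomy's ranges; each draw is
    trained for ``config.search_epochs`` epochs and scored on validation
    ROI NRMSE (ascending) and ROI Pearson r (descending); the winner
    minimises the rank sum of the two criteria.

    Returns ``(best_weights, results_frame)``.
    """
    preset = PRESETS[config.anatomy]
    rng = np.random.default_rng(config.seed)
    rows = []
    for it in range(config.search_iterations):
        w = _sample_weights(rng, preset)
        model = model_factory(seed=config.seed + 1000 + it)
        short = replace(config, max_epochs=config.search_epochs,
                        patience=max(config.patience, config.search_epochs),
                        seed=config.seed + it)
        train(model, train_samples, val_samples, short, weights=w,
              extractor=extractor)
        nr, rs = [], []
        model.eval()
        for s in val_samples:
            with no_grad():
                pred = model(Tensor(s.echoes[None].astype(np.float32)))
            pmap = pred.data.reshape(s.target.shape)
            nr.append(roi_nrmse(s.target, pmap, s.roi))
            try:
                rs.append(pearson_roi(s.target, pmap, s.roi)[0])
            except ValueError:
                rs.append(0.0)
        rows.append({"iteration": it, "lam_l1": w.lam_l1,
                     "lam_l1_roi": w.lam_l1_roi, "lam_ssim": w.lam_ssim,
                     "lam_feature": w.lam_feature,
                     "val_nrmse": float(np.mean(nr)),
                     "val_pearson_r": float(np.mean(rs))})
    frame = pd.DataFrame(rows)
    rank = frame["val_nrmse"].rank() + frame["val_pearson_r"].rank(
        ascending=False)
    ibest = int(rank.idxmin())
    row = frame.loc[ibest]
    best = LossWeights(lam_l1=row["lam_l1"], lam_l1_roi=row["lam_l1_roi"],
                       lam_ssim=row["lam_ssim"],
                       lam_feature=row["lam_feature"])
    return best, frame
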