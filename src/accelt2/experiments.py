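"""Canned desk-scale experiments.

These bundle the study conditions used to validate the toolkit end to end:
the zero-fill degradation trend across acceleration factors, and the
smoke-scale training benchmark comparing a trained Reduced-Parameters
network against the zero-fill fitting baseline at R = 4.  Problem sizes
are chosen so each experiment runs in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import fit_t2
from .losses import LossWeights
from .metrics import roi_nrmse
from .model import (ModelConfig, UNET_ENCODER_DEPTHS, build_model,
                    n_levels_for_grid, predict_map)
from .phantom import PhantomConfig, generate_phantom
from .training import TrainConfig, TrainSample, scale_signals, train
from .undersample import SamplingPlan, undersample_volume

__all__ = ["zero_fill_r_trend", "smoke_training_benchmark",
           "SmokeTrainResult"]


def zero_fill_r_trend(seeds=range(10), accelerations=(2.0, 4.0, 8.0),
                      grid=(64, 64, 8), anatomy="knee"):
    """ROI NRMSE of zero-fill-fitted T2 maps per phantom seed and R.

    Returns an array of shape (n_seeds, n_R).  Averaged over seeds the
    error is expected to grow with the acceleration factor.
    """
    rows = []
    for seed in seeds:
        ph = generate_phantom(PhantomConfig(grid=grid, anatomy=anatomy,
                                            seed=int(seed)))
        row = []
        for R in accelerations:
            plan = SamplingPlan(R=float(R), grid=(grid[0], grid[2]),
                                seed=int(seed))
            aliased, _ = undersample_volume(ph.echo_series, plan)
            zf = fit_t2(aliased).masked()
            row.append(roi_nrmse(ph.t2_true, zf, ph.roi.mask))
        rows.append(row)
    return np.asarray(rows)


@dataclass
class SmokeTrainResult:
    model_nrmse: list
    zero_fill_nrmse: list
    history: object
    best_epoch: int

    @property
    def model_mean(self) -> float:
        return float(np.mean(self.model_nrmse))

    @property
    def zero_fill_mean(self) -> float:
        return float(np.mean(self.zero_fill_nrmse))


def _aliased_samples(seed, R, grid, anatomy, slices):
    ph = generate_phantom(PhantomConfig(grid=grid, anatomy=anatomy,
                                        seed=int(seed)))
    plan = SamplingPlan(R=float(R), grid=(grid[0], grid[2]), seed=int(seed))
    aliased, _ = undersample_volume(ph.echo_series, plan)
    scaled = scale_signals(aliased, anatomy)
    samples = [TrainSample(echoes=scaled.slice(z),
                           target=ph.t2_true[:, :, z],
                           roi=ph.roi.labels[:, :, z]) for z in slices]
    return ph, aliased, samples


def smoke_training_benchmark(seed: int = 0, R: float = 4.0,
                             n_train_phantoms: int = 16,
                             n_val_phantoms: int = 4,
                             n_test_phantoms: int = 4,
                             grid=(32, 32, 8), anatomy="knee",
                             max_epochs: int = 10,
                             patience: int = 4) -> SmokeTrainResult:
    """Train a Reduced-Parameters network at desk scale and compare its
    ROI NRMSE on held-out phantoms against the zero-fill fitting baseline.

    Two slices per training phantom, the middle slice for validation and
    test.  The UNet encoder depth list is truncated to fit the slice size;
    the loss uses the knee preset sigmoid with weights
    (lam_l1, lam_l1_roi, lam_ssim, lam_feature) = (1, 100, 1, 0).
    """
    base = int(seed) * 10_000
    train_s, val_s = [], []
    for i in range(n_train_phantoms):
        train_s += _aliased_samples(base + 100 + i, R, grid, anatomy,
                                    (3, 5))[2]
    for i in range(n_val_phantoms):
        val_s += _aliased_samples(base + 900 + i, R, grid, anatomy, (4,))[2]

    n_lev = n_levels_for_grid(grid[0], grid[1])
    mcfg = ModelConfig(variant="reduced",
                       unet_encoder_depths=UNET_ENCODER_DEPTHS[:n_lev],
                       seed=base + 1)
    model = build_model(mcfg)
    tcfg = TrainConfig(anatomy=anatomy, max_epochs=max_epochs,
                       patience=patience, seed=base + 3,
                       translate_px=3.0, rotate_deg=5.0)
    res = train(model, train_s, val_s, tcfg,
                weights=LossWeights(1.0, 100.0, 1.0, 0.0))

    model_nr, zf_nr = [], []
    for i in range(n_test_phantoms):
        ph, aliased, samples = _aliased_samples(base + 500 + i, R, grid,
                                                anatomy, (4,))
        s = samples[0]
        pred = predict_map(model, s.echoes)
        zf = fit_t2(aliased).masked()
        model_nr.append(roi_nrmse(ph.t2_true[:, :, 4], pred, s.roi))
        zf_nr.append(roi_nrmse(ph.t2_true[:, :, 4], zf[:, :, 4], s.roi))
    return SmokeTrainResult(model_nrmse=model_nr, zero_fill_nrmse=zf_nr,
                            history=res.history, best_epoch=res.best_epoch)
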