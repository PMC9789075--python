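"""Basic figures: Bland-Altman agreement and training curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .metrics import AgreementReport

__all__ = ["bland_altman_plot", "training_curves_plot"]


def bland_altman_plot(report: AgreementReport, ax=None, unit="ms"):
    """Scatter of pair means vs differences with bias and limits of
    agreement."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(report.means, report.diffs, s=18, alpha=0.8)
    ax.axhline(report.bias, color="k", lw=1.2,
               label=f"bias {report.bias:+.2f} {unit}")
    for y, style in ((report.loa_low, "--"), (report.loa_high, "--")):
        ax.axhline(y, color="gray", ls=style, lw=1.0)
    ax.set_xlabel(f"mean of pair ({unit})")
    ax.set_ylabel(f"difference pred - true ({unit})")
    ax.legend(loc="best", frameon=False)
    return ax


def training_curves_plot(history, ax=None):
    """Training/validation loss per epoch from a train() history frame."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(history["epoch"], history["train_loss"], label="train")
    ax.plot(history["epoch"], history["val_loss"], label="validation")
    ax.set_xlabel("epoch")
    ax.set_ylabel("loss")
    ax.legend(loc="best", frameon=False)
    return ax
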