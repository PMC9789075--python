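"""Recurrent-UNet architecture for multi-echo T2 map prediction.

Three variants map the 4 aliased echo images of a slice to one T2 map:

* ``full`` — a recurrent front end followed by a UNet.  Every echo image
  passes through the *same* 5-layer stream of 3x3 stride-1 convolutions
  (depths 64, 128, 256, 512, 1; batch-normalised hidden layers) with a
  residual connection from the input image to the stream output.  At each
  hidden layer a 3x3 convolution carries the corresponding hidden state of
  the temporally adjacent (earlier) echo into the current echo, scaled by
  a weighting factor lambda_w = 0.2 — soft weighted view-sharing of
  neighbouring echo-time feature maps.  The four stream outputs are
  concatenated and fed to the UNet.
* ``no_rnn`` — the UNet alone on the concatenated aliased inputs.
* ``reduced`` — the full model with every layer depth halved except the
  inputs to the recurrent portion and to the UNet (single-channel layers
  stay single-channel).

The UNet encoder is a stack of 3x3 stride-2 convolutions with channel
depths (64, 128, 256, 512, 512, 512, 512); the decoder mirrors it with
4x4 stride-2 transposed convolutions and concatenation skips; every
convolution except the output layer is batch-normalised (and therefore
carries no bias); a bias-free 1x1 convolution adds an input-to-output
residual.  With these depths the trainable-parameter counts of the three
variants reproduce the printed values 39,808,710 / 35,116,037 / 9,958,246
exactly; those counts act as the specification of record for details the
architecture figure leaves ambiguous.

For inputs smaller than the native 256x128 slice grid the encoder depth
list can be truncated (``n_levels_for_grid``) so the bottleneck stays at
least one pixel; the variant halving rule is unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor, concat, no_grad
from .nn.layers import BatchNorm2d, Conv2d, ConvTranspose2d, Module

__all__ = ["ModelConfig", "RecurrentUNet", "build_model", "predict_map",
           "PARAMETER_COUNTS", "n_levels_for_grid"]

# printed trainable-parameter counts per variant (specification of record)
PARAMETER_COUNTS = {"full": 39_808_710, "no_rnn": 35_116_037,
                    "reduced": 9_958_246}

STREAM_DEPTHS = (64, 128, 256, 512, 1)
UNET_ENCODER_DEPTHS = (64, 128, 256, 512, 512, 512, 512)


def n_levels_for_grid(n_y: int, n_x: int) -> int:
    """Deepest UNet that keeps a >= 1-pixel bottleneck for this slice size."""
    m = min(n_y, n_x)
    return max(1, min(len(UNET_ENCODER_DEPTHS), int(np.log2(m))))


@dataclass
class ModelConfig:
    variant: str = "full"
    n_echoes: int = 4
    stream_depths: tuple = STREAM_DEPTHS
    unet_encoder_depths: tuple = UNET_ENCODER_DEPTHS
    lambda_w: float = 0.2
    reverse_stream_direction: bool = False
    output_bias_init: float = 40.0  # ms; typical tissue T2 starting level
    seed: int = 0
    dtype: object = np.float32

    def __post_init__(self):
        if self.variant not in ("full", "no_rnn", "reduced"):
            raise ValueError(f"unsupported variant {self.variant!r}")
        if self.stream_depths[-1] != 1:
            raise ValueError("stream output depth must be 1")

    def effective_depths(self):
        """Depths after the variant halving rule (inputs keep full depth,
        which for channel counts means only layer outputs are halved;
        single-channel layers stay)."""
        if self.variant != "reduced":
            return tuple(self.stream_depths), tuple(self.unet_encoder_depths)

        def half(d):
            return d if d <= 1 else d // 2

        return (tuple(half(d) for d in self.stream_depths),
                tuple(half(d) for d in self.unet_encoder_depths))


class _EchoStream(Module):
    """Shared per-echo processing stream with inter-echo hidden transfer."""

    def __init__(self, depths, rng, dtype):
        super().__init__()
        self.depths = tuple(depths)
        ci = 1
        for i, co in enumerate(depths):
            setattr(self, f"conv{i}", Conv2d(ci, co, 3, 1, 1, rng, dtype))
            if i < len(depths) - 1:
                setattr(self, f"bn{i}", BatchNorm2d(co, dtype=dtype))
                # inter-echo (recurrent) transfer at this hidden depth
                setattr(self, f"rconv{i}", Conv2d(co, co, 3, 1, 1, rng, dtype))
                setattr(self, f"rbn{i}", BatchNorm2d(co, dtype=dtype))
            ci = co

    def forward(self, x: Tensor, hidden_prev, lambda_w: float):
        hidden = []
        h = x
        n = len(self.depths)
        for i in range(n):
            h = getattr(self, f"conv{i}")(h)
            if i < n - 1:
                h = getattr(self, f"bn{i}")(h)
                if hidden_prev is not None and lambda_w != 0.0:
                    t = getattr(self, f"rconv{i}")(hidden_prev[i])
                    t = getattr(self, f"rbn{i}")(t)
                    h = h + t * lambda_w
                h = h.relu()
                hidden.append(h)
        return h + x, hidden  # residual: input image -> stream output


class _UNet(Module):
    """Stride-2 conv encoder / 4x4 transposed-conv decoder with concat
    skips and a 1x1 input residual; batch norm everywhere but the output."""

    def __init__(self, in_ch, enc_depths, rng, dtype):
        super().__init__()
        self.n_levels = len(enc_depths)
        self.enc_depths = tuple(enc_depths)
        ci = in_ch
        for i, co in enumerate(enc_depths):
            setattr(self, f"enc{i}",
                    Conv2d(ci, co, 3, 2, 1, rng, dtype, bias=False))
            setattr(self, f"ebn{i}", BatchNorm2d(co, dtype=dtype))
            ci = co
        dec_depths = list(enc_depths[::-1][1:]) + [1]
        for i, co in enumerate(dec_depths):
            cin = ci + (enc_depths[self.n_levels - 1 - i] if i > 0 else 0)
            last = i == len(dec_depths) - 1
            setattr(self, f"dec{i}",
                    ConvTranspose2d(cin, co, 4, 2, 1, rng, dtype, bias=last))
            if not last:
                setattr(self, f"dbn{i}", BatchNorm2d(co, dtype=dtype))
            ci = co
        self.res = Conv2d(in_ch, 1, kernel=1, stride=1, padding=0, rng=rng,
                          dtype=dtype, bias=False)
        # zero-init the input residual so the initial output scale is set by
        # the (biased) output layer, not by raw echo intensities
        self.res.weight.data[:] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        feats = []
        h = x
        for i in range(self.n_levels):
            h = getattr(self, f"enc{i}")(h)
            h = getattr(self, f"ebn{i}")(h).relu()
            feats.append(h)
        for i in range(self.n_levels):
            if i > 0:
                h = concat([h, feats[self.n_levels - 1 - i]], axis=1)
            h = getattr(self, f"dec{i}")(h)
            if i != self.n_levels - 1:
                h = getattr(self, f"dbn{i}")(h).relu()
        return h + self.res(x)


class RecurrentUNet(Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        stream_d, enc_d = config.effective_depths()
        self.has_stream = config.variant != "no_rnn"
        if self.has_stream:
            self.stream = _EchoStream(stream_d, rng, config.dtype)
        self.unet = _UNet(config.n_echoes, enc_d, rng, config.dtype)
        out_layer = getattr(self.unet, f"dec{self.unet.n_levels - 1}")
        out_layer.bias.data[:] = config.output_bias_init

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, n_echoes, H, W) aliased echo images -> (N, 1, H, W) map."""
        n_e = self.config.n_echoes
        if x.shape[1] != n_e:
            raise ValueError(f"expected {n_e} echo channels, got {x.shape[1]}")
        h, w = x.shape[2], x.shape[3]
        div = 2 ** self.unet.n_levels
        if h % div or w % div:
            raise ValueError(
                f"spatial dims {(h, w)} must be divisible by {div}; "
                "use n_levels_for_grid to size the UNet for small slices")
        if self.has_stream:
            order = range(n_e)
            if self.config.reverse_stream_direction:
                order = reversed(order)
            outs = [None] * n_e
            hidden = None
            for e in order:
                out_e, hidden = self.stream(x[:, e:e + 1], hidden,
                                            self.config.lambda_w)
                outs[e] = out_e
            feats = concat(outs, axis=1)
        else:
            feats = x
        return self.unet(feats)


def build_model(config: ModelConfig) -> RecurrentUNet:
    """Instantiate a variant; at the native depths the trainable-parameter
    counts match the printed values exactly."""
    return RecurrentUNet(config)


def predict_map(model: RecurrentUNet, echo_slice: np.ndarray) -> np.ndarray:
    """Predict the T2 map of one slice from its (n_echoes, H, W) images."""
    arr = np.asarray(echo_slice, dtype=model.config.dtype)
    if arr.ndim != 3:
        raise ValueError("echo slice must be (n_echoes, H, W)")
    model.eval()
    with no_grad():
        out = model(Tensor(arr[None]))
    pred = out.data[0, 0]
    if not np.isfinite(pred).all():
        raise FloatingPointError("non-finite values in predicted map")
    return pred
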