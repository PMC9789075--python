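"""Synthetic multi-echo T2 phantoms.

Generates aligned multi-echo magnitude acquisitions with known ground-truth
T2, proton density and tissue-of-interest masks, emulating the statistical
structure of a T2-prepared snapshot gradient-echo (MAPSS-style) scan:
four echo images per slice, a thin high-T2 curved "cartilage" band (knee,
hip) or elliptical "IVDs" (spine) embedded in a lower-T2 background, and
Rician noise on the coil-combined magnitude images.

The signal model is mono-exponential, ``S(TE) = PD * exp(-TE / T2)``, and
noise is applied as the magnitude of a complex Gaussian perturbation
(Rician), matching magnitude-image statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KNEE_TES", "HIP_TES", "SPINE_TES", "PhantomConfig", "EchoSeries",
           "RoiMask", "PhantomTruth", "generate_phantom", "simulate_echoes"]

# Echo times (ms) of the emulated acquisitions, per anatomy.
KNEE_TES = (0.0, 12.9, 25.7, 51.4)
HIP_TES = (0.0, 10.4, 20.8, 41.7)
SPINE_TES = (0.0, 12.9, 25.7, 51.4)

_DEFAULT_TES = {"knee": KNEE_TES, "hip": HIP_TES, "spine": SPINE_TES}

# T2 ranges (ms) per tissue class.  The tissue of interest sits well above
# the background so its loss-relevant dynamic range matches the sigmoid
# scaling window of each anatomy (knee/hip transition ends near 100/60 ms,
# spine near 150 ms).
_DEFAULT_T2 = {
    "knee": {"background": (20.0, 20.0), "roi": (30.0, 60.0)},
    "hip": {"background": (20.0, 20.0), "roi": (25.0, 50.0)},
    "spine": {"background": (40.0, 40.0), "roi": (60.0, 130.0)},
}


@dataclass
class EchoSeries:
    """Multi-echo magnitude volume: ``data[echo, y, x, z]`` plus TEs (ms)."""

    data: np.ndarray
    echo_times: tuple

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.echo_times = tuple(float(t) for t in self.echo_times)
        if self.data.ndim != 4:
            raise ValueError("EchoSeries data must be 4-D (echo, y, x, z)")
        if self.data.shape[0] != len(self.echo_times):
            raise ValueError("one image per echo time required")

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times)

    @property
    def grid(self) -> tuple:
        return self.data.shape[1:]

    def slice(self, z: int) -> np.ndarray:
        """Echo images of one slice, shape (n_echoes, n_y, n_x)."""
        return self.data[:, :, :, z]


@dataclass
class RoiMask:
    """Labelled tissue-of-interest pixels; 0 = outside, 1..K = compartments."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def compartments(self):
        return [int(v) for v in np.unique(self.labels) if v > 0]

    def compartment(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class PhantomConfig:
    grid: tuple = (64, 64, 8)
    anatomy: str = "knee"
    echo_times: tuple | None = None
    t2_ranges: dict | None = None
    proton_density_range: tuple = (350.0, 500.0)
    lesion_count: int = 3
    lesion_t2_delta: float = 15.0
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.anatomy not in ("knee", "hip", "spine"):
            raise ValueError(f"unknown anatomy {self.anatomy!r}")
        if self.echo_times is None:
            self.echo_times = _DEFAULT_TES[self.anatomy]
        self.echo_times = tuple(float(t) for t in self.echo_times)
        if self.echo_times[0] != 0.0:
            raise ValueError("first echo time must be 0 ms")
        if any(b <= a for a, b in zip(self.echo_times, self.echo_times[1:])):
            raise ValueError("echo times must be strictly increasing")
        if self.t2_ranges is None:
            self.t2_ranges = {k: tuple(v) for k, v in
                              _DEFAULT_T2[self.anatomy].items()}
        for cls, (lo, hi) in self.t2_ranges.items():
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid T2 range for {cls!r}: {(lo, hi)}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.proton_density_range[0] <= 0:
            raise ValueError("proton density must be positive")


@dataclass
class PhantomTruth:
    t2_true: np.ndarray
    pd_true: np.ndarray
    roi: RoiMask
    echo_series: EchoSeries
    config: PhantomConfig = field(repr=False, default=None)


def _sample_range(rng, rg):
    lo, hi = rg
    return lo if hi == lo else float(rng.uniform(lo, hi))


def _arc_roi(rng, n_y, n_x):
    """Thin curved band (annulus sector), 2-6 pixels thick."""
    cy = n_y * 0.5 + rng.uniform(-0.08, 0.08) * n_y
    cx = n_x * 0.5 + rng.uniform(-0.08, 0.08) * n_x
    radius = 0.30 * min(n_y, n_x) * rng.uniform(0.85, 1.15)
    thickness = rng.uniform(2.0, 6.0)
    theta0 = rng.uniform(0, 2 * np.pi)
    span = rng.uniform(0.5 * np.pi, np.pi)
    yy, xx = np.mgrid[0:n_y, 0:n_x]
    rr = np.hypot(yy - cy, xx - cx)
    ang = np.mod(np.arctan2(yy - cy, xx - cx) - theta0, 2 * np.pi)
    return (np.abs(rr - radius) <= thickness / 2.0) & (ang <= span), (cy, cx)


def _ellipse_rois(rng, n_y, n_x, n_rois=2):
    """Stacked elliptical compartments (disc-like)."""
    labels = np.zeros((n_y, n_x), dtype=np.int16)
    centers = np.linspace(0.3, 0.7, n_rois) * n_y
    for k, cy0 in enumerate(centers, start=1):
        cy = cy0 + rng.uniform(-2, 2)
        cx = n_x * 0.5 + rng.uniform(-0.05, 0.05) * n_x
        ay = max(2.0, 0.06 * n_y * rng.uniform(0.8, 1.3))
        ax = max(3.0, 0.18 * n_x * rng.uniform(0.8, 1.2))
        yy, xx = np.mgrid[0:n_y, 0:n_x]
        inside = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
        labels[inside] = k
    return labels


def generate_phantom(config: PhantomConfig) -> PhantomTruth:
    """Build ground-truth maps, ROI masks and the noisy echo series.

    Deterministic for a fixed ``config.seed``.  The tissue of interest is a
    thin curved band (knee/hip) or a set of elliptical compartments (spine)
    whose class T2 is drawn from the configured range; optional focal
    lesions raise T2 by ``lesion_t2_delta`` inside the ROI.
    """
    n_y, n_x, n_z = config.grid
    if min(n_y, n_x) < 16 or n_z < 1:
        raise ValueError(
            f"grid {config.grid} too small to place the tissue ROI "
            "(need at least 16x16 in-plane)")
    rng = np.random.default_rng(config.seed)

    t2_bg = _sample_range(rng, config.t2_ranges["background"])
    t2_roi = _sample_range(rng, config.t2_ranges["roi"])
    pd_body = _sample_range(rng, config.proton_density_range)
    pd_roi = _sample_range(rng, config.proton_density_range)

    # body support: large centered ellipse; outside it PD = 0 (air)
    yy, xx = np.mgrid[0:n_y, 0:n_x]
    body2d = (((yy - (n_y - 1) / 2) / (0.47 * n_y)) ** 2 +
              ((xx - (n_x - 1) / 2) / (0.47 * n_x)) ** 2) <= 1.0

    t2 = np.zeros((n_y, n_x, n_z))
    pd = np.zeros((n_y, n_x, n_z))
    labels = np.zeros((n_y, n_x, n_z), dtype=np.int16)

    if config.anatomy in ("knee", "hip"):
        roi2d, _ = _arc_roi(rng, n_y, n_x)
    else:
        roi2d = _ellipse_rois(rng, n_y, n_x)

    # smooth through-slice drift of the ROI keeps k_z non-trivial
    dy = np.clip(np.cumsum(rng.integers(-1, 2, size=n_z)), -2, 2)
    dx = np.clip(np.cumsum(rng.integers(-1, 2, size=n_z)), -2, 2)
    pd_mod = 1.0 + 0.05 * np.sin(np.linspace(0, np.pi, n_z) +
                                 rng.uniform(0, np.pi))

    for z in range(n_z):
        r2d = np.roll(np.roll(np.asarray(roi2d), int(dy[z]), axis=0),
                      int(dx[z]), axis=1)
        r2d = r2d & body2d
        t2z = np.where(body2d, t2_bg, 0.0)
        pdz = np.where(body2d, pd_body * pd_mod[z], 0.0)
        t2z = np.where(r2d > 0, t2_roi, t2z)
        pdz = np.where(r2d > 0, pd_roi * pd_mod[z], pdz)
        t2[:, :, z] = t2z
        pd[:, :, z] = pdz
        labels[:, :, z] = r2d.astype(np.int16) if r2d.dtype == bool else r2d

    if not (labels > 0).any():
        raise ValueError("grid too small: ROI fell outside the body support")

    # focal lesions: small balls of elevated T2 inside the ROI
    roi_idx = np.argwhere(labels > 0)
    for _ in range(config.lesion_count):
        cy, cx, cz = roi_idx[rng.integers(len(roi_idx))]
        rad = rng.uniform(1.0, 2.5)
        zrad = max(1.0, rad / 2.0)
        yy3, xx3, zz3 = np.mgrid[0:n_y, 0:n_x, 0:n_z]
        ball = ((yy3 - cy) ** 2 + (xx3 - cx) ** 2) / rad ** 2 + \
            ((zz3 - cz) ** 2) / zrad ** 2 <= 1.0
        t2 = np.where(ball & (labels > 0), t2 + config.lesion_t2_delta, t2)

    echoes = simulate_echoes(t2, pd, config.echo_times, config.noise_sigma,
                             seed=int(rng.integers(2**31)))
    return PhantomTruth(t2_true=t2, pd_true=pd, roi=RoiMask(labels),
                        echo_series=echoes, config=config)


def simulate_echoes(t2_true, pd_true, echo_times, noise_sigma: float,
                    seed: int = 0) -> EchoSeries:
    """Mono-exponential echo images with Rician magnitude noise.

    Noise-free signal is ``PD * exp(-TE/T2)``; with ``noise_sigma > 0`` two
    independent Gaussian channels of s.d. ``noise_sigma * max(PD)`` are
    added in quadrature (real channel carries the signal).
    """
    t2_true = np.asarray(t2_true, dtype=float)
    pd_true = np.asarray(pd_true, dtype=float)
    if t2_true.shape != pd_true.shape:
        raise ValueError("t2_true and pd_true shapes differ")
    if t2_true.ndim == 2:  # single slice: promote to a 1-slice volume
        t2_true = t2_true[..., None]
        pd_true = pd_true[..., None]
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    echo_times = tuple(float(t) for t in echo_times)
    if echo_times[0] != 0.0:
        raise ValueError("first echo time must be 0 ms")

    with np.errstate(divide="ignore", invalid="ignore"):
        decay = np.stack([np.where(t2_true > 0, np.exp(-te / np.maximum(t2_true, 1e-12)), 0.0)
                          for te in echo_times])
    signal = decay * pd_true[None]
    signal[:, pd_true <= 0] = 0.0
    # TE = 0: exp(0) = 1 exactly, even where t2 = 0 but pd > 0
    signal[0] = np.where(pd_true > 0, pd_true, 0.0)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        sig = noise_sigma * float(pd_true.max())
        n1 = rng.normal(0.0, sig, size=signal.shape)
        n2 = rng.normal(0.0, sig, size=signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2 ** 2)
    return EchoSeries(data=signal, echo_times=echo_times)
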