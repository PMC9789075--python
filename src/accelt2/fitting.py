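"""Per-pixel mono-exponential T2 estimation.

The estimator fits ``S(TE) = A * exp(-TE / T2)`` to multi-echo magnitude
images by Levenberg-Marquardt, initialized from the log-linear
least-squares line through ``(TE, log S)``.  The whole image is fitted at
once: the damped normal equations of the 2-parameter model are solved in
closed form per pixel, with an independent damping factor per pixel, so no
Python-level per-pixel loop is needed.

A thin statsmodels-style wrapper (:class:`MonoExponentialModel` /
:class:`T2FitResults`) exposes the same computation as a model object with
a ``fit()`` method and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import EchoSeries

__all__ = ["FitOptions", "T2Map", "fit_t2", "MonoExponentialModel",
           "T2FitResults"]


@dataclass
class FitOptions:
    t2_bounds: tuple = (1.0, 300.0)
    signal_floor: float = 1e-3
    max_iterations: int = 30
    convergence_tolerance: float = 1e-10

    def __post_init__(self):
        lo, hi = self.t2_bounds
        if lo <= 0 or hi <= lo:
            raise ValueError("t2_bounds must be positive and ordered")


@dataclass
class T2Map:
    t2: np.ndarray          # ms; 0 sentinel where invalid
    amplitude: np.ndarray   # a.u.
    valid: np.ndarray       # converged, above-floor pixels
    clamped: np.ndarray = None  # pixels pushed to a T2 bound

    def masked(self, fill=0.0) -> np.ndarray:
        return np.where(self.valid, self.t2, fill)


def _loglinear_init(signals: np.ndarray, tes: np.ndarray, floor: float):
    """Least-squares line through (TE, log S) per pixel.

    Returns (A0, rate0) with rate = 1/T2.  Echoes at or below the floor are
    down-weighted by clipping; the TE=0 echo anchors the amplitude.
    """
    s = np.clip(signals, max(floor, 1e-12), None)
    logs = np.log(s)
    n = len(tes)
    tbar = tes.mean()
    lbar = logs.mean(axis=0)
    cov = ((tes[:, None] - tbar) * (logs - lbar[None])).sum(axis=0)
    var = ((tes - tbar) ** 2).sum()
    slope = cov / var
    intercept = lbar - slope * tbar
    rate0 = np.maximum(-slope, 1e-6)
    a0 = np.exp(intercept)
    return a0, rate0


def _lm_refine(signals, tes, a, rate, options: FitOptions):
    """Vectorized Levenberg-Marquardt on (A, rate = 1/T2)."""
    lam = np.full(a.shape, 1e-3)
    y = signals

    def sse(a_, r_):
        model = a_[None] * np.exp(-tes[:, None] * r_[None])
        resid = model - y
        return (resid ** 2).sum(axis=0), resid, model

    cost, resid, model = sse(a, rate)
    for _ in range(options.max_iterations):
        # Jacobian of residuals wrt (A, rate)
        e = model / np.where(a == 0, 1.0, a)[None]     # exp(-TE*rate)
        ja = e                                         # d model / dA
        jr = -tes[:, None] * model                     # d model / d rate
        g_a = (ja * resid).sum(axis=0)
        g_r = (jr * resid).sum(axis=0)
        h_aa = (ja * ja).sum(axis=0)
        h_rr = (jr * jr).sum(axis=0)
        h_ar = (ja * jr).sum(axis=0)
        # damped normal equations, solved in closed form per pixel
        daa = h_aa * (1 + lam)
        drr = h_rr * (1 + lam)
        det = daa * drr - h_ar ** 2
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        step_a = -(drr * g_a - h_ar * g_r) / det
        step_r = -(daa * g_r - h_ar * g_a) / det
        new_a = a + step_a
        new_r = rate + step_r
        new_cost, new_resid, new_model = sse(new_a, new_r)
        better = new_cost < cost
        a = np.where(better, new_a, a)
        rate = np.where(better, new_r, rate)
        lam = np.where(better, lam * 0.3, lam * 4.0)
        lam = np.clip(lam, 1e-12, 1e12)
        improved = cost - np.where(better, new_cost, cost)
        cost = np.where(better, new_cost, cost)
        model = np.where(better[None], new_model, model)
        resid = np.where(better[None], new_resid, resid)
        if (improved <= options.convergence_tolerance *
                np.maximum(cost, 1e-30)).all():
            break
    return a, rate, cost


def fit_t2(echo_series: EchoSeries, options: FitOptions | None = None) -> T2Map:
    """Fit T2 and amplitude maps from a multi-echo magnitude series."""
    options = options or FitOptions()
    if echo_series.n_echoes < 3:
        raise ValueError("at least 3 echoes are required for a stable fit")
    tes = np.asarray(echo_series.echo_times, dtype=float)
    shape = echo_series.grid
    y = echo_series.data.reshape(echo_series.n_echoes, -1).astype(float)

    above = y[0] > options.signal_floor
    a0, r0 = _loglinear_init(y, tes, options.signal_floor)
    a, rate, _ = _lm_refine(y, tes, a0, r0, options)

    lo, hi = options.t2_bounds
    with np.errstate(divide="ignore"):
        t2 = np.where(rate > 0, 1.0 / np.maximum(rate, 1e-12), np.inf)
    clamped = (t2 < lo) | (t2 > hi)
    t2 = np.clip(t2, lo, hi)
    valid = above & np.isfinite(a) & (a > 0)
    t2 = np.where(valid, t2, 0.0)
    a = np.where(valid, a, 0.0)
    return T2Map(t2=t2.reshape(shape), amplitude=a.reshape(shape),
                 valid=valid.reshape(shape), clamped=clamped.reshape(shape))


class MonoExponentialModel:
    """Mono-exponential decay model for a multi-echo series.

    Statsmodels-style entry point::

        res = MonoExponentialModel(echoes).fit()
        res.t2_map, res.summary()
    """

    def __init__(self, echo_series: EchoSeries,
                 options: FitOptions | None = None):
        self.echo_series = echo_series
        self.options = options or FitOptions()

    def fit(self) -> "T2FitResults":
        return T2FitResults(self, fit_t2(self.echo_series, self.options))


@dataclass
class T2FitResults:
    model: MonoExponentialModel = field(repr=False)
    t2_map: T2Map = None

    def summary(self) -> str:
        t2 = self.t2_map.t2[self.t2_map.valid]
        lines = [
            "Mono-exponential T2 fit",
            "=" * 31,
            f"echo times (ms) : {list(self.model.echo_series.echo_times)}",
            f"pixels fitted   : {int(self.t2_map.valid.sum())}"
            f" / {self.t2_map.valid.size}",
            f"clamped pixels  : {int(self.t2_map.clamped.sum())}",
        ]
        if t2.size:
            lines += [
                f"T2 median (ms)  : {np.median(t2):.2f}",
                f"T2 IQR (ms)     : [{np.percentile(t2, 25):.2f}, "
                f"{np.percentile(t2, 75):.2f}]",
            ]
        return "\n".join(lines)
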