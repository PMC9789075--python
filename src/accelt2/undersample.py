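"""Retrospective k-space undersampling of multi-echo volumes.

Emulates accelerated Cartesian acquisition in the two phase-encode
dimensions (k_y, k_z): a centered elliptical coverage region (corner
k-space never acquired), center-weighted variable-density Poisson-disc
sampling calibrated to a target acceleration factor R, a fully sampled
central square, a unique pattern per echo, temporally-closest-echo line
sharing, and zero-filling of lines sampled at no echo.  The readout
direction is fully sampled.

Conventions: DC at the grid center (fftshift layout), 0-based indices,
and R defined with respect to ellipse-interior points only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import EchoSeries

__all__ = ["SamplingPlan", "SamplingMask", "make_elliptical_support",
           "make_poisson_mask", "share_echo_lines", "undersample_volume"]


@dataclass
class SamplingPlan:
    R: float
    grid: tuple  # (n_ky, n_kz)
    n_echoes: int = 4
    ellipse_area_fraction: float = 0.7
    central_square_area_fraction: float = 0.05
    seed: int = 0
    calibration_tolerance: float = 0.02
    density_alpha: float = 2.0

    def __post_init__(self):
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if not (0 < self.ellipse_area_fraction <= 1):
            raise ValueError("ellipse_area_fraction must be in (0, 1]")
        if not (0 < self.central_square_area_fraction <
                self.ellipse_area_fraction):
            raise ValueError("central_square_area_fraction must be in "
                             "(0, ellipse_area_fraction)")


@dataclass
class SamplingMask:
    masks: np.ndarray            # (n_echoes, n_ky, n_kz) boolean
    ellipse: np.ndarray          # (n_ky, n_kz) boolean support
    realized_R: list
    plan: SamplingPlan = field(repr=False, default=None)


def make_elliptical_support(n_ky: int, n_kz: int,
                            ellipse_area_fraction: float = 0.7) -> np.ndarray:
    """Centered axis-aligned discrete ellipse covering the requested
    fraction of the rectangular grid area (within +/- 0.01)."""
    if n_ky < 4 or n_kz < 4:
        raise ValueError("grid must be at least 4x4")
    if not (0 < ellipse_area_fraction <= 1):
        raise ValueError("ellipse_area_fraction must be in (0, 1]")
    if ellipse_area_fraction == 1.0:
        return np.ones((n_ky, n_kz), dtype=bool)

    cy, cz = (n_ky - 1) / 2.0, (n_kz - 1) / 2.0
    yy, zz = np.mgrid[0:n_ky, 0:n_kz]
    # semi-axes proportional to the half-extents; continuous-area scale
    # sqrt(fraction / (pi/4)) is the starting point, then discretely tuned
    ry = np.where(True, (yy - cy) / (n_ky / 2.0), 0)
    rz = (zz - cz) / (n_kz / 2.0)
    rad2 = ry**2 + rz**2
    n_total = n_ky * n_kz

    def frac(scale):
        return np.count_nonzero(rad2 <= scale**2) / n_total

    lo, hi = 0.1, 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if frac(mid) < ellipse_area_fraction:
            lo = mid
        else:
            hi = mid
    best = min((abs(frac(s) - ellipse_area_fraction), s) for s in (lo, hi))[1]
    achieved = frac(best)
    if abs(achieved - ellipse_area_fraction) > 0.01:
        raise ValueError(
            f"requested ellipse area fraction {ellipse_area_fraction} not "
            f"reachable on a {n_ky}x{n_kz} grid; closest achievable is "
            f"{achieved:.3f}")
    return rad2 <= best**2


def _central_square(n_ky: int, n_kz: int, area_fraction: float) -> np.ndarray:
    """Fully sampled central square: `area_fraction` of the grid area,
    side = sqrt(area_fraction) of each extent, rounded to odd pixel counts
    so the square is symmetric about DC."""
    side = np.sqrt(area_fraction)
    hy = max(1, int(round(side * n_ky)))
    hz = max(1, int(round(side * n_kz)))
    hy += 1 - hy % 2  # odd
    hz += 1 - hz % 2
    hy, hz = min(hy, n_ky), min(hz, n_kz)
    mask = np.zeros((n_ky, n_kz), dtype=bool)
    y0 = (n_ky - hy) // 2
    z0 = (n_kz - hz) // 2
    mask[y0:y0 + hy, z0:z0 + hz] = True
    return mask


def _elliptical_radius(n_ky, n_kz):
    cy, cz = (n_ky - 1) / 2.0, (n_kz - 1) / 2.0
    yy, zz = np.mgrid[0:n_ky, 0:n_kz]
    return np.sqrt(((yy - cy) / (n_ky / 2.0)) ** 2 +
                   ((zz - cz) / (n_kz / 2.0)) ** 2)


def _dart_throw(order, coords, radii, shape):
    """Sequential dart throwing: accept a candidate if no already accepted
    point lies within its exclusion radius (occupancy-grid neighbourhood)."""
    occupied = np.zeros(shape, dtype=bool)
    accepted = np.zeros(len(coords), dtype=bool)
    n_ky, n_kz = shape
    for idx in order:
        y, z = coords[idx]
        r = radii[idx]
        ri = int(np.ceil(r))
        y0, y1 = max(0, y - ri), min(n_ky, y + ri + 1)
        z0, z1 = max(0, z - ri), min(n_kz, z + ri + 1)
        window = occupied[y0:y1, z0:z1]
        if window.any():
            wy, wz = np.nonzero(window)
            if (((wy + y0 - y) ** 2 + (wz + z0 - z) ** 2) <= r * r).any():
                continue
        occupied[y, z] = True
        accepted[idx] = True
    return occupied, accepted


def make_poisson_mask(plan: SamplingPlan, echo_index: int = 0,
                      ellipse: np.ndarray | None = None,
                      return_realized: bool = False):
    """Center-weighted Poisson-disc mask for one echo.

    The exclusion radius grows linearly with normalized elliptical radius,
    ``r(d) = r0 * (1 + alpha * d)``; ``r0`` is calibrated by bisection so
    the realized acceleration (ellipse points / sampled points) matches the
    target within ``plan.calibration_tolerance``.  The central square is
    always fully sampled and the pattern is unique per echo index.
    """
    n_ky, n_kz = plan.grid
    if ellipse is None:
        ellipse = make_elliptical_support(n_ky, n_kz,
                                          plan.ellipse_area_fraction)
    square = _central_square(n_ky, n_kz, plan.central_square_area_fraction)
    square &= ellipse
    n_ellipse = int(ellipse.sum())

    tol = plan.calibration_tolerance
    if plan.R <= 1 + tol:
        mask = ellipse.copy()
        realized = 1.0
        if abs(realized - plan.R) / plan.R > tol:
            raise RuntimeError("cannot reach R < 1")
        return (mask, realized) if return_realized else mask

    d = _elliptical_radius(n_ky, n_kz)
    cand = ellipse & ~square
    coords = np.argwhere(cand)
    dvals = d[cand]
    rng = np.random.default_rng([plan.seed, echo_index])
    order = rng.permutation(len(coords))

    # target sampled-point count: the integer closest to n_ellipse / R
    n_square = int(square.sum())
    m_star, err = None, np.inf
    for m in (int(np.floor(n_ellipse / plan.R)),
              int(np.ceil(n_ellipse / plan.R))):
        if m >= n_square and m <= n_ellipse and \
                abs(n_ellipse / m - plan.R) < err:
            m_star, err = m, abs(n_ellipse / m - plan.R)
    if m_star is None or err / plan.R > tol:
        achieved = n_ellipse / m_star if m_star else float("nan")
        raise RuntimeError(
            f"Poisson-disc calibration cannot reach R={plan.R} on this "
            f"grid: closest achievable R={achieved:.3f}")

    def throw(r0):
        radii = r0 * (1.0 + plan.density_alpha * dvals)
        occupied, accepted = _dart_throw(order, coords, radii, (n_ky, n_kz))
        return occupied, accepted

    # bisect r0 to the sparsest pattern with at least m_star points,
    # then trim the latest-accepted darts to hit the count exactly
    # (trimming cannot violate the exclusion radii)
    lo, hi = 0.0, 0.5 * max(n_ky, n_kz)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        occupied, accepted = throw(mid)
        n = int((occupied | square).sum())
        if n >= m_star:
            lo = mid
        else:
            hi = mid
    occupied, accepted = throw(lo)
    mask = occupied | square
    excess = int(mask.sum()) - m_star
    if excess > 0:
        dart_order = [i for i in order if accepted[i]]
        for i in reversed(dart_order):
            if excess == 0:
                break
            y, z = coords[i]
            if mask[y, z] and not square[y, z]:
                mask[y, z] = False
                excess -= 1
    realized = n_ellipse / int(mask.sum())
    if abs(realized - plan.R) / plan.R > tol:
        raise RuntimeError(
            f"Poisson-disc calibration did not converge: target R={plan.R}, "
            f"achieved R={realized:.3f}")
    return (mask, realized) if return_realized else mask


def make_sampling_mask(plan: SamplingPlan) -> SamplingMask:
    """Per-echo masks plus ellipse support and realized accelerations."""
    n_ky, n_kz = plan.grid
    ellipse = make_elliptical_support(n_ky, n_kz, plan.ellipse_area_fraction)
    masks, realized = [], []
    for e in range(plan.n_echoes):
        m, r = make_poisson_mask(plan, e, ellipse=ellipse,
                                 return_realized=True)
        masks.append(m)
        realized.append(r)
    return SamplingMask(masks=np.stack(masks), ellipse=ellipse,
                        realized_R=realized, plan=plan)


def share_echo_lines(kspaces: np.ndarray, masks: np.ndarray,
                     echo_times) -> np.ndarray:
    """Fill unsampled (k_y, k_z) lines from the temporally closest echo.

    For each line and echo: keep own data if sampled; otherwise copy the
    line from the sampled echo whose TE is closest (ties resolved toward
    the earlier, higher-SNR echo); zero if no echo sampled it.

    ``kspaces``: complex, shape (n_echoes, n_ky, n_kx, n_kz) (or any shape
    whose axes 1 and -1 are k_y and k_z).  ``masks``: boolean
    (n_echoes, n_ky, n_kz).
    """
    kspaces = np.asarray(kspaces)
    masks = np.asarray(masks, dtype=bool)
    n_e = kspaces.shape[0]
    if masks.shape[0] != n_e or len(echo_times) != n_e:
        raise ValueError("one mask and one echo time per echo required")
    if masks.shape[1] != kspaces.shape[1] or masks.shape[2] != kspaces.shape[-1]:
        raise ValueError(
            f"mask grid {masks.shape[1:]} does not match k-space phase-"
            f"encode grid {(kspaces.shape[1], kspaces.shape[-1])}")
    tes = np.asarray(echo_times, dtype=float)

    out = np.zeros_like(kspaces)
    for e in range(n_e):
        # echo preference: ascending |TE difference|, ties toward earlier TE
        pref = sorted(range(n_e), key=lambda d: (abs(tes[d] - tes[e]), tes[d]))
        donor = np.full(masks.shape[1:], -1, dtype=int)
        for dn in reversed(pref):
            donor[masks[dn]] = dn
        for dn in range(n_e):
            sel = donor == dn  # (n_ky, n_kz); lines not donated stay zero
            if sel.any():
                out[e] = np.where(sel[:, None, :], kspaces[dn], out[e])
    return out


def undersample_volume(echo_series: EchoSeries, plan: SamplingPlan,
                       sampling_mask: SamplingMask | None = None):
    """Simulate accelerated acquisition of a multi-echo volume.

    Each echo volume is Fourier transformed over (y, z), restricted to the
    elliptical coverage, undersampled with its echo-specific mask with
    temporally-closest line sharing, inverse transformed, and returned as
    magnitude images.
    """
    n_y, n_x, n_z = echo_series.grid
    if plan.grid != (n_y, n_z):
        raise ValueError(
            f"plan grid {plan.grid} does not match volume phase-encode grid "
            f"{(n_y, n_z)}")
    if sampling_mask is None:
        sampling_mask = make_sampling_mask(plan)
    if plan.n_echoes != echo_series.n_echoes:
        raise ValueError("plan n_echoes does not match echo series")

    data = echo_series.data.astype(complex)
    k = np.fft.fftshift(np.fft.fftn(data, axes=(1, 3)), axes=(1, 3))
    k *= sampling_mask.ellipse[None, :, None, :]
    masks = sampling_mask.masks & sampling_mask.ellipse[None]
    shared = share_echo_lines(k, masks, echo_series.echo_times)
    img = np.fft.ifftn(np.fft.ifftshift(shared, axes=(1, 3)), axes=(1, 3))
    aliased = EchoSeries(data=np.abs(img), echo_times=echo_series.echo_times)
    return aliased, sampling_mask
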