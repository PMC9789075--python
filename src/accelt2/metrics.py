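"""Evaluation battery for predicted T2 maps.

Implements the ROI-restricted NRMSE, T2-value error equivalents, pooled
Pearson correlation, Bland-Altman agreement, and a texture-retention
framework: gray-level co-occurrence matrix (GLCM) metrics computed inside
the tissue of interest at four one-pixel offsets, compared between
ground-truth and predicted maps across scans with an intraclass
correlation coefficient (two-way mixed effects, single rater).

The GLCM is accumulated only over pixel pairs whose *both* members lie in
the ROI, so mask edges contribute no spurious co-occurrences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["roi_nrmse", "t2_equivalent", "bland_altman", "glcm_metrics",
           "icc_single_rater", "pearson_roi", "AgreementReport",
           "GLCM_METRIC_NAMES", "MetricReport", "compute_metric_report"]

GLCM_METRIC_NAMES = ("contrast", "dissimilarity", "homogeneity", "asm",
                     "energy")

# offsets (dy, dx) for theta = 0, 45, 90, 135 degrees at distance 1
_GLCM_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def roi_nrmse(t2_true, t2_pred, roi) -> float:
    """||T2 - T2_hat||_2 / ||T2||_2 over tissue-of-interest pixels."""
    roi = np.asarray(roi) > 0
    if not roi.any():
        raise ValueError("empty ROI")
    t = np.asarray(t2_true, dtype=float)[roi]
    p = np.asarray(t2_pred, dtype=float)[roi]
    denom = np.linalg.norm(t)
    if denom == 0:
        raise ValueError("ROI ground truth has zero norm")
    return float(np.linalg.norm(p - t) / denom)


def t2_equivalent(nrmse: float, t2_true, roi) -> float:
    """NRMSE expressed in ms: error rate times mean ROI T2."""
    roi = np.asarray(roi) > 0
    if not roi.any():
        raise ValueError("empty ROI")
    return float(nrmse * np.asarray(t2_true, dtype=float)[roi].mean())


@dataclass
class AgreementReport:
    bias: float
    loa_low: float
    loa_high: float
    sd: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(true_values, pred_values) -> AgreementReport:
    """Bias and +/- 1.96 s.d. limits of agreement of paired measurements."""
    t = np.asarray(true_values, dtype=float)
    p = np.asarray(pred_values, dtype=float)
    if t.shape != p.shape or t.size < 2:
        raise ValueError("need >= 2 pairs of equal length")
    diffs = p - t
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementReport(bias=bias, loa_low=bias - 1.96 * sd,
                           loa_high=bias + 1.96 * sd, sd=sd,
                           means=(t + p) / 2.0, diffs=diffs)


def _quantize(t2_map, roi, n_levels, t2_range):
    lo, hi = t2_range
    x = np.clip(np.asarray(t2_map, dtype=float), lo, hi)
    q = np.floor((x - lo) / (hi - lo) * n_levels).astype(int)
    return np.clip(q, 0, n_levels - 1)


def glcm_metrics(t2_map, roi, n_levels: int = 32,
                 t2_range: tuple = (0.0, 150.0)) -> dict:
    """GLCM texture metrics inside the ROI, averaged over 4 offsets.

    The map is clipped to ``t2_range`` and uniformly quantized to
    ``n_levels`` gray levels.  For each offset, symmetric co-occurrence
    counts are accumulated over in-ROI pairs (both pixels inside the ROI);
    for 3-D inputs counts are pooled across slices (the co-occurrence
    offsets stay in-plane).  Metrics per offset::

        contrast      sum p(i,j) (i-j)^2
        dissimilarity sum p(i,j) |i-j|
        homogeneity   sum p(i,j) / (1 + (i-j)^2)
        asm           sum p(i,j)^2
        energy        sqrt(asm)

    are averaged over the 4 offsets.
    """
    roi = np.asarray(roi) > 0
    t2_map = np.asarray(t2_map, dtype=float)
    if t2_map.shape != roi.shape:
        raise ValueError("map and ROI shapes differ")
    if t2_map.ndim == 2:
        t2_map = t2_map[..., None]
        roi = roi[..., None]
    q = _quantize(t2_map, roi, n_levels, t2_range)

    levels = np.arange(n_levels)
    di = levels[:, None] - levels[None, :]
    per_offset = {m: [] for m in GLCM_METRIC_NAMES}
    for dy, dx in _GLCM_OFFSETS:
        counts = np.zeros((n_levels, n_levels))
        for z in range(q.shape[2]):
            qz, rz = q[:, :, z], roi[:, :, z]
            h, w = qz.shape
            y0, y1 = max(0, -dy), min(h, h - dy)
            x0, x1 = max(0, -dx), min(w, w - dx)
            a = qz[y0:y1, x0:x1]
            b = qz[y0 + dy:y1 + dy, x0 + dx:x1 + dx]
            ok = rz[y0:y1, x0:x1] & rz[y0 + dy:y1 + dy, x0 + dx:x1 + dx]
            if ok.any():
                np.add.at(counts, (a[ok], b[ok]), 1)
        counts = counts + counts.T  # symmetric
        total = counts.sum()
        if total == 0:
            raise ValueError(
                "ROI has no valid in-plane neighbour pairs at offset "
                f"{(dy, dx)}")
        p = counts / total
        per_offset["contrast"].append(float((p * di**2).sum()))
        per_offset["dissimilarity"].append(float((p * np.abs(di)).sum()))
        per_offset["homogeneity"].append(float((p / (1.0 + di**2)).sum()))
        asm = float((p**2).sum())
        per_offset["asm"].append(asm)
        per_offset["energy"].append(float(np.sqrt(asm)))
    return {m: float(np.mean(v)) for m, v in per_offset.items()}


def icc_single_rater(x, y, form: str = "consistency"):
    """ICC between paired per-scan measurements (two-way mixed effects,
    single measurement).

    ``form='consistency'`` gives ICC(3,1); ``form='agreement'`` the
    absolute-agreement variant ICC(2,1)-style for the mixed model.
    Returns ``(icc, ci_low, ci_high, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired scans")
    if np.allclose(x, x[0]) and np.allclose(y, y[0]):
        raise ValueError("zero variance across scans: ICC undefined")
    n, k = x.size, 2
    data = np.stack([x, y], axis=1)
    grand = data.mean()
    ms_rows = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    ss_err = (((data - grand) ** 2).sum() - (n - 1) * ms_rows -
              (k - 1) * ms_cols)
    ms_err = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    if form == "consistency":
        icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err) \
            if ms_rows + (k - 1) * ms_err > 0 else 1.0
        df1, df2 = n - 1, (n - 1) * (k - 1)
        if ms_err == 0:
            return (1.0, 1.0, 1.0, 0.0)
        f_obs = ms_rows / ms_err
        p = float(stats.f.sf(f_obs, df1, df2))
        fl = f_obs / stats.f.ppf(0.975, df1, df2)
        fu = f_obs * stats.f.ppf(0.975, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return (float(icc), float(lo), float(hi), p)

    # absolute agreement: delegate to the reliability library
    import pingouin as pg
    frame = pd.DataFrame({
        "scan": np.tile(np.arange(n), 2),
        "rater": np.repeat(["truth", "prediction"], n),
        "value": np.concatenate([x, y]),
    })
    table = pg.intraclass_corr(data=frame, targets="scan", raters="rater",
                               ratings="value")
    table = table.set_index(table["Type"].str.replace(r"[()]", "", regex=True))
    row = table.loc["ICCA,1"] if "ICCA,1" in table.index else table.loc["ICC2"]
    ci = row.get("CI95%", row.get("CI95"))
    return (float(row["ICC"]), float(ci[0]), float(ci[1]), float(row["pval"]))


def pearson_roi(t2_true, t2_pred, roi):
    """Voxel-wise Pearson r over pooled ROI pixels; two-sided p."""
    roi = np.asarray(roi) > 0
    t = np.asarray(t2_true, dtype=float)[roi]
    p = np.asarray(t2_pred, dtype=float)[roi]
    if t.size < 3:
        raise ValueError("need >= 3 ROI pixels")
    if t.std() == 0 or p.std() == 0:
        raise ValueError("degenerate (zero-variance) ROI values")
    r, pv = stats.pearsonr(t, p)
    return float(r), float(pv)


@dataclass
class MetricReport:
    nrmse: float
    t2_equiv: float
    pearson_r: float
    pearson_p: float
    mean_t2_true: float
    mean_t2_pred: float


def compute_metric_report(t2_true, t2_pred, roi) -> MetricReport:
    """Standard per-scan, per-compartment reconstruction metrics."""
    roi = np.asarray(roi) > 0
    nr = roi_nrmse(t2_true, t2_pred, roi)
    r, pv = pearson_roi(t2_true, t2_pred, roi)
    return MetricReport(
        nrmse=nr,
        t2_equiv=t2_equivalent(nr, t2_true, roi),
        pearson_r=r, pearson_p=pv,
        mean_t2_true=float(np.asarray(t2_true, dtype=float)[roi].mean()),
        mean_t2_pred=float(np.asarray(t2_pred, dtype=float)[roi].mean()),
    )
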