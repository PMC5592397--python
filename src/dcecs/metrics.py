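"""Image-quality and parameter-agreement metrics.

* SER — signal-to-error ratio in dB of a reconstruction against the fully
  sampled reference, ``-20 log10(||Xhat - X_FS|| / ||X_FS||)``.
* CCC — Lin's concordance correlation coefficient between parameter maps,
  ``2 cov(a, b) / (var a + var b + (mean a - mean b)^2)`` with population
  (1/n) moments. A literal variant that mixes standard deviations in the
  numerator with variances in the denominator is available via
  ``form="as_printed"``; it is not an agreement measure (it returns 1 for
  perfectly anticorrelated equal-variance inputs) and exists only for
  comparison.
* Tumor means, ROI curve differences, Bland-Altman tables, and paired
  Wilcoxon signed-rank comparisons across sampling-mask seeds (Holm
  adjusted).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EvalRecord",
    "ser",
    "ccc",
    "tumor_mean",
    "curve_difference",
    "bland_altman",
    "paired_compare",
]


@dataclass
class EvalRecord:
    """Per-(mask seed, regularizer) evaluation row."""

    seed: int
    regularizer: str
    ser_db: float
    ccc_ktrans: float
    ccc_ve: float
    tumor_mean_ktrans: float
    tumor_mean_ve: float
    achieved_R: float
    ccc_ktrans_tumor: float = np.nan
    ccc_ve_tumor: float = np.nan


def ser(x_hat: np.ndarray, x_fs: np.ndarray) -> float:
    """Signal-to-error ratio in dB; ``inf`` for an exact reconstruction."""
    x_hat = np.asarray(x_hat)
    x_fs = np.asarray(x_fs)
    if x_hat.shape != x_fs.shape:
        raise ValueError("shapes disagree")
    ref = float(np.linalg.norm(x_fs.ravel()))
    if ref == 0.0:
        raise ValueError("reference image is identically zero")
    err = float(np.linalg.norm((x_hat - x_fs).ravel()))
    if err == 0.0:
        return float("inf")
    return -20.0 * np.log10(err / ref)


def ccc(a: np.ndarray, b: np.ndarray, form: str = "lin") -> float:
    """Concordance correlation coefficient between two parameter vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("length mismatch")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    mu_a, mu_b = a.mean(), b.mean()
    var_a = float(np.mean((a - mu_a) ** 2))
    var_b = float(np.mean((b - mu_b) ** 2))
    denom = var_a + var_b + (mu_a - mu_b) ** 2
    if denom == 0.0:
        raise ValueError("both inputs are constant and equal")
    if form == "lin":
        cov = float(np.mean((a - mu_a) * (b - mu_b)))
        return 2.0 * cov / denom
    if form == "as_printed":
        return 2.0 * np.sqrt(var_a) * np.sqrt(var_b) / denom
    raise ValueError("form must be 'lin' or 'as_printed'")


def tumor_mean(param_map: np.ndarray, tumor_mask: np.ndarray) -> float:
    """Mean of the defined (finite) estimates over the tumor ROI."""
    param_map = np.asarray(param_map, dtype=float)
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if not tumor_mask.any():
        raise ValueError("tumor mask is empty")
    vals = param_map[tumor_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no defined estimates inside the tumor mask")
    return float(vals.mean())


def curve_difference(x_hat: np.ndarray, x_fs: np.ndarray,
                     tumor_mask: np.ndarray,
                     voxel: tuple[int, int] | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """ROI-mean and per-voxel magnitude signal differences over time.

    Returns ``(mean_delta, voxel_delta)`` where ``mean_delta[t]`` is the
    difference of the ROI-mean magnitudes at dynamic ``t`` and
    ``voxel_delta`` is either the requested voxel's difference curve or the
    full (n_roi, d) array of per-voxel difference curves.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if not tumor_mask.any():
        raise ValueError("tumor mask is empty")
    a = np.abs(np.asarray(x_hat))
    b = np.abs(np.asarray(x_fs))
    if a.shape != b.shape:
        raise ValueError("shapes disagree")
    mean_delta = a[tumor_mask].mean(axis=0) - b[tumor_mask].mean(axis=0)
    if voxel is not None:
        voxel_delta = a[voxel] - b[voxel]
    else:
        voxel_delta = a[tumor_mask] - b[tumor_mask]
    return mean_delta, voxel_delta


def bland_altman(a: np.ndarray, b_fs: np.ndarray,
                 abscissa: str = "reference") -> dict:
    """Bland-Altman data for parameter agreement against a reference.

    ``abscissa="reference"`` plots differences against the fully sampled
    values; ``"mean"`` uses the conventional pairwise mean. Limits of
    agreement are ``bias +/- 1.96 SD``.
    """
    a = np.asarray(a, dtype=float).ravel()
    b_fs = np.asarray(b_fs, dtype=float).ravel()
    if a.size != b_fs.size:
        raise ValueError("length mismatch")
    if abscissa == "reference":
        x = b_fs.copy()
    elif abscissa == "mean":
        x = 0.5 * (a + b_fs)
    else:
        raise ValueError("abscissa must be 'reference' or 'mean'")
    diff = a - b_fs
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    return {
        "abscissa": x,
        "difference": diff,
        "bias": bias,
        "loa_lower": bias - 1.96 * sd,
        "loa_upper": bias + 1.96 * sd,
    }


def paired_compare(records_by_regularizer: dict[str, np.ndarray],
                   metric: str = "", adjust: str = "holm") -> pd.DataFrame:
    """Pairwise paired Wilcoxon signed-rank tests across mask seeds.

    Every regularizer must contribute a metric vector over the same seed
    set. Returns a tidy frame with raw and Holm-adjusted two-sided
    p-values; identical vectors give p = 1.
    """
    names = list(records_by_regularizer)
    if len(names) < 2:
        raise ValueError("need at least two regularizers")
    lengths = {len(np.asarray(v)) for v in records_by_regularizer.values()}
    if len(lengths) != 1:
        raise ValueError("metric vectors must cover the same seed set")
    rows = []
    for a_name, b_name in combinations(names, 2):
        a = np.asarray(records_by_regularizer[a_name], dtype=float)
        b = np.asarray(records_by_regularizer[b_name], dtype=float)
        if np.allclose(a, b):
            p = 1.0
        else:
            p = float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
        rows.append({"regularizer_a": a_name, "regularizer_b": b_name,
                     "metric": metric, "p_raw": p})
    frame = pd.DataFrame(rows)
    frame["p_adjusted"] = multipletests(frame["p_raw"].to_numpy(),
                                        method=adjust)[1]
    return frame
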