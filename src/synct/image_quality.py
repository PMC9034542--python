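"""Stage-1 validation: slice-wise MAE, PSNR and SSIM with cohort stats.

MAE is the voxel mean of absolute differences; PSNR is
``10 log10(MAX_I^2 / MSE)`` with ``MAX_I`` the maximum possible pixel
value (default 650, the [-150, 500] HU contrast-window width, since
metrics are computed on the clipped-HU scale); SSIM follows the
Wang et al. formulation with an 11 x 11 Gaussian window (sigma 1.5) and
stabilizers ``c1 = (k1 L)^2``, ``c2 = (k2 L)^2`` (k1 = 0.01, k2 = 0.03).

Cohort evaluation compares two arms (synthetic-vs-real and
input-vs-real) per slice and reports mean +- SD per metric with a
two-sample t-test between arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import correlate1d


@dataclass(frozen=True)
class MetricConfig:
    max_val: float = 650.0          # contrast-window width on the clipped-HU scale
    ssim_window: int = 11
    ssim_sigma: float = 1.5
    ssim_k1: float = 0.01
    ssim_k2: float = 0.03
    equal_var_ttest: bool = True    # Welch variant when False

    def __post_init__(self):
        if self.max_val <= 0:
            raise ValueError("max_val must be positive")
        if self.ssim_window % 2 == 0:
            raise ValueError("ssim window size must be odd")


def mae(x, y) -> float:
    """Mean absolute error over voxels."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    return float(np.abs(y - x).mean())


def psnr(x, y, config: MetricConfig = MetricConfig()) -> float:
    """Peak signal-to-noise ratio in dB; identical images give +inf."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    mse = float(((y - x) ** 2).mean())
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(config.max_val ** 2 / mse))


def _gaussian_kernel(size, sigma):
    r = np.arange(size) - (size - 1) / 2
    k = np.exp(-(r ** 2) / (2 * sigma ** 2))
    return k / k.sum()


def ssim(x, y, config: MetricConfig = MetricConfig()) -> float:
    """Structural similarity on 2-D images, Gaussian-window statistics.

    Local means, variances and covariance are computed under a
    normalized Gaussian window; the per-position index map is averaged
    over all positions where the window fits entirely inside the image.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    w = config.ssim_window
    if min(x.shape) < w:
        raise ValueError(f"image {x.shape} smaller than SSIM window {w}")
    L = config.max_val
    c1 = (config.ssim_k1 * L) ** 2
    c2 = (config.ssim_k2 * L) ** 2
    k = _gaussian_kernel(w, config.ssim_sigma)

    def filt(a):
        return correlate1d(correlate1d(a, k, axis=0), k, axis=1)

    pad = (w - 1) // 2
    valid = (slice(pad, x.shape[0] - pad), slice(pad, x.shape[1] - pad))
    mu_x = filt(x)[valid]
    mu_y = filt(y)[valid]
    var_x = filt(x * x)[valid] - mu_x ** 2
    var_y = filt(y * y)[valid] - mu_y ** 2
    cov = filt(x * y)[valid] - mu_x * mu_y
    num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
    den = (mu_x ** 2 + mu_y ** 2 + c1) * (var_x + var_y + c2)
    return float((num / den).mean())


def ssim_brute_force(x, y, config: MetricConfig = MetricConfig()) -> float:
    """Reference SSIM by explicit window loops (oracle for :func:`ssim`)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    w = config.ssim_window
    L = config.max_val
    c1 = (config.ssim_k1 * L) ** 2
    c2 = (config.ssim_k2 * L) ** 2
    k1d = _gaussian_kernel(w, config.ssim_sigma)
    k2d = np.outer(k1d, k1d)
    vals = []
    for i in range(x.shape[0] - w + 1):
        for j in range(x.shape[1] - w + 1):
            xw = x[i:i + w, j:j + w]
            yw = y[i:i + w, j:j + w]
            mx = (k2d * xw).sum()
            my = (k2d * yw).sum()
            vx = (k2d * xw * xw).sum() - mx ** 2
            vy = (k2d * yw * yw).sum() - my ** 2
            cxy = (k2d * xw * yw).sum() - mx * my
            vals.append(((2 * mx * my + c1) * (2 * cxy + c2))
                        / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))
    return float(np.mean(vals))


@dataclass
class CohortMetrics:
    """Per-slice metrics for both arms, summaries and t-test p-values."""

    per_slice: pd.DataFrame            # columns: arm, slice, mae, psnr, ssim
    summary: pd.DataFrame              # arm x metric mean/sd
    p_values: dict[str, float]
    psnr_inf_counts: dict[str, int]
    config: MetricConfig


def arm_ttest(values_a, values_b, equal_var=True):
    """Two-sample t-test between per-slice metric arms."""
    res = stats.ttest_ind(np.asarray(values_a, float),
                          np.asarray(values_b, float), equal_var=equal_var)
    return float(res.pvalue)


def summarize_arms(per_slice: pd.DataFrame, config: MetricConfig):
    """Mean +- SD per arm and per-metric t-tests; +inf PSNR is excluded
    from summaries with an exclusion count rather than clamped."""
    arms = sorted(per_slice["arm"].unique())
    rows, pvals, inf_counts = [], {}, {}
    for arm in arms:
        sub = per_slice[per_slice["arm"] == arm]
        finite_psnr = sub["psnr"][np.isfinite(sub["psnr"])]
        inf_counts[arm] = int((~np.isfinite(sub["psnr"])).sum())
        rows.append({
            "arm": arm,
            "mae_mean": sub["mae"].mean(), "mae_sd": sub["mae"].std(ddof=1),
            "psnr_mean": finite_psnr.mean(), "psnr_sd": finite_psnr.std(ddof=1),
            "ssim_mean": sub["ssim"].mean(), "ssim_sd": sub["ssim"].std(ddof=1),
        })
    if len(arms) == 2:
        a = per_slice[per_slice["arm"] == arms[0]]
        b = per_slice[per_slice["arm"] == arms[1]]
        for m in ("mae", "psnr", "ssim"):
            va, vb = a[m], b[m]
            if m == "psnr":
                va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
            pvals[m] = arm_ttest(va, vb, config.equal_var_ttest)
    return pd.DataFrame(rows).set_index("arm"), pvals, inf_counts


def evaluate_cohort(triplets, config: MetricConfig = MetricConfig()) -> CohortMetrics:
    """Slice-wise metrics for SCECT-vs-CECT and NCT-vs-CECT arms.

    ``triplets`` is an iterable of (nct, scect, cect) stacks, each shaped
    (n_slices, H, W) on the clipped-HU scale (or any common scale; the
    scale must match ``config.max_val``).
    """
    records = []
    n_done = 0
    for t_idx, (nct, scect, cect) in enumerate(triplets):
        nct, scect, cect = (np.asarray(v, float) for v in (nct, scect, cect))
        for k in range(cect.shape[0]):
            records.append({"arm": "scect_vs_cect", "case": t_idx, "slice": k,
                            "mae": mae(scect[k], cect[k]),
                            "psnr": psnr(scect[k], cect[k], config),
                            "ssim": ssim(scect[k], cect[k], config)})
            records.append({"arm": "nct_vs_cect", "case": t_idx, "slice": k,
                            "mae": mae(nct[k], cect[k]),
                            "psnr": psnr(nct[k], cect[k], config),
                            "ssim": ssim(nct[k], cect[k], config)})
        n_done += 1
    if n_done < 2:
        raise ValueError("cohort evaluation needs at least 2 cases")
    per_slice = pd.DataFrame.from_records(records)
    summary, pvals, inf_counts = summarize_arms(per_slice, config)
    return CohortMetrics(per_slice, summary, pvals, inf_counts, config)
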