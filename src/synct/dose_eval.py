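"""Stage-3 validation: DVH computation and dose-volume metric comparison.

Dose is resampled (trilinearly) onto the CT grid so one structure
voxelization serves both the geometric and dosimetric stages.  Volumes
are voxel-counted (every structure voxel weighs the same); ``D_max`` is
the maximum voxel dose, ``D_mean`` the arithmetic voxel mean, and
``V_t`` the percentage of structure voxels receiving >= t Gy
(inclusive threshold).  Cumulative DVHs use a uniform bin width
(default 0.01 Gy), start at 100% at 0 Gy and decrease monotonically
to 0 beyond the maximum dose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import CTVolume, DoseGrid, GeometryError, Grid, StructureMask

DEFAULT_THRESHOLDS = (5.0, 10.0, 20.0, 30.0, 40.0)


@dataclass
class DVHCurve:
    """Cumulative dose-volume curve for one structure."""

    dose_bins: np.ndarray          # Gy edges, uniform width, starting at 0
    cumulative_volume: np.ndarray  # fraction of volume receiving >= edge dose
    structure: str
    total_volume_cc: float

    def __post_init__(self):
        cv = self.cumulative_volume
        if cv[0] != 1.0 or np.any(np.diff(cv) > 1e-12):
            raise ValueError("cumulative DVH must start at 1.0 and be "
                             "monotone non-increasing")

    @property
    def bin_width(self):
        return float(self.dose_bins[1] - self.dose_bins[0])


@dataclass
class DoseMetrics:
    d_max: float
    d_mean: float
    v_at: dict[float, float]   # threshold Gy -> % volume

    def as_row(self):
        row = {"d_max_gy": self.d_max, "d_mean_gy": self.d_mean}
        row.update({f"v{int(t)}gy_pct": v for t, v in self.v_at.items()})
        return row


def resample_dose_to_grid(dose: DoseGrid, reference: CTVolume) -> DoseGrid:
    """Trilinear resample of the dose onto the reference voxel centers.

    Points outside the dose grid get 0 Gy; if any fall outside, a
    coverage-fraction warning is issued.  Zero spatial overlap raises.
    """
    if dose.grid.same_as(reference.grid):
        return DoseGrid(dose.voxels.copy(), dose.grid)
    idx = []
    inside_frac = 1.0
    for a in range(3):
        world = (reference.grid.origin[a]
                 + np.arange(reference.grid.shape[a]) * reference.grid.spacing[a])
        idx.append((world - dose.grid.origin[a]) / dose.grid.spacing[a])
    I, J, K = np.meshgrid(*idx, indexing="ij")
    inside = np.ones(I.shape, dtype=bool)
    for arr, n in zip((I, J, K), dose.grid.shape):
        inside &= (arr >= 0) & (arr <= n - 1)
    if not inside.any():
        raise GeometryError("dose grid and reference grid do not overlap")
    inside_frac = float(inside.mean())
    if inside_frac < 1.0:
        warnings.warn(f"dose grid covers only {inside_frac:.1%} of the "
                      "reference grid; uncovered voxels set to 0 Gy")
    out = ndimage.map_coordinates(dose.voxels, np.stack([I, J, K]),
                                  order=1, mode="constant", cval=0.0)
    out[~inside] = 0.0
    return DoseGrid(np.maximum(out, 0.0).astype(np.float32), reference.grid)


def structure_doses(mask: StructureMask, dose: DoseGrid) -> np.ndarray:
    if not mask.grid.same_as(dose.grid):
        raise GeometryError("structure and dose must share a grid")
    if mask.is_empty:
        raise ValueError(f"structure {mask.name!r} is empty")
    return np.asarray(dose.voxels[mask.mask], dtype=float)


def compute_dvh(mask: StructureMask, dose: DoseGrid,
                bin_width: float = 0.01) -> DVHCurve:
    """Cumulative DVH over structure voxels (unweighted voxel counting)."""
    doses = structure_doses(mask, dose)
    n_bins = int(np.ceil(doses.max() / bin_width)) + 2
    edges = np.arange(n_bins + 1) * bin_width
    # fraction of voxels with dose >= edge
    counts, _ = np.histogram(doses, bins=np.append(edges, np.inf))
    cum = counts[::-1].cumsum()[::-1] / doses.size
    return DVHCurve(edges, np.append(cum, 0.0)[:len(edges)], mask.name,
                    mask.volume_cc)


def dose_metrics(curve_or_voxels, thresholds=DEFAULT_THRESHOLDS) -> DoseMetrics:
    """D_max, D_mean and V_t metrics from voxel doses or a DVH curve."""
    if isinstance(curve_or_voxels, DVHCurve):
        c = curve_or_voxels
        diff = -np.diff(np.append(c.cumulative_volume, 0.0))
        centers = c.dose_bins + c.bin_width / 2
        d_mean = float((diff * centers).sum())
        nz = np.nonzero(diff)[0]
        d_max = float(centers[nz[-1]]) if len(nz) else 0.0
        v_at = {}
        for t in thresholds:
            k = int(np.searchsorted(c.dose_bins, t, side="left"))
            v_at[t] = float(100.0 * c.cumulative_volume[min(k, len(c.cumulative_volume) - 1)]) \
                if t <= c.dose_bins[-1] else 0.0
        return DoseMetrics(d_max, d_mean, v_at)
    doses = np.asarray(curve_or_voxels, dtype=float)
    if doses.size == 0:
        raise ValueError("no voxel doses given")
    return DoseMetrics(
        d_max=float(doses.max()),
        d_mean=float(doses.mean()),
        v_at={t: float(100.0 * (doses >= t).mean()) for t in thresholds},
    )


def average_dvh(curves) -> DVHCurve:
    """Pointwise mean of cumulative fractions across curves (shared binning)."""
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    width = curves[0].bin_width
    n = max(len(c.dose_bins) for c in curves)
    edges = np.arange(n) * width
    acc = np.zeros(n)
    for c in curves:
        if abs(c.bin_width - width) > 1e-12:
            raise ValueError("curves must share bin width")
        cv = np.zeros(n)
        cv[:len(c.cumulative_volume)] = c.cumulative_volume
        acc += cv
    mean_cv = acc / len(curves)
    return DVHCurve(edges, mean_cv, "average",
                    float(np.mean([c.total_volume_cc for c in curves])))


def compare_dosimetry(sets_a, sets_b, doses, thresholds=DEFAULT_THRESHOLDS):
    """Absolute dose-metric differences per structure, cohort mean +- SD.

    ``sets_a`` / ``sets_b`` are per-case structure-set dicts (paired by
    position) and ``doses`` the per-case dose grids already on the
    structure grid; the same dose field is applied to both sets of each
    case (plan transfer, no re-optimization).  Returns a table of
    mean +- SD absolute differences per metric with per-metric
    two-sample t-test p-values across the cohorts, plus missing-row
    flags.
    """
    sets_a, sets_b, doses = list(sets_a), list(sets_b), list(doses)
    if not (len(sets_a) == len(sets_b) == len(doses)):
        raise ValueError("cohorts must pair case-by-case")
    names = sorted({n for s in sets_a for n in s} | {n for s in sets_b for n in s})
    diff_records, raw_a, raw_b, missing = [], [], [], []
    for case, (sa, sb, dg) in enumerate(zip(sets_a, sets_b, doses)):
        for name in names:
            if name not in sa or name not in sb or sa[name].is_empty \
                    or sb[name].is_empty:
                missing.append((case, name))
                continue
            ma = dose_metrics(structure_doses(sa[name], dg), thresholds)
            mb = dose_metrics(structure_doses(sb[name], dg), thresholds)
            ra, rb = ma.as_row(), mb.as_row()
            raw_a.append({"case": case, "structure": name, **ra})
            raw_b.append({"case": case, "structure": name, **rb})
            diff_records.append({"case": case, "structure": name,
                                 **{k: abs(ra[k] - rb[k]) for k in ra}})
    if not diff_records:
        raise ValueError("no comparable structures in any case")
    diffs = pd.DataFrame.from_records(diff_records)
    metric_cols = [c for c in diffs.columns if c not in ("case", "structure")]
    table = diffs.groupby("structure")[metric_cols].agg(["mean", "std"])
    da = pd.DataFrame.from_records(raw_a)
    db = pd.DataFrame.from_records(raw_b)
    pvals = {}
    for c in metric_cols:
        va, vb = da[c].to_numpy(), db[c].to_numpy()
        if np.allclose(va, va[0]) and np.allclose(vb, vb[0]):
            # zero-variance cohorts: the test is degenerate
            pvals[c] = 1.0 if np.isclose(va[0], vb[0]) else 0.0
        elif va.size < 2:
            pvals[c] = float("nan")
        else:
            pvals[c] = float(stats.ttest_ind(va, vb).pvalue)
    return table, diffs, pvals, missing
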