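"""Procedural paired-CT phantom generator.

Builds co-registered non-contrast / contrast-enhanced chest phantoms with
known ground truth: an elliptical torso with two low-density lungs, a
four-chamber heart (ellipsoid partitioned by two curved septal surfaces,
wrapped in a myocardial shell), two surface coronary vessels (LAD on the
anterior left-ventricular surface, RCA in the right atrioventricular
groove) and a great-vessel stub.  The contrast-enhanced member adds a
per-sample jittered enhancement to every blood-pool voxel; both members
carry independent Gaussian noise.  A tangential-wedge dose field with
exponential lateral falloff emulates breast-radiotherapy exposure of the
heart.

All geometry is parameterised by the grid extent, so the same anatomy
scales from desk-size grids to clinical resolution.  Identical
``(config, index)`` always reproduces bit-identical samples.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from .core import CTVolume, DoseGrid, Grid, GeometryError, PairedSample, StructureMask

AIR_HU = -1000.0


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for phantom generation.

    HU baselines are chosen so that windowing at [-150, 500] HU never
    clips enhanced blood (45 + 150 + 50 = 245 HU worst case).
    """

    grid_shape: tuple[int, int, int] = (192, 192, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.5)
    body_hu: float = 40.0
    lung_hu: float = -750.0
    myocardium_hu: float = 40.0
    blood_hu: float = 45.0
    enhancement_hu: float = 150.0
    enhancement_jitter_hu: float = 50.0
    noise_sigma: float = 10.0
    vessel_radius_mm: float = 2.5
    n_samples: int = 8
    seed: int = 0

    def __post_init__(self):
        if any(s < 32 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be >= 32 per axis, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.enhancement_jitter_hu < 0:
            raise ValueError("enhancement jitter must be non-negative")

    @property
    def grid(self):
        return Grid(self.grid_shape, self.spacing)


@dataclass
class PhantomSample:
    """One generated phantom: image pair, truth masks, optional dose."""

    index: int
    pair: PairedSample
    structures: dict[str, StructureMask]
    truth_enhancement: np.ndarray
    dose: DoseGrid | None = None
    applied_enhancement_hu: float = 0.0

    @property
    def grid(self):
        return self.pair.grid

    @property
    def blood_pool(self):
        return self.truth_enhancement != 0


def _normalized_heart_coords(grid):
    """World meshgrid, heart center and semi-axes, normalized coords."""
    ex, ey, ez = grid.extent
    cx, cy, cz = ex / 2, ey / 2, ez / 2
    center = np.array([cx + 0.07 * ex, cy - 0.05 * ey, cz])
    semi = np.array([0.17 * ex, 0.17 * ey, 0.30 * ez])
    if np.any(semi / np.array(grid.spacing) < 4):
        raise GeometryError(
            f"grid {grid.shape} at spacing {grid.spacing} is too small to "
            "contain the heart model (needs >= 4 voxels per heart semi-axis)")
    ax = grid.voxel_centers()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    U = (X - center[0]) / semi[0]
    V = (Y - center[1]) / semi[1]
    W = (Z - center[2]) / semi[2]
    return (X, Y, Z), center, semi, (U, V, W)


def _tube_mask(grid, curve_points, radius_mm):
    """Voxels whose center lies within radius of a sampled 3-D curve."""
    ax = grid.voxel_centers()
    lo = curve_points.min(axis=0) - radius_mm - max(grid.spacing)
    hi = curve_points.max(axis=0) + radius_mm + max(grid.spacing)
    sl = tuple(slice(int(np.searchsorted(a, l)), int(np.searchsorted(a, h)) + 1)
               for a, l, h in zip(ax, lo, hi))
    sub_ax = [a[s] for a, s in zip(ax, sl)]
    X, Y, Z = np.meshgrid(*sub_ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    d, _ = cKDTree(curve_points).query(pts, workers=1)
    mask = np.zeros(grid.shape, dtype=bool)
    mask[sl] = (d <= radius_mm).reshape(X.shape)
    return mask


def _build_geometry(grid):
    """Deterministic anatomy masks; no randomness enters here."""
    (X, Y, Z), center, semi, (U, V, W) = _normalized_heart_coords(grid)
    ex, ey, ez = grid.extent
    cx, cy = ex / 2, ey / 2

    torso = (((X - cx) / (0.45 * ex)) ** 2 + ((Y - cy) / (0.38 * ey)) ** 2) <= 1.0

    lungs = np.zeros(grid.shape, dtype=bool)
    for sx in (-1.0, 1.0):
        lc = np.array([cx + sx * 0.24 * ex, cy - 0.03 * ey, ez / 2])
        lungs |= (((X - lc[0]) / (0.15 * ex)) ** 2
                  + ((Y - lc[1]) / (0.26 * ey)) ** 2
                  + ((Z - lc[2]) / (0.42 * ez)) ** 2) <= 1.0
    lungs &= torso

    rho2 = U * U + V * V + W * W
    heart = rho2 <= 1.0
    interior = rho2 <= 0.8 ** 2  # blood-pool candidate; shell outside is myocardium

    # two curved septal surfaces partition the interior into four chambers
    f_lr = U - 0.18 * np.sin(np.pi * np.clip(V, -1, 1))      # left-right septum
    f_av = W - 0.15 * np.sin(np.pi * np.clip(U, -1, 1)) - 0.2  # atrioventricular plane
    t1, t2 = 0.08, 0.08
    chambers = {
        "lv": interior & (f_lr > t1) & (f_av < -t2),
        "rv": interior & (f_lr < -t1) & (f_av < -t2),
        "la": interior & (f_lr > t1) & (f_av > t2),
        "ra": interior & (f_lr < -t1) & (f_av > t2),
    }

    # LAD: spline down the anterior LV surface (patient left = +x, anterior = -y)
    t = np.linspace(0.0, 1.0, 200)
    phi = np.pi * (0.18 + 0.55 * t)
    theta = -1.25 + 0.55 * np.sin(np.pi * t)
    lad_pts = center + np.column_stack([
        np.sin(phi) * np.cos(theta) * semi[0],
        np.sin(phi) * np.sin(theta) * semi[1],
        np.cos(phi) * semi[2],
    ])
    # RCA: along the right atrioventricular groove
    phi_r = np.arccos(np.clip(0.22 + 0.10 * np.sin(np.pi * t), -1, 1))
    theta_r = -1.95 - 0.85 * t
    rca_pts = center + np.column_stack([
        np.sin(phi_r) * np.cos(theta_r) * semi[0],
        np.sin(phi_r) * np.sin(theta_r) * semi[1],
        np.cos(phi_r) * semi[2],
    ])
    vessel_masks = {"lad": lad_pts, "rca": rca_pts}

    # ascending great-vessel stub, connecting the heart base upward
    stub_center = center + np.array([0.1 * semi[0], 0.1 * semi[1], 0.0])
    stub = ((X - stub_center[0]) ** 2 + (Y - stub_center[1]) ** 2
            <= (0.06 * ex) ** 2) & (Z >= center[2] + 0.5 * semi[2]) \
        & (Z <= center[2] + 1.6 * semi[2])
    stub &= torso

    return torso, lungs, heart, chambers, vessel_masks, stub


def simulate_pair(config: PhantomConfig, index: int) -> PhantomSample:
    """Generate one co-registered NCT/CECT phantom with truth masks.

    Randomness (noise fields, per-sample enhancement jitter) derives from
    ``(config.seed, index)`` only.
    """
    if index >= config.n_samples:
        raise ValueError(f"index {index} >= n_samples {config.n_samples}")
    grid = config.grid
    torso, lungs, heart, chambers, vessel_curves, stub = _build_geometry(grid)

    vessels = {name: _tube_mask(grid, pts, config.vessel_radius_mm)
               for name, pts in vessel_curves.items()}

    chamber_blood = np.zeros(grid.shape, dtype=bool)
    for m in chambers.values():
        chamber_blood |= m
    blood = chamber_blood | vessels["lad"] | vessels["rca"] | stub

    template = np.full(grid.shape, AIR_HU, dtype=np.float32)
    template[torso] = config.body_hu
    template[lungs] = config.lung_hu
    template[heart] = config.myocardium_hu
    template[blood] = config.blood_hu

    rng = np.random.default_rng([config.seed, index])
    jitter = rng.uniform(-config.enhancement_jitter_hu, config.enhancement_jitter_hu) \
        if config.enhancement_jitter_hu > 0 else 0.0
    enhancement = float(config.enhancement_hu + jitter)

    truth = np.zeros(grid.shape, dtype=np.float32)
    truth[blood] = enhancement

    def noisy(base):
        if config.noise_sigma > 0:
            return base + rng.normal(0.0, config.noise_sigma,
                                     size=grid.shape).astype(np.float32)
        return base.copy()

    nct = noisy(template)
    cect = noisy(template + truth)

    structures = {"heart": StructureMask("heart", heart, grid)}
    for name, m in chambers.items():
        structures[name] = StructureMask(name, m, grid)
    for name, m in vessels.items():
        structures[name] = StructureMask(name, m, grid)

    return PhantomSample(
        index=index,
        pair=PairedSample(CTVolume(nct, grid), CTVolume(cect, grid)),
        structures=structures,
        truth_enhancement=truth,
        applied_enhancement_hu=enhancement,
    )


def simulate_dose(sample: PhantomSample, laterality: str = "left",
                  prescription: float = 40.0, falloff_mm: float = 20.0) -> DoseGrid:
    """Tangential-wedge dose field with exponential lateral falloff.

    The wedge covers the anterior chest wall of the given side at full
    prescription; dose decays as ``exp(-d / falloff_mm)`` with distance
    ``d`` from the wedge boundary.  ``falloff_mm -> 0`` gives a binary
    field.  Default left-sided geometry keeps the mean heart dose below
    the 5 Gy range typical of tangential breast plans.
    """
    if laterality not in ("left", "right", "bilateral"):
        raise ValueError(f"unknown laterality {laterality!r}")
    grid = sample.grid
    ex, ey, _ = grid.extent
    ax = grid.voxel_centers()
    X, Y = np.meshgrid(ax[0], ax[1], indexing="ij")

    def side_distance(sign):
        # plane through the anterior chest-wall corner of that side,
        # normal pointing into the torso
        p0 = np.array([ex / 2 + sign * 0.25 * ex, ey / 2 - 0.30 * ey])
        n = np.array([-sign * 0.6, 1.0])
        n = n / np.linalg.norm(n)
        return n[0] * (X - p0[0]) + n[1] * (Y - p0[1])

    if laterality == "left":
        d = side_distance(+1.0)
    elif laterality == "right":
        d = side_distance(-1.0)
    else:
        d = np.minimum(side_distance(+1.0), side_distance(-1.0))

    if falloff_mm <= 0:
        plane = (d <= 0).astype(np.float32) * prescription
    else:
        plane = prescription * np.exp(-np.maximum(d, 0.0) / falloff_mm)
        plane = plane.astype(np.float32)
    dose = np.repeat(plane[:, :, None], grid.shape[2], axis=2)
    return DoseGrid(dose, grid)


def simulate_cohort(config: PhantomConfig, laterality: str = "left",
                    prescription: float = 40.0):
    """Generate all ``config.n_samples`` phantoms, each with its dose field."""
    samples = []
    for i in range(config.n_samples):
        s = simulate_pair(config, i)
        s.dose = simulate_dose(s, laterality=laterality, prescription=prescription)
        samples.append(s)
    return samples


def write_sample(sample: PhantomSample, out_dir: str):
    """Write NCT/CECT/dose and per-structure masks as NIfTI plus a manifest."""
    from . import ct_io

    os.makedirs(out_dir, exist_ok=True)
    tag = f"sample_{sample.index:03d}"
    paths = {
        "nct": os.path.join(out_dir, f"{tag}_nct.nii"),
        "cect": os.path.join(out_dir, f"{tag}_cect.nii"),
    }
    ct_io.write_nifti(sample.pair.nct, paths["nct"])
    ct_io.write_nifti(sample.pair.cect, paths["cect"])
    if sample.dose is not None:
        paths["dose"] = os.path.join(out_dir, f"{tag}_dose.nii")
        ct_io.write_nifti(CTVolume(sample.dose.voxels, sample.grid), paths["dose"])
    for name, sm in sample.structures.items():
        p = os.path.join(out_dir, f"{tag}_mask_{name}.nii")
        ct_io.write_nifti(CTVolume(sm.mask.astype(np.float32), sm.grid), p)
        paths[f"mask_{name}"] = p
    manifest = {
        "index": sample.index,
        "applied_enhancement_hu": sample.applied_enhancement_hu,
        "paths": paths,
    }
    with open(os.path.join(out_dir, f"{tag}_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
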