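"""Synthetic fMOST-like data: atlases, ground-truth puncta, rendered volumes.

The generator stands in for the study's raw whole-brain imaging data. It
emulates block-face fluorescence tomography sampled at 0.2 x 0.2 x 1 um and
puncta of ~0.8 um full width at half maximum, laid down at region-dependent
densities expressed in the field's convention: puncta per mm^3 of region
volume per starter neuron. The inverse of that convention gives the expected
count used for sampling::

    E[count in region] = density * region_volume_mm3 * n_starters

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence` spawning, so each sample and each stage
(spot placement, rendering noise) is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .volumes import CHANNEL_GREEN, CHANNEL_RED, UM3_PER_MM3, ImageVolume, LabelAtlas

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548

#: Columns of a ground-truth spot table.
TRUTH_COLUMNS = ["id", "z_um", "y_um", "x_um", "region_label", "amplitude"]

# Stage tags mixed into spawned seed sequences so that e.g. re-rendering a
# fixed ground truth does not perturb spot placement.
_STAGE_SPOTS = 101
_STAGE_RENDER = 202
_STAGE_COHORT = 303


class AtlasPartitionError(ValueError):
    """Raised when a requested region count cannot tile the brain mask."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic imaging experiment.

    Defaults follow the imaging conditions the pipeline targets: fMOST-style
    anisotropic voxels of 1 x 0.2 x 0.2 um (z, y, x), puncta of 0.8 um FWHM,
    starter-neuron counts in the 1519-2351 range, cohorts of 4 samples per
    group, and a per-region density scale of ~2450 puncta/mm^3/neuron typical
    of strongly innervated target regions.
    """

    volume_shape: tuple[int, int, int] = (64, 128, 128)
    voxel_size: tuple[float, float, float] = (1.0, 0.2, 0.2)
    n_regions: int = 6
    region_density: Mapping[int, float] | None = None  # puncta / mm^3 / neuron
    uniform_density: float = 2450.0  # used when region_density is None
    n_starters: int = 2000
    punctum_fwhm: float = 0.8  # um
    punctum_amplitude: float = 150.0  # peak intensity above background, AU
    background_level: float = 100.0  # AU
    noise_model: str = "poisson+gaussian"  # poisson | gaussian | poisson+gaussian | none
    gaussian_sigma: float = 10.0  # read-noise sd, AU
    cluster_fraction: float = 0.0
    cluster_radius: float = 5.0  # um
    cluster_mean_size: int = 10  # mean puncta per basket-like cluster
    group_effect: Mapping[int, float] | None = None  # region -> AD density factor
    n_per_group: int = 4
    starter_range: tuple[int, int] = (1519, 2351)
    sample_cv: float = 0.10  # between-sample lognormal CV on densities
    seed: int = 0

    def __post_init__(self) -> None:
        self.volume_shape = tuple(int(s) for s in self.volume_shape)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(s < 1 for s in self.volume_shape):
            raise ValueError("volume_shape entries must be >= 1")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.punctum_fwhm <= 0:
            raise ValueError("punctum_fwhm must be positive")
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise ValueError("cluster_fraction must lie in [0, 1]")
        if self.region_density is not None and any(d < 0 for d in self.region_density.values()):
            raise ValueError("densities must be >= 0")
        if self.uniform_density < 0:
            raise ValueError("densities must be >= 0")
        if self.group_effect is not None and any(g < 0 for g in self.group_effect.values()):
            raise ValueError("group_effect factors must be >= 0")
        if self.sample_cv < 0:
            raise ValueError("sample_cv must be >= 0")

    def densities_for(self, atlas: LabelAtlas) -> dict[int, float]:
        """Resolve the per-region density map for a concrete atlas."""
        if self.region_density is not None:
            return {int(k): float(v) for k, v in self.region_density.items()}
        return {label: self.uniform_density for label in atlas.region_labels()}


@dataclass
class GroundTruth:
    """Generated puncta with their generative parameters.

    ``spots`` is a DataFrame with columns ``id, z_um, y_um, x_um,
    region_label, amplitude`` (coordinates in micrometres, amplitudes in the
    dimensionless units later scaled by ``punctum_amplitude`` at render time).
    """

    spots: pd.DataFrame
    per_region_expected_count: dict[int, float]
    per_region_true_density: dict[int, float]
    seed: int

    def __post_init__(self) -> None:
        missing = [c for c in TRUTH_COLUMNS if c not in self.spots.columns]
        if missing:
            raise ValueError(f"ground-truth table missing columns {missing}")

    @property
    def coords_um(self) -> np.ndarray:
        return self.spots[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)


@dataclass
class CohortSample:
    """One synthetic animal: atlas, truth, starter count and optional render."""

    sample_id: str
    group: str  # "CON" or "AD"
    atlas: LabelAtlas
    ground_truth: GroundTruth
    starter_count: int
    densities: dict[int, float]
    volume: ImageVolume | None = None


def make_atlas(
    volume_shape: Sequence[int],
    voxel_size: Sequence[float] = (1.0, 0.2, 0.2),
    n_regions: int = 6,
    seed: int = 0,
) -> LabelAtlas:
    """Build a toy brain atlas: an ellipsoid mask tiled into equal slabs.

    The mask is the ellipsoid inscribed in the volume (evaluated at voxel
    centres); label 0 marks voxels outside it. In-mask voxels, ordered
    lexicographically by (x, y, z), are split into ``n_regions`` contiguous
    chunks of near-equal voxel count, yielding axis-aligned slabs whose
    volumes are analytically checkable. The partition is deterministic; the
    seed is accepted for interface stability and recorded downstream.
    """
    shape = tuple(int(s) for s in volume_shape)
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    zz, yy, xx = np.meshgrid(
        (np.arange(shape[0]) + 0.5) / shape[0] * 2.0 - 1.0,
        (np.arange(shape[1]) + 0.5) / shape[1] * 2.0 - 1.0,
        (np.arange(shape[2]) + 0.5) / shape[2] * 2.0 - 1.0,
        indexing="ij",
    )
    mask = zz**2 + yy**2 + xx**2 <= 1.0
    n_mask = int(mask.sum())
    if n_mask < n_regions:
        raise AtlasPartitionError(
            f"atlas partition infeasible: {n_regions} regions requested but the "
            f"brain mask holds only {n_mask} voxels"
        )
    labels = np.zeros(shape, dtype=np.uint16)
    zi, yi, xi = np.nonzero(mask)
    order = np.lexsort((zi, yi, xi))  # x-major raster order -> x slabs
    bounds = np.linspace(0, n_mask, n_regions + 1).round().astype(int)
    for region in range(1, n_regions + 1):
        sel = order[bounds[region - 1] : bounds[region]]
        labels[zi[sel], yi[sel], xi[sel]] = region
    ontology = {0: {"acronym": "BG", "name": "outside brain"}}
    for region in range(1, n_regions + 1):
        ontology[region] = {"acronym": f"R{region:02d}", "name": f"synthetic region {region}"}
    return LabelAtlas(labels=labels, voxel_size=tuple(voxel_size), ontology=ontology)


def _region_voxels(atlas: LabelAtlas) -> dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    out = {}
    for label in atlas.region_labels():
        out[label] = np.nonzero(atlas.labels == label)
    return out


def sample_spots(
    atlas: LabelAtlas,
    region_density: Mapping[int, float],
    n_starters: int,
    cluster_fraction: float = 0.0,
    cluster_radius: float = 5.0,
    seed: int = 0,
    cluster_mean_size: int = 10,
    amplitude: float = 1.0,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Draw ground-truth puncta positions for one sample.

    Per region the count is Poisson with mean ``density * volume_mm3 *
    n_starters``. A ``1 - cluster_fraction`` share of the puncta is placed
    uniformly over the region's voxels (uniform jitter within the voxel); the
    rest go into basket-like Gaussian clusters of scale ``cluster_radius``
    around uniformly drawn centres, rejecting draws that land outside the
    region.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_SPOTS]))
    d = np.asarray(atlas.voxel_size)
    voxels = _region_voxels(atlas)
    for label in region_density:
        if int(label) not in voxels:
            raise KeyError(f"region label {label} not present in atlas")

    rows_z, rows_y, rows_x, rows_label = [], [], [], []
    expected: dict[int, float] = {}
    for label in sorted(int(k) for k in region_density):
        density = float(region_density[label])
        if density < 0:
            raise ValueError(f"density for region {label} must be >= 0")
        vol_mm3 = atlas.region_volume_mm3(label)
        lam = density * vol_mm3 * n_starters
        expected[label] = lam
        n = int(rng.poisson(lam))
        if n == 0:
            continue
        vz, vy, vx = voxels[label]
        n_clustered = int(round(cluster_fraction * n))
        n_uniform = n - n_clustered

        def uniform_draw(count: int) -> np.ndarray:
            idx = rng.integers(0, len(vz), size=count)
            base = np.stack([vz[idx], vy[idx], vx[idx]], axis=1).astype(float)
            return (base + rng.random((count, 3))) * d

        pts = [uniform_draw(n_uniform)] if n_uniform else []
        if n_clustered:
            n_clusters = max(1, int(round(n_clustered / max(cluster_mean_size, 1))))
            centers = uniform_draw(n_clusters)
            assignment = rng.integers(0, n_clusters, size=n_clustered)
            pos = centers[assignment] + rng.normal(0.0, cluster_radius, size=(n_clustered, 3))
            # rejection: resample offsets until the point lies inside the region
            for _ in range(200):
                idx = np.floor(pos / d).astype(int)
                ok = np.all(idx >= 0, axis=1) & np.all(idx < atlas.labels.shape, axis=1)
                inside = np.zeros(len(pos), dtype=bool)
                if ok.any():
                    sub = idx[ok]
                    inside[ok] = atlas.labels[sub[:, 0], sub[:, 1], sub[:, 2]] == label
                bad = ~inside
                if not bad.any():
                    break
                pos[bad] = centers[assignment[bad]] + rng.normal(
                    0.0, cluster_radius, size=(int(bad.sum()), 3)
                )
            else:
                pos[bad] = uniform_draw(int(bad.sum()))
            pts.append(pos)
        allpts = np.concatenate(pts, axis=0)
        rows_z.append(allpts[:, 0])
        rows_y.append(allpts[:, 1])
        rows_x.append(allpts[:, 2])
        rows_label.append(np.full(n, label, dtype=int))

    if rows_z:
        z = np.concatenate(rows_z)
        y = np.concatenate(rows_y)
        x = np.concatenate(rows_x)
        lab = np.concatenate(rows_label)
    else:
        z = y = x = np.empty(0)
        lab = np.empty(0, dtype=int)
    spots = pd.DataFrame(
        {
            "id": np.arange(1, len(z) + 1),
            "z_um": z,
            "y_um": y,
            "x_um": x,
            "region_label": lab,
            "amplitude": np.full(len(z), float(amplitude)),
        }
    )
    return GroundTruth(
        spots=spots,
        per_region_expected_count=expected,
        per_region_true_density={int(k): float(v) for k, v in region_density.items()},
        seed=int(seed),
    )


def sample_spots_min_spacing(
    atlas: LabelAtlas,
    n_spots: int,
    min_spacing: float,
    seed: int = 0,
    region_label: int | None = None,
    max_tries: int = 200,
) -> GroundTruth:
    """Benchmark utility: dart-throwing placement with a pairwise spacing floor.

    Used to build detection benchmarks where every punctum is resolvable
    (e.g. pairwise spacing >= 2 um). Draws uniform candidates inside the
    region (or the whole mask) and keeps those at least ``min_spacing`` um
    from all previously kept points.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_SPOTS, 7]))
    d = np.asarray(atlas.voxel_size)
    if region_label is None:
        sel = atlas.labels > 0
    else:
        sel = atlas.labels == int(region_label)
    vz, vy, vx = np.nonzero(sel)
    if len(vz) == 0:
        raise ValueError("no voxels available for placement")
    kept: list[np.ndarray] = []
    for _ in range(max_tries * n_spots):
        if len(kept) == n_spots:
            break
        i = rng.integers(0, len(vz))
        p = (np.array([vz[i], vy[i], vx[i]], dtype=float) + rng.random(3)) * d
        if not kept or cKDTree(np.array(kept)).query(p)[0] >= min_spacing:
            kept.append(p)
    if len(kept) < n_spots:
        raise RuntimeError(
            f"could only place {len(kept)}/{n_spots} spots at spacing {min_spacing} um"
        )
    pts = np.array(kept)
    idx = np.floor(pts / d).astype(int)
    lab = atlas.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
    spots = pd.DataFrame(
        {
            "id": np.arange(1, n_spots + 1),
            "z_um": pts[:, 0],
            "y_um": pts[:, 1],
            "x_um": pts[:, 2],
            "region_label": lab.astype(int),
            "amplitude": np.ones(n_spots),
        }
    )
    return GroundTruth(
        spots=spots, per_region_expected_count={}, per_region_true_density={}, seed=int(seed)
    )


def render_volume(
    ground_truth: GroundTruth,
    config: SyntheticConfig,
    channel: str = CHANNEL_GREEN,
    fwhm_um: float | None = None,
    rng: np.random.Generator | None = None,
) -> ImageVolume:
    """Render ground-truth puncta into a noisy intensity volume.

    Each spot becomes a 3D Gaussian with the same physical FWHM on every
    axis; the per-axis sigma in voxels is ``FWHM / (2.3548 * voxel_size)``,
    so anisotropic voxels produce anisotropic voxel-space footprints.
    Background is added, then the configured noise model (Poisson photon
    noise and/or additive Gaussian read noise), and the result is clipped at
    zero.
    """
    fwhm = config.punctum_fwhm if fwhm_um is None else float(fwhm_um)
    if fwhm <= 0:
        raise ValueError("punctum FWHM must be positive")
    shape = config.volume_shape
    d = np.asarray(config.voxel_size)
    sigma_phys = fwhm / FWHM_TO_SIGMA
    sigma_vox = sigma_phys / d
    img = np.zeros(shape, dtype=float)

    coords = ground_truth.coords_um
    amps = ground_truth.spots["amplitude"].to_numpy(dtype=float) * config.punctum_amplitude
    extent = np.array([n * dd for n, dd in zip(shape, d)])
    if len(coords) and (np.any(coords < 0) or np.any(coords >= extent)):
        raise ValueError("ground-truth spots must lie inside the volume bounds")

    radius = np.maximum(np.ceil(4.0 * sigma_vox).astype(int), 1)
    axes = [np.arange(-r, r + 1) for r in radius]
    for (cz, cy, cx), amp in zip(coords, amps):
        center = np.array([cz, cy, cx]) / d - 0.5  # grid coords of voxel centres
        base = np.round(center).astype(int)
        profs = []
        slices = []
        ok = True
        for ax in range(3):
            lo = base[ax] - radius[ax]
            hi = base[ax] + radius[ax] + 1
            sel = (axes[ax] + base[ax] >= 0) & (axes[ax] + base[ax] < shape[ax])
            pos = (axes[ax] + base[ax])[sel]
            if pos.size == 0:
                ok = False
                break
            profs.append(np.exp(-((pos - center[ax]) ** 2) / (2.0 * sigma_vox[ax] ** 2)))
            slices.append(pos)
        if not ok:
            continue
        patch = amp * profs[0][:, None, None] * profs[1][None, :, None] * profs[2][None, None, :]
        img[np.ix_(slices[0], slices[1], slices[2])] += patch

    img += config.background_level
    if config.noise_model != "none":
        if rng is None:
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STAGE_RENDER]))
        if "poisson" in config.noise_model:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if "gaussian" in config.noise_model:
            img = img + rng.normal(0.0, config.gaussian_sigma, size=img.shape)
    img = np.clip(img, 0, None)
    return ImageVolume(data=img, voxel_size=tuple(d), channel=channel)


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean lognormal multipliers with the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    s2 = np.log(1.0 + cv**2)
    return rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=size)


def make_cohort(config: SyntheticConfig, render: bool = True) -> list[CohortSample]:
    """Generate a two-group cohort (CON vs AD) of synthetic samples.

    CON samples draw puncta at the configured densities; AD samples at those
    densities multiplied by ``group_effect[region]`` (default 1). Each sample
    additionally receives a unit-mean lognormal density multiplier with CV
    ``sample_cv``, emulating between-animal variability, and a starter count
    drawn uniformly from ``starter_range``. Per-sample seeds are spawned from
    the master seed, so the whole cohort is reproducible bit-identically.
    """
    if config.n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (t test undefined otherwise)")
    atlas = make_atlas(config.volume_shape, config.voxel_size, config.n_regions, config.seed)
    base = config.densities_for(atlas)
    effect = {int(k): float(v) for k, v in (config.group_effect or {}).items()}
    master = np.random.SeedSequence([config.seed, _STAGE_COHORT])
    children = master.spawn(2 * config.n_per_group)
    samples: list[CohortSample] = []
    i = 0
    for group in ("CON", "AD"):
        for k in range(config.n_per_group):
            ss = children[i]
            i += 1
            rng = np.random.default_rng(ss)
            starters = int(rng.integers(config.starter_range[0], config.starter_range[1] + 1))
            factor = float(_lognormal_factor(rng, config.sample_cv, 1)[0])
            dens = {
                label: base[label]
                * factor
                * (effect.get(label, 1.0) if group == "AD" else 1.0)
                for label in base
            }
            truth = sample_spots(
                atlas,
                dens,
                starters,
                cluster_fraction=config.cluster_fraction,
                cluster_radius=config.cluster_radius,
                cluster_mean_size=config.cluster_mean_size,
                seed=config.seed,
                rng=rng,
            )
            vol = None
            if render:
                vol = render_volume(truth, _with_shape(config), rng=rng)
            samples.append(
                CohortSample(
                    sample_id=f"{group}{k + 1}",
                    group=group,
                    atlas=atlas,
                    ground_truth=truth,
                    starter_count=starters,
                    densities=dens,
                    volume=vol,
                )
            )
    return samples


def _with_shape(config: SyntheticConfig) -> SyntheticConfig:
    # make_cohort renders with the cohort's own config; hook kept for clarity
    return config


def sample_cohort_densities(
    region_volume_mm3: Mapping[int, float],
    region_density: Mapping[int, float],
    n_per_group: int = 4,
    group_effect: Mapping[int, float] | None = None,
    starter_range: tuple[int, int] = (1519, 2351),
    sample_cv: float = 0.10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts-only cohort sampler for statistical simulations.

    Draws per-region Poisson counts (with the same generative model as
    :func:`make_cohort`, minus spatial placement and rendering) and converts
    them to observed densities ``count / volume / starters``. Returns two
    DataFrames (CON, AD), one row per sample, one column per region label.
    The group comparison consumes only these densities, so large replicate
    simulations (null false-positive rate, power) run in milliseconds.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    labels = sorted(int(k) for k in region_density)
    vols = np.array([float(region_volume_mm3[k]) for k in labels])
    base = np.array([float(region_density[k]) for k in labels])
    effect = {int(k): float(v) for k, v in (group_effect or {}).items()}
    eff = np.array([effect.get(k, 1.0) for k in labels])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_COHORT, 11]))
    out = {}
    for group, factors in (("CON", np.ones(len(labels))), ("AD", eff)):
        rows = []
        for _ in range(n_per_group):
            starters = int(rng.integers(starter_range[0], starter_range[1] + 1))
            f = float(_lognormal_factor(rng, sample_cv, 1)[0])
            lam = base * factors * f * vols * starters
            counts = rng.poisson(lam)
            rows.append(counts / vols / starters)
        out[group] = pd.DataFrame(rows, columns=labels)
    return out["CON"], out["AD"]
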