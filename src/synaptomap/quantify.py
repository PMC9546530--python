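"""Region-level statistics of assigned presynaptic puncta.

Three statistics summarise each brain region, mirroring how terminal fields
are quantified in mesoscale projection mapping:

* **intensity proportion** — the region's share of total punctum
  fluorescence, in percent of the whole-brain sum (per-punctum mean gray
  values summed per region; all in-brain puncta together define 100%);
* **density** — puncta per mm^3 of region volume per starter neuron,
  ``count / volume_mm3 / n_starters``, the per-neuron connection-strength
  measure;
* **average distance** — for each punctum, the mean Euclidean distance to
  its nine nearest neighbours in the same region, averaged over the region's
  puncta; a dispersion/aggregation measure, undefined below ten puncta.

Axis profiles histogram puncta along an anatomical axis
(anterior-posterior, medial-lateral, dorsal-ventral) and test uniformity
with a one-sample Kolmogorov-Smirnov test against the uniform distribution
on the region's extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .volumes import LabelAtlas

#: Default mapping from anatomical axes to array axes (z, y, x).
DEFAULT_AXIS_MAP = {"AP": 0, "DV": 1, "ML": 2}

QUANT_COLUMNS = [
    "region_label",
    "acronym",
    "spot_count",
    "volume_mm3",
    "intensity_sum",
    "intensity_proportion_pct",
    "syp_density_per_mm3_per_neuron",
    "avg_distance_um",
]


class NoSignalError(ValueError):
    """Raised when a proportion is requested but total intensity is zero."""


def _with_intensity(spots: pd.DataFrame) -> pd.DataFrame:
    """Accept ground-truth tables, whose amplitude column plays intensity."""
    if "intensity" not in spots.columns and "amplitude" in spots.columns:
        spots = spots.rename(columns={"amplitude": "intensity"})
    return spots


def region_volume(atlas: LabelAtlas, label: int) -> float:
    """Region volume in mm^3: voxel count x voxel volume / 1e9."""
    return atlas.region_volume_mm3(label)


def intensity_proportion(spots: pd.DataFrame, atlas: LabelAtlas) -> dict[int, float]:
    """Percent of total punctum fluorescence per region.

    The whole-brain total (all spots with a nonzero region label) counts as
    100%; regions present in the atlas but holding no spots report 0.
    """
    spots = _with_intensity(spots)
    in_brain = spots[spots["region_label"] > 0]
    total = float(in_brain["intensity"].sum()) if len(in_brain) else 0.0
    if total <= 0:
        raise NoSignalError("no signal: total in-brain intensity is zero")
    sums = in_brain.groupby("region_label")["intensity"].sum()
    out = {label: 0.0 for label in atlas.region_labels()}
    for label, s in sums.items():
        out[int(label)] = 100.0 * float(s) / total
    return out


def syp_density(spot_count: int, region_volume_mm3: float, n_starters: int) -> float:
    """Puncta per mm^3 per starter neuron: ``count / volume / starters``."""
    if region_volume_mm3 <= 0:
        raise ValueError("region volume must be positive")
    if n_starters < 1:
        raise ValueError("n_starters must be >= 1 (normalization undefined at 0)")
    return spot_count / region_volume_mm3 / n_starters


def average_distance(coords_um: np.ndarray, k: int = 9) -> float:
    """Mean over spots of the mean distance to each spot's k nearest neighbours.

    Exact nearest-neighbour search (k-d tree); coincident points contribute
    zero distances. Returns NaN — the "undefined" marker — when fewer than
    ``k + 1`` spots are supplied, rather than fabricating a value.
    """
    coords = np.asarray(coords_um, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        coords = coords.reshape(-1, 3)
    n = len(coords)
    if n < k + 1:
        return float("nan")
    dists, _ = cKDTree(coords).query(coords, k=k + 1)
    return float(dists[:, 1:].mean())


@dataclass
class AxisProfile:
    """Histogram of puncta along one anatomical axis plus a uniformity test."""

    axis: str
    bin_edges: np.ndarray  # um, len n_bins + 1
    bin_counts: np.ndarray
    uniformity_p: float


def axis_profile(
    spots_in_region: pd.DataFrame,
    atlas: LabelAtlas,
    axis: str,
    n_bins: int = 10,
    axis_map: dict[str, int] | None = None,
) -> AxisProfile:
    """Profile punctum positions along an anatomical axis within a region.

    The binning range is the region's physical extent along the mapped array
    axis (taken from the atlas, so empty bins at the region's margins are
    preserved). ``uniformity_p`` is the one-sample KS p value of the
    coordinates against the uniform distribution on that extent.
    """
    amap = axis_map or DEFAULT_AXIS_MAP
    if axis not in amap:
        raise ValueError(f"unknown axis {axis!r}; expected one of {sorted(amap)}")
    if len(spots_in_region) == 0:
        raise ValueError("axis profile requires at least one spot")
    labels = spots_in_region["region_label"].unique()
    if len(labels) != 1:
        raise ValueError(f"spots span multiple regions {sorted(labels)}; profile one region")
    label = int(labels[0])
    arr_axis = amap[axis]
    idx = np.nonzero(atlas.labels == label)[arr_axis]
    if idx.size == 0:
        raise KeyError(f"label {label} not present in atlas")
    d = atlas.voxel_size[arr_axis]
    lo, hi = idx.min() * d, (idx.max() + 1) * d
    if hi <= lo:
        raise ValueError("degenerate region extent along the requested axis")
    col = ["z_um", "y_um", "x_um"][arr_axis]
    coords = spots_in_region[col].to_numpy(dtype=float)
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(coords, bins=edges)
    ks = stats.kstest(coords, stats.uniform(loc=lo, scale=hi - lo).cdf)
    return AxisProfile(axis=axis, bin_edges=edges, bin_counts=counts, uniformity_p=float(ks.pvalue))


def quantify_sample(
    spots: pd.DataFrame,
    atlas: LabelAtlas,
    n_starters: int,
    k: int = 9,
    regions: list[int] | None = None,
) -> pd.DataFrame:
    """Assemble all three region statistics for one sample.

    Covers every atlas region with at least one spot plus any regions listed
    explicitly; spots outside the brain mask (label 0) never contribute.
    If the sample carries no fluorescence at all, proportions are reported
    as 0 rather than raising, so empty samples still produce a table.
    """
    spots = _with_intensity(spots)
    in_brain = spots[spots["region_label"] > 0]
    wanted = sorted(
        set(int(l) for l in in_brain["region_label"].unique()) | set(regions or [])
    )
    try:
        proportions = intensity_proportion(spots, atlas)
    except NoSignalError:
        proportions = {}
    rows = []
    for label in wanted:
        sub = in_brain[in_brain["region_label"] == label]
        vol = atlas.region_volume_mm3(label)
        coords = sub[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
        rows.append(
            {
                "region_label": label,
                "acronym": atlas.acronym(label),
                "spot_count": len(sub),
                "volume_mm3": vol,
                "intensity_sum": float(sub["intensity"].sum()) if "intensity" in sub else 0.0,
                "intensity_proportion_pct": proportions.get(label, 0.0),
                "syp_density_per_mm3_per_neuron": syp_density(len(sub), vol, n_starters),
                "avg_distance_um": average_distance(coords, k=k),
            }
        )
    return pd.DataFrame(rows, columns=QUANT_COLUMNS)
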