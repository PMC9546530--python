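"""File formats: multi-page TIFF volumes with JSON sidecars, SWC point
clouds, spot/quantification CSVs and ontology JSON.

Voxel size is mandatory metadata: a volume without a declared physical
spacing is an error, never silently assumed to be 1 um. Volumes travel as
grayscale multi-page TIFF (one page per z plane; unsigned 8/16-bit or
32-bit float) with a ``<path>.json`` sidecar declaring ``voxel_size_um``
(z, y, x order) and the channel tag.

SWC files follow the point-cloud dialect: one line per spot,
``id type x y z radius parent`` with type 0, parent -1 (disconnected
points) and radius encoding half the spot diameter. Note SWC column order
is x y z while arrays are (z, y, x).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detection import SPOT_COLUMNS, empty_spot_table
from .volumes import ImageVolume, LabelAtlas

_SUPPORTED_DTYPES = ("uint8", "uint16", "float32")


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_volume(volume: ImageVolume, path) -> Path:
    """Write a volume as multi-page grayscale TIFF plus a JSON sidecar."""
    path = Path(path)
    if volume.data.dtype.name not in _SUPPORTED_DTYPES:
        raise ValueError(
            f"unsupported dtype {volume.data.dtype.name}; "
            f"convert to one of {_SUPPORTED_DTYPES} (e.g. via to_uint16)"
        )
    tifffile.imwrite(path, volume.data)
    _sidecar_path(path).write_text(
        json.dumps(
            {"voxel_size_um": list(volume.voxel_size), "channel": volume.channel}, indent=2
        )
    )
    return path


def read_volume(path, voxel_size=None, channel=None) -> ImageVolume:
    """Read a multi-page grayscale TIFF volume.

    Voxel size and channel come from the sidecar JSON if present, else from
    the arguments; a missing voxel size is an error.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise ValueError(f"unsupported: multichannel or {data.ndim}D TIFF (shape {data.shape})")
    if data.dtype.name not in _SUPPORTED_DTYPES:
        raise ValueError(f"unsupported dtype {data.dtype.name}; expected {_SUPPORTED_DTYPES}")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        voxel_size = voxel_size or tuple(meta["voxel_size_um"])
        channel = channel or meta.get("channel")
    if voxel_size is None:
        raise ValueError(f"voxel size for {path} not declared (no sidecar, no argument)")
    return ImageVolume(data=data, voxel_size=tuple(voxel_size), channel=channel or "syp_egfp")


def to_uint16(volume: ImageVolume) -> ImageVolume:
    """Round and clip intensities into the uint16 range for TIFF export."""
    data = np.clip(np.round(volume.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return ImageVolume(data=data, voxel_size=volume.voxel_size, channel=volume.channel)


def write_atlas(atlas: LabelAtlas, path, ontology_path=None) -> Path:
    """Write the label grid as 16-bit TIFF plus the ontology JSON."""
    path = Path(path)
    tifffile.imwrite(path, atlas.labels.astype(np.uint16))
    _sidecar_path(path).write_text(
        json.dumps({"voxel_size_um": list(atlas.voxel_size), "channel": "atlas"}, indent=2)
    )
    opath = Path(ontology_path) if ontology_path else path.with_suffix(".ontology.json")
    opath.write_text(json.dumps({str(k): v for k, v in atlas.ontology.items()}, indent=2))
    return path


def read_atlas(path, ontology_path=None, voxel_size=None) -> LabelAtlas:
    path = Path(path)
    labels = tifffile.imread(path)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        voxel_size = voxel_size or tuple(meta["voxel_size_um"])
    if voxel_size is None:
        raise ValueError(f"voxel size for atlas {path} not declared")
    opath = Path(ontology_path) if ontology_path else path.with_suffix(".ontology.json")
    ontology = {}
    if opath.exists():
        ontology = {int(k): v for k, v in json.loads(opath.read_text()).items()}
    return LabelAtlas(labels=np.asarray(labels).astype(np.int64), voxel_size=voxel_size, ontology=ontology)


def write_spots_csv(spots: pd.DataFrame, path) -> Path:
    path = Path(path)
    cols = [c for c in SPOT_COLUMNS if c in spots.columns] + [
        c for c in spots.columns if c not in SPOT_COLUMNS
    ]
    spots.to_csv(path, index=False, columns=cols, float_format="%.6f")
    return path


def read_spots_csv(path) -> pd.DataFrame:
    table = pd.read_csv(Path(path))
    if "region_acronym" in table.columns:
        table["region_acronym"] = table["region_acronym"].fillna("")
    return table


def write_swc(spots: pd.DataFrame, path, spot_diameter: float = 0.8) -> Path:
    """Write spots as an SWC point cloud (type 0, parent -1, radius = D/2)."""
    path = Path(path)
    radius = spot_diameter / 2.0
    lines = [
        "# SWC point cloud of detected presynaptic puncta",
        "# units: micrometres; columns: id type x y z radius parent",
        "# disconnected points: type 0, parent -1; radius = spot_diameter / 2",
    ]
    for row in spots.itertuples(index=False):
        lines.append(
            f"{int(row.id)} 0 {row.x_um:.6f} {row.y_um:.6f} {row.z_um:.6f} {radius:.6f} -1"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_swc(path) -> pd.DataFrame:
    """Read an SWC point cloud back into a spot table."""
    path = Path(path)
    ids, xs, ys, zs = [], [], [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 7:
            raise ValueError(f"{path}:{lineno}: malformed SWC line ({len(parts)} fields)")
        try:
            ids.append(int(parts[0]))
            xs.append(float(parts[2]))
            ys.append(float(parts[3]))
            zs.append(float(parts[4]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed SWC line: {exc}") from None
    if not ids:
        return empty_spot_table()
    return pd.DataFrame(
        {
            "id": ids,
            "z_um": zs,
            "y_um": ys,
            "x_um": xs,
            "intensity": np.nan,
            "region_label": 0,
            "region_acronym": "",
        }
    )
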