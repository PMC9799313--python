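"""Per-object feature descriptors.

Each detected component is summarised by three raw-unit features —
summed intensity, pixel area and summed Laplacian response — the
low-dimensional descriptor that feeds the reference models.  No
per-image normalisation happens here; all standardisation is applied
downstream in the belief stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .detection import ComponentSet, ImageGrid, ResponseMap, as_image

__all__ = [
    "FeatureVector",
    "ObjectRecord",
    "FEATURE_COLUMNS",
    "extract_features",
    "objects_from_components",
    "features_table",
    "write_objects_csv",
    "read_objects_csv",
    "rle_encode",
    "rle_decode",
]

FEATURE_COLUMNS = ["intensity_sum", "area", "laplacian_sum"]

TABLE_COLUMNS = [
    "image_id",
    "object_id",
    "row_min",
    "col_min",
    "n_pixels",
    "intensity_sum",
    "area",
    "laplacian_sum",
]


class FeatureVector(NamedTuple):
    intensity_sum: float
    area: int
    laplacian_sum: float


@dataclass
class ObjectRecord:
    """One detected object: pixel support plus its feature vector."""

    object_id: int
    source_image_id: str
    pixel_coords: np.ndarray  # (m, 2) rows of (row, col)
    features: FeatureVector


def extract_features(
    component: np.ndarray,
    image: ImageGrid | np.ndarray,
    response: ResponseMap | np.ndarray,
) -> FeatureVector:
    """Sum intensity, count pixels and sum the response over a component.

    Permutation-invariant in pixel order; raw (unnormalised) units.
    """
    coords = np.asarray(component)
    if coords.size == 0:
        raise ValueError("cannot extract features from an empty component")
    pixels = as_image(image).pixels
    values = response.values if isinstance(response, ResponseMap) else np.asarray(response)
    if values.shape != pixels.shape:
        raise ValueError("image and response shapes differ")
    rows, cols = coords[:, 0], coords[:, 1]
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= pixels.shape[0] or cols.max() >= pixels.shape[1]:
        raise ValueError("component pixels fall outside the image bounds")
    return FeatureVector(
        intensity_sum=float(pixels[rows, cols].sum()),
        area=int(coords.shape[0]),
        laplacian_sum=float(values[rows, cols].sum()),
    )


def objects_from_components(
    components: ComponentSet,
    image: ImageGrid | np.ndarray,
    response: ResponseMap | np.ndarray,
    image_id: str,
) -> list[ObjectRecord]:
    """Build one :class:`ObjectRecord` per detected component."""
    return [
        ObjectRecord(
            object_id=idx,
            source_image_id=image_id,
            pixel_coords=coords,
            features=extract_features(coords, image, response),
        )
        for idx, coords in enumerate(components.components, start=1)
    ]


def features_table(objects: Iterable[ObjectRecord]) -> pd.DataFrame:
    """Row-per-object table in a stable (image_id, object_id) order.

    Raises on duplicate (image_id, object_id) keys so tables stay
    joinable downstream.
    """
    rows = []
    for obj in objects:
        coords = obj.pixel_coords
        rows.append(
            {
                "image_id": obj.source_image_id,
                "object_id": obj.object_id,
                "row_min": int(coords[:, 0].min()),
                "col_min": int(coords[:, 1].min()),
                "n_pixels": int(coords.shape[0]),
                "intensity_sum": obj.features.intensity_sum,
                "area": obj.features.area,
                "laplacian_sum": obj.features.laplacian_sum,
            }
        )
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if df.duplicated(subset=["image_id", "object_id"]).any():
        dupes = df.loc[
            df.duplicated(subset=["image_id", "object_id"]), ["image_id", "object_id"]
        ]
        raise ValueError(f"duplicate object keys: {dupes.values.tolist()}")
    return df.sort_values(["image_id", "object_id"], kind="stable").reset_index(drop=True)


def write_objects_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_objects_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def rle_encode(coords: np.ndarray, width: int) -> str:
    """Run-length encode a pixel set as ``start:length`` runs over the
    raster-scan linear index; the sidecar mask format."""
    coords = np.asarray(coords)
    if coords.size == 0:
        return ""
    flat = np.sort(coords[:, 0].astype(np.int64) * width + coords[:, 1])
    breaks = np.where(np.diff(flat) != 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [flat.size - 1]])
    return ";".join(f"{flat[s]}:{e - s + 1}" for s, e in zip(starts, ends))


def rle_decode(rle: str, width: int) -> np.ndarray:
    """Inverse of :func:`rle_encode`; returns (m, 2) raster-ordered coords."""
    if not rle:
        return np.empty((0, 2), dtype=np.int64)
    flat = []
    for run in rle.split(";"):
        start, length = (int(tok) for tok in run.split(":"))
        flat.extend(range(start, start + length))
    flat_arr = np.asarray(sorted(flat), dtype=np.int64)
    return np.column_stack([flat_arr // width, flat_arr % width])
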