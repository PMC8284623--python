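"""Masking, master-mask object detection and per-cell intensity measurement.

Turns a multi-channel fluorescence image into a single-cell table: each
marker channel is binarised, the binary masks are combined into a single
"master mask" containing all myeloid cells, connected components of the
master mask are treated as cells (touching cells merge — no watershed
splitting), and the mean intensity of every marker is measured within each
cell.  The resulting table is the flow-cytometry-style hand-off consumed
by the gating module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import IntegrityError, SchemaError, ValidationError
from .simulate import MICROGLIAL_MARKERS, TISSUE_TYPES

__all__ = [
    "MultiplexImage",
    "BinaryMask",
    "LabeledMask",
    "CellTable",
    "intensity_column",
    "make_channel_mask",
    "combine_masks",
    "label_objects",
    "measure_cells",
    "pool_cases",
]


def intensity_column(marker: str) -> str:
    """Name of the per-cell mean-intensity column for ``marker``."""
    return f"mean_{marker}"


@dataclass
class MultiplexImage:
    """Named marker channels as 2-D intensity rasters with physical pixel size."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    case_id: str = "case"
    tissue_type: str = "grade_iv"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("image must have at least one channel")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValidationError(f"all channels must share one shape, got {shapes}")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        if "Iba1" not in self.channels:
            raise ValidationError("image must contain an Iba1 channel")
        mg = [m for m in self.channels if m in MICROGLIAL_MARKERS]
        if len(mg) != 1:
            raise ValidationError(
                "image must contain exactly one microglial marker "
                f"({'/'.join(MICROGLIAL_MARKERS)}), found {mg}"
            )
        if self.tissue_type not in TISSUE_TYPES:
            raise ValidationError(f"tissue_type must be one of {TISSUE_TYPES}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.channels)

    @property
    def microglial_marker(self) -> str:
        return next(m for m in self.channels if m in MICROGLIAL_MARKERS)

    def channel(self, marker: str) -> np.ndarray:
        try:
            return self.channels[marker]
        except KeyError:
            raise SchemaError(f"marker {marker!r} not in image ({list(self.channels)})")

    @property
    def area_mm2(self) -> float:
        h, w = self.shape
        return h * w * (self.pixel_size_um / 1000.0) ** 2


@dataclass
class BinaryMask:
    """A thresholded channel; the threshold actually applied is recorded."""

    data: np.ndarray
    source_marker: str
    threshold_used: float
    method: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def n_set(self) -> int:
        return int(self.data.sum())


@dataclass
class LabeledMask:
    """Connected components of the master mask; labels are consecutive 1..K."""

    labels: np.ndarray
    n_objects: int
    min_area_px: int
    connectivity: int


def make_channel_mask(
    image: MultiplexImage,
    marker: str,
    method: str = "otsu",
    param: float | None = None,
) -> BinaryMask:
    """Binarise one channel: pixel is set iff intensity >= resolved threshold.

    method="fixed"    — param is the threshold (intensity units, >= 0)
    method="otsu"     — threshold from Otsu's criterion on the channel
    method="quantile" — threshold at the param-quantile of pixel intensities
    """
    chan = image.channel(marker)
    if method == "fixed":
        if param is None or param < 0:
            raise ValidationError("fixed method requires a threshold param >= 0")
        thr = float(param)
    elif method == "otsu":
        thr = float(threshold_otsu(chan))
    elif method == "quantile":
        if param is None or not 0.0 < param < 1.0:
            raise ValidationError("quantile param must be in (0, 1)")
        thr = float(np.quantile(chan, param))
    else:
        raise ValidationError(f"unknown threshold method {method!r}")
    return BinaryMask(chan >= thr, source_marker=marker, threshold_used=thr, method=method)


def combine_masks(masks: Sequence[BinaryMask]) -> BinaryMask:
    """Pixelwise union of per-marker masks — the master mask of all myeloid cells."""
    if not masks:
        raise ValidationError("combine_masks requires at least one mask")
    shapes = {m.data.shape for m in masks}
    if len(shapes) != 1:
        raise ValidationError(f"mask shapes differ: {shapes}")
    union = np.logical_or.reduce([m.data for m in masks])
    return BinaryMask(
        union,
        source_marker="+".join(m.source_marker for m in masks),
        threshold_used=float("nan"),
        method="union",
    )


def label_objects(
    master: BinaryMask, min_area_px: int = 20, connectivity: int = 8
) -> LabeledMask:
    """Label connected components of the master mask; each object is one cell.

    Components smaller than ``min_area_px`` are removed (size-based debris
    exclusion) and the survivors relabeled consecutively 1..K.
    """
    if min_area_px < 1:
        raise ValidationError("min_area_px must be >= 1")
    if connectivity not in (4, 8):
        raise ValidationError("connectivity must be 4 or 8")
    skimage_conn = 1 if connectivity == 4 else 2
    lab = measure.label(master.data, connectivity=skimage_conn)
    if min_area_px > 1 and lab.max() > 0:
        sizes = np.bincount(lab.ravel())
        keep = (sizes >= min_area_px)[lab] & (lab > 0)
        lab = measure.label(keep, connectivity=skimage_conn)
    n = int(lab.max())
    return LabeledMask(labels=lab, n_objects=n, min_area_px=min_area_px, connectivity=connectivity)


@dataclass
class CellTable:
    """One row per master-mask object, with per-marker mean intensities.

    Columns: case_id, cell_id, tissue_type, x, y (pixel centroid, 0-based,
    x = column), area_px, area_um2, tissue_area_mm2 and one
    ``mean_<marker>`` column per measured marker.  The per-case tissue area
    is carried per row so the table round-trips through a single CSV.
    """

    df: pd.DataFrame
    area_method: str = "full_image"

    _CORE = ("case_id", "cell_id", "tissue_type", "x", "y", "area_px", "area_um2", "tissue_area_mm2")

    def __post_init__(self) -> None:
        missing = [c for c in self._CORE if c not in self.df.columns]
        if missing:
            raise SchemaError(f"CellTable missing columns {missing}")
        if len(self.df):
            if (self.df["tissue_area_mm2"] <= 0).any():
                raise ValidationError("tissue_area_mm2 must be > 0")
            dup = self.df.duplicated(subset=["case_id", "cell_id"])
            if dup.any():
                raise IntegrityError("duplicate (case_id, cell_id) rows in CellTable")

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(c[len("mean_"):] for c in self.df.columns if c.startswith("mean_"))

    @property
    def n_cells(self) -> int:
        return len(self.df)

    @property
    def case_ids(self) -> tuple[str, ...]:
        return tuple(self.df["case_id"].unique())

    def area_mm2(self, case_id: str) -> float:
        sub = self.df.loc[self.df["case_id"] == case_id, "tissue_area_mm2"]
        if sub.empty:
            raise SchemaError(f"unknown case_id {case_id!r}")
        return float(sub.iloc[0])

    def intensities(self, marker: str) -> pd.Series:
        col = intensity_column(marker)
        if col not in self.df.columns:
            raise SchemaError(f"marker {marker!r} not measured in this table")
        return self.df[col]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, area_method: str = "full_image") -> "CellTable":
        return cls(pd.read_csv(path), area_method=area_method)


def _tissue_area_mm2(image: MultiplexImage, method: str) -> float:
    """Stained-tissue area used to normalise densities.

    "full_image" uses the whole field of view; "channel_sum_otsu" thresholds
    the sum of all channels (Otsu) and fills holes, for slides containing
    empty glass.
    """
    if method == "full_image":
        return image.area_mm2
    if method == "channel_sum_otsu":
        total = sum(image.channels.values())
        mask = total >= threshold_otsu(total)
        mask = ndimage.binary_fill_holes(mask)
        n = int(mask.sum())
        if n == 0:
            raise ValidationError("tissue mask is empty; cannot compute tissue area")
        return n * (image.pixel_size_um / 1000.0) ** 2
    raise ValidationError(f"unknown tissue-area method {method!r}")


def measure_cells(
    labeled: LabeledMask,
    image: MultiplexImage,
    tissue_area_method: str = "full_image",
) -> CellTable:
    """Measure every labeled object: centroid, area, per-marker mean intensity."""
    if labeled.labels.shape != image.shape:
        raise ValidationError("labeled mask shape does not match image")
    area = _tissue_area_mm2(image, tissue_area_method)
    markers = list(image.channels)
    if labeled.n_objects == 0:
        cols = {c: [] for c in CellTable._CORE}
        cols.update({intensity_column(m): [] for m in markers})
        df = pd.DataFrame(cols)
        df["tissue_area_mm2"] = df["tissue_area_mm2"].astype(float)
        return CellTable(df, area_method=tissue_area_method)

    stack = np.stack([image.channels[m] for m in markers], axis=-1)
    props = measure.regionprops_table(
        labeled.labels,
        intensity_image=stack,
        properties=("label", "area", "centroid", "intensity_mean"),
    )
    df = pd.DataFrame(
        {
            "case_id": image.case_id,
            "cell_id": props["label"].astype(int),
            "tissue_type": image.tissue_type,
            "x": props["centroid-1"],
            "y": props["centroid-0"],
            "area_px": props["area"].astype(int),
        }
    )
    df["area_um2"] = df["area_px"] * image.pixel_size_um**2
    df["tissue_area_mm2"] = area
    for i, m in enumerate(markers):
        df[intensity_column(m)] = props[f"intensity_mean-{i}"]
    return CellTable(df, area_method=tissue_area_method)


def pool_cases(tables: Iterable[CellTable]) -> CellTable:
    """Concatenate per-case tables, preserving provenance columns.

    Duplicate (case_id, cell_id) pairs raise an IntegrityError — pooling the
    same case twice, or colliding ids, would double-count cells.
    """
    tables = list(tables)
    if not tables:
        raise ValidationError("pool_cases requires at least one table")
    df = pd.concat([t.df for t in tables], ignore_index=True)
    if df.duplicated(subset=["case_id", "cell_id"]).any():
        raise IntegrityError("duplicate (case_id, cell_id) across pooled tables")
    methods = {t.area_method for t in tables}
    return CellTable(df, area_method=methods.pop() if len(methods) == 1 else "mixed")
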