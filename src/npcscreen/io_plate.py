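"""Plate-level I/O: field images, plate layouts and feature tables.

This module fixes the on-disk contract for the whole pipeline: single-plane
grayscale TIFFs (8- or 16-bit) for images, UTF-8 CSV with a header row for
plate layouts and per-well feature tables.  Image intensities are always
normalized by the dtype maximum (255 or 65535), never by the per-image
maximum, so that intensity-derived features remain comparable across wells.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

MIN_IMAGE_SIZE = 64

LAYOUT_COLUMNS = ["plate", "well", "field", "channel", "path",
                  "treatment", "dose_uM", "role"]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class FormatError(ValueError):
    """Raised when a file is readable but not in the expected format."""


class Channel(str, enum.Enum):
    GFP = "GFP"
    HOECHST = "HOECHST"
    FILIPIN = "FILIPIN"
    MARKER = "MARKER"


class Role(str, enum.Enum):
    LIBRARY = "library"
    VEHICLE = "vehicle"
    POSITIVE_CONTROL = "positive_control"
    MARGINAL_POSITIVE = "marginal_positive"
    BLANK = "blank"


@dataclass(frozen=True)
class ImageField:
    """One grayscale field image with intensities scaled to [0, 1].

    Pixel coordinates are (row, col), 0-based.  Images smaller than
    ``MIN_IMAGE_SIZE`` in either dimension are rejected: the processing
    chains use neighbourhoods up to 35 px and degenerate below that scale.
    """

    pixels: np.ndarray
    channel: Channel
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValidationError(f"expected a 2-D image, got ndim={px.ndim}")
        if px.shape[0] < MIN_IMAGE_SIZE or px.shape[1] < MIN_IMAGE_SIZE:
            raise ValidationError(
                f"image {px.shape} smaller than {MIN_IMAGE_SIZE}x{MIN_IMAGE_SIZE}")
        if not np.all(np.isfinite(px)):
            raise ValidationError("image contains non-finite intensities")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValidationError("intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "channel", Channel(self.channel))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def read_field_image(path: str | os.PathLike, channel: Channel | str) -> ImageField:
    """Read a single-plane grayscale TIFF and normalize by the dtype maximum.

    8-bit images are divided by 255, 16-bit by 65535.  RGB or multi-plane
    TIFFs are rejected with :class:`FormatError`.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        arr = tifffile.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # unreadable / truncated file
        raise IOError(f"cannot read TIFF {path!r}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(
            f"{path!r}: expected a single-plane grayscale image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        raise FormatError(f"{path!r}: unsupported dtype {arr.dtype}, expected uint8/uint16")
    return ImageField(arr.astype(np.float64) / scale, Channel(channel), source_path=path)


def write_field_image(path: str | os.PathLike, pixels: np.ndarray) -> None:
    """Write a [0,1] float image as a 16-bit grayscale TIFF."""
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    tifffile.imwrite(os.fspath(path), np.round(arr * 65535.0).astype(np.uint16))


@dataclass(frozen=True)
class PlateLayout:
    """Validated mapping from (plate, well, field, channel) to an image file.

    Invariants enforced at construction:

    * the (plate, well, field, channel) key is unique;
    * every GFP field has a matching HOECHST field;
    * at most ``max_fields`` fields per well;
    * treatment, dose and role are constant within a well.
    """

    table: pd.DataFrame
    max_fields: int = 6

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"layout missing columns: {missing}")
        df["field"] = df["field"].astype(int)
        if (df["field"] < 1).any():
            raise ValidationError("field indices must be >= 1")
        try:
            df["channel"] = df["channel"].map(lambda c: Channel(c).value)
        except ValueError as exc:
            allowed = [c.value for c in Channel]
            raise ValidationError(f"unknown channel ({exc}); allowed: {allowed}") from None
        try:
            df["role"] = df["role"].map(lambda r: Role(r).value)
        except ValueError as exc:
            allowed = [r.value for r in Role]
            raise ValidationError(f"unknown role ({exc}); allowed: {allowed}") from None
        df["dose_uM"] = df["dose_uM"].astype(float)
        if (df["dose_uM"] < 0).any():
            raise ValidationError("dose_uM must be non-negative")

        key = ["plate", "well", "field", "channel"]
        dup = df.duplicated(subset=key)
        if dup.any():
            raise ValidationError(
                f"duplicate layout keys: {df.loc[dup, key].values.tolist()}")

        gfp = df[df["channel"] == Channel.GFP.value]
        hoe = df[df["channel"] == Channel.HOECHST.value]
        hoe_keys = set(map(tuple, hoe[["plate", "well", "field"]].values))
        for _, row in gfp.iterrows():
            k = (row["plate"], row["well"], row["field"])
            if k not in hoe_keys:
                raise ValidationError(f"GFP field {k} has no matching HOECHST field")

        nfields = df.groupby(["plate", "well"])["field"].nunique()
        if (nfields > self.max_fields).any():
            bad = nfields[nfields > self.max_fields].index.tolist()
            raise ValidationError(f"more than {self.max_fields} fields per well: {bad}")

        meta = df.groupby(["plate", "well"])[["treatment", "dose_uM", "role"]].nunique()
        if (meta > 1).any().any():
            bad = meta[(meta > 1).any(axis=1)].index.tolist()
            raise ValidationError(f"treatment/dose/role not constant within wells: {bad}")

        object.__setattr__(self, "table", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)

    def wells(self) -> pd.DataFrame:
        """One row per (plate, well) with treatment/dose/role metadata."""
        return (self.table.groupby(["plate", "well"], as_index=False)
                [["treatment", "dose_uM", "role"]].first())

    def to_csv(self, path: str | os.PathLike) -> None:
        self.table[LAYOUT_COLUMNS].to_csv(path, index=False)


def read_plate_layout(path: str | os.PathLike, max_fields: int = 6) -> PlateLayout:
    """Read and validate a plate-layout CSV (columns: plate,well,field,channel,
    path,treatment,dose_uM,role)."""
    df = pd.read_csv(path, dtype={"plate": str, "well": str, "treatment": str})
    return PlateLayout(df, max_fields=max_fields)


# feature-table serialization ------------------------------------------------

_FLOAT_FMT = "%.12g"


def write_feature_table(records, path: str | os.PathLike) -> None:
    """Write per-well records as CSV, one row per well.

    NaN-valued features (invalid wells) are serialized as empty cells; the
    record's ``qc_flag`` column marks why.  Column order is deterministic so
    the file round-trips losslessly through :func:`read_feature_table`.
    """
    from .features import WellRecord  # local import to avoid a cycle

    records = list(records)
    if not records:
        raise ValidationError("no records to write")
    rows = [r.to_dict() for r in records]
    df = pd.DataFrame(rows, columns=WellRecord.columns())
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_feature_table(path: str | os.PathLike):
    """Read a feature-table CSV back into a list of WellRecord."""
    from .features import WellRecord

    df = pd.read_csv(path, dtype={"plate_id": str, "well_id": str, "treatment": str})
    return [WellRecord.from_dict(row) for row in df.to_dict(orient="records")]
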