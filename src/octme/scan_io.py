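"""Reading and writing B-scans, sidecar metadata, and observation tables.

A B-scan is a single 2-D cross-sectional OCT image: row index is axial
depth (row 0 shallow, air-calibrated optical path), column index is
lateral position.  Physical calibration travels with the image as a
sidecar YAML/JSON file rather than TIFF tags, which keeps the metadata
trivially readable from any language.

Conventions used throughout the package (stated once, here):

* 0-based row/column indexing; depth increases with the row index.
* Intensities are normalised to a common floating scale in ``[0, 1]``.
* Day 0 is the inoculation day; baseline imaging maps to day 0.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml

#: Closed set of experimental group labels.
GROUPS = ("control", "no_treatment", "low_dose", "high_dose")

#: Column order of observation CSV files (documented in the file header).
OBSERVATION_COLUMNS = [
    "animal",
    "ear",
    "day",
    "group",
    "thickness_mean_um",
    "thickness_sd_um",
    "mee_class",
    "mee_present",
    "biofilm_present",
    "blocked",
    "n_scans_used",
]


class CalibrationError(ValueError):
    """Pixel pitch metadata is missing — physical thickness is undefined."""


class MetadataError(ValueError):
    """Sidecar metadata is missing required keys or malformed."""


@dataclass
class BScan:
    """One cross-sectional OCT image with physical calibration and labels.

    Parameters
    ----------
    pixels
        2-D float array of non-negative intensities in ``[0, 1]``.
    axial_pitch_um
        Air-equivalent optical path per pixel row, in micrometres.
    lateral_pitch_um
        Physical width per pixel column, in micrometres.
    animal, ear, day, group
        Provenance labels; ``day`` is an integer with day 0 = inoculation.
    blocked
        True when the ear-canal view was blocked (no usable image).
    """

    pixels: np.ndarray
    axial_pitch_um: float
    lateral_pitch_um: float
    animal: str = "NA"
    ear: str = "NA"
    day: int = 0
    group: str = "control"
    blocked: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"B-scan pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("B-scan pixels must be finite")
        if self.axial_pitch_um <= 0 or self.lateral_pitch_um <= 0:
            raise CalibrationError("pixel pitches must be strictly positive")
        if self.day < 0:
            raise ValueError("day must be >= 0 (day 0 = inoculation)")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; valid groups: {GROUPS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def labels(self) -> dict:
        return {
            "animal": self.animal,
            "ear": self.ear,
            "day": self.day,
            "group": self.group,
        }


def _load_metadata(path: str | os.PathLike) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        if str(path).endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh)


def read_bscan(image_path: str | os.PathLike, metadata_path: str | os.PathLike) -> BScan:
    """Read a grayscale TIFF/PNG B-scan plus its sidecar metadata.

    Integer images are rescaled by their dtype maximum so that 8-bit and
    16-bit encodings of the same scene produce identical normalised
    pixels up to the coarser quantisation step.
    """
    import imageio.v3 as iio

    if str(image_path).lower().endswith((".tif", ".tiff")):
        raw = tifffile.imread(image_path)
    else:
        raw = iio.imread(image_path)
    raw = np.asarray(raw)
    if raw.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {raw.shape}")
    if np.issubdtype(raw.dtype, np.integer):
        pixels = raw.astype(float) / float(np.iinfo(raw.dtype).max)
    else:
        pixels = raw.astype(float)

    meta = _load_metadata(metadata_path)
    if meta is None:
        raise MetadataError(f"empty metadata file: {metadata_path}")
    for key in ("axial_pitch_um", "lateral_pitch_um"):
        if key not in meta:
            raise CalibrationError(
                f"metadata {metadata_path} lacks {key!r}: thickness in um is "
                "impossible without pixel calibration"
            )
    for key in ("animal", "ear", "day", "group"):
        if key not in meta:
            raise MetadataError(f"metadata {metadata_path} lacks required key {key!r}")
    return BScan(
        pixels=pixels,
        axial_pitch_um=float(meta["axial_pitch_um"]),
        lateral_pitch_um=float(meta["lateral_pitch_um"]),
        animal=str(meta["animal"]),
        ear=str(meta["ear"]),
        day=int(meta["day"]),
        group=str(meta["group"]),
        blocked=bool(meta.get("blocked", False)),
    )


def write_bscan(
    scan: BScan, image_path: str | os.PathLike, metadata_path: str | os.PathLike
) -> None:
    """Write a B-scan as 16-bit grayscale TIFF with a YAML/JSON sidecar."""
    img16 = np.clip(np.round(scan.pixels * 65535.0), 0, 65535).astype(np.uint16)
    tifffile.imwrite(image_path, img16)
    meta = {
        "axial_pitch_um": float(scan.axial_pitch_um),
        "lateral_pitch_um": float(scan.lateral_pitch_um),
        "animal": scan.animal,
        "ear": scan.ear,
        "day": int(scan.day),
        "group": scan.group,
        "blocked": bool(scan.blocked),
    }
    with open(metadata_path, "w", encoding="utf-8") as fh:
        if str(metadata_path).endswith(".json"):
            json.dump(meta, fh, indent=2)
        else:
            yaml.safe_dump(meta, fh, sort_keys=True)


def observations_to_frame(records) -> pd.DataFrame:
    """Convert EarObservation records to a DataFrame in documented column order."""
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec):
            d = dataclasses.asdict(rec)
        else:
            d = dict(rec)
        rows.append({col: d.get(col) for col in OBSERVATION_COLUMNS})
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def write_observations(records, path: str | os.PathLike) -> None:
    """Write one row per ear x day to CSV (UTF-8, '.' decimal).

    The first line is a ``#`` comment documenting the column order.
    Duplicate ``(animal, ear, day)`` keys are rejected.
    """
    frame = observations_to_frame(records)
    if len(frame):
        dup = frame.duplicated(subset=["animal", "ear", "day"])
        if dup.any():
            first = frame.loc[dup.idxmax(), ["animal", "ear", "day"]].tolist()
            raise ValueError(f"duplicate (animal, ear, day) row: {first}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# columns: " + ",".join(OBSERVATION_COLUMNS) + "\n")
        frame.to_csv(fh, index=False)


def read_observations(path: str | os.PathLike) -> pd.DataFrame:
    """Read an observation CSV written by :func:`write_observations`."""
    frame = pd.read_csv(path, comment="#")
    if len(frame) == 0:
        return pd.DataFrame(columns=OBSERVATION_COLUMNS)
    for col in ("mee_present", "biofilm_present", "blocked"):
        frame[col] = frame[col].astype(bool)
    return frame[OBSERVATION_COLUMNS]
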