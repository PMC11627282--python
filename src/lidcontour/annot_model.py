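"""Annotation data model: landmark schema, validation, and tabular writers.

A *photo annotation* records every manually placed landmark needed to
measure upper-eyelid contours on one frontal photograph: the pupil
center, the nasal and temporal limbus (the white-to-white endpoints used
for metric calibration), the lateral canthus, and the traced
upper-eyelid-margin polyline -- for both eyes -- plus patient sex,
timepoint and which side is ptotic.

Coordinates are raw image pixels in raster convention (y grows
downward). Conversion to a millimetre, y-up, pupil-centered frame is the
job of :mod:`lidcontour.normalize`.

Annotations serialize to a versioned JSON document (``schema_version``)
so that measurement inputs are diffable and reproducible.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

SCHEMA_VERSION = 1

#: Horizontal white-to-white corneal diameter used for in-image metric
#: calibration, by sex (mm).
WTW_MM: dict[str, float] = {"male": 11.77, "female": 11.64}

#: Column labels of the 10-position contour profile, nasal to temporal.
PROFILE_COLUMNS = ("N8", "N6", "N4", "N2", "MRD1", "T2", "T4", "T6", "T8", "T10")

Side = Literal["right", "left"]
Sex = Literal["male", "female"]
Timepoint = Literal["preop", "postop6m"]


class Point2D(BaseModel):
    """A finite 2-D coordinate pair (pixels or mm depending on context)."""

    model_config = ConfigDict(frozen=True)

    x: float
    y: float

    @field_validator("x", "y")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("coordinate must be finite")
        return v

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


class EyeAnnotation(BaseModel):
    """Landmarks of one eye in image pixel coordinates.

    ``margin`` is the hand-traced upper-eyelid-margin polyline, ordered
    roughly along the lid; monotonicity in x is only enforced after tilt
    correction, not here.
    """

    model_config = ConfigDict(frozen=True)

    side: Side
    pupil_center: Point2D
    limbus_nasal: Point2D
    limbus_temporal: Point2D
    lateral_canthus: Point2D
    margin: tuple[Point2D, ...] = Field(min_length=2)
    pupil_diameter: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _limbus_distinct(self) -> "EyeAnnotation":
        if self.limbus_nasal == self.limbus_temporal:
            raise ValueError("limbus_nasal and limbus_temporal must be distinct points")
        return self


class PhotoAnnotation(BaseModel):
    """One photograph's full landmark set: both eyes plus study metadata."""

    model_config = ConfigDict(frozen=True)

    schema_version: int = SCHEMA_VERSION
    patient_id: str
    timepoint: Timepoint
    sex: Sex
    ptotic_side: Side
    eyes: dict[Side, EyeAnnotation]
    image_path: Optional[str] = None
    metadata: dict[str, object] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _both_eyes(self) -> "PhotoAnnotation":
        missing = {"right", "left"} - set(self.eyes)
        if missing:
            raise ValueError(f"annotation must contain both eyes; missing: {sorted(missing)}")
        for key, eye in self.eyes.items():
            if eye.side != key:
                raise ValueError(f"eye stored under '{key}' is labeled side='{eye.side}'")
        return self

    @property
    def ptotic_eye(self) -> EyeAnnotation:
        return self.eyes[self.ptotic_side]

    @property
    def fellow_side(self) -> Side:
        return "left" if self.ptotic_side == "right" else "right"

    @property
    def fellow_eye(self) -> EyeAnnotation:
        return self.eyes[self.fellow_side]


def load_photo_annotation(path: str | Path) -> PhotoAnnotation:
    """Read and fully validate a photo-annotation JSON file.

    Raises ``FileNotFoundError`` if the file is absent and
    ``pydantic.ValidationError`` (naming the offending field) on any
    schema or invariant violation.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return PhotoAnnotation.model_validate(payload)


def save_photo_annotation(photo: PhotoAnnotation, path: str | Path) -> Path:
    """Write an annotation to JSON (stable key order, round-trip safe)."""
    path = Path(path)
    path.write_text(
        json.dumps(photo.model_dump(mode="json"), indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return path


def write_profile_table(
    profiles: list[tuple[str, str, str, "object"]],
    path: str | Path,
) -> pd.DataFrame:
    """Serialize contour profiles to CSV, one row per (patient, timepoint, eye role).

    ``profiles`` holds ``(patient_id, timepoint, eye_role, ContourProfile)``
    tuples. Columns follow the nasal-to-temporal order N8 ... T10; missing
    heights become empty cells. Duplicate keys are an error.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    keys = [(pid, tp, role) for pid, tp, role, _ in profiles]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (patient_id, timepoint, eye_role) rows: {dupes}")
    rows = []
    for pid, tp, role, prof in profiles:
        row: dict[str, object] = {"patient_id": pid, "timepoint": tp, "eye_role": role}
        row.update(prof.as_dict())
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["patient_id", "timepoint", "eye_role", *PROFILE_COLUMNS])
    frame.to_csv(path, index=False, float_format="%.9g")
    return frame


def read_profile_table(path: str | Path) -> pd.DataFrame:
    """Read a profile CSV written by :func:`write_profile_table` (NaN = missing)."""
    return pd.read_csv(path, dtype={"patient_id": str})
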