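"""Domain types, radiograph readers/writers, report parsing and dataset splits.

A :class:`Radiograph` is the package's canonical in-memory image: a 2-D grid
of non-negative integers plus bit depth, sex and optional age labels.  Bone
ages are integer year classes from 5 to 18 (the cohort excludes ages 0-4;
skeletally mature hands are capped at 18).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import pydicom

from .errors import (
    AmbiguousReportError,
    FormatError,
    InsufficientDataError,
    OutOfCohortError,
    UnparseableReportError,
)

MIN_BONE_AGE = 5
MAX_BONE_AGE = 18
#: Integer bone-age classes, youngest to oldest.
AGE_CLASSES = tuple(range(MIN_BONE_AGE, MAX_BONE_AGE + 1))


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"

    @classmethod
    def coerce(cls, value) -> "Sex":
        if isinstance(value, Sex):
            return value
        v = str(value).strip().lower()
        if v in ("f", "female"):
            return cls.FEMALE
        if v in ("m", "male"):
            return cls.MALE
        raise ValueError(f"unknown sex: {value!r}")


@dataclass
class Radiograph:
    """A hand/wrist radiograph with acquisition metadata.

    ``pixels`` is a 2-D integer array (row-major, origin top-left); values
    must lie in ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    sex: Sex | None = None
    chronological_age_years: float | None = None
    bone_age_label: int | None = None
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise FormatError("radiograph pixels must be a non-empty 2-D grid")
        if self.bit_depth not in (8, 16):
            raise FormatError(f"unsupported bit depth {self.bit_depth}")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise FormatError("radiograph pixels must be integers")
        if self.pixels.min() < 0 or self.pixels.max() > self.max_value:
            raise FormatError("pixel values outside the bit-depth range")
        if self.sex is not None:
            self.sex = Sex.coerce(self.sex)
        if self.bone_age_label is not None:
            lbl = int(self.bone_age_label)
            if not MIN_BONE_AGE <= lbl <= MAX_BONE_AGE:
                raise OutOfCohortError(f"bone age label {lbl} outside [5, 18]")
            self.bone_age_label = lbl

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def astype_float(self) -> np.ndarray:
        """Intensities scaled to [0, 1] as float32 (network ingestion scale)."""
        return self.pixels.astype(np.float32) / self.max_value

    def with_pixels(self, pixels: np.ndarray) -> "Radiograph":
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class DatasetSplit:
    """70/15/15 train/validation/test partition of study ids."""

    train_ids: frozenset
    validation_ids: frozenset
    test_ids: frozenset
    seed: int

    def __post_init__(self):
        sets = (self.train_ids, self.validation_ids, self.test_ids)
        total = sum(len(s) for s in sets)
        union = self.train_ids | self.validation_ids | self.test_ids
        if len(union) != total:
            raise ValueError("split sets must be pairwise disjoint")

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "train_ids": sorted(map(str, self.train_ids)),
                "validation_ids": sorted(map(str, self.validation_ids)),
                "test_ids": sorted(map(str, self.test_ids)),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "DatasetSplit":
        d = json.loads(text)
        return cls(
            frozenset(d["train_ids"]),
            frozenset(d["validation_ids"]),
            frozenset(d["test_ids"]),
            int(d["seed"]),
        )


# ---------------------------------------------------------------------------
# Report parsing
# ---------------------------------------------------------------------------

_KEYWORD_RE = re.compile(r"bone\s*age|skeletal", re.IGNORECASE)
_MATURE_RE = re.compile(r"matur", re.IGNORECASE)
_NUM = r"(\d+(?:\.\d+)?)"
_RANGE_RE = re.compile(
    _NUM + r"\s*(?:years?)?\s*(?:to|through|–|—|-)\s*" + _NUM + r"\s*years?",
    re.IGNORECASE,
)
_SINGLE_RE = re.compile(
    _NUM + r"\s*years?(?:\s*(?:,|and)?\s*(\d+)\s*months?)?",
    re.IGNORECASE,
)

#: characters scanned after each keyword for a bone-age statement
_WINDOW = 70


def _statement_months(window: str) -> float | None:
    """Months encoded by the first bone-age statement in ``window``."""
    if _MATURE_RE.search(window):
        return 12.0 * MAX_BONE_AGE
    m = _RANGE_RE.search(window)
    if m:
        lo, hi = float(m.group(1)), float(m.group(2))
        return (lo * 12.0 + hi * 12.0) / 2.0
    m = _SINGLE_RE.search(window)
    if m:
        months = float(m.group(1)) * 12.0
        if m.group(2):
            months += float(m.group(2))
        return months
    return None


def parse_bone_age(report_text: str) -> int:
    """Extract an integer bone-age class in [5, 18] from report text.

    The statement must follow one of the keywords "bone age" or "skeletal".
    Ranges ("13 to 14 years", "13-14 years") resolve to the arithmetic mean
    of the range; the result is computed in months and floored to whole
    years, so "13 to 14 years" gives 13.  "Skeletally mature" and any value
    above 18 map to 18.

    Raises
    ------
    UnparseableReportError
        If no keyword-anchored statement is found, or (subclass
        :class:`AmbiguousReportError`) if the report contains conflicting
        bone-age statements.
    OutOfCohortError
        If the parsed age is below 5 years (the 0-4 cohort is excluded).
    """
    values: list[float] = []
    for kw in _KEYWORD_RE.finditer(report_text):
        window = report_text[kw.end(): kw.end() + _WINDOW]
        months = _statement_months(window)
        if months is not None:
            values.append(months)
    if not values:
        raise UnparseableReportError(
            "no bone-age statement found near a 'bone age'/'skeletal' keyword"
        )
    distinct = sorted({math.floor(v / 12.0) for v in values})
    if len(distinct) > 1:
        raise AmbiguousReportError(
            f"conflicting bone-age statements (years {distinct}); report rejected"
        )
    years = distinct[0]
    if years > MAX_BONE_AGE:
        years = MAX_BONE_AGE
    if years < MIN_BONE_AGE:
        raise OutOfCohortError(
            f"parsed bone age {years} y is below the 5-18 year cohort"
        )
    return int(years)


# ---------------------------------------------------------------------------
# Dataset splitting
# ---------------------------------------------------------------------------

def split_dataset(
    ids: Iterable,
    seed: int,
    stratify_labels: Mapping | None = None,
) -> DatasetSplit:
    """Randomly split ids 70/15/15 into train/validation/test.

    Deterministic for a given seed; ids are sorted before shuffling so the
    result does not depend on input order.  ``stratify_labels`` (id -> label)
    optionally stratifies the split per label group; the default matches the
    simple random split used for the clinical cohort.
    """
    ids = sorted(set(ids), key=str)
    n = len(ids)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 ids to split, got {n}")

    if stratify_labels is not None:
        groups: dict = {}
        for i in ids:
            groups.setdefault(stratify_labels[i], []).append(i)
        train, val, test = [], [], []
        for k, (label, members) in enumerate(sorted(groups.items(), key=lambda kv: str(kv[0]))):
            sub = _simple_split(members, seed + k)
            train += sub[0]
            val += sub[1]
            test += sub[2]
    else:
        train, val, test = _simple_split(ids, seed)
    return DatasetSplit(frozenset(train), frozenset(val), frozenset(test), seed)


def _simple_split(ids: Sequence, seed: int):
    n = len(ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(round(0.15 * n))
    n_val = int(round(0.15 * n))
    shuffled = [ids[i] for i in order]
    test = shuffled[:n_test]
    val = shuffled[n_test: n_test + n_val]
    train = shuffled[n_test + n_val:]
    return train, val, test


# ---------------------------------------------------------------------------
# Image file I/O
# ---------------------------------------------------------------------------

def read_radiograph(path, sex=None, source_id: str | None = None) -> Radiograph:
    """Read a DICOM or 8/16-bit grayscale PNG file into a Radiograph.

    DICOM monochrome photometric interpretation is honored: MONOCHROME1
    (minimum = white) images are inverted so that higher stored values are
    always brighter.  Color images are rejected.
    """
    path = Path(path)
    sid = source_id if source_id is not None else path.stem
    if path.suffix.lower() in (".dcm", ".dicom") or _looks_like_dicom(path):
        return _read_dicom(path, sex, sid)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - wrap any decoder failure
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(
            f"{path} is not single-channel grayscale (shape {arr.shape})"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(f"{path}: unsupported pixel type {arr.dtype}")
    return Radiograph(arr, bit_depth=depth, sex=sex, source_id=sid)


def _looks_like_dicom(path: Path) -> bool:
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def _read_dicom(path: Path, sex, sid: str) -> Radiograph:
    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read DICOM {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(f"{path}: DICOM pixel data is not 2-D grayscale")
    bits = int(getattr(ds, "BitsStored", 0) or 0)
    depth = 16 if bits > 8 or arr.dtype.itemsize > 1 else 8
    arr = arr.astype(np.uint16 if depth == 16 else np.uint8)
    photometric = str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2"))
    if photometric == "MONOCHROME1":
        arr = ((1 << depth) - 1) - arr
    if sex is None:
        patient_sex = str(getattr(ds, "PatientSex", "") or "")
        if patient_sex.upper() in ("F", "M"):
            sex = Sex.coerce(patient_sex)
    return Radiograph(arr, bit_depth=depth, sex=sex, source_id=sid)


def write_radiograph(r: Radiograph, path) -> None:
    """Write a Radiograph as an 8- or 16-bit grayscale PNG."""
    dtype = np.uint8 if r.bit_depth == 8 else np.uint16
    iio.imwrite(Path(path), r.pixels.astype(dtype))


# ---------------------------------------------------------------------------
# Dataset manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("id", "path", "sex")


def read_manifest(path) -> pd.DataFrame:
    """Read a dataset manifest CSV.

    Required columns: id, path, sex.  Optional: chronological_age plus either
    bone_age (integer class) or report_text (parsed with
    :func:`parse_bone_age`).  Returns the frame with a resolved integer
    ``bone_age`` column where available.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing columns {missing}")
    if "bone_age" not in df.columns and "report_text" in df.columns:
        df["bone_age"] = [parse_bone_age(t) for t in df["report_text"]]
    return df


def load_manifest(path) -> list[Radiograph]:
    """Read every radiograph referenced by a manifest CSV."""
    df = read_manifest(path)
    base = Path(path).parent
    out = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        r = read_radiograph(p, sex=Sex.coerce(row.sex), source_id=str(row.id))
        if hasattr(row, "bone_age") and not pd.isna(row.bone_age):
            r.bone_age_label = int(row.bone_age)
        if hasattr(row, "chronological_age") and not pd.isna(row.chronological_age):
            r.chronological_age_years = float(row.chronological_age)
        out.append(r)
    return out
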