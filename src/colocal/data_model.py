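"""Domain types for segmented-cell point patterns and study metadata.

A study is a collection of images; each image is a marked point pattern:
cell centroids in a rectangular observation window, marked by cell type.
Images belong to subjects, subjects carry a condition (the tested variable)
and optional covariates. Input and output are plain delimited tables with
one row per cell.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Window",
    "CellImage",
    "ImageSet",
    "ValidationReport",
    "DEFAULT_COLUMNS",
    "load_cells",
    "write_cells",
    "validate_imageset",
]

#: Default header names for cell tables.
DEFAULT_COLUMNS = {
    "image_id": "imageID",
    "x": "x",
    "y": "y",
    "cell_type": "cellType",
    "subject_id": "subjectID",
    "condition": "condition",
}


class ConfigurationError(ValueError):
    """Raised when user-supplied configuration is inconsistent."""


@dataclass(frozen=True)
class Window:
    """Rectangular observation window; its area enters the K-function."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate window [{self.x_min},{self.x_max}]x[{self.y_min},{self.y_max}]"
            )

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership test."""
        return (
            (x >= self.x_min) & (x <= self.x_max) & (y >= self.y_min) & (y <= self.y_max)
        )


@dataclass
class CellImage:
    """One segmented image as a marked point pattern.

    Parameters
    ----------
    image_id : str
        Opaque identifier, unique within a study.
    x, y : ndarray of float
        Cell centroid coordinates, continuous, same units as the radii
        used downstream.
    marks : ndarray of str
        One cell-type label per point (whitespace-trimmed, matched
        case-sensitively).
    window : Window
        Observation window containing all points.
    """

    image_id: str
    x: np.ndarray
    y: np.ndarray
    marks: np.ndarray
    window: Window

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.marks = np.asarray(self.marks, dtype=object)
        if not (len(self.x) == len(self.y) == len(self.marks)):
            raise ValueError("x, y and marks must have equal length")
        inside = self.window.contains(self.x, self.y)
        if not inside.all():
            bad = np.flatnonzero(~inside)
            raise ValueError(
                f"image {self.image_id!r}: {bad.size} point(s) outside window "
                f"(first offending indices: {bad[:10].tolist()})"
            )

    @property
    def n_cells(self) -> int:
        return len(self.x)

    def counts(self) -> dict[str, int]:
        """Number of cells per type label."""
        labels, n = np.unique(self.marks.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), n.tolist()))

    def coords_of(self, cell_type: str) -> np.ndarray:
        """(n, 2) coordinate array of the cells carrying ``cell_type``."""
        sel = self.marks == cell_type
        return np.column_stack([self.x[sel], self.y[sel]])


@dataclass
class ImageSet:
    """A study: images plus subject / condition / covariate metadata.

    ``subject_of`` maps image id to subject id; ``condition_of`` maps
    subject id to the condition value. A subject's condition must be
    constant across its images (enforced by construction here since the
    map is keyed by subject). The number of images per subject is free.
    """

    images: dict[str, CellImage] = field(default_factory=dict)
    subject_of: dict[str, str] = field(default_factory=dict)
    condition_of: dict[str, object] = field(default_factory=dict)
    covariates_of: dict[str, dict[str, object]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.images)

    def image_ids(self) -> list[str]:
        return list(self.images)

    def subjects(self) -> list[str]:
        return sorted(set(self.subject_of.values()))

    def types(self) -> list[str]:
        labels: set[str] = set()
        for img in self.images.values():
            labels.update(map(str, img.marks))
        return sorted(labels)

    def add_image(
        self,
        image: CellImage,
        subject_id: str | None = None,
        condition: object | None = None,
        covariates: Mapping[str, object] | None = None,
    ) -> None:
        if image.image_id in self.images:
            raise ValueError(f"duplicate image id {image.image_id!r}")
        self.images[image.image_id] = image
        if subject_id is not None:
            self.subject_of[image.image_id] = subject_id
            if condition is not None:
                prev = self.condition_of.get(subject_id)
                if prev is not None and prev != condition:
                    raise ValueError(
                        f"subject {subject_id!r} assigned conflicting conditions "
                        f"{prev!r} and {condition!r}"
                    )
                self.condition_of[subject_id] = condition
        if covariates:
            self.covariates_of[image.image_id] = dict(covariates)

    def metadata_frame(self) -> pd.DataFrame:
        """One row per image: image id, subject, condition, covariates."""
        rows = []
        for iid in self.images:
            sid = self.subject_of.get(iid)
            row = {
                "image_id": iid,
                "subject_id": sid,
                "condition": self.condition_of.get(sid) if sid is not None else None,
            }
            row.update(self.covariates_of.get(iid, {}))
            rows.append(row)
        return pd.DataFrame(rows)

    def to_frame(self, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Export as a long cell table (one row per cell)."""
        cols = dict(DEFAULT_COLUMNS)
        if column_map:
            cols.update(column_map)
        frames = []
        for iid, img in self.images.items():
            df = pd.DataFrame(
                {
                    cols["image_id"]: iid,
                    cols["x"]: img.x,
                    cols["y"]: img.y,
                    cols["cell_type"]: img.marks.astype(str),
                }
            )
            sid = self.subject_of.get(iid)
            if sid is not None:
                df[cols["subject_id"]] = sid
                cond = self.condition_of.get(sid)
                if cond is not None:
                    df[cols["condition"]] = cond
            for name, value in self.covariates_of.get(iid, {}).items():
                df[name] = value
            frames.append(df)
        if not frames:
            return pd.DataFrame(columns=[cols["image_id"], cols["x"], cols["y"], cols["cell_type"]])
        return pd.concat(frames, ignore_index=True)


def _resolve_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def load_cells(
    path: str | Path | io.IOBase,
    column_map: Mapping[str, str] | None = None,
    window_policy: str | Window = "bounding_box",
    sep: str | None = None,
) -> ImageSet:
    """Read a delimited cell table into an :class:`ImageSet`.

    Parameters
    ----------
    path : path or file-like
        CSV/TSV file with at least image-id, x, y and cell-type columns.
        TSV is assumed for ``.tsv``/``.txt`` extensions; pass ``sep`` to
        override.
    column_map : mapping, optional
        Overrides for the default header names (keys: ``image_id``, ``x``,
        ``y``, ``cell_type``, ``subject_id``, ``condition``).
    window_policy : "bounding_box", Window, or mapping image id -> Window
        How to set each image's observation window. ``"bounding_box"``
        uses the image's own point bounding box; a :class:`Window`
        instance fixes the same window for every image; a mapping gives
        each image its own window (points outside raise in both explicit
        forms). The window area enters the K-function directly, so this
        choice is deliberately explicit.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    use_sep = _resolve_sep(path if isinstance(path, (str, Path)) else "x.csv", sep)
    df = pd.read_csv(path, sep=use_sep)

    for key in ("image_id", "x", "y", "cell_type"):
        if cols[key] not in df.columns:
            raise ConfigurationError(
                f"required column {cols[key]!r} (role {key!r}) not found in input; "
                f"available: {list(df.columns)}"
            )
    for axis in ("x", "y"):
        vals = pd.to_numeric(df[cols[axis]], errors="coerce")
        bad = vals.isna() & df[cols[axis]].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric {axis} coordinate at row {row + 2} "
                f"(value {df[cols[axis]].iloc[row]!r})"
            )
        df[cols[axis]] = vals

    has_subject = cols["subject_id"] in df.columns
    has_condition = cols["condition"] in df.columns

    s = ImageSet()
    for iid, grp in df.groupby(cols["image_id"], sort=True):
        x = grp[cols["x"]].to_numpy(float)
        y = grp[cols["y"]].to_numpy(float)
        marks = grp[cols["cell_type"]].astype(str).str.strip().to_numpy(object)
        if isinstance(window_policy, (Window, Mapping)):
            if isinstance(window_policy, Mapping):
                try:
                    win = window_policy[str(iid)]
                except KeyError:
                    raise ConfigurationError(
                        f"no window supplied for image {iid!r}"
                    ) from None
            else:
                win = window_policy
            inside = win.contains(x, y)
            if not inside.all():
                rows = (grp.index[~inside] + 2).tolist()
                raise ValueError(
                    f"image {iid!r}: points outside the supplied window at "
                    f"file rows {rows[:20]}"
                )
        elif window_policy == "bounding_box":
            win = Window(x.min(), max(x.max(), x.min() + 1e-9),
                         y.min(), max(y.max(), y.min() + 1e-9))
        else:
            raise ConfigurationError(f"unknown window_policy {window_policy!r}")
        subject = str(grp[cols["subject_id"]].iloc[0]) if has_subject else None
        condition = grp[cols["condition"]].iloc[0] if has_condition else None
        known = set(cols.values())
        covariates = {
            c: grp[c].iloc[0] for c in df.columns if c not in known
        } or None
        s.add_image(
            CellImage(str(iid), x, y, marks, win),
            subject_id=subject,
            condition=condition,
            covariates=covariates,
        )
    return s


def write_cells(
    s: ImageSet,
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> None:
    """Write an :class:`ImageSet` back to a delimited cell table."""
    df = s.to_frame(column_map)
    df.to_csv(path, sep=_resolve_sep(path, sep), index=False)


@dataclass
class ValidationReport:
    """Structural summary of a study; never raises, only reports."""

    n_images: int
    counts: pd.DataFrame  # per-image per-type cell counts
    images_per_subject: pd.Series
    zero_count_images: dict[str, list[str]]  # type -> image ids with 0 cells
    inconsistent_subjects: list[str]

    @property
    def ok(self) -> bool:
        return not self.inconsistent_subjects

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"images: {self.n_images}",
            f"subjects: {len(self.images_per_subject)}",
        ]
        if len(self.images_per_subject):
            lines.append(
                "images/subject: "
                f"min {int(self.images_per_subject.min())}, "
                f"max {int(self.images_per_subject.max())}"
            )
        for t, ids in self.zero_count_images.items():
            if ids:
                lines.append(f"type {t!r} absent from {len(ids)} image(s)")
        if self.inconsistent_subjects:
            lines.append(
                f"INCONSISTENT condition within subjects: {self.inconsistent_subjects}"
            )
        return "\n".join(lines)


def validate_imageset(s: ImageSet, types: Sequence[str] | None = None) -> ValidationReport:
    """Check study structure and tabulate per-image per-type counts.

    ``condition_of`` is keyed by subject, so a per-subject condition can
    only conflict if the caller keyed it by image id instead; both keying
    styles are checked.
    """
    all_types = list(types) if types is not None else s.types()
    count_rows = []
    for iid, img in s.images.items():
        c = img.counts()
        count_rows.append({"image_id": iid, **{t: c.get(t, 0) for t in all_types}})
    counts = pd.DataFrame(count_rows).set_index("image_id") if count_rows else pd.DataFrame()

    zero: dict[str, list[str]] = {
        t: counts.index[counts[t] == 0].tolist() if len(counts) else []
        for t in all_types
    }

    meta = s.metadata_frame()
    if len(meta) and meta["subject_id"].notna().any():
        images_per_subject = meta.groupby("subject_id")["image_id"].count()
    else:
        images_per_subject = pd.Series(dtype=int)

    inconsistent = []
    if len(meta):
        # condition conflicts can arise when conditions were keyed by image id
        per_img_cond = {
            iid: s.condition_of.get(iid, s.condition_of.get(s.subject_of.get(iid)))
            for iid in s.images
        }
        df = pd.DataFrame(
            {"subject": [s.subject_of.get(i) for i in per_img_cond],
             "cond": list(per_img_cond.values())}
        ).dropna(subset=["subject"])
        for subj, grp in df.groupby("subject"):
            vals = grp["cond"].dropna().unique()
            if len(vals) > 1:
                inconsistent.append(str(subj))

    return ValidationReport(
        n_images=len(s),
        counts=counts,
        images_per_subject=images_per_subject,
        zero_count_images=zero,
        inconsistent_subjects=sorted(inconsistent),
    )
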