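"""Readers and writers for the delimited-text tables the pipeline consumes.

Three table kinds are handled: keypoint pose tracks (the DeepLabCut CSV
dialect with its three-row scorer/bodyparts/coords header, plus a plain
single-header dialect), per-frame motif label series, and cohort metadata.
Readers validate on load and never coerce silently: every repair (missing
cell, likelihood-filtered coordinate) is counted in a :class:`ParseSummary`.

All outputs are UTF-8 with LF line endings and a fixed field order so that
files diff bit-exactly across runs.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ParseSummary",
    "PoseTrack",
    "LabelSeries",
    "CohortTable",
    "read_pose_table",
    "write_pose_table",
    "read_label_series",
    "write_label_series",
    "read_cohort",
    "write_cohort",
]

COHORT_COLUMNS = ["subject_id", "genotype", "sex", "group", "session_minutes"]


class FormatError(ValueError):
    """A file does not match the declared dialect (bad header, ragged rows)."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant (bad label, duplicate id)."""


@dataclass
class ParseSummary:
    """Tally of every repair a reader applied; nothing is fixed silently."""

    missing_cells: int = 0
    likelihood_filtered: int = 0
    notes: list[str] = field(default_factory=list)


@dataclass
class PoseTrack:
    """One subject's keypoint track: (x, y) pixels + confidence per part.

    ``coords`` has shape (n_frames, n_parts, 2) with NaN marking missing
    observations (zeros are valid pixel coordinates, so NaN is the only
    missing sentinel). ``likelihood`` has shape (n_frames, n_parts).
    """

    subject_id: str
    fps: float
    parts: list[str]
    coords: np.ndarray
    likelihood: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        n_parts = len(self.parts)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (n_parts, 2):
            raise ValidationError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"{n_parts} parts"
            )
        if self.likelihood.shape != self.coords.shape[:2]:
            raise ValidationError("likelihood shape inconsistent with coords")
        finite = self.likelihood[np.isfinite(self.likelihood)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("likelihoods must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def part_index(self, name: str) -> int:
        try:
            return self.parts.index(name)
        except ValueError:
            raise ValidationError(
                f"unknown body part {name!r}; available: {self.parts}"
            ) from None

    def mask_low_likelihood(self, floor: float) -> tuple["PoseTrack", ParseSummary]:
        """Return a copy with coordinates below the confidence floor set missing."""
        summary = ParseSummary()
        coords = self.coords.copy()
        low = self.likelihood < floor
        summary.likelihood_filtered = int(low.sum())
        coords[low] = np.nan
        return (
            PoseTrack(self.subject_id, self.fps, list(self.parts), coords,
                      self.likelihood.copy()),
            summary,
        )


@dataclass
class LabelSeries:
    """Per-frame integer motif (or community) labels at a fixed frame rate."""

    subject_id: str
    fps: float
    labels: np.ndarray
    alphabet_size: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValidationError("labels must be a nonempty 1-D sequence")
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        if self.alphabet_size <= 0:
            raise ValidationError("alphabet_size must be positive")
        bad = np.where((self.labels < 0) | (self.labels >= self.alphabet_size))[0]
        if bad.size:
            raise ValidationError(
                f"label {int(self.labels[bad[0]])} at index {int(bad[0])} "
                f"outside alphabet [0, {self.alphabet_size})"
            )

    @property
    def n_frames(self) -> int:
        return int(self.labels.size)

    @property
    def seconds(self) -> float:
        return self.n_frames / self.fps


class CohortTable:
    """Validated cohort metadata: subject, genotype, sex, group, duration."""

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in COHORT_COLUMNS if c not in table.columns]
        if missing:
            raise ValidationError(f"cohort table missing columns: {missing}")
        table = table.loc[:, COHORT_COLUMNS].reset_index(drop=True)
        dup = table["subject_id"][table["subject_id"].duplicated()].tolist()
        if dup:
            raise ValidationError(f"duplicate subject_id values: {sorted(set(dup))}")
        if (table["session_minutes"] <= 0).any():
            raise ValidationError("session_minutes must be positive")
        self.table = table
        self.genotypes = sorted(table["genotype"].unique().tolist())
        self.sexes = sorted(table["sex"].unique().tolist())
        self.groups = sorted(table["group"].unique().tolist())

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    def row(self, subject_id: str) -> pd.Series:
        hit = self.table[self.table["subject_id"] == subject_id]
        if hit.empty:
            raise ValidationError(f"unknown subject {subject_id!r}")
        return hit.iloc[0]

    def subjects_where(self, **levels: str) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        for col, val in levels.items():
            mask &= self.table[col] == val
        return self.table.loc[mask, "subject_id"].tolist()


# ---------------------------------------------------------------------------
# Pose tables


def _parse_float(cell: str, row_idx: int, path: Path) -> float:
    cell = cell.strip()
    if cell == "" or cell.lower() in {"nan", "na"}:
        return np.nan
    try:
        return float(cell)
    except ValueError:
        raise FormatError(
            f"{path}: non-numeric value {cell!r} in data row {row_idx}"
        ) from None


def read_pose_table(
    path: str | Path,
    dialect: str = "dlc_multiheader",
    fps: float = 25.0,
    subject_id: str | None = None,
) -> tuple[PoseTrack, ParseSummary]:
    """Read a pose CSV in the DeepLabCut or plain dialect.

    The DLC dialect carries three header rows (scorer, bodyparts, coords)
    and a leading frame-index column; each part contributes an
    (x, y, likelihood) column triplet. The plain dialect has one header row
    ``frame,<part>_x,<part>_y,<part>_likelihood,...``.
    """
    path = Path(path)
    if subject_id is None:
        subject_id = path.stem
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")

    if dialect == "dlc_multiheader":
        if len(rows) < 4:
            raise FormatError(f"{path}: DLC dialect needs 3 header rows + data")
        scorer_row, parts_row, coords_row = rows[0], rows[1], rows[2]
        if scorer_row[0].strip().lower() != "scorer":
            raise FormatError(f"{path}: header row 1 must start with 'scorer'")
        if parts_row[0].strip().lower() != "bodyparts":
            raise FormatError(f"{path}: header row 2 must start with 'bodyparts'")
        if coords_row[0].strip().lower() != "coords":
            raise FormatError(f"{path}: header row 3 must start with 'coords'")
        part_cells = [c.strip() for c in parts_row[1:]]
        coord_cells = [c.strip().lower() for c in coords_row[1:]]
        if len(part_cells) % 3 != 0:
            raise FormatError(
                f"{path}: bodyparts header row does not list x/y/likelihood "
                "triplets"
            )
        parts = part_cells[0::3]
        for i, p in enumerate(parts):
            if part_cells[3 * i: 3 * i + 3] != [p, p, p]:
                raise FormatError(
                    f"{path}: bodyparts header row inconsistent around {p!r}"
                )
            if coord_cells[3 * i: 3 * i + 3] != ["x", "y", "likelihood"]:
                raise FormatError(
                    f"{path}: coords header row must repeat x,y,likelihood"
                )
        data_rows = rows[3:]
        expected_len = 1 + 3 * len(parts)
    elif dialect == "plain":
        header = [c.strip() for c in rows[0]]
        if not header or header[0] != "frame":
            raise FormatError(f"{path}: plain dialect header must start 'frame'")
        cols = header[1:]
        if len(cols) % 3 != 0:
            raise FormatError(f"{path}: plain header does not list triplets")
        parts = []
        for i in range(0, len(cols), 3):
            if not (cols[i].endswith("_x") and cols[i + 1].endswith("_y")
                    and cols[i + 2].endswith("_likelihood")):
                raise FormatError(
                    f"{path}: plain header malformed near column {cols[i]!r}"
                )
            parts.append(cols[i][:-2])
        data_rows = rows[1:]
        expected_len = 1 + 3 * len(parts)
    else:
        raise ValidationError(f"unknown pose dialect {dialect!r}")

    n = len(data_rows)
    coords = np.full((n, len(parts), 2), np.nan)
    like = np.full((n, len(parts)), np.nan)
    summary = ParseSummary()
    for r, row in enumerate(data_rows):
        if len(row) != expected_len:
            raise FormatError(
                f"{path}: data row {r} has {len(row)} cells, header implies "
                f"{expected_len}"
            )
        for p in range(len(parts)):
            x = _parse_float(row[1 + 3 * p], r, path)
            y = _parse_float(row[2 + 3 * p], r, path)
            lk = _parse_float(row[3 + 3 * p], r, path)
            if np.isnan(x) or np.isnan(y):
                summary.missing_cells += 1
                x = y = np.nan
            coords[r, p] = (x, y)
            like[r, p] = lk
    track = PoseTrack(subject_id, fps, parts, coords, like)
    return track, summary


def write_pose_table(track: PoseTrack, path: str | Path,
                     dialect: str = "dlc_multiheader",
                     scorer: str = "motifkit") -> None:
    path = Path(path)
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")

    def fmt(v: float) -> str:
        return "" if np.isnan(v) else repr(float(v))

    if dialect == "dlc_multiheader":
        w.writerow(["scorer"] + [scorer] * (3 * len(track.parts)))
        w.writerow(["bodyparts"] + [p for part in track.parts for p in (part,) * 3])
        w.writerow(["coords"] + ["x", "y", "likelihood"] * len(track.parts))
    elif dialect == "plain":
        header = ["frame"]
        for p in track.parts:
            header += [f"{p}_x", f"{p}_y", f"{p}_likelihood"]
        w.writerow(header)
    else:
        raise ValidationError(f"unknown pose dialect {dialect!r}")
    for r in range(track.n_frames):
        row = [str(r)]
        for p in range(len(track.parts)):
            row += [fmt(track.coords[r, p, 0]), fmt(track.coords[r, p, 1]),
                    fmt(track.likelihood[r, p])]
        w.writerow(row)
    path.write_text(buf.getvalue(), encoding="utf-8", newline="")


# ---------------------------------------------------------------------------
# Label series


def read_label_series(path: str | Path, fps: float, alphabet_size: int,
                      subject_id: str | None = None) -> LabelSeries:
    """Read a label file: either one label per line, or (frame, label) rows.

    A single header line naming the columns is accepted and skipped.
    """
    path = Path(path)
    if subject_id is None:
        subject_id = path.stem
    labels: list[int] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            cells = [c for c in line.replace(",", "\t").split("\t") if c != ""]
            if lineno == 0 and not cells[-1].lstrip("-").isdigit():
                continue  # header
            try:
                value = int(cells[-1])
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer label {cells[-1]!r} on line {lineno + 1}"
                ) from None
            if value < 0 or value >= alphabet_size:
                raise ValidationError(
                    f"{path}: label {value} at index {len(labels)} outside "
                    f"alphabet [0, {alphabet_size})"
                )
            labels.append(value)
    return LabelSeries(subject_id, fps, np.array(labels, dtype=np.int64),
                       alphabet_size)


def write_label_series(series: LabelSeries, path: str | Path) -> None:
    lines = ["frame\tlabel"]
    lines += [f"{i}\t{int(v)}" for i, v in enumerate(series.labels)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="")


# ---------------------------------------------------------------------------
# Cohort tables


def read_cohort(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    buf = cohort.table.to_csv(sep="\t", index=False, lineterminator="\n")
    Path(path).write_text(buf, encoding="utf-8", newline="")


def write_tidy(df: pd.DataFrame, path: str | Path,
               float_format: str = "%.10g") -> None:
    """Write a tidy result table: TSV, UTF-8, LF, fixed column order."""
    buf = df.to_csv(sep="\t", index=False, lineterminator="\n",
                    float_format=float_format)
    Path(path).write_text(buf, encoding="utf-8", newline="")
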