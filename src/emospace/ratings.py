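"""Line-segment rating data: containers, I/O, validation and descriptive summaries.

Raters judge each emotion word on several aspects (by default valence,
arousal, control and utility) by marking a 10 cm line; the mark position is
read in millimetres from the left end, giving a continuous 0–100 score per
(participant, emotion, aspect) cell.  The left pole is the low end of each
aspect (unpleasant / calm / uncontrolled / harmful) and the right pole the
high end.  This module holds that tensor, reads and writes it as long or
wide CSV, validates it, and aggregates it into per-cell means and standard
deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateEntryError,
    FormatError,
    RangeError,
    SummarizationError,
)

#: Canonical aspect order used throughout the package.
DEFAULT_ASPECTS: tuple[str, ...] = ("valence", "arousal", "control", "utility")

LONG_COLUMNS = ("participant_id", "emotion", "aspect", "value_mm")


def mm_to_score(mark_position):
    """Convert a mark position (mm from the left end of a 10 cm line) to a rating.

    The instrument is read directly in millimetres, so this is the identity
    map onto the 0–100 scale; it exists to document the convention (left =
    low pole, right = high pole) and to enforce the physical range.

    Parameters
    ----------
    mark_position : float or array-like
        Distance of the mark from the left line end, in mm.

    Returns
    -------
    float or ndarray
        The rating value(s), identical to the input.

    Raises
    ------
    RangeError
        If any position lies outside [0, 100] (off the printed line).
    """
    arr = np.asarray(mark_position, dtype=float)
    if np.any(~np.isnan(arr) & ((arr < 0.0) | (arr > 100.0))):
        bad = arr[~np.isnan(arr) & ((arr < 0.0) | (arr > 100.0))].flat[0]
        raise RangeError(f"mark position {bad} mm is outside the 0-100 mm line")
    if np.isscalar(mark_position):
        return float(arr)
    return arr


@dataclass
class RatingDataset:
    """Participant × emotion × aspect tensor of 0–100 line-segment ratings.

    ``values[i, j, k]`` is participant ``participant_ids[i]``'s rating of
    emotion ``emotions[j]`` on aspect ``aspects[k]`` in mm; missing cells
    are NaN.
    """

    participant_ids: list
    emotions: list
    aspects: list
    values: np.ndarray  # shape (n_participants, n_emotions, n_aspects); NaN = missing

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.participant_ids), len(self.emotions), len(self.aspects))
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match labels {expected}"
            )

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    def aspect_slice(self, aspect: str) -> pd.DataFrame:
        """Participant × emotion matrix for one aspect."""
        k = self.aspects.index(aspect)
        return pd.DataFrame(
            self.values[:, :, k], index=self.participant_ids, columns=self.emotions
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table with one row per non-missing cell, canonical order."""
        p, e, a = np.meshgrid(
            np.arange(self.n_participants),
            np.arange(len(self.emotions)),
            np.arange(len(self.aspects)),
            indexing="ij",
        )
        flat = self.values.ravel()
        frame = pd.DataFrame(
            {
                "participant_id": np.asarray(self.participant_ids, dtype=object)[p.ravel()],
                "emotion": np.asarray(self.emotions, dtype=object)[e.ravel()],
                "aspect": np.asarray(self.aspects, dtype=object)[a.ravel()],
                "value_mm": flat,
            }
        )
        return frame[~frame["value_mm"].isna()].reset_index(drop=True)


def _unique_in_order(seq: Iterable) -> list:
    seen: dict = {}
    for item in seq:
        seen.setdefault(item, None)
    return list(seen)


def _frame_to_dataset(frame: pd.DataFrame, clip: bool) -> RatingDataset:
    frame = frame.copy()
    try:
        frame["value_mm"] = frame["value_mm"].astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"unparseable rating value: {exc}") from exc

    dup = frame.duplicated(subset=["participant_id", "emotion", "aspect"])
    if dup.any():
        row = frame[dup].iloc[0]
        raise DuplicateEntryError(
            "duplicate rating for participant "
            f"{row['participant_id']!r}, emotion {row['emotion']!r}, "
            f"aspect {row['aspect']!r}"
        )

    out_of_range = (frame["value_mm"] < 0) | (frame["value_mm"] > 100)
    if out_of_range.any():
        if clip:
            frame.loc[:, "value_mm"] = frame["value_mm"].clip(0.0, 100.0)
        else:
            idx = out_of_range.idxmax()
            row = frame.loc[idx]
            raise RangeError(
                f"row {idx}: value {row['value_mm']} mm outside [0, 100] "
                f"(participant {row['participant_id']!r}, emotion "
                f"{row['emotion']!r}, aspect {row['aspect']!r}); "
                "pass clip=True to clamp instead"
            )

    participants = _unique_in_order(frame["participant_id"])
    emotions = _unique_in_order(frame["emotion"])
    aspects = _unique_in_order(frame["aspect"])

    values = np.full((len(participants), len(emotions), len(aspects)), np.nan)
    p_idx = {p: i for i, p in enumerate(participants)}
    e_idx = {e: i for i, e in enumerate(emotions)}
    a_idx = {a: i for i, a in enumerate(aspects)}
    for p, e, a, v in frame[list(LONG_COLUMNS)].itertuples(index=False):
        values[p_idx[p], e_idx[e], a_idx[a]] = v
    return RatingDataset(participants, emotions, aspects, values)


def load_ratings(path, layout: str = "long", clip: bool = False) -> RatingDataset:
    """Read a rating CSV into a :class:`RatingDataset`.

    Parameters
    ----------
    path : str or file-like
        CSV file.  ``long`` layout has columns
        ``participant_id,emotion,aspect,value_mm``; ``wide`` layout has one
        row per participant × aspect (columns ``participant_id,aspect``
        followed by one column per emotion).
    layout : {"long", "wide"}
    clip : bool
        If True, values outside [0, 100] are clamped instead of raising
        (mirrors the CLI ``--clip`` flag).  Default is to raise, because
        silent clipping hides instrument or transcription errors.

    Label order preserves order of first appearance in the file.
    """
    try:
        frame = pd.read_csv(path, dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise FormatError(f"could not read ratings file {path!r}: {exc}") from exc

    if layout == "long":
        missing = set(LONG_COLUMNS) - set(frame.columns)
        if missing:
            raise FormatError(f"long layout is missing columns {sorted(missing)}")
        frame = frame[list(LONG_COLUMNS)]
    elif layout == "wide":
        for col in ("participant_id", "aspect"):
            if col not in frame.columns:
                raise FormatError(f"wide layout is missing column {col!r}")
        emotions = [c for c in frame.columns if c not in ("participant_id", "aspect")]
        if not emotions:
            raise FormatError("wide layout has no emotion columns")
        frame = frame.melt(
            id_vars=["participant_id", "aspect"],
            value_vars=emotions,
            var_name="emotion",
            value_name="value_mm",
        )
        frame = frame[list(LONG_COLUMNS)]
    else:
        raise ValueError(f"unknown layout {layout!r}; expected 'long' or 'wide'")
    return _frame_to_dataset(frame, clip=clip)


def save_ratings(dataset: RatingDataset, path, layout: str = "long") -> None:
    """Write a dataset as CSV with canonical ordering and fixed formatting.

    Long output is sorted (participant, emotion, aspect) in the dataset's
    label order with 6-decimal values, so save→load→save is byte-identical.
    """
    if layout == "long":
        frame = dataset.to_long_frame()
        frame.to_csv(path, index=False, float_format="%.6f")
    elif layout == "wide":
        frame = dataset.to_long_frame()
        wide = frame.pivot_table(
            index=["participant_id", "aspect"],
            columns="emotion",
            values="value_mm",
            sort=False,
        ).reset_index()
        # pivot_table sorts the index lexically; restore dataset order
        order = {
            (p, a): i
            for i, (p, a) in enumerate(
                (p, a) for p in dataset.participant_ids for a in dataset.aspects
            )
        }
        wide = wide.iloc[
            sorted(range(len(wide)), key=lambda i: order[(wide.iloc[i, 0], wide.iloc[i, 1])])
        ]
        wide = wide[["participant_id", "aspect"] + list(dataset.emotions)]
        wide.to_csv(path, index=False, float_format="%.6f")
    else:
        raise ValueError(f"unknown layout {layout!r}")


@dataclass
class AspectSummaryTable:
    """Per (emotion, aspect) arithmetic mean M, sample SD and n, in mm units."""

    table: pd.DataFrame  # columns: emotion, aspect, mean, sd, n

    def __post_init__(self):
        required = {"emotion", "aspect", "mean", "sd", "n"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"summary table needs columns {sorted(required)}")
        if self.table.duplicated(subset=["emotion", "aspect"]).any():
            raise DuplicateEntryError("duplicate (emotion, aspect) row in summary")

    @property
    def emotions(self) -> list:
        return _unique_in_order(self.table["emotion"])

    @property
    def aspects(self) -> list:
        return _unique_in_order(self.table["aspect"])

    def mean_matrix(self) -> pd.DataFrame:
        """Emotion × aspect matrix of means (rows/columns in table order)."""
        return (
            self.table.pivot(index="emotion", columns="aspect", values="mean")
            .loc[self.emotions, self.aspects]
        )

    def sd_matrix(self) -> pd.DataFrame:
        return (
            self.table.pivot(index="emotion", columns="aspect", values="sd")
            .loc[self.emotions, self.aspects]
        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path) -> "AspectSummaryTable":
        return cls(pd.read_csv(path))


def summarize(dataset: RatingDataset) -> AspectSummaryTable:
    """Aggregate ratings into per-cell mean, sample SD (n−1) and count.

    Missing values are excluded cell-wise; a cell with zero observations is
    an error because its mean is undefined.
    """
    rows = []
    for j, emotion in enumerate(dataset.emotions):
        for k, aspect in enumerate(dataset.aspects):
            col = dataset.values[:, j, k]
            col = col[~np.isnan(col)]
            if col.size == 0:
                raise SummarizationError(
                    f"no observations for emotion {emotion!r}, aspect {aspect!r}"
                )
            # constant cells get the exact value (no accumulation rounding)
            if np.all(col == col[0]):
                mean, sd = float(col[0]), 0.0
            else:
                mean = float(np.mean(col))
                sd = float(np.std(col, ddof=1)) if col.size > 1 else 0.0
            rows.append((emotion, aspect, mean, sd, int(col.size)))
    return AspectSummaryTable(
        pd.DataFrame(rows, columns=["emotion", "aspect", "mean", "sd", "n"])
    )


@dataclass
class Violation:
    """One invariant violation: where, which rule, what was observed."""

    location: tuple
    rule: str
    observed: object


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    @property
    def overall_ok(self) -> bool:
        return not self.violations


def validate(dataset: RatingDataset) -> ValidationReport:
    """Check every dataset invariant; violations are returned, not raised."""
    report = ValidationReport()

    for name, labels in (("emotion", dataset.emotions), ("aspect", dataset.aspects),
                         ("participant", dataset.participant_ids)):
        seen = set()
        for label in labels:
            if label in seen:
                report.violations.append(
                    Violation((name, label), f"duplicate_{name}_label", label)
                )
            seen.add(label)
            if name != "participant" and (label is None or str(label) == ""):
                report.violations.append(
                    Violation((name, label), f"empty_{name}_label", label)
                )

    bad = np.argwhere(
        ~np.isnan(dataset.values)
        & ((dataset.values < 0.0) | (dataset.values > 100.0))
    )
    for i, j, k in bad:
        report.violations.append(
            Violation(
                (dataset.participant_ids[i], dataset.emotions[j], dataset.aspects[k]),
                "value_out_of_range",
                float(dataset.values[i, j, k]),
            )
        )
    return report
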