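"""Dissimilarity construction: profile distances, correlation-derived proximities.

Two families of inter-emotion dissimilarity are built from the rating data:

* **Profile distances** — Euclidean distances between the emotions'
  4-vectors of mean ratings (valence, arousal, control, utility), each axis
  on the 0–100 mm scale.  With four aspects the theoretical range is
  0 to 200 = 100·√4, the main diagonal of a hypercube of side 100.

* **Correlation-derived proximities** — one matrix per aspect: the Spearman
  correlation between every pair of emotions across participants, mapped to
  a dissimilarity by d = 1 − r, so r = 1 ↦ 0, r = 0 ↦ 1 and r = −1 ↦ 2.
  These four matrices are the sources fed jointly to the multi-source MDS
  engine.

The module also provides the pairwise aspect-independence check (Bonferroni
over the 6 aspect pairs) that motivates treating the four aspects as
distinct input qualities.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    AlignmentError,
    DimensionalityError,
    UndefinedCoefficientError,
)
from .ratings import AspectSummaryTable, RatingDataset

PROXIMITY_KINDS = ("profile_distance", "correlation_derived", "configuration_distance")


@dataclass
class ProximityMatrix:
    """Labelled symmetric nonnegative dissimilarity matrix.

    ``scale_max`` documents the theoretical maximum of the measure: 200 for
    4-aspect profile distances, 2 for correlation-derived proximities.
    """

    labels: list
    values: np.ndarray
    kind: str
    aspect_tag: Optional[str] = None
    scale_max: Optional[float] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if self.kind not in PROXIMITY_KINDS:
            raise ValueError(f"kind must be one of {PROXIMITY_KINDS}, got {self.kind!r}")
        finite = np.isfinite(self.values)
        if not np.allclose(
            self.values[finite & finite.T],
            self.values.T[finite & finite.T],
            atol=1e-9,
        ):
            raise ValueError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("dissimilarity matrix has a nonzero diagonal")
        if np.any(self.values[finite] < -1e-12):
            raise ValueError("dissimilarities must be nonnegative")
        if self.scale_max is not None and np.any(
            self.values[finite] > self.scale_max + 1e-9
        ):
            raise ValueError(f"entries exceed scale_max={self.scale_max}")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def lower_triangle(self) -> np.ndarray:
        """Strict lower-triangle entries as a condensed vector (n(n−1)/2)."""
        i, j = np.tril_indices(self.n, -1)
        return self.values[i, j]

    def reorder(self, labels) -> "ProximityMatrix":
        """Return a copy with rows/columns aligned to ``labels``."""
        if set(labels) != set(self.labels):
            raise AlignmentError("label sets differ; cannot reorder")
        idx = [self.labels.index(lab) for lab in labels]
        return ProximityMatrix(
            list(labels), self.values[np.ix_(idx, idx)], self.kind,
            self.aspect_tag, self.scale_max,
        )

    def to_csv(self, path, precision: int = 6) -> None:
        """Write as a labelled square CSV with metadata comment headers."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# kind: {self.kind}\n")
            if self.aspect_tag is not None:
                fh.write(f"# aspect: {self.aspect_tag}\n")
            if self.scale_max is not None:
                fh.write(f"# scale_max: {self.scale_max:g}\n")
            self.to_frame().to_csv(fh, float_format=f"%.{precision}f")

    @classmethod
    def from_csv(cls, path) -> "ProximityMatrix":
        meta = {}
        with open(path, encoding="utf-8") as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            frame = pd.read_csv(fh, index_col=0)
        return cls(
            labels=list(frame.index),
            values=frame.to_numpy(dtype=float),
            kind=meta.get("kind", "configuration_distance"),
            aspect_tag=meta.get("aspect"),
            scale_max=float(meta["scale_max"]) if "scale_max" in meta else None,
        )


@dataclass
class CorrelationMatrix:
    """Labelled symmetric correlation matrix with per-pair observation counts."""

    labels: list
    values: np.ndarray
    method: str
    n_pairs: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9, equal_nan=True):
            raise ValueError("correlation matrix is not symmetric")
        if np.any(np.abs(self.values[np.isfinite(self.values)]) > 1 + 1e-9):
            raise ValueError("correlation coefficients must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def profile_distance_matrix(
    summary: AspectSummaryTable, allow_any_aspect_count: bool = False
) -> ProximityMatrix:
    """Euclidean distances between the emotions' mean aspect profiles.

    For emotions with mean vectors differing by (w, x, y, z) on the four
    aspects the distance is s = √(w² + x² + y² + z²); entries lie in
    [0, 100·√k] for k aspects (200 for the canonical four).

    Raises :class:`DimensionalityError` unless the summary has exactly four
    aspects; pass ``allow_any_aspect_count=True`` for the generalised √Σ
    form with a different k.
    """
    means = summary.mean_matrix()
    k = means.shape[1]
    if k != 4 and not allow_any_aspect_count:
        raise DimensionalityError(
            f"profile distance is defined for 4 aspects, got {k}; "
            "pass allow_any_aspect_count=True for the generalised form"
        )
    if means.isna().any().any():
        raise ValueError("summary has missing means; cannot form profiles")
    dist = squareform(pdist(means.to_numpy(), metric="euclidean"))
    return ProximityMatrix(
        labels=list(means.index),
        values=dist,
        kind="profile_distance",
        scale_max=100.0 * np.sqrt(k),
    )


def _check_variances(frame: pd.DataFrame, what: str) -> None:
    nunique = frame.nunique(dropna=True)
    flat = nunique[nunique <= 1]
    if len(flat):
        raise UndefinedCoefficientError(
            f"{what} {flat.index[0]!r} has zero variance; "
            "its correlation coefficients are undefined"
        )


def aspect_correlation_matrix(
    dataset: RatingDataset, aspect: str, method: str = "spearman"
) -> CorrelationMatrix:
    """Inter-emotion correlation across participants for one fixed aspect.

    Spearman (average ranks for ties) by default; pairwise-complete
    observations; the per-pair observation count is recorded.
    """
    if aspect not in dataset.aspects:
        raise AlignmentError(f"aspect {aspect!r} not in dataset aspects {dataset.aspects}")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    frame = dataset.aspect_slice(aspect)
    _check_variances(frame, "emotion")
    present = frame.notna().to_numpy().astype(int)
    n_pairs = present.T @ present
    if np.any(n_pairs < 3):
        raise ValueError("need at least 3 complete observations per emotion pair")
    corr = frame.corr(method=method).to_numpy()
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(list(frame.columns), corr, method, n_pairs)


def correlation_to_proximity(corr: CorrelationMatrix) -> ProximityMatrix:
    """Map correlations to dissimilarities by d = 1 − r (so r=1↦0, r=0↦1, r=−1↦2)."""
    values = 1.0 - corr.values
    np.fill_diagonal(values, 0.0)
    values = np.clip(values, 0.0, 2.0)
    return ProximityMatrix(
        labels=list(corr.labels),
        values=values,
        kind="correlation_derived",
        scale_max=2.0,
    )


def build_mds_sources(
    dataset: RatingDataset, method: str = "spearman"
) -> list[ProximityMatrix]:
    """One correlation-derived proximity matrix per aspect, in aspect order.

    These are the multiple source matrices for the multi-source MDS fit; all
    share the dataset's emotion label order.
    """
    sources = []
    for aspect in dataset.aspects:
        prox = correlation_to_proximity(
            aspect_correlation_matrix(dataset, aspect, method=method)
        )
        prox.aspect_tag = aspect
        sources.append(prox)
    return sources


@dataclass
class IndependenceReport:
    """Pairwise aspect correlations with Bonferroni-adjusted p-values."""

    table: pd.DataFrame  # columns: aspect_a, aspect_b, r, p_raw, p_adjusted
    alpha: float
    unit_of_analysis: str
    method: str

    @property
    def all_independent(self) -> bool:
        """True when no pair is significant at alpha after adjustment."""
        return bool((self.table["p_adjusted"] > self.alpha).all())


def aspect_independence_test(
    dataset: RatingDataset,
    alpha: float = 0.05,
    unit: str = "pooled_observations",
    method: str = "pearson",
) -> IndependenceReport:
    """Test whether the rated aspects carry mutually independent information.

    All aspect pairs (6 for the canonical four aspects) are correlated and
    Bonferroni-corrected: adjusted p = min(1, m·p) for m pairs.

    ``unit`` selects the unit of analysis: ``pooled_observations``
    correlates the flattened participant × emotion vectors of two aspects
    (every individual judgment is a data point); ``emotion_means``
    correlates the emotions' mean profiles (one point per emotion).
    """
    if unit not in ("pooled_observations", "emotion_means"):
        raise ValueError(f"unknown unit {unit!r}")
    if unit == "pooled_observations":
        columns = {
            aspect: dataset.aspect_slice(aspect).to_numpy().ravel()
            for aspect in dataset.aspects
        }
    else:
        from .ratings import summarize

        means = summarize(dataset).mean_matrix()
        columns = {aspect: means[aspect].to_numpy() for aspect in dataset.aspects}

    frame = pd.DataFrame(columns)
    _check_variances(frame, "aspect")
    pairs = list(combinations(dataset.aspects, 2))
    rows = []
    for a, b in pairs:
        x, y = frame[a], frame[b]
        keep = x.notna() & y.notna()
        if method == "pearson":
            r, p = stats.pearsonr(x[keep], y[keep])
        else:
            r, p = stats.spearmanr(x[keep], y[keep])
        rows.append((a, b, float(r), float(p)))
    table = pd.DataFrame(rows, columns=["aspect_a", "aspect_b", "r", "p_raw"])
    # Bonferroni over the aspect pairs: adjusted p = min(1, m * p)
    table["p_adjusted"] = multipletests(table["p_raw"], method="bonferroni")[1]
    return IndependenceReport(table, alpha=alpha, unit_of_analysis=unit, method=method)
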