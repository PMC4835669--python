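"""Analysis of fitted configurations: distances, matrix correlation,
frontier emotions, central-area occupancy, 2D projections, Procrustes.

MDS output is defined only up to translation, rotation and reflection, so
configurations are compared either through their distance matrices
(:func:`matrix_correlation`) or after Procrustes alignment
(:func:`procrustes_align`); raw coordinates of two independent fits are
never compared directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import orthogonal_procrustes

from .exceptions import AlignmentError, UndefinedCoefficientError
from .mds import Configuration
from .proximity import ProximityMatrix


def configuration_distances(config: Configuration) -> ProximityMatrix:
    """Pairwise Euclidean distances between configuration points."""
    return ProximityMatrix(
        labels=list(config.labels),
        values=config.distances(),
        kind="configuration_distance",
    )


@dataclass
class MatrixCorrelationReport:
    """Correlation between the lower triangles of two dissimilarity matrices.

    ``p_value`` is the naive test treating the n(n−1)/2 pairs as
    independent observations (they are not — distance-matrix entries share
    objects); ``permutation_p`` is the Mantel-style alternative from
    simultaneous row/column permutations and is the better-calibrated
    choice when available.
    """

    r: float
    n_pairs: int
    method: str
    p_value: float
    permutation_p: Optional[float] = None
    n_permutations: int = 0
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "n_pairs": self.n_pairs,
            "method": self.method,
            "p_value": self.p_value,
            "permutation_p": self.permutation_p,
            "n_permutations": self.n_permutations,
        }


def matrix_correlation(
    A: ProximityMatrix,
    B: ProximityMatrix,
    method: str = "pearson",
    permutations: int = 0,
    seed: Optional[int] = None,
) -> MatrixCorrelationReport:
    """Correlate two labelled dissimilarity matrices over their lower triangles.

    B is aligned to A's label order first.  With ``permutations > 0`` a
    Mantel-style one-sided p-value (greater) is computed by permuting B's
    objects; the observed ordering counts toward the numerator.
    """
    if set(A.labels) != set(B.labels):
        raise AlignmentError("matrices do not share a label set")
    B = B.reorder(list(A.labels))
    a = A.lower_triangle()
    b = B.lower_triangle()
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise UndefinedCoefficientError("a matrix has a constant lower triangle")
    if method == "pearson":
        r, p = stats.pearsonr(a, b)
    elif method == "spearman":
        r, p = stats.spearmanr(a, b)
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")

    perm_p = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        n = B.n
        count = 0
        vals = B.values
        for _ in range(permutations):
            perm = rng.permutation(n)
            bp = vals[np.ix_(perm, perm)]
            i, j = np.tril_indices(n, -1)
            if method == "pearson":
                r_perm = stats.pearsonr(a, bp[i, j])[0]
            else:
                r_perm = stats.spearmanr(a, bp[i, j])[0]
            if r_perm >= r:
                count += 1
        perm_p = (count + 1) / (permutations + 1)

    return MatrixCorrelationReport(
        r=float(r), n_pairs=len(a), method=method, p_value=float(p),
        permutation_p=perm_p, n_permutations=permutations, seed=seed,
    )


@dataclass
class DimensionFrontier:
    """Extreme (frontier) emotions of one dimension, with near-extreme runners-up."""

    dimension: int  # 1-based
    positive_label: str
    positive_coordinate: float
    negative_label: str
    negative_coordinate: float
    positive_runners_up: list = field(default_factory=list)  # [(label, coord)]
    negative_runners_up: list = field(default_factory=list)
    positive_ties: list = field(default_factory=list)
    negative_ties: list = field(default_factory=list)


@dataclass
class FrontierReport:
    dimensions: list  # of DimensionFrontier
    margin: float

    def frontier(self, dimension: int) -> DimensionFrontier:
        """The frontier record for a 1-based dimension number."""
        return self.dimensions[dimension - 1]


def frontiers(config: Configuration, margin: float = 0.05) -> FrontierReport:
    """Identify the emotions bounding the space on each dimension.

    The positive/negative frontier of a dimension is its arg-max/arg-min
    coordinate (ties broken by label order and reported); runners-up within
    ``margin`` of an extreme are listed alongside it, since jointly-extreme
    emotions bound the space together.
    """
    coords = config.coordinates
    labels = list(config.labels)
    out = []
    for k in range(config.n_dimensions):
        col = coords[:, k]
        i_pos = int(np.argmax(col))
        i_neg = int(np.argmin(col))
        pos_ties = [labels[i] for i in np.flatnonzero(col == col[i_pos]) if i != i_pos]
        neg_ties = [labels[i] for i in np.flatnonzero(col == col[i_neg]) if i != i_neg]
        pos_runners = [
            (labels[i], float(col[i]))
            for i in np.argsort(-col)
            if i != i_pos and col[i_pos] - col[i] <= margin and col[i] != col[i_pos]
        ]
        neg_runners = [
            (labels[i], float(col[i]))
            for i in np.argsort(col)
            if i != i_neg and col[i] - col[i_neg] <= margin and col[i] != col[i_neg]
        ]
        out.append(
            DimensionFrontier(
                dimension=k + 1,
                positive_label=labels[i_pos],
                positive_coordinate=float(col[i_pos]),
                negative_label=labels[i_neg],
                negative_coordinate=float(col[i_neg]),
                positive_runners_up=pos_runners,
                negative_runners_up=neg_runners,
                positive_ties=pos_ties,
                negative_ties=neg_ties,
            )
        )
    return FrontierReport(out, margin=margin)


@dataclass
class CentralAreaReport:
    """Occupancy of the origin-centered ball spanning a fraction of the space."""

    occupied: bool
    closest_label: str
    min_norm: float
    max_norm: float
    radius: float
    radius_fraction: float


def central_area_check(
    config: Configuration, radius_fraction: float = 0.25
) -> CentralAreaReport:
    """Check whether any point lies in the central area of the space.

    The central area is the origin-centered ball of radius
    ``radius_fraction`` × (largest point norm).  Requires a mean-centered
    configuration (printed 3-decimal coordinates count as centered).
    """
    if not config.is_centered(atol=1e-2):
        raise ValueError("configuration is not mean-centered; call .center() first")
    norms = np.linalg.norm(config.coordinates, axis=1)
    radius = radius_fraction * float(norms.max())
    i_min = int(np.argmin(norms))
    return CentralAreaReport(
        occupied=bool(norms[i_min] < radius) or (radius == 0.0 and norms[i_min] == 0.0),
        closest_label=config.labels[i_min],
        min_norm=float(norms[i_min]),
        max_norm=float(norms.max()),
        radius=radius,
        radius_fraction=radius_fraction,
    )


def project_2d(config: Configuration, dims: tuple[int, int]) -> Configuration:
    """Select two dimensions of a configuration as a 2D view (no re-fitting).

    ``dims`` uses 1-based dimension numbers (Dimension 1 is the first
    column).  Projections are views of the same space, not new solutions.
    """
    d1, d2 = dims
    if d1 == d2:
        raise IndexError("projection dimensions must be distinct")
    for d in (d1, d2):
        if not (1 <= d <= config.n_dimensions):
            raise IndexError(
                f"dimension {d} out of range 1..{config.n_dimensions}"
            )
    coords = config.coordinates[:, [d1 - 1, d2 - 1]]
    return Configuration(list(config.labels), coords, centered=config.centered,
                         center_atol=config.center_atol)


def procrustes_align(
    A: Configuration, B: Configuration, allow_scaling: bool = True
) -> tuple[Configuration, float]:
    """Optimally align B to A by translation + orthogonal transform (+ scale).

    Returns the aligned copy of B (in A's frame) and the disparity: the
    minimized sum of squared coordinate differences divided by the centered
    sum of squares of A.  With scaling allowed the disparity lies in [0, 1].
    """
    if list(A.labels) != list(B.labels):
        raise AlignmentError("configurations do not share an identical label order")
    if A.n_dimensions != B.n_dimensions:
        raise AlignmentError("configurations differ in dimensionality")
    Ac = A.coordinates - A.coordinates.mean(axis=0, keepdims=True)
    Bc = B.coordinates - B.coordinates.mean(axis=0, keepdims=True)
    ssA = float(np.sum(Ac ** 2))
    ssB = float(np.sum(Bc ** 2))
    if ssA == 0.0 or ssB == 0.0:
        raise ValueError("degenerate configuration (all points coincident)")
    R, s = orthogonal_procrustes(Bc, Ac)  # minimises ||Bc R - Ac||
    scale = s / ssB if allow_scaling else 1.0
    aligned = scale * Bc @ R + A.coordinates.mean(axis=0, keepdims=True)
    disparity = float(np.sum((Ac - scale * Bc @ R) ** 2) / ssA)
    return (
        Configuration(list(B.labels), aligned, centered=A.is_centered(1e-9)),
        disparity,
    )
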