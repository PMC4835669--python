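"""Multi-source metric MDS by stress majorization (SMACOF).

Given K dissimilarity matrices δ⁽ᵏ⁾ over the same n objects (here: one
correlation-derived proximity matrix per rated aspect), the engine finds a
single common configuration X ∈ ℝ^{n×p} minimising the **normalized raw
stress**

    σ(X) = Σₖ Σ_{i<j} w⁽ᵏ⁾ᵢⱼ (δ⁽ᵏ⁾ᵢⱼ − dᵢⱼ(X))²  /  Σₖ Σ_{i<j} w⁽ᵏ⁾ᵢⱼ (δ⁽ᵏ⁾ᵢⱼ)² ,

where dᵢⱼ(X) is the Euclidean distance between rows i and j.  This is the
identity (common-space, unweighted-by-source) model: every source is fitted
by the same configuration.  The complementary goodness measure is the
total fit = 1 − σ.

Minimisation uses the Guttman transform.  Because the per-pair quadratic
terms add across sources, the pooled problem is equivalent to a weighted
single-matrix SMACOF on the effective dissimilarity
δ̄ᵢⱼ = Σₖ wᵢⱼₖ δᵢⱼₖ / Σₖ wᵢⱼₖ with pair weight Σₖ wᵢⱼₖ; each iteration
solves the quadratic majorizer exactly, so stress never increases.
Solutions are identified only up to translation, rotation and reflection;
fitted configurations are mean-centered, and comparisons should go through
Procrustes alignment or distance matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state

from .exceptions import AlignmentError, DegenerateInputError
from .proximity import ProximityMatrix


# ---------------------------------------------------------------------------
# configuration container

@dataclass
class Configuration:
    """Objects × dimensions coordinate matrix (dimensionless MDS space)."""

    labels: list
    coordinates: np.ndarray
    centered: bool = False
    #: tolerance for the centering invariant; coordinates printed at 3
    #: decimals are centered only to ~1e-3, engine output to machine precision
    center_atol: float = 1e-9

    def __post_init__(self):
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        if self.coordinates.shape[0] != len(self.labels):
            raise ValueError("row count does not match label count")
        if self.coordinates.shape[1] < 1:
            raise ValueError("configuration needs at least one dimension")
        if self.centered and not self.is_centered(self.center_atol):
            raise ValueError(
                f"declared centered but column means exceed {self.center_atol}"
            )

    @property
    def n_objects(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_dimensions(self) -> int:
        return self.coordinates.shape[1]

    def is_centered(self, atol: float = 1e-9) -> bool:
        scale = max(1.0, float(np.abs(self.coordinates).max(initial=0.0)))
        return bool(np.all(np.abs(self.coordinates.mean(axis=0)) <= atol * scale))

    def center(self) -> "Configuration":
        coords = self.coordinates - self.coordinates.mean(axis=0, keepdims=True)
        return Configuration(list(self.labels), coords, centered=True)

    def distances(self) -> np.ndarray:
        return squareform(pdist(self.coordinates))

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{k + 1}" for k in range(self.n_dimensions)]
        frame = pd.DataFrame(self.coordinates, columns=cols)
        frame.insert(0, "emotion", self.labels)
        return frame

    def to_csv(self, path, precision: Optional[int] = 3) -> None:
        """Write as CSV; default 3-decimal formatting, None for full precision."""
        fmt = None if precision is None else f"%.{precision}f"
        self.to_frame().to_csv(path, index=False, float_format=fmt)

    @classmethod
    def from_csv(cls, path, centered: bool = False,
                 center_atol: float = 1e-2) -> "Configuration":
        frame = pd.read_csv(path)
        labels = list(frame.iloc[:, 0])
        coords = frame.iloc[:, 1:].to_numpy(dtype=float)
        return cls(labels, coords, centered=centered, center_atol=center_atol)


# ---------------------------------------------------------------------------
# stress

def _coerce_sources(
    sources: Sequence[Union[ProximityMatrix, np.ndarray]],
) -> tuple[list, np.ndarray]:
    """Validate a list of sources and stack them as (K, n, n) with shared labels."""
    if len(sources) == 0:
        raise ValueError("at least one dissimilarity source is required")
    mats, labels = [], None
    for src in sources:
        if isinstance(src, ProximityMatrix):
            if labels is None:
                labels = list(src.labels)
            elif list(src.labels) != labels:
                raise AlignmentError("sources do not share an identical label order")
            mats.append(src.values)
        else:
            arr = np.asarray(src, dtype=float)
            if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
                raise ValueError("array sources must be square matrices")
            if labels is None:
                labels = list(range(arr.shape[0]))
            elif arr.shape[0] != len(labels):
                raise AlignmentError("sources differ in size")
            mats.append(arr)
    return labels, np.stack(mats)


def normalized_raw_stress(
    sources: Sequence[Union[ProximityMatrix, np.ndarray]],
    config: Configuration,
    weights: Optional[np.ndarray] = None,
) -> float:
    """Normalized raw stress of a configuration against one or more sources.

    σ = Σₖ Σ_{i<j} wᵢⱼₖ (δᵢⱼₖ − dᵢⱼ)² / Σₖ Σ_{i<j} wᵢⱼₖ δᵢⱼₖ².  Missing
    dissimilarities (NaN) get weight 0.  For any configuration no worse
    than the all-coincident one this lies in [0, 1]; it is 0 iff every
    weighted distance equals its dissimilarity.
    """
    labels, delta = _coerce_sources(sources)
    if isinstance(sources[0], ProximityMatrix) and list(config.labels) != labels:
        raise AlignmentError("configuration labels do not match source labels")
    if config.n_objects != delta.shape[1]:
        raise AlignmentError("configuration size does not match sources")
    w = _effective_weights(delta, weights)
    d = config.distances()[None, :, :]
    iu = np.triu_indices(delta.shape[1], 1)
    num = float(np.nansum((w * (np.nan_to_num(delta) - d) ** 2)[:, iu[0], iu[1]]))
    den = float(np.nansum((w * np.nan_to_num(delta) ** 2)[:, iu[0], iu[1]]))
    if den <= 0.0:
        raise DegenerateInputError("all dissimilarities are zero or missing")
    return num / den


def _effective_weights(delta: np.ndarray, weights: Optional[np.ndarray]) -> np.ndarray:
    if weights is None:
        w = np.ones_like(delta)
    else:
        w = np.broadcast_to(np.asarray(weights, dtype=float), delta.shape).copy()
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
    w = np.where(np.isnan(delta), 0.0, w)
    return w


# ---------------------------------------------------------------------------
# initial configurations

def _mean_source(delta: np.ndarray, w: np.ndarray) -> np.ndarray:
    wsum = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(wsum > 0, (w * np.nan_to_num(delta)).sum(axis=0) / wsum, 0.0)
    np.fill_diagonal(mean, 0.0)
    return mean


def classical_scaling(dissimilarity: np.ndarray, p: int) -> np.ndarray:
    """Torgerson double-centering eigendecomposition (classical MDS)."""
    n = dissimilarity.shape[0]
    if p >= n:
        raise ValueError(f"classical scaling needs p < n_objects, got p={p}, n={n}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dissimilarity ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:p]
    lam = np.clip(eigval[order], 0.0, None)
    X = eigvec[:, order] * np.sqrt(lam)
    return X - X.mean(axis=0, keepdims=True)


def simplex_configuration(n_objects: int, p: int) -> np.ndarray:
    """Regular-simplex vertices projected onto p dimensions and centered.

    For p = n−1 all pairwise distances are equal (the exact regular simplex);
    smaller p takes the first p principal axes of the centered simplex.
    """
    E = np.eye(n_objects) - np.ones((n_objects, n_objects)) / n_objects
    # E is the centered simplex Gram/coordinate matrix; its left singular
    # vectors span the simplex hyperplane
    U, s, _ = np.linalg.svd(E)
    X = U[:, :p] * s[:p]
    return X - X.mean(axis=0, keepdims=True)


def init_configuration(
    n_objects: int,
    p: int,
    method: str = "classical",
    sources: Optional[Sequence] = None,
    seed: Optional[int] = None,
) -> Configuration:
    """Build a starting configuration: classical (Torgerson), simplex or random."""
    labels: list = list(range(n_objects))
    if method == "classical":
        if sources is None:
            raise ValueError("classical initialisation needs the sources")
        labels, delta = _coerce_sources(sources)
        w = _effective_weights(delta, None)
        X = classical_scaling(_mean_source(delta, w), p)
    elif method == "simplex":
        X = simplex_configuration(n_objects, p)
        if sources is not None:
            labels = _coerce_sources(sources)[0]
    elif method == "random":
        if seed is None:
            raise ValueError("random initialisation requires a seed")
        rng = check_random_state(seed)
        X = rng.standard_normal((n_objects, p))
        X -= X.mean(axis=0, keepdims=True)
        if sources is not None:
            labels = _coerce_sources(sources)[0]
    else:
        raise ValueError(f"unknown init method {method!r}")
    return Configuration(labels, X, centered=True)


# ---------------------------------------------------------------------------
# results

class TrajectoryStep(NamedTuple):
    iteration: int
    stress: float
    improvement: float


@dataclass
class MDSResult:
    """Fitted configuration with stress, fit and the iteration trajectory."""

    configuration: Configuration
    stress: float
    trajectory: list
    converged: bool
    n_iterations: int
    settings: dict = field(default_factory=dict)

    @property
    def fit(self) -> float:
        """Total fit = 1 − normalized raw stress."""
        return 1.0 - self.stress

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trajectory, columns=["iteration", "stress", "improvement"])


def total_fit(stress: float) -> float:
    """Total fit = 1 − stress; the complement of normalized raw stress."""
    if not (0.0 <= stress <= 1.0):
        raise ValueError(f"stress must lie in [0, 1], got {stress}")
    return 1.0 - stress


_KRUSKAL_BINS = (
    (0.025, "excellent"),
    (0.05, "good"),
    (0.1, "fair"),
    (0.2, "poor"),
)


def kruskal_label(stress: float) -> str:
    """Qualitative stress label: 0 perfect, ≤0.025 excellent, ≤0.05 good,
    ≤0.1 fair, ≤0.2 poor, above that unacceptable."""
    if stress < 0:
        raise ValueError(f"stress must be nonnegative, got {stress}")
    if stress == 0.0:
        return "perfect"
    for upper, label in _KRUSKAL_BINS:
        if stress <= upper:
            return label
    return "unacceptable"


# ---------------------------------------------------------------------------
# the estimator

class MultiSourceMDS(BaseEstimator):
    """Metric MDS over multiple dissimilarity sources, SMACOF majorization.

    Fits one common configuration to K dissimilarity matrices by minimising
    pooled normalized raw stress (identity model: no per-source weights or
    transformations).  Follows the scikit-learn estimator protocol:
    ``fit(X)`` with X a list of :class:`ProximityMatrix`/arrays (or a
    single matrix), then read ``embedding_``, ``stress_``, ``fit_``.

    Parameters
    ----------
    n_components : int
        Target dimensionality p.
    init : {"classical", "simplex", "random"} or Configuration or ndarray
        Starting configuration.  Classical (Torgerson scaling of the mean
        source) is the default; "simplex" starts from regular-simplex
        vertices; "random" draws seeded normal coordinates.
    tol : float
        Minimum stress improvement; iteration stops when an update improves
        stress by less than this.
    max_iter : int
        Iteration cap.
    n_restarts : int
        Additional seeded random starts; the lowest-stress solution is kept
        (guards against local minima).
    random_state : int, RandomState or None
        Seed for random initialisation and restarts.

    Attributes
    ----------
    embedding_ : ndarray of shape (n_objects, n_components)
        Mean-centered final coordinates.
    labels_ : list
        Object labels shared by the sources.
    stress_ : float
        Final normalized raw stress.
    fit_ : float
        Total fit = 1 − stress_.
    trajectory_ : list of (iteration, stress, improvement)
        Stress at the initial configuration (iteration 0) and after each
        Guttman update; improvements are nonnegative up to rounding.
    converged_ : bool
    n_iter_ : int
    """

    def __init__(
        self,
        n_components: int = 3,
        init: Union[str, Configuration, np.ndarray] = "classical",
        tol: float = 1e-4,
        max_iter: int = 1000,
        n_restarts: int = 0,
        random_state=None,
    ):
        self.n_components = n_components
        self.init = init
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- internals ----------------------------------------------------------

    def _initial(self, labels, delta, w, seed) -> np.ndarray:
        if isinstance(self.init, Configuration):
            if list(self.init.labels) != list(labels) and not all(
                isinstance(l, int) for l in self.init.labels
            ):
                raise AlignmentError("explicit init labels do not match sources")
            X0 = np.array(self.init.coordinates, dtype=float)
        elif isinstance(self.init, np.ndarray):
            X0 = np.array(self.init, dtype=float)
        elif self.init == "classical":
            X0 = classical_scaling(_mean_source(delta, w), self.n_components)
        elif self.init == "simplex":
            X0 = simplex_configuration(delta.shape[1], self.n_components)
        elif self.init == "random":
            rng = check_random_state(seed)
            X0 = rng.standard_normal((delta.shape[1], self.n_components))
        else:
            raise ValueError(f"unknown init {self.init!r}")
        if X0.shape != (delta.shape[1], self.n_components):
            raise ValueError(
                f"initial configuration shape {X0.shape} != "
                f"({delta.shape[1]}, {self.n_components})"
            )
        return X0 - X0.mean(axis=0, keepdims=True)

    @staticmethod
    def _majorize(delta_eff, w_eff, Vpinv, denom, X0, tol, max_iter):
        """Weighted SMACOF loop on the effective single-matrix problem."""
        n = delta_eff.shape[0]
        iu = np.triu_indices(n, 1)

        def stress_of(X):
            d = squareform(pdist(X))
            return float(np.sum(w_eff[iu] * (delta_eff[iu] - d[iu]) ** 2)) / denom

        X = X0
        sigma = stress_of(X)
        trajectory = [TrajectoryStep(0, sigma, np.nan)]
        converged = False
        for it in range(1, max_iter + 1):
            d = squareform(pdist(X))
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, delta_eff / np.where(d > 0, d, 1.0), 0.0)
            Bmat = -w_eff * ratio
            np.fill_diagonal(Bmat, 0.0)
            np.fill_diagonal(Bmat, -Bmat.sum(axis=1))
            X_new = Vpinv @ (Bmat @ X)
            X_new -= X_new.mean(axis=0, keepdims=True)
            if not np.all(np.isfinite(X_new)):
                raise FloatingPointError(
                    f"non-finite coordinates at iteration {it}"
                )
            sigma_new = stress_of(X_new)
            improvement = sigma - sigma_new
            X, sigma = X_new, sigma_new
            trajectory.append(TrajectoryStep(it, sigma_new, improvement))
            if improvement < tol:
                converged = True
                break
        return X, sigma, trajectory, converged

    # -- API ----------------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the common configuration to the dissimilarity sources in X."""
        sources = [X] if isinstance(X, (ProximityMatrix, np.ndarray)) else list(X)
        labels, delta = _coerce_sources(sources)
        n = delta.shape[1]
        if n < 3:
            raise ValueError("need at least 3 objects")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")

        w = _effective_weights(delta, None)
        iu = np.triu_indices(n, 1)
        denom = float(np.sum((w * np.nan_to_num(delta) ** 2)[:, iu[0], iu[1]]))
        if denom <= 0:
            raise DegenerateInputError("all dissimilarities are zero or missing")

        # pooled problem -> weighted single-matrix problem
        w_eff = w.sum(axis=0)
        delta_eff = _mean_source(delta, w)

        V = np.diag(w_eff.sum(axis=1)) - w_eff
        Vpinv = np.linalg.pinv(V)

        rng = check_random_state(self.random_state)
        starts: list[tuple[np.ndarray, object]] = []
        base_seed = rng.randint(0, 2**31 - 1)
        starts.append(self._initial(labels, delta, w, base_seed))
        for _ in range(self.n_restarts):
            r = check_random_state(rng.randint(0, 2**31 - 1))
            X0 = r.standard_normal((n, self.n_components))
            starts.append(X0 - X0.mean(axis=0, keepdims=True))

        best = None
        for X0 in starts:
            Xf, sigma, trajectory, converged = self._majorize(
                delta_eff, w_eff, Vpinv, denom, X0, self.tol, self.max_iter
            )
            if best is None or sigma < best[1]:
                best = (Xf, sigma, trajectory, converged)

        Xf, sigma, trajectory, converged = best
        self.labels_ = labels
        self.embedding_ = Xf - Xf.mean(axis=0, keepdims=True)
        self.stress_ = sigma
        self.fit_ = 1.0 - sigma
        self.trajectory_ = trajectory
        self.converged_ = converged
        self.n_iter_ = trajectory[-1].iteration
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).embedding_

    def result_(self) -> MDSResult:
        """Package the fitted attributes as an :class:`MDSResult`."""
        if not hasattr(self, "embedding_"):
            raise AttributeError("estimator is not fitted")
        return MDSResult(
            configuration=Configuration(list(self.labels_), self.embedding_, centered=True),
            stress=self.stress_,
            trajectory=list(self.trajectory_),
            converged=self.converged_,
            n_iterations=self.n_iter_,
            settings=self.get_params(),
        )


def smacof_multi(
    sources,
    p: int = 3,
    init: Union[str, Configuration, np.ndarray] = "classical",
    tol: float = 1e-4,
    max_iter: int = 1000,
    n_restarts: int = 0,
    seed=None,
) -> MDSResult:
    """Functional wrapper around :class:`MultiSourceMDS`.

    Returns the full :class:`MDSResult` (centered configuration, stress,
    trajectory, convergence flag).  Deterministic given init and seed.
    """
    est = MultiSourceMDS(
        n_components=p, init=init, tol=tol, max_iter=max_iter,
        n_restarts=n_restarts, random_state=seed,
    )
    est.fit(sources)
    return est.result_()


# ---------------------------------------------------------------------------
# dimensionality sweep

@dataclass
class ScreeTable:
    """Stress/fit per candidate dimensionality with marginal fit gains."""

    table: pd.DataFrame  # columns: p, stress, fit, gain

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6f")


def scree(
    sources,
    p_range=range(1, 13),
    init: str = "classical",
    tol: float = 1e-4,
    max_iter: int = 1000,
    n_restarts: int = 0,
    seed=None,
    warm_start: bool = False,
) -> ScreeTable:
    """Fit the sources at each dimensionality in ``p_range``.

    Each p gets an independent fit by default; with ``warm_start=True``
    each p ≥ min(p_range)+1 starts from the previous solution padded with a
    zero column, which makes fit non-decreasing in p.
    """
    p_list = sorted(set(int(p) for p in p_range))
    if not p_list:
        raise ValueError("empty dimensionality range")
    labels, delta = _coerce_sources(
        [sources] if isinstance(sources, (ProximityMatrix, np.ndarray)) else list(sources)
    )
    if max(p_list) >= delta.shape[1]:
        raise ValueError("max dimensionality must be below the object count")
    rows = []
    prev_fit = None
    prev_result = None
    for p in p_list:
        use_init: Union[str, np.ndarray] = init
        if warm_start and prev_result is not None:
            prev_coords = prev_result.configuration.coordinates
            pad = np.zeros((prev_coords.shape[0], p - prev_coords.shape[1]))
            use_init = np.hstack([prev_coords, pad])
        result = smacof_multi(
            sources, p=p, init=use_init, tol=tol, max_iter=max_iter,
            n_restarts=n_restarts, seed=seed,
        )
        gain = np.nan if prev_fit is None else result.fit - prev_fit
        rows.append((p, result.stress, result.fit, gain))
        prev_fit, prev_result = result.fit, result
    return ScreeTable(pd.DataFrame(rows, columns=["p", "stress", "fit", "gain"]))


class SelectedDimensionality(NamedTuple):
    p: int
    #: True when selection fell back to the largest p because no marginal
    #: gain dropped below the threshold
    saturated_range: bool


def select_dimensionality(
    scree_table: ScreeTable, gain_threshold: float = 0.01
) -> SelectedDimensionality:
    """Pick the smallest p whose successor adds less than ``gain_threshold`` fit.

    Falls back to the largest p (flagged) when every gain exceeds the
    threshold; the scree must cover a contiguous p range.
    """
    table = scree_table.table
    if table.empty:
        raise ValueError("empty scree table")
    ps = list(table["p"])
    if ps != list(range(ps[0], ps[-1] + 1)):
        raise ValueError("scree table must cover a contiguous p range")
    for i in range(len(ps) - 1):
        if table["gain"].iloc[i + 1] < gain_threshold:
            return SelectedDimensionality(int(ps[i]), False)
    warnings.warn(
        "every marginal fit gain exceeds the threshold; returning the largest p",
        stacklevel=2,
    )
    return SelectedDimensionality(int(ps[-1]), True)
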