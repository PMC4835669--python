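"""Synthetic rating and proximity generation with known ground truth.

The study's per-participant ratings were never released, so the pipeline is
exercised on synthetic stand-ins:

* :func:`simulate_ratings` draws a participant × emotion × aspect tensor
  whose cell means and SDs match a target table (by default the published
  summary moments, 187 participants), using exact truncated-normal
  sampling on [0, 100] so no probability mass piles up at the line ends.
  Optionally a low-dimensional latent geometry is *planted*: participant
  scores then share latent factors so that the inter-emotion correlation
  pattern within each aspect mirrors the latent distances
  (target r = 1 − distance/max distance, the inverse of the d = 1 − r
  proximity transform), which lets recovery of a known configuration be
  tested end to end.

* :func:`simulate_sources` perturbs the exact distance matrix of a known
  configuration with multiplicative noise to produce multi-source MDS
  inputs with a planted ground truth.

All draws are seeded; the same spec and seed reproduce the same tensor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from scipy.optimize import brentq

from .exceptions import FeasibilityError
from .mds import Configuration
from .proximity import ProximityMatrix
from .ratings import RatingDataset


@dataclass
class PlantedStructure:
    """Latent geometry planted into synthetic ratings.

    ``configuration`` places the emotions in a latent space; the generator
    targets inter-emotion correlations r_ij = clip(1 − d_ij / max d, −1, 1)
    within every aspect, realised by drawing participant scores from a
    shared-factor (multivariate normal) model with that correlation
    matrix (projected to the nearest positive semi-definite matrix).
    """

    configuration: Configuration

    def target_correlations(self) -> np.ndarray:
        d = self.configuration.distances()
        dmax = d.max()
        if dmax == 0:
            raise FeasibilityError("latent configuration has all points coincident")
        r = np.clip(1.0 - d / dmax, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        return r


@dataclass
class GeneratorSpec:
    """Specification of a synthetic rating dataset.

    ``means`` and ``sds`` are emotion × aspect DataFrames on the 0–100 mm
    scale; ``seed`` is mandatory whenever any draw is stochastic.
    """

    emotions: list
    aspects: list
    means: pd.DataFrame  # emotions × aspects
    sds: pd.DataFrame
    n_participants: int = 187
    planted: Optional[PlantedStructure] = None
    seed: Optional[int] = None

    def __post_init__(self):
        self.means = self.means.loc[self.emotions, self.aspects].astype(float)
        self.sds = self.sds.loc[self.emotions, self.aspects].astype(float)
        if ((self.means < 0) | (self.means > 100)).any().any():
            raise ValueError("target means must lie in [0, 100]")
        if (self.sds < 0).any().any():
            raise ValueError("target SDs must be nonnegative")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        stochastic = (self.sds.to_numpy() > 0).any() or self.planted is not None
        if stochastic and self.seed is None:
            raise ValueError("a seed is required for stochastic simulation")

    @classmethod
    def from_summary(cls, summary, n_participants: int = 187,
                     planted: Optional[PlantedStructure] = None,
                     seed: Optional[int] = None) -> "GeneratorSpec":
        """Build a spec targeting the moments of an AspectSummaryTable."""
        return cls(
            emotions=summary.emotions,
            aspects=summary.aspects,
            means=summary.mean_matrix(),
            sds=summary.sd_matrix(),
            n_participants=n_participants,
            planted=planted,
            seed=seed,
        )

    @classmethod
    def reference(cls, n_participants: int = 187,
                  planted: Optional[PlantedStructure] = None,
                  seed: Optional[int] = None) -> "GeneratorSpec":
        """Spec targeting the published study moments (16 emotions, 187 raters)."""
        from .reference import load_reference_summary

        return cls.from_summary(
            load_reference_summary(), n_participants=n_participants,
            planted=planted, seed=seed,
        )


def _calibrated_loc(mean: float, sd: float, emotion, aspect) -> float:
    """Location μ such that a N(μ, sd²) truncated to [0, 100] has the target mean.

    Truncation pulls the mean of a boundary-near cell toward the interior;
    shifting the untruncated location outward compensates, so realised cell
    means are unbiased.  (Realised SDs are not compensated: the truncated
    SD is at most the underlying one, a documented shrinkage that grows
    toward the line ends and is unavoidable for targets near the
    theoretical SD bound of a [0, 100] variable.)

    Raises :class:`FeasibilityError` when no location works: the truncated
    mean lies strictly inside (0, 100), so boundary target means with
    positive SD cannot be realised, nor can targets needing a shift so far
    out that essentially no mass (rejection acceptance < 1e-4 in the
    equivalent rejection sampler) remains on the line.
    """

    def truncated_mean(loc):
        a, b = (0.0 - loc) / sd, (100.0 - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    # beyond ~3.7 sd of outward shift the acceptance rate drops below 1e-4
    max_shift = 3.7 * sd
    lo, hi = -max_shift, 100.0 + max_shift
    if not (0.0 < mean < 100.0) or truncated_mean(lo) > 0.0 or truncated_mean(hi) < 0.0:
        raise FeasibilityError(
            f"cell ({emotion!r}, {aspect!r}): target mean {mean} with SD {sd} "
            "cannot be realised by a truncated normal on [0, 100]"
        )
    return float(brentq(truncated_mean, lo, hi, xtol=1e-10))


def _nearest_correlation_factor(R: np.ndarray) -> np.ndarray:
    """Factor L with L Lᵀ ≈ R after clipping negative eigenvalues."""
    eigval, eigvec = np.linalg.eigh((R + R.T) / 2)
    eigval = np.clip(eigval, 1e-10, None)
    L = eigvec * np.sqrt(eigval)
    # renormalise so the implied variances are exactly 1
    norms = np.linalg.norm(L, axis=1, keepdims=True)
    return L / norms


def simulate_ratings(spec: GeneratorSpec) -> RatingDataset:
    """Draw a rating tensor matching the spec's cell moments.

    Without planted structure every cell is an independent truncated
    normal on [0, 100]: exact inverse-CDF sampling (no boundary point
    masses), with the underlying location calibrated per cell so the
    truncated mean equals the target mean.  Realised SDs are shrunk by the
    truncation for boundary-near cells (see :func:`_calibrated_loc`).
    With planted structure, participant scores within each aspect are
    drawn jointly from the shared-factor model and participants whose row
    leaves [0, 100] are redrawn.
    """
    rng = np.random.default_rng(spec.seed)
    n_p = spec.n_participants
    n_e, n_a = len(spec.emotions), len(spec.aspects)
    means = spec.means.to_numpy()
    sds = spec.sds.to_numpy()
    locs = np.array(
        [
            [
                means[j, k]
                if sds[j, k] == 0.0
                else _calibrated_loc(means[j, k], sds[j, k],
                                     spec.emotions[j], spec.aspects[k])
                for k in range(n_a)
            ]
            for j in range(n_e)
        ]
    )

    values = np.empty((n_p, n_e, n_a))
    if spec.planted is None:
        for j in range(n_e):
            for k in range(n_a):
                loc, s = locs[j, k], sds[j, k]
                if s == 0.0:
                    values[:, j, k] = loc
                else:
                    a, b = (0.0 - loc) / s, (100.0 - loc) / s
                    values[:, j, k] = stats.truncnorm.rvs(
                        a, b, loc=loc, scale=s, size=n_p, random_state=rng
                    )
    else:
        L = _nearest_correlation_factor(spec.planted.target_correlations())
        max_redraws = 1000
        for k in range(n_a):
            loc, s = locs[:, k], sds[:, k]
            filled = np.zeros(n_p, dtype=bool)
            for _ in range(max_redraws):
                todo = np.flatnonzero(~filled)
                if todo.size == 0:
                    break
                z = rng.standard_normal((todo.size, n_e)) @ L.T
                draw = loc[None, :] + s[None, :] * z
                ok = np.all((draw >= 0.0) & (draw <= 100.0), axis=1)
                values[todo[ok], :, k] = draw[ok]
                filled[todo[ok]] = True
            else:
                raise FeasibilityError(
                    f"aspect {spec.aspects[k]!r}: could not draw in-range "
                    "participant rows; reduce the SDs or move means inward"
                )

    participants = [f"p{i + 1:03d}" for i in range(n_p)]
    return RatingDataset(participants, list(spec.emotions), list(spec.aspects), values)


def simulate_sources(
    config: Configuration,
    n_sources: int = 4,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> list[ProximityMatrix]:
    """Noisy copies of a configuration's distance matrix as MDS sources.

    Each source is D ∘ (1 + ε) with ε ~ N(0, noise_sd²) drawn independently
    per pair and per source (symmetric by construction, zero diagonal,
    clipped at 0 so entries stay nonnegative).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required when noise_sd > 0")
    rng = np.random.default_rng(seed)
    d = pdist(config.coordinates)
    sources = []
    for k in range(n_sources):
        noisy = d * (1.0 + noise_sd * rng.standard_normal(d.shape)) if noise_sd > 0 else d
        noisy = np.clip(noisy, 0.0, None)
        sources.append(
            ProximityMatrix(
                labels=list(config.labels),
                values=squareform(noisy),
                kind="configuration_distance",
                aspect_tag=f"source{k + 1}",
            )
        )
    return sources
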