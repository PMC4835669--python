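"""Packaged reference tables for the 16-emotion judgment study.

The package ships the published summary statistics of a study in which 187
raters judged 16 emotion words (anger … jealousy) on four aspects rated as
marks on 10 cm lines (0–100 mm):

* ``load_reference_summary`` — per emotion × aspect mean and SD;
* ``load_reference_profile_distances`` — the published 4-aspect
  mean-profile distance matrix (0–200 scale);
* ``load_reference_configuration`` — the published mean-centered 3D MDS
  configuration of the 16 emotions;
* ``load_reference_model_distances`` — the published distance matrix of
  that 3D configuration.

The raw per-participant ratings behind these tables were never released;
the synthetic generator (:mod:`emospace.simulate`) emulates them from the
summary moments.  Note that the published profile-distance entries
involving *envy* are not consistent with the published summary means
(recomputation differs by up to ~22 on the 0–200 scale; e.g. love–envy
prints 114.2 but recomputes to ≈97.1), and three published SDs (envy
arousal 49.3, contempt arousal 43.8, happiness control 62.2) are
implausibly large relative to their neighbours — probable transcription
issues in the source tables, reproduced here verbatim and not "corrected".
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .mds import Configuration
from .proximity import ProximityMatrix
from .ratings import AspectSummaryTable

#: The 16 emotion words in canonical (published) order.
EMOTIONS: tuple[str, ...] = (
    "anger", "fear", "sadness", "happiness", "disgust", "hope", "love",
    "hate", "contempt", "guilt", "compassion", "shame", "gratefulness",
    "envy", "disappointment", "jealousy",
)

#: The four rated aspects in canonical order.
ASPECTS: tuple[str, ...] = ("valence", "arousal", "control", "utility")


def _data_path(name: str):
    return resources.files("emospace").joinpath("data", name)


def load_reference_summary() -> AspectSummaryTable:
    """Published per-cell mean/SD summary (n = 187 raters per cell)."""
    with resources.as_file(_data_path("reference_summary.csv")) as path:
        return AspectSummaryTable(pd.read_csv(path))


def load_reference_configuration() -> Configuration:
    """Published mean-centered 3D configuration of the 16 emotions.

    Coordinates are printed at 3 decimals, so column means vanish only to
    ~1e-4; the centering tolerance is relaxed accordingly.
    """
    with resources.as_file(_data_path("reference_configuration.csv")) as path:
        frame = pd.read_csv(path)
    return Configuration(
        labels=list(frame["emotion"]),
        coordinates=frame[["dim1", "dim2", "dim3"]].to_numpy(),
        centered=True,
        center_atol=1e-2,
    )


def _load_matrix(name: str, kind: str, scale_max=None) -> ProximityMatrix:
    with resources.as_file(_data_path(name)) as path:
        frame = pd.read_csv(path, index_col=0)
    return ProximityMatrix(
        labels=list(frame.index),
        values=frame.to_numpy(dtype=float),
        kind=kind,
        scale_max=scale_max,
    )


def load_reference_profile_distances() -> ProximityMatrix:
    """Published 4-aspect mean-profile distance matrix (0–200 scale)."""
    return _load_matrix(
        "reference_profile_distances.csv", "profile_distance", scale_max=200.0
    )


def load_reference_model_distances() -> ProximityMatrix:
    """Published distance matrix of the 3D MDS configuration."""
    return _load_matrix("reference_model_distances.csv", "configuration_distance")
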