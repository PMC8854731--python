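"""Correntropy covariance features.

Each joint contributes three univariate coordinate time series
(joint-major, axis order mediolateral / anteroposterior / vertical),
giving D = 3 x joints dimensions.  The pairwise kernel similarity

    K(x_i, x_j) = exp(-||x_i - x_j||_2^2 / (2 sigma^2 T^2))

with T the series length in frames is computed for every dimension
pair; the strictly lower triangle of the symmetric D x D matrix,
enumerated row-major, is the decoding feature vector (1770 elements
for 20 joints).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .kinematics import AXIS_NAMES, JointRecording

__all__ = [
    "DEFAULT_SIGMA",
    "CorrentropyMatrix",
    "FeatureVector",
    "correntropy",
    "correntropy_matrix",
    "vectorize_lower",
    "feature_pair_index",
    "features_to_frame",
    "frame_to_feature_matrix",
]

DEFAULT_SIGMA = 12.0


def correntropy(x, y, sigma: float = DEFAULT_SIGMA) -> float:
    """Gaussian-kernel similarity of two equal-length series, in (0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError(f"need equal-length 1-D series, got {x.shape} and {y.shape}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite input")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    T = x.size
    d2 = float(np.sum((x - y) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2 * T**2)))


@dataclass
class CorrentropyMatrix:
    K: np.ndarray  # (D, D)
    sigma: float
    T: int  # series length in frames
    dim_labels: list[tuple[str, str]]  # (joint, axis), joint-major
    source_kind: str  # position | velocity
    participant_id: str = ""
    stimulus_id: str = ""

    @property
    def D(self) -> int:
        return self.K.shape[0]


def correntropy_matrix(jrec: JointRecording, sigma: float = DEFAULT_SIGMA) -> CorrentropyMatrix:
    """Pairwise correntropy over all 3J coordinate dimensions."""
    if jrec.coordinate_frame != "local":
        raise ValueError("features are defined on local-coordinate data")
    if jrec.n_joints < 2:
        raise ValueError("need at least 2 joints")
    if jrec.n_frames < 1:
        raise ValueError("empty recording")
    T = jrec.n_frames
    # (D, T) with D = 3J, joint-major dimension order
    series = jrec.values.transpose(1, 2, 0).reshape(-1, T)
    d2 = squareform(pdist(series, metric="sqeuclidean"))
    K = np.exp(-d2 / (2.0 * sigma**2 * T**2))
    np.fill_diagonal(K, 1.0)
    dim_labels = [(j, a) for j in jrec.joint_labels for a in AXIS_NAMES]
    return CorrentropyMatrix(
        K=K,
        sigma=sigma,
        T=T,
        dim_labels=dim_labels,
        source_kind=jrec.frame_kind,
        participant_id=jrec.participant_id,
        stimulus_id=jrec.stimulus_id,
    )


@dataclass
class FeatureVector:
    """Strictly-lower-triangle vectorization of a correntropy matrix."""

    values: np.ndarray  # (D(D-1)/2,)
    dim_i: np.ndarray  # row index per element (dim_i > dim_j)
    dim_j: np.ndarray
    participant_id: str = ""
    stimulus_id: str = ""
    source_kind: str = "position"

    def __len__(self) -> int:
        return self.values.size


def vectorize_lower(cm: CorrentropyMatrix, atol: float = 1e-8) -> FeatureVector:
    """Row-major enumeration of K[i, j] for i = 1..D-1, j = 0..i-1."""
    K = cm.K
    if not np.allclose(K, K.T, atol=atol):
        raise ValueError("correntropy matrix is not symmetric")
    ii, jj = np.tril_indices(K.shape[0], k=-1)
    return FeatureVector(
        values=K[ii, jj],
        dim_i=ii,
        dim_j=jj,
        participant_id=cm.participant_id,
        stimulus_id=cm.stimulus_id,
        source_kind=cm.source_kind,
    )


def feature_pair_index(D: int) -> pd.DataFrame:
    """Element -> (dim_i, dim_j, joint_i, joint_j) lookup for D dimensions.

    Dimension d belongs to joint d // 3 under the joint-major layout; the
    table has D(D-1)/2 rows in feature-vector order.
    """
    if D % 3 != 0:
        raise ValueError(f"D={D} is not a multiple of 3")
    ii, jj = np.tril_indices(D, k=-1)
    return pd.DataFrame(
        {
            "element": np.arange(ii.size),
            "dim_i": ii,
            "dim_j": jj,
            "joint_i": ii // 3,
            "joint_j": jj // 3,
        }
    )


def features_to_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a tidy table, one row per recording."""
    if not vectors:
        raise ValueError("no feature vectors")
    F = len(vectors[0])
    cols = [f"e{k:04d}" for k in range(F)]
    rows = []
    for fv in vectors:
        if len(fv) != F:
            raise ValueError("feature vectors differ in length")
        rows.append([fv.participant_id, fv.stimulus_id, fv.source_kind, *fv.values])
    return pd.DataFrame(rows, columns=["participant_id", "stimulus_id", "source_kind", *cols])


def frame_to_feature_matrix(df: pd.DataFrame) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Split a feature table into (N, F) matrix and (participant, stimulus) ids."""
    cols = [c for c in df.columns if c.startswith("e") and c[1:].isdigit()]
    X = df[cols].to_numpy(dtype=float)
    ids = list(zip(df["participant_id"].astype(str), df["stimulus_id"].astype(str)))
    return X, ids
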