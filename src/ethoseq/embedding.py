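"""PCA embedding of merged pose sessions.

The embedding is fit once on the valid frames of all sessions pooled
together (default 15 components), then applied per session; gap frames are
projected too but remain masked downstream.
"""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA

from .types import PCAModel, PoseSession

__all__ = ["fit_pca", "transform_sessions"]


def fit_pca(sessions: list[PoseSession], n_components: int = 15) -> PCAModel:
    """Fit PCA on the pooled valid frames of all sessions.

    ``explained_variance`` equals the top eigenvalues of the pooled sample
    covariance (ddof=1).  Raises if more components than feature dimensions
    are requested or too few valid frames exist.
    """
    X = np.concatenate([s.features[s.valid_mask] for s in sessions], axis=0)
    if n_components > X.shape[1]:
        raise ValueError(f"n_components={n_components} exceeds feature dimension {X.shape[1]}")
    if X.shape[0] < n_components:
        raise ValueError("fewer valid frames than requested components")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    return PCAModel(
        mean=pca.mean_,
        loadings=pca.components_.T,
        explained_variance=pca.explained_variance_,
    )


def transform_sessions(model: PCAModel, sessions: list[PoseSession]) -> list[np.ndarray]:
    """Project every session to (T, P) score matrices (gap frames included)."""
    return [model.transform(s.features) for s in sessions]
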