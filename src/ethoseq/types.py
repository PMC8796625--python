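"""Core domain containers for the motion-sequencing and EEG pipelines.

The containers are deliberately thin (frozen-ish dataclasses around numpy
arrays) so that every stage of the pipeline can be driven from plain arrays
in tests while still carrying the metadata (fps, masks, seeds) that the
statistics downstream depend on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PoseSession",
    "GroundTruth",
    "EEGRecording",
    "PCAModel",
    "ARHMMModel",
    "StateSequence",
    "EnsembleResult",
    "Bout",
    "FilterSpec",
    "DetectorSpec",
    "RippleEvent",
]


@dataclass
class PoseSession:
    """One recording session of pose features.

    ``features`` is a (T, D) matrix of pose descriptors sampled at ``fps``
    frames/second.  ``valid_mask`` is False inside acquisition gaps: the
    behavior continues through a gap, but no usable observation exists there,
    so downstream stages must never count a bout or a transition across a
    False run.
    """

    animal_id: str
    genotype: str
    fps: float
    features: np.ndarray
    valid_mask: np.ndarray
    session_minutes: float

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.features.ndim != 2:
            raise ValueError("features must be a (T, D) matrix")
        if self.valid_mask.shape != (self.features.shape[0],):
            raise ValueError("valid_mask length must match number of frames")
        if not np.isfinite(self.features[self.valid_mask]).all():
            raise ValueError("non-finite feature values inside valid frames")

    @property
    def n_frames(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def valid_minutes(self) -> float:
        return float(self.valid_mask.sum()) / self.fps / 60.0


@dataclass
class GroundTruth:
    """Generator-side truth attached to a synthetic session or EEG trace.

    ``states`` covers every frame, including gap frames: a gap interrupts the
    recording, not the behavior.
    """

    states: np.ndarray | None = None
    model: "ARHMMModel | None" = None
    events: list["RippleEvent"] = field(default_factory=list)


@dataclass
class EEGRecording:
    """Multichannel EEG: (C, N) samples in microvolts at ``fs`` Hz."""

    channel_names: list[str]
    samples: np.ndarray
    fs: float
    antialias_lowpass: float = 2000.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names length must match sample rows")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class PCAModel:
    """PCA embedding fit on the merged dataset (valid frames only)."""

    mean: np.ndarray
    loadings: np.ndarray  # (D, P), columns orthonormal
    explained_variance: np.ndarray  # (P,), non-increasing

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, features: np.ndarray) -> np.ndarray:
        """Project (T, D) features to (T, P) scores. Gap frames project too;
        masking is the caller's concern."""
        return (np.asarray(features, dtype=np.float64) - self.mean) @ self.loadings


@dataclass
class ARHMMModel:
    """K-state switching AR(L) model with Gaussian innovations.

    Per state k: x_t = intercepts[k] + sum_l ar_coefs[k, l] @ x_{t-1-l} + e,
    e ~ N(0, covariances[k]).  ``transition_matrix`` rows are the Markov
    transition probabilities; ``initial_distribution`` starts each contiguous
    observation block.
    """

    ar_coefs: np.ndarray  # (K, L, P, P)
    intercepts: np.ndarray  # (K, P)
    covariances: np.ndarray  # (K, P, P)
    transition_matrix: np.ndarray  # (K, K)
    initial_distribution: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        self.ar_coefs = np.asarray(self.ar_coefs, dtype=np.float64)
        self.intercepts = np.asarray(self.intercepts, dtype=np.float64)
        self.covariances = np.asarray(self.covariances, dtype=np.float64)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=np.float64)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=np.float64)

    @property
    def n_states(self) -> int:
        return self.ar_coefs.shape[0]

    @property
    def ar_order(self) -> int:
        return self.ar_coefs.shape[1]

    @property
    def n_dims(self) -> int:
        return self.ar_coefs.shape[3]

    def validate(self, atol: float = 1e-8) -> None:
        K, L, P, P2 = self.ar_coefs.shape
        if P != P2:
            raise ValueError("AR coefficient matrices must be square")
        if self.intercepts.shape != (K, P):
            raise ValueError("intercepts shape mismatch")
        if self.covariances.shape != (K, P, P):
            raise ValueError("covariances shape mismatch")
        if self.transition_matrix.shape != (K, K):
            raise ValueError("transition matrix must be K x K")
        rows = self.transition_matrix.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=max(atol, 1e-12)):
            raise ValueError("transition matrix rows must sum to 1")
        if (self.transition_matrix < -atol).any():
            raise ValueError("transition matrix must be non-negative")
        if not np.isclose(self.initial_distribution.sum(), 1.0, atol=max(atol, 1e-12)):
            raise ValueError("initial distribution must sum to 1")
        for k in range(K):
            S = self.covariances[k]
            if not np.allclose(S, S.T, atol=1e-10):
                raise ValueError(f"covariance of state {k} not symmetric")
            if np.linalg.eigvalsh(S).min() <= 0:
                raise ValueError(f"covariance of state {k} not positive definite")

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of the state chain (leading left eigenvector)."""
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def state_stationary_moments(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Stationary observation mean and covariance of state ``k``'s AR process.

        Only defined for L=1 dynamics; for L>1 the lag-stacked companion form
        is used.
        """
        from scipy.linalg import solve_discrete_lyapunov

        L, P = self.ar_order, self.n_dims
        if L == 1:
            A = self.ar_coefs[k, 0]
            mean = np.linalg.solve(np.eye(P) - A, self.intercepts[k])
            cov = solve_discrete_lyapunov(A, self.covariances[k])
            return mean, cov
        # companion form for higher lags
        A = np.zeros((L * P, L * P))
        A[:P, :] = np.concatenate([self.ar_coefs[k, l] for l in range(L)], axis=1)
        A[P:, :-P] = np.eye((L - 1) * P)
        b = np.zeros(L * P)
        b[:P] = self.intercepts[k]
        Q = np.zeros((L * P, L * P))
        Q[:P, :P] = self.covariances[k]
        mean_full = np.linalg.solve(np.eye(L * P) - A, b)
        cov_full = solve_discrete_lyapunov(A, Q)
        return mean_full[:P], cov_full[:P, :P]


@dataclass
class StateSequence:
    """Per-frame state labels of one session under one fitted model.

    ``labels`` has length T with -1 at invalid (gap) frames.
    """

    labels: np.ndarray
    log_likelihood: float
    seed: int
    fit_id: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)


@dataclass
class ARHMMFit:
    """One EM fit: the model, its decodes, and the likelihood trace."""

    model: ARHMMModel
    state_sequences: list[StateSequence]
    log_likelihoods: np.ndarray
    seed: int
    fit_id: int = 0
    converged: bool = False
    n_restarts: int = 0


@dataclass
class EnsembleResult:
    """R independent ARHMM fits of the same embedded sessions."""

    fits: list[ARHMMFit]

    @property
    def n_fits(self) -> int:
        return len(self.fits)

    def labels_matrix(self, session_index: int) -> np.ndarray:
        """(T, R) matrix of per-fit labels for one session (-1 at gaps)."""
        return np.stack(
            [f.state_sequences[session_index].labels for f in self.fits], axis=1
        )


@dataclass
class Bout:
    """Maximal uninterrupted run of one syllable within a valid block."""

    syllable: int
    start: int  # frame, inclusive
    end: int  # frame, exclusive
    duration_s: float

    @property
    def n_frames(self) -> int:
        return self.end - self.start


@dataclass
class FilterSpec:
    """Band-pass specification for the fast-ripple detection band."""

    band: tuple[float, float] = (200.0, 550.0)
    order: int = 2
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ValueError("need 0 < low < high")
        if hi >= fs / 2:
            raise ValueError("band edge at or above Nyquist")


@dataclass
class DetectorSpec:
    """Thresholds of the fast-ripple detector.

    An event requires ``min_oscillations`` consecutive band-limited
    oscillations whose amplitude exceeds ``amplitude_ratio`` times the SD of
    the ``baseline_window_ms`` of surrounding baseline signal.
    """

    min_oscillations: int = 4
    amplitude_ratio: float = 3.0
    baseline_window_ms: float = 250.0
    merge_gap_ms: float = 10.0
    # implementation knobs (documented in docs/methods.md)
    group_gap_ms: float = 6.0
    guard_ms: float = 10.0
    envelope_smooth_ms: float = 4.0

    def validate(self) -> None:
        if self.min_oscillations < 1:
            raise ValueError("min_oscillations must be >= 1")
        if self.amplitude_ratio <= 0:
            raise ValueError("amplitude_ratio must be positive")


@dataclass
class RippleEvent:
    """One detected (or injected) high-frequency oscillation event."""

    channel: str
    start: int  # sample, inclusive
    end: int  # sample, exclusive
    n_oscillations: int
    peak_amplitude_ratio: float
    frequency_hz: float

    def overlaps(self, other: "RippleEvent") -> bool:
        return self.channel == other.channel and self.start < other.end and other.start < self.end
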