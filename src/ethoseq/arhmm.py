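"""Autoregressive HMM fitting (EM), Viterbi decoding, and ensemble runs.

The fit is expectation-maximization (Baum-Welch with AR-Gaussian emissions)
from a seed-controlled k-means initialization, so a given seed always
reproduces the same fit.  The likelihood factorizes over contiguous valid
blocks: no transition is counted across an acquisition gap, and each block
restarts from the initial distribution.  Per-frame states are assigned by
Viterbi decoding.

An ensemble is simply R independent fits with distinct seeds; the stochastic
frame-assignment differences between fits are the raw material for the
consensus-syllable stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from sklearn.cluster import KMeans

from ._kernels import forward_backward, viterbi
from .types import ARHMMFit, ARHMMModel, EnsembleResult, StateSequence

logger = logging.getLogger(__name__)

__all__ = ["fit_arhmm", "viterbi_decode", "run_ensemble", "match_states"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class _BlockData:
    """Contiguous valid blocks of all sessions, stacked for EM.

    Y[m] is the frame predicted from design row Phi[m] (lagged frames plus a
    constant).  ``block_bounds`` delimits blocks in the stacked arrays;
    ``frame_index`` maps stacked rows back to (session, frame).
    """

    Y: np.ndarray  # (M, P)
    Phi: np.ndarray  # (M, L*P + 1)
    block_bounds: list[tuple[int, int]]
    frame_index: list[tuple[int, np.ndarray]]  # per block: (session id, frame ids)
    short_blocks: list[tuple[int, np.ndarray]]  # blocks with < L+1 frames
    n_sessions: int
    session_lengths: list[int]


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[splits + 1]])
    ends = np.concatenate([idx[splits] + 1, [idx[-1] + 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def _prepare_blocks(scores: list[np.ndarray], masks: list[np.ndarray] | None, L: int) -> _BlockData:
    Ys, Phis, bounds, frame_index, short_blocks = [], [], [], [], []
    m = 0
    for si, X in enumerate(scores):
        X = np.asarray(X, dtype=np.float64)
        T = X.shape[0]
        mask = np.ones(T, dtype=bool) if masks is None else np.asarray(masks[si], dtype=bool)
        for a, b in _contiguous_runs(mask):
            if b - a < L + 1:
                short_blocks.append((si, np.arange(a, b)))
                continue
            Y = X[a + L : b]
            cols = [X[a + L - 1 - l : b - 1 - l] for l in range(L)]
            Phi = np.concatenate(cols + [np.ones((b - a - L, 1))], axis=1)
            Ys.append(Y)
            Phis.append(Phi)
            bounds.append((m, m + Y.shape[0]))
            frame_index.append((si, np.arange(a + L, b)))
            m += Y.shape[0]
    if not Ys:
        raise ValueError("no contiguous valid block of length >= L+1")
    return _BlockData(
        Y=np.concatenate(Ys, axis=0),
        Phi=np.concatenate(Phis, axis=0),
        block_bounds=bounds,
        frame_index=frame_index,
        short_blocks=short_blocks,
        n_sessions=len(scores),
        session_lengths=[np.asarray(x).shape[0] for x in scores],
    )


def _emission_loglik(data: _BlockData, weights: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """(M, K) log N(Y | Phi @ W_k, Sigma_k)."""
    M = data.Y.shape[0]
    K, P = covs.shape[0], covs.shape[1]
    logB = np.empty((M, K))
    for k in range(K):
        resid = data.Y - data.Phi @ weights[k]
        chol = np.linalg.cholesky(covs[k])
        sol = solve_triangular(chol, resid.T, lower=True)
        quad = np.einsum("ij,ij->j", sol, sol)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        logB[:, k] = -0.5 * (P * _LOG2PI + logdet + quad)
    return logB


def _m_step(
    data: _BlockData, gamma: np.ndarray, ridge: float, cov_reg: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    K = gamma.shape[1]
    M, P = data.Y.shape
    d = data.Phi.shape[1]
    weights = np.empty((K, d, P))
    covs = np.empty((K, P, P))
    occ = gamma.sum(axis=0)
    for k in range(K):
        w = gamma[:, k]
        Pw = data.Phi * w[:, None]
        A = data.Phi.T @ Pw + ridge * np.eye(d)
        B = Pw.T @ data.Y
        Wk = np.linalg.solve(A, B)
        resid = data.Y - data.Phi @ Wk
        S = (resid * w[:, None]).T @ resid / max(occ[k], 1e-300)
        covs[k] = 0.5 * (S + S.T) + cov_reg * np.eye(P)
        weights[k] = Wk
    return weights, covs, occ


def _init_from_labels(
    data: _BlockData, labels: np.ndarray, K: int, ridge: float, cov_reg: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    gamma = np.zeros((labels.shape[0], K))
    gamma[np.arange(labels.shape[0]), labels] = 1.0
    # soften so every state has some mass
    gamma = gamma * 0.95 + 0.05 / K
    weights, covs, _ = _m_step(data, gamma, ridge, cov_reg)
    trans = np.full((K, K), 1.0)
    for a, b in data.block_bounds:
        lb = labels[a:b]
        np.add.at(trans, (lb[:-1], lb[1:]), 1.0)
    trans = trans / trans.sum(axis=1, keepdims=True)
    init = np.bincount(labels[[a for a, _ in data.block_bounds]], minlength=K) + 1.0
    return weights, covs, trans, init / init.sum()


def _weights_to_model(weights: np.ndarray, covs: np.ndarray, trans: np.ndarray, init: np.ndarray, L: int) -> ARHMMModel:
    K, d, P = weights.shape
    ar = np.empty((K, L, P, P))
    for k in range(K):
        for l in range(L):
            ar[k, l] = weights[k, l * P : (l + 1) * P].T
    return ARHMMModel(
        ar_coefs=ar,
        intercepts=weights[:, -1, :].copy(),
        covariances=covs,
        transition_matrix=trans,
        initial_distribution=init,
    )


def _model_to_weights(model: ARHMMModel) -> tuple[np.ndarray, np.ndarray]:
    K, L, P, _ = model.ar_coefs.shape
    weights = np.empty((K, L * P + 1, P))
    for k in range(K):
        for l in range(L):
            weights[k, l * P : (l + 1) * P] = model.ar_coefs[k, l].T
        weights[k, -1] = model.intercepts[k]
    return weights, model.covariances


def fit_arhmm(
    scores: list[np.ndarray],
    masks: list[np.ndarray] | None = None,
    K: int = 15,
    L: int = 1,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    cov_reg: float = 1e-6,
    ridge: float = 1e-8,
    fit_id: int = 0,
    max_restarts: int = 3,
) -> ARHMMFit:
    """EM fit of a K-state AR(L) HMM on embedded sessions.

    Stops when the relative log-likelihood improvement falls below ``tol``
    ("equilibrium") or after ``max_iter`` iterations; the per-iteration
    log-likelihood is non-decreasing.  A state that loses all responsibility
    triggers a re-seeded restart (logged); persistent degeneracy raises.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    data = _prepare_blocks(scores, masks, L)
    M = data.Y.shape[0]
    if M <= K * (L * data.Y.shape[1] + 1):
        raise ValueError("too few valid frames for the requested model size")

    attempt_seed = seed
    for attempt in range(max_restarts + 1):
        try:
            fit = _fit_once(data, K, L, attempt_seed, max_iter, tol, cov_reg, ridge)
            model, lls = fit
            break
        except _DegenerateState as exc:
            logger.warning(
                "fit seed %d: degenerate state %d at iteration %d; restarting with new seed",
                attempt_seed, exc.state, exc.iteration,
            )
            attempt_seed = attempt_seed + 10007 * (attempt + 1)
    else:
        raise RuntimeError(f"EM degenerate after {max_restarts} restarts (seed {seed})")

    state_sequences = [
        viterbi_decode(model, scores[i], None if masks is None else masks[i], seed=seed, fit_id=fit_id)
        for i in range(len(scores))
    ]
    converged = len(lls) < max_iter or (
        len(lls) >= 2 and abs(lls[-1] - lls[-2]) <= tol * abs(lls[-2])
    )
    return ARHMMFit(
        model=model,
        state_sequences=state_sequences,
        log_likelihoods=np.asarray(lls),
        seed=seed,
        fit_id=fit_id,
        converged=converged,
        n_restarts=attempt,
    )


class _DegenerateState(Exception):
    def __init__(self, state: int, iteration: int):
        self.state = state
        self.iteration = iteration


def _fit_once(data: _BlockData, K, L, seed, max_iter, tol, cov_reg, ridge):
    P = data.Y.shape[1]
    if K == 1:
        gamma = np.ones((data.Y.shape[0], 1))
        weights, covs, _ = _m_step(data, gamma, ridge, cov_reg)
        model = _weights_to_model(weights, covs, np.ones((1, 1)), np.ones(1), L)
        logB = _emission_loglik(data, weights, covs)
        return model, [float(logB.sum())]

    km = KMeans(n_clusters=K, random_state=seed % (2**31), n_init=3)
    lagged = np.concatenate([data.Phi[:, :-1], data.Y], axis=1)
    labels = km.fit_predict(lagged)
    weights, covs, trans, init = _init_from_labels(data, labels, K, ridge, cov_reg)

    lls: list[float] = []
    for it in range(max_iter):
        logB = _emission_loglik(data, weights, covs)
        gamma = np.empty_like(logB)
        xi_sum = np.zeros((K, K))
        start_sum = np.zeros(K)
        ll = 0.0
        for a, b in data.block_bounds:
            g, xi, g0, l = forward_backward(logB[a:b], trans, init)
            gamma[a:b] = g
            xi_sum += xi
            start_sum += g0
            ll += l
        lls.append(ll)
        occ = gamma.sum(axis=0)
        min_frames = L * P + 2
        if occ.min() < min_frames:
            raise _DegenerateState(int(occ.argmin()), it)
        weights, covs, occ = _m_step(data, gamma, ridge, cov_reg)
        rows = xi_sum.sum(axis=1, keepdims=True)
        trans = np.where(rows > 0, xi_sum / np.maximum(rows, 1e-300), 1.0 / K)
        trans = trans / trans.sum(axis=1, keepdims=True)
        init = start_sum / start_sum.sum()
        if len(lls) >= 2 and (lls[-1] - lls[-2]) <= tol * abs(lls[-2]):
            break
    model = _weights_to_model(weights, covs, trans, init, L)
    return model, lls


def viterbi_decode(
    model: ARHMMModel,
    scores: np.ndarray,
    mask: np.ndarray | None = None,
    seed: int = 0,
    fit_id: int = 0,
) -> StateSequence:
    """Maximum-a-posteriori state path per contiguous valid block.

    The first L frames of each block (which only condition the AR emissions)
    inherit the first decoded label of the block.  Blocks shorter than L+1
    frames are labeled by emission-only argmax under each state's stationary
    observation distribution and logged.  Gap frames stay -1.
    """
    model.validate()
    X = np.asarray(scores, dtype=np.float64)
    T = X.shape[0]
    L = model.ar_order
    labels = np.full(T, -1, dtype=np.int64)
    mask_arr = np.ones(T, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    with np.errstate(divide="ignore"):
        log_trans = np.log(model.transition_matrix)
        log_init = np.log(model.initial_distribution)
    weights, covs = _model_to_weights(model)
    total_ll = 0.0
    short_frames = []
    for a, b in _contiguous_runs(mask_arr):
        if b - a < L + 1:
            short_frames.append((a, b))
            continue
        blk = _BlockData(
            Y=X[a + L : b],
            Phi=np.concatenate([X[a + L - 1 - l : b - 1 - l] for l in range(L)] + [np.ones((b - a - L, 1))], axis=1),
            block_bounds=[(0, b - a - L)],
            frame_index=[],
            short_blocks=[],
            n_sessions=1,
            session_lengths=[T],
        )
        logB = _emission_loglik(blk, weights, covs)
        path, ll = viterbi(logB, log_trans, log_init)
        labels[a + L : b] = path
        labels[a : a + L] = path[0]
        total_ll += ll
    if short_frames:
        logger.warning("%d block(s) shorter than L+1: emission-only labels", len(short_frames))
        for a, b in short_frames:
            labels[a:b] = _stationary_argmax(model, X[a:b])
    return StateSequence(labels=labels, log_likelihood=float(total_ll), seed=seed, fit_id=fit_id)


def _stationary_argmax(model: ARHMMModel, X: np.ndarray) -> np.ndarray:
    K = model.n_states
    ll = np.empty((X.shape[0], K))
    for k in range(K):
        mean, cov = model.state_stationary_moments(k)
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
        sol = np.linalg.solve(chol, (X - mean).T)
        quad = np.einsum("ij,ij->j", sol, sol)
        ll[:, k] = -0.5 * (quad + 2 * np.log(np.diag(chol)).sum())
    return ll.argmax(axis=1)


def run_ensemble(
    scores: list[np.ndarray],
    masks: list[np.ndarray] | None = None,
    K: int = 15,
    L: int = 1,
    R: int = 8,
    master_seed: int = 0,
    **fit_kwargs,
) -> EnsembleResult:
    """R independent ARHMM fits with seeds master_seed + 0 .. R-1.

    Any aborting fit fails the ensemble with its seed in the error message.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    fits = []
    for r in range(R):
        s = master_seed + r
        try:
            fits.append(fit_arhmm(scores, masks, K=K, L=L, seed=s, fit_id=r, **fit_kwargs))
        except Exception as exc:  # noqa: BLE001 - re-raise with seed context
            raise RuntimeError(f"ensemble fit {r} (seed {s}) failed: {exc}") from exc
    return EnsembleResult(fits=fits)


def match_states(true_labels: np.ndarray, est_labels: np.ndarray, K: int) -> np.ndarray:
    """Optimal permutation mapping estimated states onto true states
    (Hungarian algorithm on the confusion matrix)."""
    from scipy.optimize import linear_sum_assignment

    conf = np.zeros((K, K))
    ok = (true_labels >= 0) & (est_labels >= 0)
    np.add.at(conf, (est_labels[ok], true_labels[ok]), 1.0)
    rows, cols = linear_sum_assignment(-conf)
    perm = np.empty(K, dtype=np.int64)
    perm[rows] = cols
    return perm
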