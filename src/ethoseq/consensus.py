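"""Consensus syllables from ensembles of ARHMM fits.

Each valid frame carries an R-tuple of state labels — one per independent
fit — called its signature.  Because every fit labels states in its own
arbitrary order, signatures are clustered (WPGMA on normalized Hamming
distance between unique signatures) and the tree is cut to a fixed number
of clusters; the clusters are the consensus behavioral syllables, indexed
by descending total frame count so that syllable 0 is the most used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist

from .types import EnsembleResult

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureCatalog",
    "SyllableAssignment",
    "build_signatures",
    "signature_distance",
    "cluster_signatures",
    "assign_syllables",
    "linkage_to_newick",
]

NO_LABEL = -1


@dataclass
class SignatureCatalog:
    """Unique frame signatures with occurrence counts.

    ``signatures`` is (U, R); ``counts`` sums to the number of valid frames;
    after clustering, ``linkage_matrix`` holds the WPGMA tree and
    ``syllable_map`` the signature-row -> syllable assignment.
    """

    signatures: np.ndarray  # (U, R) int
    counts: np.ndarray  # (U,)
    linkage_matrix: np.ndarray | None = None
    syllable_map: np.ndarray | None = None

    @property
    def n_unique(self) -> int:
        return self.signatures.shape[0]

    @property
    def n_fits(self) -> int:
        return self.signatures.shape[1]


@dataclass
class SyllableAssignment:
    """Per-session, per-frame consensus syllable ids (NO_LABEL at gaps)."""

    labels: list[np.ndarray]
    n_syllables: int
    syllable_names: dict[int, str] | None = None

    def pooled(self) -> np.ndarray:
        return np.concatenate(self.labels)


def build_signatures(ensemble: EnsembleResult) -> tuple[list[np.ndarray], SignatureCatalog]:
    """Collect the per-frame R-vector of states into a unique-signature catalog.

    Returns per-session (T, R) signature matrices (rows of -1 at gaps) and
    the catalog over valid frames.  All fits must cover the same frames.
    """
    n_sessions = len(ensemble.fits[0].state_sequences)
    per_session = []
    valid_rows = []
    for s in range(n_sessions):
        mat = ensemble.labels_matrix(s)
        valid = mat[:, 0] >= 0
        if not ((mat >= 0) == valid[:, None]).all():
            raise ValueError("fits disagree on which frames are valid")
        per_session.append(mat)
        valid_rows.append(mat[valid])
    stacked = np.concatenate(valid_rows, axis=0)
    uniq, counts = np.unique(stacked, axis=0, return_counts=True)
    return per_session, SignatureCatalog(signatures=uniq, counts=counts)


def signature_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized Hamming distance between two signatures, in [0, 1]."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("signatures must have equal length")
    return float(np.mean(a != b))


def _weighted_upgma(D: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """UPGMA recurrence with arbitrary initial leaf weights (count-weighted
    variant).  O(n^2) memory, straightforward scan per merge; intended for
    catalogs up to a few thousand unique signatures."""
    n = D.shape[0]
    D = D.copy().astype(np.float64)
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    ids = np.arange(n)
    w = sizes.astype(np.float64).copy()
    Z = np.zeros((n - 1, 4))
    next_id = n
    idx = {i: i for i in range(n)}
    members = {i: 1 for i in range(n)}
    for step in range(n - 1):
        sub = np.where(active)[0]
        flat = D[np.ix_(sub, sub)]
        k = np.argmin(flat)
        i, j = sub[k // len(sub)], sub[k % len(sub)]
        h = D[i, j]
        Z[step] = [ids[i], ids[j], h, members[i] + members[j]]
        # weighted average update into slot i
        new_w = w[i] + w[j]
        for m in sub:
            if m == i or m == j:
                continue
            D[i, m] = D[m, i] = (w[i] * D[i, m] + w[j] * D[j, m]) / new_w
        w[i] = new_w
        members[i] = members[i] + members[j]
        ids[i] = next_id
        active[j] = False
        D[j, :] = np.inf
        D[:, j] = np.inf
        next_id += 1
    return Z


def cluster_signatures(
    catalog: SignatureCatalog,
    n_clusters: int = 44,
    linkage_method: str = "weighted",
    count_weighted: bool = False,
    max_signatures: int = 30000,
) -> np.ndarray:
    """Agglomerative WPGMA clustering of the signature catalog.

    Cuts the tree to exactly ``n_clusters`` and re-indexes syllables by
    descending total frame count (syllable 0 = most frames).  The default is
    the unweighted catalog (each unique signature enters once); set
    ``count_weighted`` for the frame-count-weighted variant.  Returns the
    signature-row -> syllable map and stores it (plus the linkage tree) on
    the catalog.
    """
    U = catalog.n_unique
    if n_clusters > U:
        raise ValueError(f"n_clusters={n_clusters} exceeds {U} unique signatures")
    if U > max_signatures:
        raise MemoryError(
            f"{U} unique signatures exceed max_signatures={max_signatures}: "
            "subsample the catalog by a frame-count threshold (drop rare "
            "signatures and assign their frames via the nearest-signature "
            "fallback) before clustering"
        )
    if U == 1:
        catalog.linkage_matrix = np.zeros((0, 4))
        catalog.syllable_map = np.zeros(1, dtype=np.int64)
        return catalog.syllable_map
    if count_weighted:
        D = cdist(catalog.signatures, catalog.signatures, metric="hamming")
        Z = _weighted_upgma(D, catalog.counts)
    else:
        d = pdist(catalog.signatures, metric="hamming")
        Z = linkage(d, method=linkage_method)
    raw = fcluster(Z, t=n_clusters, criterion="maxclust") - 1
    # re-index by descending frame count
    totals = np.zeros(raw.max() + 1)
    np.add.at(totals, raw, catalog.counts)
    order = np.argsort(-totals, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.shape[0])
    catalog.linkage_matrix = Z
    catalog.syllable_map = rank[raw].astype(np.int64)
    return catalog.syllable_map


def assign_syllables(
    per_session_signatures: list[np.ndarray],
    catalog: SignatureCatalog,
) -> SyllableAssignment:
    """Map every frame's signature to its consensus syllable.

    Frames with identical signatures always receive identical syllables.
    A signature absent from the catalog (e.g. new data under a frozen map)
    falls back to the nearest catalogued signature by Hamming distance and
    is logged.
    """
    if catalog.syllable_map is None:
        raise ValueError("catalog has no syllable map; run cluster_signatures first")
    # hashable lookup of catalogued signatures
    lut = {tuple(row): int(catalog.syllable_map[i]) for i, row in enumerate(catalog.signatures)}
    labels = []
    n_fallback = 0
    for mat in per_session_signatures:
        T = mat.shape[0]
        out = np.full(T, NO_LABEL, dtype=np.int64)
        valid = mat[:, 0] >= 0
        rows = mat[valid]
        assigned = np.empty(rows.shape[0], dtype=np.int64)
        misses = []
        for i, row in enumerate(map(tuple, rows)):
            hit = lut.get(row)
            if hit is None:
                misses.append(i)
            else:
                assigned[i] = hit
        if misses:
            n_fallback += len(misses)
            d = cdist(rows[misses], catalog.signatures, metric="hamming")
            nearest = d.argmin(axis=1)
            assigned[misses] = catalog.syllable_map[nearest]
        out[valid] = assigned
        labels.append(out)
    if n_fallback:
        logger.warning("%d frames had unseen signatures; nearest-signature fallback used", n_fallback)
    n_syll = int(catalog.syllable_map.max()) + 1
    return SyllableAssignment(labels=labels, n_syllables=n_syll)


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str] | None = None) -> str:
    """Render a scipy linkage matrix as a Newick string (branch lengths from
    merge heights), for dendrogram review outside the pipeline."""
    n = Z.shape[0] + 1
    names = leaf_names or [f"sig{i}" for i in range(n)]
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: names[i] for i in range(n)}
    for step in range(Z.shape[0]):
        a, b, h, _ = Z[step]
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        nodes[n + step] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + step] = h
        del nodes[a], nodes[b]
    return next(iter(nodes.values())) + ";"
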