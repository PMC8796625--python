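"""Per-animal syllable statistics, genotype comparison, transition networks.

Three characteristics per animal x syllable, as used to phenotype the
cohorts:

* frequency (min^-1): bouts initiated per minute of valid recording,
* mean length (s): mean duration of an uninterrupted bout,
* proportion (%): share of valid recording time spent in the syllable.

On gap-free data these obey frequency x mean_length = 0.6 x proportion
exactly, which the tests use as an algebraic check.  Genotype comparison is
a Kruskal-Wallis omnibus per syllable x metric followed by Dunn's pairwise
z-tests on the pooled tie-corrected ranks.  Transition networks count
ordered pairs of consecutive distinct syllables (never across a gap) and
express each edge as a percentage of all transitions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .types import Bout

__all__ = [
    "extract_bouts",
    "compute_metrics",
    "metrics_table",
    "compare_groups",
    "dunn_test",
    "build_transition_graph",
    "transition_matrix",
]

METRICS = ("frequency", "mean_length", "proportion")


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal value: (value, start, end) with end exclusive."""
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [labels.size]])
    return [(int(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def _valid_blocks(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    cut = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[cut + 1]])
    ends = np.concatenate([idx[cut] + 1, [idx[-1] + 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def extract_bouts(labels: np.ndarray, valid_mask: np.ndarray | None, fps: float) -> list[Bout]:
    """Maximal runs of one syllable within contiguous valid blocks.

    A gap always terminates a bout: a run of the same syllable on both sides
    of a gap yields two bouts.  Unlabeled frames (label < 0) inside valid
    blocks are skipped the same way.
    """
    labels = np.asarray(labels)
    mask = np.ones(labels.shape[0], dtype=bool) if valid_mask is None else np.asarray(valid_mask, dtype=bool)
    mask = mask & (labels >= 0)
    bouts: list[Bout] = []
    for a, b in _valid_blocks(mask):
        for v, s, e in _runs(labels[a:b]):
            bouts.append(Bout(syllable=v, start=a + s, end=a + e, duration_s=(e - s) / fps))
    return bouts


def compute_metrics(
    bouts: list[Bout],
    total_valid_minutes: float,
    n_syllables: int,
    animal_id: str = "",
    genotype: str = "",
) -> pd.DataFrame:
    """Frequency, mean length, and proportion for one animal.

    frequency = bout count / valid minutes; mean_length = mean bout duration
    (NaN for an unused syllable); proportion = 100 x time in syllable /
    total valid time.  Proportions sum to 100 per animal by construction.
    """
    if total_valid_minutes <= 0:
        raise ValueError("total_valid_minutes must be positive")
    counts = np.zeros(n_syllables)
    time_s = np.zeros(n_syllables)
    for b in bouts:
        counts[b.syllable] += 1
        time_s[b.syllable] += b.duration_s
    total_s = total_valid_minutes * 60.0
    freq = counts / total_valid_minutes
    with np.errstate(invalid="ignore"):
        mean_len = np.where(counts > 0, time_s / np.maximum(counts, 1), np.nan)
    prop = 100.0 * time_s / total_s
    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "genotype": genotype,
            "syllable": np.arange(n_syllables),
            "frequency": freq,
            "mean_length": mean_len,
            "proportion": prop,
        }
    )


def metrics_table(
    assignments: list[np.ndarray],
    valid_masks: list[np.ndarray | None],
    fps: float,
    n_syllables: int,
    animal_ids: list[str],
    genotypes: list[str],
) -> pd.DataFrame:
    """Stack per-animal metrics into one animal x syllable table."""
    frames = []
    for labels, mask, aid, geno in zip(assignments, valid_masks, animal_ids, genotypes):
        m = np.ones(len(labels), dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
        minutes = float((m & (np.asarray(labels) >= 0)).sum()) / fps / 60.0
        bouts = extract_bouts(labels, mask, fps)
        frames.append(compute_metrics(bouts, minutes, n_syllables, aid, geno))
    return pd.concat(frames, ignore_index=True)


def dunn_test(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Dunn's pairwise z-tests on pooled tie-corrected ranks.

    Returns (z, p) matrices over group pairs (upper triangle meaningful),
    with z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - C)(1/n_i + 1/n_j)),
    where C = sum(t^3 - t) / (12 (N - 1)) corrects for ties; p two-sided
    normal.
    """
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    C = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - C
    means = []
    off = 0
    for n in sizes:
        means.append(ranks[off : off + n].mean())
        off += n
    G = len(groups)
    z = np.zeros((G, G))
    p = np.ones((G, G))
    for i, j in itertools.combinations(range(G), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            zij = 0.0
        else:
            zij = (means[i] - means[j]) / se
        z[i, j] = z[j, i] = zij
        p[i, j] = p[j, i] = 2.0 * stats.norm.sf(abs(zij))
    return z, p


def compare_groups(
    table: pd.DataFrame,
    alpha: float = 0.05,
    gate_on_omnibus: bool = True,
    p_adjust: str | None = None,
) -> pd.DataFrame:
    """Kruskal-Wallis omnibus plus Dunn pairwise tests per syllable x metric.

    One output row per (syllable, metric, genotype pair) with group medians,
    the omnibus statistic/p, the Dunn z/p, and a significance flag at
    ``alpha`` (pairwise p < alpha, and omnibus p < alpha when
    ``gate_on_omnibus``).  ``p_adjust`` ('fdr_bh', 'bonferroni', ...)
    optionally corrects the pairwise p-values across syllables per metric;
    default is no correction.  NaN values (unused syllables) are dropped per
    animal; constant data yields statistic 0, p 1.
    """
    genotypes = list(dict.fromkeys(table["genotype"]))
    if len(genotypes) < 2:
        raise ValueError("need at least two genotype groups")
    rows = []
    for metric in METRICS:
        for syll, sub in table.groupby("syllable"):
            groups = []
            for g in genotypes:
                vals = sub.loc[sub["genotype"] == g, metric].to_numpy(dtype=float)
                groups.append(vals[np.isfinite(vals)])
            if any(len(g) < 2 for g in groups):
                continue
            pooled = np.concatenate(groups)
            if np.ptp(pooled) == 0:
                kw_stat, kw_p = 0.0, 1.0
                z = np.zeros((len(groups), len(groups)))
                p = np.ones_like(z)
            else:
                kw_stat, kw_p = stats.kruskal(*groups)
                z, p = dunn_test(groups)
            for i, j in itertools.combinations(range(len(genotypes)), 2):
                rows.append(
                    {
                        "syllable": syll,
                        "metric": metric,
                        "group_a": genotypes[i],
                        "group_b": genotypes[j],
                        "median_a": float(np.median(groups[i])),
                        "median_b": float(np.median(groups[j])),
                        "kw_stat": float(kw_stat),
                        "kw_p": float(kw_p),
                        "dunn_z": float(z[i, j]),
                        "dunn_p": float(p[i, j]),
                    }
                )
    out = pd.DataFrame(rows)
    if out.empty:
        out["significant"] = pd.Series(dtype=bool)
        return out
    if p_adjust is not None:
        from statsmodels.stats.multitest import multipletests

        adj = np.empty(len(out))
        for (metric, _a, _b), idx in out.groupby(["metric", "group_a", "group_b"]).groups.items():
            adj[np.asarray(idx)] = multipletests(out.loc[idx, "dunn_p"], method=p_adjust)[1]
        out["dunn_p_adj"] = adj
        pair_p = out["dunn_p_adj"]
    else:
        pair_p = out["dunn_p"]
    sig = pair_p < alpha
    if gate_on_omnibus:
        sig &= out["kw_p"] < alpha
    out["significant"] = sig
    return out


def transition_matrix(
    assignments: list[np.ndarray],
    valid_masks: list[np.ndarray | None],
    n_syllables: int,
) -> np.ndarray:
    """Percentage matrix of consecutive distinct-syllable transitions,
    pooled over the given sessions; entries sum to 100 (no self-edges,
    nothing counted across a gap)."""
    counts = np.zeros((n_syllables, n_syllables))
    for labels, mask in zip(assignments, valid_masks):
        labels = np.asarray(labels)
        m = np.ones(labels.shape[0], dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
        m = m & (labels >= 0)
        for a, b in _valid_blocks(m):
            lb = labels[a:b]
            runs = [v for v, _s, _e in _runs(lb)]
            for u, v in zip(runs[:-1], runs[1:]):
                counts[u, v] += 1
    total = counts.sum()
    if total == 0:
        return counts
    return 100.0 * counts / total


def build_transition_graph(
    assignments: list[np.ndarray],
    valid_masks: list[np.ndarray | None],
    n_syllables: int,
    syllable_proportions: np.ndarray | None = None,
    edge_threshold: float = 0.01,
) -> tuple[nx.DiGraph, np.ndarray]:
    """Directed syllable transition network for one genotype.

    Node attribute ``proportion`` is the syllable's overall time share (%);
    edge ``weight`` is the transition's percentage of all recorded
    transitions.  Edges below ``edge_threshold`` (%) are excluded from the
    graph but retained in the returned full matrix.
    """
    W = transition_matrix(assignments, valid_masks, n_syllables)
    G = nx.DiGraph()
    for s in range(n_syllables):
        prop = float(syllable_proportions[s]) if syllable_proportions is not None else 0.0
        G.add_node(int(s), proportion=prop)
    for u in range(n_syllables):
        for v in range(n_syllables):
            if u != v and W[u, v] >= edge_threshold and W[u, v] > 0:
                G.add_edge(int(u), int(v), weight=float(W[u, v]))
    return G, W
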