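"""Consensus-syllable tests: signatures, WPGMA linkage, tree cuts, recovery."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import adjusted_rand_score

import ethoseq as eq
from ethoseq.consensus import NO_LABEL, SignatureCatalog, _weighted_upgma, linkage_to_newick
from ethoseq.types import ARHMMFit, EnsembleResult, StateSequence


def _ensemble_from_label_matrix(mat: np.ndarray) -> EnsembleResult:
    """Wrap a (T, R) label matrix as an R-fit ensemble of one session."""
    fits = []
    for r in range(mat.shape[1]):
        seq = StateSequence(labels=mat[:, r], log_likelihood=0.0, seed=r, fit_id=r)
        fits.append(ARHMMFit(model=None, state_sequences=[seq], log_likelihoods=np.zeros(1), seed=r))
    return EnsembleResult(fits=fits)


class TestSignatures:
    def test_catalog_counts_conserve_valid_frames(self):
        rng = np.random.default_rng(0)
        mat = rng.integers(0, 4, size=(300, 5))
        mat[10:20] = -1  # gap frames
        per, cat = eq.build_signatures(_ensemble_from_label_matrix(mat))
        assert cat.counts.sum() == 290
        assert cat.n_fits == 5

    def test_single_fit_signature_count_bounded_by_states(self):
        rng = np.random.default_rng(1)
        mat = rng.integers(0, 6, size=(500, 1))
        _, cat = eq.build_signatures(_ensemble_from_label_matrix(mat))
        assert cat.n_unique <= 6

    def test_label_permuted_fits_preserve_signature_count(self):
        """Two fits that are label permutations of each other yield exactly as
        many unique signatures as one fit has unique states."""
        rng = np.random.default_rng(2)
        base = rng.integers(0, 5, size=400)
        perm = np.array([3, 4, 0, 1, 2])
        mat = np.stack([base, perm[base]], axis=1)
        _, cat = eq.build_signatures(_ensemble_from_label_matrix(mat))
        assert cat.n_unique == len(np.unique(base))

    def test_mismatched_valid_frames_rejected(self):
        mat = np.ones((50, 2), dtype=np.int64)
        mat[0, 0] = -1
        with pytest.raises(ValueError):
            eq.build_signatures(_ensemble_from_label_matrix(mat))


class TestSignatureDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 1, 2, 2), (1, 1, 2, 2), 0.0),
            ((0, 1, 2, 3), (4, 5, 6, 7), 1.0),
            ((1, 1, 2, 2), (1, 3, 2, 4), 0.5),
        ],
    )
    def test_normalized_hamming(self, a, b, expected):
        assert eq.signature_distance(np.array(a), np.array(b)) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            eq.signature_distance(np.array([1, 2]), np.array([1, 2, 3]))


class TestWPGMA:
    # 4-point metric: d(AB)=2, d(AC)=4, d(AD)=6, d(BC)=4, d(BD)=6, d(CD)=3
    CONDENSED = np.array([2.0, 4.0, 6.0, 4.0, 6.0, 3.0])

    def test_merge_heights_match_hand_computation(self):
        """WPGMA merges AB at 2, CD at 3, then (AB)(CD) at (4+6+4+6)/4 = 5."""
        Z = linkage(self.CONDENSED, method="weighted")
        np.testing.assert_allclose(sorted(Z[:, 2]), [2.0, 3.0, 5.0])
        cut = fcluster(Z, t=2, criterion="maxclust")
        assert cut[0] == cut[1] and cut[2] == cut[3] and cut[0] != cut[2]

    def test_weighted_variant_reduces_to_wpgma_for_unit_sizes(self):
        """The count-weighted UPGMA recurrence equals WPGMA when every leaf
        has weight 1 at the first merges, and matches the hand-computed tree
        here."""
        D = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        D[iu] = self.CONDENSED
        D += D.T
        Z = _weighted_upgma(D, np.ones(4))
        np.testing.assert_allclose(sorted(Z[:, 2]), [2.0, 3.0, 5.0])

    def test_newick_export_contains_all_leaves(self):
        Z = linkage(self.CONDENSED, method="weighted")
        nwk = linkage_to_newick(Z, ["A", "B", "C", "D"])
        assert nwk.endswith(";") and all(x in nwk for x in "ABCD")


class TestClustering:
    def _catalog(self, rng, n=40, R=6, K=5):
        sigs = np.unique(rng.integers(0, K, size=(n, R)), axis=0)
        counts = rng.integers(1, 50, size=sigs.shape[0])
        return SignatureCatalog(signatures=sigs, counts=counts)

    def test_identity_map_when_clusters_equal_signatures(self):
        cat = self._catalog(np.random.default_rng(3))
        m = eq.cluster_signatures(cat, n_clusters=cat.n_unique)
        assert len(np.unique(m)) == cat.n_unique

    def test_syllables_ordered_by_descending_frame_count(self):
        cat = self._catalog(np.random.default_rng(4))
        m = eq.cluster_signatures(cat, n_clusters=5)
        totals = np.zeros(5)
        np.add.at(totals, m, cat.counts)
        assert (np.diff(totals) <= 0).all()

    def test_cut_is_monotone_in_cluster_count(self):
        """Raising n_clusters only splits clusters from the same tree, never
        merges them (nested partitions)."""
        cat = self._catalog(np.random.default_rng(5), n=60)
        maps = {}
        for k in (3, 6, 12):
            maps[k] = eq.cluster_signatures(cat, n_clusters=k).copy()
        for k_small, k_big in ((3, 6), (6, 12)):
            fine, coarse = maps[k_big], maps[k_small]
            # every fine cluster lies inside exactly one coarse cluster
            for c in np.unique(fine):
                assert len(np.unique(coarse[fine == c])) == 1

    def test_determinism(self):
        cat1 = self._catalog(np.random.default_rng(6))
        cat2 = SignatureCatalog(cat1.signatures.copy(), cat1.counts.copy())
        np.testing.assert_array_equal(
            eq.cluster_signatures(cat1, 7), eq.cluster_signatures(cat2, 7)
        )

    def test_oversized_catalog_fails_with_subsampling_instruction(self):
        cat = self._catalog(np.random.default_rng(7))
        with pytest.raises(MemoryError, match="subsample"):
            eq.cluster_signatures(cat, 5, max_signatures=10)

    def test_more_clusters_than_signatures_rejected(self):
        cat = self._catalog(np.random.default_rng(8))
        with pytest.raises(ValueError):
            eq.cluster_signatures(cat, cat.n_unique + 1)


class TestAssignment:
    def test_single_signature_all_syllable_zero(self):
        mat = np.ones((30, 3), dtype=np.int64)
        per, cat = eq.build_signatures(_ensemble_from_label_matrix(mat))
        eq.cluster_signatures(cat, 1)
        asn = eq.assign_syllables(per, cat)
        assert (asn.labels[0] == 0).all()

    def test_equal_signatures_get_equal_syllables(self):
        rng = np.random.default_rng(9)
        mat = rng.integers(0, 4, size=(400, 4))
        mat[50:60] = -1
        per, cat = eq.build_signatures(_ensemble_from_label_matrix(mat))
        eq.cluster_signatures(cat, 6)
        asn = eq.assign_syllables(per, cat)
        lab = asn.labels[0]
        assert (lab[50:60] == NO_LABEL).all()
        sig_to_syll = {}
        for row, s in zip(map(tuple, mat), lab):
            if s == NO_LABEL:
                continue
            assert sig_to_syll.setdefault(row, s) == s

    def test_unseen_signature_falls_back_to_nearest(self, caplog):
        mat = np.array([[0, 0, 0]] * 10 + [[1, 1, 1]] * 10)
        per, cat = eq.build_signatures(_ensemble_from_label_matrix(mat))
        eq.cluster_signatures(cat, 2)
        new = np.array([[0, 0, 1]] * 3)  # closer to (0,0,0)
        asn = eq.assign_syllables([new], cat)
        expected = cat.syllable_map[np.where((cat.signatures == [0, 0, 0]).all(axis=1))[0][0]]
        assert (asn.labels[0] == expected).all()

    def test_consensus_recovers_generator_states(self, demo_model_5):
        """Ensemble + signature clustering to 5 syllables recovers the 5
        ground-truth states with ARI >= 0.8, and the consensus is no worse
        than the best single fit by more than 0.02."""
        cohort = eq.make_cohort(demo_model_5, {}, {"wt": 2}, minutes=2, fps=30, seed=31)
        sessions = [s for s, _ in cohort]
        pca = eq.fit_pca(sessions, n_components=5)
        scores = eq.transform_sessions(pca, sessions)
        masks = [s.valid_mask for s in sessions]
        ens = eq.run_ensemble(scores, masks, K=5, L=1, R=4, master_seed=2)
        per, cat = eq.build_signatures(ens)
        eq.cluster_signatures(cat, 5)
        asn = eq.assign_syllables(per, cat)
        truth = np.concatenate([g.states for _, g in cohort])
        lab = asn.pooled()
        ok = lab >= 0
        consensus_ari = adjusted_rand_score(truth[ok], lab[ok])
        assert consensus_ari >= 0.8
        single = []
        for f in ens.fits:
            sl = np.concatenate([s.labels for s in f.state_sequences])
            single.append(adjusted_rand_score(truth[sl >= 0], sl[sl >= 0]))
        assert consensus_ari >= max(single) - 0.02
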