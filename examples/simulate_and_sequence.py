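"""Simulate a small cohort and recover its behavioral states end to end.

Builds a 5-state switching-AR model, simulates four 2-minute sessions with
acquisition gaps, fits an ensemble of four ARHMMs, clusters the per-frame
ensemble signatures into consensus syllables, and scores recovery against
the generator's ground truth.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import ethoseq as eq

model = eq.build_demo_model(K=5, P=5)
cohort = eq.make_cohort(model, {}, {"wt": 2, "hom": 2}, minutes=2, fps=30, seed=0)
sessions = [s for s, _ in cohort]

pca = eq.fit_pca(sessions, n_components=5)
scores = eq.transform_sessions(pca, sessions)
masks = [s.valid_mask for s in sessions]

ensemble = eq.run_ensemble(scores, masks, K=5, L=1, R=4, master_seed=0)
per_frame, catalog = eq.build_signatures(ensemble)
eq.cluster_signatures(catalog, n_clusters=5)
assignment = eq.assign_syllables(per_frame, catalog)

truth = np.concatenate([g.states for _, g in cohort])
labels = assignment.pooled()
valid = labels >= 0
ari = adjusted_rand_score(truth[valid], labels[valid])

print(f"sessions: {len(sessions)} x {sessions[0].n_frames} frames at {sessions[0].fps:.0f} fps")
print(f"unique ensemble signatures: {catalog.n_unique}")
print(f"consensus syllables: {assignment.n_syllables}")
print(f"adjusted Rand index vs ground truth: {ari:.3f}")
print("ARI near 1 means the consensus syllables recover the generating"
      " behavioral states almost frame-perfectly despite 4 independent,"
      " differently-seeded model fits.")
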