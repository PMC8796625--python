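"""Per-animal syllable statistics and a genotype comparison.

Simulates a cohort in which mutants use syllable 0 half as much as
wild-types, computes frequency (min^-1), mean bout length (s) and time
proportion (%) per animal x syllable, then runs Kruskal-Wallis + Dunn
tests per syllable and metric.
"""

import numpy as np

import ethoseq as eq

model = eq.build_demo_model(K=5, P=5)
mult = eq.multiplier_for_occupancy(model, state=0, target_ratio=0.5)
cohort = eq.make_cohort(
    model, {"hom": {0: mult}}, {"wt": 6, "hom": 6}, minutes=2, fps=30, seed=1
)

# use the generator's ground-truth states as syllable labels (masked at gaps)
labels = [np.where(s.valid_mask, g.states, -1) for s, g in cohort]
table = eq.metrics_table(
    labels,
    [s.valid_mask for s, _ in cohort],
    fps=30.0,
    n_syllables=5,
    animal_ids=[s.animal_id for s, _ in cohort],
    genotypes=[s.genotype for s, _ in cohort],
)

means = table.groupby(["genotype", "syllable"])["proportion"].mean().unstack()
print("mean proportion (%) per genotype x syllable:")
print(means.round(2).to_string())

comparison = eq.compare_groups(table, alpha=0.05)
flagged = comparison[comparison.significant]
print("\nsignificant genotype differences (Dunn p < 0.05):")
print(flagged[["syllable", "metric", "group_a", "group_b", "dunn_z", "dunn_p"]]
      .round(4).to_string(index=False))
print("\nSyllable 0 should dominate the list: its occupancy was halved in"
      " 'hom' animals by construction. Secondary flags on other syllables"
      " can be real, too — time not spent in syllable 0 redistributes to"
      " the rest.")
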