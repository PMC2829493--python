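"""Compare observed PI occurrences against shuffled-operon nulls.

Builds a corpus with strong AW/RB co-operon structure, predicts pathways,
then re-runs the prediction on 100 shuffled corpora (gene-to-operon
allocation randomised; operon count, sizes and per-species gene content
fixed). The within-operon A~W signal should stand far outside the null
band, and the chi-square test of homogeneity should reject equality of the
observed and shuffled PI tables.
"""

import warnings

from cheops.null_models import chi_square_homogeneity, replicate_statistics
from cheops.pathway_inference import count_pi_occurrences, predict_corpus
from cheops.synthetic_data import SyntheticSpec, generate_corpus, truth_operons

weights = {"AW": 0.30, "RB": 0.25, "Y": 0.25, "ABRWY": 0.20}
spec = SyntheticSpec(n_species=40, seed=55, composition_weights=weights)
genes, truth = generate_corpus(spec)
operons = truth_operons(genes, truth)

observed = count_pi_occurrences(predict_corpus(operons, "ABRWY"))
null = replicate_statistics(operons, "ABRWY", n_reps=100, base_seed=55)

print(f"{'PI':<6}{'scope':<9}{'observed':>9}{'null mean':>11}{'2*SE':>8}")
for (pi_type, scope), row in observed.iterrows():
    mean = null.summary.loc[(pi_type, scope), "mean"]
    se = null.summary.loc[(pi_type, scope), "se"]
    print(f"{pi_type:<6}{scope:<9}{row['relative']:>9.3f}{mean:>11.3f}{2*se:>8.3f}")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    stat, df, p = chi_square_homogeneity(
        observed["occurrence"].to_numpy(), null.pi_counts.sum(axis=0).to_numpy()
    )
print(f"\nchi-square homogeneity: statistic={stat:.1f}, df={df}, p={p:.2e}")
print("relative occurrences are per-cell shares of all PI registrations;")
print("observed within A~W far above the null band marks the planted structure")
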