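"""Prognostic screening: dichotomise expression at the median and log-rank test.

Generates a 500-patient cohort with planted hazardous genes (hazard ratio 2
above the median) and screens every gene for association with outcome.
"""

from proximap.survival import screen_genes, screen_table
from proximap.synthetic import GeneratorConfig, generate_cohort

config = GeneratorConfig(seed=1, n_patients=500, n_cohort_genes=50, n_hazardous=5)
cohort, truth = generate_cohort(config)

results = screen_genes(cohort, cutoff_mode="median", alpha=0.05)
table = screen_table(results)
flagged = table[table["significant"]]
print(f"genes flagged at p < 0.05: {len(flagged)} of {len(table)}")
print(flagged.sort_values("p_value").head(8)[
    ["gene", "p_value", "direction", "n_low", "n_high"]
].to_string(index=False))

planted = set(truth.hazardous)
print(f"planted hazardous genes recovered: "
      f"{len(planted & set(flagged['gene']))}/{len(planted)}")
# With n = 500 and HR = 2 the median-split log-rank test has essentially
# full power; additional flags are null genes at the ~5% false-positive rate.
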