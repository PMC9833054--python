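"""Full cohort run: two genotypes, two days, with a performance deficit
configured for one group, then genotype contrasts from the summary table.

The same run is available from the shell:
    waterreach run-all --config examples/cohort.yaml

Run:  python examples/04_cohort_run.py
"""

from waterreach import RunConfig, genotype_compare, run

config = RunConfig(
    seed=5,
    out_dir="example_run",
    n_trials=40,
    cohort={"WT": ["wt1", "wt2"], "HD": ["hd1", "hd2"]},
    days=[8, 45],
    # On day 45 the HD group succeeds less often; the remaining category
    # mass is rescaled proportionally.
    day_params={"HD": {45: {"success": 0.35}}},
)

table = run(config)
print(table.to_string(index=False))
print()

# Genotype contrast: mean of per-animal values, SEM over animals.
for measure in ("success_frac", "path_mean"):
    print(genotype_compare(table, measure).to_string(index=False))
    print()
print("tables written to example_run/ (summary_table.csv, trial_records.csv)")
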