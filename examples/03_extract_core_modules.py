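"""Run the whole pipeline: extract and certify mutated core modules.

Candidate subnetworks are extracted by the multiplicative-update
optimisation and certified by the weight-sum significance test (p1) and the
switching-permutation exclusivity test (p2); a p-value printed as 0 means
none of the 1000 permutations reached the observed statistic (p < 0.001).
"""

from coremod import PlantConfig, RunConfig, evaluate_recovery, \
    generate_dataset, run_from_data

somatic, cnv, expression, truth = generate_dataset(PlantConfig(seed=11))
report = run_from_data(somatic, cnv, expression, RunConfig(seed=11))

for line in report.summary_lines():
    print(line)

print("\nextraction rounds (candidates before testing):")
for r in report.rounds:
    print(f"  {r['status']:>13}: {', '.join(r['candidate_units'])}")

rec = evaluate_recovery(report.modules, truth)
print(f"\nbest Jaccard vs the planted module: "
      f"{rec['per_module'][0]['best_jaccard']:.2f} "
      "(1.0 = exact recovery)")
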