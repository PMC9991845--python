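"""Simulate a matched study and score guideline adherence at suggested
cut-points.

Generates 150 age/area-matched case-control pairs with right-skewed
QFFQ-style intakes, aggregates item intakes into food-group exposures, and
scores the nine scorable dietary guidelines (0/0.5/1 each, max 9).
"""

import safbdg as sb

synthetic = sb.simulate_study(sb.SimulationConfig(n_pairs=150), seed=1)
study = synthetic.study
exposures = sb.aggregate_groups(study.intakes, study.nutrients,
                                sb.toy_foods())
scores = sb.score_suggested(exposures, study.participants)
prevalence = sb.adherence_prevalence(scores, study.participants["status"])

print(prevalence.round(1).to_string())
print()
print(f"Mean overall score: {scores['overall'].mean():.2f} / 9")
half = scores.groupby(study.participants["status"])["half_adherent"].mean()
print(f"Half adherence (> 4.5): cases {100 * half['case']:.1f} %, "
      f"controls {100 * half['control']:.1f} %")
print()
print("Each row is the percent of an arm meeting one recommendation (or "
      "sub-recommendation); low percentages reproduce the strongly "
      "one-sided adherence this population shows.")
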