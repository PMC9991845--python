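"""Tertile-based adherence scoring and the matched association analysis.

Re-scores each recommendation on control-derived tertiles of a continuous
compliance metric, categorises subjects by control overall-score tertiles,
and fits the 1:1 conditional logistic regression of case status on
adherence category. The generating conditional OR is 0.56.
"""

import safbdg as sb
from safbdg.stats import fit_category_contrasts, trend_test

synthetic = sb.simulate_study(sb.SimulationConfig(n_pairs=396), seed=1)
study = synthetic.study
exposures = sb.aggregate_groups(study.intakes, study.nutrients,
                                sb.toy_foods())
metrics = sb.compliance_metrics(exposures, study.participants)

controls = study.participants.index[study.participants["status"] == "control"]
cutpoints = sb.derive_cutpoints(metrics.loc[controls])
scores = sb.score_tertile(metrics, cutpoints)
categories, (q33, q66) = sb.overall_tertile_category(
    scores["overall"], controls)
print(f"Control overall-score tertile boundaries: low <= {q33:.2f}, "
      f"high > {q66:.2f}")

analysis = study.participants.reset_index()[["pair_id", "status"]].copy()
analysis["category"] = categories["category"].to_numpy()
fit = fit_category_contrasts(analysis, "category")
for term in ("mid_vs_low", "high_vs_low"):
    lo, hi = fit.ci95(term)
    print(f"{term}: OR {fit.or_(term):.2f} (95 % CI {lo:.2f}, {hi:.2f}), "
          f"p = {fit.p(term):.4f}")
trend = trend_test(analysis, "category")
print(f"Trend across tertiles: p = {trend.p_trend:.4f}")
print()
print("An OR below 1 for high_vs_low means higher guideline adherence is "
      "associated with lower breast-cancer odds within matched pairs; the "
      "estimate should sit near the generating OR of 0.56 up to sampling "
      "and tertile-derivation noise.")
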