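import collections

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import safbdg as sb
from safbdg.tertile import (
    METRIC_DEFS,
    TERTILE_PROBS,
    compliance_metrics,
    derive_cutpoints,
    overall_tertile_category,
    score_metric_tertile,
    score_tertile,
    skewness_report,
)

from conftest import make_exposures, make_participant


def _metric_frame(values, metric="fruit_veg"):
    frame = pd.DataFrame(
        {m.id: np.ones(len(values)) for m in METRIC_DEFS},
        index=pd.Index([f"s{i}" for i in range(len(values))],
                       name="subject_id"))
    # keep other metrics non-degenerate
    for m in METRIC_DEFS:
        frame[m.id] = np.linspace(1.0, 2.0, len(values))
    frame[metric] = np.asarray(values, dtype=float)
    return frame


class TestComplianceMetrics:
    def test_fat_range_distance(self):
        m = compliance_metrics(make_exposures(fat_pct_te=25.0),
                               make_participant())
        assert m["fats_range"].iloc[0] == 0.0
        m = compliance_metrics(make_exposures(fat_pct_te=35.0),
                               make_participant())
        assert m["fats_range"].iloc[0] == 5.0
        m = compliance_metrics(make_exposures(fat_pct_te=15.0),
                               make_participant())
        assert m["fats_range"].iloc[0] == 5.0

    def test_dairy_uses_cheese_equivalence(self):
        m = compliance_metrics(
            make_exposures(dairy_liquid_g=100.0, cheese_g=25.0),
            make_participant())
        assert m["dairy"].iloc[0] == pytest.approx(100.0 + 8 * 25.0)


class TestCutpoints:
    def test_uniform_grid(self):
        cp = derive_cutpoints(_metric_frame(np.arange(1.0, 100.0)))
        assert cp.q33["fruit_veg"] == pytest.approx(33.0)
        assert cp.q66["fruit_veg"] == pytest.approx(66.0)

    def test_constant_metric_warns_degenerate(self):
        with pytest.warns(sb.DegenerateCutpointWarning, match="legumes"):
            cp = derive_cutpoints(_metric_frame([5.0] * 30, metric="legumes"))
        assert cp.q33["legumes"] == cp.q66["legumes"] == 5.0

    def test_too_few_controls_rejected(self):
        with pytest.raises(sb.DomainError):
            derive_cutpoints(_metric_frame([1.0, 2.0]))

    def test_thirds_up_to_ties_on_continuous_metric(self):
        """Counting oracle: tie-free controls split ~1/3 per tertile."""
        rng = np.random.default_rng(4)
        vals = rng.normal(size=300)
        cp = derive_cutpoints(_metric_frame(vals))
        scores = score_metric_tertile(vals, cp.q33["fruit_veg"],
                                      cp.q66["fruit_veg"], "higher")
        counts = collections.Counter(scores)
        n = len(vals)
        assert counts[0.0] == int(np.ceil(TERTILE_PROBS[0] * n))
        assert counts[1.0] == n - int(np.ceil(TERTILE_PROBS[1] * n))
        for share in (counts[0.0] / n, counts[0.5] / n, counts[1.0] / n):
            assert abs(share - 1 / 3) < 0.02

    def test_yaml_round_trip(self, tmp_path):
        cp = derive_cutpoints(_metric_frame(np.arange(1.0, 100.0)))
        cp.to_yaml(tmp_path / "cp.yaml")
        import yaml
        data = yaml.safe_load((tmp_path / "cp.yaml").read_text())
        assert data["metrics"]["fruit_veg"]["q33"] == pytest.approx(33.0)


class TestTertileScores:
    def test_orientation(self):
        assert score_metric_tertile(10.0, 3.0, 6.0, "higher") == 1.0
        assert score_metric_tertile(10.0, -6.0, -3.0, "lower") == 0.0
        assert score_metric_tertile(1.0, -6.0, -3.0, "lower") == 1.0

    def test_ties_fall_to_lower_tertile(self):
        assert score_metric_tertile(6.0, 3.0, 6.0, "higher") == 0.5
        assert score_metric_tertile(3.0, 3.0, 6.0, "higher") == 0.0

    def test_sub_recommendations_average_to_quarter_steps(self):
        """Both fats subs in the middle tertile give 0.25 + 0.25 = 0.5."""
        controls = _metric_frame(np.arange(1.0, 100.0))
        cp = derive_cutpoints(controls)
        metrics = controls.iloc[[0]].copy()
        for sub in ("fats_range", "fats_sfa"):
            # lower-better: mid tertile means between the oriented cuts
            metrics[sub] = -0.5 * (cp.q33[sub] + cp.q66[sub])
        scores = score_tertile(metrics, cp)
        assert scores["fats_range"].iloc[0] == 0.25
        assert scores["fats_sfa"].iloc[0] == 0.25
        assert scores["fats"].iloc[0] == 0.5

    def test_components_on_quarter_grid_and_overall_sum(self,
                                                        small_synthetic,
                                                        mapping):
        study = small_synthetic.study
        exposures = sb.aggregate_groups(study.intakes, study.nutrients,
                                        mapping)
        metrics = compliance_metrics(exposures, study.participants)
        controls = study.participants["status"] == "control"
        cp = derive_cutpoints(metrics[controls])
        scores = score_tertile(metrics, cp)
        guideline_cols = list(sb.GUIDELINES)
        values = scores[guideline_cols].to_numpy()
        assert np.isin(values, [0.0, 0.25, 0.5, 0.75, 1.0]).all()
        np.testing.assert_allclose(scores["overall"],
                                   scores[guideline_cols].sum(axis=1))
        assert scores["overall"].between(0, 9).all()

    @given(st.sampled_from(["exp", "cube", "affine", "logish"]))
    def test_invariance_under_strictly_monotone_transforms(self, name):
        transforms = {
            "exp": np.exp,
            "cube": lambda x: x ** 3,
            "affine": lambda x: 2.5 * x + 7.0,
            "logish": lambda x: np.log1p(np.abs(x)) * np.sign(x) + x / 10.0,
        }
        f = transforms[name]
        rng = np.random.default_rng(17)
        controls = rng.normal(size=120)
        out_of_sample = rng.normal(size=200)
        cp_raw = derive_cutpoints(_metric_frame(controls))
        cp_tr = derive_cutpoints(_metric_frame(f(controls)))
        s_raw = score_metric_tertile(out_of_sample, cp_raw.q33["fruit_veg"],
                                     cp_raw.q66["fruit_veg"], "higher")
        s_tr = score_metric_tertile(f(out_of_sample), cp_tr.q33["fruit_veg"],
                                    cp_tr.q66["fruit_veg"], "higher")
        np.testing.assert_array_equal(s_raw, s_tr)

    def test_raising_sugar_never_raises_score(self):
        controls = _metric_frame(np.linspace(1, 20, 60), metric="sugar")
        cp = derive_cutpoints(controls)
        grid = np.linspace(0, 25, 200)
        scores = score_metric_tertile(grid, cp.q33["sugar"], cp.q66["sugar"],
                                      "lower")
        assert (np.diff(scores) <= 0).all()

    def test_nan_metric_flags_subject(self):
        controls = _metric_frame(np.arange(1.0, 100.0))
        cp = derive_cutpoints(controls)
        metrics = controls.iloc[[0]].copy()
        metrics["sugar"] = np.nan
        scores = score_tertile(metrics, cp)
        assert bool(scores["incomplete"].iloc[0])
        assert np.isfinite(scores["overall"].iloc[0])


class TestOverallCategory:
    def test_counting_oracle_three_three_three(self):
        overall = pd.Series(
            [3.0, 3.0, 3.0, 5.0, 5.0, 5.0, 6.0, 6.0, 6.0],
            index=[f"s{i}" for i in range(9)])
        frame, (q33, q66) = overall_tertile_category(overall, overall.index)
        assert q33 == 3.0 and q66 == 5.0
        counts = frame["category"].value_counts()
        assert counts["low"] == counts["mid"] == counts["high"] == 3

    def test_identical_scores_collapse_with_warning(self):
        overall = pd.Series([4.0] * 10, index=[f"s{i}" for i in range(10)])
        with pytest.warns(sb.DegenerateCutpointWarning):
            frame, _ = overall_tertile_category(overall, overall.index)
        assert set(frame["category"]) == {"low"}

    def test_too_few_controls_rejected(self):
        overall = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(sb.DomainError):
            overall_tertile_category(overall, ["a", "b"])

    def test_synthetic_default_reproduces_published_boundaries(self):
        """Control overall-score tertile bounds near the reported 3.5 / 5.0."""
        syn = sb.simulate_study(sb.SimulationConfig(n_pairs=250), seed=23)
        study = syn.study
        exposures = sb.aggregate_groups(study.intakes, study.nutrients,
                                        sb.toy_foods())
        metrics = compliance_metrics(exposures, study.participants)
        controls = study.participants.index[
            study.participants["status"] == "control"]
        cp = derive_cutpoints(metrics.loc[controls])
        scores = score_tertile(metrics, cp)
        _, (q33, q66) = overall_tertile_category(scores["overall"], controls)
        assert 2.8 <= q33 <= 4.2
        assert 4.0 <= q66 <= 6.0


class TestSkewness:
    def _scores(self, case_split, control_split, n=100):
        rows = []
        for arm, split in (("case", case_split), ("control", control_split)):
            n_adh = int(round(split * n))
            rows += [{"arm": arm, "fruit_veg": 1.0}] * n_adh
            rows += [{"arm": arm, "fruit_veg": 0.0}] * (n - n_adh)
        df = pd.DataFrame(rows)
        df.index = pd.Index([f"s{i}" for i in range(len(df))],
                            name="subject_id")
        for g in sb.GUIDELINES:
            if g != "fruit_veg":
                df[g] = np.tile([0.0, 1.0], len(df) // 2)
        return df[list(sb.GUIDELINES)], df["arm"]

    def test_eighty_twenty_both_arms_flagged(self):
        scores, status = self._scores(0.8, 0.8)
        report = skewness_report(scores, status)
        assert bool(report.loc["fruit_veg", "skewed"])

    def test_fifty_fifty_not_flagged(self):
        scores, status = self._scores(0.5, 0.5)
        report = skewness_report(scores, status)
        assert not bool(report.loc["fruit_veg", "skewed"])

    def test_matches_brute_force_tabulation(self, small_synthetic, mapping):
        study = small_synthetic.study
        exposures = sb.aggregate_groups(study.intakes, study.nutrients,
                                        mapping)
        scores = sb.score_suggested(exposures, study.participants)
        status = study.participants["status"]
        report = skewness_report(scores, status)
        for g in sb.GUIDELINES:
            flags = []
            for arm in ("case", "control"):
                counter = collections.Counter(scores.loc[status == arm, g])
                flags.append(max(counter.values()) / sum(counter.values()))
            assert bool(report.loc[g, "skewed"]) == (
                flags[0] >= 0.73 and flags[1] >= 0.73)
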