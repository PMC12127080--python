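"""DID designs: 2x2 identity, event study, moderation, per-outcome loop."""

import numpy as np
import pandas as pd
import pytest

from staggerdid import (CohortConfig, EventStudy, ModelSpec, ModerationSpec,
                        PolicySchedule, build_pan_cancer_outcome,
                        build_treatment_indicator, estimate_did,
                        estimate_event_study, estimate_moderation,
                        estimate_per_outcome, forest_frame, generate_panel,
                        generate_policy_schedule)


def _two_period_panel(rng, n_per_cell=50):
    """Two regions, two waves, one region adopts in the second wave."""
    rows = []
    means = {("T", 2011): 100, ("T", 2013): 60, ("C", 2011): 90, ("C", 2013): 95}
    k = 0
    for region in ("T", "C"):
        for wave in (2011, 2013):
            p = means[(region, wave)] / 1000
            for _ in range(n_per_cell):
                rows.append({
                    "individual_id": f"i{k}", "region_id": region, "wave": wave,
                    "cancer": int(rng.random() < p) * 1000,
                })
                k += 1
    return pd.DataFrame(rows)


class TestTwoByTwoIdentity:
    def test_equals_difference_in_means(self, rng):
        """With two periods and simultaneous adoption the regression DID
        equals the four-cell difference of group x period means."""
        panel = _two_period_panel(rng)
        sched = PolicySchedule({"T": 2013}, regions=("T", "C"))
        spec = ModelSpec(cluster=None)
        res = estimate_did(panel, sched, spec)
        cell = panel.groupby(["region_id", "wave"])["cancer"].mean()
        manual = (cell["T", 2013] - cell["T", 2011]) - \
                 (cell["C", 2013] - cell["C", 2011])
        assert res.treatment_effect() == pytest.approx(manual, abs=1e-8)

    def test_no_treated_observations_errors(self, rng):
        panel = _two_period_panel(rng)
        sched = PolicySchedule({}, regions=("T", "C"))
        with pytest.raises(ValueError, match="no treated"):
            estimate_did(panel, sched, ModelSpec(cluster=None))


class TestInvariances:
    def test_region_relabeling_and_row_order(self, small_panel, small_schedule,
                                             demo_spec, rng):
        base = estimate_did(small_panel, small_schedule, demo_spec)
        # permute record order
        shuffled = small_panel.sample(frac=1.0, random_state=3)
        got = estimate_did(shuffled, small_schedule, demo_spec)
        assert got.treatment_effect() == pytest.approx(
            base.treatment_effect(), abs=1e-9)
        # relabel regions consistently
        mapping = {r: f"Z{r}" for r in small_schedule.regions}
        renamed = small_panel.copy()
        renamed["region_id"] = renamed["region_id"].map(mapping)
        sched2 = PolicySchedule(
            {mapping[r]: y for r, y in small_schedule.adoption.items()},
            regions=tuple(mapping[r] for r in small_schedule.regions))
        got2 = estimate_did(renamed.drop(columns=["cetp_post", "treated"]),
                            sched2, demo_spec)
        assert got2.treatment_effect() == pytest.approx(
            base.treatment_effect(), abs=1e-9)


class TestEventStudy:
    def test_reference_outside_window_errors(self, small_panel, small_schedule):
        with pytest.raises(ValueError, match="outside window"):
            EventStudy(small_panel, small_schedule, pre_periods=2,
                       post_periods=3, reference=-5)

    def test_curve_invariants(self, small_panel, small_schedule, demo_spec):
        curve = estimate_event_study(small_panel, small_schedule, demo_spec)
        frame = curve.to_frame()
        assert frame["period"].is_monotonic_increasing
        ref = frame[frame.is_reference]
        assert len(ref) == 1
        assert ref["coef"].iloc[0] == 0.0
        assert ref["ci_low"].iloc[0] == 0.0 == ref["ci_high"].iloc[0]

    def test_post_coefficients_track_effect(self):
        """Post-adoption coefficients sit near tau, pre-period ones near 0."""
        cfg = CohortConfig(n_regions=60, treated_cohorts=((2013, 3), (2014, 2), (2016, 1)),
                           n_individuals_per_region=300, treatment_effect=-60.0,
                           covariate_effects={}, seed=17)
        sched = generate_policy_schedule(cfg)
        panel = build_treatment_indicator(generate_panel(cfg, sched), sched)
        curve = estimate_event_study(panel, sched, ModelSpec(covariates=()))
        pre = curve.pre_periods()
        post = curve.post_periods()
        assert ((pre.ci_low <= 0) & (pre.ci_high >= 0)).all()
        assert (post.coef < -20).all()

    def test_post_average_approximates_did(self):
        """Treated-observation-weighted mean of post-period coefficients
        approximates the single DID coefficient under homogeneous effects."""
        cfg = CohortConfig(n_regions=60, treated_cohorts=((2013, 3), (2014, 2), (2016, 1)),
                           n_individuals_per_region=300, treatment_effect=-60.0,
                           covariate_effects={}, seed=19)
        sched = generate_policy_schedule(cfg)
        panel = build_treatment_indicator(generate_panel(cfg, sched), sched)
        spec = ModelSpec(covariates=())
        did = estimate_did(panel, sched, spec).treatment_effect()
        es = EventStudy(panel, sched, spec)
        curve = es.fit()
        post = curve.post_periods()
        weights = [es.panel[f"rel[{p}]"].sum() for p in post.period]
        avg = np.average(post.coef, weights=weights)
        assert avg == pytest.approx(did, abs=10.0)


class TestModeration:
    def _setup(self, moderation, tau=-10.0, seed=23, n=100):
        cfg = CohortConfig(n_regions=40, treated_cohorts=((2013, 3), (2014, 2), (2016, 1)),
                           n_individuals_per_region=n, treatment_effect=tau,
                           moderation_effect=moderation, seed=seed)
        sched = generate_policy_schedule(cfg)
        panel = build_treatment_indicator(generate_panel(cfg, sched), sched)
        return panel, sched

    def test_zero_moderator_reduces_to_plain_did(self, demo_spec):
        panel, sched = self._setup(0.0)
        panel = panel.copy()
        panel["null_mod"] = 0.0
        plain = estimate_did(panel, sched, demo_spec)
        mod = estimate_moderation(panel, sched,
                                  ModerationSpec("null_mod", demo_spec))
        assert mod.params["cetp_post"] == pytest.approx(
            plain.treatment_effect(), abs=1e-9)
        assert any("identically zero" in n for n in mod.notes)

    def test_constant_nonzero_moderator_errors(self, demo_spec):
        panel, sched = self._setup(0.0)
        panel = panel.copy()
        panel["const_mod"] = 2.5
        with pytest.raises(ValueError, match="constant"):
            estimate_moderation(panel, sched,
                                ModerationSpec("const_mod", demo_spec))

    def test_interaction_sign_structure(self, demo_spec):
        """Moderator raising risk, policy x moderator lowering it — the
        qualitative pattern of the depression-score moderation."""
        panel, sched = self._setup(-3.0, n=250, seed=29)
        res = estimate_moderation(panel, sched,
                                  ModerationSpec("cesd", demo_spec))
        assert res.params["cesd"] > 0
        assert res.params["cetp_post:cesd"] < 0
        lo, hi = res.wald_interval("cetp_post:cesd")
        assert hi < 0  # significantly negative


class TestPanCancer:
    SIX = ("endometrium", "cervix", "stomach", "esophagus", "breast", "lung")

    def _panel(self):
        base = {
            "individual_id": ["a", "b", "c"], "region_id": ["r"] * 3,
            "wave": [2011] * 3,
        }
        frame = pd.DataFrame(base)
        for site in self.SIX + ("liver",):
            frame[site] = 0
        frame.loc[0, "cervix"] = 1000   # in the six
        frame.loc[1, "liver"] = 1000    # outside the six
        return frame

    def test_member_site_flags_composite(self):
        out = build_pan_cancer_outcome(self._panel(), self.SIX)
        assert out["pan_cancer"].tolist() == [1000, 0, 0]

    def test_all_zero_outcomes(self):
        frame = self._panel()
        frame[list(self.SIX)] = 0
        out = build_pan_cancer_outcome(frame, self.SIX)
        assert (out["pan_cancer"] == 0).all()

    def test_empty_list_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            build_pan_cancer_outcome(self._panel(), [])


class TestPerOutcomeLoop:
    def test_results_in_input_order_and_consistency(self, small_config,
                                                    small_schedule):
        cfg = small_config.replace(cancer_catalog={
            "lung": (30.0, -15.0), "liver": (18.0, 0.0), "skin": (4.0, 0.0)})
        panel = build_treatment_indicator(generate_panel(cfg, small_schedule),
                                          small_schedule)
        spec = ModelSpec(covariates=("female", "age"))
        outcomes = ["lung", "liver", "skin"]
        results = estimate_per_outcome(panel, small_schedule, spec, outcomes)
        assert len(results) == 3
        frame = forest_frame(results, outcomes)
        assert frame["outcome"].tolist() == outcomes
        single = estimate_did(panel, small_schedule, spec.replace(outcome="lung"))
        assert results[0].treatment_effect() == pytest.approx(
            single.treatment_effect(), abs=1e-10)

    def test_bh_flag_appends_adjusted_p(self, small_config, small_schedule):
        cfg = small_config.replace(cancer_catalog={
            "lung": (30.0, 0.0), "liver": (18.0, 0.0)})
        panel = build_treatment_indicator(generate_panel(cfg, small_schedule),
                                          small_schedule)
        spec = ModelSpec(covariates=())
        results = estimate_per_outcome(panel, small_schedule, spec,
                                       ["lung", "liver"], bh_correct=True)
        assert all(any(n.startswith("bh_adjusted_p=") for n in r.notes)
                   for r in results)
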