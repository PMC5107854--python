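"""Group assignment, ROC cutoffs, ANOVA/Scheffé, and cohort reporting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import respstab as rs
from respstab.errors import AnalysisError, InputError

from oracles import brute_force_auc, oneway_f


class TestClassifyTrace:
    def test_regular_group_a_indices(self):
        """Cohort-mean indices of an all-regular pattern (SD_x 0.069,
        A1 0.178, MUD-MDD 0.242) sit on the regular side of every
        cutoff."""
        rep = rs.classify_trace(sd_x=0.069, sd_v=0.053, a1=0.178,
                                mud_mdd=0.242)
        assert rep.group == "A"
        assert rep.drift_present is False

    def test_doubly_irregular_with_drift(self):
        rep = rs.classify_trace(sd_x=0.251, sd_v=0.095, a1=0.078,
                                mud_mdd=0.793)
        assert rep.group == "D"
        assert rep.drift_present is True

    def test_all_four_quadrants(self):
        cases = {(0.05, 0.2): "A", (0.05, 0.05): "B",
                 (0.3, 0.2): "C", (0.3, 0.05): "D"}
        for (sd_x, a1), expected in cases.items():
            rep = rs.classify_trace(sd_x=sd_x, sd_v=0.05, a1=a1,
                                    mud_mdd=0.1)
            assert rep.group == expected

    def test_boundary_is_regular(self):
        """Values exactly at a cutoff classify as regular (inclusive
        convention)."""
        rep = rs.classify_trace(sd_x=0.11, sd_v=0.062, a1=0.117,
                                mud_mdd=0.349)
        assert rep.group == "A"
        assert rep.drift_present is False

    def test_a1_direction_higher_is_more_regular(self):
        low = rs.classify_trace(sd_x=0.05, sd_v=0.03, a1=0.05, mud_mdd=0.1)
        high = rs.classify_trace(sd_x=0.05, sd_v=0.03, a1=0.50, mud_mdd=0.1)
        assert low.period_regular is False
        assert high.period_regular is True

    def test_nonfinite_rejected(self):
        with pytest.raises(InputError):
            rs.classify_trace(sd_x=np.nan, sd_v=0.05, a1=0.2, mud_mdd=0.1)

    def test_amp_rule_variants(self):
        kwargs = dict(sd_v=0.1, a1=0.2, mud_mdd=0.1)   # sd_v irregular
        assert rs.classify_trace(sd_x=0.05, **kwargs).group == "A"
        assert rs.classify_trace(sd_x=0.05, amp_rule="sd_v",
                                 **kwargs).group == "C"
        assert rs.classify_trace(sd_x=0.05, amp_rule="both",
                                 **kwargs).group == "C"

    def test_cutoff_validation(self):
        with pytest.raises(InputError):
            rs.Cutoffs(sd_x_cut=0.0)


class TestRocCutoff:
    def test_perfect_separation(self):
        res = rs.roc_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert res.cutoff == pytest.approx(0.5)
        assert res.sensitivity == 1.0
        assert res.specificity == 1.0

    def test_complete_ties(self):
        res = rs.roc_cutoff([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1])
        assert res.auc == 0.5

    def test_interleaved(self):
        """3 of 4 positive-negative pairs concordant."""
        res = rs.roc_cutoff([1, 2, 3, 4], [0, 1, 0, 1])
        assert res.auc == pytest.approx(0.75)

    def test_orientation_flip(self):
        fwd = rs.roc_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        rev = rs.roc_cutoff([-0.1, -0.2, -0.8, -0.9], [0, 0, 1, 1])
        assert rev.auc == fwd.auc == 1.0
        assert rev.flipped is True
        assert rev.cutoff == pytest.approx(-0.5)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            rs.roc_cutoff([1, 2, 3], [1, 1, 1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-5, 5, allow_nan=False, width=32),
                    min_size=4, max_size=60),
           st.data())
    def test_auc_matches_brute_force_pair_counting(self, scores, data):
        labels = data.draw(st.lists(st.integers(0, 1),
                                    min_size=len(scores),
                                    max_size=len(scores)))
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        res = rs.roc_cutoff(scores, labels)
        expected = brute_force_auc(scores, labels)
        expected = max(expected, 1.0 - expected)
        assert res.auc == pytest.approx(expected, abs=1e-12)


class TestAnovaScheffe:
    def test_two_group_textbook_f(self):
        """Groups {1,2,3} and {4,5,6}: SSB 13.5, SSW 4, df (1,4)."""
        res = rs.anova_scheffe({"g1": [1, 2, 3], "g2": [4, 5, 6]})
        assert res.F == pytest.approx(13.5, abs=1e-10)
        assert res.F == pytest.approx(
            oneway_f([[1, 2, 3], [4, 5, 6]]), abs=1e-10)
        assert res.subsets == "g1 < g2"

    def test_zero_variance_rejected(self):
        with pytest.raises(AnalysisError):
            rs.anova_scheffe({"a": [1, 1], "b": [1, 1]})

    def test_too_few_groups_rejected(self):
        with pytest.raises(InputError):
            rs.anova_scheffe({"a": [1, 2, 3]})

    def test_well_separated_four_groups(self):
        rng = np.random.default_rng(1)
        groups = {name: rng.normal(loc, 0.25, size=15)
                  for name, loc in zip("ABCD", [0.0, 0.1, 1.0, 1.1])}
        res = rs.anova_scheffe(groups)
        assert res.p < 1e-6
        assert res.subsets == "A, B < C, D"

    def test_null_rejection_rate_calibrated(self):
        """Type-I error of the F test at alpha 0.05 over seeded null
        simulations."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            groups = {k: rng.normal(size=20) for k in "ABCD"}
            if rs.anova_scheffe(groups).p < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_sim <= 0.08


class TestCohortReport:
    def test_single_trace(self, quiet_config):
        trace, _ = rs.generate_trace(rs.preset("A", seed=0))
        rep = rs.cohort_report([trace], config=quiet_config)
        assert len(rep.table) == 1
        assert rep.anova == {}

    def test_labeled_cohort_statistics(self, quiet_config):
        traces, labels = [], []
        for group, drift in (("A", False), ("C", True)):
            for seed in range(8):
                tr, _ = rs.generate_trace(rs.preset(group, drift=drift,
                                                    seed=seed))
                traces.append(tr)
                labels.append(group)
        rep = rs.cohort_report(traces, labels=labels, config=quiet_config)
        assert rep.group_stats is not None
        # amplitude irregularity is separable by construction
        assert rep.roc["sd_x"].auc > 0.9
        assert rep.anova["sd_x"].p < 0.01

    def test_failed_trace_flagged_not_raised(self, quiet_config):
        good, _ = rs.generate_trace(rs.preset("A", seed=0))
        t = np.arange(200) / 25.0
        flat = rs.RespTrace(t=t, x=np.zeros(200), fs=25.0)
        rep = rs.cohort_report([good, flat], config=quiet_config)
        assert len(rep.table) == 2
        assert rep.table.loc[1, "error"] != ""
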