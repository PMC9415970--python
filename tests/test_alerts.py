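"""Alert detection and summary statistics."""

import numpy as np
import pytest

from breathalert.alerts import (
    AlertSeries,
    alert_fraction,
    cohort_summary,
    detect_alerts,
    detect_bivariate_alerts,
    ra_la_counts,
)
from breathalert.baseline import (
    BivariateFrame,
    GaussianBaseline,
    QuantileThresholds,
    fit_bivariate_frame,
    fit_gaussian_baseline,
)
from breathalert.exceptions import AlignmentError, ContractError
from breathalert.windowed_features import FeatureSeries, WindowSpec


def feature_series(values, kind="amplitude", subject="s1", variant="combined"):
    return FeatureSeries(kind=kind, values=np.asarray(values, float),
                         window=WindowSpec(12), source_subject=subject, variant=variant)


def unit_baseline(kind="amplitude"):
    return GaussianBaseline(mu=0.0, sigma=1.0, alpha=1.0, lower=-1.0, upper=1.0,
                            feature_kind=kind)


class TestDetectAlerts:
    def test_huge_alpha_silences_everything(self, rng):
        train = feature_series(rng.uniform(0, 1, 500))
        test = feature_series(rng.uniform(0, 1, 500))
        base = fit_gaussian_baseline(train, alpha=1e6)
        assert detect_alerts(test, base).n_alerts == 0

    def test_upper_only_rate_matches_gaussian_tail(self):
        # Held-out same-distribution features alert at 1 - Phi(1.5).
        from scipy.stats import norm
        rng = np.random.default_rng(99)
        base = fit_gaussian_baseline(feature_series(rng.standard_normal(10_000)), 1.5)
        alerts = detect_alerts(feature_series(rng.standard_normal(10_000)), base, "upper_only")
        expected = 1 - norm.cdf(1.5)
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert alerts.fraction == pytest.approx(expected, abs=3 * se)

    def test_sides_follow_direction_of_violation(self):
        alerts = detect_alerts(feature_series([2.0, -2.0, 0.0]), unit_baseline())
        assert list(alerts.flags) == [True, True, False]
        assert list(alerts.sides) == ["above", "below", "none"]

    def test_deep_and_shallow_breath_rules(self):
        # Deep breathing: moving max above the band; shallow: moving min below.
        deep = detect_alerts(feature_series([2.0, 0.5], kind="moving_max"),
                             unit_baseline("moving_max"), "upper_only")
        assert list(deep.sides) == ["above", "none"]
        shallow = detect_alerts(feature_series([-2.0, 0.5], kind="moving_min"),
                                unit_baseline("moving_min"), "lower_only")
        assert list(shallow.sides) == ["below", "none"]

    def test_values_exactly_at_threshold_do_not_alert(self):
        alerts = detect_alerts(feature_series([1.0, -1.0]), unit_baseline())
        assert alerts.n_alerts == 0

    def test_two_sided_is_union_of_one_sided(self, rng):
        test = feature_series(rng.standard_normal(300))
        base = unit_baseline()
        both = detect_alerts(test, base, "two_sided").flags
        up = detect_alerts(test, base, "upper_only").flags
        lo = detect_alerts(test, base, "lower_only").flags
        assert (both == (up | lo)).all()
        assert not (up & lo).any()

    def test_fraction_nonincreasing_in_alpha(self, rng):
        train = feature_series(rng.standard_normal(2000))
        test = feature_series(rng.standard_normal(2000))
        fracs = [detect_alerts(test, fit_gaussian_baseline(train, a)).fraction
                 for a in (0.5, 1.0, 1.5, 2.0, 3.0)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_kind_mismatch_rejected(self):
        with pytest.raises(ContractError):
            detect_alerts(feature_series([1.0], kind="moving_min"), unit_baseline("moving_max"))

    def test_quantile_baseline_reproduces_training_fraction(self, rng):
        from breathalert.baseline import fit_quantile_thresholds
        v = rng.standard_normal(2000)
        thr = fit_quantile_thresholds(feature_series(v), 0.05)
        alerts = detect_alerts(feature_series(v), thr, "two_sided")
        assert abs(alerts.fraction - 0.05) <= 1 / 2000


class TestBivariateAlerts:
    def frame(self):
        q = lambda lo, up: QuantileThresholds(lo, up, 0.05)
        return BivariateFrame(q(-1, 1), q(-2, 2), 0.05, jitter_seed=0, jitter_halfwidth=0.5)

    def test_centroid_points_never_alert(self):
        x = feature_series(np.zeros(10), kind="dominant_frequency")
        y = feature_series(np.zeros(10), kind="dominant_frequency")
        assert detect_bivariate_alerts(x, y, self.frame()).n_alerts == 0

    def test_outside_both_axes_counts_once(self):
        x = feature_series([5.0, 0.0], kind="dominant_frequency")
        y = feature_series([5.0, 0.0], kind="dominant_frequency")
        alerts = detect_bivariate_alerts(x, y, self.frame())
        assert alerts.n_alerts == 1

    def test_identically_distributed_test_set_matches_fraction(self):
        rng = np.random.default_rng(5)
        xt, yt = rng.standard_normal((2, 4000))
        frame = fit_bivariate_frame(
            feature_series(xt, kind="dominant_frequency"),
            feature_series(yt, kind="dominant_frequency"), 0.05, jitter_seed=5,
            jitter_halfwidth=1e-9)
        xs, ys = rng.standard_normal((2, 4000))
        alerts = detect_bivariate_alerts(
            feature_series(xs, kind="dominant_frequency"),
            feature_series(ys, kind="dominant_frequency"), frame)
        assert alerts.fraction == pytest.approx(0.05, abs=0.015)

    def test_alignment_enforced(self):
        with pytest.raises(AlignmentError):
            detect_bivariate_alerts(feature_series([1.0, 2.0]), feature_series([1.0]), self.frame())


class TestSummaries:
    def make_alerts(self, flags, values=None, subject="s1", variant="combined"):
        flags = np.asarray(flags, bool)
        values = np.zeros(flags.size) if values is None else np.asarray(values, float)
        sides = np.where(flags, "above", "none").astype(object)
        return AlertSeries(flags, sides, values, "amplitude", subject, variant)

    def test_alert_fraction_counts(self):
        assert alert_fraction(self.make_alerts([False] * 5)) == 0.0
        assert alert_fraction(self.make_alerts([True] * 5)) == 1.0
        assert alert_fraction(self.make_alerts([True] * 3 + [False] * 9)) == 0.25

    def test_empty_series_has_no_fraction(self):
        empty = self.make_alerts([])
        with pytest.raises(ContractError):
            alert_fraction(empty)

    def test_ra_la_split_by_training_mean(self):
        base = unit_baseline()
        values = np.array([2.0, -2.0, 3.0, 0.5])
        feats = feature_series(values)
        alerts = detect_alerts(feats, base, "two_sided")
        counts = ra_la_counts(feats, alerts, base)
        assert (counts.ra, counts.la) == (2, 1)
        assert counts.window_size == 12

    def test_ra_la_no_alerts(self):
        base = unit_baseline()
        feats = feature_series([0.1, -0.2])
        counts = ra_la_counts(feats, detect_alerts(feats, base), base)
        assert (counts.ra, counts.la) == (0, 0)

    def test_ra_la_values_at_mean_count_neither(self):
        # Degenerate sigma=0 baseline: any deviation alerts, but a value
        # exactly at the mean is neither right nor left of it.
        base = GaussianBaseline(mu=1.0, sigma=0.0, alpha=1.5, lower=1.0, upper=1.0)
        feats = feature_series([1.0, 2.0])
        alerts = detect_alerts(feats, base, "two_sided")
        counts = ra_la_counts(feats, alerts, base)
        assert alerts.n_alerts == 1 and (counts.ra, counts.la) == (1, 0)

    def test_ra_exceeds_la_under_upward_shift(self, rng):
        train = feature_series(rng.standard_normal(1000))
        base = fit_gaussian_baseline(train, 1.5)
        shifted = feature_series(rng.standard_normal(1000) + 3 * base.sigma)
        alerts = detect_alerts(shifted, base, "two_sided")
        counts = ra_la_counts(shifted, alerts, base)
        assert counts.ra > counts.la

    def test_cohort_summary_single_subject(self):
        table = cohort_summary([self.make_alerts([True, False, False, False])])
        row = table.iloc[0]
        assert row.mean_fraction == 0.25 and row.sd_fraction == 0.0 and row.n_subjects == 1

    def test_cohort_summary_two_pass_oracle(self):
        a = self.make_alerts([True, False, False, False, False], subject="s1")  # 0.2
        b = self.make_alerts([True, True, False, False, False], subject="s2")  # 0.4
        table = cohort_summary([a, b])
        fracs = [0.2, 0.4]
        mean = sum(fracs) / 2
        sd = (sum((f - mean) ** 2 for f in fracs) / 2) ** 0.5
        row = table.iloc[0]
        assert row.mean_fraction == pytest.approx(0.3)
        assert row.sd_fraction == pytest.approx(sd)

    def test_variant_mixing_rejected(self):
        a = self.make_alerts([True], variant="talking")
        b = self.make_alerts([False], variant="combined", subject="s2")
        with pytest.raises(ContractError):
            cohort_summary([a, b], require_variant="talking")

    def test_duplicate_subject_in_group_rejected(self):
        with pytest.raises(ContractError):
            cohort_summary([self.make_alerts([True]), self.make_alerts([False])])

    def test_empty_collection_rejected(self):
        with pytest.raises(ContractError):
            cohort_summary([])

    def test_sides_contract_enforced(self):
        with pytest.raises(ContractError):
            AlertSeries(np.array([True]), np.array(["none"], object),
                        np.array([1.0]), "amplitude")
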