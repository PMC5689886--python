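"""Retrospective failure counting, report assembly and figures."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qadb.audit import (
    AuditConfig,
    StratumPolicy,
    audit_report,
    count_limit_failures,
    default_dose_limits,
    default_gamma_limits,
    render_figures,
)
from qadb.limits import LimitPolicy, LimitSet
from qadb.records import CohortTable
from qadb.synthetic import default_config, generate_cohort

from conftest import make_record


IPLAN_LIMITS = LimitSet(al_low=-4.4, al_high=2.2, tl_low=-5.0, tl_high=3.9)


def dose_table(values):
    return CohortTable(
        records=tuple(
            make_record(record_id=f"R{i}", mean_dose_diff_pct=v)
            for i, v in enumerate(values)
        )
    )


class TestCountFailures:
    def test_empty_cohort_gives_zero_counts(self):
        fc = count_limit_failures(
            CohortTable(records=()), IPLAN_LIMITS, "mean_dose_diff_pct"
        )
        assert (
            fc.n_total, fc.n_fail_al_low, fc.n_fail_al_high,
            fc.n_fail_tl_low, fc.n_fail_tl_high,
        ) == (0, 0, 0, 0, 0)

    def test_strict_inequality_counting(self):
        # {−4.5, 0, 2.5}: AL failures 2 (−4.5 below −4.4, 2.5 above 2.2),
        # TL failures 0 (neither crosses −5.0 / 3.9)
        fc = count_limit_failures(
            dose_table([-4.5, 0.0, 2.5]), IPLAN_LIMITS, "mean_dose_diff_pct"
        )
        assert fc.n_fail_al_low == 1 and fc.n_fail_al_high == 1
        assert fc.n_fail_tl_low == 0 and fc.n_fail_tl_high == 0

    def test_value_exactly_on_limit_passes(self):
        fc = count_limit_failures(
            dose_table([2.2, -4.4]), IPLAN_LIMITS, "mean_dose_diff_pct"
        )
        assert fc.n_fail_al_low == fc.n_fail_al_high == 0

    def test_one_sided_gamma_only_counts_low_side(self):
        table = CohortTable(
            records=tuple(
                make_record(record_id=f"R{i}", gamma_pass_pct=v)
                for i, v in enumerate([80.0, 92.0, 100.0])
            )
        )
        fc = count_limit_failures(table, default_gamma_limits(), "gamma_pass_pct")
        assert fc.n_fail_al_low == 1  # 80 < 90
        assert fc.n_fail_tl_low == 1  # 80 < 85
        assert fc.n_fail_al_high == fc.n_fail_tl_high == 0

    @given(
        values=st.lists(st.floats(-8, 8, allow_nan=False), min_size=0, max_size=40)
    )
    def test_matches_independent_linear_scan(self, values):
        fc = count_limit_failures(
            dose_table(values), IPLAN_LIMITS, "mean_dose_diff_pct"
        )
        assert fc.n_fail_al_low == sum(1 for v in values if v < -4.4)
        assert fc.n_fail_al_high == sum(1 for v in values if v > 2.2)
        assert fc.n_fail_tl_low == sum(1 for v in values if v < -5.0)
        assert fc.n_fail_tl_high == sum(1 for v in values if v > 3.9)
        # nested limits: every TL failure is also an AL failure
        assert fc.n_fail_tl_low <= fc.n_fail_al_low
        assert fc.n_fail_tl_high <= fc.n_fail_al_high

    def test_order_and_duplicates_safe(self):
        values = [-4.5, 2.5, -4.5, 0.0]
        a = count_limit_failures(dose_table(values), IPLAN_LIMITS, "mean_dose_diff_pct")
        b = count_limit_failures(
            dose_table(values[::-1]), IPLAN_LIMITS, "mean_dose_diff_pct"
        )
        assert (a.n_fail_al_low, a.n_fail_al_high) == (b.n_fail_al_low, b.n_fail_al_high) == (2, 1)


@pytest.fixture(scope="module")
def synthetic_cohort():
    return generate_cohort(default_config(seed=11))


class TestAuditReport:
    def test_default_strata_present_with_consistent_n(self, synthetic_cohort):
        report = audit_report(synthetic_cohort)
        labels = [s.label for s in report.strata]
        assert labels == ["Eclipse", "iPlan", "Lung", "all-gamma"]
        by_label = {s.label: s for s in report.strata}
        assert by_label["Eclipse"].stats.n + by_label["iPlan"].stats.n == 1000
        assert by_label["Lung"].stats.n == 32
        assert by_label["all-gamma"].stats.n == 1000

    def test_default_dose_limits_show_zero_failures_on_truncated_cohort(
        self, synthetic_cohort
    ):
        report = audit_report(synthetic_cohort)
        for s in report.strata:
            if s.metric == "mean_dose_diff_pct":
                fd = s.failures_default
                assert (
                    fd.n_fail_al_low + fd.n_fail_al_high
                    + fd.n_fail_tl_low + fd.n_fail_tl_high
                ) == 0

    def test_derived_limits_never_fail_fewer_than_default(self, synthetic_cohort):
        # derived (tighter) dose bounds can only add failures over ±5
        report = audit_report(synthetic_cohort)
        for s in report.strata:
            if s.metric == "mean_dose_diff_pct" and not s.withheld:
                assert (
                    s.failures_derived.n_fail_al_low + s.failures_derived.n_fail_al_high
                    >= s.failures_default.n_fail_al_low + s.failures_default.n_fail_al_high
                )

    def test_tl_failures_nested_in_al_failures(self, synthetic_cohort):
        report = audit_report(synthetic_cohort)
        for s in report.strata:
            for fc in (s.failures_default, s.failures_derived):
                if fc is not None:
                    assert fc.n_fail_tl_low <= fc.n_fail_al_low
                    assert fc.n_fail_tl_high <= fc.n_fail_al_high

    def test_small_stratum_withholds_limits(self, synthetic_cohort):
        config = AuditConfig(
            strata=(
                StratumPolicy("Lung", {"treatment_site": "Lung"}),
            ),
            min_n=50,
        )
        report = audit_report(synthetic_cohort, config)
        (s,) = report.strata
        assert s.withheld and "min_n" in s.withheld_reason
        assert s.derived_limits is None

    def test_json_and_tsv_render(self, synthetic_cohort):
        report = audit_report(synthetic_cohort)
        payload = json.loads(report.to_json())
        assert payload["n_records"] == 1000
        assert len(payload["strata"]) == 4
        tsv = report.to_tsv()
        assert tsv.splitlines()[0].startswith("stratum\tmetric")
        assert len(tsv.splitlines()) == 5


class TestFigures:
    def test_figures_exist_and_nonempty(self, tmp_path, mixed_cohort):
        paths = render_figures(mixed_cohort, tmp_path / "figs")
        assert len(paths) == 3
        for p in paths:
            assert p.exists() and p.stat().st_size > 0

    def test_empty_cohort_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            render_figures(CohortTable(records=()), tmp_path)

    def test_inset_moments_match_summaries(self, synthetic_cohort):
        # the inset mu/sigma printed on histograms come from the same
        # arithmetic as summarize_cohort; cross-check at display precision
        from qadb.records import filter_cohort, summarize_cohort

        sub = filter_cohort(synthetic_cohort, {"tps": "iPlan"})
        (s,) = summarize_cohort(sub, [], "mean_dose_diff_pct")
        v = np.array([r.mean_dose_diff_pct for r in sub.records])
        assert f"{v.mean():.2f}" == f"{s.mu:.2f}"
        assert f"{v.std(ddof=1):.2f}" == f"{s.sigma:.2f}"
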