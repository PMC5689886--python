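"""Retrospective audit of a cohort against default and derived limits.

Applies limit sets to every record, counts failures per bound, and renders
the report surfaces an analyst reviews: a per-stratum statistics table, a
limits table with capped-bound annotations and failure counts, scatter
plots of the dose difference over time, per-stratum histograms with μ/σ
inset, and the all-data gamma histogram.

Failing a bound uses *strict* inequality (a value exactly on a limit
passes): printed limits are rounded, so boundary equality is common and
the lenient convention is the documented one.

The vendor-default gamma limits (AL 90 / TL 85) reference a (5%, 3 mm)
criterion while cohorts store (3%, 3 mm) pass rates; the default-gamma
audit therefore overstates failures and is reported with that caveat.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .limits import LimitPolicy, LimitPolicyError, LimitSet, derive_dose_limits, derive_gamma_limits
from .records import CohortTable, SubgroupStats, filter_cohort, summarize_cohort

__all__ = [
    "FailureCounts",
    "StratumPolicy",
    "AuditConfig",
    "StratumReport",
    "AuditReport",
    "count_limit_failures",
    "default_dose_limits",
    "default_gamma_limits",
    "audit_report",
    "render_figures",
]

#: Vendor-default gamma limits reference a (5%, 3 mm) criterion; cohorts
#: store (3%, 3 mm) pass rates, so default-gamma failure counts are an
#: overestimate.
DEFAULT_GAMMA_CAVEAT = (
    "default gamma limits reference a (5%, 3 mm) criterion but are audited "
    "against stored (3%, 3 mm) pass rates; the true failure count under the "
    "default criterion would likely be much less"
)


@dataclass(frozen=True)
class FailureCounts:
    """Records breaching each bound of one limit set within one stratum."""

    n_total: int
    n_fail_al_low: int
    n_fail_al_high: int
    n_fail_tl_low: int
    n_fail_tl_high: int
    limit_set: LimitSet
    stratum: str = ""

    def __post_init__(self) -> None:
        counts = (
            self.n_fail_al_low,
            self.n_fail_al_high,
            self.n_fail_tl_low,
            self.n_fail_tl_high,
        )
        if any(c < 0 or c > self.n_total for c in counts):
            raise ValueError("counts must lie in [0, n_total]")
        if self.n_fail_tl_low > self.n_fail_al_low:
            raise ValueError("TL-low failures cannot exceed AL-low failures")
        if self.n_fail_tl_high > self.n_fail_al_high:
            raise ValueError("TL-high failures cannot exceed AL-high failures")


def default_dose_limits() -> LimitSet:
    """Vendor-default mean-dose-difference limits: ±5% for both AL and TL.

    AL and TL coincide, so the nesting is degenerate by design.
    """
    return LimitSet(al_low=-5.0, al_high=5.0, tl_low=-5.0, tl_high=5.0)


def default_gamma_limits() -> LimitSet:
    """Vendor-default gamma limits: AL 90 / TL 85, one-sided low."""
    return LimitSet(
        al_low=90.0, al_high=100.0, tl_low=85.0, tl_high=100.0, one_sided=True
    )


def count_limit_failures(
    table: CohortTable, limits: LimitSet, metric: str
) -> FailureCounts:
    """Count records strictly outside each bound; empty tables give zeros."""
    values = np.asarray([getattr(r, metric) for r in table.records], dtype=float)
    if values.size == 0:
        return FailureCounts(0, 0, 0, 0, 0, limit_set=limits)
    al_low = int((values < limits.al_low).sum())
    tl_low = int((values < limits.tl_low).sum())
    if limits.one_sided:
        al_high = tl_high = 0
    else:
        al_high = int((values > limits.al_high).sum())
        tl_high = int((values > limits.tl_high).sum())
    return FailureCounts(
        n_total=int(values.size),
        n_fail_al_low=al_low,
        n_fail_al_high=al_high,
        n_fail_tl_low=tl_low,
        n_fail_tl_high=tl_high,
        limit_set=limits,
    )


@dataclass(frozen=True)
class StratumPolicy:
    """One audited stratum: selection criteria, metric, and limit policy."""

    label: str
    criteria: dict
    metric: str = "mean_dose_diff_pct"
    policy: LimitPolicy = field(default_factory=LimitPolicy)


def default_strata() -> tuple[StratumPolicy, ...]:
    """The published stratification: Eclipse (symmetric), iPlan, Lung, all-gamma."""
    return (
        StratumPolicy("Eclipse", {"tps": "Eclipse"}, policy=LimitPolicy(mode="symmetric")),
        StratumPolicy("iPlan", {"tps": "iPlan"}, policy=LimitPolicy(mode="asymmetric")),
        StratumPolicy("Lung", {"treatment_site": "Lung"}, policy=LimitPolicy(mode="asymmetric")),
        StratumPolicy("all-gamma", {}, metric="gamma_pass_pct"),
    )


@dataclass(frozen=True)
class AuditConfig:
    strata: tuple[StratumPolicy, ...] = field(default_factory=default_strata)
    min_n: int = 20  # small-sample guard: below this, limits are withheld

    @classmethod
    def from_dict(cls, data: dict) -> "AuditConfig":
        strata = []
        for entry in data.get("strata", []):
            policy_kwargs = entry.get("policy", {})
            strata.append(
                StratumPolicy(
                    label=entry["label"],
                    criteria=entry.get("criteria", {}),
                    metric=entry.get("metric", "mean_dose_diff_pct"),
                    policy=LimitPolicy(**policy_kwargs),
                )
            )
        return cls(strata=tuple(strata), min_n=int(data.get("min_n", 20)))


@dataclass(frozen=True)
class StratumReport:
    label: str
    metric: str
    stats: SubgroupStats | None
    derived_limits: LimitSet | None
    failures_default: FailureCounts | None
    failures_derived: FailureCounts | None
    withheld: bool = False
    withheld_reason: str = ""
    caveat: str = ""


@dataclass(frozen=True)
class AuditReport:
    strata: tuple[StratumReport, ...]
    n_records: int

    def to_json(self) -> str:
        out = []
        for s in self.strata:
            entry: dict = {"label": s.label, "metric": s.metric, "withheld": s.withheld}
            if s.withheld:
                entry["reason"] = s.withheld_reason
            if s.stats is not None:
                entry["stats"] = {
                    "n": s.stats.n,
                    "mu": s.stats.mu,
                    "sigma": s.stats.sigma,
                    "max": s.stats.max_v,
                    "min": s.stats.min_v,
                }
            if s.derived_limits is not None:
                ls = s.derived_limits
                entry["derived_limits"] = {
                    "al_low": ls.al_low,
                    "al_high": ls.al_high,
                    "tl_low": ls.tl_low,
                    "tl_high": ls.tl_high,
                    "capped": sorted(ls.capped_flags),
                    "one_sided": ls.one_sided,
                }
            for key, fc in (
                ("failures_default", s.failures_default),
                ("failures_derived", s.failures_derived),
            ):
                if fc is not None:
                    entry[key] = {
                        "al_low": fc.n_fail_al_low,
                        "al_high": fc.n_fail_al_high,
                        "tl_low": fc.n_fail_tl_low,
                        "tl_high": fc.n_fail_tl_high,
                    }
            if s.caveat:
                entry["caveat"] = s.caveat
            out.append(entry)
        return json.dumps({"n_records": self.n_records, "strata": out}, indent=1)

    def to_tsv(self) -> str:
        header = [
            "stratum", "metric", "n", "mu", "sigma",
            "al_low", "al_high", "tl_low", "tl_high", "capped",
            "fail_al_default", "fail_tl_default", "fail_al_derived", "fail_tl_derived",
            "withheld",
        ]
        lines = ["\t".join(header)]
        for s in self.strata:
            st, ls = s.stats, s.derived_limits
            fmt = lambda v: "" if v is None else f"{v:.4g}"
            def fails(fc, which):
                if fc is None:
                    return ""
                if which == "al":
                    return str(fc.n_fail_al_low + fc.n_fail_al_high)
                return str(fc.n_fail_tl_low + fc.n_fail_tl_high)
            lines.append(
                "\t".join(
                    [
                        s.label,
                        s.metric,
                        str(st.n) if st else "",
                        fmt(st.mu if st else None),
                        fmt(st.sigma if st else None),
                        fmt(ls.al_low if ls else None),
                        fmt(ls.al_high if ls and not ls.one_sided else None),
                        fmt(ls.tl_low if ls else None),
                        fmt(ls.tl_high if ls and not ls.one_sided else None),
                        ",".join(sorted(ls.capped_flags)) if ls else "",
                        fails(s.failures_default, "al"),
                        fails(s.failures_default, "tl"),
                        fails(s.failures_derived, "al"),
                        fails(s.failures_derived, "tl"),
                        str(s.withheld).lower(),
                    ]
                )
            )
        return "\n".join(lines) + "\n"


def audit_report(table: CohortTable, config: AuditConfig | None = None) -> AuditReport:
    """Per-stratum statistics, derived limits, and default/derived failure counts.

    Strata below the small-sample guard get statistics but no limits, with
    an explanatory flag.
    """
    config = config or AuditConfig()
    reports = []
    for sp in config.strata:
        subset = filter_cohort(table, sp.criteria)
        stats_list = summarize_cohort(subset, [], sp.metric)
        stats = stats_list[0] if stats_list else None
        if stats is not None:
            # carry the stratum label rather than the generic "all"
            stats = SubgroupStats(
                label=sp.label, metric=stats.metric, n=stats.n, mu=stats.mu,
                sigma=stats.sigma, max_v=stats.max_v, min_v=stats.min_v,
            )
        is_gamma = sp.metric == "gamma_pass_pct"
        default_limits = default_gamma_limits() if is_gamma else default_dose_limits()
        failures_default = count_limit_failures(subset, default_limits, sp.metric)
        if stats is None or stats.n < config.min_n:
            reports.append(
                StratumReport(
                    label=sp.label,
                    metric=sp.metric,
                    stats=stats,
                    derived_limits=None,
                    failures_default=failures_default,
                    failures_derived=None,
                    withheld=True,
                    withheld_reason=(
                        f"n={stats.n if stats else 0} below the small-sample "
                        f"guard (min_n={config.min_n}); limits withheld"
                    ),
                )
            )
            continue
        try:
            if is_gamma:
                derived = derive_gamma_limits(stats, sp.policy)
            else:
                derived = derive_dose_limits(stats, sp.policy)
        except LimitPolicyError as exc:
            reports.append(
                StratumReport(
                    label=sp.label, metric=sp.metric, stats=stats,
                    derived_limits=None, failures_default=failures_default,
                    failures_derived=None, withheld=True, withheld_reason=str(exc),
                )
            )
            continue
        failures_derived = count_limit_failures(subset, derived, sp.metric)
        reports.append(
            StratumReport(
                label=sp.label,
                metric=sp.metric,
                stats=stats,
                derived_limits=derived,
                failures_default=failures_default,
                failures_derived=failures_derived,
                caveat=DEFAULT_GAMMA_CAVEAT if is_gamma else "",
            )
        )
    return AuditReport(strata=tuple(reports), n_records=len(table))


# ---------------------------------------------------------------------------
# Figures

#: histogram grains: 0.5%-wide bins for dose differences, 1% for gamma
DOSE_BIN_WIDTH = 0.5
GAMMA_BIN_WIDTH = 1.0


def _bins(values, width):
    lo = np.floor(min(values) / width) * width
    hi = np.ceil(max(values) / width) * width
    if hi <= lo:
        hi = lo + width
    return np.arange(lo, hi + width / 2, width)


def render_figures(table: CohortTable, out_dir: str | Path) -> list[Path]:
    """Scatter-over-time panels, dose-difference histograms with μ/σ inset,
    and the all-data gamma histogram. Deterministic file names; returns the
    paths written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(table) == 0:
        raise ValueError("cannot render figures for an empty cohort")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    dates = [r.check_date for r in table.records]
    dose = np.asarray([r.mean_dose_diff_pct for r in table.records])
    gamma = np.asarray([r.gamma_pass_pct for r in table.records])
    paths = []

    # scatter over time, keyed by linac / technique / TPS
    fig, axes = plt.subplots(3, 1, figsize=(8, 10), sharex=True)
    for ax, keyfield in zip(axes, ("linac", "technique", "tps")):
        groups = sorted({getattr(r, keyfield) for r in table.records})
        for g in groups:
            sel = [i for i, r in enumerate(table.records) if getattr(r, keyfield) == g]
            ax.plot([dates[i] for i in sel], dose[sel], ".", ms=4, label=g)
        ax.set_ylabel("mean dose diff (%)")
        ax.legend(loc="upper right", fontsize=7, title=keyfield)
    axes[-1].set_xlabel("check date")
    fig.autofmt_xdate()
    p = out_dir / "dose_scatter_time.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)

    # per-stratum dose-difference histograms with mu/sigma inset
    strata = [("All", {}), ("Eclipse", {"tps": "Eclipse"}),
              ("iPlan", {"tps": "iPlan"}), ("Lung", {"treatment_site": "Lung"})]
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for ax, (label, crit) in zip(axes.ravel(), strata):
        sub = filter_cohort(table, crit)
        if len(sub) == 0:
            ax.set_title(f"{label} (no records)")
            ax.set_axis_off()
            continue
        v = np.asarray([r.mean_dose_diff_pct for r in sub.records])
        ax.hist(v, bins=_bins(v, DOSE_BIN_WIDTH), edgecolor="black")
        mu = v.mean()
        sd = v.std(ddof=1) if v.size > 1 else float("nan")
        ax.set_title(label)
        ax.text(
            0.02, 0.95, f"$\\mu$={mu:.2f}\n$\\sigma$={sd:.2f}",
            transform=ax.transAxes, va="top", fontsize=8,
            bbox=dict(boxstyle="round", fc="white", alpha=0.8),
        )
        ax.set_xlabel("mean dose diff (%)")
        ax.set_ylabel("count")
    fig.tight_layout()
    p = out_dir / "dose_histograms.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)

    # all-data gamma histogram
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.hist(gamma, bins=_bins(gamma, GAMMA_BIN_WIDTH), edgecolor="black")
    ax.set_xlabel("gamma pass rate (3%, 3 mm) (%)")
    ax.set_ylabel("count")
    fig.tight_layout()
    p = out_dir / "gamma_histogram.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)

    return paths
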