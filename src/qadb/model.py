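"""Model/Results interface over the limit-setting pipeline.

:class:`ToleranceModel` is built from a cohort of verification records and
a stratification; ``fit()`` runs the full procedure for every stratum —
summary statistics, normal-probability-plot vetting, μ ± 2σ / μ ± 3σ limit
derivation with capping, and the retrospective audit against both the
vendor-default and the newly derived limits — and returns a
:class:`ToleranceResults` whose ``summary()`` is the analyst-facing table.

    >>> from qadb import ToleranceModel, synthetic
    >>> cohort = synthetic.generate_cohort(synthetic.default_config(seed=1))
    >>> res = ToleranceModel(cohort).fit()
    >>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .audit import AuditConfig, AuditReport, StratumReport, audit_report, render_figures
from .normality import DEFAULT_R_THRESHOLD, NormalityFit, normal_probability_fit, normality_verdict
from .records import CohortTable, filter_cohort, read_cohort

__all__ = ["ToleranceModel", "ToleranceResults"]


class ToleranceModel:
    """Per-stratum normal model of verification metrics with μ ± kσ limits.

    Parameters
    ----------
    cohort : CohortTable
        The verification records.
    config : AuditConfig, optional
        Stratification and limit policies; defaults to the published
        four-stratum layout (Eclipse symmetric, iPlan, Lung, all-gamma).
    r_threshold : float
        Advisory probability-plot correlation threshold for the normality
        verdict.
    """

    def __init__(
        self,
        cohort: CohortTable,
        config: AuditConfig | None = None,
        r_threshold: float = DEFAULT_R_THRESHOLD,
    ):
        self.cohort = cohort
        self.config = config or AuditConfig()
        self.r_threshold = float(r_threshold)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "ToleranceModel":
        return cls(read_cohort(path), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ToleranceModel":
        return cls(CohortTable.from_dataframe(df), **kwargs)

    def fit(self) -> "ToleranceResults":
        report = audit_report(self.cohort, self.config)
        normality: dict[str, NormalityFit | None] = {}
        verdicts: dict[str, bool | None] = {}
        for sp in self.config.strata:
            subset = filter_cohort(self.cohort, sp.criteria)
            values = [getattr(r, sp.metric) for r in subset.records]
            try:
                fit = normal_probability_fit(values)
            except ValueError:
                fit = None
            normality[sp.label] = fit
            verdicts[sp.label] = (
                normality_verdict(fit, self.r_threshold) if fit else None
            )
        return ToleranceResults(
            model=self, report=report, normality=normality, verdicts=verdicts
        )


@dataclass
class ToleranceResults:
    """Fitted per-stratum statistics, limits, diagnostics and audits."""

    model: ToleranceModel
    report: AuditReport
    normality: dict
    verdicts: dict

    @property
    def strata(self) -> tuple[StratumReport, ...]:
        return self.report.strata

    def stratum(self, label: str) -> StratumReport:
        for s in self.report.strata:
            if s.label == label:
                return s
        raise KeyError(f"no stratum {label!r}")

    def to_frame(self) -> pd.DataFrame:
        """One row per stratum: n, μ, σ, plot r, verdict, limits, failures."""
        rows = []
        for s in self.strata:
            fit = self.normality.get(s.label)
            ls = s.derived_limits
            fd, fv = s.failures_default, s.failures_derived
            rows.append(
                {
                    "stratum": s.label,
                    "metric": s.metric,
                    "n": s.stats.n if s.stats else 0,
                    "mu": s.stats.mu if s.stats else float("nan"),
                    "sigma": (
                        s.stats.sigma
                        if s.stats and s.stats.sigma is not None
                        else float("nan")
                    ),
                    "plot_r": fit.r if fit else float("nan"),
                    "normal": self.verdicts.get(s.label),
                    "al_low": ls.al_low if ls else float("nan"),
                    "al_high": ls.al_high if ls and not ls.one_sided else float("nan"),
                    "tl_low": ls.tl_low if ls else float("nan"),
                    "tl_high": ls.tl_high if ls and not ls.one_sided else float("nan"),
                    "capped": ",".join(sorted(ls.capped_flags)) if ls else "",
                    "fail_al_default": (
                        fd.n_fail_al_low + fd.n_fail_al_high if fd else 0
                    ),
                    "fail_al_derived": (
                        fv.n_fail_al_low + fv.n_fail_al_high if fv else 0
                    ),
                    "fail_tl_derived": (
                        fv.n_fail_tl_low + fv.n_fail_tl_high if fv else 0
                    ),
                    "withheld": s.withheld,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable per-stratum table with limits and diagnostics."""
        df = self.to_frame()
        lines = [
            "Verification tolerance model",
            "=" * 96,
            f"records: {self.report.n_records}   "
            f"normality threshold r >= {self.model.r_threshold}",
            "-" * 96,
            df.to_string(
                index=False,
                float_format=lambda v: f"{v:.3f}",
                na_rep="--",
            ),
            "-" * 96,
        ]
        for s in self.strata:
            if s.withheld:
                lines.append(f"note [{s.label}]: {s.withheld_reason}")
            if s.caveat:
                lines.append(f"note [{s.label}]: {s.caveat}")
        return "\n".join(lines)

    def plot_diagnostics(self, out_dir: str | Path) -> list[Path]:
        """Write the scatter/histogram report figures; returns paths."""
        return render_figures(self.model.cohort, out_dir)
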