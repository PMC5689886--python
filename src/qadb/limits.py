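"""Action levels and tolerances from subgroup statistics.

For a stratum whose metric is adequately normal, the action level (AL) is
set at μ ± 2σ and the tolerance (TL) at μ ± 3σ: under normality roughly
4.55% of future results land outside the AL and 0.27% outside the TL, so
the AL flags results approaching the limit of clinical acceptance (the TL).

Dose-difference limits are two-sided. In *asymmetric* mode the systematic
offset μ is kept and each bound is rounded to a fine grain (default 0.1%);
in *symmetric* mode a small μ is treated as negligible and the bounds are
±(kσ) rounded to a coarser grain (default 0.5%). Bounds whose magnitude
exceeds the clinical cap (default 5%) are clamped to it and flagged.

Gamma passing-rate limits are one-sided low (a pass rate cannot usefully
exceed 100%): AL = μ − 2σ, TL = μ − 3σ, floored at 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats as _stats

from .records import SubgroupStats

__all__ = [
    "LimitPolicy",
    "LimitSet",
    "LimitPolicyError",
    "derive_dose_limits",
    "derive_gamma_limits",
    "expected_failure_fraction",
    "round_to_step",
]


class LimitPolicyError(ValueError):
    """Limits cannot be derived under the given policy (degenerate σ or
    a cap tighter than the action level)."""


@dataclass(frozen=True)
class LimitPolicy:
    """How μ ± kσ is turned into printable clinical limits.

    mode            : 'asymmetric' keeps the offset μ; 'symmetric' treats it
                      as negligible and centres the bounds on zero.
    cap_pct         : magnitude cap for dose-difference bounds, percent.
    round_step_asym : rounding grain for asymmetric bounds, percent.
    round_step_sym  : rounding grain for symmetric bounds, percent.
    auto_symmetric / symmetric_if_abs_mu_below : optional automation that
    switches to symmetric mode when |μ| is below the threshold; off by
    default (mode selection is normally an explicit clinical choice).
    """

    mode: str = "asymmetric"
    cap_pct: float = 5.0
    round_step_asym: float = 0.1
    round_step_sym: float = 0.5
    auto_symmetric: bool = False
    symmetric_if_abs_mu_below: float = 0.3

    def __post_init__(self) -> None:
        if self.mode not in ("symmetric", "asymmetric"):
            raise ValueError("mode must be 'symmetric' or 'asymmetric'")
        if self.cap_pct <= 0:
            raise ValueError("cap_pct must be positive")
        if self.round_step_asym <= 0 or self.round_step_sym <= 0:
            raise ValueError("rounding grains must be positive")

    def resolve_mode(self, mu: float) -> str:
        if self.auto_symmetric and abs(mu) < self.symmetric_if_abs_mu_below:
            return "symmetric"
        return self.mode


@dataclass(frozen=True)
class LimitSet:
    """Derived bounds with capping provenance.

    Two-sided sets satisfy tl_low ≤ al_low < al_high ≤ tl_high and contain
    the source mean. One-sided (gamma) sets pin the upper bounds at 100,
    which is not a reportable limit.
    """

    al_low: float
    al_high: float
    tl_low: float
    tl_high: float
    capped_flags: dict = field(default_factory=dict)
    source_stats: SubgroupStats | None = None
    policy: LimitPolicy | None = None
    one_sided: bool = False

    def __post_init__(self) -> None:
        if not (self.tl_low <= self.al_low < self.al_high <= self.tl_high):
            raise ValueError(
                "limits must nest: tl_low <= al_low < al_high <= tl_high "
                f"(got {self.tl_low}, {self.al_low}, {self.al_high}, {self.tl_high})"
            )
        if self.source_stats is not None and not self.one_sided:
            if not (self.al_low <= self.source_stats.mu <= self.al_high):
                raise ValueError("source mean must lie inside the action levels")


def round_to_step(x: float, step: float) -> float:
    """Round to the nearest multiple of ``step``, halves away from zero.

    Mirror-symmetric for negative values, so lower and upper bounds round
    identically in magnitude. A small epsilon absorbs binary-float noise on
    exact halves.
    """
    n = math.floor(abs(x) / step + 0.5 + 1e-9)
    # drop binary-float noise from n*step (e.g. 39*0.1 = 3.9000000000000004)
    return math.copysign(round(n * step, 12), x)


def _require_sigma(stats: SubgroupStats) -> float:
    if stats.sigma is None or stats.sigma <= 0:
        raise LimitPolicyError(
            f"stratum {stats.label!r}: sigma absent or degenerate, limits undefined"
        )
    return stats.sigma


def derive_dose_limits(stats: SubgroupStats, policy: LimitPolicy) -> LimitSet:
    """Two-sided dose-difference limits: AL = μ ± 2σ, TL = μ ± 3σ.

    Bounds are rounded per policy mode, then clamped to ±cap_pct with a
    ``capped_flags`` entry per clamped bound. An action level already
    outside the cap is a policy conflict and raises
    :class:`LimitPolicyError` (a cap that tight makes the AL meaningless).
    """
    sigma = _require_sigma(stats)
    mode = policy.resolve_mode(stats.mu)
    if mode == "asymmetric":
        step = policy.round_step_asym
        bounds = {
            "al_low": round_to_step(stats.mu - 2 * sigma, step),
            "al_high": round_to_step(stats.mu + 2 * sigma, step),
            "tl_low": round_to_step(stats.mu - 3 * sigma, step),
            "tl_high": round_to_step(stats.mu + 3 * sigma, step),
        }
    else:
        step = policy.round_step_sym
        al_mag = round_to_step(2 * sigma, step)
        tl_mag = round_to_step(3 * sigma, step)
        bounds = {
            "al_low": -al_mag,
            "al_high": al_mag,
            "tl_low": -tl_mag,
            "tl_high": tl_mag,
        }
    cap = policy.cap_pct
    if abs(bounds["al_low"]) > cap or abs(bounds["al_high"]) > cap:
        raise LimitPolicyError(
            f"stratum {stats.label!r}: action level exceeds the ±{cap}% cap; "
            "the cap is tighter than the action level (policy conflict)"
        )
    capped = {}
    for name in ("tl_low", "tl_high"):
        if abs(bounds[name]) > cap:
            bounds[name] = math.copysign(cap, bounds[name])
            capped[name] = True
    return LimitSet(
        **bounds, capped_flags=capped, source_stats=stats, policy=policy
    )


def derive_gamma_limits(stats: SubgroupStats, policy: LimitPolicy) -> LimitSet:
    """One-sided lower limits for gamma pass rates: AL = μ − 2σ, TL = μ − 3σ.

    Rounded to the asymmetric grain and floored at 0; upper bounds are
    pinned at 100 and are not reportable limits.
    """
    sigma = _require_sigma(stats)
    step = policy.round_step_asym
    al_low = max(0.0, round_to_step(stats.mu - 2 * sigma, step))
    tl_low = max(0.0, round_to_step(stats.mu - 3 * sigma, step))
    capped = {"tl_low": True} if stats.mu - 3 * sigma < 0 else {}
    return LimitSet(
        al_low=al_low,
        al_high=100.0,
        tl_low=tl_low,
        tl_high=100.0,
        capped_flags=capped,
        source_stats=stats,
        policy=policy,
        one_sided=True,
    )


def expected_failure_fraction(k_sigma: float) -> float:
    """Percent of a normal population outside μ ± kσ: 100 × 2Φ(−k).

    k = 2 → 4.55%, k = 3 → 0.27% — the "approximately 5% and 1%" of
    results expected to breach the action level and tolerance.
    """
    if k_sigma < 0:
        raise ValueError("k_sigma must be non-negative")
    return 100.0 * 2.0 * float(_stats.norm.cdf(-k_sigma))
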