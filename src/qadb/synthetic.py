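"""Synthetic verification cohorts and dose-grid pairs.

The clinic's verification database itself is not published; this module
generates stand-in cohorts with the same statistical structure so the
whole pipeline (summaries, normality vetting, limit derivation, audit) can
be exercised and tested end to end.

Per subgroup, the mean dose difference is drawn from a normal distribution
truncated to clinical bounds (default ±5%, mirroring the observation that
every recorded value fell within the ±5% default limits), and the gamma
pass rate is 100 − X with X gamma-distributed, moment-matched to the
target mean and SD — a bounded, left-skewed family matching the observed
shape of pass-rate histograms. The two metrics are drawn independently;
any real per-plan correlation between them is not modelled.

The default configuration reproduces the published database structure:
1000 records over about seven months, Eclipse n=856 (μ 0.25, σ 0.98) with
the Lung site (n=32, μ 1.74, σ 1.18) carved out of the Eclipse allocation
(lung plans were exclusively Eclipse), iPlan n=144 (μ −1.10, σ 1.66), and
overall gamma moments 97.3/2.9. Technique, linac, energy and non-lung site
labels are assigned with proportions taken from the published margins but
are cosmetic: only the modelled strata carry distributional meaning.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .metrics import DoseGrid
from .records import CohortTable, VerificationRecord

__all__ = [
    "SubgroupSpec",
    "CohortConfig",
    "default_config",
    "generate_cohort",
    "generate_dose_pair",
    "SCENARIOS",
]


@dataclass(frozen=True)
class SubgroupSpec:
    """Target moments and labels for one generated subgroup.

    dose_mu/dose_sigma are the moments of the *untruncated* normal; with
    the default ±5 bounds the truncated moments differ slightly (the shift
    is largest for the iPlan-like subgroup, about +0.04 on the mean).
    """

    name: str
    labels: dict
    n: int
    dose_mu: float
    dose_sigma: float
    dose_bounds: tuple[float, float] = (-5.0, 5.0)
    gamma_mu: float = 97.3
    gamma_sigma: float = 2.9
    gamma_max: float = 100.0
    #: cosmetic categorical label pools: field -> (values, probabilities)
    label_pools: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.dose_sigma <= 0:
            raise ValueError("dose_sigma must be positive")
        lo, hi = self.dose_bounds
        if not (lo < self.dose_mu < hi):
            raise ValueError("dose_bounds must contain dose_mu")
        if self.gamma_mu > 100.0:
            raise ValueError("gamma_mu cannot exceed 100")


@dataclass(frozen=True)
class CohortConfig:
    subgroups: tuple[SubgroupSpec, ...]
    date_start: datetime.date
    date_end: datetime.date
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "subgroups", tuple(self.subgroups))
        if self.seed is None:
            raise ValueError("a seed is mandatory for generation")
        if self.date_end <= self.date_start:
            raise ValueError("date_end must follow date_start")

    @property
    def n_total(self) -> int:
        return sum(s.n for s in self.subgroups)


_SITES_NONLUNG = (
    "Prostate",
    "Breast",
    "Head and Neck",
    "Brain",
    "Pelvis",
    "Rectum",
    "Bladder",
    "Oesophagus",
)


def default_config(seed: int) -> CohortConfig:
    """The default 1000-record cohort mirroring the published database.

    Subgroup allocations: Eclipse non-lung 824, Eclipse Lung 32 (lung is
    exclusively Eclipse), iPlan 144. Linac/technique/energy proportions per
    subgroup follow the published margins (cosmetic labels).
    """
    eclipse_nonlung = SubgroupSpec(
        name="eclipse_nonlung",
        labels={"tps": "Eclipse"},
        n=824,
        dose_mu=0.25,
        dose_sigma=0.98,
        label_pools={
            "technique": (("3DCRT", "IMRT"), (0.70, 0.30)),
            "linac": (("LA1", "LA2", "LA3", "LA4"), (0.28, 0.12, 0.31, 0.29)),
            "energy": (("6X", "10X", "6/10X"), (0.26, 0.56, 0.18)),
            "treatment_site": (
                _SITES_NONLUNG,
                tuple([1.0 / len(_SITES_NONLUNG)] * len(_SITES_NONLUNG)),
            ),
        },
    )
    lung = SubgroupSpec(
        name="lung",
        labels={"tps": "Eclipse", "treatment_site": "Lung"},
        n=32,
        dose_mu=1.74,
        dose_sigma=1.18,
        label_pools={
            "technique": (("3DCRT", "IMRT"), (0.70, 0.30)),
            "linac": (("LA1", "LA2", "LA3", "LA4"), (0.19, 0.34, 0.09, 0.38)),
            "energy": (("6X", "10X", "6/10X"), (0.5, 0.3, 0.2)),
        },
    )
    iplan = SubgroupSpec(
        name="iplan",
        labels={"tps": "iPlan"},
        n=144,
        dose_mu=-1.10,
        dose_sigma=1.66,
        label_pools={
            "technique": (("DCA", "IMRS"), (0.72, 0.28)),
            "linac": (("LA2", "LA4"), (0.79, 0.21)),
            "energy": (("6FFF", "6X"), (0.97, 0.03)),
            "treatment_site": (("Brain", "Spine", "Lymph Node"), (0.6, 0.25, 0.15)),
        },
    )
    return CohortConfig(
        subgroups=(eclipse_nonlung, lung, iplan),
        date_start=datetime.date(2015, 1, 5),
        date_end=datetime.date(2015, 8, 5),
        seed=seed,
    )


def _truncated_normal(
    rng: np.random.Generator, mu: float, sigma: float, bounds, size: int
) -> np.ndarray:
    """Rejection sampling from N(mu, sigma²) truncated to bounds."""
    lo, hi = bounds
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mu, sigma, size=max(size - filled, 16))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _gamma_pass_sample(
    rng: np.random.Generator, gamma_mu: float, gamma_sigma: float, gamma_max: float, size: int
) -> np.ndarray:
    """100 − X with X ~ Gamma, moment-matched to (100 − μ, σ), kept in [0, 100]."""
    if gamma_sigma <= 0:
        raise ValueError("gamma_sigma must be positive for moment matching")
    m = 100.0 - gamma_mu
    if m <= 0:
        raise ValueError("gamma_mu must be below 100 for moment matching")
    shape = (m / gamma_sigma) ** 2
    scale = gamma_sigma**2 / m
    out = np.empty(size)
    filled = 0
    while filled < size:
        x = rng.gamma(shape, scale, size=max(size - filled, 16))
        keep = x[x <= 100.0]
        take = min(keep.size, size - filled)
        out[filled : filled + take] = 100.0 - keep[:take]
        filled += take
    return np.minimum(out, gamma_max)


def generate_cohort(config: CohortConfig) -> CohortTable:
    """Generate a cohort table; deterministic given (config, seed).

    Records are ordered by check date and given sequential ids, emulating
    consecutive clinical calculations over the accrual period.
    """
    rng = np.random.default_rng(config.seed)
    span = (config.date_end - config.date_start).days
    rows = []
    for spec in config.subgroups:
        dose = _truncated_normal(
            rng, spec.dose_mu, spec.dose_sigma, spec.dose_bounds, spec.n
        )
        gpass = _gamma_pass_sample(
            rng, spec.gamma_mu, spec.gamma_sigma, spec.gamma_max, spec.n
        )
        day_offsets = rng.integers(0, span + 1, size=spec.n)
        labels = {}
        for fieldname, (values, probs) in spec.label_pools.items():
            labels[fieldname] = rng.choice(list(values), size=spec.n, p=list(probs))
        for i in range(spec.n):
            row = {
                "treatment_site": "Unspecified",
                "software_version": "V1.5.2",
                **spec.labels,
            }
            for fieldname in labels:
                if fieldname not in spec.labels:
                    row[fieldname] = str(labels[fieldname][i])
            rows.append(
                (
                    config.date_start + datetime.timedelta(days=int(day_offsets[i])),
                    row,
                    float(dose[i]),
                    float(gpass[i]),
                )
            )
    rows.sort(key=lambda t: t[0])
    records = []
    for idx, (date, row, dose_v, gamma_v) in enumerate(rows, start=1):
        records.append(
            VerificationRecord(
                record_id=f"R{idx:04d}",
                check_date=date,
                treatment_site=row["treatment_site"],
                technique=row["technique"],
                linac=row["linac"],
                energy=row["energy"],
                software_version=row["software_version"],
                tps=row["tps"],
                mean_dose_diff_pct=dose_v,
                gamma_pass_pct=gamma_v,
            )
        )
    return CohortTable(
        records=tuple(records), provenance=f"synthetic(seed={config.seed})"
    )


SCENARIOS = ("identical", "uniform_scale", "gaussian_blob_shift", "noise")


def _blob_field(shape, spacing, centers_mm, widths_mm, peak=2.0, background=0.05):
    """Smooth synthetic dose: superposed 3D Gaussians on a low background."""
    zz, yy, xx = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    values = np.full(shape, background * peak)
    for c, w in zip(centers_mm, widths_mm):
        r2 = (
            ((zz - c[0]) / w[0]) ** 2
            + ((yy - c[1]) / w[1]) ** 2
            + ((xx - c[2]) / w[2]) ** 2
        )
        values += peak * np.exp(-0.5 * r2)
    return values


def generate_dose_pair(
    shape: Sequence[int],
    spacing: Sequence[float],
    scenario: str,
    seed: int,
    *,
    scale: float = 1.0,
    shift_mm: float = 0.0,
    noise_pct: float = 0.0,
) -> tuple[DoseGrid, DoseGrid]:
    """Reference/evaluated dose-grid pair for exercising the gamma pipeline.

    Scenarios: ``identical`` (same grid), ``uniform_scale`` (evaluated =
    scale × reference), ``gaussian_blob_shift`` (target translated by
    shift_mm along x), ``noise`` (multiplicative Gaussian noise of
    noise_pct percent). Deterministic given the seed.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario {scenario!r} not in {SCENARIOS}")
    shape = tuple(int(n) for n in shape)
    spacing = tuple(float(s) for s in spacing)
    rng = np.random.default_rng(seed)
    extent = [(n - 1) * s for n, s in zip(shape, spacing)]
    center = np.array(extent) / 2.0
    jitter = rng.uniform(-0.05, 0.05, size=3) * np.array(extent)
    c0 = center + jitter
    widths = [max(0.18 * e, 2.0) for e in extent]
    centers = [c0, c0 + np.array([0.15 * e for e in extent])]
    widths_all = [widths, [0.6 * w for w in widths]]

    ref_values = _blob_field(shape, spacing, centers, widths_all)
    reference = DoseGrid(values=ref_values, spacing=spacing)

    if scenario == "identical":
        ev_values = ref_values.copy()
    elif scenario == "uniform_scale":
        if scale <= 0:
            raise ValueError("scale must be positive")
        ev_values = ref_values * scale
    elif scenario == "gaussian_blob_shift":
        shifted = [np.asarray(c) + np.array([0.0, 0.0, shift_mm]) for c in centers]
        ev_values = _blob_field(shape, spacing, shifted, widths_all)
    else:  # noise
        factor = 1.0 + noise_pct / 100.0 * rng.standard_normal(shape)
        ev_values = np.clip(ref_values * factor, 0.0, None)
    evaluated = DoseGrid(values=ev_values, spacing=spacing)
    return reference, evaluated
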