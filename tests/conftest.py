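import datetime

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qadb.records import CohortTable, VerificationRecord

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    # read-only fixtures are safe to share across generated examples
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


def make_record(**overrides) -> VerificationRecord:
    base = dict(
        record_id="R0001",
        check_date=datetime.date(2015, 3, 1),
        treatment_site="Prostate",
        technique="IMRT",
        linac="LA1",
        energy="6X",
        software_version="V1.5.2",
        tps="Eclipse",
        mean_dose_diff_pct=0.4,
        gamma_pass_pct=98.5,
    )
    base.update(overrides)
    return VerificationRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def mixed_cohort() -> CohortTable:
    """Three records: Eclipse/Prostate, Eclipse/Lung, iPlan/Brain."""
    return CohortTable(
        records=(
            make_record(record_id="R0001", mean_dose_diff_pct=0.4),
            make_record(
                record_id="R0002",
                treatment_site="Lung",
                technique="3DCRT",
                mean_dose_diff_pct=2.1,
                gamma_pass_pct=97.0,
            ),
            make_record(
                record_id="R0003",
                tps="iPlan",
                technique="DCA",
                linac="LA2",
                energy="6FFF",
                mean_dose_diff_pct=-1.5,
                gamma_pass_pct=95.5,
            ),
        )
    )


def brute_force_gamma(reference, evaluated, criteria) -> np.ndarray:
    """Exhaustive per-voxel gamma: independent oracle for gamma_map.

    Loops over every evaluated voxel within the physical search radius of
    each included reference voxel.
    """
    ref, ev = reference.values, evaluated.values
    spacing = np.asarray(reference.spacing)
    ref_max = ref.max()
    included = ref >= criteria.threshold_pct / 100.0 * ref_max
    radius = criteria.search_radius_factor * criteria.dta_mm
    out = np.full(ref.shape, np.nan)
    for idx in np.ndindex(ref.shape):
        if not included[idx]:
            continue
        if criteria.normalization == "global":
            dcrit = criteria.dose_pct / 100.0 * ref_max
        else:
            dcrit = criteria.dose_pct / 100.0 * ref[idx]
        best = np.inf
        for jdx in np.ndindex(ev.shape):
            d = np.sqrt(
                sum(((i - j) * s) ** 2 for i, j, s in zip(idx, jdx, spacing))
            )
            if d > radius:
                continue
            dd = ev[jdx] - ref[idx]
            if dcrit > 0:
                g2 = (d / criteria.dta_mm) ** 2 + (dd / dcrit) ** 2
            else:
                g2 = (d / criteria.dta_mm) ** 2 if dd == 0 else np.inf
            best = min(best, g2)
        out[idx] = np.sqrt(best)
    return out
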