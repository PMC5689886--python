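"""Normality vetting via the normal probability plot.

Before μ ± kσ limits are trusted, each stratum's metric is checked for
consistency with a normal distribution: the ordered sample is plotted
against standard-normal quantiles at Blom plotting positions
p_i = (i − 0.375)/(n + 0.25), and an ordinary least-squares line is fit.
For a normal sample the points fall on a line whose slope estimates σ and
intercept estimates μ; the correlation coefficient r of the plot is the
linearity diagnostic (a Filliben-style statistic). The verdict threshold
is advisory — reports always print r so the analyst can judge, as the plot
itself is a visual tool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DEFAULT_R_THRESHOLD",
    "NormalityFit",
    "plotting_positions",
    "normal_probability_fit",
    "normality_verdict",
]

#: Advisory correlation threshold for samples of n ≈ 150–1000; close to the
#: Filliben 5% critical values over that range.
DEFAULT_R_THRESHOLD = 0.987


@dataclass(frozen=True)
class NormalityFit:
    """Normal-probability-plot regression: slope ≈ σ, intercept ≈ μ."""

    n: int
    slope: float
    intercept: float
    r: float
    positions: str = "blom"

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("probability-plot fit requires n >= 3")
        if not (-1.0 <= self.r <= 1.0 + 1e-12):
            raise ValueError(f"correlation out of range: {self.r}")


def plotting_positions(n: int) -> np.ndarray:
    """Blom plotting positions (i − 0.375)/(n + 0.25) for i = 1..n."""
    if n < 1:
        raise ValueError("n must be at least 1")
    i = np.arange(1, n + 1, dtype=float)
    return (i - 0.375) / (n + 0.25)


def normal_probability_fit(values) -> NormalityFit:
    """OLS fit of the sorted sample against normal quantiles at Blom positions.

    Order of the input is irrelevant (the sample is sorted internally).
    Constant input has no defined plot slope and raises ``ValueError``.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if x[0] == x[-1]:
        raise ValueError("constant input: zero variance, fit undefined")
    q = stats.norm.ppf(plotting_positions(x.size))
    fit = stats.linregress(q, x)
    return NormalityFit(
        n=int(x.size),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
    )


def normality_verdict(fit: NormalityFit, r_threshold: float = DEFAULT_R_THRESHOLD) -> bool:
    """True when the plot correlation reaches the threshold (normal-enough)."""
    return fit.r >= r_threshold
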