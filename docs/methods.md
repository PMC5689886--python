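# Methods

## The statistical model

Each verification record carries two metrics: the mean target-dose
difference %Δ = 100 × (D_indep − D_TPS) / D_ref (percent of the plan
maximum point dose; positive when the independent calculation is higher)
and the global (3%, 3 mm) gamma passing rate. Within a stratum (a TPS, a
technique, a treatment site), %Δ is modelled as approximately normal with
mean μ (the stratum's systematic offset between the two dose engines) and
standard deviation σ (its plan-to-plan reproducibility). Limits are the
classical control-chart bounds: action level μ ± 2σ, tolerance μ ± 3σ.
Under the normal model a future result breaches the AL with probability
2Φ(−2) ≈ 4.55% and the TL with 2Φ(−3) ≈ 0.27% — i.e. an AL/TL breach
places a plan in roughly the worst 5% / 1% of historical results, which is
the clinical interpretation the limits are built for.

Sample σ uses the n−1 denominator (the records are a sample of the ongoing
process, not the population). Single-record groups report σ as explicitly
absent rather than zero; limit derivation on such groups is an error, and
the audit withholds limits for strata below a configurable minimum size
(default 20) because a 2σ estimate from a handful of plans is noise.

## Normality vetting

μ ± kσ limits are only meaningful if the stratum is adequately normal.
The check is the normal probability plot: sorted values are paired with
standard-normal quantiles at Blom plotting positions
p_i = (i − 0.375)/(n + 0.25), and an ordinary least-squares line is fit.
On a normal sample the points are linear with slope ≈ σ and intercept ≈ μ;
curvature (heavy tails, skew) depresses the correlation r. Blom's
convention was chosen because its quantile pairing is close to the
expected normal order statistics, making the slope/intercept nearly
unbiased estimates; any of the common conventions would serve, and the
label is recorded on the fit object.

The verdict compares r to an advisory threshold (default 0.987, in the
region of the Filliben 5% critical values for n ≈ 150–1000). It is
deliberately advisory: the decision the plot supports is a judgement call,
so every report prints r (and the CLI can emit the plot) rather than
hiding the evidence behind a boolean. Gamma pass rates are bounded above
by 100 and left-skewed; they fail the check by design, and the one-sided
μ − kσ limits applied to them are flagged with that caveat — they are used
for uniformity of process, not because the normal model fits.

## Limit derivation conventions

- **Asymmetric mode** keeps the systematic offset: each of μ ± 2σ and
  μ ± 3σ is rounded to a 0.1% grain. **Symmetric mode** treats a small μ
  as negligible: bounds are ±(kσ) rounded to a coarser 0.5% grain (a
  deliberately rounder number for day-to-day clinical use). The two grains
  reproduce every published asymmetric bound from the printed subgroup
  moments, and 2σ = 1.96 → ±2.0, 3σ = 2.94 → ±3.0 for the symmetric
  stratum.
- Rounding is half-away-from-zero so negative and positive bounds behave
  mirror-symmetrically; an epsilon absorbs binary-float noise on exact
  halves.
- Dose bounds are clamped to a clinical-acceptability cap (default ±5%,
  the vendor default) with a per-bound capped flag. A cap tighter than the
  *action level* is a policy conflict and an error rather than a silent
  clamp. Capping both TL bounds preserves the AL ⊂ TL nesting.
- Mode selection is an explicit policy choice. An optional automation
  (`auto_symmetric`) switches to symmetric when |μ| is under a threshold
  (default 0.3%), but it is off by default: the published choice was made
  "for simplicity" by the physicists, not by a rule.
- Gamma limits are one-sided low (AL = μ − 2σ, TL = μ − 3σ, floored at 0);
  an upper bound on a pass rate capped at 100 carries no information.
  On the printed overall moments (97.3, 2.9) this gives AL 91.5 and
  TL 88.6; the published tolerance is 88.5, evidently computed from
  unrounded moments, a 0.1 discrepancy documented here and not chased.

## Audit conventions

A value exactly on a printed bound **passes** (strict inequalities define
failure): printed limits are rounded, so boundary equality is common and
the lenient convention is the safer default to state explicitly. Failure
counts are per bound; for nested limits every TL failure is an AL failure,
asserted on every audit. The vendor-default gamma limits (AL 90 / TL 85)
reference a (5%, 3 mm) criterion while the database stores (3%, 3 mm)
rates; the default-gamma audit is reported with that caveat since it
overstates failures.

## The gamma index

For each reference voxel at or above the low-dose threshold (default 10%
of the reference maximum), gamma is the minimum over evaluated voxel
centres within a search sphere (radius 3 × dta) of
sqrt(Δr²/dta² + ΔD²/ΔD_crit²). Global normalisation (the headline mode)
takes ΔD_crit as dose_pct% of the reference maximum; local normalisation
uses each reference voxel's own dose. Version-1 scope: equal-geometry
grids, voxel-centre evaluation, no sub-voxel interpolation. The optimised
implementation scans lattice offsets in order of increasing physical
distance and stops when the pure distance term exceeds every running
minimum; it is tested for exact equality against an exhaustive
brute-force search on grids up to 11³.

Voxel-centre evaluation has a visible discretisation effect: a spatial
shift that is an exact multiple of the voxel size can score *better* than
a smaller off-lattice shift, because only aligned shifts allow a perfect
dose match at some lattice offset. Monotonicity of the pass rate in the
shift magnitude therefore holds along lattice-aligned shifts;
interpolation, which would smooth this out, is future work.

## The synthetic cohort

The generator stands in for the (unpublished) clinical database. Its
defaults encode the published structure: 1000 records over a ~7-month
accrual, Eclipse 856 (μ 0.25, σ 0.98), iPlan 144 (μ −1.10, σ 1.66), with
the Lung site (32, μ 1.74, σ 1.18) carved out of the Eclipse allocation
since lung plans were exclusively Eclipse-planned; overall gamma moments
97.3/2.9 applied to every subgroup by default (per-stratum overrides are
configuration).

- **Dose differences** are drawn from a normal truncated to ±5% by
  rejection — justified by the observation that all 1000 recorded values
  fell inside the ±5% defaults and by the bell-shaped histograms.
  Truncation shifts the realised moments: negligibly for the Eclipse-like
  subgroup, but by about +0.04 on the mean (and −0.05 on the SD) for the
  iPlan-like one, whose −5 bound sits at 2.3σ. Tests therefore compare
  sample moments against the analytic truncated-normal moments
  (scipy `truncnorm`), not the untruncated targets.
- **Gamma pass rates** are 100 − X with X gamma-distributed,
  moment-matched to mean 100 − μ and SD σ and truncated to [0, 100]: the
  minimal bounded, left-skewed, two-moment family consistent with the
  published histogram shape. The family is a modelling choice, not data.
- **Labels** (technique, linac, energy, non-lung site) are sampled from
  per-subgroup categorical pools with proportions taken from the published
  margins. They are cosmetic — the published technique margins do not nest
  exactly inside the TPS margins, so no joint distribution reproduces both,
  and only the modelled strata moments carry meaning.
- The two metrics are generated independently per record; any real
  per-plan correlation between dose difference and gamma is unmodelled — a
  known limitation. Dates are uniform over the accrual window, so the
  generator has no time trends; passing audits say nothing about temporal
  drift in real data, which the scatter-over-time figure exists to reveal.

Dose-grid pairs for the gamma pipeline are smooth synthetic fields
(superposed 3D Gaussian targets on a 5% background, peak 2 Gy) under four
scenarios: identical, uniform scaling, target translation, and
multiplicative Gaussian noise. All generation is deterministic given the
seed (NumPy `default_rng`).

## Problem sizes and numerical choices

Moment-recovery tests use 10,000-record subgroups (sampling SE of the
mean ≈ σ/100, well inside the 0.05 assertion window); the end-to-end
symmetric-limit reproduction uses 5,000 records, where the ±0.5-grain
rounding basin (σ̂ ∈ [0.917, 1.083] for ±3.0) is dozens of standard errors
wide. Gamma-oracle equality runs on 7³–11³ grids with 2 mm voxels.
Exceedance simulation uses 100,000 standard-normal draws. CSV floats are
written as shortest round-tripping representations so write∘read is the
identity on files the package wrote.

## Known limitations

- No CUSUM/EWMA or other sequential monitoring; limits are static μ ± kσ.
- No distribution-free tolerance intervals or transformations for the
  skewed gamma metric (kept μ/σ-based for uniformity, as published).
- Gamma v1 requires equal grid geometry; no resampling, no interpolation.
- The synthetic cohort reproduces moments and truncation, not the real
  database's time structure, label correlations, or metric correlations.
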