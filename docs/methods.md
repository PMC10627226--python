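# Methods

## Scope and model

`ojip` analyses dark-adapted chlorophyll-*a* fluorescence induction
transients (the O–J–I–P rise recorded by PEA-class instruments on a
logarithmic time grid, ~10 µs to 1 s) and derives the JIP-test parameter
suite per trace, followed by treatment-level statistics in the style of
agronomy reports.  It does not fit or deconvolve the transient, model PSII
connectivity (L band), quantify the H step, or analyse light-adapted
quenching; it also makes no attempt to reproduce published group-mean
performance-index values, because group means of a nonlinear function of
the landmarks are not recoverable from other group means.

## Fiducial extraction

Landmark values are the *nearest grid sample* to the nominal times
(O 50 µs, K 300 µs, J 2 ms, I 30 ms), never interpolated — interpolation
would manufacture precision between log-spaced samples that the instrument
does not have.  A landmark is covered when its nearest sample lies within a
multiplicative factor of 1.25 in time; this factor matches log spacing
(additive tolerances do not) and is configurable.  Fm is the maximum over
the whole trace, recorded with its time, so post-peak dips (H-step-like
features) cannot corrupt it.  A trace with Fm − F0 ≤ 10⁻⁶·Fm is degenerate
(no variable fluorescence) and the engine refuses it with a specific error;
the validator reports the same condition as a flag without raising.

## Parameter conventions

Where the JIP framework admits variants, the package fixes these
conventions (all exposed in code, none silently):

- **Mo** = 4·(F300 − F50)/(Fm − F50) in ms⁻¹ — the standard initial-slope
  estimate consistent with TRo/RC = Mo/Vj.
- **RC/ABS** = φPo·Vj/Mo, with γRC = RC/(RC+ABS) so γRC/(1−γRC) equals the
  density exactly.
- **KN, KP**: ABS per excited cross-section is proxied by F0 and KF fixed
  at 1 arbitrary unit, giving the dimensionless KN = F0/Fm and
  KP = 1 − F0/Fm ("in KF units") with KN + KP = 1 and KP = φPo.  The proxy
  preserves every between-treatment comparison; an alternative constant
  proxy is available via `DeexcitationConvention`.
- **DFtotal** = log10(PItotal), the established driving-force definition.
- **K band**: the raw-fluorescence ratio Fk/Fj (not variable-fluorescence),
  flagged above the 0.6 empirical limit with a *strict* inequality, so a
  ratio of exactly 0.6 does not flag.
- **δRo under noise**: measurement noise can invert Vi < Vj; δRo > 1 is
  then reported unclamped with a `vi_anomaly` flag (field reports do print
  δRo above 1), and PItotal/DFtotal become NaN because their defining
  ratio leaves its domain.
- **Report rounding**: half away from zero, three decimals for φPo (Fv/Fm),
  two elsewhere — the convention of printed treatment tables.

## Synthetic transients

The generator is phenomenological by design: the analysis needs correct
landmark structure, not electron-transport kinetics, so a mechanistic ODE
model would add parameters without adding test power.  The model is

    F(t) = F0·(1 + k·g(t)) + (Fm − F0)·S(t)/S(t_max),
    S(t) = Σ_p a_p·(1 − exp(−(t − 50 µs)₊/τ_p)),  p ∈ {OJ, JI, IP}

with defaults F0 = 500, Fm = 2500 a.u., amplitudes (0.5, 0.3, 0.2) and
time constants (250 µs, 5 ms, 60 ms) on a 140-point log grid (10 µs–1 s)
with the four fiducial times inserted exactly.  Two deliberate numerical
choices make noise-free recovery exact rather than approximate: the phase
rise is anchored at the O mark and normalised to reach exactly 1 at the
last grid point (otherwise the exponential tail alone leaves a ~10⁻⁷
residual in φPo), and the K-band bump — a log-time Gaussian centred at
300 µs, width 0.15 decades — has compact support (±4σ, i.e. 75 µs–1.2 ms)
so it cannot perturb the O/J/I landmarks at all.  Noise is per-point
multiplicative lognormal with unit mean (default CV 0.02, a typical
clean-trace variability) plus lognormal pot-level random effects on F0 and
Fm (default σ 0.05) drawn once per replicate and shared by its
measurements — this is what makes replicate means the right ANOVA unit.
All generation is a pure function of (preset, grid, seed) via
`numpy.random.SeedSequence` spawning.

Treatment scenarios are multiplicative preset shifts: raised F0, lowered
Fm and an added K band for heat; a scaled-down I–P amplitude (then
renormalised) for chilling.  The shipped temperature and day-length presets
are **directional illustrations, not fits** — no quantitative transient
data exist to fit.  Two emergent properties deserve note when interpreting
synthetic runs.  First, the default kinetics put the control Fk/Fj near
0.68, above the 0.6 damage limit, so on synthetic data the *comparative*
K-band shift carries the signal, not the absolute flag.  Second, because
the V ratios are taken relative to the measured Fm, suppressing the I–P
amplitude raises Vi and therefore *lowers* δRo in this model; the δRo
*increase* reported for chilled field plants arises from Vi anomalies
(δRo > 1 implies Vi < Vj) that a monotone kinetic model cannot and should
not produce.  Passing tests therefore demonstrate correct plumbing and
directional sensitivity, not realism of any particular parameter value;
real instrument quirks (detector saturation, autocorrelated noise, leaf
heterogeneity) are out of scope.

The synthetic harvest generator maps each scenario to a scalar severity
s = 1 − dFm/dF0 and shifts lognormal (CV 0.15) compartment means: leaf and
stem mass decline moderately, pod mass collapses linearly to zero at
severity 0.35 (the severe-heat preset's level — pods abort entirely), and
apparent leaf area rises slightly under stress.

## Statistics

Observations entering the per-maturity-group one-way ANOVA are **replicate
(pot) means** by default: the 15 within-pot measurements are
pseudo-replicates sharing the pot random effect, and using them raw would
inflate the error degrees of freedom (a config flag switches to raw
measurements for comparison).  The ANOVA is the classical fixed-effects
decomposition, implemented directly because Duncan's test needs the MSE and
error df; it is cross-checked against an independent library routine in the
tests.

Duncan's multiple range test is implemented from its definition: means
sorted descending; the least significant range for a span of p means uses
the studentized-range quantile at protection level 1 − (1 − α)^(p−1)
(quantiles cached — each evaluation costs ~0.25 s); a range contained in a
non-significant wider range is never declared significant; harmonic-mean n
under imbalance.  Letters come from the insert-and-absorb compact-letter
display, ordered so "a" sits on the largest mean.  The test suite checks
the resulting partition against an exhaustive-span oracle that evaluates
every containing span directly, on 120+ random designs, and verifies the
display never separates a pair the range test declares non-significant.

Significance stars use inclusive thresholds (*** p ≤ 0.001, ** p ≤ 0.01,
* p ≤ 0.05, else "ns").  Correlations are Pearson (configurable), pooled
across all treatments and groups, with constant columns dropped under a
warning; heatmap ordering is average-linkage clustering on 1 − r with
optimal leaf ordering, rendered on a brown–teal diverging scale.

Type-I calibration of the whole simulate→extract→ANOVA chain is checked by
500 null experiments (three neutral levels, 5 pots × 2 measurements —
the rejection rate is invariant to the measurement count, so 2 keeps the
check fast); the empirical rate must fall in [0.03, 0.07] at α = 0.05.

## Pipeline determinism

One top-level seed drives all stages; text outputs (CSV/JSON) are
byte-stable and hashed (SHA-256) into the run manifest.  Image outputs are
written but not hashed, since plot-backend metadata is not guaranteed
byte-stable across versions.

## Known limitations

- Kinetics are monotone sums of exponentials: no H step, no connectivity
  sigmoidicity, no Vi-anomaly mechanism (see above).
- Scenario presets are qualitative; synthetic group differences should not
  be read as predicted effect sizes.
- One treatment axis per experiment table (matching the underlying design);
  no two-way or mixed-model ANOVA, and no multiple-testing correction
  across parameters (deliberately, matching standard reporting practice in
  this literature).
- Proprietary binary instrument exports are not parsed; the long-format
  CSV/TSV layout is the interchange format.
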