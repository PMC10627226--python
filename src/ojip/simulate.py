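"""Synthetic OJIP transient and experiment generator.

The simulator emulates dark-adapted Handy-PEA measurements: a polyphasic
fluorescence rise with O (50 µs), J (~2 ms), I (~30 ms) and P phases on a
logarithmic time grid, an optional K-band bump near 300 µs, multiplicative
measurement noise, and between-replicate (pot-level) variability.  It exists
so every downstream stage — fiducial extraction, the JIP parameter suite,
ANOVA/Duncan reporting — is testable without instrument data.

Kinetic model (phenomenological, not a mechanistic PSII model)::

    F(t) = F0·(1 + k·g(t)) + (Fm − F0)·S(t)/S(t_max)
    S(t) = Σ_p a_p·(1 − exp(−(t − t_O)₊/τ_p)),  p ∈ {OJ, JI, IP}

with the phase rise anchored at the O time mark t_O = 50 µs and normalised
to reach exactly 1 at the last grid point, so a noise-free trace hits F0 at
the O mark and Fm at its maximum *exactly* — the engine then recovers the
preset's 1 − F0/Fm as φPo to machine precision.  g is a Gaussian bump in
log-time centred at 300 µs with width 0.15 decades (the K band).  Noise is
per-point multiplicative lognormal (unit mean, coefficient of variation
``noise_cv``) plus lognormal replicate random effects on F0 and Fm shared by
all measurements of a replicate.

Treatment scenarios are multiplicative shifts of the preset
(:class:`ScenarioEffect`); the shipped presets are qualitative — directional
stand-ins for heat (raised F0, lowered Fm, K band), cold (suppressed I–P
amplitude) and long-day-length responses — not fits to any measured data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .growth import PlantHarvest
from .transients import FIDUCIAL_TIMES_US, Transient, TreatmentDesign

_T_O_US = FIDUCIAL_TIMES_US["O"]
_KBAND_CENTER_US = FIDUCIAL_TIMES_US["K"]
_KBAND_WIDTH_DECADES = 0.15


@dataclass(frozen=True)
class KineticPreset:
    """Generator parameters for one treatment condition.

    ``phase_amplitudes`` are the relative contributions of the O–J, J–I and
    I–P rise phases (non-negative, summing to 1); ``phase_taus`` their time
    constants in µs, strictly increasing.  ``noise_cv`` is the per-point
    multiplicative noise CV; ``replicate_sd`` the lognormal sigma of the
    pot-level random effect on F0 and Fm.
    """

    F0_base: float = 500.0
    Fm_base: float = 2500.0
    phase_amplitudes: tuple[float, float, float] = (0.5, 0.3, 0.2)
    phase_taus: tuple[float, float, float] = (250.0, 5_000.0, 60_000.0)
    k_band_amplitude: float = 0.0
    noise_cv: float = 0.02
    replicate_sd: float = 0.05

    def validate(self) -> None:
        a = np.asarray(self.phase_amplitudes, dtype=float)
        tau = np.asarray(self.phase_taus, dtype=float)
        if np.any(a < 0) or not np.isclose(a.sum(), 1.0, atol=1e-9):
            raise ValidationError(
                f"phase amplitudes must be >= 0 and sum to 1, got {tuple(a)}"
            )
        if np.any(np.diff(tau) <= 0) or np.any(tau <= 0):
            raise ValidationError(
                f"phase taus must be positive and strictly increasing, got {tuple(tau)}"
            )
        if not (0 < self.F0_base < self.Fm_base):
            raise ValidationError(
                f"need 0 < F0_base < Fm_base, got {self.F0_base}, {self.Fm_base}"
            )
        if self.noise_cv < 0 or self.replicate_sd < 0:
            raise ValidationError("noise_cv and replicate_sd must be >= 0")
        if self.k_band_amplitude < 0:
            raise ValidationError("k_band_amplitude must be >= 0")


@dataclass(frozen=True)
class ScenarioEffect:
    """Multiplicative treatment shifts applied to a :class:`KineticPreset`.

    Neutral defaults (all factors 1, additive K band 0) leave the preset
    unchanged.  ``d_IP`` scales the I–P phase amplitude, after which the
    amplitudes are renormalised to sum to 1.
    """

    d_F0: float = 1.0
    d_Fm: float = 1.0
    d_IP: float = 1.0
    d_Kband: float = 0.0


NEUTRAL = ScenarioEffect()
#: Severe-heat shifts: raised F0, collapsed Fm, prominent K band.
HEAT_SCENARIO = ScenarioEffect(d_F0=1.2, d_Fm=0.75, d_Kband=0.15)
#: Chilling shifts: suppressed I–P phase amplitude.
COLD_SCENARIO = ScenarioEffect(d_IP=0.4)

#: Illustrative presets for the day/night temperature levels of the design.
TEMPERATURE_SCENARIOS: Mapping[str, ScenarioEffect] = {
    "22/14": ScenarioEffect(d_F0=1.10, d_Fm=0.85, d_IP=0.45),
    "26/18": NEUTRAL,
    "30/22": ScenarioEffect(d_Fm=0.97),
    "34/26": ScenarioEffect(d_F0=1.10, d_Fm=0.88, d_IP=0.70, d_Kband=0.08),
    "40/32": ScenarioEffect(d_F0=1.20, d_Fm=0.75, d_IP=0.60, d_Kband=0.15),
}

#: Illustrative presets for the day-length (hours) levels of the design.
DAY_LENGTH_SCENARIOS: Mapping[float, ScenarioEffect] = {
    12.5: NEUTRAL,
    13.5: ScenarioEffect(d_F0=1.05, d_Fm=0.92, d_IP=0.80),
    14.5: ScenarioEffect(d_F0=1.08, d_Fm=0.88, d_IP=0.70),
}

DEFAULT_MATURITY_GROUPS = ("0", "III", "IX", "X")
CONTROL_DAY_LENGTH_H = 12.5
CONTROL_TEMPERATURE = (26.0, 18.0)


def default_grid(n_points: int = 140) -> np.ndarray:
    """Log-spaced time grid, 10 µs – 1 s, with the four fiducials inserted.

    ``n_points`` counts the final grid including the inserted landmark
    times, so nearest-sample fiducial extraction is exact on this grid.
    """
    fiducials = np.array(sorted(FIDUCIAL_TIMES_US.values()))
    base = np.geomspace(10.0, 1e6, n_points - len(fiducials))
    return np.unique(np.concatenate([base, fiducials]))


def apply_scenario(preset: KineticPreset, effect: ScenarioEffect) -> KineticPreset:
    """Apply treatment shifts to a preset; a neutral effect is the identity."""
    a_oj, a_ji, a_ip = preset.phase_amplitudes
    a_ip = a_ip * effect.d_IP
    total = a_oj + a_ji + a_ip
    if a_ip < 0 or total <= 0:
        raise ValidationError("amplitude renormalisation impossible under effect")
    if effect.d_IP == 1.0:
        amplitudes = preset.phase_amplitudes  # exact identity for neutral d_IP
    else:
        amplitudes = (a_oj / total, a_ji / total, a_ip / total)
    shifted = replace(
        preset,
        F0_base=preset.F0_base * effect.d_F0,
        Fm_base=preset.Fm_base * effect.d_Fm,
        phase_amplitudes=amplitudes,
        k_band_amplitude=preset.k_band_amplitude + effect.d_Kband,
    )
    shifted.validate()
    return shifted


def _kband_bump(times_us: np.ndarray) -> np.ndarray:
    # log-time Gaussian, compact support (+-4 sigma ~ 75 us - 1.2 ms): the
    # band must leave the O/J/I landmarks exactly untouched
    z = np.log10(times_us / _KBAND_CENTER_US) / _KBAND_WIDTH_DECADES
    return np.where(np.abs(z) <= 4.0, np.exp(-0.5 * z * z), 0.0)


def _noise_free_curve(preset: KineticPreset, grid: np.ndarray) -> np.ndarray:
    a = np.asarray(preset.phase_amplitudes)
    tau = np.asarray(preset.phase_taus)
    dt = np.clip(grid[:, None] - _T_O_US, 0.0, None)
    s = (a * (1.0 - np.exp(-dt / tau))).sum(axis=1)
    s_max = s[-1]
    if s_max <= 0:
        raise ValidationError("kinetic rise vanished: check taus against the grid")
    s /= s_max
    f0, fm = preset.F0_base, preset.Fm_base
    curve = f0 + (fm - f0) * s
    if preset.k_band_amplitude > 0:
        curve = curve + f0 * preset.k_band_amplitude * _kband_bump(grid)
    return curve


def relative_rise(preset: KineticPreset, t_us: float,
                  grid: np.ndarray | None = None) -> float:
    """Closed-form V(t) of the noise-free model (independent of noise)."""
    if grid is None:
        grid = default_grid()
    a = np.asarray(preset.phase_amplitudes)
    tau = np.asarray(preset.phase_taus)

    def s(t: float) -> float:
        return float((a * (1.0 - np.exp(-max(t - _T_O_US, 0.0) / tau))).sum())

    return s(t_us) / s(float(grid[-1]))


def simulate_transient(
    preset: KineticPreset,
    grid: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    meta: TreatmentDesign | None = None,
) -> Transient:
    """Simulate one OJIP transient.

    With ``noise_cv = 0`` the output is the deterministic closed form;
    otherwise each point is multiplied by a unit-mean lognormal factor.
    The same seed always yields a bit-identical trace.
    """
    preset.validate()
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    curve = _noise_free_curve(preset, grid)
    if preset.noise_cv > 0:
        sigma = np.sqrt(np.log1p(preset.noise_cv**2))
        curve = curve * rng.lognormal(-0.5 * sigma**2, sigma, size=len(grid))
    if meta is None:
        meta = TreatmentDesign(
            maturity_group="0",
            day_length_h=CONTROL_DAY_LENGTH_H,
            temperature_day_c=CONTROL_TEMPERATURE[0],
            temperature_night_c=CONTROL_TEMPERATURE[1],
        )
    return Transient(grid, curve, meta)


def _level_meta(axis: str, level) -> dict:
    if axis == "temperature":
        day, night = (float(x) for x in str(level).split("/"))
        return {
            "day_length_h": CONTROL_DAY_LENGTH_H,
            "temperature_day_c": day,
            "temperature_night_c": night,
        }
    if axis == "day_length":
        return {
            "day_length_h": float(level),
            "temperature_day_c": CONTROL_TEMPERATURE[0],
            "temperature_night_c": CONTROL_TEMPERATURE[1],
        }
    raise ConfigurationError(f"unknown treatment axis: {axis!r}")


def generate_experiment(
    levels: Sequence,
    scenarios: Mapping,
    maturity_groups: Sequence[str] = DEFAULT_MATURITY_GROUPS,
    axis: str = "temperature",
    n_reps: int = 5,
    n_meas: int = 15,
    seed: int = 0,
    preset: KineticPreset = KineticPreset(),
    grid: np.ndarray | None = None,
) -> list[Transient]:
    """Generate a full factorial experiment of simulated transients.

    Produces ``len(maturity_groups) × len(levels) × n_reps × n_meas``
    traces.  Replicate (pot-level) lognormal random effects on F0 and Fm
    are drawn once per (group, level, replicate) and shared by that
    replicate's measurements.  Fully reproducible from ``seed``.
    """
    if n_reps < 1 or n_meas < 1:
        raise ConfigurationError("n_reps and n_meas must be >= 1")
    missing = [lv for lv in levels if lv not in scenarios]
    if missing:
        raise ConfigurationError(
            f"no scenario configured for level(s): {missing}"
        )
    if grid is None:
        grid = default_grid()
    root = np.random.SeedSequence(seed)
    n_cells = len(maturity_groups) * len(levels) * n_reps
    children = root.spawn(n_cells)
    traces: list[Transient] = []
    cell = 0
    for mg in maturity_groups:
        for level in levels:
            level_preset = apply_scenario(preset, scenarios[level])
            meta_kwargs = _level_meta(axis, level)
            for rep in range(1, n_reps + 1):
                rng = np.random.default_rng(children[cell])
                cell += 1
                if level_preset.replicate_sd > 0:
                    sd = level_preset.replicate_sd
                    f0_fac, fm_fac = rng.lognormal(-0.5 * sd**2, sd, size=2)
                else:
                    f0_fac = fm_fac = 1.0
                rep_preset = replace(
                    level_preset,
                    F0_base=level_preset.F0_base * f0_fac,
                    Fm_base=max(level_preset.Fm_base * fm_fac,
                                level_preset.F0_base * f0_fac * 1.05),
                )
                for meas in range(1, n_meas + 1):
                    meta = TreatmentDesign(
                        maturity_group=str(mg),
                        replicate=rep,
                        measurement=meas,
                        **meta_kwargs,
                    )
                    traces.append(
                        simulate_transient(rep_preset, grid, rng, meta)
                    )
    return traces


# ---------------------------------------------------------------------------
# synthetic plant harvests (aboveground biomass + leaf area)
# ---------------------------------------------------------------------------

#: Baseline per-plant means: leaf area cm², leaf/stem/pod dry mass g.
HARVEST_BASELINE = {"leaf_area": 900.0, "leaf": 6.0, "stem": 7.0, "pod": 10.0}

#: Severity at which pod set fails entirely (the severe-heat preset's level).
POD_ABORT_SEVERITY = 0.35


def _stress_index(effect: ScenarioEffect) -> float:
    """Scalar stress severity in [0, 1] derived from a scenario's shifts."""
    return float(np.clip(1.0 - effect.d_Fm / effect.d_F0, 0.0, 1.0))


def generate_harvests(
    levels: Sequence,
    scenarios: Mapping,
    maturity_groups: Sequence[str] = DEFAULT_MATURITY_GROUPS,
    axis: str = "temperature",
    n_reps: int = 5,
    seed: int = 0,
    cv: float = 0.15,
) -> list[PlantHarvest]:
    """Generate lognormal plant harvests with scenario-linked mean shifts.

    Severity (from the scenario's F0/Fm shifts) scales the means: pods
    collapse fastest (none left under the severe-heat shifts), leaf and stem
    mass decline moderately, apparent leaf area increases slightly under
    stress (thicker, spongier leaves).
    """
    missing = [lv for lv in levels if lv not in scenarios]
    if missing:
        raise ConfigurationError(f"no scenario configured for level(s): {missing}")
    root = np.random.SeedSequence([seed, 9157])
    rng = np.random.default_rng(root)
    sigma = np.sqrt(np.log1p(cv**2))
    harvests: list[PlantHarvest] = []
    for mg in maturity_groups:
        for level in levels:
            s = _stress_index(scenarios[level])
            means = {
                "leaf_area": HARVEST_BASELINE["leaf_area"] * (1 + 0.2 * s),
                "leaf": HARVEST_BASELINE["leaf"] * (1 - 0.5 * s),
                "stem": HARVEST_BASELINE["stem"] * (1 - 0.4 * s),
                "pod": HARVEST_BASELINE["pod"]
                * max(0.0, 1.0 - s / POD_ABORT_SEVERITY),
            }
            meta_kwargs = _level_meta(axis, level)
            for rep in range(1, n_reps + 1):
                draw = {
                    k: (m * rng.lognormal(-0.5 * sigma**2, sigma) if m > 0 else 0.0)
                    for k, m in means.items()
                }
                harvests.append(
                    PlantHarvest(
                        leaf_area_cm2=draw["leaf_area"],
                        leaf_dry_g=draw["leaf"],
                        stem_dry_g=draw["stem"],
                        pod_dry_g=draw["pod"],
                        meta=TreatmentDesign(
                            maturity_group=str(mg), replicate=rep, **meta_kwargs
                        ),
                    )
                )
    return harvests
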