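"""JIP-test engine: OJIP fiducial extraction and the derived parameter suite.

The JIP test converts the landmark fluorescence values of a dark-adapted
OJIP transient — F0 at the O mark (50 µs), Fk at the K band (300 µs), Fj at
the J step (2 ms), Fi at the I step (30 ms) and the maximum Fm — into
quantum yields, specific energy fluxes per active PSII reaction center,
de-excitation rate constants and performance indices.

Core definitions (all dimensionless unless noted):

- relative variable fluorescence  V(t) = (F(t) − F0) / (Fm − F0)
- initial slope                    Mo = 4·(F300 − F50)/(Fm − F50)   [ms⁻¹]
- maximum PSII photochemical yield φPo = Fv/Fm = 1 − F0/Fm
- heat-dissipation yield           φDo = F0/Fm = 1 − φPo
- electron-transport probability   ψEo = 1 − Vj
- electron-transport yield         φEo = φPo·ψEo
- PSI-end transfer efficiency      δRo = (1 − Vi)/(1 − Vj)
- PSI-end reduction yield          φRo = φEo·δRo
- trapping flux per RC             TRo/RC = Mo/Vj
- transport flux per RC            ETo/RC = (Mo/Vj)·(1 − Vj)
- PSI-end flux per RC              REo/RC = (Mo/Vj)·(1 − Vi)
- RC density                       γRC/(1 − γRC) = RC/ABS = φPo·Vj/Mo
- performance index                PIabs = RC/ABS · φPo/(1−φPo) · ψEo/(1−ψEo)
- total performance index          PItotal = PIabs · δRo/(1−δRo)
- structure–function index         SFabs = γRC·φPo·ψEo
- total driving force              DFtotal = log10(PItotal)
- K-band ratio                     Fk/Fj, with an oxygen-evolving-complex
                                   damage flag when the ratio exceeds the
                                   0.6 empirical limit.

Landmark values are nearest-sample, never interpolated, matching instrument
behaviour on a log-spaced grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dataclass_fields
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateTraceError, DomainError, FiducialGapError
from .transients import (
    DEFAULT_TOLERANCE_FACTOR,
    FIDUCIAL_TIMES_US,
    Transient,
    metadata_frame,
)

#: Fk/Fj above this empirical limit flags donor-side (OEC) damage.
DEFAULT_KBAND_LIMIT: float = 0.6

#: Relative Fv threshold below which a trace is treated as degenerate.
DEGENERACY_THRESHOLD: float = 1e-6


@dataclass(frozen=True)
class FiducialSet:
    """Landmark fluorescence values of one transient plus derived ratios."""

    F0: float
    Fk: float
    Fj: float
    Fi: float
    Fm: float
    t_Fm_us: float
    Fv: float
    Vk: float
    Vj: float
    Vi: float
    Mo: float  # ms^-1

    @classmethod
    def from_landmarks(
        cls, F0: float, Fk: float, Fj: float, Fi: float, Fm: float,
        t_Fm_us: float = 0.0,
    ) -> "FiducialSet":
        """Build a FiducialSet from raw landmark values (Vx and Mo derived)."""
        fv = Fm - F0
        if fv <= DEGENERACY_THRESHOLD * Fm:
            raise DegenerateTraceError(
                f"no variable fluorescence: Fm={Fm:g}, F0={F0:g}"
            )
        return cls(
            F0=F0, Fk=Fk, Fj=Fj, Fi=Fi, Fm=Fm, t_Fm_us=t_Fm_us, Fv=fv,
            Vk=(Fk - F0) / fv,
            Vj=(Fj - F0) / fv,
            Vi=(Fi - F0) / fv,
            Mo=4.0 * (Fk - F0) / (Fm - F0),
        )


@dataclass(frozen=True)
class DeexcitationConvention:
    """Convention for the antenna de-excitation rate constants KN and KP.

    KN = (ABS/CSo)·KF/Fm and KP = (ABS/CSo)·KF·(1/F0 − 1/Fm).  ABS per
    excited cross-section is approximated by F0 (the customary proxy) and KF
    is an arbitrary-unit constant, so with the defaults KN = F0/Fm and
    KP = 1 − F0/Fm: both dimensionless "in KF units", with KN + KP = 1 and
    KP = φPo.  All comparative structure between treatments is preserved.
    """

    abs_per_cs_proxy: str = "F0"  # {"F0", "constant"}
    K_F: float = 1.0

    def __post_init__(self) -> None:
        if self.K_F <= 0:
            raise DomainError(f"K_F must be > 0, got {self.K_F}")
        if self.abs_per_cs_proxy not in ("F0", "constant"):
            raise DomainError(
                f"abs_per_cs_proxy must be 'F0' or 'constant', "
                f"got {self.abs_per_cs_proxy!r}"
            )


@dataclass
class JipParameters:
    """The full JIP-test parameter suite for one transient."""

    phi_Po: float
    phi_Do: float
    psi_Eo: float
    phi_Eo: float
    delta_Ro: float
    phi_Ro: float
    TRo_RC: float
    ETo_RC: float
    REo_RC: float
    rc_density: float
    gamma_RC: float
    K_N: float
    K_P: float
    PI_abs: float
    PI_total: float
    SF_abs: float
    DF_total: float
    Fk_Fj: float
    oec_flag: bool
    vi_anomaly: bool = False  # Vi < Vj (noise): delta_Ro > 1 reported unclamped

    @classmethod
    def column_names(cls) -> list[str]:
        return [f.name for f in dataclass_fields(cls)]


# ---------------------------------------------------------------------------
# fiducial extraction
# ---------------------------------------------------------------------------

def _nearest_sample(trace: Transient, t_us: float, tolerance_factor: float,
                    name: str) -> float:
    idx = int(np.argmin(np.abs(trace.times_us - t_us)))
    t_near = trace.times_us[idx]
    if max(t_near / t_us, t_us / t_near) > tolerance_factor:
        raise FiducialGapError(
            f"no sample within factor {tolerance_factor:g} of landmark "
            f"{name} ({t_us:g} us); nearest is {t_near:g} us"
        )
    return float(trace.fluorescence[idx])


def extract_fiducials(
    trace: Transient,
    fiducial_times: Mapping[str, float] = FIDUCIAL_TIMES_US,
    tolerance_factor: float = DEFAULT_TOLERANCE_FACTOR,
) -> FiducialSet:
    """Extract O/K/J/I landmark values and Fm from a transient.

    Landmark fluorescence is the nearest grid sample within the
    multiplicative time tolerance; Fm is the maximum over the whole trace
    (recorded with its time, so post-peak dips never corrupt it).

    Raises
    ------
    DegenerateTraceError
        If Fm − F0 ≤ 1e-6·Fm (no variable fluorescence).
    FiducialGapError
        If any landmark has no grid sample within tolerance.
    """
    f0 = _nearest_sample(trace, fiducial_times["O"], tolerance_factor, "O")
    fk = _nearest_sample(trace, fiducial_times["K"], tolerance_factor, "K")
    fj = _nearest_sample(trace, fiducial_times["J"], tolerance_factor, "J")
    fi = _nearest_sample(trace, fiducial_times["I"], tolerance_factor, "I")
    i_max = int(np.argmax(trace.fluorescence))
    fm = float(trace.fluorescence[i_max])
    t_fm = float(trace.times_us[i_max])
    return FiducialSet.from_landmarks(f0, fk, fj, fi, fm, t_Fm_us=t_fm)


# ---------------------------------------------------------------------------
# parameter operations
# ---------------------------------------------------------------------------

def compute_quantum_yields(f: FiducialSet) -> dict[str, float]:
    """Quantum yields and flux probabilities: φPo, φDo, ψEo, φEo, δRo, φRo.

    φPo + φDo = 1 holds exactly by construction.  When noise makes Vi < Vj,
    δRo > 1 is reported unclamped (callers may flag it); Vj = 1 raises a
    :class:`DomainError` since δRo is then undefined.
    """
    phi_po = f.Fv / f.Fm
    phi_do = f.F0 / f.Fm
    psi_eo = 1.0 - f.Vj
    phi_eo = phi_po * psi_eo
    if f.Vj >= 1.0:
        raise DomainError("Vj = 1: delta_Ro undefined (1 - Vj vanishes)")
    delta_ro = (1.0 - f.Vi) / (1.0 - f.Vj)
    phi_ro = phi_eo * delta_ro
    return {
        "phi_Po": phi_po,
        "phi_Do": phi_do,
        "psi_Eo": psi_eo,
        "phi_Eo": phi_eo,
        "delta_Ro": delta_ro,
        "phi_Ro": phi_ro,
    }


def compute_specific_fluxes(f: FiducialSet) -> dict[str, float]:
    """Specific fluxes per active reaction center: TRo/RC, ETo/RC, REo/RC."""
    if f.Vj <= 0:
        raise DomainError("Vj must be > 0 for per-RC fluxes")
    tro = f.Mo / f.Vj
    return {
        "TRo_RC": tro,
        "ETo_RC": tro * (1.0 - f.Vj),
        "REo_RC": tro * (1.0 - f.Vi),
    }


def compute_rc_density(f: FiducialSet, phi_Po: float) -> dict[str, float]:
    """Active reaction-center density RC/ABS = φPo·Vj/Mo and γRC.

    γRC = RC/(RC+ABS) so that γRC/(1−γRC) equals the density exactly.
    """
    if f.Mo <= 0:
        raise DomainError("Mo must be > 0 for reaction-center density")
    rc = phi_Po * f.Vj / f.Mo
    return {"rc_density": rc, "gamma_RC": rc / (1.0 + rc)}


def compute_deexcitation_constants(
    f: FiducialSet, conv: DeexcitationConvention = DeexcitationConvention()
) -> dict[str, float]:
    """De-excitation rate constants KN, KP under the chosen convention."""
    if f.F0 <= 0 or f.Fm <= 0:
        raise DomainError("F0 and Fm must be > 0 for de-excitation constants")
    abs_cs = f.F0 if conv.abs_per_cs_proxy == "F0" else 1.0
    k_n = abs_cs * conv.K_F / f.Fm
    k_p = abs_cs * conv.K_F * (1.0 / f.F0 - 1.0 / f.Fm)
    return {"K_N": k_n, "K_P": k_p}


def compute_performance_indices(
    rc_density: float, gamma_RC: float, phi_Po: float, psi_Eo: float,
    delta_Ro: float,
) -> dict[str, float]:
    """Performance indices PIabs / PItotal, SFabs and the driving force.

    DFtotal = log10(PItotal); when PItotal ≤ 0 (possible only for anomalous
    δRo ≥ 1) DFtotal is NaN rather than an error, so batch runs survive
    noisy traces.
    """
    for name, x in (("phi_Po", phi_Po), ("psi_Eo", psi_Eo),
                    ("delta_Ro", delta_Ro)):
        if x >= 1.0:
            raise DomainError(f"performance index undefined: 1 - {name} = 0 or < 0")
    pi_abs = rc_density * (phi_Po / (1.0 - phi_Po)) * (psi_Eo / (1.0 - psi_Eo))
    pi_total = pi_abs * delta_Ro / (1.0 - delta_Ro)
    sf_abs = gamma_RC * phi_Po * psi_Eo
    df_total = math.log10(pi_total) if pi_total > 0 else float("nan")
    return {
        "PI_abs": pi_abs,
        "PI_total": pi_total,
        "SF_abs": sf_abs,
        "DF_total": df_total,
    }


def k_band_diagnostic(
    f: FiducialSet, limit: float = DEFAULT_KBAND_LIMIT
) -> tuple[float, bool]:
    """K-band ratio Fk/Fj and the OEC-damage flag (strictly above the limit).

    Ratios above ~0.6 on the raw fluorescence scale indicate donor-side
    (oxygen-evolving complex) damage, typically from heat stress.
    """
    if f.Fj <= 0:
        raise DomainError("Fj must be > 0 for the K-band ratio")
    ratio = f.Fk / f.Fj
    return ratio, ratio > limit


def compute_jip_parameters(
    source: Transient | FiducialSet,
    conv: DeexcitationConvention = DeexcitationConvention(),
    fiducial_times: Mapping[str, float] = FIDUCIAL_TIMES_US,
    tolerance_factor: float = DEFAULT_TOLERANCE_FACTOR,
    kband_limit: float = DEFAULT_KBAND_LIMIT,
) -> JipParameters:
    """Full JIP-test parameter suite for one transient (or FiducialSet).

    δRo ≥ 1 (Vi < Vj under noise) is reported unclamped with
    ``vi_anomaly=True``; the δRo-dependent PI_total and DF_total are then
    NaN because their defining ratio leaves its domain.
    """
    if isinstance(source, FiducialSet):
        f = source
    else:
        f = extract_fiducials(source, fiducial_times, tolerance_factor)
    y = compute_quantum_yields(f)
    fluxes = compute_specific_fluxes(f)
    rc = compute_rc_density(f, y["phi_Po"])
    kk = compute_deexcitation_constants(f, conv)
    vi_anomaly = f.Vi < f.Vj
    if y["delta_Ro"] < 1.0:
        pis = compute_performance_indices(
            rc["rc_density"], rc["gamma_RC"], y["phi_Po"], y["psi_Eo"],
            y["delta_Ro"],
        )
    else:
        pi_abs = (rc["rc_density"] * (y["phi_Po"] / (1 - y["phi_Po"]))
                  * (y["psi_Eo"] / (1 - y["psi_Eo"])))
        pis = {"PI_abs": pi_abs, "PI_total": float("nan"),
               "SF_abs": rc["gamma_RC"] * y["phi_Po"] * y["psi_Eo"],
               "DF_total": float("nan")}
    ratio, flag = k_band_diagnostic(f, kband_limit)
    return JipParameters(
        **y, **fluxes, **rc, **kk, **pis,
        Fk_Fj=ratio, oec_flag=flag, vi_anomaly=vi_anomaly,
    )


def compute_parameter_table(
    traces: Sequence[Transient],
    conv: DeexcitationConvention = DeexcitationConvention(),
    fiducial_times: Mapping[str, float] = FIDUCIAL_TIMES_US,
    tolerance_factor: float = DEFAULT_TOLERANCE_FACTOR,
    kband_limit: float = DEFAULT_KBAND_LIMIT,
) -> pd.DataFrame:
    """One JIP-parameter row per trace, with metadata columns attached."""
    meta = metadata_frame(traces)
    rows = []
    for i, tr in enumerate(traces):
        try:
            p = compute_jip_parameters(
                tr, conv, fiducial_times, tolerance_factor, kband_limit
            )
        except (DegenerateTraceError, FiducialGapError, DomainError) as exc:
            raise type(exc)(f"trace ({tr.meta.label()}): {exc}") from exc
        rows.append(vars(p))
    return pd.concat([meta, pd.DataFrame(rows)], axis=1)


# ---------------------------------------------------------------------------
# report rounding
# ---------------------------------------------------------------------------

def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero (report convention; 0.125 → 0.13 at 2 dp)."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


#: Printed precision per report column: 3 decimals for Fv/Fm, 2 elsewhere.
REPORT_DECIMALS: Mapping[str, int] = {"phi_Po": 3}


def report_round(name: str, x: float) -> float:
    """Round a parameter to its report-table precision."""
    return round_half_away(x, REPORT_DECIMALS.get(name, 2))
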