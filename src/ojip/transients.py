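"""Data model and file I/O for chlorophyll-a fluorescence induction transients.

A :class:`Transient` is one dark-adapted OJIP measurement: a strictly
increasing time grid in microseconds (log-spaced by PEA-class instruments,
spanning roughly 10 µs to 1 s) and the fluorescence signal in arbitrary
units, plus the treatment metadata (:class:`TreatmentDesign`) that places the
measurement in the factorial experiment.

Files are long-format delimited text (CSV or TSV, autodetected by extension)
with one row per sample and the metadata repeated on every row.  Time is
always microseconds in files and in memory; readers convert declared ms/s
columns only via an explicit ``time_unit`` flag, never by guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError, ValidationError

#: PEA-convention landmark times, µs: O at 50 µs, K-band at 300 µs,
#: J step at 2 ms, I step at 30 ms.
FIDUCIAL_TIMES_US: Mapping[str, float] = {
    "O": 50.0,
    "K": 300.0,
    "J": 2_000.0,
    "I": 30_000.0,
}

#: A landmark is "covered" when the nearest grid sample lies within this
#: multiplicative factor in time (log-spaced grids cannot hit exact times).
DEFAULT_TOLERANCE_FACTOR: float = 1.25

#: Column layout of the long-format transient table.
METADATA_COLUMNS = (
    "maturity_group",
    "day_length_h",
    "temp_day_c",
    "temp_night_c",
    "replicate",
    "measurement",
)
TABLE_COLUMNS = ("time_us", "fluorescence") + METADATA_COLUMNS

_TIME_UNIT_TO_US = {"us": 1.0, "ms": 1_000.0, "s": 1_000_000.0}


@dataclass(frozen=True)
class TreatmentDesign:
    """Factor coordinates of one measurement in the factorial experiment.

    Exactly one of the two treatment axes (day length, day/night temperature)
    varies within an experiment table; the other is held at its control
    level.  That is an experiment-level constraint checked by the analysis
    stages, not per record.
    """

    maturity_group: str
    day_length_h: float
    temperature_day_c: float
    temperature_night_c: float
    replicate: int = 1
    measurement: int = 1

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if self.measurement < 1:
            raise ValidationError(f"measurement must be >= 1, got {self.measurement}")

    @property
    def temperature_label(self) -> str:
        def _fmt(x: float) -> str:
            return f"{x:g}"

        return f"{_fmt(self.temperature_day_c)}/{_fmt(self.temperature_night_c)}"

    def label(self) -> str:
        return (
            f"MG {self.maturity_group}, {self.day_length_h:g} h, "
            f"{self.temperature_label} degC, rep {self.replicate}, meas {self.measurement}"
        )


@dataclass
class Transient:
    """One fluorescence induction trace.

    Parameters
    ----------
    times_us
        Sample times in microseconds, strictly increasing, all positive.
    fluorescence
        Fluorescence in instrument arbitrary units, same length as
        ``times_us``, all positive and finite.
    meta
        Treatment metadata.
    instrument_saturating_intensity
        Actinic intensity of the saturating pulse in µmol m⁻² s⁻¹
        (annotation only; 3000 is the Handy-PEA class default).
    """

    times_us: np.ndarray
    fluorescence: np.ndarray
    meta: TreatmentDesign
    instrument_saturating_intensity: float = 3000.0

    def __post_init__(self) -> None:
        self.times_us = np.asarray(self.times_us, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)

    def __len__(self) -> int:
        return len(self.times_us)


def _nearest_factor(grid: np.ndarray, t: float) -> float:
    """Multiplicative distance from ``t`` to the nearest positive grid sample."""
    pos = grid[grid > 0]
    if len(pos) == 0:
        return np.inf
    ratios = np.maximum(pos / t, t / pos)
    return float(ratios.min())


def validate_transient(
    trace: Transient,
    fiducial_times: Mapping[str, float] = FIDUCIAL_TIMES_US,
    tolerance_factor: float = DEFAULT_TOLERANCE_FACTOR,
) -> list[str]:
    """Return the list of violated invariants (empty means valid).

    Validation is total: it never raises on finite or non-finite numeric
    input.  Report codes:

    - ``too-short`` — fewer than 10 samples
    - ``non-positive-time`` / ``non-increasing-times``
    - ``non-finite-fluorescence`` / ``non-positive-fluorescence``
    - ``fiducial-gap at <L>`` — no sample within ``tolerance_factor`` of
      landmark L's time
    - ``no-variable-fluorescence`` — max(F) indistinguishable from F at the
      O mark (degenerate trace, the engine cannot be run on it)
    """
    report: list[str] = []
    t = trace.times_us
    f = trace.fluorescence
    if len(t) != len(f):
        report.append("length-mismatch")
        return report
    if len(t) < 10:
        report.append("too-short")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        report.append("non-positive-time")
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        report.append("non-increasing-times")
    if np.any(~np.isfinite(f)):
        report.append("non-finite-fluorescence")
    elif np.any(f <= 0):
        report.append("non-positive-fluorescence")

    if "non-positive-time" not in report:
        for name, ft in fiducial_times.items():
            if _nearest_factor(t, ft) > tolerance_factor:
                report.append(f"fiducial-gap at {name}")

    if not report and len(t) >= 1:
        o_time = fiducial_times.get("O", 50.0)
        f0 = f[int(np.argmin(np.abs(t - o_time)))]
        fm = f.max()
        if fm - f0 <= 1e-6 * fm:
            report.append("no-variable-fluorescence")
    return report


def write_transient_table(
    traces: Sequence[Transient],
    path: str | Path,
) -> Path:
    """Write transients as a long-format delimited table (CSV/TSV by extension).

    UTF-8, "." decimal separator, header mandatory.  Floats are written with
    shortest round-tripping repr so ``read(write(x)) == x`` exactly.
    """
    traces = list(traces)
    if not traces:
        raise UsageError("cannot write an empty collection of transients")
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frames = []
    for tr in traces:
        m = tr.meta
        frames.append(
            pd.DataFrame(
                {
                    "time_us": tr.times_us,
                    "fluorescence": tr.fluorescence,
                    "maturity_group": m.maturity_group,
                    "day_length_h": m.day_length_h,
                    "temp_day_c": m.temperature_day_c,
                    "temp_night_c": m.temperature_night_c,
                    "replicate": m.replicate,
                    "measurement": m.measurement,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)
    return path


def read_transient_table(
    path: str | Path,
    time_unit: str = "us",
    validate: bool = True,
) -> list[Transient]:
    """Read a long-format transient table into a list of :class:`Transient`.

    Rows are grouped into traces by the six metadata columns; row order
    within a group is preserved and must give strictly increasing times.

    Parameters
    ----------
    time_unit
        Unit of the ``time_us`` column as written: ``"us"`` (default),
        ``"ms"`` or ``"s"``.  Conversion is explicit, never guessed.
    validate
        When true (default), raise :class:`ValidationError` naming the
        offending trace on non-increasing times or non-positive fluorescence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    if time_unit not in _TIME_UNIT_TO_US:
        raise UsageError(f"time_unit must be one of {sorted(_TIME_UNIT_TO_US)}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    scale = _TIME_UNIT_TO_US[time_unit]
    traces: list[Transient] = []
    for key, grp in df.groupby(list(METADATA_COLUMNS), sort=False):
        meta = TreatmentDesign(
            maturity_group=str(key[0]),
            day_length_h=float(key[1]),
            temperature_day_c=float(key[2]),
            temperature_night_c=float(key[3]),
            replicate=int(key[4]),
            measurement=int(key[5]),
        )
        times = grp["time_us"].to_numpy(dtype=float) * scale
        fluo = grp["fluorescence"].to_numpy(dtype=float)
        tr = Transient(times, fluo, meta)
        if validate:
            if len(times) > 1 and np.any(np.diff(times) <= 0):
                raise ValidationError(
                    f"non-increasing times in trace ({meta.label()}) of {path}"
                )
            if np.any(~np.isfinite(fluo)) or np.any(fluo <= 0):
                raise ValidationError(
                    f"non-positive or non-finite fluorescence in trace "
                    f"({meta.label()}) of {path}"
                )
        traces.append(tr)
    return traces


def metadata_frame(traces: Iterable[Transient]) -> pd.DataFrame:
    """One metadata row per trace, in order (helper for the analysis stages)."""
    rows = []
    for tr in traces:
        m = tr.meta
        rows.append(
            {
                "maturity_group": m.maturity_group,
                "day_length_h": m.day_length_h,
                "temp_day_c": m.temperature_day_c,
                "temp_night_c": m.temperature_night_c,
                "temperature": m.temperature_label,
                "replicate": m.replicate,
                "measurement": m.measurement,
            }
        )
    return pd.DataFrame(rows)
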