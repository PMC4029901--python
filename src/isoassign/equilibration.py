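"""Comparative equilibration of raw d2H measurements.

Feather d2H cannot be compared across laboratories directly because a
fraction of feather hydrogen exchanges with ambient water vapour.  The
comparative-equilibration workflow corrects for this by co-analysing
keratin standards of known non-exchangeable-H composition in every
analytical run, fitting a per-run ordinary-least-squares line mapping
measured raw values to accepted values, and pushing each sample replicate
through that line.  Reported sample values are the mean of the (typically
triplicate) calibrated replicates.

Control standards (e.g. IAEA CH7) monitor instrument performance only:
they are excluded from the calibration fit but appear in QC reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KeratinStandard",
    "AnalyticalRun",
    "RunCalibration",
    "CalibratedSample",
    "StandardQC",
    "DEFAULT_STANDARDS",
    "fit_run_calibration",
    "calibrate_samples",
    "qc_run",
    "read_runs",
    "write_qc_report",
]


class EquilibrationError(ValueError):
    """Raised on degenerate runs or unknown standards."""


@dataclass(frozen=True)
class KeratinStandard:
    """A reference keratin with an accepted d2H value (permil, VSMOW)."""

    name: str
    accepted_value: float
    tolerance: float
    control_only: bool = False  # excluded from the calibration fit

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise EquilibrationError(f"standard {self.name!r}: tolerance must be > 0")


#: The keratin reference set used for feather d2H work: three calibration
#: standards plus the IAEA CH7 instrument-performance control.
DEFAULT_STANDARDS: tuple[KeratinStandard, ...] = (
    KeratinStandard("CFS", -147.0, 5.0),
    KeratinStandard("CHS", -187.0, 2.0),
    KeratinStandard("BWB-II", -108.0, 4.0),
    KeratinStandard("CH7", -100.3, 2.0, control_only=True),
)


@dataclass(frozen=True)
class AnalyticalRun:
    """One mass-spectrometer run: standards plus replicated samples."""

    run_id: str
    standard_measurements: tuple[tuple[str, float], ...]
    sample_measurements: tuple[tuple[str, int, float], ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for sid, rep, _ in self.sample_measurements:
            if (sid, rep) in seen:
                raise EquilibrationError(
                    f"run {self.run_id!r}: duplicate replicate {rep} for sample {sid!r}"
                )
            seen.add((sid, rep))


@dataclass(frozen=True)
class RunCalibration:
    """A fitted measured -> accepted line with per-measurement residuals."""

    run_id: str
    slope: float
    intercept: float
    residuals: tuple[tuple[str, float], ...]  # (standard name, accepted - fitted)

    def apply(self, raw: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(raw) + self.intercept


@dataclass(frozen=True)
class CalibratedSample:
    sample_id: str
    calibrated_values: tuple[float, ...]
    mean: float
    n_replicates: int


@dataclass(frozen=True)
class StandardQC:
    standard: str
    n: int
    spread: float  # max - min of calibrated replicate values
    bias: float  # |calibrated mean - accepted|
    flagged: bool
    control_only: bool = False


def _standards_by_name(standards: Sequence[KeratinStandard]) -> Mapping[str, KeratinStandard]:
    return {s.name: s for s in standards}


def fit_run_calibration(
    run: AnalyticalRun, standards: Sequence[KeratinStandard] = DEFAULT_STANDARDS
) -> RunCalibration:
    """OLS line mapping measured raw values to accepted values for one run.

    Control-only standards are excluded from the fit.  Requires at least
    two distinct measured values among calibration standards.
    """
    lookup = _standards_by_name(standards)
    xs, ys, names = [], [], []
    for name, measured in run.standard_measurements:
        if name not in lookup:
            raise EquilibrationError(f"run {run.run_id!r}: unknown standard {name!r}")
        if lookup[name].control_only:
            continue
        xs.append(measured)
        ys.append(lookup[name].accepted_value)
        names.append(name)
    xs_arr = np.asarray(xs, dtype=float)
    ys_arr = np.asarray(ys, dtype=float)
    if len(np.unique(xs_arr)) < 2:
        raise EquilibrationError(
            f"run {run.run_id!r}: degenerate calibration — need >=2 distinct "
            f"measured standard values, got {len(np.unique(xs_arr))}"
        )
    fit = stats.linregress(xs_arr, ys_arr)
    fitted = fit.slope * xs_arr + fit.intercept
    residuals = tuple(zip(names, (ys_arr - fitted).tolist()))
    return RunCalibration(run.run_id, float(fit.slope), float(fit.intercept), residuals)


def calibrate_samples(
    run: AnalyticalRun, slope: float, intercept: float
) -> list[CalibratedSample]:
    """Map every sample replicate through the run's line; mean per sample.

    Samples with zero replicates cannot occur by construction of
    :class:`AnalyticalRun`; replicate counts other than three are reported
    so downstream QC can flag them.
    """
    by_sample: dict[str, list[float]] = {}
    for sid, _rep, raw in run.sample_measurements:
        by_sample.setdefault(sid, []).append(slope * raw + intercept)
    out = []
    for sid, vals in by_sample.items():
        out.append(
            CalibratedSample(
                sample_id=sid,
                calibrated_values=tuple(vals),
                mean=float(np.mean(vals)),
                n_replicates=len(vals),
            )
        )
    return out


def qc_run(
    run: AnalyticalRun,
    slope: float,
    intercept: float,
    standards: Sequence[KeratinStandard] = DEFAULT_STANDARDS,
    spread_bound: float = 4.0,
) -> list[StandardQC]:
    """Per-standard QC: calibrated replicate spread and bias vs accepted.

    A standard is flagged when its calibrated spread (max - min) exceeds
    ``spread_bound`` (default 4 permil).  Report-only; nothing is rejected.
    """
    lookup = _standards_by_name(standards)
    by_std: dict[str, list[float]] = {}
    for name, measured in run.standard_measurements:
        if name not in lookup:
            raise EquilibrationError(f"run {run.run_id!r}: unknown standard {name!r}")
        by_std.setdefault(name, []).append(slope * measured + intercept)
    report = []
    for name, vals in by_std.items():
        std = lookup[name]
        spread = float(max(vals) - min(vals)) if len(vals) > 1 else 0.0
        bias = float(abs(np.mean(vals) - std.accepted_value))
        report.append(
            StandardQC(
                standard=name,
                n=len(vals),
                spread=spread,
                bias=bias,
                flagged=spread > spread_bound,
                control_only=std.control_only,
            )
        )
    return report


def write_qc_report(report: Sequence[StandardQC], path: str | Path) -> Path:
    """Write a per-standard QC table as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([vars(r) for r in report]).to_csv(path, index=False)
    return path


def read_runs(path: str | Path) -> list[AnalyticalRun]:
    """Read analytical runs from CSV.

    Columns: ``run_id, role, name_or_id, replicate, raw_value`` with role
    one of ``standard``, ``control`` or ``sample``.  Control rows are kept
    as standard measurements (QC-only standards carry the exclusion flag).
    """
    df = pd.read_csv(path)
    required = {"run_id", "role", "name_or_id", "replicate", "raw_value"}
    missing = required - set(df.columns)
    if missing:
        raise EquilibrationError(f"run file missing column(s): {sorted(missing)}")
    runs = []
    for run_id, sub in df.groupby("run_id", sort=False):
        std_rows: list[tuple[str, float]] = []
        sample_rows: list[tuple[str, int, float]] = []
        for _, row in sub.iterrows():
            role = str(row["role"]).strip().lower()
            if role in ("standard", "control"):
                std_rows.append((str(row["name_or_id"]), float(row["raw_value"])))
            elif role == "sample":
                sample_rows.append(
                    (str(row["name_or_id"]), int(row["replicate"]), float(row["raw_value"]))
                )
            else:
                raise EquilibrationError(f"run {run_id!r}: unknown role {role!r}")
        runs.append(
            AnalyticalRun(
                run_id=str(run_id),
                standard_measurements=tuple(std_rows),
                sample_measurements=tuple(sample_rows),
            )
        )
    return runs
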