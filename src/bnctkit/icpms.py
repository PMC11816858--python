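"""ICP-MS boron-10 quantification.

The instrument measures the 10B isotope signal.  The calibration standard
contains boron at natural isotopic abundance (19.9% 10B, 80.1% 11B) with
concentrations expressed as total boron, while the cell samples were loaded
with a monoisotopic 10B compound.  Reading a monoisotopic sample off the
natural-abundance curve therefore overestimates its 10B content by 1/f10,
and the apparent concentration must be multiplied by f10 = 0.199.  Blank
subtraction, the 10x dilution of the digest, a QC-drift check, and the
conversion to ppm (ug 10B / g pellet) and ug 10B / 1e6 cells live here too.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, InputDomainError

__all__ = [
    "CalibrationCurve",
    "IcpmsRun",
    "IsotopeAbundance",
    "CellPellet",
    "QuantResult",
    "UptakeSummary",
    "fit_calibration",
    "quantify_b10",
    "concentration_ppm",
    "concentration_per_million_cells",
    "uptake_summary",
    "viability_gate",
]

logger = logging.getLogger(__name__)

QC_DRIFT_TOLERANCE = 0.05


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear response: intensity = slope * conc(total B, ug/L) + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self):
        if self.slope <= 0:
            raise InputDomainError("calibration slope must be positive")


@dataclass(frozen=True)
class IsotopeAbundance:
    """Isotopic composition of the calibration standard."""

    f10: float = 0.199
    f11: float = 0.801

    def __post_init__(self):
        if not 0 < self.f10 < 1 or abs(self.f10 + self.f11 - 1) > 1e-9:
            raise InputDomainError("abundances must be fractions summing to 1")


@dataclass(frozen=True)
class CellPellet:
    """Weighed cell pellet digested for ICP-MS (typically 0.050-0.100 g)."""

    mass: float
    cell_count: float
    viability: float = 1.0

    def __post_init__(self):
        if self.mass <= 0 or self.cell_count <= 0:
            raise InputDomainError("pellet mass and cell count must be positive")
        if not 0 <= self.viability <= 1:
            raise InputDomainError("viability must be a fraction")


@dataclass(frozen=True)
class IcpmsRun:
    """One measurement: sample + blank intensities and the calibration data."""

    sample_intensity: float
    blank_intensity: float
    standard_points: tuple = ()
    dilution_factor: float = 10.0
    qc_nominal: float | None = None  # mg/L
    qc_measured: float | None = None  # mg/L equivalent from the curve

    def __post_init__(self):
        if self.dilution_factor < 1:
            raise InputDomainError("dilution factor must be >= 1")


class QuantResult(NamedTuple):
    b10_ug_per_l: float  # in the original digest, after dilution correction
    below_detection: bool
    qc_drift: float | None


def fit_calibration(standard_points: Sequence[tuple]) -> CalibrationCurve:
    """Ordinary least squares on (known total-B conc ug/L, intensity) points."""
    pts = np.asarray(standard_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise InputDomainError("need at least two calibration points")
    conc, inten = pts[:, 0], pts[:, 1]
    if np.ptp(conc) == 0:
        raise DegenerateDesignError("all calibration concentrations identical")
    res = stats.linregress(conc, inten)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def quantify_b10(
    run: IcpmsRun,
    curve: CalibrationCurve,
    abundance: IsotopeAbundance = IsotopeAbundance(),
    noise_floor: float = 0.0,
) -> QuantResult:
    """10B concentration (ug/L) in the original digest.

    apparent total-B = (sample - blank - intercept) / slope, read off the
    natural-abundance curve; the monoisotopic correction multiplies by f10;
    the dilution factor restores the digest concentration.  Net intensities
    below -noise_floor flag the sample as below detection; small negative
    values clamp to zero with a warning.
    """
    if run.sample_intensity < 0 or run.blank_intensity < 0:
        raise InputDomainError("intensities must be nonnegative")
    net = run.sample_intensity - run.blank_intensity - curve.intercept
    below = run.sample_intensity - run.blank_intensity < -noise_floor
    apparent = net / curve.slope
    b10 = apparent * abundance.f10 * run.dilution_factor
    if b10 < 0:
        warnings.warn("negative corrected concentration clamped to 0", stacklevel=2)
        b10 = 0.0
    drift = None
    if run.qc_nominal and run.qc_measured is not None:
        drift = abs(run.qc_measured - run.qc_nominal) / run.qc_nominal
        if drift > QC_DRIFT_TOLERANCE:
            warnings.warn(
                f"QC standard drifted {drift:.1%} (> {QC_DRIFT_TOLERANCE:.0%})",
                stacklevel=2,
            )
    return QuantResult(b10_ug_per_l=float(b10), below_detection=bool(below), qc_drift=drift)


def concentration_ppm(b10_mass_ug: float, pellet: CellPellet) -> float:
    """ppm = ug 10B per g of cell mass."""
    if b10_mass_ug < 0:
        raise InputDomainError("boron mass cannot be negative")
    return b10_mass_ug / pellet.mass


def concentration_per_million_cells(b10_mass_ug: float, pellet: CellPellet) -> float:
    """ug 10B per 1e6 cells."""
    if b10_mass_ug < 0:
        raise InputDomainError("boron mass cannot be negative")
    return b10_mass_ug / (pellet.cell_count / 1e6)


class UptakeSummary(NamedTuple):
    times_h: tuple
    means: tuple
    sds: tuple
    peak_time_h: float


def uptake_summary(timecourse: Sequence[tuple]) -> UptakeSummary:
    """Per-time mean and SD (n-1) of replicate uptake values, plus peak time.

    ``timecourse`` is a sequence of (time_h, replicate values).  The peak is
    the argmax of the means; on a tie the earliest time wins.
    """
    if not timecourse:
        raise InputDomainError("empty timecourse")
    times, means, sds = [], [], []
    for t, reps in sorted(timecourse, key=lambda x: x[0]):
        arr = np.asarray(reps, dtype=float)
        if arr.size == 0:
            raise InputDomainError(f"no replicates at t={t} h")
        times.append(float(t))
        means.append(float(arr.mean()))
        sds.append(float(arr.std(ddof=1)) if arr.size > 1 else 0.0)
    peak = times[int(np.argmax(means))]
    return UptakeSummary(tuple(times), tuple(means), tuple(sds), peak)


class ViabilityResult(NamedTuple):
    fraction: float
    passed: bool


def viability_gate(live: int, dead: int, threshold: float = 0.95) -> ViabilityResult:
    """Trypan-blue viability check: pass iff live/(live+dead) > threshold."""
    if live < 0 or dead < 0 or live + dead == 0:
        raise InputDomainError("need nonnegative counts with live+dead > 0")
    frac = live / (live + dead)
    return ViabilityResult(fraction=frac, passed=frac > threshold)
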