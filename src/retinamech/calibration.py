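"""Glass-fiber force-sensor calibration and FD-curve assembly.

The sensor is a pair of 200 um glass fibers acting as a single effective
spring.  Known brass-wire masses (150-2200 mg) are hung on the sensor and
the fiber extension is read off camera images; ordinary least squares of the
gravitational force ``F = m g`` against extension gives the spring constant
``k`` as the slope.  Forces during a stretching experiment then follow from
Hooke's law, ``F = k x``.

The fit uses a free intercept: a constant offset in the dot-tracking
reference shifts every extension by the same amount and would otherwise bias
the slope; the intercept is reported as a diagnostic and never applied when
converting extensions to forces.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .curves import FDCurve
from .synthetic import G_STANDARD, CalibrationTable

__all__ = [
    "CalibrationError",
    "SpringModel",
    "SpringCalibration",
    "fit_spring_constant",
    "extension_to_force",
    "assemble_fd_curve",
]

log = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    """Degenerate or physically impossible calibration fit."""


@dataclass(frozen=True)
class SpringModel:
    """Calibrated Hookean spring: results object of :class:`SpringCalibration`.

    Attributes
    ----------
    k : float
        Spring constant [N/m] (slope of force vs. extension).
    k_se : float
        Standard error of the slope [N/m].
    intercept : float
        Fitted force offset [N]; diagnostic only.
    n : int
        Number of calibration points.
    """

    k: float
    k_se: float
    intercept: float
    n: int

    def __post_init__(self):
        if not self.k > 0:
            raise CalibrationError("fitted spring constant must be positive")
        if self.k_se < 0 or self.n < 2:
            raise ValueError("invalid SpringModel diagnostics")

    def summary(self) -> str:
        return (
            "Glass-fiber spring calibration (OLS, free intercept)\n"
            f"  n points    : {self.n}\n"
            f"  k           : {self.k:.4f} N/m\n"
            f"  SE(k)       : {self.k_se:.4f} N/m\n"
            f"  intercept   : {self.intercept:.3e} N (diagnostic)\n"
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"k_N_per_m": self.k, "k_se_N_per_m": self.k_se,
                 "intercept_N": self.intercept, "n": self.n},
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SpringModel":
        d = json.loads(Path(path).read_text())
        return cls(k=d["k_N_per_m"], k_se=d["k_se_N_per_m"],
                   intercept=d["intercept_N"], n=d["n"])


class SpringCalibration:
    """OLS model for the mass-extension calibration of the force sensor."""

    def __init__(self, table: CalibrationTable):
        self.table = table

    @classmethod
    def from_arrays(cls, masses, extensions) -> "SpringCalibration":
        return cls(CalibrationTable(np.asarray(masses), np.asarray(extensions)))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpringCalibration":
        return cls(CalibrationTable.from_csv(path))

    def fit(self) -> SpringModel:
        """Regress gravitational force on extension; slope is ``k``."""
        x = self.table.extensions
        F = self.table.masses * G_STANDARD
        if np.unique(x).size < 2:
            raise CalibrationError("all extensions identical: slope is undefined")
        res = stats.linregress(x, F)
        if not res.slope > 0:
            raise CalibrationError(
                f"calibration slope is non-positive ({res.slope:.3g} N/m); "
                "extensions do not increase with load"
            )
        k_se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
        return SpringModel(k=float(res.slope), k_se=k_se,
                           intercept=float(res.intercept), n=self.table.n)


def fit_spring_constant(table: CalibrationTable) -> SpringModel:
    """Functional wrapper: fit the spring constant from a calibration table."""
    return SpringCalibration(table).fit()


def extension_to_force(extension, model: SpringModel) -> np.ndarray:
    """Hooke's law ``F = k x`` (the calibration intercept is not applied)."""
    x = np.asarray(extension, dtype=float)
    if np.any(x < 0):
        log.warning("negative fiber extension encountered; force will be negative")
    return model.k * x


def assemble_fd_curve(motor_positions, dot_positions, model: SpringModel,
                      rate: float) -> FDCurve:
    """Build an FD curve from raw motor and sensor-dot position series.

    The fiber extension is the dot position relative to its first sample and
    the displacement is the motor travel relative to its first sample
    (motor travel, *not* corrected for sensor deflection; the corrected gap
    is attached as the optional ``gap`` column).
    """
    motor = np.asarray(motor_positions, dtype=float)
    dot = np.asarray(dot_positions, dtype=float)
    if motor.shape != dot.shape or motor.ndim != 1:
        raise ValueError("motor and dot position series must be 1-D and equal length")
    if motor.size < 2:
        raise ValueError("need at least two samples to assemble an FD curve")
    if np.any(np.diff(motor) < 0):
        raise ValueError("motor positions must be non-decreasing")
    displacement = motor - motor[0]
    extension = dot - dot[0]
    force = extension_to_force(extension, model)
    return FDCurve(
        displacement=displacement,
        force=force,
        rate=rate,
        provenance="measured",
        gap=displacement - extension,
    )
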