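"""Synthetic stand-ins for the stretcher experiment.

The wet-lab data behind the analysis (porcine retinae stretched on two
TiO2-nanotube scaffolds) are not deposited anywhere, so this module generates
the two kinds of raw tables the pipeline consumes with the statistical
structure the analysis assumes:

* mass-extension calibration tables for the glass-fiber force sensor,
  following Hooke's law around a known true spring constant, and
* four-regime force-distance (FD) curves: a nonlinear toe below 0.01 mm,
  a linear elastic rise (regime 1), a constant-force plateau about 200 um
  long (regime 2), a second, steeper linear rise (regime 3) and a second
  plateau (regime 4).

Rate presets encode the published regime-1 elastic constants and yield
forces: k1 = 21.5 N/m and F_y1 = 1.5 mN at 2.0 um/s, k1 = 33.5 N/m and
F_y1 = 2.2 mN at 0.1 um/s.  Quantities never published numerically (k3,
F_y2, the 0.5 um/s values) take documented defaults and are flagged
``invented`` on the preset.

Every generator takes an explicit seed; there is no hidden global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import FDCurve

__all__ = [
    "RegimeParams",
    "CalibrationTable",
    "make_rate_preset",
    "generate_fd_curve",
    "generate_calibration_table",
    "hooke_extension",
    "G_STANDARD",
    "DEFAULT_K_TRUE",
    "DEFAULT_MASSES_KG",
]

G_STANDARD = 9.81
"""Standard gravity [m/s^2] used to turn calibration masses into forces."""

DEFAULT_K_TRUE = 54.96
"""Default true spring constant [N/m] for synthetic calibration tables
(the glass-fiber pair of the force sensor)."""

#: Default calibration mass grid [kg]: 10 brass-wire masses spanning 150-2200 mg.
DEFAULT_MASSES_KG = np.linspace(1.5e-4, 2.2e-3, 10)

# Published regime-1 anchors: rate [um/s] -> (k1 [N/m], F_y1 [N]).
_PRINTED = {2.0: (21.5, 1.5e-3), 0.1: (33.5, 2.2e-3)}

_TOE_END = 1.0e-5  # [m] linearity begins at 0.01 mm
_PLATEAU2_LEN = 200e-6  # [m] regime-2 length, ~200 um
_D_MAX = 1.0e-3  # [m] total motor travel, up to 1 mm


@dataclass(frozen=True)
class RegimeParams:
    """Parameters of the four-regime mean FD curve.

    All quantities are SI.  ``invented`` lists the field names whose values
    are module defaults rather than published numbers; ``extrapolated`` marks
    presets requested at a rate outside the measured 0.1-2.0 um/s range.
    """

    rate: float  # displacement rate [m/s]
    toe_end: float  # displacement where linearity begins [m]
    k1: float  # regime-1 slope [N/m]
    F_y1: float  # first yield force [N]
    plateau2_len: float  # length of constant-force regime 2 [m]
    k3: float  # regime-3 slope [N/m]
    F_y2: float  # second yield force [N]
    d_max: float  # total displacement [m]
    invented: frozenset = field(default_factory=frozenset)
    extrapolated: bool = False

    def __post_init__(self):
        for name in ("rate", "toe_end", "k1", "F_y1", "plateau2_len", "k3", "F_y2", "d_max"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"RegimeParams.{name} must be positive")
        if not self.k3 > self.k1:
            raise ValueError("regime 3 must rise more steeply than regime 1 (k3 > k1)")
        if not self.F_y2 > self.F_y1:
            raise ValueError("second yield force must exceed the first (F_y2 > F_y1)")
        if not self.breakpoints[3] < self.d_max:
            raise ValueError("regimes do not fit inside d_max")

    # -------------------------------------------------------- derived geometry
    @property
    def toe_force(self) -> float:
        """Force at the toe/regime-1 boundary [N] (cubic toe, see mean_force)."""
        return 2.0 / 3.0 * self.k1 * self.toe_end

    @property
    def breakpoints(self) -> tuple[float, float, float, float]:
        """Displacements of the toe->1, 1->2, 2->3 and 3->4 transitions [m]."""
        d1 = self.toe_end + (self.F_y1 - self.toe_force) / self.k1
        d2 = d1 + self.plateau2_len
        d3 = d2 + (self.F_y2 - self.F_y1) / self.k3
        return (self.toe_end, d1, d2, d3)

    def mean_force(self, d) -> np.ndarray:
        """Noiseless mean force [N] at displacement(s) ``d`` [m].

        The toe is the cubic ``k1*toe_end*(u^2 - u^3/3)`` with
        ``u = d/toe_end``: zero force and zero slope at the origin, slope k1
        and zero curvature at ``toe_end`` (C1-matched to regime 1, so the toe
        does not bias the regime-1 slope).  The remaining pieces are the two
        lines and two plateaus with exact corner points.
        """
        d = np.asarray(d, dtype=float)
        t0, d1, d2, d3 = self.breakpoints
        u = np.clip(d / self.toe_end, 0.0, 1.0)
        toe = self.k1 * self.toe_end * (u**2 - u**3 / 3.0)
        out = np.select(
            [d <= t0, d <= d1, d <= d2, d <= d3],
            [
                toe,
                self.toe_force + self.k1 * (d - t0),
                self.F_y1,
                self.F_y1 + self.k3 * (d - d2),
            ],
            default=self.F_y2,
        )
        return out


def make_rate_preset(rate_um_s: float, d_max: float = _D_MAX) -> RegimeParams:
    """Regime parameters for a displacement rate given in um/s.

    The published anchors are 0.1 and 2.0 um/s; any other rate takes
    linearly interpolated (or, outside that range, extrapolated and flagged)
    regime-1 values.  k3 defaults to 2*k1 and F_y2 to 2.5*F_y1 since the
    regime-3/4 levels were only ever shown graphically.
    """
    if not rate_um_s > 0:
        raise ValueError("displacement rate must be positive")
    invented = {"k3", "F_y2", "d_max"}
    if rate_um_s in _PRINTED:
        k1, fy1 = _PRINTED[rate_um_s]
    else:
        rates = np.array(sorted(_PRINTED))
        k1 = float(np.interp(rate_um_s, rates, [_PRINTED[r][0] for r in rates]))
        fy1 = float(np.interp(rate_um_s, rates, [_PRINTED[r][1] for r in rates]))
        if rate_um_s < rates[0] or rate_um_s > rates[-1]:
            # np.interp clamps; extend the line instead and flag it.
            slope_k = (_PRINTED[2.0][0] - _PRINTED[0.1][0]) / (2.0 - 0.1)
            slope_f = (_PRINTED[2.0][1] - _PRINTED[0.1][1]) / (2.0 - 0.1)
            k1 = _PRINTED[0.1][0] + slope_k * (rate_um_s - 0.1)
            fy1 = _PRINTED[0.1][1] + slope_f * (rate_um_s - 0.1)
            if k1 <= 0 or fy1 <= 0:
                raise ValueError(f"rate {rate_um_s} um/s extrapolates to a non-physical preset")
        invented |= {"k1", "F_y1"}
    return RegimeParams(
        rate=rate_um_s * 1e-6,
        toe_end=_TOE_END,
        k1=k1,
        F_y1=fy1,
        plateau2_len=_PLATEAU2_LEN,
        k3=2.0 * k1,
        F_y2=2.5 * fy1,
        d_max=d_max,
        invented=frozenset(invented),
        extrapolated=not (0.1 <= rate_um_s <= 2.0),
    )


def generate_fd_curve(
    params: RegimeParams,
    n_points: int = 1000,
    noise_sd: float = 0.0,
    *,
    seed: int,
) -> FDCurve:
    """Sample a synthetic FD curve on a uniform displacement grid.

    Additive zero-mean Gaussian noise with standard deviation ``noise_sd``
    [N] is applied to the force channel only (the motor grid is exact).
    Identical inputs give bit-identical output.
    """
    if n_points < 50:
        raise ValueError("n_points must be at least 50")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    d = np.linspace(0.0, params.d_max, n_points)
    f = params.mean_force(d)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=n_points)
    return FDCurve(
        displacement=d,
        force=f,
        rate=params.rate,
        provenance="synthetic",
        meta={
            "seed": int(seed),
            "noise_sd_N": float(noise_sd),
            "preset_rate_um_s": params.rate * 1e6,
        },
    )


def hooke_extension(mass_kg, k: float) -> np.ndarray:
    """Noise-free fiber extension [m] under gravitational load ``m*g/k``."""
    if not k > 0:
        raise ValueError("spring constant must be positive")
    return np.asarray(mass_kg, dtype=float) * G_STANDARD / k


@dataclass(frozen=True)
class CalibrationTable:
    """Mass-extension records for the force-sensor calibration.

    ``k_true`` is only present for synthetic tables (the generating spring
    constant); measured tables leave it ``None``.
    """

    masses: np.ndarray  # [kg]
    extensions: np.ndarray  # [m]
    k_true: float | None = None

    def __post_init__(self):
        m = np.asarray(self.masses, dtype=float)
        x = np.asarray(self.extensions, dtype=float)
        object.__setattr__(self, "masses", m)
        object.__setattr__(self, "extensions", x)
        if m.ndim != 1 or m.shape != x.shape:
            raise ValueError("masses and extensions must be 1-D arrays of equal length")
        if np.any(m <= 0):
            raise ValueError("calibration masses must be strictly positive")
        if np.any(x < 0):
            raise ValueError("fiber extensions must be non-negative")

    @property
    def n(self) -> int:
        return int(self.masses.size)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"mass_kg": self.masses, "extension_m": self.extensions}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationTable":
        frame = pd.read_csv(path)
        for col in ("mass_kg", "extension_m"):
            if col not in frame.columns:
                raise ValueError(f"calibration CSV is missing column {col!r}")
        return cls(frame["mass_kg"].to_numpy(), frame["extension_m"].to_numpy())


def generate_calibration_table(
    k_true: float = DEFAULT_K_TRUE,
    masses=None,
    noise_sd: float = 0.0,
    *,
    seed: int,
) -> CalibrationTable:
    """Synthetic mass-extension table: ``x_i = m_i g / k_true + N(0, noise_sd^2)``.

    ``masses`` defaults to 10 values spanning the 150-2200 mg brass-wire
    range used to calibrate the sensor.  ``noise_sd`` is the camera tracking
    noise on the extension readout [m].
    """
    if not k_true > 0:
        raise ValueError("k_true must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    m = DEFAULT_MASSES_KG.copy() if masses is None else np.asarray(masses, dtype=float)
    if np.any(m <= 0):
        raise ValueError("calibration masses must be strictly positive")
    rng = np.random.default_rng(seed)
    x = hooke_extension(m, k_true)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=m.size)
    x = np.clip(x, 0.0, None)
    return CalibrationTable(masses=m, extensions=x, k_true=float(k_true))
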