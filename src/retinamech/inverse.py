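"""Inverse identification of the retina's effective Young's modulus.

The measured quantity is a structural stiffness (the regime-1 slope of the
FD curve, N/m); the material property of interest is the single isotropic
Young's modulus E that makes the stretcher FE model reproduce that
stiffness.  The identification iterates the forward model: because the
scaffolds are effectively rigid, the sidewall displacement is very nearly
inversely proportional to E, so one forward solve at a trial modulus gives
a near-exact first iterate ``E1 = E0 * u(E0) / u_target``; secant updates
on log E then drive the relative displacement mismatch below tolerance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fem.stretcher import StretcherConfig, StretcherModel

__all__ = [
    "InverseTarget",
    "InverseResult",
    "estimate_modulus",
    "modulus_rate_table",
    "REFERENCE_LOAD",
]

REFERENCE_LOAD = 1.0e-3
"""Load [N] at which slope targets are converted to displacement targets
(the worked-example load; the choice is immaterial by linearity)."""


@dataclass(frozen=True)
class InverseTarget:
    """A (load, displacement) pair the simulation must reproduce."""

    load: float          # [N]
    displacement: float  # [m]
    slope: float | None = None  # originating stiffness [N/m], if any

    def __post_init__(self):
        if not (self.load > 0 and self.displacement > 0):
            raise ValueError("target load and displacement must be positive")

    @classmethod
    def from_pair(cls, load: float, displacement: float) -> "InverseTarget":
        return cls(load=load, displacement=displacement)

    @classmethod
    def from_slope(cls, k_exp: float, reference_load: float = REFERENCE_LOAD) -> "InverseTarget":
        """Convert a measured FD slope [N/m] to a displacement target."""
        if not k_exp > 0:
            raise ValueError("target slope must be positive")
        return cls(load=reference_load, displacement=reference_load / k_exp, slope=k_exp)


@dataclass(frozen=True)
class InverseResult:
    """Identified modulus with convergence diagnostics."""

    E_hat: float        # [Pa]
    iterations: int     # number of forward solves
    residual: float     # relative displacement mismatch at E_hat
    bracket: tuple      # admissible modulus interval [Pa]
    target: InverseTarget
    converged: bool

    def __post_init__(self):
        lo, hi = self.bracket
        if not lo <= self.E_hat <= hi:
            raise ValueError("identified modulus escaped the search bracket")

    def summary(self) -> str:
        return (
            "Inverse modulus identification (scaling iterate + log-secant)\n"
            f"  E_hat          : {self.E_hat:.1f} Pa\n"
            f"  forward solves : {self.iterations}\n"
            f"  residual       : {self.residual:.2e} (relative)\n"
            f"  bracket        : [{self.bracket[0]:.0f}, {self.bracket[1]:.0f}] Pa\n"
            f"  converged      : {self.converged}\n"
        )

    def to_dict(self) -> dict:
        return {
            "E_hat_Pa": self.E_hat,
            "iterations": self.iterations,
            "residual": self.residual,
            "bracket_Pa": list(self.bracket),
            "target_load_N": self.target.load,
            "target_displacement_m": self.target.displacement,
            "converged": self.converged,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


class BracketError(RuntimeError):
    """Target displacement unreachable within the modulus bracket."""


def estimate_modulus(
    target: InverseTarget,
    config: StretcherConfig | None = None,
    resolution: int = 4,
    tol: float = 1e-3,
    bracket: tuple = (10.0, 1e5),
    model: StretcherModel | None = None,
    max_iter: int = 12,
) -> InverseResult:
    """Identify E such that the forward model matches the target displacement.

    A pre-built ``model`` may be passed to amortise meshing/assembly across
    calls (the same mesh is used for every solve of one inversion, so the
    iteration carries no discretisation bias).
    """
    if not 0 < tol <= 0.1:
        raise ValueError("tol must lie in (0, 0.1]")
    lo, hi = bracket
    if not 0 < lo < hi:
        raise ValueError("invalid modulus bracket")
    if model is None:
        model = StretcherModel(config, resolution=resolution)

    u_star = target.displacement
    E0 = math.sqrt(lo * hi)
    solves = 0

    def u_of(E: float) -> float:
        nonlocal solves
        solves += 1
        return model.solve(E_retina=E, load=target.load).u_x

    u0 = u_of(E0)
    # scaling iterate: exact if u_x were exactly proportional to 1/E
    E1 = E0 * u0 / u_star
    if not lo <= E1 <= hi:
        raise BracketError(
            f"target displacement {u_star:.3e} m maps to modulus {E1:.3e} Pa "
            f"outside the bracket [{lo:.0f}, {hi:.0f}] Pa"
        )

    logE_prev, logu_prev = math.log(E0), math.log(u0)
    E = E1
    residual = math.inf
    converged = False
    for _ in range(max_iter):
        u = u_of(E)
        residual = abs(u - u_star) / u_star
        if residual <= tol:
            converged = True
            break
        logE, logu = math.log(E), math.log(u)
        denom = logu - logu_prev
        if denom == 0:
            break
        slope = (logE - logE_prev) / denom  # ~ -1 by near-proportionality
        logE_next = logE + slope * (math.log(u_star) - logu)
        logE_prev, logu_prev = logE, logu
        E = float(np.clip(math.exp(logE_next), lo, hi))

    return InverseResult(
        E_hat=float(E),
        iterations=solves,
        residual=float(residual),
        bracket=(float(lo), float(hi)),
        target=target,
        converged=converged,
    )


def modulus_rate_table(
    summaries: dict,
    config: StretcherConfig | None = None,
    resolution: int = 4,
    tol: float = 1e-3,
    model: StretcherModel | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Identify the effective modulus per displacement rate.

    ``summaries`` maps rate [m/s] to either a ReplicateSummary (its mean k1
    is used) or a bare slope [N/m].  Returns a tidy table
    (rate_um_s, k1_N_m, E_Pa) and the per-rate InverseResult objects.
    One FE model is shared by all rates.
    """
    if not summaries:
        raise ValueError("modulus_rate_table needs at least one rate")
    if model is None:
        model = StretcherModel(config, resolution=resolution)
    rows = []
    results = {}
    for rate in sorted(summaries):
        entry = summaries[rate]
        k1 = entry if np.isscalar(entry) else entry.stats["k1"][0]
        if not k1 > 0:
            raise ValueError(f"rate {rate}: mean regime-1 slope must be positive")
        res = estimate_modulus(InverseTarget.from_slope(k1), tol=tol, model=model)
        results[rate] = res
        rows.append({"rate_um_s": round(rate * 1e6, 6), "k1_N_m": k1, "E_Pa": res.E_hat})
    return pd.DataFrame(rows), results
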