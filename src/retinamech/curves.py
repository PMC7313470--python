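"""Force-distance curve container and plain-text I/O.

An :class:`FDCurve` holds one tensile test record from the two-scaffold
tissue stretcher: force measured by the glass-fiber sensor against motor
travel ("distance" is the distance of motor movement, not the gap corrected
for sensor deflection).  Curves round-trip through CSV with a JSON sidecar
for metadata so that every pipeline stage can be re-run from disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FDCurve"]

_CSV_COLUMNS = ["displacement_m", "force_N"]


@dataclass(frozen=True)
class FDCurve:
    """Paired displacement/force samples at one displacement rate.

    Parameters
    ----------
    displacement : ndarray
        Motor travel in metres, strictly increasing, starting at 0.
    force : ndarray
        Sensor force in newtons, same length as ``displacement``.
    rate : float
        Displacement rate in m/s (the motor velocity).
    provenance : str
        ``"synthetic"`` or ``"measured"``.
    gap : ndarray, optional
        Sensor-deflection-corrected scaffold separation (motor travel minus
        fiber extension); diagnostic extra column, not used by the fits.
    """

    displacement: np.ndarray
    force: np.ndarray
    rate: float
    provenance: str = "measured"
    gap: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.asarray(self.displacement, dtype=float)
        f = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "force", f)
        if d.ndim != 1 or f.ndim != 1 or d.shape != f.shape:
            raise ValueError("displacement and force must be 1-D arrays of equal length")
        if d.size < 2:
            raise ValueError("an FD curve needs at least two samples")
        if abs(d[0]) > 1e-12:
            raise ValueError("displacement must start at 0 (motor travel is zero-referenced)")
        if np.any(np.diff(d) <= 0):
            raise ValueError("displacement must be strictly increasing")
        if not np.isfinite(f).all():
            raise ValueError("force contains non-finite values")
        if not (self.rate > 0):
            raise ValueError("displacement rate must be positive")
        if self.gap is not None:
            g = np.asarray(self.gap, dtype=float)
            if g.shape != d.shape:
                raise ValueError("gap column must match the sample count")
            object.__setattr__(self, "gap", g)

    @property
    def n(self) -> int:
        return int(self.displacement.size)

    @property
    def max_displacement(self) -> float:
        return float(self.displacement[-1])

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path) -> None:
        """Write ``displacement_m,force_N`` CSV plus a ``.json`` sidecar."""
        path = Path(path)
        frame = pd.DataFrame(
            {"displacement_m": self.displacement, "force_N": self.force}
        )
        if self.gap is not None:
            frame["gap_m"] = self.gap
        frame.to_csv(path, index=False)
        sidecar = {
            "rate_m_per_s": self.rate,
            "provenance": self.provenance,
            **self.meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True)
        )

    @classmethod
    def from_csv(cls, path: str | Path, rate: float | None = None) -> "FDCurve":
        """Read a curve written by :meth:`to_csv`.

        ``rate`` overrides the sidecar value (required if no sidecar exists).
        """
        path = Path(path)
        frame = pd.read_csv(path)
        missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"FD curve CSV is missing columns {missing}")
        meta: dict = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        if rate is None:
            rate = meta.pop("rate_m_per_s", None)
        else:
            meta.pop("rate_m_per_s", None)
        if rate is None:
            raise ValueError("no displacement rate in sidecar; pass rate= explicitly")
        provenance = meta.pop("provenance", "measured")
        gap = frame["gap_m"].to_numpy() if "gap_m" in frame.columns else None
        return cls(
            displacement=frame["displacement_m"].to_numpy(),
            force=frame["force_N"].to_numpy(),
            rate=float(rate),
            provenance=provenance,
            gap=gap,
            meta=meta,
        )
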