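"""End-to-end orchestration: calibrate -> FD curves -> segment -> summarise -> invert.

A run is driven by one :class:`PipelineConfig` (YAML-serialisable).  In
``synthetic`` mode the raw data are generated from the rate presets with an
explicit seed; in ``measured`` mode calibration tables and raw position
series are read from CSV.  Every stage writes its intermediate artifacts to
the output directory so stages can be re-run individually, and the final
:class:`Report` is deterministic given (config, seed) — it carries no
timestamps, only a hash of the resolved configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .calibration import SpringCalibration, SpringModel, assemble_fd_curve
from .curves import FDCurve
from .inverse import modulus_rate_table
from .fem.stretcher import StretcherConfig, StretcherModel
from .segmentation import SegmentationOptions, segment_regimes, summarize_replicates
from .synthetic import (
    DEFAULT_K_TRUE,
    CalibrationTable,
    generate_calibration_table,
    generate_fd_curve,
    make_rate_preset,
)

__all__ = ["PipelineConfig", "Report", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)

#: replicate counts used in the experiments: five at 0.1 um/s, three at the others
DEFAULT_REPLICATES = {0.1: 5, 0.5: 3, 2.0: 3}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run."""

    mode: str = "synthetic"              # "synthetic" | "measured"
    rates_um_s: tuple = (0.1, 0.5, 2.0)
    replicates: dict = field(default_factory=lambda: dict(DEFAULT_REPLICATES))
    seed: int = 0
    n_points: int = 1000
    noise_sd: float = 0.02e-3            # force noise [N]
    calibration_noise_sd: float = 2e-6   # extension noise [m]
    k_true: float = DEFAULT_K_TRUE
    stretcher: StretcherConfig = field(default_factory=StretcherConfig)
    resolution: int = 4
    inversion_tol: float = 1e-3
    segmentation: SegmentationOptions = field(default_factory=SegmentationOptions)
    # measured mode inputs
    calibration_csv: str | None = None
    curve_csvs: dict = field(default_factory=dict)  # rate_um_s -> list of CSV paths

    def __post_init__(self):
        if self.mode not in ("synthetic", "measured"):
            raise ValueError("mode must be 'synthetic' or 'measured'")
        if not self.rates_um_s:
            raise ValueError("at least one displacement rate is required")
        for r in self.rates_um_s:
            if self.replicates.get(r, 1) < 1:
                raise ValueError("replicates must be >= 1 for every rate")
        if self.mode == "measured":
            if not self.calibration_csv or not Path(self.calibration_csv).exists():
                raise ValueError("measured mode requires an existing calibration_csv")
            for r in self.rates_um_s:
                for p in self.curve_csvs.get(r, []):
                    if not Path(p).exists():
                        raise ValueError(f"curve CSV not found: {p}")

    # ------------------------------------------------------------- serialisation
    def to_dict(self) -> dict:
        d = asdict(self)
        d["stretcher"] = asdict(self.stretcher) if not isinstance(self.stretcher, dict) else self.stretcher
        d["segmentation"] = asdict(self.segmentation) if not isinstance(self.segmentation, dict) else self.segmentation
        d["rates_um_s"] = list(self.rates_um_s)
        d["replicates"] = {str(k): v for k, v in self.replicates.items()}
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stretcher" in d and isinstance(d["stretcher"], dict):
            d["stretcher"] = StretcherConfig(**d["stretcher"])
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            d["segmentation"] = SegmentationOptions(**d["segmentation"])
        if "rates_um_s" in d:
            d["rates_um_s"] = tuple(float(r) for r in d["rates_um_s"])
        if "replicates" in d:
            d["replicates"] = {float(k): int(v) for k, v in d["replicates"].items()}
        if "curve_csvs" in d:
            d["curve_csvs"] = {float(k): list(v) for k, v in d["curve_csvs"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class Report:
    """Structured result of one pipeline run (JSON-serialisable)."""

    schema_version: str
    software_version: str
    config_hash: str
    spring: dict
    fits: dict        # rate -> list of RegimeFit dicts
    summaries: dict   # rate -> ReplicateSummary dict
    inverse: dict     # rate -> InverseResult dict
    rate_table: list

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _stage(name: str, func, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = func(*args, **kwargs)
    except Exception as exc:
        log.error("stage=%s status=failed error=%s", name, exc)
        raise PipelineError(name, str(exc)) from exc
    log.info("stage=%s status=ok elapsed_s=%.2f", name, time.perf_counter() - t0)
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Report:
    """Execute the full analysis and write all artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.resolved.yaml")
    rng_base = int(config.seed)

    # ---- calibration ------------------------------------------------------
    def calibrate() -> SpringModel:
        if config.mode == "synthetic":
            table = generate_calibration_table(
                config.k_true, noise_sd=config.calibration_noise_sd, seed=rng_base
            )
        else:
            table = CalibrationTable.from_csv(config.calibration_csv)
        table.to_csv(outdir / "calibration_table.csv")
        spring = SpringCalibration(table).fit()
        spring.to_json(outdir / "spring_model.json")
        return spring

    spring = _stage("calibrate", calibrate)

    # ---- curves -----------------------------------------------------------
    def curves_for(rate: float) -> list[FDCurve]:
        if config.mode == "synthetic":
            preset = make_rate_preset(rate)
            n_rep = config.replicates.get(rate, 1)
            out = []
            for i in range(n_rep):
                seed = rng_base * 1000 + int(round(rate * 10)) * 100 + i
                out.append(generate_fd_curve(
                    preset, config.n_points, config.noise_sd, seed=seed
                ))
            return out
        return [FDCurve.from_csv(p, rate=rate * 1e-6) for p in config.curve_csvs[rate]]

    fits_by_rate: dict = {}
    summaries: dict = {}
    for rate in config.rates_um_s:
        curves = _stage(f"curves[{rate}]", curves_for, rate)
        fits = []
        for i, curve in enumerate(curves):
            curve.to_csv(outdir / f"curve_rate{rate}_rep{i}.csv")
            fit = _stage(f"segment[{rate}:{i}]", segment_regimes, curve, config.segmentation)
            fit.to_json(outdir / f"fit_rate{rate}_rep{i}.json")
            fits.append(fit)
        summary = _stage(f"summarize[{rate}]", summarize_replicates, fits)
        summary.to_json(outdir / f"summary_rate{rate}.json")
        fits_by_rate[rate] = fits
        summaries[rate] = summary

    # ---- inversion --------------------------------------------------------
    def invert():
        model = StretcherModel(config.stretcher, resolution=config.resolution)
        table, results = modulus_rate_table(
            {s.rate: s for s in summaries.values()},
            tol=config.inversion_tol, model=model,
        )
        table.to_csv(outdir / "modulus_rate_table.csv", index=False)
        return table, results

    table, inv_results = _stage("invert", invert)

    report = Report(
        schema_version="1",
        software_version=__version__,
        config_hash=config.config_hash(),
        spring={"k_N_per_m": spring.k, "k_se_N_per_m": spring.k_se,
                "intercept_N": spring.intercept, "n": spring.n},
        fits={str(r): [f.to_dict() for f in fits] for r, fits in fits_by_rate.items()},
        summaries={str(r): s.to_dict() for r, s in summaries.items()},
        inverse={f"{rate * 1e6:g}": res.to_dict() for rate, res in inv_results.items()},
        rate_table=table.to_dict(orient="records"),
    )
    report.to_json(outdir / "report.json")
    return report
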