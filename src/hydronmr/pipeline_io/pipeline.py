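"""End-to-end batch analysis: fit every configured dataset, derive tables.

The report is plain JSON-serialisable data with a schema version; numeric
results are floats, with parenthesis-notation strings alongside for human
reading.  Partial failures are recorded as warnings, not aborts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np

from .. import estimation as est
from .. import core_models as cm
from ..datasets import IsothermData
from .config import AnalysisConfig, ConfigError
from . import io as pio

logger = logging.getLogger("hydronmr")

SCHEMA_VERSION = 1


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("hydronmr")
    except Exception:
        return "unknown"


def _params_dict(params) -> dict:
    out = {}
    for k, v in dataclasses.asdict(params).items():
        if v is None or isinstance(v, (int, float, str)):
            out[k] = v
    return out


def fit_record(result: est.FitResult, source: str, options: dict) -> dict:
    """Serialise one FitResult with provenance."""
    return {
        "input": source,
        "options": options,
        "params": _params_dict(result.params),
        "sigma": {k: float(v) for k, v in result.sigma.items()},
        "pretty": result.summary(),
        "rss": float(result.rss),
        "n_points": int(result.n_points),
        "model_order": int(result.model_order),
        "criterion_values": {
            k: (float(v) if isinstance(v, (int, float)) else v)
            for k, v in result.criterion_values.items()
        },
        "flags": list(result.flags),
    }


@dataclasses.dataclass
class AnalysisReport:
    """Serialisable record of one full pipeline run."""

    schema_version: int = SCHEMA_VERSION
    package_version: str = ""
    seed: int = 0
    kinetics: list = dataclasses.field(default_factory=list)
    dehydration: list = dataclasses.field(default_factory=list)
    hydration_table: list = dataclasses.field(default_factory=list)
    isotherm: Optional[dict] = None
    isotherm_from_courses: Optional[dict] = None
    fid: Optional[dict] = None
    spectrum: Optional[dict] = None
    solute: Optional[dict] = None
    threshold: Optional[dict] = None
    warnings: list = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "AnalysisReport":
        p = Path(str(source))
        raw = json.loads(p.read_text() if p.exists() else str(source))
        return cls(**raw)


def run_full_analysis(
    config: AnalysisConfig, base_dir: Optional[Path] = None
) -> AnalysisReport:
    """Fit every dataset in ``config`` and assemble the derived tables.

    Hydration courses with recorded target humidities are additionally
    reduced to saturation levels C^h; when at least five humidities are
    available these are assembled into a sorption isotherm and fitted with
    the configured isotherm options.
    """
    base = Path(base_dir) if base_dir is not None else None
    config.validate_paths(base)

    def _resolve(p: str) -> Path:
        return (base / p) if base is not None else Path(p)

    report = AnalysisReport(
        package_version=_package_version(), seed=config.seed
    )

    def guard(section: str, fn):
        try:
            return fn()
        except Exception as exc:
            msg = f"{section}: {type(exc).__name__}: {exc}"
            logger.warning(msg)
            report.warnings.append(msg)
            return None

    ch_points = []
    for spec in config.courses:
        def _one(spec=spec):
            if spec.direction == "dehydration":
                course = pio.read_course(
                    _resolve(spec.path), direction="dehydration"
                )
                result = est.fit_dehydration(course)
                report.dehydration.append(
                    fit_record(result, spec.path, {"direction": "dehydration"})
                )
                return None
            course = pio.read_course(_resolve(spec.path), humidity=spec.humidity)
            result = est.fit_kinetics(course, order=spec.order)
            rec = fit_record(
                result, spec.path,
                {"direction": "hydration", "order": spec.order,
                 "humidity": spec.humidity},
            )
            ch = cm.total_hydration(result.params)
            rec["total_hydration"] = float(ch)
            report.kinetics.append(rec)
            if spec.humidity is not None:
                report.hydration_table.append(
                    {"p_over_p0": spec.humidity, "c_h": float(ch)}
                )
                ch_points.append((spec.humidity, float(ch)))
        guard(f"course {spec.path}", _one)

    if len({h for h, _ in ch_points}) >= 5:
        def _assembled():
            h = np.array([p[0] for p in ch_points])
            c = np.array([p[1] for p in ch_points])
            data = IsothermData(p_over_p0=h, c_h=c)
            result = est.fit_isotherm(
                data, model=config.isotherm_model, method=config.isotherm_method
            )
            report.isotherm_from_courses = fit_record(
                result, "<derived from hydration courses>",
                {"model": config.isotherm_model, "method": config.isotherm_method},
            )
        guard("isotherm_from_courses", _assembled)

    if config.isotherm is not None:
        def _iso():
            data = pio.read_isotherm(
                _resolve(config.isotherm.path),
                humidity_unit=config.isotherm.humidity_unit,
            )
            result = est.fit_isotherm(
                data, model=config.isotherm.model, method=config.isotherm.method
            )
            report.isotherm = fit_record(
                result, config.isotherm.path,
                config.isotherm.model_dump(exclude={"path"}),
            )
        guard("isotherm", _iso)

    if config.fid is not None:
        def _fid():
            trace = pio.read_fid(_resolve(config.fid.path))
            result = est.fit_fid(
                trace, liquid_order=config.fid.liquid_order,
                skip_points=config.fid.skip_points,
            )
            report.fid = fit_record(
                result, config.fid.path, config.fid.model_dump(exclude={"path"})
            )
        guard("fid", _fid)

    if config.spectrum is not None:
        def _spec():
            spectrum = pio.read_spectrum(_resolve(config.spectrum.path))
            result = est.fit_spectrum(
                spectrum, lorentzian_order=config.spectrum.lorentzian_order
            )
            rec = fit_record(
                result, config.spectrum.path,
                config.spectrum.model_dump(exclude={"path"}),
            )
            rec["ratios"] = {
                k: float(v) for k, v in result.params.ratio_table().items()
            }
            report.spectrum = rec
        guard("spectrum", _spec)

    if config.solute is not None:
        def _sol():
            ratios = pio.read_solute(_resolve(config.solute.path))
            if ratios.l_over_s is not None and ratios.l1_over_l is not None:
                result = est.fit_solute_combined(
                    ratios, ratios,
                    gamma_mode=config.solute.gamma_mode,
                    gamma_value=config.solute.gamma_value,
                )
                report.solute = fit_record(
                    result, config.solute.path,
                    config.solute.model_dump(exclude={"path"}),
                )
            if (
                config.solute.detect_threshold
                and ratios.l_over_s is not None
                and len(ratios) >= 12
            ):
                tfit = est.detect_threshold(ratios)
                report.threshold = {
                    "input": config.solute.path,
                    "threshold": tfit.threshold,
                    "above_slope": tfit.above_slope,
                    "above_intercept": tfit.above_intercept,
                    "evidence": float(tfit.evidence)
                    if np.isfinite(tfit.evidence) else None,
                    "below_params": _params_dict(tfit.below_params)
                    if tfit.below_params is not None else None,
                    "criterion_values": {
                        k: float(v) for k, v in tfit.criterion_values.items()
                    },
                }
        guard("solute", _sol)

    if config.output_dir is not None:
        outdir = _resolve(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_json(outdir / "report.json")

    return report
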