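"""Configuration loading and validation.

One YAML file with per-stage blocks (``fixture``, ``severity``, ``services``,
``benefit``, ``seed``) drives the whole pipeline.  Validation is fail-fast
but exhaustive: every schema violation found is reported, not just the
first.  A packaged default configuration encodes the study conditions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .burden import SeverityClass, SeverityModel
from .services import (
    CarePackage,
    Provider,
    StaffingParameters,
    Treatment,
    TREATMENT_TYPES,
    VISIT_TYPES,
)


class ConfigError(ValueError):
    """Raised with the full list of schema violations in ``errors``."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.errors))


REQUIRED_BLOCKS = ("fixture", "severity", "services", "benefit")


@dataclass(frozen=True)
class RunConfig:
    raw: dict
    seed: int
    fixture: dict
    severity: dict[str, SeverityModel]
    packages: tuple[CarePackage, ...]
    staffing: StaffingParameters
    services: dict
    benefit: dict
    source: str = "<dict>"


def default_config_path() -> Path:
    return Path(importlib.resources.files("mhplan") / "data" / "default.yaml")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML configuration (packaged default if ``None``)."""
    path = Path(path) if path is not None else default_config_path()
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = parse_config(raw)
    object.__setattr__(cfg, "source", str(path))
    return cfg


def parse_config(raw: dict) -> RunConfig:
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping"])
    for block in REQUIRED_BLOCKS:
        if block not in raw:
            errors.append(f"missing block {block!r}")
    if errors:
        raise ConfigError(errors)

    severity = _build_severity(raw["severity"], errors)
    packages = _build_packages(raw["services"].get("packages"), errors)
    staffing = _build_staffing(raw["services"].get("staffing"), errors)
    _check_fixture(raw["fixture"], errors)
    _check_benefit(raw["benefit"], errors)
    if errors:
        raise ConfigError(errors)
    return RunConfig(
        raw=raw,
        seed=int(raw.get("seed", 20150101)),
        fixture=raw["fixture"],
        severity=severity,
        packages=packages,
        staffing=staffing,
        services=raw["services"],
        benefit=raw["benefit"],
    )


def _proportion(value, name: str, errors: list[str], lo=0.0, hi=1.0) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError):
        errors.append(f"{name}: not a number ({value!r})")
        return 0.0
    if not lo <= v <= hi:
        errors.append(f"{name}: value {v} outside [{lo}, {hi}]")
    return v


def _build_severity(block, errors) -> dict[str, SeverityModel]:
    out: dict[str, SeverityModel] = {}
    if not isinstance(block, dict):
        errors.append("severity: must map disorder -> model")
        return out
    for disorder, spec in block.items():
        classes = []
        for cls in spec.get("classes", []):
            _proportion(cls.get("proportion"), f"severity.{disorder}.{cls.get('name')}.proportion", errors)
            _proportion(cls.get("dw"), f"severity.{disorder}.{cls.get('name')}.dw", errors)
            try:
                classes.append(
                    SeverityClass(
                        cls["name"], float(cls["proportion"]), float(cls["dw"]),
                        cls.get("dw_lower95"), cls.get("dw_upper95"),
                    )
                )
            except (KeyError, ValueError) as exc:
                errors.append(f"severity.{disorder}: {exc}")
        try:
            out[disorder] = SeverityModel(
                disorder, tuple(classes), float(spec["moderate_severe_prop"])
            )
        except (KeyError, ValueError) as exc:
            errors.append(f"severity.{disorder}: {exc}")
    return out


def _build_packages(block, errors) -> tuple[CarePackage, ...]:
    if not isinstance(block, dict):
        errors.append("services.packages: must map package name -> spec")
        return ()
    packages = []
    for name, spec in block.items():
        treatments = {}
        for ttype, t in (spec.get("treatments") or {}).items():
            if ttype not in TREATMENT_TYPES:
                errors.append(f"services.packages.{name}: unknown treatment type {ttype!r}")
                continue
            _proportion(t.get("proportion", 1.0), f"services.packages.{name}.{ttype}.proportion", errors)
            try:
                treatments[ttype] = Treatment(
                    proportion=float(t.get("proportion", 1.0)),
                    visits_per_person=float(t.get("visits_per_person", 0.0)),
                    minutes_per_visit=float(t.get("minutes_per_visit", 30.0)),
                    bed_days_per_person=float(t.get("bed_days_per_person", 0.0)),
                )
            except ValueError as exc:
                errors.append(f"services.packages.{name}.{ttype}: {exc}")
        target = _proportion(spec.get("coverage_target"), f"services.packages.{name}.coverage_target", errors)
        try:
            packages.append(
                CarePackage(
                    name=name,
                    applies_to=tuple(spec.get("applies_to", ())),
                    coverage_target=target,
                    treatments=treatments,
                    inpatient_allowed=bool(spec.get("inpatient_allowed", True)),
                )
            )
        except ValueError as exc:
            errors.append(f"services.packages.{name}: {exc}")
    return tuple(packages)


def _build_staffing(block, errors) -> StaffingParameters:
    fallback = StaffingParameters(
        providers={"nurse": Provider(230, {v: 10 for v in VISIT_TYPES}, 1.0)},
        shares={v: {"nurse": 1.0} for v in VISIT_TYPES},
    )
    if not isinstance(block, dict):
        errors.append("services.staffing: missing or malformed block")
        return fallback
    providers = {}
    for name, p in (block.get("providers") or {}).items():
        try:
            providers[name] = Provider(
                days_per_year=float(p["days_per_year"]),
                consults_per_day={k: float(v) for k, v in (p.get("consults_per_day") or {}).items()},
                staff_per_ward=float(p.get("staff_per_ward", 0.0)),
            )
        except (KeyError, ValueError) as exc:
            errors.append(f"services.staffing.providers.{name}: {exc}")
    shares = {
        ttype: {prov: float(s) for prov, s in mapping.items()}
        for ttype, mapping in (block.get("shares") or {}).items()
    }
    try:
        return StaffingParameters(
            providers=providers,
            shares=shares,
            ward_size_beds=float(block.get("ward_size_beds", 25)),
            occupancy_factor=float(block.get("occupancy_factor", 1.15)),
        )
    except ValueError as exc:
        errors.append(f"services.staffing: {exc}")
        return fallback


def _check_fixture(block, errors) -> None:
    if not isinstance(block, dict):
        errors.append("fixture: must be a mapping")
        return
    if block.get("total_population", 1) <= 0:
        errors.append("fixture.total_population: must be > 0")
    for key in ("comorbid_rho",):
        if key in block:
            _proportion(block[key], f"fixture.{key}", errors)


def _check_benefit(block, errors) -> None:
    if not isinstance(block, dict):
        errors.append("benefit: must be a mapping")
        return
    streams = block.get("streams")
    if not isinstance(streams, dict):
        errors.append("benefit.streams: must map stream name -> parameters")
        return
    for name in ("ptsd", "comorbid"):
        if name not in streams:
            errors.append(f"benefit.streams: missing stream {name!r}")
            continue
        s = streams[name]
        if "remission" not in s or float(s.get("remission", -1)) < 0:
            errors.append(f"benefit.streams.{name}.remission: missing or negative")
        eff = s.get("effects", {})
        _proportion(eff.get("delta_dw", 0), f"benefit.streams.{name}.effects.delta_dw", errors)
        for p in s.get("packages", []):
            _proportion(p.get("efficacy"), f"benefit.streams.{name}.packages.{p.get('name')}.efficacy", errors)
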