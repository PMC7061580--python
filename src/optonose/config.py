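"""Run configuration: one YAML document driving the whole pipeline.

Defaults mirror the instrument protocol (45 cycles of 5 s exposure + 15 s
recovery at 90 Hz, duplicate assays, smoothing window of 100 points, RBF SVM
with C=100 and gamma=0.1 under stratified 10-fold CV).  Unknown keys are
rejected; all violations are collected and reported together.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .classification import CVConfig
from .preprocessing import SmoothConfig
from .synthetic import (
    DEFAULT_NOISE_SD,
    VOC_NAMES,
    AssaySchedule,
    FilmModel,
    default_film_set,
)

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config", "default_config"]


class ConfigError(ValueError):
    """Invalid run configuration; carries the full list of violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(violations))


@dataclass(frozen=True)
class RunConfig:
    schedule: AssaySchedule = field(default_factory=AssaySchedule)
    films: tuple[FilmModel, ...] = field(default_factory=lambda: tuple(default_film_set()))
    voc_names: tuple[str, ...] = VOC_NAMES
    voc_seed: int = 0
    noise_sd: float = DEFAULT_NOISE_SD
    n_replicates: int = 2
    smoothing: SmoothConfig = field(default_factory=SmoothConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    master_seed: int = 0
    output_dir: str = "results"

    def to_dict(self) -> dict:
        return {
            "schedule": asdict(self.schedule),
            "films": [asdict(f) for f in self.films],
            "voc_names": list(self.voc_names),
            "voc_seed": self.voc_seed,
            "noise_sd": self.noise_sd,
            "n_replicates": self.n_replicates,
            "smoothing": asdict(self.smoothing),
            "cv": asdict(self.cv),
            "master_seed": self.master_seed,
            "output_dir": self.output_dir,
        }

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def default_config() -> RunConfig:
    return RunConfig()


_TOP_KEYS = {
    "schedule",
    "films",
    "voc_names",
    "voc_seed",
    "noise_sd",
    "n_replicates",
    "smoothing",
    "cv",
    "master_seed",
    "output_dir",
}


def _build_section(cls, raw: dict, name: str, violations: list[str]):
    """Instantiate a config dataclass, folding errors into ``violations``."""
    allowed = set(cls.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        violations.append(f"{name}: unknown key(s) {sorted(unknown)}")
        raw = {k: v for k, v in raw.items() if k in allowed}
    try:
        return cls(**raw)
    except (TypeError, ValueError) as exc:
        violations.append(f"{name}: {exc}")
        return None


def validate_config(raw: str | dict) -> RunConfig:
    """Parse and validate a YAML document (or pre-parsed mapping).

    Raises :class:`ConfigError` listing every violation found.
    """
    if isinstance(raw, str):
        try:
            raw = yaml.safe_load(raw) or {}
        except yaml.YAMLError as exc:
            raise ConfigError([f"not valid YAML: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError(["configuration must be a mapping"])

    violations: list[str] = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        violations.append(f"unknown top-level key(s): {sorted(unknown)}")

    schedule = _build_section(AssaySchedule, raw.get("schedule", {}), "schedule", violations)
    smoothing = _build_section(SmoothConfig, raw.get("smoothing", {}), "smoothing", violations)
    cv = _build_section(CVConfig, raw.get("cv", {}), "CVConfig", violations)

    films_raw = raw.get("films")
    if films_raw is None:
        films = tuple(default_film_set())
    else:
        films = []
        for i, fr in enumerate(films_raw):
            film = _build_section(FilmModel, fr, f"films[{i}]", violations)
            if film is not None:
                films.append(film)
        films = tuple(films)
        if not films:
            violations.append("films: at least one film is required")

    voc_names = tuple(raw.get("voc_names", VOC_NAMES))
    bad_names = [n for n in voc_names if n not in VOC_NAMES]
    if bad_names:
        violations.append(f"voc_names: unknown VOC(s) {bad_names}; known: {list(VOC_NAMES)}")
    if not voc_names:
        violations.append("voc_names: at least one VOC is required")

    noise_sd = raw.get("noise_sd", DEFAULT_NOISE_SD)
    if noise_sd < 0:
        violations.append("noise_sd must be >= 0")
    n_replicates = raw.get("n_replicates", 2)
    if n_replicates < 1:
        violations.append("n_replicates must be >= 1")

    if violations:
        raise ConfigError(violations)
    return RunConfig(
        schedule=schedule,
        films=films,
        voc_names=voc_names,
        voc_seed=int(raw.get("voc_seed", 0)),
        noise_sd=float(noise_sd),
        n_replicates=int(n_replicates),
        smoothing=smoothing,
        cv=cv,
        master_seed=int(raw.get("master_seed", 0)),
        output_dir=str(raw.get("output_dir", "results")),
    )


def load_config(path: str | Path | None) -> RunConfig:
    """Load a config file, or the built-in defaults when ``path`` is None."""
    if path is None:
        return default_config()
    return validate_config(Path(path).read_text())
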