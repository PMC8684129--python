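"""Structured pipeline configuration (YAML mapping with strict keys)."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import SyntheticCohortSpec, spec_from_dict
from .types import AnalysisConfig, STAGE_ORDER


@dataclass
class InputPaths:
    """Locations of pre-existing cohort inputs (all optional individually)."""

    accessibility: str | None = None
    peaks_dir: str | None = None
    tracks_dir: str | None = None
    expression: str | None = None
    metadata: str | None = None
    genome: str | None = None
    tss: str | None = None
    motifs: str | None = None


@dataclass
class PipelineConfig:
    """Validated end-to-end configuration.

    Either ``simulate`` (a synthetic cohort spec) or ``inputs`` (file paths)
    must provide the cohort; ``analysis`` carries the thresholds and sizes;
    ``seed`` seeds every stochastic stage. Unknown keys are rejected.
    """

    seed: int = 0
    outdir: str = "chromstrat_out"
    simulate: SyntheticCohortSpec | None = None
    inputs: InputPaths = field(default_factory=InputPaths)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    stage_order: tuple[str, ...] = STAGE_ORDER

    def validate(self) -> None:
        has_matrix = self.inputs.accessibility or (
            self.inputs.peaks_dir and self.inputs.tracks_dir
        )
        if self.simulate is None and not has_matrix:
            raise ValueError(
                "config must provide either 'simulate' or inputs with an "
                "accessibility matrix (or peaks_dir + tracks_dir)"
            )
        if self.simulate is None:
            for name in ("expression", "metadata"):
                p = getattr(self.inputs, name)
                if p and not Path(p).exists():
                    raise ValueError(f"configured {name} file does not exist: {p}")
            if self.inputs.accessibility and not Path(self.inputs.accessibility).exists():
                raise ValueError(
                    f"configured accessibility file does not exist: {self.inputs.accessibility}"
                )


def _strict_build(cls, data: dict, what: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {what} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {"seed", "outdir", "simulate", "inputs", "analysis", "stage_order"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", "chromstrat_out")),
    )
    if "simulate" in raw and raw["simulate"] is not None:
        sim = dict(raw["simulate"])
        sim.setdefault("seed", cfg.seed)
        cfg.simulate = spec_from_dict(sim)
    if "inputs" in raw and raw["inputs"] is not None:
        cfg.inputs = _strict_build(InputPaths, dict(raw["inputs"]), "inputs")
    if "analysis" in raw and raw["analysis"] is not None:
        adict = dict(raw["analysis"])
        if "alpha_stars" in adict:
            adict["alpha_stars"] = tuple(float(a) for a in adict["alpha_stars"])
        adict.setdefault("seed", cfg.seed)
        cfg.analysis = _strict_build(AnalysisConfig, adict, "analysis")
    if "stage_order" in raw and raw["stage_order"] is not None:
        cfg.stage_order = tuple(str(s) for s in raw["stage_order"])
    cfg.validate()
    return cfg
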