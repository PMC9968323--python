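"""Run configuration: schema, validation and seed derivation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from .simulate import SimConfig

KNOWN_TOP_KEYS = {
    "seed",
    "out_dir",
    "timepoints",
    "sample_generations",
    "n_generations",
    "sim",
    "extract",
    "lineage",
    "transitions",
    "whitelist",
    "log_level",
}


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.errors


@dataclass
class RunConfig:
    """Full pipeline configuration (see docs for the YAML schema)."""

    seed: int = 0
    out_dir: str = "out"
    timepoints: list[str] = field(default_factory=lambda: ["Day0", "Day5"])
    sample_generations: list[int] = field(default_factory=lambda: [2, 5])
    n_generations: int = 5
    sim: dict = field(default_factory=dict)
    extract: dict = field(default_factory=dict)
    lineage: dict = field(default_factory=dict)
    transitions: dict = field(default_factory=dict)
    whitelist: str | None = None
    log_level: str = "info"
    extra_keys: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        known = {f.name for f in dc_fields(cls)} - {"extra_keys"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = sorted(set(raw) - KNOWN_TOP_KEYS)
        return cls(**kwargs, extra_keys=extra)

    def sim_config(self) -> SimConfig:
        params = dict(self.sim)
        params.setdefault("seed", self.stage_seed(0))
        return SimConfig(**params)

    def stage_seed(self, stage: int) -> int:
        """Deterministic per-stage child seed derived from the global seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(stage,))
        return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)

    def validate(self, check_files: bool = True) -> ValidationReport:
        report = ValidationReport()
        err = report.errors.append
        if not isinstance(self.seed, int) or self.seed < 0:
            err("seed: must be a non-negative integer")
        if not self.timepoints:
            err("timepoints: must be a non-empty list")
        if len(set(self.timepoints)) != len(self.timepoints):
            err("timepoints: must be unique")
        if len(self.sample_generations) != len(self.timepoints):
            err("sample_generations: must have one entry per timepoint")
        elif list(self.sample_generations) != sorted(self.sample_generations):
            err("sample_generations: must be ascending (ordered like timepoints)")
        if self.sample_generations and self.n_generations < max(
            self.sample_generations, default=0
        ):
            err("n_generations: must cover the last sampled generation")
        try:
            self.sim_config()
        except (TypeError, ValueError) as exc:
            err(f"sim: {exc}")
        for block, keys in (
            ("extract", {"max_flank_mismatch", "max_spacer_mismatch", "min_umi",
                         "umi_hamming", "barcode_hamming", "flank5", "flank3"}),
            ("lineage", {"min_shared", "min_margin", "saturation_fractions",
                         "saturation_reps", "min_barcodes_per_cell"}),
            ("transitions", {"min_count", "markov_labels"}),
        ):
            unknown = sorted(set(getattr(self, block)) - keys)
            if unknown:
                report.warnings.append(f"{block}: unknown keys {unknown} ignored")
        for name in ("min_shared", "min_margin"):
            v = self.lineage.get(name)
            if v is not None and (not isinstance(v, int) or v < 0):
                err(f"lineage.{name}: must be a non-negative integer")
        if check_files and self.whitelist is not None and not Path(self.whitelist).exists():
            err(f"whitelist: file {self.whitelist!r} does not exist")
        if self.extra_keys:
            report.warnings.append(f"unknown top-level keys {self.extra_keys} ignored")
        return report


def validate_config(path) -> ValidationReport:
    """Load and validate a config file, returning per-field messages."""
    try:
        config = RunConfig.from_yaml(path)
    except (OSError, ValueError, TypeError, yaml.YAMLError) as exc:
        return ValidationReport(errors=[f"config: {exc}"])
    return config.validate()
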