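"""Run configuration for the command-line pipeline.

A flat YAML file of paths, thresholds and the seed.  Unknown keys are
rejected; thresholds are range-checked at load so a bad value fails
before any stage runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .errors import MissingInputError, ValidationError


@dataclass
class RunConfig:
    # paths
    reference: str = ""
    annotation: str = ""
    germline_db: str = ""
    metadata: str = ""
    alignments: str = ""
    haplotypes: str = ""
    reads: str = ""
    output_dir: str = "results"
    # thresholds
    min_ac_exclusive: int = 1
    mismatch_fraction_threshold: float = 0.25
    conversion_margin: float = 0.002
    sv_min_covered_fraction: float = 0.9
    sv_max_deleted_fraction: float = 0.1
    window_size: int = 10_000
    seed: int = 0

    _RANGES = {
        "min_ac_exclusive": (0, 10_000),
        "mismatch_fraction_threshold": (0.0, 1.0),
        "conversion_margin": (0.0, 1.0),
        "sv_min_covered_fraction": (0.0, 1.0),
        "sv_max_deleted_fraction": (0.0, 1.0),
        "window_size": (1, 10_000_000),
    }

    def validate(self) -> None:
        for key, (lo, hi) in self._RANGES.items():
            v = getattr(self, key)
            if not (lo <= v <= hi):
                raise ValidationError(f"{key}={v} outside [{lo}, {hi}]")
        if self.sv_max_deleted_fraction >= self.sv_min_covered_fraction:
            raise ValidationError(
                "sv_max_deleted_fraction must be below sv_min_covered_fraction"
            )

    def thresholds(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "min_ac_exclusive",
                "mismatch_fraction_threshold",
                "conversion_margin",
                "sv_min_covered_fraction",
                "sv_max_deleted_fraction",
                "window_size",
                "seed",
            )
        }

    @classmethod
    def load(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        except FileNotFoundError:
            raise MissingInputError(f"config file not found: {path}") from None
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a flat mapping")
        known = {f.name for f in fields(cls) if not f.name.startswith("_")}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg
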