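"""Run configuration: JSON loading and cross-module validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .calculator import STRAIN_PRESETS, StrainThresholds
from .signal_io import SpectrogramParams
from .twostep_cluster import CFTreeParams


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Bundle of all pipeline parameters, loadable from JSON.

    Strain presets may be extended or overridden via the ``strains`` map
    (name -> {step_threshold_khz, high_low_boundary_khz}).
    """

    spectrogram: SpectrogramParams = field(default_factory=SpectrogramParams)
    detection_threshold_db: float = 10.0
    detection_hold_ms: float = 5.0
    contour_placement: str = "midpoint"
    step_threshold_khz: float = 20.0
    clustering: CFTreeParams = field(default_factory=CFTreeParams)
    k_max: int = 15
    seed: int = 0
    strains: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.contour_placement not in ("midpoint", "endpoint"):
            raise ConfigError(f"unknown contour_placement {self.contour_placement!r}")
        if self.detection_threshold_db <= 0:
            raise ConfigError("detection_threshold_db must be positive")
        if self.detection_hold_ms < 0:
            raise ConfigError("detection_hold_ms must be non-negative")
        if self.step_threshold_khz <= 0:
            raise ConfigError("step_threshold_khz must be positive")
        if self.k_max < 2:
            raise ConfigError("k_max must be >= 2")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            raw = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        kwargs = dict(raw)
        try:
            if "spectrogram" in kwargs:
                kwargs["spectrogram"] = SpectrogramParams(**kwargs["spectrogram"])
            if "clustering" in kwargs:
                kwargs["clustering"] = CFTreeParams(**kwargs["clustering"])
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc

    def thresholds_for(
        self,
        strain: str | None,
        boundary_khz: float | None = None,
        step_khz: float | None = None,
    ) -> StrainThresholds:
        """Resolve classification thresholds from a strain name or overrides."""
        if strain is not None:
            table = {**STRAIN_PRESETS, **{
                k: (v["step_threshold_khz"], v["high_low_boundary_khz"])
                for k, v in self.strains.items()
            }}
            if strain not in table:
                raise ConfigError(
                    f"unknown strain {strain!r}; presets: {sorted(table)}; "
                    "or pass explicit --boundary-khz/--step-khz"
                )
            step, boundary = table[strain]
        else:
            if boundary_khz is None:
                raise ConfigError("either a strain name or --boundary-khz is required")
            step, boundary = self.step_threshold_khz, boundary_khz
        if step_khz is not None:
            step = step_khz
        if boundary_khz is not None:
            boundary = boundary_khz
        return StrainThresholds(step, boundary, strain_name=strain or "custom")

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance records."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
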