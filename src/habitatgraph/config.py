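"""Pipeline configuration with printed-method defaults.

Defaults follow the study design this package implements: an 8-pixel grid over
1 mm isotropic slices, a 10,000-tree random forest, and 5-fold stratified
cross-validation. The circular GRLM window is unbounded by default and the
run-length cap is 10 edges.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

from .errors import ParameterError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    grid_spacing_pixels: int = 8
    gmm_seed: int = 0
    window_radius_mm: float | None = None  # None = unbounded window
    l_max: int = 10
    rf_trees: int = 10_000
    cv_folds: int = 5
    rf_seed: int = 0
    slice_selection: str | int = "max-area"
    spacing_mm: tuple[float, float] | None = None  # override for PNG input

    def __post_init__(self) -> None:
        for name in ("grid_spacing_pixels", "l_max", "rf_trees", "cv_folds"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be positive")
        if self.window_radius_mm is not None and self.window_radius_mm <= 0:
            raise ParameterError("window_radius_mm must be positive or None")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "spacing_mm" in payload and payload["spacing_mm"] is not None:
            payload["spacing_mm"] = tuple(payload["spacing_mm"])
        return cls(**payload)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        if payload["spacing_mm"] is not None:
            payload["spacing_mm"] = list(payload["spacing_mm"])
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
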