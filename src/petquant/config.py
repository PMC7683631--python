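"""Structured pipeline configuration with YAML loading."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .corrections import UptakeCorrectionParams


@dataclass
class PipelineConfig:
    """One config object drives every pipeline stage, for reproducibility.

    ``psf_fwhm_mm`` is the assumed reconstructed-image resolution (the
    cold-wall correction magnitudes depend on it); ``model_sbr`` the
    sphere-to-background ratio used by the convolution RC model.
    """

    psf_fwhm_mm: float = 6.5
    model_sbr: float = 2.26
    wall_mm: float = 1.0
    peak_voi_ml: float = 1.0
    interpolation: str = "pchip-logvolume"
    time_mode: str = "approx"  # {"approx", "exact"}
    t0_min: float = 60.0
    vr: float = 0.53
    b: float = 0.313
    grouping_policy: str = "amp_with_wt"
    exclude_near_treated: bool = False
    biopsy_confirmed_only: bool = False
    seed: int = 0
    phantom_noise_sd: float = 0.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.psf_fwhm_mm <= 0:
            raise ValueError("psf_fwhm_mm must be positive")
        if self.model_sbr <= 1:
            raise ValueError("model_sbr must exceed 1 for hot spheres")
        if self.wall_mm < 0:
            raise ValueError("wall_mm must be >= 0")
        if self.time_mode not in ("approx", "exact"):
            raise ValueError("time_mode must be 'approx' or 'exact'")

    @property
    def uptake_params(self) -> UptakeCorrectionParams:
        return UptakeCorrectionParams(t0_min=self.t0_min, vr=self.vr, b=self.b)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extra=extra)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
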