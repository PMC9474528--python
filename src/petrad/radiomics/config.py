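"""Extraction configuration."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PreprocessConfig:
    """Interpolation and discretisation settings.

    CT is resampled to isotropic voxels with cubic B-spline interpolation;
    PET stays on its native (near-isotropic) grid. Grey levels use a fixed
    bin size anchored at the in-mask minimum.
    """

    ct_iso_spacing: float = 1.5     # mm
    pet_interpolate: bool = False
    pet_bin_width: float = 0.5      # g/mL
    ct_bin_width: float = 25.0      # HU

    def __post_init__(self) -> None:
        if self.ct_iso_spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.pet_bin_width <= 0 or self.ct_bin_width <= 0:
            raise ValueError("bin widths must be positive")
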