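"""Model menu: biochemistry, SUV_max, 3-factor and 3-feature imaging models,
each optionally combined with the biochemical profile."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

BIOCHEM_COLS = ["adrenergic", "noradrenergic", "dopaminergic"]

BASE_SPECS = ("biochem", "suvmax", "pet3factor", "petct3factor", "pet3feature")


@dataclass(frozen=True)
class ModelSpec:
    """A named predictor recipe.

    base: one of BASE_SPECS. add_biochem appends the three dichotomous
    catecholamine flags to the imaging predictors (6 predictors total for
    the 3-factor/3-feature models).
    """

    base: str
    add_biochem: bool = False

    def __post_init__(self) -> None:
        if self.base not in BASE_SPECS:
            raise ValueError(f"unknown model spec {self.base!r}")
        if self.base == "biochem" and self.add_biochem:
            raise ValueError("biochem model already contains the biochemical profile")

    @property
    def name(self) -> str:
        return self.base + ("+biochem" if self.add_biochem else "")

    @property
    def needs_factors(self) -> bool:
        return self.base in ("pet3factor", "petct3factor", "pet3feature")


def model_menu() -> list[ModelSpec]:
    """The nine evaluated models: biochem, then each imaging base +/- biochem."""
    menu = [ModelSpec("biochem")]
    for base in BASE_SPECS[1:]:
        menu.append(ModelSpec(base))
        menu.append(ModelSpec(base, add_biochem=True))
    return menu


def pet_columns(df: pd.DataFrame) -> list[str]:
    """PET-derived feature columns (105 per-modality features plus TLG)."""
    return [c for c in df.columns if c.startswith("PET_")]


def imaging_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith(("PET_", "CT_"))]
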