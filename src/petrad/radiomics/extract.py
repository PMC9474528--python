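"""Per-modality and per-lesion feature extraction.

A lesion record holds 105 PET features + 105 CT features + total lesion
glycolysis (TLG = SUV_mean x metabolic tumour volume) = 211 named values.
"""

from __future__ import annotations

from collections import OrderedDict

from petrad.imaging_io import ImageVolume, VoiMask
from petrad.radiomics.config import PreprocessConfig
from petrad.radiomics.firstorder import first_order_features
from petrad.radiomics.glcm import glcm_features
from petrad.radiomics.gldm import gldm_features
from petrad.radiomics.glrlm import glrlm_features
from petrad.radiomics.glszm import glszm_features
from petrad.radiomics.ngtdm import ngtdm_features
from petrad.radiomics.preprocess import (
    crop_to_mask,
    crop_volume_to_mask,
    discretise,
    resample_isotropic,
)
from petrad.radiomics.shape import shape_features

__all__ = ["modality_features", "extract_lesion", "tlg"]


def tlg(suv_mean: float, mtv_cm3: float) -> float:
    """Total lesion glycolysis (g): mean SUV (g/mL) x metabolic volume (cm^3)."""
    return float(suv_mean) * float(mtv_cm3)


def modality_features(
    volume: ImageVolume,
    mask: VoiMask,
    bin_width: float,
    modality: str = "PET",
) -> tuple["OrderedDict[str, float]", dict]:
    """105 features of one modality on its (already preprocessed) grid.

    Returns ``(features, flags)``; `flags` records degenerate texture
    families (e.g. single grey level) without dropping the lesion.
    """
    if not mask.same_grid(volume):
        raise ValueError("mask grid does not match volume grid")
    mask.validate()
    labels, n_levels, single_bin = discretise(volume, mask, bin_width)
    flags: dict[str, bool] = {"single_bin": single_bin}

    values = volume.data[mask.data]
    fo = first_order_features(values, labels[mask.data], n_levels, volume.voxel_volume_mm3)
    sh = shape_features(mask.data, volume.spacing)

    (cropped_labels,), _ = crop_to_mask([labels], mask.data)
    glcm, flags["glcm_degenerate"] = glcm_features(cropped_labels, n_levels)
    glrlm, _ = glrlm_features(cropped_labels, n_levels)
    glszm, _ = glszm_features(cropped_labels, n_levels)
    ngtdm, flags["ngtdm_degenerate"] = ngtdm_features(cropped_labels, n_levels)
    gldm, _ = gldm_features(cropped_labels, n_levels)

    out: OrderedDict[str, float] = OrderedDict()
    for family, feats in (
        ("firstorder", fo),
        ("shape", sh),
        ("glcm", glcm),
        ("glrlm", glrlm),
        ("glszm", glszm),
        ("ngtdm", ngtdm),
        ("gldm", gldm),
    ):
        for name, value in feats.items():
            out[f"{modality}_{family}_{name}"] = value
    return out, flags


def extract_lesion(
    pet: ImageVolume,
    pet_mask: VoiMask,
    ct: ImageVolume,
    ct_mask: VoiMask,
    config: PreprocessConfig | None = None,
) -> tuple["OrderedDict[str, float]", dict]:
    """Full 211-value extraction: PET (native grid) + CT (1.5 mm iso) + TLG."""
    config = config or PreprocessConfig()
    pet_feats, pet_flags = modality_features(pet, pet_mask, config.pet_bin_width, "PET")
    # crop to the lesion neighbourhood before the B-spline resample (speed only)
    ct_crop, ct_mask_crop = crop_volume_to_mask(ct, ct_mask, margin_mm=3 * config.ct_iso_spacing)
    ct_iso, ct_mask_iso = resample_isotropic(ct_crop, config.ct_iso_spacing, ct_mask_crop)
    ct_mask_iso.validate()
    ct_feats, ct_flags = modality_features(ct_iso, ct_mask_iso, config.ct_bin_width, "CT")

    out: OrderedDict[str, float] = OrderedDict()
    out.update(pet_feats)
    out.update(ct_feats)
    mtv_cm3 = pet_feats["PET_shape_MeshVolume"] / 1000.0
    out["PET_TLG"] = tlg(pet_feats["PET_firstorder_Mean"], mtv_cm3)
    flags = {f"pet_{k}": v for k, v in pet_flags.items()}
    flags.update({f"ct_{k}": v for k, v in ct_flags.items()})
    return out, flags
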