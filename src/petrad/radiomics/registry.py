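"""Canonical feature name registry: 18 + 14 + 73 = 105 per modality.

The co-occurrence family nominally has 24 members; ``SumAverage``
(redundant with JointAverage for a symmetric matrix, 2*JointAverage) and
``MCC`` are excluded from the default registry so the texture families
total 73 (22 + 16 + 16 + 5 + 14). Both are still computed by
:mod:`petrad.radiomics.glcm` and can be re-enabled.
"""

from __future__ import annotations

FIRST_ORDER = [
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
]

SHAPE = [
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
]

GLCM = [
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Imc1",
    "Imc2",
    "Idm",
    "Idmn",
    "Id",
    "Idn",
    "InverseVariance",
    "MaximumProbability",
    "SumEntropy",
    "SumSquares",
]

GLCM_EXCLUDED = ["SumAverage", "MCC"]

GLRLM = [
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]

GLSZM = [
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]

NGTDM = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]

GLDM = [
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]

FAMILY_FEATURES = {
    "firstorder": FIRST_ORDER,
    "shape": SHAPE,
    "glcm": GLCM,
    "glrlm": GLRLM,
    "glszm": GLSZM,
    "ngtdm": NGTDM,
    "gldm": GLDM,
}

TEXTURE_FAMILIES = ("glcm", "glrlm", "glszm", "ngtdm", "gldm")


def texture_feature_count() -> int:
    return sum(len(FAMILY_FEATURES[f]) for f in TEXTURE_FAMILIES)


def features_per_modality() -> int:
    return sum(len(v) for v in FAMILY_FEATURES.values())


def feature_names(modality: str) -> list[str]:
    """Qualified names, e.g. ``PET_firstorder_Entropy``."""
    return [
        f"{modality}_{family}_{name}"
        for family in ("firstorder", "shape", "glcm", "glrlm", "glszm", "ngtdm", "gldm")
        for name in FAMILY_FEATURES[family]
    ]


assert len(FIRST_ORDER) == 18
assert len(SHAPE) == 14
assert texture_feature_count() == 73
assert features_per_modality() == 105
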