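"""Phantom PET/CT lesion simulator with cluster-dependent structure.

Generates ellipsoidal lesions with a smooth radial uptake profile on a
native PET grid, a paired low-dose-CT-like volume on a finer grid, an
analytic truth mask, and dichotomous biochemistry flags. Cluster-1 lesions
are configured hotter, larger and texturally more heterogeneous than
cluster-2 lesions; "sporadic" lesions are drawn from a mixture of
cluster-2-like (majority) and cluster-1-like (minority) parameter sets.

Seeding is counter-based: lesion ``i`` of a cohort uses
``SeedSequence([master_seed, i])`` so extending a cohort never reshuffles
earlier lesions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from petrad.imaging_io import ImageVolume, VoiMask

__all__ = [
    "ClusterParams",
    "ClusterSimParams",
    "SyntheticLesion",
    "DEFAULT_PARAMS",
    "default_params",
    "simulate_lesion",
    "simulate_biochemistry",
    "simulate_cohort",
    "draw_lesion_traits",
    "scale_effect",
]

CLUSTERS = ("cluster1", "cluster2", "sporadic")

# Decay constant such that the uptake profile crosses 41% of the
# peak-to-background contrast exactly at the ellipsoid boundary (rho = 1).
_PROFILE_K = math.log(1.0 / 0.41)
# Radius (in units of rho) beyond which the profile is truncated to background;
# with the default exponent 6 the remaining contrast there is < 2%.
_PROFILE_TRUNC = 1.45


@dataclass(frozen=True)
class ClusterParams:
    """Generative distribution for one lesion phenotype.

    amp_median/amp_log_sd: log-normal peak SUV (g/mL, absolute).
    radius_mean/radius_sd: normal mean ellipsoid radius (mm), clipped.
    heterogeneity_mean/sd: weight in [0, 1] of the multiplicative
        correlated-noise texture field.
    necrosis_prob: probability of a central photopenic core.
    hu_mean/hu_sd: lesion CT attenuation (HU).
    p_adrenergic / p_noradrenergic / p_dopaminergic: Bernoulli rates.
    """

    amp_median: float
    amp_log_sd: float
    radius_mean: float
    radius_sd: float
    heterogeneity_mean: float
    heterogeneity_sd: float
    necrosis_prob: float
    hu_mean: float
    hu_sd: float
    p_adrenergic: float
    p_noradrenergic: float
    p_dopaminergic: float

    def __post_init__(self) -> None:
        for p in (self.p_adrenergic, self.p_noradrenergic, self.p_dopaminergic,
                  self.necrosis_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.radius_mean <= 0:
            raise ValueError("radius must be positive")
        if self.amp_median <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class ClusterSimParams:
    """Full simulator configuration (grids, background, per-cluster laws)."""

    cluster1: ClusterParams
    cluster2: ClusterParams
    sporadic_c1like: ClusterParams
    sporadic_c2like: ClusterParams
    sporadic_mix_c2: float = 0.75  # weight toward the cluster-2-like component
    background_suv: float = 1.0
    pet_noise_sd: float = 0.12
    ct_background_hu: float = 35.0
    ct_noise_sd: float = 6.0
    pet_spacing: tuple[float, float, float] = (3.18, 3.18, 3.0)
    pet_shape: tuple[int, int, int] = (64, 64, 64)
    ct_spacing: tuple[float, float, float] = (0.98, 0.98, 3.0)
    ct_extent_mm: float = 112.0
    radius_bounds: tuple[float, float] = (8.0, 34.0)
    amp_cap: float = 26.0  # keeps pooled SUV_max within the emulated range
    profile_exponent: float = 6.0  # super-Gaussian falloff; 41% crossing stays at rho=1
    texture_corr_vox: float = 1.2
    distractor: bool = False  # adjacent hot blob (kidney surrogate), for boxing tests
    distractor_offset_mm: float = 70.0
    distractor_amp: float = 12.0

    def params_for(self, cluster: str) -> ClusterParams:
        if cluster == "cluster1":
            return self.cluster1
        if cluster == "cluster2":
            return self.cluster2
        raise ValueError(f"unknown cluster {cluster!r}")


def default_params() -> ClusterSimParams:
    """Defaults emulating the cohort's pooled SUV/volume ranges.

    Pooled SUV_max over a 40-lesion cohort spans roughly 1.7-36 g/mL and
    metabolic volumes roughly 2-250 cm^3, with cluster 1 hotter, larger
    and more heterogeneous than cluster 2. Per-cluster biochemistry rates
    are chosen so the (13, 18, 9)-weighted marginals are about
    17/40 adrenergic, 24/40 noradrenergic and 6/40 dopaminergic.
    """
    cluster1 = ClusterParams(
        amp_median=14.0, amp_log_sd=0.45,
        radius_mean=22.0, radius_sd=5.0,
        heterogeneity_mean=0.55, heterogeneity_sd=0.12,
        necrosis_prob=0.40,
        hu_mean=38.0, hu_sd=9.0,
        p_adrenergic=0.05, p_noradrenergic=0.92, p_dopaminergic=0.28,
    )
    cluster2 = ClusterParams(
        amp_median=3.6, amp_log_sd=0.30,
        radius_mean=13.0, radius_sd=3.0,
        heterogeneity_mean=0.15, heterogeneity_sd=0.06,
        necrosis_prob=0.08,
        hu_mean=45.0, hu_sd=6.0,
        p_adrenergic=0.61, p_noradrenergic=0.40, p_dopaminergic=0.06,
    )
    # sporadic: mostly cluster-2-like with a mild shift, occasionally
    # cluster-1-like; biochemistry rates close to cluster 2 (the profile
    # separates cluster 1 from 2 well but sporadic poorly)
    sporadic_c2like = replace(
        cluster2,
        amp_median=5.4, radius_mean=15.0, heterogeneity_mean=0.28,
        p_adrenergic=0.60, p_noradrenergic=0.54, p_dopaminergic=0.13,
    )
    sporadic_c1like = replace(
        cluster1,
        amp_median=11.0, radius_mean=19.0, heterogeneity_mean=0.45,
        p_adrenergic=0.60, p_noradrenergic=0.54, p_dopaminergic=0.13,
    )
    return ClusterSimParams(
        cluster1=cluster1,
        cluster2=cluster2,
        sporadic_c1like=sporadic_c1like,
        sporadic_c2like=sporadic_c2like,
    )


DEFAULT_PARAMS = default_params()


def scale_effect(params: ClusterSimParams, effect: float) -> ClusterSimParams:
    """Interpolate cluster-1 (and sporadic-c1-like) laws toward cluster 2.

    ``effect=1`` returns `params` unchanged; ``effect=0`` collapses the
    planted cluster-1 separation onto the cluster-2 law. Amplitudes are
    interpolated geometrically, sizes and heterogeneity linearly.
    """
    if not 0.0 <= effect <= 1.0:
        raise ValueError("effect must be in [0, 1]")

    def _blend(hi: ClusterParams, lo: ClusterParams) -> ClusterParams:
        return replace(
            hi,
            amp_median=lo.amp_median * (hi.amp_median / lo.amp_median) ** effect,
            radius_mean=lo.radius_mean + effect * (hi.radius_mean - lo.radius_mean),
            heterogeneity_mean=lo.heterogeneity_mean
            + effect * (hi.heterogeneity_mean - lo.heterogeneity_mean),
            necrosis_prob=lo.necrosis_prob + effect * (hi.necrosis_prob - lo.necrosis_prob),
        )

    return replace(
        params,
        cluster1=_blend(params.cluster1, params.cluster2),
        sporadic_c1like=_blend(params.sporadic_c1like, params.sporadic_c2like),
    )


@dataclass
class SyntheticLesion:
    pet: ImageVolume
    ct: ImageVolume
    truth_mask: VoiMask          # on the PET grid
    ct_truth_mask: VoiMask       # on the CT grid
    cluster: str
    biochemistry: tuple[bool, bool, bool]  # (adrenergic, noradrenergic, dopaminergic)
    true_diameter_mm: float
    true_suvmax: float
    lesion_id: str = ""


def _component_params(cluster: str, params: ClusterSimParams, rng: np.random.Generator) -> ClusterParams:
    """Resolve the generative law, drawing the sporadic mixture component."""
    if cluster == "sporadic":
        if rng.random() < params.sporadic_mix_c2:
            return params.sporadic_c2like
        return params.sporadic_c1like
    return params.params_for(cluster)


def draw_lesion_traits(
    cluster: str, params: ClusterSimParams, rng: np.random.Generator
) -> tuple[float, np.ndarray, float, bool]:
    """Draw (amplitude, ellipsoid radii mm, heterogeneity weight, necrotic).

    Amplitude must exceed the background; redraws internally and raises
    after 100 failures.
    """
    cp = _component_params(cluster, params, rng)
    amp = None
    for _ in range(100):
        cand = cp.amp_median * math.exp(cp.amp_log_sd * rng.standard_normal())
        cand = min(cand, params.amp_cap)
        if cand > params.background_suv:
            amp = cand
            break
    if amp is None:
        raise RuntimeError("could not draw amplitude above background in 100 attempts")
    base_r = float(np.clip(rng.normal(cp.radius_mean, cp.radius_sd), *params.radius_bounds))
    radii = base_r * np.exp(rng.normal(0.0, 0.15, size=3))
    radii = np.clip(radii, params.radius_bounds[0] * 0.7, params.radius_bounds[1] * 1.2)
    het = float(np.clip(rng.normal(cp.heterogeneity_mean, cp.heterogeneity_sd), 0.0, 1.0))
    necrotic = bool(rng.random() < cp.necrosis_prob)
    return amp, radii, het, necrotic


def _ellipsoid_rho(vol_shape, spacing, centre_mm, radii_mm) -> np.ndarray:
    """Normalised ellipsoidal radius of every voxel centre."""
    ax = [(np.arange(n) * s - c) / r for n, s, c, r in zip(vol_shape, spacing, centre_mm, radii_mm)]
    x2 = (ax[0] ** 2)[:, None, None]
    y2 = (ax[1] ** 2)[None, :, None]
    z2 = (ax[2] ** 2)[None, None, :]
    return np.sqrt(x2 + y2 + z2)


def _texture_field(shape, rng: np.random.Generator, corr_vox: float) -> np.ndarray:
    """Smoothed, unit-variance correlated noise field."""
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=corr_vox)
    sd = g.std()
    return g / sd if sd > 0 else g


def simulate_lesion(cluster: str, params: ClusterSimParams, seed: int) -> SyntheticLesion:
    """Render one synthetic lesion; deterministic given (cluster, params, seed)."""
    if cluster not in CLUSTERS:
        raise ValueError(f"cluster must be one of {CLUSTERS}, got {cluster!r}")
    rng = np.random.default_rng(np.random.SeedSequence([0x1E51, seed]))
    amp, radii, het, necrotic = draw_lesion_traits(cluster, params, rng)
    cp = _component_params_for_ct(cluster, params, rng)

    bg = params.background_suv
    pet_shape = params.pet_shape
    pet_spacing = params.pet_spacing
    centre = [0.5 * (n - 1) * s for n, s in zip(pet_shape, pet_spacing)]
    # jitter the centre sub-voxel so isocontours are not grid-aligned
    centre = [c + rng.uniform(-0.5, 0.5) * s for c, s in zip(centre, pet_spacing)]

    rho = _ellipsoid_rho(pet_shape, pet_spacing, centre, radii)
    profile = np.exp(-_PROFILE_K * rho**params.profile_exponent)
    profile[rho > _PROFILE_TRUNC] = 0.0
    uptake = bg + (amp - bg) * profile

    inside = rho <= 1.0
    if het > 0:
        field = _texture_field(pet_shape, rng, params.texture_corr_vox)
        mod = 1.0 + het * 0.45 * field
        uptake = bg + (uptake - bg) * np.clip(mod, 0.1, 1.5)
    if necrotic:
        core = 1.0 - 0.7 * np.exp(-((rho / 0.35) ** 2))
        uptake = bg + (uptake - bg) * core
    if params.pet_noise_sd > 0:
        uptake = uptake + rng.normal(0.0, params.pet_noise_sd, size=pet_shape)
    if params.distractor:
        off = params.distractor_offset_mm
        d_centre = [centre[0] + off, centre[1], centre[2]]
        d_rho = _ellipsoid_rho(pet_shape, pet_spacing, d_centre, [18.0, 18.0, 18.0])
        uptake = uptake + params.distractor_amp * np.exp(
            -_PROFILE_K * d_rho**params.profile_exponent
        ) * (d_rho <= _PROFILE_TRUNC)
    uptake = np.clip(uptake, 0.0, None)

    pet = ImageVolume(uptake, pet_spacing)
    truth = VoiMask(inside, pet_spacing)
    truth.validate()

    # --- paired CT on its own (finer) grid, aligned in world space ---
    ct_spacing = params.ct_spacing
    ct_shape = tuple(max(int(round(params.ct_extent_mm / s)), 8) for s in ct_spacing)
    pet_centre_world = centre
    ct_origin = tuple(
        pc - 0.5 * (n - 1) * s for pc, n, s in zip(pet_centre_world, ct_shape, ct_spacing)
    )
    ct_centre_local = [pc - o for pc, o in zip(pet_centre_world, ct_origin)]
    ct_rho = _ellipsoid_rho(ct_shape, ct_spacing, ct_centre_local, radii)
    ct_inside = ct_rho <= 1.0
    hu = np.full(ct_shape, params.ct_background_hu)
    hu[ct_inside] = cp.hu_mean
    if het > 0:
        ct_field = _texture_field(ct_shape, rng, params.texture_corr_vox * 1.5)
        hu = hu + cp.hu_sd * het * 1.5 * ct_field * ct_inside
    if params.ct_noise_sd > 0:
        hu = hu + rng.normal(0.0, params.ct_noise_sd, size=ct_shape)
    ct = ImageVolume(hu, ct_spacing, ct_origin)
    ct_truth = VoiMask(ct_inside, ct_spacing, ct_origin)
    ct_truth.validate()

    biochem = simulate_biochemistry(cluster, params, rng=rng, component=cp)

    true_suvmax = float(uptake[inside].max())
    true_diameter = float(2.0 * radii.max())
    return SyntheticLesion(
        pet=pet,
        ct=ct,
        truth_mask=truth,
        ct_truth_mask=ct_truth,
        cluster=cluster,
        biochemistry=biochem,
        true_diameter_mm=true_diameter,
        true_suvmax=true_suvmax,
    )


def _component_params_for_ct(cluster, params, rng) -> ClusterParams:
    # CT appearance and biochemistry follow the non-mixture law for the
    # named clusters; sporadic CT/biochemistry rates are shared by both
    # mixture components, so either component is representative.
    if cluster == "sporadic":
        return params.sporadic_c2like
    return params.params_for(cluster)


def simulate_biochemistry(
    cluster: str,
    params: ClusterSimParams,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    component: ClusterParams | None = None,
) -> tuple[bool, bool, bool]:
    """Three independent Bernoulli draws (adrenergic, noradrenergic, dopaminergic).

    Combinations of positive profiles are allowed; rates are per-cluster.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([0xB10C, int(seed or 0)]))
    if component is None:
        component = _component_params_for_ct(cluster, params, rng)
    u = rng.random(3)
    return (
        bool(u[0] < component.p_adrenergic),
        bool(u[1] < component.p_noradrenergic),
        bool(u[2] < component.p_dopaminergic),
    )


def simulate_cohort(
    n1: int = 13,
    n2: int = 18,
    ns: int = 9,
    params: ClusterSimParams | None = None,
    seed: int = 0,
) -> list[SyntheticLesion]:
    """Simulate a cohort of n1 cluster-1, n2 cluster-2 and ns sporadic lesions.

    Per-lesion seeds derive from ``SeedSequence([seed, counter])`` so the
    cohort is extensible without reshuffling existing lesions.
    """
    if min(n1, n2, ns) < 0:
        raise ValueError("cohort sizes must be non-negative")
    if n1 + n2 + ns == 0:
        raise ValueError("cohort must contain at least one lesion")
    params = params or default_params()
    lesions: list[SyntheticLesion] = []
    counter = 0
    for cluster, n in (("cluster1", n1), ("cluster2", n2), ("sporadic", ns)):
        for _ in range(n):
            sub = int(np.random.SeedSequence([int(seed), counter]).generate_state(1)[0])
            lesion = simulate_lesion(cluster, params, sub)
            lesion.lesion_id = f"L{counter:03d}"
            lesions.append(lesion)
            counter += 1
    return lesions
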