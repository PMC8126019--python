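"""Synthetic multiparametric phantom cohorts with four nested tumor subregions.

Each phantom subject is a set of co-registered volumes (T1CE, T2W, FLAIR,
ADC) in which four nested ellipsoidal compartments play the roles of
necrosis, solid part, peritumoral tissue and peritumoral edema.  Every
(region, modality) pair has its own intensity profile: a mean level, a noise
standard deviation, a texture correlation length (realized by Gaussian
smoothing of white noise) and a histogram skew parameter.  A scalar
``separation`` in [0, 1] scales all inter-region profile differences: at 1
the regions carry their full declared contrast, at 0 every region shares the
same voxel-value distribution, so intensity and texture features carry no
class signal.

The geometry of the four shells is jittered per subject (bounded random
perturbation of semi-axes and center) so that shape features vary across the
cohort.  The compartments remain strictly nested by construction; their
shapes therefore always differ between regions, independent of
``separation`` — see the methods note for what that implies for null
experiments.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import skewnorm

from ._types import MODALITIES, REGION_CODES, REGION_NAMES, MultiparametricSample

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegionProfile:
    """Per-(region, modality) appearance model, in arbitrary intensity units."""

    mean: float
    noise_sd: float
    corr_length: float   # Gaussian-smoothing sigma, voxels
    skew: float          # skew-normal shape parameter of the white noise


def _default_profiles() -> dict[str, dict[str, RegionProfile]]:
    """Default appearance table, region -> modality -> profile.

    Mean levels follow the qualitative contrast logic of glioblastoma MRI:
    the enhancing solid part is bright on T1CE while necrosis is dark; the
    fluid-rich necrotic core is bright on ADC (inverted with respect to
    T1CE) and edema is bright on FLAIR.  Texture correlation length grows
    from the fine-grained core outward so that GLCM/GLRLM/LBP features see
    real structure, and the skew parameter varies so histogram-shape
    features differ between regions.
    """
    means = {
        #            T1CE   T2W   FLAIR  ADC
        "necrosis":   (60.0, 150.0,  70.0, 170.0),
        "solid":     (160.0,  95.0, 115.0,  80.0),
        "peritumoral": (110.0, 115.0, 135.0, 105.0),
        "edema":      (85.0, 135.0, 160.0, 140.0),
    }
    noise_sd = {"necrosis": 8.0, "solid": 12.0, "peritumoral": 10.0, "edema": 9.0}
    corr_len = {"necrosis": 0.6, "solid": 1.0, "peritumoral": 1.4, "edema": 1.8}
    skew = {"necrosis": 0.0, "solid": 3.0, "peritumoral": -3.0, "edema": 5.0}
    table: dict[str, dict[str, RegionProfile]] = {}
    for region in REGION_NAMES:
        table[region] = {
            mod: RegionProfile(
                mean=means[region][i],
                noise_sd=noise_sd[region],
                corr_length=corr_len[region],
                skew=skew[region],
            )
            for i, mod in enumerate(MODALITIES)
        }
    return table


#: Default nested shell semi-axes (voxels), innermost first.  Gaps are wide
#: enough that the ±10% per-subject jitter can never break strict nesting.
_DEFAULT_SEMI_AXES: tuple[tuple[float, float, float], ...] = (
    (6.0, 5.0, 3.5),
    (10.0, 8.5, 5.5),
    (14.0, 12.0, 8.0),
    (19.0, 16.0, 11.0),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic cohort.

    ``separation`` linearly interpolates every profile parameter between the
    across-region mean (0) and the declared per-region value (1).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 32)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center: tuple[float, float, float] | None = None
    semi_axes: tuple[tuple[float, float, float], ...] = _DEFAULT_SEMI_AXES
    region_profiles: dict[str, dict[str, RegionProfile]] = field(
        default_factory=_default_profiles
    )
    separation: float = 1.0
    n_subjects: int = 23
    seed: int = 0
    jitter_axes_frac: float = 0.10
    jitter_center_vox: float = 2.0
    modalities: tuple[str, ...] = MODALITIES

    def __post_init__(self) -> None:
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError(f"separation must lie in [0, 1], got {self.separation}")
        if len(self.semi_axes) != 4:
            raise ValueError("exactly four nested shells are required")
        for axes in self.semi_axes:
            if any(a <= 0 for a in axes):
                raise ValueError(f"semi-axes must be positive, got {axes}")
        for inner, outer in zip(self.semi_axes, self.semi_axes[1:]):
            # strict nesting must survive the worst-case ±jitter draw
            worst = self.jitter_axes_frac
            for a_in, a_out in zip(inner, outer):
                if a_in * (1 + worst) >= a_out * (1 - worst):
                    raise ValueError(
                        f"shells {inner} and {outer} can overlap under "
                        f"±{worst:.0%} jitter; widen the gap"
                    )
        missing = [r for r in REGION_NAMES if r not in self.region_profiles]
        if missing:
            raise ValueError(f"region_profiles missing {missing}")
        for region in REGION_NAMES:
            for mod in self.modalities:
                if mod not in self.region_profiles[region]:
                    raise ValueError(f"no profile for ({region}, {mod})")

    @property
    def effective_center(self) -> tuple[float, float, float]:
        if self.center is not None:
            return self.center
        return tuple(s / 2.0 for s in self.grid_shape)


def _effective_profiles(spec: PhantomSpec) -> dict[str, dict[str, RegionProfile]]:
    """Interpolate each profile parameter toward its across-region mean.

    effective = base + separation * (declared - base), where base is the
    mean of the parameter over the four regions (per modality).  At
    separation 0 all regions share one profile, hence one distribution.
    """
    s = spec.separation
    out: dict[str, dict[str, RegionProfile]] = {r: {} for r in REGION_NAMES}
    for mod in spec.modalities:
        declared = {r: spec.region_profiles[r][mod] for r in REGION_NAMES}
        base = {
            f: float(np.mean([getattr(declared[r], f) for r in REGION_NAMES]))
            for f in ("mean", "noise_sd", "corr_length", "skew")
        }
        for r in REGION_NAMES:
            p = declared[r]
            out[r][mod] = RegionProfile(
                mean=base["mean"] + s * (p.mean - base["mean"]),
                noise_sd=base["noise_sd"] + s * (p.noise_sd - base["noise_sd"]),
                corr_length=base["corr_length"] + s * (p.corr_length - base["corr_length"]),
                skew=base["skew"] + s * (p.skew - base["skew"]),
            )
    return out


def _jittered_geometry(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw this subject's shell semi-axes (4x3) and shared center (3,)."""
    axes = np.asarray(spec.semi_axes, dtype=float)
    factors = rng.uniform(1 - spec.jitter_axes_frac, 1 + spec.jitter_axes_frac, size=axes.shape)
    center = np.asarray(spec.effective_center, dtype=float) + rng.uniform(
        -spec.jitter_center_vox, spec.jitter_center_vox, size=3
    )
    return axes * factors, center


def _rasterize_labels(
    grid_shape: tuple[int, int, int], axes: np.ndarray, center: np.ndarray
) -> np.ndarray:
    """Label volume: innermost shell wins; label k = inside shell k only."""
    coords = np.indices(grid_shape, dtype=float)
    labels = np.zeros(grid_shape, dtype=np.uint8)
    for k in range(4, 0, -1):  # outermost first so inner shells overwrite
        a = axes[k - 1]
        d2 = sum(((coords[i] - center[i]) / a[i]) ** 2 for i in range(3))
        labels[d2 <= 1.0] = k
    return labels


def _correlated_field(
    shape: tuple[int, int, int], profile: RegionProfile, rng: np.random.Generator
) -> np.ndarray:
    """Skewed white noise, Gaussian-smoothed, re-standardized to unit sd."""
    white = skewnorm.rvs(a=profile.skew, size=shape, random_state=rng)
    if profile.corr_length > 0:
        field_ = gaussian_filter(white, sigma=profile.corr_length)
    else:
        field_ = white
    sd = field_.std()
    if sd > 0:
        field_ = (field_ - field_.mean()) / sd
    return profile.mean + profile.noise_sd * field_


def generate_phantom(spec: PhantomSpec, subject_index: int) -> MultiparametricSample:
    """Generate one subject, deterministically from (spec.seed, subject_index)."""
    if not 0 <= subject_index < spec.n_subjects:
        raise ValueError(
            f"subject_index {subject_index} outside cohort of {spec.n_subjects}"
        )
    rng = np.random.default_rng([spec.seed, subject_index])
    axes, center = _jittered_geometry(spec, rng)
    labels = _rasterize_labels(spec.grid_shape, axes, center)
    for code, region in REGION_CODES.items():
        if not np.any(labels == code):
            raise RuntimeError(
                f"subject {subject_index}: region {region!r} rasterized to zero "
                "voxels; geometry is degenerate for this grid"
            )

    profiles = _effective_profiles(spec)
    volumes: dict[str, np.ndarray] = {}
    for mod in spec.modalities:
        vol = np.zeros(spec.grid_shape, dtype=np.float64)
        for code, region in REGION_CODES.items():
            mask = labels == code
            field_ = _correlated_field(spec.grid_shape, profiles[region][mod], rng)
            vol[mask] = field_[mask]
        volumes[mod] = vol

    return MultiparametricSample(
        subject_id=f"sub-{subject_index:03d}",
        modalities=volumes,
        label_mask=labels,
        voxel_spacing=spec.voxel_spacing,
    )


def generate_cohort(spec: PhantomSpec) -> list[MultiparametricSample]:
    """Generate the whole cohort; requires at least two subjects (LOOCV)."""
    if spec.n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects for leave-one-out CV")
    logger.info(
        "generating %d phantom subjects (separation=%.2f, seed=%d)",
        spec.n_subjects, spec.separation, spec.seed,
    )
    return [generate_phantom(spec, i) for i in range(spec.n_subjects)]
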