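"""Synthetic inputs: head phantoms, atlas sets and simulated cohorts.

The imaging pipeline is exercised on T1-like head phantoms: an
ellipsoidal head with a handful of internal structures and two small
bilateral mammillary-body (MB) ellipsoids just off the midline, with
ground-truth labels (1 = left MB, 2 = right MB in RAS world
coordinates, left = the negative-R side of the midline plane).
Inter-subject variation is emulated by random affine jitter plus a
smooth, fold-free random deformation. Cohort tables are drawn from the
published normative models so that fitting them back recovers the
printed coefficients.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .volgrid_io import LabelMap, VolGridError, VolumeImage

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "DeformationSpec",
    "AffineJitter",
    "CohortSpec",
    "AtlasSample",
    "build_phantom",
    "analytic_labels",
    "ground_truth_labels",
    "phantom_grid_center",
    "make_random_deformation",
    "make_atlas_set",
    "simulate_cohort",
    "neonatal_cohort_spec",
    "child_cohort_spec",
    "corrected_child_cohort_spec",
    "LATERALITY_INTERCEPT",
    "LATERALITY_SLOPE",
    "NEONATAL_AGE_SLOPE",
    "NEONATAL_SEX_OFFSET",
    "GROWTH_COEFFS",
    "CORRECTED_GROWTH_COEFFS",
]

# Published normative constants (generating-model defaults).
LATERALITY_INTERCEPT = -0.31542  # left = intercept + slope * right  [mm^3]
LATERALITY_SLOPE = 1.00702
NEONATAL_AGE_SLOPE = 0.51  # mm^3 per week of age at scan
NEONATAL_SEX_OFFSET = 0.75  # mm^3, males minus females
GROWTH_COEFFS = (68.61, 6.53, -0.19)  # total mm^3 vs age in years
CORRECTED_GROWTH_COEFFS = (0.059, 2.52e-3, -7.349e-5)  # (mm^3/cm^3) vs years


# --------------------------------------------------------------------------
# Phantoms


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic T1-like head phantom.

    The default grid is 64^3 voxels at 1.0 mm native spacing; the
    pipeline resamples to 0.5 mm. MB semiaxes default to
    (2.5, 1.5, 1.5) mm, giving a true per-MB volume of ~23.6 mm^3,
    in the range the normative models imply for small subcortical
    structures.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 1.0
    head_semiaxes_mm: tuple[float, float, float] = (24.0, 28.0, 22.0)
    mb_center_offset_mm: float = 3.0
    mb_semiaxes_mm: tuple[float, float, float] = (2.5, 1.5, 1.5)
    tissue_intensities: dict = field(
        default_factory=lambda: {
            "background": 0.0,
            "head": 100.0,
            "ventricle": 55.0,
            "brainstem": 140.0,
            "mb": 200.0,
        }
    )
    noise_sd: float = 2.0
    bias_amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.spacing_mm <= 0:
            raise VolGridError("spacing_mm must be positive")
        if np.any(np.asarray(self.head_semiaxes_mm) <= 0):
            raise VolGridError("head semiaxes must be positive")
        if np.any(np.asarray(self.mb_semiaxes_mm) <= 0):
            raise VolGridError("MB semiaxes must be positive")
        if self.mb_center_offset_mm <= 0:
            raise VolGridError("mb_center_offset_mm must be positive")
        # MB bounding box (center offset from head center, see _mb_centers)
        # must sit strictly inside the head ellipsoid.
        h = np.asarray(self.head_semiaxes_mm, dtype=float)
        s = np.asarray(self.mb_semiaxes_mm, dtype=float)
        for c in _mb_center_offsets(self):
            corner = np.abs(c) + s
            if np.sum((corner / h) ** 2) >= 1.0:
                raise VolGridError("MB structure extends outside the head ellipsoid")


def _mb_center_offsets(spec: PhantomSpec) -> list[np.ndarray]:
    """MB centers relative to head center: left (−x) then right (+x).

    MBs sit slightly anterior/inferior of center, off voxel centers so
    discretization is not grid-aligned.
    """
    off = float(spec.mb_center_offset_mm)
    return [
        np.array([-off, -4.3, -6.2]),
        np.array([+off, -4.3, -6.2]),
    ]


def _ellipsoid_mask(coords, center, semiaxes) -> np.ndarray:
    q = sum(((coords[i] - center[i]) / semiaxes[i]) ** 2 for i in range(3))
    return q <= 1.0


def phantom_grid_center(spec: PhantomSpec) -> np.ndarray:
    """World position of the phantom grid's center (head center)."""
    return np.array([(n - 1) * spec.spacing_mm / 2.0 for n in spec.grid_shape])


def analytic_labels(spec: PhantomSpec, geometry, mapping=None) -> LabelMap:
    """Rasterize the MB ground truth on an arbitrary grid.

    Voxel-center world points of ``geometry`` (optionally pushed
    through ``mapping``, e.g. a generating warp's fixed->base
    correspondence) are tested against the analytic MB ellipsoids, so
    warped/resampled ground truth carries no nearest-neighbor
    quantization from an intermediate grid.
    """
    shape = geometry.shape
    idx = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    pts = np.stack(idx, axis=-1) * np.asarray(geometry.spacing_mm, float)
    pts = pts @ np.asarray(geometry.orientation, float).T + np.asarray(
        geometry.origin_mm, float
    )
    if mapping is not None:
        pts = mapping.apply(pts.reshape(-1, 3)).reshape(pts.shape)
    center = phantom_grid_center(spec)
    rel = [pts[..., i] - center[i] for i in range(3)]
    labels = np.zeros(shape, dtype=np.int16)
    for lab, c in zip((1, 2), _mb_center_offsets(spec)):
        labels[_ellipsoid_mask(rel, c, spec.mb_semiaxes_mm)] = lab
    return LabelMap(labels, geometry.spacing_mm, geometry.origin_mm, geometry.orientation)


def build_phantom(spec: PhantomSpec) -> tuple[VolumeImage, LabelMap]:
    """Rasterize the phantom; returns intensity image and ground-truth labels.

    With ``noise_sd = 0`` and ``bias_amplitude = 0`` the image is
    piecewise constant over tissue classes. Deterministic given the
    spec's seed; labels have exactly one 6-connected component per MB.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    sp = float(spec.spacing_mm)
    # world coordinates of voxel centers, head centered on the grid
    axes = [np.arange(n, dtype=float) * sp for n in shape]
    center = np.array([(n - 1) * sp / 2.0 for n in shape])
    coords = np.meshgrid(*axes, indexing="ij")
    rel = [coords[i] - center[i] for i in range(3)]

    t = spec.tissue_intensities
    img = np.full(shape, float(t.get("background", 0.0)))
    head = _ellipsoid_mask(rel, np.zeros(3), spec.head_semiaxes_mm)
    img[head] = float(t.get("head", 100.0))

    h = np.asarray(spec.head_semiaxes_mm, dtype=float)
    if "ventricle" in t:
        # paired superior para-midline cavities; add internal contrast
        for sx in (-1.0, 1.0):
            c = np.array([sx * 0.22 * h[0], 0.1 * h[1], 0.35 * h[2]])
            m = _ellipsoid_mask(rel, c, 0.16 * h)
            img[m & head] = float(t["ventricle"])
    if "brainstem" in t:
        c = np.array([0.0, -0.12 * h[1], -0.52 * h[2]])
        m = _ellipsoid_mask(rel, c, (0.18 * h[0], 0.22 * h[1], 0.34 * h[2]))
        img[m & head] = float(t["brainstem"])

    labels = np.zeros(shape, dtype=np.int16)
    mb_int = float(t.get("mb", 200.0))
    for lab, c in zip((1, 2), _mb_center_offsets(spec)):
        m = _ellipsoid_mask(rel, c, spec.mb_semiaxes_mm)
        img[m] = mb_int
        labels[m] = lab

    rng = np.random.default_rng(spec.seed)
    if spec.bias_amplitude > 0:
        raw = rng.standard_normal(shape)
        smooth = ndimage.gaussian_filter(raw, sigma=max(8.0, 16.0 / sp))
        peak = np.max(np.abs(smooth))
        if peak > 0:
            img = img * (1.0 + spec.bias_amplitude * smooth / peak)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)

    geom = dict(spacing_mm=np.full(3, sp), origin_mm=np.zeros(3), orientation=np.eye(3))
    return VolumeImage(img, **geom), LabelMap(labels, **geom)


# --------------------------------------------------------------------------
# Random deformations and atlas sets


@dataclass(frozen=True)
class DeformationSpec:
    """Smooth random displacement field: max |u| = amplitude, Gaussian
    correlation length = smoothness. Fields are rejected (and the
    amplitude reduced) until the map id+u has everywhere-positive
    Jacobian determinant."""

    amplitude_mm: float = 2.0
    smoothness_mm: float = 8.0
    seed: int = 0
    max_retries: int = 5

    def __post_init__(self):
        if self.amplitude_mm < 0:
            raise VolGridError("amplitude_mm must be >= 0")
        if self.smoothness_mm <= 0:
            raise VolGridError("smoothness_mm must be positive")


def min_jacobian_det(field) -> float:
    """Minimum over voxels of det(I + grad u) by central differences."""
    u = field.vectors
    sp = field.spacing_mm
    J = np.empty(u.shape[:3] + (3, 3))
    for comp in range(3):
        grads = np.gradient(u[..., comp], *sp, axis=(0, 1, 2))
        for ax in range(3):
            J[..., comp, ax] = grads[ax]
    J += np.eye(3)
    return float(np.min(np.linalg.det(J)))


def make_random_deformation(geometry, spec: DeformationSpec):
    """Draw a smooth random displacement field on ``geometry``'s grid.

    Returns a :class:`mamvol.registration.DisplacementField` whose
    maximum displacement magnitude equals ``amplitude_mm`` and whose
    Jacobian determinant is positive everywhere. Raises after bounded
    retries if no fold-free field is found.
    """
    from .registration import DisplacementField  # local: avoid import cycle

    shape = geometry.shape
    sp = np.asarray(geometry.spacing_mm, dtype=float)
    if spec.amplitude_mm == 0:
        return DisplacementField(
            np.zeros(shape + (3,)), sp, geometry.origin_mm, geometry.orientation
        )
    rng = np.random.default_rng(spec.seed)
    amplitude = float(spec.amplitude_mm)
    for attempt in range(spec.max_retries + 1):
        raw = rng.standard_normal(shape + (3,))
        sigma_vox = spec.smoothness_mm / sp
        u = np.stack(
            [ndimage.gaussian_filter(raw[..., i], sigma=tuple(sigma_vox)) for i in range(3)],
            axis=-1,
        )
        mag = np.sqrt(np.sum(u**2, axis=-1))
        peak = float(np.max(mag))
        if peak == 0:
            continue
        u *= amplitude / peak
        fld = DisplacementField(u, sp, geometry.origin_mm, geometry.orientation)
        if min_jacobian_det(fld) > 0:
            return fld
        amplitude *= 0.7
        logger.warning(
            "deformation folded; retry %d with amplitude %.2f mm", attempt + 1, amplitude
        )
    raise VolGridError(
        f"could not generate fold-free deformation (amplitude {spec.amplitude_mm} mm, "
        f"smoothness {spec.smoothness_mm} mm)"
    )


@dataclass(frozen=True)
class AffineJitter:
    """Uniform random 9-parameter jitter applied to each atlas."""

    max_rot_deg: float = 3.0
    max_scale: float = 0.03
    max_trans_mm: float = 1.5

    @property
    def is_zero(self) -> bool:
        return self.max_rot_deg == 0 and self.max_scale == 0 and self.max_trans_mm == 0


@dataclass(frozen=True)
class AtlasSample:
    """One synthetic atlas with its generating (ground-truth) transforms."""

    image: VolumeImage
    labels: LabelMap
    true_affine: object  # AffineTransform
    true_field: object  # DisplacementField

    def __iter__(self):
        return iter((self.image, self.labels))


def make_atlas_set(
    base_spec: PhantomSpec,
    k: int = 5,
    deform: DeformationSpec | None = None,
    affine_jitter: AffineJitter | None = None,
    seed: int | None = None,
) -> list[AtlasSample]:
    """Generate ``k`` geometrically perturbed phantoms with consistent labels.

    Five atlases is the working default (one multi-atlas set). Each
    atlas is the base phantom (re-rendered with its own intensity noise)
    warped by a random similarity jitter composed with a smooth random
    deformation; the generating transforms are recorded on each sample
    for oracle checks. ``k=1`` with zero jitter and zero deformation
    reproduces the base phantom exactly.
    """
    from .registration import AffineTransform, compose, warp_image, warp_labels

    if k < 1:
        raise VolGridError("k must be >= 1")
    deform = deform if deform is not None else DeformationSpec()
    jit = affine_jitter if affine_jitter is not None else AffineJitter()
    seed = base_spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    samples: list[AtlasSample] = []
    for i in range(k):
        spec_i = replace(base_spec, seed=int(rng.integers(0, 2**31 - 1)))
        img, lab = build_phantom(spec_i)
        if jit.is_zero:
            aff = AffineTransform.identity(center=img.world_center())
        else:
            rot = np.deg2rad(rng.uniform(-jit.max_rot_deg, jit.max_rot_deg, 3))
            scale = 1.0 + rng.uniform(-jit.max_scale, jit.max_scale, 3)
            trans = rng.uniform(-jit.max_trans_mm, jit.max_trans_mm, 3)
            aff = AffineTransform(
                rotation=rot, scale=scale, translation=trans, center=img.world_center()
            )
        dspec = replace(deform, seed=int(rng.integers(0, 2**31 - 1)))
        fld = make_random_deformation(img, dspec)
        if jit.is_zero and deform.amplitude_mm == 0:
            samples.append(AtlasSample(img, lab, aff, fld))
            continue
        mapping = compose(aff, fld)
        samples.append(
            AtlasSample(
                warp_image(img, mapping, mode="trilinear"),
                analytic_labels(spec_i, img, mapping=mapping),
                aff,
                fld,
            )
        )
    return samples


def ground_truth_labels(
    base_spec: PhantomSpec, sample: AtlasSample, target_mm: float | None = None
) -> LabelMap:
    """Analytic ground truth of a perturbed subject on its analysis grid.

    Evaluates the subject's generating transform at the (optionally
    resampled) grid's voxel centers, avoiding double label
    quantization when comparing against a 0.5 mm segmentation.
    """
    from .registration import compose

    geom = sample.labels
    if target_mm is not None:
        from .volgrid_io import resample_labels

        geom = resample_labels(sample.labels, target_mm)
    mapping = compose(sample.true_affine, sample.true_field)
    return analytic_labels(base_spec, geom, mapping=mapping)


# --------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Generating model of a simulated volumetry cohort.

    ``mode`` selects the age axis: ``"neonatal"`` uses postmenstrual age
    at scan in weeks and adds gestational age at birth plus a
    prematurity flag; ``"child"`` uses years and adds intracranial
    volume. ``gen_coeffs`` are (intercept, age, age^2, sex_male) of the
    generating mean; with ``response="corrected"`` the mean model is in
    MB/ICV units (mm^3 per cm^3) and total volume is corrected x ICV.
    ``residual_sd`` is a free parameter of the generator (per-subject
    volume variance is not part of the published models).
    """

    n: int
    age_range: tuple[float, float]
    sex_ratio: float
    gen_coeffs: tuple[float, float, float, float]
    residual_sd: float
    mode: str = "child"
    response: str = "total"
    icv_model: tuple[float, float] | None = None
    prematurity_fraction: float | None = None
    laterality: tuple[float, float] = (LATERALITY_INTERCEPT, LATERALITY_SLOPE)
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise VolGridError("cohort size n must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise VolGridError("sex_ratio must be in [0, 1]")
        if self.residual_sd < 0:
            raise VolGridError("residual_sd must be >= 0")
        if self.mode not in ("neonatal", "child"):
            raise VolGridError(f"unknown cohort mode {self.mode!r}")
        if self.response not in ("total", "corrected"):
            raise VolGridError(f"unknown response {self.response!r}")
        if self.response == "corrected" and self.icv_model is None:
            raise VolGridError("corrected response requires icv_model")
        if self.age_range[1] < self.age_range[0]:
            raise VolGridError("age_range must be (min, max)")


def neonatal_cohort_spec(
    n: int = 256,
    residual_sd: float = 2.0,
    seed: int = 0,
    intercept: float = 4.0,
) -> CohortSpec:
    """Neonatal reference cohort: 256 subjects (156 male / 100 female),
    postmenstrual age at scan 29.3–45.1 weeks, total MB volume growing
    0.51 mm^3/week with a +0.75 mm^3 male offset. The intercept is not
    published; the default places term-age total volume near 25 mm^3."""
    return CohortSpec(
        n=n,
        age_range=(29.3, 45.1),
        sex_ratio=156 / 256,
        gen_coeffs=(intercept, NEONATAL_AGE_SLOPE, 0.0, NEONATAL_SEX_OFFSET),
        residual_sd=residual_sd,
        mode="neonatal",
        prematurity_fraction=0.5,
        seed=seed,
    )


def child_cohort_spec(n: int = 250, residual_sd: float = 12.0, seed: int = 0) -> CohortSpec:
    """Pediatric/young-adult reference cohort: 250 subjects (166 male / 84 female),
    total volume following 68.61 + 6.53 Age − 0.19 Age^2 (years)."""
    return CohortSpec(
        n=n,
        age_range=(6.0, 24.0),
        sex_ratio=166 / 250,
        gen_coeffs=(*GROWTH_COEFFS, 0.0),
        residual_sd=residual_sd,
        mode="child",
        icv_model=(1500.0, 120.0),
        seed=seed,
    )


def corrected_child_cohort_spec(
    n: int = 250, residual_sd: float = 0.008, seed: int = 0
) -> CohortSpec:
    """6–24 y cohort whose ICV-corrected volume (mm^3 per cm^3 of ICV)
    follows 0.059 + 2.52e-3 Age − 7.349e-5 Age^2."""
    return CohortSpec(
        n=n,
        age_range=(6.0, 24.0),
        sex_ratio=166 / 250,
        gen_coeffs=(*CORRECTED_GROWTH_COEFFS, 0.0),
        residual_sd=residual_sd,
        mode="child",
        response="corrected",
        icv_model=(1500.0, 120.0),
        seed=seed,
    )


COHORT_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "ga_birth",
    "premature",
    "left_mb_mm3",
    "right_mb_mm3",
    "icv_cm3",
]


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table from the generating model.

    Ages are uniform on ``age_range``; sex is Bernoulli(sex_ratio)
    (male=1 event). Total volume is the mean model plus N(0,
    residual_sd) noise, resampled if negative. The left/right split
    inverts the published laterality map (left = a + b*right with
    left+right = total) and adds an antisymmetric perturbation that
    preserves the total exactly and vanishes in the noiseless case.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    age = rng.uniform(spec.age_range[0], spec.age_range[1], n)
    male = rng.random(n) < spec.sex_ratio
    c0, c1, c2, cs = spec.gen_coeffs
    mean = c0 + c1 * age + c2 * age**2 + cs * male

    value = mean + rng.normal(0.0, spec.residual_sd, n) if spec.residual_sd > 0 else mean.copy()
    bad = value <= 0
    tries = 0
    while np.any(bad) and tries < 100:
        logger.warning("resampling %d non-positive generated volumes", int(bad.sum()))
        value[bad] = mean[bad] + rng.normal(0.0, spec.residual_sd, int(bad.sum()))
        bad = value <= 0
        tries += 1
    if np.any(bad):
        raise VolGridError("generating model produces persistently negative volumes")

    icv = np.full(n, np.nan)
    if spec.icv_model is not None:
        icv_mean, icv_sd = spec.icv_model
        icv = rng.normal(icv_mean, icv_sd, n)
        icv = np.clip(icv, 0.5 * icv_mean, 1.5 * icv_mean)

    if spec.response == "corrected":
        total = value * icv
        split_sd = 0.25 * spec.residual_sd * float(np.nanmean(icv))
    else:
        total = value
        split_sd = 0.25 * spec.residual_sd

    a, b = spec.laterality
    right = (total - a) / (1.0 + b)
    left = total - right
    if split_sd > 0:
        d = rng.normal(0.0, split_sd, n)
        # keep both sides non-negative while preserving the total
        d = np.clip(d, -right + 1e-9, left - 1e-9)
        left = left + d
        right = right - d

    ga_birth = np.full(n, np.nan)
    premature = np.full(n, np.nan)
    if spec.mode == "neonatal":
        frac = spec.prematurity_fraction if spec.prematurity_fraction is not None else 0.5
        prem = rng.random(n) < frac
        prem |= age < 37.0  # scanned before term => necessarily born preterm
        lo = np.where(prem, 26.0, 37.0)
        hi = np.where(prem, np.minimum(36.9, age), np.minimum(42.3, age))
        ga_birth = rng.uniform(lo, np.maximum(hi, lo + 1e-6), n)
        premature = (ga_birth < 37.0).astype(float)
        icv = np.full(n, np.nan)

    df = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "age": age,
            "sex": np.where(male, "male", "female"),
            "ga_birth": ga_birth,
            "premature": premature,
            "left_mb_mm3": left,
            "right_mb_mm3": right,
            "icv_cm3": icv,
        },
        columns=COHORT_COLUMNS,
    )
    df.attrs["mode"] = spec.mode
    df.attrs["seed"] = spec.seed
    return df
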