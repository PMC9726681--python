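"""Spatial alignment: linear (phase-based) and variational deformable stages.

The segmentation pipeline aligns each atlas to the subject in two
stages. The *linear* stage estimates a 9-parameter transform
(3 rotations, 3 anisotropic scales, 3 translations) by matching local
quadrature-filter phase along the three image axes — a feature that is
invariant to global intensity scaling and offset — with the translation
initialized by phase correlation and the parameters refined
coarse-to-fine. The *deformable* stage minimizes the variational energy

    E(u) = sum_x (fixed(x) - moving(x + u(x)))^2  +  alpha * sum_x ||grad u||^2

by explicit gradient descent with backtracking line search over a
multiresolution pyramid, so the recorded energy is non-increasing by
construction.

Transform convention: a transform ``T`` maps *fixed*-image world points
to *moving*-image world points, so warping resamples
``moving(T(x))`` onto the fixed grid. ``estimate_*`` therefore return
the mapping used directly by :func:`warp_image` / :func:`warp_labels`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize

from .volgrid_io import (
    GeometryMismatchError,
    LabelMap,
    VolGridError,
    VolumeImage,
    same_geometry,
)

__all__ = [
    "AffineTransform",
    "MatrixTransform",
    "DisplacementField",
    "ComposedMapping",
    "RegistrationConfig",
    "RegistrationError",
    "estimate_linear",
    "estimate_deformable",
    "compose",
    "warp_image",
    "warp_labels",
    "phase_correlation_shift",
]


class RegistrationError(VolGridError):
    """Raised when a registration stage cannot produce a valid result."""


# --------------------------------------------------------------------------
# Transforms


def _rotation_matrix(angles: np.ndarray) -> np.ndarray:
    """Intrinsic rotations about world x, y, z (applied as Rz @ Ry @ Rx)."""
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass(frozen=True)
class AffineTransform:
    """9-parameter world->world similarity-type transform.

    ``T(x) = R * diag(scale) * (x - center) + center + translation``
    with ``R`` built from the three rotation angles (radians). The
    rotation center decouples rotation/scale from the translation
    estimate; the linear stage uses the fixed image's world center.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        for name in ("rotation", "scale", "translation", "center"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            object.__setattr__(self, name, v)
        if np.any(self.scale <= 0):
            raise VolGridError(f"scale factors must be positive, got {self.scale}")

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "AffineTransform":
        return cls(center=np.asarray(center, dtype=float))

    @property
    def matrix(self) -> np.ndarray:
        """Derived 4x4 homogeneous world->world map."""
        A = _rotation_matrix(self.rotation) @ np.diag(self.scale)
        M = np.eye(4)
        M[:3, :3] = A
        M[:3, 3] = self.center + self.translation - A @ self.center
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        M = self.matrix
        return pts @ M[:3, :3].T + M[:3, 3]

    def inverse(self) -> "MatrixTransform":
        return MatrixTransform(np.linalg.inv(self.matrix))


@dataclass(frozen=True)
class MatrixTransform:
    """General 4x4 homogeneous world->world affine map."""

    matrix: np.ndarray

    def __post_init__(self):
        M = np.asarray(self.matrix, dtype=float)
        if M.shape != (4, 4):
            raise VolGridError("matrix must be 4x4")
        if np.linalg.det(M[:3, :3]) <= 0:
            raise VolGridError("affine matrix must have positive determinant")
        object.__setattr__(self, "matrix", M)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "MatrixTransform":
        return MatrixTransform(np.linalg.inv(self.matrix))


@dataclass(frozen=True)
class DisplacementField:
    """Dense per-voxel displacement (mm, world offsets) on a fixed grid.

    ``energy_history`` records the total variational energy at each
    accepted outer iteration, one tuple per pyramid level (the energy is
    resolution-dependent, so monotonicity holds within a level).
    """

    vectors: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    energy_history: tuple = ()

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 4 or v.shape[-1] != 3:
            raise VolGridError(f"vectors must be (nx,ny,nz,3), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise VolGridError("displacement components must be finite")
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "spacing_mm", np.asarray(self.spacing_mm, float).reshape(3))
        object.__setattr__(self, "origin_mm", np.asarray(self.origin_mm, float).reshape(3))
        object.__setattr__(self, "orientation", np.asarray(self.orientation, float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    def grid_world_points(self) -> np.ndarray:
        """(nx,ny,nz,3) world coordinates of the grid's voxel centers."""
        idx = np.meshgrid(*[np.arange(n, dtype=float) for n in self.shape], indexing="ij")
        stacked = np.stack(idx, axis=-1) * self.spacing_mm
        return stacked @ self.orientation.T + self.origin_mm

    def sample_at(self, points: np.ndarray) -> np.ndarray:
        """Trilinearly interpolate the displacement at world points."""
        pts = np.asarray(points, dtype=float)
        rel = (pts - self.origin_mm) @ self.orientation / self.spacing_mm
        coords = rel.reshape(-1, 3).T
        out = np.stack(
            [
                ndimage.map_coordinates(
                    self.vectors[..., i], coords, order=1, mode="nearest"
                )
                for i in range(3)
            ],
            axis=-1,
        )
        return out.reshape(pts.shape)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) + self.sample_at(points)


@dataclass(frozen=True)
class ComposedMapping:
    """``x -> affine(x + u(x))``: deformable stage then linear stage.

    This is the full fixed->moving correspondence used to propagate an
    atlas: ``u`` undoes residual morphology on the fixed grid, the
    affine then carries the point into the moving (atlas) image.
    """

    affine: AffineTransform | MatrixTransform
    fld: DisplacementField

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.affine.apply(self.fld.apply(points))

    @property
    def target_geometry(self) -> DisplacementField:
        return self.fld


def compose(affine, fld: DisplacementField) -> ComposedMapping:
    """Compose the linear and deformable results into one mapping."""
    return ComposedMapping(affine, fld)


# --------------------------------------------------------------------------
# Warping


def _target_geometry(mapping, fallback):
    if isinstance(mapping, ComposedMapping):
        return mapping.fld
    if isinstance(mapping, DisplacementField):
        return mapping
    return fallback


def _world_points_of(geom) -> np.ndarray:
    idx = np.meshgrid(*[np.arange(n, dtype=float) for n in geom.shape], indexing="ij")
    stacked = np.stack(idx, axis=-1) * np.asarray(geom.spacing_mm, float)
    return stacked @ np.asarray(geom.orientation, float).T + np.asarray(geom.origin_mm, float)


def warp_image(
    image: VolumeImage, mapping, mode: str = "trilinear", target=None
) -> VolumeImage:
    """Resample ``image`` through ``mapping`` onto the target grid.

    The target grid defaults to the mapping's displacement-field grid
    (for deformable / composed mappings) or to the image's own grid for
    pure affines. The identity mapping returns the image unchanged
    (bit-exactly, up to float sampling at integer coordinates).
    """
    if mode not in ("trilinear", "nearest"):
        raise VolGridError(f"unknown interpolation mode {mode!r}")
    geom = target if target is not None else _target_geometry(mapping, image)
    pts = _world_points_of(geom)
    mapped = mapping.apply(pts.reshape(-1, 3))
    idx = image.world_to_index(mapped).T
    out = ndimage.map_coordinates(
        image.voxels,
        idx,
        order=1 if mode == "trilinear" else 0,
        mode="constant",
        cval=image.background_value(),
    ).reshape(geom.shape)
    return VolumeImage(out, geom.spacing_mm, geom.origin_mm, geom.orientation)


def warp_labels(labels: LabelMap, mapping, target=None) -> LabelMap:
    """Nearest-neighbor label propagation through ``mapping``."""
    geom = target if target is not None else _target_geometry(mapping, labels)
    pts = _world_points_of(geom)
    mapped = mapping.apply(pts.reshape(-1, 3))
    idx = labels.world_to_index(mapped).T
    out = ndimage.map_coordinates(
        labels.labels, idx, order=0, mode="constant", cval=0
    ).reshape(geom.shape)
    return LabelMap(out, geom.spacing_mm, geom.origin_mm, geom.orientation)


# --------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class RegistrationConfig:
    """Hyper-parameters of both alignment stages.

    The deformable energy is computed on intensity-normalized images
    (zero mean, unit SD over the fixed field of view), which makes
    ``alpha`` a unitless trade-off between data fidelity and field
    smoothness. ``finest_spacing_mm`` caps the finest pyramid
    resolution; ``None`` registers at the fixed image's own spacing.
    """

    pyramid_levels: int = 3
    max_iters: int = 60
    alpha: float = 0.1
    step_size: float = 0.25  # initial update, in voxels of the current level
    stop_tol: float = 1e-4
    finest_spacing_mm: float | None = None
    # linear-stage knobs
    filter_wavelength_vox: float = 8.0
    filter_sigma: float = 0.65
    max_eval_points: int = 12000

    def __post_init__(self):
        if self.pyramid_levels < 1:
            raise VolGridError("pyramid_levels must be >= 1")
        if self.alpha < 0:
            raise VolGridError("alpha must be >= 0")
        if self.stop_tol <= 0:
            raise VolGridError("stop_tol must be positive")


# --------------------------------------------------------------------------
# Pyramid helpers


def _smooth_resample(image: VolumeImage, target_mm: float) -> VolumeImage:
    """Anti-aliased isotropic downsampling (Gaussian then trilinear)."""
    from .volgrid_io import resample_isotropic

    factor = target_mm / np.asarray(image.spacing_mm, float)
    sigma = np.maximum(0.0, 0.5 * (factor - 1.0))
    vox = image.voxels
    if np.any(sigma > 0):
        vox = ndimage.gaussian_filter(vox, sigma=tuple(sigma))
    return resample_isotropic(image.with_voxels(vox), target_mm, mode="trilinear")


def _level_spacings(config: RegistrationConfig, native_mm: float) -> list[float]:
    finest = config.finest_spacing_mm
    if finest is None or finest < native_mm:
        finest = native_mm
    return [finest * 2 ** (config.pyramid_levels - 1 - i) for i in range(config.pyramid_levels)]


def _check_inputs(fixed: VolumeImage, moving: VolumeImage) -> None:
    for name, img in (("fixed", fixed), ("moving", moving)):
        if float(np.std(img.voxels)) < 1e-9:
            raise RegistrationError(f"{name} image is flat; registration is undefined")
    # world-space bounding boxes must overlap
    boxes = []
    for img in (fixed, moving):
        corners = np.array(
            [
                img.index_to_world(np.array(c) * (np.array(img.shape) - 1))
                for c in np.ndindex(2, 2, 2)
            ]
        )
        boxes.append((corners.min(axis=0), corners.max(axis=0)))
    (lo_f, hi_f), (lo_m, hi_m) = boxes
    if np.any(np.minimum(hi_f, hi_m) < np.maximum(lo_f, lo_m)):
        raise RegistrationError("fixed and moving images do not overlap in world space")


# --------------------------------------------------------------------------
# Phase features and phase correlation


def _quadrature_features(vox: np.ndarray, wavelength_vox: float, sigma: float) -> np.ndarray:
    """Per-axis analytic-signal phase features, (..., 6) real channels.

    A one-sided log-Gabor band-pass is applied along each axis in the
    Fourier domain; the resulting complex response q is normalized as
    q / (|q| + 0.05 mean|q|), which keeps the local phase while being
    invariant to global intensity scale and offset.
    """
    feats = []
    f0 = 1.0 / wavelength_vox
    logs2 = 2.0 * np.log(sigma) ** 2
    for ax in range(3):
        n = vox.shape[ax]
        f = np.fft.fftfreq(n)
        w = np.zeros(n)
        pos = f > 0
        w[pos] = np.exp(-(np.log(f[pos] / f0) ** 2) / logs2)
        w *= 2.0  # analytic signal: one-sided spectrum
        shape = [1, 1, 1]
        shape[ax] = n
        spec = np.fft.fft(vox, axis=ax) * w.reshape(shape)
        q = np.fft.ifft(spec, axis=ax)
        mag = np.abs(q)
        q = q / (mag + 0.05 * np.mean(mag) + 1e-30)
        feats.extend([q.real, q.imag])
    return np.stack(feats, axis=-1)


def phase_correlation_shift(fixed: VolumeImage, moving: VolumeImage) -> np.ndarray:
    """Translation t (mm) such that moving(x + t) ~ fixed(x).

    Whole-voxel estimate from the phase of the cross-power spectrum,
    refined to sub-voxel precision by a parabolic fit around the
    correlation peak. Both images must share shape and spacing.
    """
    if fixed.shape != moving.shape:
        raise GeometryMismatchError("phase correlation requires equal grid shapes")
    F = np.fft.fftn(fixed.voxels - np.mean(fixed.voxels))
    M = np.fft.fftn(moving.voxels - np.mean(moving.voxels))
    cross = F * np.conj(M)
    cross /= np.abs(cross) + 1e-30
    corr = np.real(np.fft.ifftn(cross))
    peak = np.array(np.unravel_index(np.argmax(corr), corr.shape), dtype=float)
    # parabolic sub-voxel refinement per axis
    for ax in range(3):
        n = corr.shape[ax]
        ip = int(peak[ax])
        sl = [int(p) for p in peak]
        sl_m, sl_p = list(sl), list(sl)
        sl_m[ax] = (ip - 1) % n
        sl_p[ax] = (ip + 1) % n
        c0, cm, cp = corr[tuple(sl)], corr[tuple(sl_m)], corr[tuple(sl_p)]
        denom = cm - 2 * c0 + cp
        if abs(denom) > 1e-12:
            peak[ax] += 0.5 * (cm - cp) / denom
    shape = np.array(corr.shape, dtype=float)
    shift_vox = peak.copy()
    wrap = shift_vox > shape / 2
    shift_vox[wrap] -= shape[wrap]
    # correlation peak at d means fixed(x) ~ moving(x - d); mapping
    # convention needs t with moving(x + t) = fixed(x), i.e. t = -d.
    delta_world = fixed.orientation @ (shift_vox * fixed.spacing_mm)
    return -delta_world + (np.asarray(moving.origin_mm) - np.asarray(fixed.origin_mm))


# --------------------------------------------------------------------------
# Linear stage


def _feature_ssd_factory(fixed_lvl, moving_lvl, center, config):
    ff = _quadrature_features(
        fixed_lvl.voxels, config.filter_wavelength_vox, config.filter_sigma
    )
    fm = _quadrature_features(
        moving_lvl.voxels, config.filter_wavelength_vox, config.filter_sigma
    )
    pts = _world_points_of(fixed_lvl).reshape(-1, 3)
    feats = ff.reshape(-1, 6)
    # evaluate on the most structured voxels to bound cost
    energy = np.sum(feats**2, axis=1)
    m = pts.shape[0]
    if m > config.max_eval_points:
        keep = np.argpartition(energy, m - config.max_eval_points)[
            m - config.max_eval_points :
        ]
        pts, feats = pts[keep], feats[keep]

    inv_ori = moving_lvl.orientation.T
    inv_sp = 1.0 / moving_lvl.spacing_mm
    m_origin = moving_lvl.origin_mm

    def residuals(params: np.ndarray) -> np.ndarray:
        T = AffineTransform(
            rotation=params[0:3],
            scale=np.exp(params[3:6]),
            translation=params[6:9],
            center=center,
        )
        mapped = T.apply(pts)
        idx = ((mapped - m_origin) @ inv_ori.T * inv_sp).T
        out = np.empty((pts.shape[0], 6))
        for ch in range(6):
            out[:, ch] = ndimage.map_coordinates(
                fm[..., ch], idx, order=1, mode="constant", cval=0.0
            )
        return (out - feats).ravel()

    return residuals


def estimate_linear(
    fixed: VolumeImage, moving: VolumeImage, config: RegistrationConfig | None = None
) -> AffineTransform:
    """Estimate the 9-parameter fixed->moving transform.

    Phase correlation initializes the translation; rotations, log-scales
    and translations are then refined jointly (Powell) on the
    quadrature-phase feature SSD, coarse-to-fine. The phase features
    make the result invariant to affine intensity changes of either
    image. Raises :class:`RegistrationError` on flat or non-overlapping
    inputs.
    """
    config = config or RegistrationConfig()
    _check_inputs(fixed, moving)
    center = fixed.world_center()
    native = float(max(np.max(fixed.spacing_mm), np.max(moving.spacing_mm)))
    spacings = _level_spacings(config, native)

    params = np.zeros(9)
    coarsest = spacings[0]
    fx0 = _smooth_resample(fixed, coarsest)
    mv0 = _smooth_resample(moving, coarsest)
    if fx0.shape == mv0.shape:
        try:
            params[6:9] = phase_correlation_shift(fx0, mv0)
        except VolGridError:
            pass

    scales = np.array([0.1, 0.1, 0.1, 0.05, 0.05, 0.05, 2.0, 2.0, 2.0])
    for s_mm in spacings:
        fx = _smooth_resample(fixed, s_mm)
        mv = _smooth_resample(moving, s_mm)
        resid = _feature_ssd_factory(fx, mv, center, config)
        res = optimize.least_squares(
            lambda z: resid(params + z * scales),
            np.zeros(9),
            method="trf",
            diff_step=1e-3,
            xtol=1e-8,
            ftol=1e-7,
            max_nfev=50,
        )
        params = params + res.x * scales
    return AffineTransform(
        rotation=params[0:3],
        scale=np.exp(params[3:6]),
        translation=params[6:9],
        center=center,
    )


# --------------------------------------------------------------------------
# Deformable stage


def _normalize(vox: np.ndarray) -> np.ndarray:
    sd = float(np.std(vox))
    if sd < 1e-12:
        raise RegistrationError("flat image in deformable stage")
    return (vox - float(np.mean(vox))) / sd


def _resample_field(u: np.ndarray, old_spacing, new_shape, new_spacing) -> np.ndarray:
    """Resample a displacement field between origin-anchored grids.

    Values (mm offsets) are interpolated, not rescaled; both grids share
    the first-voxel-center anchor used throughout the package.
    """
    ratio = np.asarray(new_spacing, float) / np.asarray(old_spacing, float)
    grids = np.meshgrid(
        *[np.arange(n, dtype=float) * r for n, r in zip(new_shape, ratio)],
        indexing="ij",
    )
    coords = np.stack([g.ravel() for g in grids])
    return np.stack(
        [
            ndimage.map_coordinates(u[..., i], coords, order=1, mode="nearest").reshape(
                tuple(new_shape)
            )
            for i in range(3)
        ],
        axis=-1,
    )


def _deformable_energy(fvox, mimg: VolumeImage, u, spacing, alpha):
    """Total energy and the warped moving image for the current field.

    The moving image is edge-clamped (``mode="nearest"``): a constant
    fill would make the energy discontinuous in u at the far grid edge,
    stalling the line search when the field of view ends in tissue.
    """
    shape = fvox.shape
    idx = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    coords = [idx[i] + u[..., i] / spacing[i] for i in range(3)]
    warped = ndimage.map_coordinates(
        mimg.voxels, np.stack([c.ravel() for c in coords]), order=1, mode="nearest"
    ).reshape(shape)
    data = float(np.sum((fvox - warped) ** 2))
    reg = 0.0
    for comp in range(3):
        for g in np.gradient(u[..., comp], *spacing, axis=(0, 1, 2)):
            reg += float(np.sum(g**2))
    return data + alpha * reg, warped


def estimate_deformable(
    fixed: VolumeImage,
    moving: VolumeImage,
    config: RegistrationConfig | None = None,
    init: np.ndarray | None = None,
) -> DisplacementField:
    """Estimate a dense displacement field with moving(x+u(x)) ~ fixed(x).

    Gradient descent on the sum-of-squared-differences data term plus
    the ``alpha``-weighted first-order smoothness penalty, with
    backtracking (step halving on any energy increase) so the recorded
    ``energy_history`` is non-increasing within each pyramid level.
    The moving image must already be linearly aligned to the fixed one.
    ``init`` optionally seeds the field (mm offsets on the fixed grid),
    e.g. with a locally estimated translation.
    """
    config = config or RegistrationConfig()
    _check_inputs(fixed, moving)
    native = float(np.max(fixed.spacing_mm))
    spacings = _level_spacings(config, native)

    u = None
    if init is not None:
        init = np.asarray(init, dtype=float)
        if init.shape != fixed.shape + (3,):
            raise VolGridError("init field must be (nx,ny,nz,3) on the fixed grid")
    prev_spacing = None
    history: list[tuple] = []
    for s_mm in spacings:
        fx = _smooth_resample(fixed, s_mm)
        mv = _smooth_resample(moving, s_mm)
        if not same_geometry(fx, mv):
            mv = warp_image(mv, MatrixTransform(np.eye(4)), target=fx)
        fvox = _normalize(fx.voxels)
        mnorm = VolumeImage(
            _normalize(mv.voxels), mv.spacing_mm, mv.origin_mm, mv.orientation
        )
        spacing = np.asarray(fx.spacing_mm, float)
        shape = fvox.shape
        if u is None:
            if init is not None:
                u = _resample_field(init, fixed.spacing_mm, shape, spacing)
            else:
                u = np.zeros(shape + (3,))
        else:
            u = _resample_field(u, prev_spacing, shape, spacing)
        prev_spacing = spacing

        energy, warped = _deformable_energy(fvox, mnorm, u, spacing, config.alpha)
        level_history = [energy]
        step = config.step_size * float(np.min(spacing))
        for _ in range(config.max_iters):
            # gradient of E: -2 (f - m∘phi) grad(m∘phi) - 2 alpha Laplacian(u)
            grads = np.gradient(warped, *spacing, axis=(0, 1, 2))
            resid = fvox - warped
            force = np.stack([resid * g for g in grads], axis=-1)
            if config.alpha > 0:
                lap = np.stack(
                    [ndimage.laplace(u[..., i]) / float(np.mean(spacing)) ** 2 for i in range(3)],
                    axis=-1,
                )
                force = force + config.alpha * lap
            fmax = float(np.max(np.abs(force)))
            if fmax < 1e-14:
                break
            accepted = False
            trial_step = step
            for _halving in range(12):
                u_new = u + (trial_step / fmax) * force
                e_new, w_new = _deformable_energy(fvox, mnorm, u_new, spacing, config.alpha)
                if e_new <= energy * (1.0 + 1e-12):
                    accepted = True
                    break
                trial_step *= 0.5
            if not accepted:
                break  # converged: no descent direction at any step size
            rel_drop = (energy - e_new) / max(energy, 1e-30)
            u, warped = u_new, w_new
            energy = e_new
            level_history.append(energy)
            step = min(trial_step * 1.3, config.step_size * float(np.min(spacing)))
            if rel_drop < config.stop_tol:
                break
        history.append(tuple(level_history))

    # resample the field onto the fixed image's own grid if needed
    if u.shape[:3] != fixed.shape:
        u = _resample_field(u, prev_spacing, fixed.shape, fixed.spacing_mm)
    return DisplacementField(
        u,
        fixed.spacing_mm,
        fixed.origin_mm,
        fixed.orientation,
        energy_history=tuple(history),
    )
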