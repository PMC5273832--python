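"""Rigid mutual-information registration and grid resampling.

The soft-tissue (MRI-like) volume is registered onto the bone-contrast
(CBCT-like) volume by maximizing the mutual information of the joint
intensity histogram over the overlap region, searching the 6 rigid
parameters with a derivative-free Powell optimizer seeded from a small
translation multi-start grid.  All volumes live in a right-handed mm frame;
the estimated transform maps moving-image anatomy into the fixed frame, so
``resample_to_common_grid(moving, result.transform, fixed)`` produces the
fused pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize

from .grids import MaskVolume, VoxelVolume
from .transforms import RigidTransform


@dataclass
class RegistrationConfig:
    bins: int = 32
    sample_stride: int = 2          # fixed-image voxel subsampling for MI
    grid_offsets_mm: tuple = (-4.0, 0.0, 4.0)  # 3x3x3 translation multi-start
    xtol: float = 1e-3
    ftol: float = 1e-6              # MI change convergence (nats)
    max_iterations: int = 200
    jitter_seed: int = 2371        # deterministic off-grid sampling offsets
    smoothing_sigma: float = 1.0   # voxels; image pre-smoothing for the objective


@dataclass
class RegistrationResult:
    transform: RigidTransform
    mutual_information: float       # nats
    iterations: int
    converged: bool


def _index_affine(
    volume: VoxelVolume, transform: RigidTransform, reference: VoxelVolume
) -> tuple[np.ndarray, np.ndarray]:
    """Affine (matrix, offset) mapping reference indices to ``volume`` indices
    for the pull-back resampling ``out(x) = volume(T^-1 x)``."""
    inv = transform.inverse()
    R = inv.rotation_matrix
    s_in, s_out = volume.spacing, reference.spacing
    matrix = (R * s_out[None, :]) / s_in[:, None]
    offset = (inv.apply(reference.origin[None, :])[0] - volume.origin) / s_in
    return matrix, offset


def resample_to_common_grid(
    obj: VoxelVolume,
    transform: RigidTransform,
    reference_grid: VoxelVolume,
    order: int | None = None,
    cval: float = 0.0,
    mode: str = "constant",
):
    """Resample a volume or mask under a rigid transform onto a reference grid.

    Masks use nearest-neighbor interpolation, intensity volumes trilinear,
    unless ``order`` overrides.  ``mode``/``cval`` control the fill outside
    the source extent (``"nearest"`` replicates edge values).
    """
    is_mask = isinstance(obj, MaskVolume)
    if order is None:
        order = 0 if is_mask else 1
    matrix, offset = _index_affine(obj, transform, reference_grid)
    out = ndimage.affine_transform(
        obj.data.astype(np.uint8 if is_mask else np.float64),
        matrix,
        offset=offset,
        output_shape=reference_grid.shape,
        order=order,
        mode=mode,
        cval=cval,
        prefilter=order > 1,
    )
    cls = MaskVolume if is_mask else VoxelVolume
    return cls(
        data=out,
        spacing=reference_grid.spacing.copy(),
        origin=reference_grid.origin.copy(),
    )


def _sample_moving(
    moving: VoxelVolume, transform: RigidTransform, points_world: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Moving-image intensities at fixed-frame sample points, plus validity mask."""
    idx = moving.world_to_index(transform.inverse().apply(points_world))
    upper = np.array(moving.shape) - 1
    valid = np.all((idx >= 0) & (idx <= upper), axis=1)
    values = ndimage.map_coordinates(
        moving.data.astype(np.float64), idx.T, order=1, mode="nearest"
    )
    return values, valid


def mutual_information(
    fixed: VoxelVolume,
    moving: VoxelVolume,
    transform: RigidTransform | None = None,
    bins: int = 32,
    sample_stride: int = 1,
) -> float:
    """MI (nats) of the joint intensity histogram over the overlap region."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if transform is None:
        transform = RigidTransform.identity()
    points = fixed.voxel_centers(stride=sample_stride)
    f_vals = fixed.data[::sample_stride, ::sample_stride, ::sample_stride].ravel()
    m_vals, valid = _sample_moving(moving, transform, points)
    if not valid.any():
        raise ValueError("volumes do not overlap under the given transform")
    f_vals, m_vals = f_vals[valid].astype(np.float64), m_vals[valid]
    hist, _, _ = np.histogram2d(f_vals, m_vals, bins=bins)
    p = hist / hist.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _soft_histogram2d(
    x: np.ndarray, y: np.ndarray, bins: int, x_range: tuple, y_range: tuple
) -> np.ndarray:
    """Joint histogram with linear (Parzen) binning over fixed intensity
    windows: each sample spreads bilinearly over the four neighboring cells,
    giving an MI objective that varies smoothly with pose."""

    def coords(v, lo, hi):
        span = max(hi - lo, 1e-12)
        u = np.clip((v - lo) / span * (bins - 1), 0, bins - 1)
        i0 = np.minimum(u.astype(np.int64), bins - 2)
        return i0, u - i0

    ix, fx = coords(x, *x_range)
    iy, fy = coords(y, *y_range)
    hist = np.zeros((bins, bins))
    for dx, wx in ((0, 1 - fx), (1, fx)):
        for dy, wy in ((0, 1 - fy), (1, fy)):
            np.add.at(hist, (ix + dx, iy + dy), wx * wy)
    return hist


def _params_to_transform(params: np.ndarray, center: np.ndarray) -> RigidTransform:
    return RigidTransform(
        rotation_deg=params[:3], translation=params[3:], center=center
    )


def register_rigid(
    fixed: VoxelVolume,
    moving: VoxelVolume,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed`` by MI.

    Deterministic: a coarse translation multi-start grid (MI evaluated at
    zero rotation) selects the start, followed by a single Powell refinement
    over all six parameters.  Non-convergence within the iteration cap is
    flagged on the result, not raised.
    """
    config = config or RegistrationConfig()
    center = fixed.world_center()

    # Two pyramid levels of the MI objective: heavier smoothing while far
    # from the optimum, lighter smoothing for the final refinement.
    level_cache: dict[float, tuple[VoxelVolume, VoxelVolume]] = {}

    def level(sigma: float) -> tuple[VoxelVolume, VoxelVolume]:
        if sigma not in level_cache:
            if sigma > 0:
                level_cache[sigma] = (
                    VoxelVolume(ndimage.gaussian_filter(fixed.data.astype(np.float64), sigma),
                                fixed.spacing, fixed.origin),
                    VoxelVolume(ndimage.gaussian_filter(moving.data.astype(np.float64), sigma),
                                moving.spacing, moving.origin),
                )
            else:
                level_cache[sigma] = (fixed, moving)
        return level_cache[sigma]

    # Sample points are voxel centers jittered off-grid by a fixed random
    # offset.  On-grid sampling biases MI toward grid-aligned poses (samples
    # then hit moving-image voxels exactly, sharpening the histogram), which
    # systematically pulls the rotation toward zero; jitter makes every pose
    # interpolate equally.
    rng = np.random.default_rng(config.jitter_seed)
    sample_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}

    def samples(stride: int, sigma: float) -> tuple[np.ndarray, np.ndarray]:
        key = (stride, sigma)
        if key not in sample_cache:
            fx, _ = level(sigma)
            axes = [np.arange(0, n, stride) for n in fx.shape]
            idx = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
            idx = idx + np.random.default_rng(config.jitter_seed).uniform(-0.5, 0.5, idx.shape)
            idx = np.clip(idx, 0, np.array(fx.shape) - 1)
            f_vals = ndimage.map_coordinates(
                fx.data.astype(np.float64), idx.T, order=1, mode="nearest"
            )
            sample_cache[key] = (fx.index_to_world(idx), f_vals)
        return sample_cache[key]

    def neg_mi_at(params: np.ndarray, stride: int, sigma: float) -> float:
        fx, mv = level(sigma)
        points, f_vals = samples(stride, sigma)
        transform = _params_to_transform(params, center)
        m_vals, valid = _sample_moving(mv, transform, points)
        if not valid.any():
            return 0.0
        hist = _soft_histogram2d(
            f_vals[valid], m_vals[valid], config.bins,
            (float(fx.data.min()), float(fx.data.max())),
            (float(mv.data.min()), float(mv.data.max())),
        )
        p = hist / hist.sum()
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        nz = p > 0
        return -float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))

    sigma0 = config.smoothing_sigma
    sigma1 = sigma0 / 2.0

    # stage A: translation multi-start at zero rotation, coarse sampling
    offsets = np.asarray(config.grid_offsets_mm, dtype=float)
    starts = np.stack(
        np.meshgrid(offsets, offsets, offsets, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    coarse_stride = max(config.sample_stride, 4)
    best_start, best_score = np.zeros(3), np.inf
    for t in starts:
        score = neg_mi_at(np.concatenate([np.zeros(3), t]), coarse_stride, sigma0)
        if score < best_score:
            best_score, best_start = score, t

    powell = dict(method="Powell")
    iterations = 0

    # stage B: translation-only refinement
    res_t = optimize.minimize(
        lambda t: neg_mi_at(np.concatenate([np.zeros(3), t]), config.sample_stride, sigma0),
        best_start,
        options={"xtol": 10 * config.xtol, "ftol": 10 * config.ftol,
                 "maxiter": config.max_iterations},
        **powell,
    )
    iterations += int(res_t.nit)

    # stages C/D/E: full 6-parameter search, then restarts at finer levels
    # (Powell's conjugate directions degrade; fresh starts recover accuracy)
    x = np.concatenate([np.zeros(3), res_t.x])
    fine_stride = max(1, config.sample_stride // 2)
    for stride, sigma in ((config.sample_stride, sigma0), (fine_stride, sigma0),
                          (fine_stride, sigma1)):
        res = optimize.minimize(
            lambda p: neg_mi_at(p, stride, sigma),
            x,
            options={"xtol": config.xtol, "ftol": config.ftol,
                     "maxiter": config.max_iterations, "maxfev": 20000},
            **powell,
        )
        x = res.x
        iterations += int(res.nit)

    transform = _params_to_transform(x, center)
    return RegistrationResult(
        transform=transform,
        mutual_information=float(-res.fun),
        iterations=iterations,
        converged=bool(res.success and iterations < 4 * config.max_iterations),
    )


def fast_config() -> RegistrationConfig:
    """Desk-scale settings for small phantoms (coarser sampling, small grid)."""
    return replace(RegistrationConfig(), sample_stride=2, grid_offsets_mm=(-3.0, 0.0, 3.0))
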