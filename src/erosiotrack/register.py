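"""Baseline-indexed rigid co-registration with mutual information.

Follow-up volumes are mapped onto the unaltered baseline grid: a coarse
initialization from intensity centroids and principal axes, refinement by
maximizing the mutual information of the 32-bin joint intensity histogram
with a deterministic Powell search over the 6 rigid parameters, and
trilinear re-slicing into baseline space with a validity mask marking
voxels that fall outside the follow-up stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .volume import RigidTransform, Volume3D

__all__ = [
    "RegistrationParams",
    "RegistrationResult",
    "initialize_transform",
    "mutual_information",
    "register_rigid",
    "resample_to_baseline",
    "EmptyOverlapError",
    "InitializationError",
]


class EmptyOverlapError(ValueError):
    """The transform leaves no overlap between the two volumes."""


class InitializationError(ValueError):
    """No foreground voxels available for centroid/principal-axes alignment."""


@dataclass(frozen=True)
class RegistrationParams:
    """Settings of the MI metric and the Powell refinement.

    ``pyramid`` lists (downsampling factor, sample stride) stages, coarse to
    fine; sampling strides thin the fixed-grid points fed to the metric.
    All stages are deterministic: same inputs always give the same result.
    """

    histogram_bins: int = 32
    pyramid: tuple[tuple[int, int], ...] = ((2, 2), (1, 1))
    max_iterations: int = 20
    tolerance: float = 3e-5
    background_fill: float = 0.0
    mask_to_foreground: bool = True  # bone-only metric support (dilated)
    max_samples: int = 60000  # metric sample budget per pyramid level
    #: rotation perturbations (radians, per axis, +/-) tried as extra starts
    #: at the coarsest level; guards against nearby false MI maxima
    coarse_rotation_starts: float = np.deg2rad(4.0)
    #: per-axis angles (degrees) of the exhaustive rotation-grid scan that
    #: precedes optimization; each candidate gets an overlap-refined
    #: centroid translation and is scored by coarse MI
    rotation_grid_deg: tuple[float, ...] = (-8.0, -4.0, 0.0, 4.0, 8.0)
    initial_step_rad: float = 0.02  # first line-search brackets: keep the
    initial_step_mm: float = 0.2  # search local to the initialization

    def __post_init__(self) -> None:
        if self.histogram_bins < 8:
            raise ValueError("histogram_bins must be >= 8")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    mutual_information: float
    initial_mutual_information: float
    converged: bool


def _foreground_threshold(data: np.ndarray) -> float:
    # low cut between background and the dimmest bone class: the whole bone
    # (cortex + trabecular interior) must count as foreground, else the
    # thin-shell second moments are near-degenerate and the axes wobble
    lo, hi = np.percentile(data, [1, 99])
    return float(lo + 0.25 * (hi - lo))


def _principal_axes(vol: Volume3D):
    """Centroid (mm), eigenvector basis and eigenvalues of the foreground."""
    mask = vol.data > _foreground_threshold(vol.data)
    if not mask.any():
        raise InitializationError("no above-background voxels in volume")
    coords = np.argwhere(mask) * np.asarray(vol.spacing_mm)
    centroid = coords.mean(axis=0)
    cov = np.cov((coords - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return centroid, evecs[:, order], evals[order], coords


def _well_separated(evals: np.ndarray, rel_gap: float = 0.15) -> bool:
    return bool(
        (evals[0] - evals[1]) / evals[0] > rel_gap
        and (evals[1] - evals[2]) / max(evals[1], 1e-12) > rel_gap
    )


def initialize_transform(fixed: Volume3D, moving: Volume3D) -> RigidTransform:
    """Coarse alignment from intensity centroids and principal axes.

    The rotation maps the moving foreground's principal axes onto the fixed
    ones. Eigenvector sign and ordering ambiguity (axes can swap when two
    spreads are comparable, e.g. stacks of different axial extent) is
    resolved toward the smallest rotation: among all proper rotations built
    from axis permutations and sign flips, the one with maximal trace wins.
    When either volume's moments are too close to degenerate for the axes
    to mean anything, the rotation falls back to identity — longitudinal
    re-scan motions are small — and only the centroids are aligned.
    Because the two stacks rarely cover the same anatomy (the follow-up
    acquisition is longer), the centroid alignment is refined once on the
    mutually overlapping region.
    """
    from itertools import permutations

    c_f, U_f, e_f, coords_f = _principal_axes(fixed)
    c_m, U_m, e_m, coords_m = _principal_axes(moving)
    if _well_separated(e_f) and _well_separated(e_m):
        best = None
        for perm in permutations(range(3)):
            P = np.eye(3)[:, list(perm)]
            for signs in np.array(
                np.meshgrid([1, -1], [1, -1], [1, -1])
            ).T.reshape(-1, 3):
                R = U_f @ P @ np.diag(signs) @ U_m.T
                if np.linalg.det(R) < 0:
                    continue
                if best is None or np.trace(R) > np.trace(best):
                    best = R
    else:
        best = np.eye(3)

    return _with_refined_translation(fixed, moving, best, coords_f, coords_m)


def _with_refined_translation(fixed, moving, R, coords_f, coords_m):
    """Centroid translation for rotation ``R``, refined on the overlap.

    First aligns full-foreground centroids, then drops foreground the other
    stack cannot see under that guess and re-aligns — correcting the bias a
    longer follow-up stack puts on the plain centroid.
    """
    t = coords_f.mean(axis=0) - R @ coords_m.mean(axis=0)
    T0 = RigidTransform(rotation=R, translation_mm=t)
    upper_f = (np.asarray(fixed.shape) - 1) * np.asarray(fixed.spacing_mm)
    upper_m = (np.asarray(moving.shape) - 1) * np.asarray(moving.spacing_mm)
    in_f = np.all(
        (T0.apply(coords_m) >= 0) & (T0.apply(coords_m) <= upper_f), axis=1
    )
    in_m = np.all(
        (T0.inverse().apply(coords_f) >= 0)
        & (T0.inverse().apply(coords_f) <= upper_m),
        axis=1,
    )
    if in_f.any() and in_m.any():
        t = coords_f[in_m].mean(axis=0) - R @ coords_m[in_f].mean(axis=0)
    return RigidTransform(rotation=R, translation_mm=t)


def _sample_pair(
    fixed: Volume3D,
    moving: Volume3D,
    T: RigidTransform,
    stride: int = 1,
    mask: np.ndarray | None = None,
):
    """Fixed intensities and transformed-moving intensities on the overlap."""
    idx = np.indices(fixed.shape, dtype=np.float32)
    sl = (slice(None),) + (slice(None, None, stride),) * 3
    idx = idx[sl].reshape(3, -1)
    f_vals = fixed.data[sl[1:]].reshape(-1)
    pts_mm = idx.T * np.asarray(fixed.spacing_mm, dtype=np.float32)
    src = (T.inverse().apply(pts_mm) / np.asarray(moving.spacing_mm)).T
    upper = (np.asarray(moving.shape) - 1)[:, None]
    valid = np.all((src >= 0) & (src <= upper), axis=0)
    if mask is not None:
        valid &= mask[sl[1:]].reshape(-1)
    if not valid.any():
        raise EmptyOverlapError("transform leaves no overlapping voxels")
    m_vals = ndimage.map_coordinates(moving.data, src[:, valid], order=1)
    return f_vals[valid], m_vals


def _mi_from_samples(f_vals, m_vals, bins, f_range, m_range) -> float:
    joint, _, _ = np.histogram2d(f_vals, m_vals, bins=bins, range=(f_range, m_range))
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


def _intensity_range(data: np.ndarray) -> tuple[float, float]:
    lo, hi = float(data.min()), float(data.max())
    return (lo, hi if hi > lo else lo + 1.0)


def mutual_information(
    fixed: Volume3D,
    moving: Volume3D,
    T: RigidTransform | None = None,
    bins: int = 32,
    stride: int = 1,
) -> float:
    """MI (nats) of the joint histogram of overlapping voxels under ``T``.

    Histogram bin edges span each volume's own min/max, so the metric is
    invariant to monotone intensity relabelings that preserve bin
    assignment. Raises :class:`EmptyOverlapError` when nothing overlaps.
    """
    T = RigidTransform.identity() if T is None else T
    f_vals, m_vals = _sample_pair(fixed, moving, T, stride=stride)
    return _mi_from_samples(
        f_vals, m_vals, bins, _intensity_range(fixed.data), _intensity_range(moving.data)
    )


def _downsample(vol: Volume3D, factor: int) -> Volume3D:
    if factor == 1:
        return vol
    d = vol.data
    trim = tuple(slice(0, (s // factor) * factor) for s in d.shape)
    d = d[trim]
    d = d.reshape(
        d.shape[0] // factor, factor, d.shape[1] // factor, factor,
        d.shape[2] // factor, factor,
    ).mean(axis=(1, 3, 5))
    return Volume3D(
        d, spacing_mm=tuple(s * factor for s in vol.spacing_mm),
        axial_axis=vol.axial_axis, frame=vol.frame,
    )


def register_rigid(
    fixed: Volume3D,
    moving: Volume3D,
    init: RigidTransform | None = None,
    params: RegistrationParams = RegistrationParams(),
) -> RegistrationResult:
    """Refine a rigid follow-up-to-baseline transform by maximizing MI.

    Powell's derivative-free search over (3 rotation angles about the fixed
    volume centre, 3 translations) runs through a coarse-to-fine pyramid.
    The returned transform never scores below the initialization: if the
    search ends worse (or fails to converge within ``max_iterations``), the
    best transform seen is returned with ``converged=False``.
    """
    if init is None:
        init = initialize_transform(fixed, moving)
    center = fixed.center_mm()
    f_range = _intensity_range(fixed.data)
    m_range = _intensity_range(moving.data)
    bins = params.histogram_bins

    mask_full = None
    if params.mask_to_foreground:
        # dilated so the bone/background boundary — the informative part of
        # the joint histogram — stays inside the metric support
        mask_full = ndimage.binary_dilation(
            fixed.data > _foreground_threshold(fixed.data), iterations=3
        )

    angles0, t0 = init.euler_angles(center_mm=center)
    x = np.concatenate([angles0, t0])

    converged = True
    for factor, stride in params.pyramid:
        f_lo = _downsample(fixed, factor)
        m_lo = _downsample(moving, factor)
        mask_lo = None
        if mask_full is not None:
            mask_lo = _downsample(
                Volume3D(mask_full.astype(np.float32), spacing_mm=fixed.spacing_mm),
                factor,
            ).data > 0.5

        # fixed-side sampling does not depend on the transform: precompute
        # the sample points and their histogram bin index once per level
        sl = (slice(None, None, stride),) * 3
        idx = np.indices(f_lo.shape, dtype=np.float32)[(slice(None),) + sl]
        idx = idx.reshape(3, -1)
        f_vals = f_lo.data[sl].reshape(-1)
        if mask_lo is not None:
            keep = mask_lo[sl].reshape(-1)
            idx, f_vals = idx[:, keep], f_vals[keep]
        if idx.shape[1] > params.max_samples:
            # fixed pseudo-random subsample: deterministic, and free of the
            # sublattice aliasing a coarser grid stride would introduce
            pick = np.random.default_rng(0).permutation(idx.shape[1])
            pick = np.sort(pick[: params.max_samples])
            idx, f_vals = idx[:, pick], f_vals[pick]
        pts_mm = idx.T * np.asarray(f_lo.spacing_mm, dtype=np.float32)
        f_bin = np.clip(
            ((f_vals - f_range[0]) / (f_range[1] - f_range[0]) * bins).astype(int),
            0, bins - 1,
        )
        m_spacing = np.asarray(m_lo.spacing_mm)
        m_upper = (np.asarray(m_lo.shape) - 1)[:, None]
        m_scale = bins / (m_range[1] - m_range[0])

        def neg_mi(p):
            T = RigidTransform.from_euler(tuple(p[:3]), tuple(p[3:]), center_mm=center)
            src = (T.inverse().apply(pts_mm) / m_spacing).T
            valid = np.all((src >= 0) & (src <= m_upper), axis=0)
            if not valid.any():
                return 0.0
            m_vals = ndimage.map_coordinates(m_lo.data, src[:, valid], order=1)
            m_bin = np.clip(((m_vals - m_range[0]) * m_scale).astype(int), 0, bins - 1)
            joint = np.bincount(
                f_bin[valid] * bins + m_bin, minlength=bins * bins
            ).reshape(bins, bins)
            p_joint = joint / joint.sum()
            px = p_joint.sum(axis=1, keepdims=True)
            py = p_joint.sum(axis=0, keepdims=True)
            nz = p_joint > 0
            return -float((p_joint[nz] * np.log(p_joint[nz] / (px @ py)[nz])).sum())

        if (factor, stride) == params.pyramid[0] and params.rotation_grid_deg:
            # exhaustive rotation scan: pick the best-scoring basin before
            # any local optimization (moments initialization alone can land
            # next to a false maximum when the stacks overlap partially)
            from scipy.spatial.transform import Rotation

            _, _, _, coords_f = _principal_axes(fixed)
            _, _, _, coords_m = _principal_axes(moving)
            coords_f, coords_m = coords_f[::4], coords_m[::4]
            best_p, best_val = x, neg_mi(x)
            grid = np.deg2rad(params.rotation_grid_deg)
            for a0 in grid:
                for a1 in grid:
                    for a2 in grid:
                        R = Rotation.from_euler("xyz", (a0, a1, a2)).as_matrix()
                        cand = _with_refined_translation(
                            fixed, moving, R, coords_f, coords_m
                        )
                        ang, tr = cand.euler_angles(center_mm=center)
                        p = np.concatenate([ang, tr])
                        val = neg_mi(p)
                        if val < best_val:
                            best_p, best_val = p, val
            x = np.asarray(best_p)

        direc = np.diag([params.initial_step_rad] * 3 + [params.initial_step_mm] * 3)
        starts = [x]
        if (factor, stride) == params.pyramid[0] and params.coarse_rotation_starts:
            for axis in range(3):
                for sign in (+1, -1):
                    alt = x.copy()
                    alt[axis] += sign * params.coarse_rotation_starts
                    starts.append(alt)
        best = None
        for x0 in starts:
            res = optimize.minimize(
                neg_mi, x0, method="Powell",
                options={
                    "maxiter": params.max_iterations,
                    "xtol": params.tolerance,
                    "ftol": params.tolerance,
                    "direc": direc.copy(),  # Powell mutates the direction set
                },
            )
            if best is None or res.fun < best.fun:
                best = res
        x = best.x
        converged = converged and bool(best.success)

    final = RigidTransform.from_euler(tuple(x[:3]), tuple(x[3:]), center_mm=center)
    mi_init = mutual_information(fixed, moving, init, bins=bins, stride=2)
    mi_final = mutual_information(fixed, moving, final, bins=bins, stride=2)
    if mi_final < mi_init:  # monotone acceptance: never worse than the start
        return RegistrationResult(init, mi_init, mi_init, False)
    return RegistrationResult(final, mi_final, mi_init, converged)


def resample_to_baseline(
    moving: Volume3D,
    T: RigidTransform,
    reference: Volume3D,
    fill_value: float | None = None,
) -> tuple[Volume3D, np.ndarray]:
    """Re-slice the follow-up volume onto the baseline grid.

    Trilinear interpolation at every reference grid point; voxels whose
    source coordinate falls outside the moving stack receive ``fill_value``
    (the moving volume's minimum by default) and are flagged False in the
    returned validity mask, which downstream measurement must respect.
    """
    fill = float(moving.data.min()) if fill_value is None else fill_value
    idx = np.indices(reference.shape, dtype=np.float64).reshape(3, -1)
    pts_mm = idx.T * np.asarray(reference.spacing_mm)
    src = (T.inverse().apply(pts_mm) / np.asarray(moving.spacing_mm)).T
    upper = (np.asarray(moving.shape) - 1)[:, None]
    eps = 1e-6  # tolerate round-off at the grid faces
    valid = np.all((src >= -eps) & (src <= upper + eps), axis=0).reshape(
        reference.shape
    )
    src = np.clip(src, 0, upper)
    out = ndimage.map_coordinates(
        moving.data, src, order=1, mode="constant", cval=fill
    ).reshape(reference.shape)
    out[~valid] = fill
    vol = Volume3D(
        out.astype(np.float32), spacing_mm=reference.spacing_mm,
        axial_axis=reference.axial_axis, frame="baseline-registered",
    )
    return vol, valid
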