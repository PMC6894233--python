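"""Seeded segmentation and volumetry of erosions and enthesiophytes.

An erosion is a connected sub-bone-intensity region grown from a seed
inside the periosteal envelope that reaches a break in the outer cortical
margin on at least two consecutive axial slices. An enthesiophyte is a
connected bone-intensity region grown from a seed strictly outside the
*baseline* periosteal surface — growth is always measured against that
fixed anatomical reference, carried into follow-up space by registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import Volume3D

__all__ = [
    "LesionSegParams",
    "LesionRecord",
    "segment_periosteal",
    "segment_lesion",
    "pair_lesions",
    "SeedError",
    "SegmentationError",
]

_CONN26 = np.ones((3, 3, 3), dtype=int)


class SeedError(ValueError):
    """Seed point on the wrong side of the reference surface, or off bone."""


class SegmentationError(ValueError):
    """Thresholding produced no usable bone segmentation."""


@dataclass(frozen=True)
class LesionSegParams:
    """Thresholds (intensity units) and regularization for segmentation.

    ``erosion_threshold`` separates carved-out void from trabecular bone;
    ``bone_threshold`` separates dense (cortical-level) bone from
    everything below it; ``closing_radius_mm`` bridges small cortical
    defects when recovering the periosteal envelope; ``shell_thickness_vox``
    is the outer-margin band used to detect a cortical break.
    """

    erosion_threshold: float = 175.0
    bone_threshold: float = 550.0
    closing_radius_mm: float = 0.25
    shell_thickness_vox: int = 2
    min_component_voxels: int = 27


@dataclass
class LesionRecord:
    """One segmented lesion at one time point."""

    lesion_id: int
    kind: str
    seed_vox: tuple[int, int, int]
    mask: np.ndarray  # (n, 3) voxel indices, baseline grid
    volume_mm3: float
    timepoint: str = "baseline"
    compartment: str = ""
    quadrant: str = ""
    touches_boundary: bool = False

    @property
    def centroid_vox(self) -> np.ndarray:
        return np.asarray(self.mask, dtype=float).mean(axis=0)


def _ball(radius_vox: int) -> np.ndarray:
    r = max(radius_vox, 1)
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (zz**2 + yy**2 + xx**2) <= r**2


def segment_periosteal(
    volume: Volume3D, bone_threshold: float, params: LesionSegParams = LesionSegParams()
) -> np.ndarray:
    """Recover the periosteal envelope (outer surface and interior).

    Threshold, morphologically close to seal small cortical breaks, fill
    interior holes, and discard speckle components. Raises
    :class:`SegmentationError` when thresholding yields no bone.
    """
    binary = volume.data > bone_threshold
    if not binary.any():
        raise SegmentationError(
            f"no voxels above bone_threshold={bone_threshold}; threshold must "
            "lie between background and bone intensity"
        )
    r = max(1, int(round(params.closing_radius_mm / volume.spacing_mm[0])))
    # edge-pad so closing cannot erode bone that touches the stack faces
    padded = np.pad(binary, r, mode="edge")
    closed = ndimage.binary_closing(padded, structure=_ball(r))[
        r:-r, r:-r, r:-r
    ]
    # the shaft is cut open where it leaves the scan: cap the axial faces
    # so the medullary interior counts as a hole and gets filled
    capped = np.pad(closed, ((1, 1), (0, 0), (0, 0)), constant_values=True)
    filled = ndimage.binary_fill_holes(capped)[1:-1]
    labels, n = ndimage.label(filled, structure=_CONN26)
    sizes = ndimage.sum_labels(filled, labels, index=range(1, n + 1))
    keep = np.flatnonzero(sizes >= params.min_component_voxels) + 1
    if len(keep) == 0:
        raise SegmentationError("only speckle components found above threshold")
    return np.isin(labels, keep)


def _grown_region(candidate: np.ndarray, seed: tuple[int, int, int]) -> np.ndarray:
    labels, _ = ndimage.label(candidate, structure=_CONN26)
    lab = labels[seed]
    if lab == 0:
        raise SeedError(f"seed {seed} is not inside a candidate lesion region")
    return labels == lab


def segment_lesion(
    volume: Volume3D,
    periosteal_mask: np.ndarray,
    reference_surface: np.ndarray,
    seed_vox: tuple[int, int, int],
    kind: str,
    params: LesionSegParams = LesionSegParams(),
    lesion_id: int = 0,
    timepoint: str = "baseline",
    compartment: str = "",
    quadrant: str = "",
    roi_mask: np.ndarray | None = None,
) -> LesionRecord:
    """Grow one lesion from its seed and attach its volume in mm^3.

    ``reference_surface`` is the unmodified (baseline) periosteal envelope
    that defines inside vs outside; ``periosteal_mask`` may be the same
    array or a time-point-specific segmentation. The grown region is
    clipped to the ROI when one is given and flagged when it touches the
    ROI (or image) boundary.
    """
    seed = tuple(int(v) for v in seed_vox)
    if kind == "erosion":
        if not reference_surface[seed]:
            raise SeedError("erosion seed must lie inside the periosteal surface")
        candidate = (volume.data < params.erosion_threshold) & reference_surface
        region = _grown_region(candidate, seed)
        shell = reference_surface & ~ndimage.binary_erosion(
            reference_surface, iterations=params.shell_thickness_vox
        )
        break_slices = np.unique(np.argwhere(region & shell)[:, 0])
        if len(break_slices) < 2 or not np.any(np.diff(break_slices) == 1):
            raise SegmentationError(
                "region does not reach a cortical break on >=2 consecutive slices"
            )
    elif kind == "enthesiophyte":
        if reference_surface[seed]:
            raise SeedError(
                "enthesiophyte seed must lie outside the reference periosteal surface"
            )
        candidate = (volume.data > params.bone_threshold) & ~reference_surface
        region = _grown_region(candidate, seed)
    else:
        raise ValueError(f"unknown lesion kind {kind!r}")

    touches = _touches_boundary(region, roi_mask)
    if roi_mask is not None:
        region &= roi_mask
    coords = np.argwhere(region)
    return LesionRecord(
        lesion_id=lesion_id,
        kind=kind,
        seed_vox=seed,
        mask=coords,
        volume_mm3=len(coords) * volume.voxel_volume_mm3,
        timepoint=timepoint,
        compartment=compartment,
        quadrant=quadrant,
        touches_boundary=touches,
    )


def _touches_boundary(region: np.ndarray, roi_mask: np.ndarray | None) -> bool:
    if roi_mask is not None:
        outside = region & ~roi_mask
        return bool(outside.any())
    coords = np.argwhere(region)
    upper = np.asarray(region.shape) - 1
    return bool((coords == 0).any() or (coords == upper).any())


def pair_lesions(
    baseline_records: list[LesionRecord],
    followup_records: list[LesionRecord],
    spacing_mm: float | tuple[float, float, float],
    max_centroid_distance_mm: float = 1.0,
):
    """Match lesions across time points by nearest centroid.

    Greedy matching among same-kind, same-compartment records within the
    distance gate, nearest first, ties broken by (baseline id, follow-up
    id). Unmatched follow-up records become ``new`` (baseline volume 0);
    unmatched baseline records become ``lost`` (follow-up volume 0).
    Returns a tidy pair table.
    """
    import pandas as pd

    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,))
    candidates = []
    for i, b in enumerate(baseline_records):
        for j, f in enumerate(followup_records):
            if b.kind != f.kind or b.compartment != f.compartment:
                continue
            d = float(np.linalg.norm((b.centroid_vox - f.centroid_vox) * spacing))
            if d <= max_centroid_distance_mm:
                candidates.append((d, b.lesion_id, f.lesion_id, i, j))
    candidates.sort()
    used_b, used_f, rows = set(), set(), []
    for d, _, _, i, j in candidates:
        if i in used_b or j in used_f:
            continue
        used_b.add(i)
        used_f.add(j)
        b, f = baseline_records[i], followup_records[j]
        rows.append(
            {
                "lesion_id": b.lesion_id,
                "kind": b.kind,
                "compartment": b.compartment,
                "quadrant": b.quadrant,
                "vol_t0_mm3": b.volume_mm3,
                "vol_t5_mm3": f.volume_mm3,
                "delta_mm3": f.volume_mm3 - b.volume_mm3,
                "status": "matched",
                "is_new": False,
                "centroid_distance_mm": d,
            }
        )
    for i, b in enumerate(baseline_records):
        if i not in used_b:
            rows.append(
                {
                    "lesion_id": b.lesion_id,
                    "kind": b.kind,
                    "compartment": b.compartment,
                    "quadrant": b.quadrant,
                    "vol_t0_mm3": b.volume_mm3,
                    "vol_t5_mm3": 0.0,
                    "delta_mm3": -b.volume_mm3,
                    "status": "lost",
                    "is_new": False,
                    "centroid_distance_mm": np.nan,
                }
            )
    for j, f in enumerate(followup_records):
        if j not in used_f:
            rows.append(
                {
                    "lesion_id": f.lesion_id,
                    "kind": f.kind,
                    "compartment": f.compartment,
                    "quadrant": f.quadrant,
                    "vol_t0_mm3": 0.0,
                    "vol_t5_mm3": f.volume_mm3,
                    "delta_mm3": f.volume_mm3,
                    "status": "new",
                    "is_new": True,
                    "centroid_distance_mm": np.nan,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values("lesion_id", kind="stable").reset_index(drop=True)
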