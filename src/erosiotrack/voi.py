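"""Slice matching and region-of-interest definition.

After registration, measurement happens only where baseline and re-sliced
follow-up both carry real data. ``match_slices`` finds that common axial
range; ``define_roi`` restricts it to metacarpal bone, drops the three
boundary slices at each end, and removes non-metacarpal components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import Volume3D

__all__ = ["SliceRange", "ROIMask", "match_slices", "define_roi", "CoLocalizationError"]

BOUNDARY_TRIM_SLICES = 3


class CoLocalizationError(ValueError):
    """No usable common axial range between baseline and follow-up."""


@dataclass(frozen=True)
class SliceRange:
    """Half-open 0-based axial slice range shared by both time points."""

    start: int
    end: int
    compartment: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid slice range [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ROIMask:
    """Measurement mask on the baseline grid with exclusion provenance."""

    mask: np.ndarray
    slice_range: SliceRange
    compartment: str = ""
    provenance: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def match_slices(
    baseline: Volume3D,
    registered_followup: Volume3D,
    validity_mask: np.ndarray,
    bone_mask: np.ndarray | None = None,
    compartment: str = "",
) -> SliceRange:
    """Maximal axial range where the re-sliced follow-up has valid data.

    A slice qualifies when every voxel of the in-plane bone extent (the
    ``bone_mask`` footprint on that slice; the whole slice when no mask is
    given) is covered by valid — not background-filled — follow-up data.
    Slices without bone do not constrain the range. The longest contiguous
    run of qualifying slices is returned.
    """
    if validity_mask.shape != baseline.shape:
        raise ValueError("validity mask must be on the baseline grid")
    n = baseline.n_slices
    ok = np.empty(n, dtype=bool)
    for z in range(n):
        if bone_mask is not None:
            footprint = bone_mask[z]
            ok[z] = True if not footprint.any() else bool(
                validity_mask[z][footprint].all()
            )
        else:
            ok[z] = bool(validity_mask[z].all())
    if not ok.any():
        raise CoLocalizationError("no axial slice with complete valid coverage")
    # longest contiguous run of valid slices
    best_start = best_len = 0
    start = None
    for z in range(n + 1):
        if z < n and ok[z]:
            start = z if start is None else start
        elif start is not None:
            if z - start > best_len:
                best_start, best_len = start, z - start
            start = None
    return SliceRange(best_start, best_start + best_len, compartment)


def define_roi(
    volume: Volume3D,
    periosteal_mask: np.ndarray,
    slice_range: SliceRange,
    trim_boundary: bool = True,
    inplane_box: tuple[tuple[int, int], tuple[int, int]] | None = None,
    lesion_voxels: np.ndarray | None = None,
) -> ROIMask:
    """Metacarpal-bone measurement mask inside the matched slice range.

    Bone voxels within the range; the three most distal and three most
    proximal slices are dropped when ``trim_boundary`` is set — unless
    implanted/known lesion voxels (``lesion_voxels``, an ``(n, 3)`` index
    array) touch a trimmed slab, in which case the trim is skipped with a
    warning. Connected components not anchored at the proximal face (e.g. a
    phalangeal stub drifting into the field) are removed; an optional
    in-plane bounding box restricts to one compartment.
    """
    if periosteal_mask.shape != volume.shape:
        raise ValueError("periosteal mask must match the volume grid")
    if not periosteal_mask.any():
        raise ValueError("empty periosteal mask")
    start, end = slice_range.start, slice_range.end
    provenance: dict = {"trimmed_slices": [], "removed_components": 0}

    if trim_boundary:
        if end - start < 2 * BOUNDARY_TRIM_SLICES + 1:
            raise CoLocalizationError(
                f"range of {end - start} slices leaves nothing after trimming "
                f"{BOUNDARY_TRIM_SLICES} slices per end"
            )
        trimmed = list(range(start, start + BOUNDARY_TRIM_SLICES)) + list(
            range(end - BOUNDARY_TRIM_SLICES, end)
        )
        if lesion_voxels is not None and len(lesion_voxels) and np.isin(
            np.asarray(lesion_voxels)[:, 0], trimmed
        ).any():
            warnings.warn(
                "lesions touch the boundary slab; keeping boundary slices",
                stacklevel=2,
            )
        else:
            start += BOUNDARY_TRIM_SLICES
            end -= BOUNDARY_TRIM_SLICES
            provenance["trimmed_slices"] = trimmed

    mask = np.zeros_like(periosteal_mask)
    mask[start:end] = periosteal_mask[start:end]
    if inplane_box is not None:
        (y0, y1), (x0, x1) = inplane_box
        box = np.zeros_like(mask)
        box[:, y0:y1, x0:x1] = True
        mask &= box
    if not mask.any():
        raise CoLocalizationError("no bone voxels inside the slice range")

    # keep components anchored at the proximal (high-index) face of the range
    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    anchored = np.unique(labels[end - 1])
    anchored = anchored[anchored > 0]
    if len(anchored) == 0:  # nothing proximally anchored: keep the largest
        sizes = ndimage.sum_labels(mask, labels, index=range(1, n_comp + 1))
        anchored = np.array([int(np.argmax(sizes)) + 1])
    keep = np.isin(labels, anchored)
    provenance["removed_components"] = int(n_comp - len(anchored))
    provenance["n_components_kept"] = int(len(anchored))
    return ROIMask(
        mask=keep,
        slice_range=SliceRange(start, end, slice_range.compartment),
        compartment=slice_range.compartment,
        provenance=provenance,
    )
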