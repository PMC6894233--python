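"""Digital metacarpal-head phantoms and cohort-level simulation.

The imaging phantom emulates what an XtremeCT scan of the second and third
metacarpal heads (MCH2/MCH3) looks like to the downstream pipeline: two
cortical-shell heads (hemispherical cap on a cylindrical shaft) in one grid
at 82 um isotropic voxels, with erosions carved through the cortex and
enthesiophytes added outside the periosteal surface, a known rigid motion
between time points, and additive Gaussian noise.

The cohort simulator is purely tabular: it draws per-lesion volume changes
from a progression / stable / regression mixture and per-patient DAPSA
trajectories and treatment flags, reproducing the statistical structure the
group comparisons assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import DEFAULT_VOXEL_MM, RigidTransform, Volume3D

__all__ = [
    "PhantomSpec",
    "GroundTruthLesion",
    "CohortSpec",
    "make_phantom",
    "implant_lesion",
    "make_followup",
    "simulate_cohort",
    "PhantomSizingError",
    "LesionCapacityError",
]

QUADRANTS = ("palmar", "ulnar", "dorsal", "radial")
COMPARTMENTS = ("MCH2", "MCH3")
CATEGORIES = ("progression", "stable", "regression")


class PhantomSizingError(ValueError):
    """The requested grid cannot contain the metacarpal-head geometry."""


class LesionCapacityError(ValueError):
    """The requested lesion volume exceeds the space available at its site."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise parameters of the digital phantom.

    Defaults give a 110-slice baseline stack at 0.082 mm isotropic spacing
    (9.02 mm axial extent) holding two heads of 2.0 mm outer radius with a
    0.35 mm cortical shell.
    """

    grid_shape: tuple[int, int, int] = (110, 80, 150)
    voxel_size_mm: float = DEFAULT_VOXEL_MM
    cortex_outer_radius_mm: float = 2.0
    cortex_thickness_mm: float = 0.35
    intensity_bone: float = 800.0
    intensity_trabecular: float = 300.0
    intensity_background: float = 50.0
    noise_sd: float = 0.0
    followup_slices: int = 322
    #: per-head scale on the outer radius; unequal heads (as in anatomy)
    #: also remove the two-fold symmetry an identical pair would create
    head_radius_scale: tuple[float, float] = (1.0, 0.82)
    #: Gaussian sigma (voxels) emulating the scanner's partial-volume blur;
    #: applied to the rendered tissue scene, not to implanted lesions
    edge_smoothing_vox: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        object.__setattr__(
            self, "head_radius_scale", tuple(float(s) for s in self.head_radius_scale)
        )
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if not 0 < self.cortex_thickness_mm <= self.cortex_outer_radius_mm:
            raise ValueError("cortex thickness must be in (0, outer radius]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def radius_vox(self) -> float:
        return self.cortex_outer_radius_mm / self.voxel_size_mm

    def head_centers_vox(self) -> np.ndarray:
        """Voxel centres of the MCH2 and MCH3 heads (cap apex distal)."""
        nz, ny, nx = self.grid_shape
        r = self.radius_vox
        z0 = r + 5.0  # cap apex ~5 slices in from the distal face
        return np.array(
            [[z0, ny / 2.0, nx * 0.28], [z0, ny / 2.0, nx * 0.72]], dtype=float
        )


@dataclass
class GroundTruthLesion:
    """One implanted erosion or enthesiophyte with exact voxel ground truth.

    ``mask_t0`` / ``mask_t5`` are ``(n, 3)`` voxel-index arrays in the
    baseline frame; true volumes are mask cardinality times the voxel
    volume, exactly.
    """

    lesion_id: int
    kind: str  # "erosion" | "enthesiophyte"
    compartment: str  # "MCH2" | "MCH3"
    quadrant: str
    center_vox: tuple[float, float, float]
    voxel_size_mm: float
    mask_t0: np.ndarray
    mask_t5: np.ndarray | None = None

    @property
    def volume_t0_mm3(self) -> float:
        return len(self.mask_t0) * self.voxel_size_mm**3

    @property
    def volume_t5_mm3(self) -> float | None:
        if self.mask_t5 is None:
            return None
        return len(self.mask_t5) * self.voxel_size_mm**3


# ---------------------------------------------------------------------------
# geometry


def _head_distance_vox(spec: PhantomSpec, n_slices: int) -> np.ndarray:
    """Per-voxel distance (in voxels) to each head axis/centre.

    Returns an array of shape ``(2,) + grid`` where entry h is the distance
    used against the outer radius: in-plane radial distance along the shaft
    (axial index >= cap centre) and 3-D distance inside the cap.
    """
    nz, ny, nx = n_slices, spec.grid_shape[1], spec.grid_shape[2]
    z = np.arange(nz, dtype=np.float32)[:, None, None]
    y = np.arange(ny, dtype=np.float32)[None, :, None]
    x = np.arange(nx, dtype=np.float32)[None, None, :]
    out = np.empty((2, nz, ny, nx), dtype=np.float32)
    for h, (z0, y0, x0) in enumerate(spec.head_centers_vox()):
        scale = spec.head_radius_scale[h]
        d_inplane = np.sqrt((y - y0) ** 2 + (x - x0) ** 2)
        d_cap = np.sqrt((z - z0) ** 2 + d_inplane**2)
        out[h] = np.where(z >= z0, d_inplane, d_cap) / scale
    return out


def _render_scene(spec: PhantomSpec, n_slices: int):
    """Noise-free intensity volume + periosteal / cortex masks."""
    r_out = spec.radius_vox
    r_in = (spec.cortex_outer_radius_mm - spec.cortex_thickness_mm) / spec.voxel_size_mm
    d = _head_distance_vox(spec, n_slices)
    periosteal = (d <= r_out).any(axis=0)
    interior = (d <= r_in).any(axis=0)
    cortex = periosteal & ~interior
    data = np.full(periosteal.shape, spec.intensity_background, dtype=np.float32)
    data[interior] = spec.intensity_trabecular
    data[cortex] = spec.intensity_bone
    if spec.edge_smoothing_vox > 0:
        data = ndimage.gaussian_filter(data, spec.edge_smoothing_vox)
    return data, periosteal, cortex


def make_phantom(spec: PhantomSpec) -> tuple[Volume3D, np.ndarray]:
    """Render the baseline phantom and its ground-truth periosteal mask.

    Returns
    -------
    volume:
        Baseline :class:`Volume3D` (axial axis 0, ``index * spacing``
        physical convention, Gaussian noise of ``spec.noise_sd`` added).
    periosteal_mask:
        Boolean array of voxels at or inside the cortical outer surface.
    """
    nz, ny, nx = spec.grid_shape
    r = spec.radius_vox
    for z0, y0, x0 in spec.head_centers_vox():
        if y0 - r < 0 or y0 + r >= ny or x0 - r < 0 or x0 + r >= nx or z0 >= nz:
            raise PhantomSizingError(
                f"grid {spec.grid_shape} too small for head radius "
                f"{spec.cortex_outer_radius_mm} mm"
            )
    data, periosteal, _ = _render_scene(spec, nz)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, data.shape).astype(np.float32)
    vol = Volume3D(data, spacing_mm=(spec.voxel_size_mm,) * 3, frame="baseline")
    return vol, periosteal


def _quadrant_of(center: np.ndarray, head_center: np.ndarray) -> str:
    dy = center[1] - head_center[1]
    dx = center[2] - head_center[2]
    if abs(dy) >= abs(dx):
        return "palmar" if dy >= 0 else "dorsal"
    return "radial" if dx >= 0 else "ulnar"


def _nearest_head(spec: PhantomSpec, center: np.ndarray) -> int:
    centers = spec.head_centers_vox()
    d = np.linalg.norm(centers[:, 1:] - np.asarray(center, dtype=float)[1:], axis=1)
    return int(np.argmin(d))


def _select_lesion_voxels(
    admissible_local: np.ndarray, center_local: np.ndarray, n_target: int
) -> np.ndarray:
    """Pick exactly ``n_target`` admissible voxels nearest the centre.

    Distance-ordered selection with a deterministic (z, y, x) tie-break;
    growing a quasi-spherical blob this way meets any integer voxel count
    exactly, which radius bisection cannot at count discontinuities.
    """
    coords = np.argwhere(admissible_local)
    if len(coords) < n_target:
        raise LesionCapacityError(
            f"only {len(coords)} admissible voxels for target of {n_target}"
        )
    d2 = ((coords - center_local) ** 2).sum(axis=1)
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], d2))
    return coords[order[:n_target]]


def implant_lesion(
    volume: Volume3D,
    periosteal_mask: np.ndarray,
    kind: str,
    center_vox: tuple[float, float, float],
    target_volume_mm3: float,
    spec: PhantomSpec,
    lesion_id: int = 0,
    cortex_mask: np.ndarray | None = None,
) -> tuple[Volume3D, GroundTruthLesion]:
    """Carve an erosion or add an enthesiophyte of known volume.

    The achieved true volume is ``round(target / voxel_volume)`` voxels, so
    it differs from the target by at most half a voxel volume. Erosions are
    carved to background intensity inside the periosteal surface and must
    break the cortex on at least two consecutive axial slices;
    enthesiophytes add bone-intensity voxels strictly outside the original
    periosteal surface.
    """
    if kind not in ("erosion", "enthesiophyte"):
        raise ValueError(f"unknown lesion kind {kind!r}")
    if target_volume_mm3 <= 0:
        raise ValueError("target_volume_mm3 must be positive")
    voxvol = volume.voxel_volume_mm3
    n_target = max(1, int(round(target_volume_mm3 / voxvol)))
    center = np.asarray(center_vox, dtype=float)

    if cortex_mask is None:
        _, _, cortex_mask = _render_scene(spec, volume.shape[0])

    # local window: generous radius for a half-space blob of n_target voxels
    r_est = (3.0 * n_target / (4.0 * np.pi)) ** (1.0 / 3.0)
    w = int(np.ceil(2.5 * r_est + 4))
    lo = np.maximum(np.round(center).astype(int) - w, 0)
    hi = np.minimum(np.round(center).astype(int) + w + 1, volume.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    admissible = periosteal_mask[sl] if kind == "erosion" else ~periosteal_mask[sl]

    inside = periosteal_mask[tuple(np.round(center).astype(int))]
    if kind == "erosion" and not inside:
        raise ValueError("erosion centre must lie on/inside the periosteal surface")
    if kind == "enthesiophyte" and inside:
        raise ValueError("enthesiophyte centre must lie outside the periosteal surface")

    coords_local = _select_lesion_voxels(admissible, center - lo, n_target)
    coords = coords_local + lo

    data = volume.data.copy()
    if kind == "erosion":
        data[tuple(coords.T)] = spec.intensity_background
        slices_with_break = np.unique(
            coords[cortex_mask[tuple(coords.T)], 0]
        )
        if not _has_consecutive_pair(slices_with_break):
            raise ValueError(
                "erosion does not break the cortex on >=2 consecutive axial "
                "slices; increase target volume or move the centre onto the cortex"
            )
    else:
        data[tuple(coords.T)] = spec.intensity_bone

    head = _nearest_head(spec, center)
    lesion = GroundTruthLesion(
        lesion_id=lesion_id,
        kind=kind,
        compartment=COMPARTMENTS[head],
        quadrant=_quadrant_of(center, spec.head_centers_vox()[head]),
        center_vox=tuple(center),
        voxel_size_mm=spec.voxel_size_mm,
        mask_t0=coords,
    )
    return volume.with_data(data), lesion


def _has_consecutive_pair(slices: np.ndarray) -> bool:
    return len(slices) >= 2 and bool(np.any(np.diff(np.sort(slices)) == 1))


def make_followup(
    spec: PhantomSpec,
    lesions: list[GroundTruthLesion],
    motion: RigidTransform,
    volume_deltas_mm3: dict[int, float],
    noise_sd: float | None = None,
    followup_slices: int | None = None,
    seed: int | None = None,
) -> tuple[Volume3D, list[GroundTruthLesion], Volume3D]:
    """Render the follow-up scan: grown/shrunk lesions in a moved frame.

    The time-5 scene is first built in the baseline frame on an extended
    axial grid (the follow-up stack is longer than the baseline slab, shaft
    only beyond it) with each lesion re-implanted at its baseline centre at
    target volume ``t0 + delta``; ground-truth time-5 masks and volumes are
    therefore exact in the baseline frame, where all measurement happens.
    The follow-up volume samples this scene through ``motion`` (a
    follow-up-to-baseline transform) with trilinear interpolation, then adds
    noise.

    Returns ``(followup_volume, updated_lesions, t5_baseline_frame)``.
    """
    n_fu = spec.followup_slices if followup_slices is None else followup_slices
    noise = spec.noise_sd if noise_sd is None else noise_sd
    data, periosteal, cortex = _render_scene(spec, n_fu)
    t5 = Volume3D(data, spacing_mm=(spec.voxel_size_mm,) * 3, frame="baseline")
    updated: list[GroundTruthLesion] = []
    for les in lesions:
        delta = float(volume_deltas_mm3.get(les.lesion_id, 0.0))
        target = les.volume_t0_mm3 + delta
        if target < 0:
            raise ValueError(f"lesion {les.lesion_id}: delta drives volume below 0")
        if target == 0:
            mask_t5 = np.empty((0, 3), dtype=int)
        else:
            t5, les5 = implant_lesion(
                t5, periosteal, les.kind, les.center_vox, target, spec,
                lesion_id=les.lesion_id, cortex_mask=cortex,
            )
            mask_t5 = les5.mask_t0
        les.mask_t5 = mask_t5
        updated.append(les)

    # sample the baseline-frame scene at follow-up grid points through
    # motion; float64 so identity motion lands exactly on grid nodes
    idx = np.indices((n_fu,) + spec.grid_shape[1:], dtype=np.float64)
    pts_mm = idx.reshape(3, -1).T * spec.voxel_size_mm
    src_idx = (motion.apply(pts_mm) / spec.voxel_size_mm).T
    fu = ndimage.map_coordinates(
        t5.data, src_idx, order=1, mode="constant",
        cval=spec.intensity_background,
    ).reshape((n_fu,) + spec.grid_shape[1:])
    if noise > 0:
        rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
        fu = fu + rng.normal(0.0, noise, fu.shape).astype(np.float32)
    fu_vol = Volume3D(fu, spacing_mm=(spec.voxel_size_mm,) * 3, frame="followup")
    return fu_vol, updated, t5


# ---------------------------------------------------------------------------
# cohort simulation

#: per-class (mean, SD) of 5-year volume change in mm^3
DEFAULT_CLASS_DELTAS = {
    "erosion": {
        "progression": (1.9, 1.8),
        "stable": (0.1, 0.2),
        "regression": (-1.4, 0.5),
    },
    "enthesiophyte": {
        "progression": (1.0, 0.6),
        "stable": (0.1, 0.1),
        "regression": (-0.7, 0.4),
    },
}

#: mixture over (progression, stable, regression) for pre-existing lesions
DEFAULT_WEIGHTS = {
    "erosion": (34 / 108, 64 / 108, 10 / 108),
    "enthesiophyte": (50 / 99, 38 / 99, 11 / 99),
}

#: SDL-group progression proportions (stable/regression remainder keeps the
#: overall stable:regression ratio per kind)
DEFAULT_SDL_WEIGHTS = {
    "erosion": (12 / 51, (1 - 12 / 51) * 64 / 74, (1 - 12 / 51) * 10 / 74),
    "enthesiophyte": (17 / 40, (1 - 17 / 40) * 38 / 49, (1 - 17 / 40) * 11 / 49),
}
DEFAULT_NONSDL_WEIGHTS = {
    "erosion": (25 / 60, (1 - 25 / 60) * 64 / 74, (1 - 25 / 60) * 10 / 74),
    "enthesiophyte": (33 / 59, (1 - 33 / 59) * 38 / 49, (1 - 33 / 59) * 11 / 49),
}


@dataclass(frozen=True)
class CohortSpec:
    """Statistical structure of a simulated 5-year cohort.

    Defaults reproduce the study conditions: 60 patients, 108 erosions and
    99 enthesiophytes expected at baseline, 3 expected new erosions, class
    mixtures and per-class change distributions per kind, group-specific
    progression rates for sustained-low-disease-activity (SDL) patients,
    43.3% SDL prevalence and 23.3% TNF-inhibitor-throughout exposure.
    """

    n_patients: int = 60
    lesion_rate: dict = field(
        default_factory=lambda: {"erosion": 108 / 60, "enthesiophyte": 99 / 60}
    )
    new_lesion_rate: dict = field(
        default_factory=lambda: {"erosion": 3 / 60, "enthesiophyte": 0.0}
    )
    mixture_weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    sdl_mixture_weights: dict | None = field(
        default_factory=lambda: dict(DEFAULT_SDL_WEIGHTS)
    )
    nonsdl_mixture_weights: dict | None = field(
        default_factory=lambda: dict(DEFAULT_NONSDL_WEIGHTS)
    )
    class_deltas: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_DELTAS))
    baseline_volume: dict = field(
        default_factory=lambda: {"erosion": (4.2, 4.2), "enthesiophyte": (3.4, 2.3)}
    )
    new_lesion_volume: tuple[float, float] = (1.0, 0.5)
    reading_noise_sd: float = 0.05
    p_sdl: float = 26 / 60
    p_tnfi: float = 14 / 60
    seed: int = 0

    def __post_init__(self) -> None:
        for kind, w in self.mixture_weights.items():
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(f"mixture weights for {kind} must sum to 1")
        for kind, params in self.class_deltas.items():
            for cat, (_, sd) in params.items():
                if sd < 0:
                    raise ValueError(f"{kind}/{cat}: SD must be >= 0")


def _truncated_normal(rng, mean, sd, lower, size=None):
    x = rng.normal(mean, sd, size)
    return np.maximum(x, lower)


def _dapsa_components(score: float) -> dict:
    """Decompose a target DAPSA score into plausible components.

    TJC/SJC are integers; the rounding residue is absorbed into the pain
    VAS (or CRP when the VAS would exceed its 10 cm range) so the component
    sum reproduces the score exactly.
    """
    crp = min(0.10 * score, 4.0)
    pain = min(0.25 * score, 10.0)
    glob = min(0.25 * score, 10.0)
    rest = score - crp - pain - glob
    tjc = int(np.floor(rest * 0.6))
    sjc = int(np.floor(rest * 0.4))
    resid = rest - tjc - sjc
    if pain + resid <= 10.0:
        pain += resid
    else:
        crp += resid
    return {
        "tender_joint_count": tjc,
        "swollen_joint_count": sjc,
        "patient_pain_vas_cm": pain,
        "patient_global_vas_cm": glob,
        "crp_mg_dl": crp,
    }


def _draw_dapsa_pair(rng, sdl: bool) -> tuple[float, float]:
    if sdl:
        return (
            float(np.clip(rng.normal(8.0, 3.5), 0.5, 14.0)),
            float(np.clip(rng.normal(8.0, 3.5), 0.5, 14.0)),
        )
    while True:  # at least one time point above the LDA cut
        t0 = float(max(rng.normal(16.0, 6.0), 0.5))
        t5 = float(max(rng.normal(13.0, 6.0), 0.5))
        if t0 > 14.0 or t5 > 14.0:
            return t0, t5


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a per-lesion change table and a per-patient clinical table.

    Each pre-existing lesion's true class comes from the (group-specific)
    mixture; its true change from the class normal law, truncated so
    follow-up volume stays non-negative; observed change adds reading noise.
    New erosions appear at the configured per-patient rate with baseline
    volume 0 and are progressions by definition.
    """
    rng = np.random.default_rng(spec.seed)
    lesion_rows, patient_rows = [], []
    lesion_id = 0
    for pid in range(spec.n_patients):
        sdl = bool(rng.random() < spec.p_sdl)
        tnfi = bool(rng.random() < spec.p_tnfi)
        d0, d5 = _draw_dapsa_pair(rng, sdl)
        comp0, comp5 = _dapsa_components(d0), _dapsa_components(d5)
        patient_rows.append(
            {
                "patient_id": pid,
                "dapsa_t0": d0,
                "dapsa_t5": d5,
                **{f"{k}_t0": v for k, v in comp0.items()},
                **{f"{k}_t5": v for k, v in comp5.items()},
                "tnfi_throughout": tnfi,
            }
        )
        for kind in ("erosion", "enthesiophyte"):
            weights = spec.mixture_weights[kind]
            if sdl and spec.sdl_mixture_weights is not None:
                weights = spec.sdl_mixture_weights[kind]
            elif not sdl and spec.nonsdl_mixture_weights is not None:
                weights = spec.nonsdl_mixture_weights[kind]
            n_existing = rng.poisson(spec.lesion_rate[kind])
            n_new = rng.poisson(spec.new_lesion_rate[kind])
            for _ in range(n_existing):
                cat = CATEGORIES[rng.choice(3, p=np.asarray(weights) / sum(weights))]
                v0 = float(
                    _truncated_normal(rng, *spec.baseline_volume[kind], 0.1)
                )
                mu, sd = spec.class_deltas[kind][cat]
                true_delta = float(max(rng.normal(mu, sd), -v0))
                obs_delta = true_delta + float(
                    rng.normal(0.0, spec.reading_noise_sd)
                )
                lesion_rows.append(
                    {
                        "lesion_id": lesion_id,
                        "patient_id": pid,
                        "kind": kind,
                        "compartment": COMPARTMENTS[int(rng.random() < 0.5)],
                        "quadrant": QUADRANTS[rng.integers(4)],
                        "vol_t0_mm3": v0,
                        "vol_t5_mm3": v0 + true_delta,
                        "true_class": cat,
                        "true_delta_mm3": true_delta,
                        "delta_mm3": obs_delta,
                        "is_new": False,
                    }
                )
                lesion_id += 1
            for _ in range(n_new):
                v5 = float(_truncated_normal(rng, *spec.new_lesion_volume, 0.1))
                lesion_rows.append(
                    {
                        "lesion_id": lesion_id,
                        "patient_id": pid,
                        "kind": kind,
                        "compartment": COMPARTMENTS[int(rng.random() < 0.5)],
                        "quadrant": QUADRANTS[rng.integers(4)],
                        "vol_t0_mm3": 0.0,
                        "vol_t5_mm3": v5,
                        "true_class": "progression",
                        "true_delta_mm3": v5,
                        "delta_mm3": v5,
                        "is_new": True,
                    }
                )
                lesion_id += 1
    lesions = pd.DataFrame(lesion_rows)
    patients = pd.DataFrame(patient_rows)
    return lesions, patients
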