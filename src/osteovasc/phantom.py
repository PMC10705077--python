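"""Synthetic tibia-like phantoms with known ground truth.

The generator emulates the imaging situation of contrast-enhanced µCT of a
metastatic long bone: a tapered cortical shell with trabecular rods, tortuous
contrast-filled vessel branches that may tunnel through bone, and metastatic
lesions that are visible *only* as missing bone — lesion voxels carry no
intrinsic contrast and are rendered with marrow-like intensity.  Every phantom
comes with exact ground truth (class counts, per-branch vessel radii, lesion
geometry), so each downstream measurement can be verified without real scans.

Label precedence where primitives overlap is metastasis > vessel > bone:
lesions erode bone (and anything inside them), vessels tunnel through bone.
A metastasis voxel is a voxel where bone existed before lesion erosion; the
part of a lesion ellipsoid that falls in marrow is indistinguishable from
marrow by construction, which is exactly the missing-bone signature
a segmenter has to work with.

Cohorts replicate a two-time-point, four-treatment-arm design; a group effect
can multiply vessel radii within a stated distance of the lesions (an
anti-angiogenic treatment acting locally), offset the lesion count, or scale
the cortical wall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .morphometry import _edt_um, fill_tube
from .volume import BACKGROUND, BONE, METASTASIS, VESSEL, IntensityVolume, LabelVolume, _check_voxel_size

__all__ = [
    "ShellSpec",
    "TrabeculaeSpec",
    "VesselSpec",
    "MetastasisSpec",
    "RenderSpec",
    "PhantomSpec",
    "PhantomGroundTruth",
    "GroupEffect",
    "CohortSpec",
    "CohortSample",
    "generate_labels",
    "render_intensity",
    "generate_cohort",
    "voxelize_sphere",
    "voxelize_ellipsoid",
    "voxelize_capsule",
    "fill_tube",
]


# ---------------------------------------------------------------------------
# specs


@dataclass
class ShellSpec:
    """Cortical tube: outer radius and wall thickness in µm, with a linear
    axial taper (fractional outer-radius reduction from the first to the last
    slice)."""

    outer_radius_um: float = 90.0
    wall_thickness_um: float = 25.0
    taper: float = 0.12


@dataclass
class TrabeculaeSpec:
    rod_count: int = 10
    rod_radius_um: float = 6.0


@dataclass
class VesselSpec:
    """Vessel tree parameters: piecewise-linear random-walk branches swept
    with a circular cross-section.  ``tortuosity`` is the relative direction
    perturbation per step (0 = straight)."""

    branch_count: int = 8
    radius_range_um: tuple[float, float] = (7.0, 12.0)
    tortuosity: float = 0.35
    min_length_um: float = 120.0


@dataclass
class MetastasisSpec:
    lesion_count: int = 2
    semi_axis_range_um: tuple[float, float] = (18.0, 38.0)
    max_retries: int = 10


@dataclass
class RenderSpec:
    """Intensity model.  Means emulate SR-µCT attenuation: background <
    metastasis ≈ marrow < bone, with contrast-filled vessels separable from
    bone (default above bone; the ordering is configurable).  Blur emulates
    the partial-volume effect and is applied before additive Gaussian noise."""

    background_mean: float = 0.10
    marrow_mean: float = 0.35
    bone_mean: float = 0.65
    vessel_mean: float = 0.90
    blur_um: float = 2.0
    noise_sd: float = 0.02


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_um: tuple[float, float, float] = (3.5, 3.5, 3.5)
    shell: ShellSpec = field(default_factory=ShellSpec)
    trabeculae: TrabeculaeSpec = field(default_factory=TrabeculaeSpec)
    vessels: VesselSpec = field(default_factory=VesselSpec)
    metastases: MetastasisSpec = field(default_factory=MetastasisSpec)
    render: RenderSpec = field(default_factory=RenderSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in np.broadcast_to(self.grid_shape, (3,)))
        self.voxel_size_um = _check_voxel_size(self.voxel_size_um)
        self.validate()

    def validate(self) -> None:
        if any(s < 8 for s in self.grid_shape):
            raise ValueError(f"degenerate grid {self.grid_shape}: need >= 8 voxels per axis")
        sh, ves, met, rnd = self.shell, self.vessels, self.metastases, self.render
        for name, v in [
            ("outer radius", sh.outer_radius_um),
            ("wall thickness", sh.wall_thickness_um),
            ("rod radius", self.trabeculae.rod_radius_um),
            ("min branch length", ves.min_length_um),
        ]:
            if v <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 <= sh.taper < 1:
            raise ValueError("taper must be in [0, 1)")
        if sh.wall_thickness_um >= sh.outer_radius_um:
            raise ValueError("wall thickness must be below the outer radius")
        rmin, rmax = ves.radius_range_um
        if not 0 < rmin <= rmax:
            raise ValueError("vessel radius range must satisfy 0 < min <= max")
        # vessels must fit inside the solid tube (marrow radius + wall)
        if rmax >= sh.outer_radius_um:
            raise ValueError("vessel radii must be below the shell outer radius")
        amin, amax = met.semi_axis_range_um
        if not 0 < amin <= amax:
            raise ValueError("lesion semi-axis range must satisfy 0 < min <= max")
        if amax >= sh.outer_radius_um:
            raise ValueError("lesion semi-axes must be below the shell outer radius")
        if met.lesion_count < 0 or ves.branch_count < 0 or self.trabeculae.rod_count < 0:
            raise ValueError("primitive counts must be non-negative")
        if not (rnd.background_mean < rnd.marrow_mean < min(rnd.bone_mean, rnd.vessel_mean)):
            raise ValueError(
                "intensity means must satisfy background < marrow < bone, vessel"
            )
        if rnd.bone_mean == rnd.vessel_mean:
            raise ValueError("bone and vessel means must be separable (unequal)")
        if rnd.blur_um < 0 or rnd.noise_sd < 0:
            raise ValueError("blur and noise must be non-negative")


@dataclass
class PhantomGroundTruth:
    """Exact generation record for one phantom."""

    class_counts: dict[int, int]
    analytic_volumes_um3: dict[str, float]
    branch_radii_um: list[float]
    segments: list[dict]  # branch, base/effective radius, in_effect flag
    lesions: list[dict]  # center_um, semi_axes_um
    branch_id_map: np.ndarray | None = None
    effect: dict | None = None

    def mean_radius_um(self, in_effect: bool | None = None) -> float:
        """Length-weighted mean effective branch radius, optionally restricted
        to segments inside / outside the group-effect region."""
        segs = [
            s for s in self.segments
            if in_effect is None or s["in_effect"] == in_effect
        ]
        if not segs:
            raise ValueError("no matching segments")
        w = np.array([s["length_um"] for s in segs])
        r = np.array([s["radius_um"] for s in segs])
        return float((w * r).sum() / w.sum())


@dataclass
class GroupEffect:
    """Treatment-arm effect descriptor for cohort generation."""

    label: str
    n_samples: int
    vessel_radius_factor: float = 1.0
    effect_distance_um: float = 700.0
    lesion_count_offset: int = 0
    wall_scale: float = 1.0


@dataclass
class CohortSpec:
    groups: list[GroupEffect]
    base: PhantomSpec = field(default_factory=PhantomSpec)
    time_point: str = "T2"
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        rmin = self.base.vessels.radius_range_um[0]
        h_min = min(self.base.voxel_size_um)
        for g in self.groups:
            if g.n_samples < 2:
                raise ValueError(f"group {g.label!r}: need n_samples >= 2")
            if not 0 < g.vessel_radius_factor <= 2:
                raise ValueError(f"group {g.label!r}: radius factor must be in (0, 2]")
            if g.vessel_radius_factor * rmin < h_min:
                raise ValueError(
                    f"group {g.label!r}: factor {g.vessel_radius_factor} yields sub-voxel "
                    f"vessel radii ({g.vessel_radius_factor * rmin:.2f} µm < voxel {h_min} µm)"
                )


@dataclass
class CohortSample:
    sample_id: str
    group: str
    time_point: str
    labels: LabelVolume
    truth: PhantomGroundTruth
    spec: PhantomSpec | None = None  # the per-sample spec (carries the sample seed)


# ---------------------------------------------------------------------------
# primitive voxelizers (voxel-center-in-shape tests, physical units)


def _grids_um(shape, voxel_size_um):
    h = np.broadcast_to(np.asarray(voxel_size_um, float), (3,))
    return [np.arange(n) * hi for n, hi in zip(shape, h)]


def voxelize_sphere(shape, voxel_size_um, center_um, radius_um) -> np.ndarray:
    """Mask of voxels whose centers lie within a sphere (physical units)."""
    z, y, x = _grids_um(shape, voxel_size_um)
    c = np.asarray(center_um, float)
    d2 = (
        (z[:, None, None] - c[0]) ** 2
        + (y[None, :, None] - c[1]) ** 2
        + (x[None, None, :] - c[2]) ** 2
    )
    return d2 <= radius_um**2


def voxelize_ellipsoid(shape, voxel_size_um, center_um, semi_axes_um) -> np.ndarray:
    z, y, x = _grids_um(shape, voxel_size_um)
    c = np.asarray(center_um, float)
    a = np.asarray(semi_axes_um, float)
    q = (
        ((z[:, None, None] - c[0]) / a[0]) ** 2
        + ((y[None, :, None] - c[1]) / a[1]) ** 2
        + ((x[None, None, :] - c[2]) / a[2]) ** 2
    )
    return q <= 1.0


def voxelize_capsule(shape, voxel_size_um, p0_um, p1_um, radius_um, out=None, value=True) -> np.ndarray:
    """Paint a capsule (cylinder with hemispherical caps) into a boolean mask.

    Only the bounding box of the capsule is evaluated, so repeated calls for
    many short segments stay cheap.
    """
    h = np.broadcast_to(np.asarray(voxel_size_um, float), (3,))
    p0 = np.asarray(p0_um, float)
    p1 = np.asarray(p1_um, float)
    if out is None:
        out = np.zeros(shape, bool)
    # long oblique segments would evaluate a huge bounding box; split them
    seg_len = float(np.linalg.norm(p1 - p0))
    if seg_len > 16.0 * float(h.min()):
        mid = 0.5 * (p0 + p1)
        voxelize_capsule(shape, h, p0, mid, radius_um, out=out)
        voxelize_capsule(shape, h, mid, p1, radius_um, out=out)
        return out
    lo = np.maximum(np.floor((np.minimum(p0, p1) - radius_um) / h).astype(int), 0)
    hi = np.minimum(np.ceil((np.maximum(p0, p1) + radius_um) / h).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return out
    axes = [np.arange(lo[i], hi[i]) * h[i] for i in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)  # (bz,by,bx,3)
    d = p1 - p0
    dd = float(d @ d)
    if dd == 0:
        t = np.zeros(pts.shape[:-1])
    else:
        t = np.clip(((pts - p0) @ d) / dd, 0.0, 1.0)
    nearest = p0 + t[..., None] * d
    inside = ((pts - nearest) ** 2).sum(axis=-1) <= radius_um**2
    sub = tuple(slice(lo[i], hi[i]) for i in range(3))
    out[sub] |= inside if value else False
    return out




# ---------------------------------------------------------------------------
# label generation


def _shell_masks(spec: PhantomSpec):
    """Bone shell and solid-tube masks plus per-slice outer/inner radii."""
    nz, ny, nx = spec.grid_shape
    hz, hy, hx = spec.voxel_size_um
    cy, cx = (ny - 1) / 2 * hy, (nx - 1) / 2 * hx
    y = np.arange(ny) * hy - cy
    x = np.arange(nx) * hx - cx
    rho2 = (y[:, None] ** 2 + x[None, :] ** 2)[None, :, :]
    zfrac = np.arange(nz) / max(nz - 1, 1)
    outer = spec.shell.outer_radius_um * (1.0 - spec.shell.taper * zfrac)
    inner = np.maximum(outer - spec.shell.wall_thickness_um, 0.0)
    outer3 = outer[:, None, None]
    inner3 = inner[:, None, None]
    solid = rho2 <= outer3**2
    shell = solid & (rho2 >= inner3**2)
    return shell, solid, outer, inner, (cy, cx)


def _analytic_shell_volume(spec: PhantomSpec) -> float:
    # ∫ π (outer(z)² − inner(z)²) dz over the grid's physical z extent
    nz = spec.grid_shape[0]
    hz = spec.voxel_size_um[0]
    zfrac = np.linspace(0, 1, 512)
    outer = spec.shell.outer_radius_um * (1 - spec.shell.taper * zfrac)
    inner = np.maximum(outer - spec.shell.wall_thickness_um, 0.0)
    return float(np.trapezoid(math.pi * (outer**2 - inner**2), zfrac) * (nz - 1) * hz)


def _random_unit(rng) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
    return v / n


def generate_labels(
    spec: PhantomSpec, effect: GroupEffect | None = None
) -> tuple[LabelVolume, PhantomGroundTruth]:
    """Generate a labeled phantom and its exact ground truth.

    Deterministic for a fixed ``spec.seed``.  When ``effect`` is given, branch
    radii are multiplied by ``effect.vessel_radius_factor`` for segments whose
    midpoint lies within ``effect.effect_distance_um`` of the metastasis
    compartment (the locally acting anti-angiogenic treatment of group C).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    h = np.asarray(spec.voxel_size_um, float)
    h_min = float(h.min())
    extent = (np.asarray(shape) - 1) * h

    shell, solid, outer_r, inner_r, (cy, cx) = _shell_masks(spec)

    # trabecular rods: thin capsules spanning the marrow, clipped to the tube
    rods = np.zeros(shape, bool)
    for _ in range(spec.trabeculae.rod_count):
        z0, z1 = rng.uniform(0, extent[0], size=2)
        ang0, ang1 = rng.uniform(0, 2 * math.pi, size=2)
        rad0, rad1 = rng.uniform(0, 0.9 * spec.shell.outer_radius_um, size=2)
        p0 = np.array([z0, cy + rad0 * math.sin(ang0), cx + rad0 * math.cos(ang0)])
        p1 = np.array([z1, cy + rad1 * math.sin(ang1), cx + rad1 * math.cos(ang1)])
        voxelize_capsule(shape, h, p0, p1, spec.trabeculae.rod_radius_um, out=rods)
    bone_pristine = shell | (rods & solid)

    # metastatic lesions: ellipsoids centered on bone voxels; only the eroded
    # bone is labeled metastasis (missing-bone signature)
    met = np.zeros(shape, bool)
    lesions: list[dict] = []
    n_lesions = spec.metastases.lesion_count + (effect.lesion_count_offset if effect else 0)
    if n_lesions > 0 and not bone_pristine.any():
        raise ValueError("cannot place lesions: phantom has no bone")
    bone_idx = np.argwhere(bone_pristine) if n_lesions > 0 else None
    amin, amax = spec.metastases.semi_axis_range_um
    for _ in range(max(n_lesions, 0)):
        for _attempt in range(spec.metastases.max_retries):
            center = bone_idx[rng.integers(len(bone_idx))] * h
            semi = rng.uniform(amin, amax, size=3)
            eroded = voxelize_ellipsoid(shape, h, center, semi) & bone_pristine
            if eroded.any():
                met |= eroded
                lesions.append({"center_um": center.tolist(), "semi_axes_um": semi.tolist()})
                break
        else:  # pragma: no cover - center-on-bone placement always intersects bone
            raise RuntimeError(
                f"lesion placement failed after {spec.metastases.max_retries} retries"
            )

    # region where the treatment effect modulates vessel radii
    eff_region = None
    factor = 1.0
    if effect is not None and effect.vessel_radius_factor != 1.0 and met.any():
        factor = effect.vessel_radius_factor
        eff_region = _edt_um(met, h) < effect.effect_distance_um

    # vessel branches: random walks swept with circular cross-section
    vessel = np.zeros(shape, bool)
    branch_id = np.full(shape, -1, dtype=np.int16)
    branch_radii: list[float] = []
    segments: list[dict] = []
    rmin, rmax = spec.vessels.radius_range_um
    step = max(2.0 * h_min, rmin)
    for b in range(spec.vessels.branch_count):
        base_r = float(rng.uniform(rmin, rmax))
        branch_radii.append(base_r)
        z0 = rng.uniform(0.05, 0.95) * extent[0]
        iz = min(int(round(z0 / h[0])), shape[0] - 1)
        rad = rng.uniform(0, max(inner_r[iz] - base_r, 1.0))
        ang = rng.uniform(0, 2 * math.pi)
        pos = np.array([z0, cy + rad * math.sin(ang), cx + rad * math.cos(ang)])
        dirn = _random_unit(rng)
        target_len = spec.vessels.min_length_um * (1.0 + rng.uniform(0, 1))
        length = 0.0
        bmask = np.zeros(shape, bool)
        while length < target_len:
            dirn = dirn + spec.vessels.tortuosity * rng.standard_normal(3)
            dirn /= np.linalg.norm(dirn)
            nxt = pos + step * dirn
            # keep the centerline inside the tapered tube and the z range
            if not 0.0 <= nxt[0] <= extent[0]:
                if length >= spec.vessels.min_length_um:
                    break
                dirn[0] = -dirn[0]
                nxt = pos + step * dirn
                nxt[0] = np.clip(nxt[0], 0.0, extent[0])
            izn = int(np.clip(round(nxt[0] / h[0]), 0, shape[0] - 1))
            r_allow = max(outer_r[izn] - base_r - h_min, 1.0)
            radial = nxt[1:] - (cy, cx)
            rho = np.linalg.norm(radial)
            if rho > r_allow:
                radial *= r_allow / rho
                nxt[1:] = (cy, cx) + radial
                dirn = _random_unit(rng)  # re-aim after hitting the cortex
            mid = 0.5 * (pos + nxt)
            idx = tuple(np.clip(np.round(mid / h).astype(int), 0, np.asarray(shape) - 1))
            in_eff = bool(eff_region[idx]) if eff_region is not None else False
            r_eff = base_r * factor if in_eff else base_r
            voxelize_capsule(shape, h, pos, nxt, r_eff, out=bmask)
            seg_len = float(np.linalg.norm(nxt - pos))
            segments.append(
                {
                    "branch": b,
                    "base_radius_um": base_r,
                    "radius_um": r_eff,
                    "in_effect": in_eff,
                    "length_um": seg_len,
                }
            )
            length += seg_len
            pos = nxt
        branch_id[bmask & (branch_id == -1)] = b
        vessel |= bmask

    labels = np.zeros(shape, dtype=np.uint8)
    labels[bone_pristine] = BONE
    labels[vessel] = VESSEL
    labels[met] = METASTASIS

    analytic = {
        "shell_um3": _analytic_shell_volume(spec),
        "lesions_um3": [4 / 3 * math.pi * float(np.prod(l["semi_axes_um"])) for l in lesions],
        "vessel_centerline_um3": sum(
            math.pi * s["radius_um"] ** 2 * s["length_um"] for s in segments
        ),
    }
    vol = LabelVolume(labels, tuple(h))
    truth = PhantomGroundTruth(
        class_counts=vol.class_counts(),
        analytic_volumes_um3=analytic,
        branch_radii_um=branch_radii,
        segments=segments,
        lesions=lesions,
        branch_id_map=branch_id,
        effect=(
            {
                "label": effect.label,
                "vessel_radius_factor": effect.vessel_radius_factor,
                "effect_distance_um": effect.effect_distance_um,
            }
            if effect
            else None
        ),
    )
    return vol, truth


def render_intensity(labels: LabelVolume, spec: PhantomSpec) -> IntensityVolume:
    """Render a grayscale volume from labels.

    Metastasis voxels receive the *marrow* mean — lesions contribute no
    contrast of their own and are visible only as missing bone.  Gaussian blur
    (partial-volume emulation) is applied before additive Gaussian noise.
    Deterministic for a fixed ``spec.seed``.
    """
    rnd = spec.render
    data = labels.data
    img = np.full(labels.shape, rnd.background_mean, dtype=np.float64)
    # marrow: interior of the bone envelope not occupied by any compartment
    # (lesions keep the envelope watertight — their voxels are labeled, not
    # carved out — so plain capped hole filling recovers the canal)
    env = fill_tube(data > 0)
    img[env & (data == BACKGROUND)] = rnd.marrow_mean
    img[data == METASTASIS] = rnd.marrow_mean  # no intrinsic metastasis contrast
    img[data == BONE] = rnd.bone_mean
    img[data == VESSEL] = rnd.vessel_mean
    if rnd.blur_um > 0:
        sigma = [rnd.blur_um / hi for hi in labels.voxel_size_um]
        img = ndi.gaussian_filter(img, sigma=sigma)
    if rnd.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 7919)
        img = img + rnd.noise_sd * rng.standard_normal(img.shape)
    return IntensityVolume(img, labels.voxel_size_um)


def generate_cohort(cohort: CohortSpec) -> list[CohortSample]:
    """Generate every sample of a cohort with group effects applied.

    Per-sample seeds are derived from ``(cohort.seed, global sample index)``
    so any single sample is reproducible in isolation.
    """
    cohort.validate()
    samples: list[CohortSample] = []
    idx = 0
    for g in cohort.groups:
        for j in range(g.n_samples):
            sample_seed = (cohort.seed * 1000003 + idx * 8191 + 5) % (2**31 - 1)
            spec_j = replace(cohort.base, seed=sample_seed)
            if g.wall_scale != 1.0:
                spec_j = replace(
                    spec_j,
                    shell=replace(
                        cohort.base.shell,
                        wall_thickness_um=cohort.base.shell.wall_thickness_um * g.wall_scale,
                    ),
                )
            labels, truth = generate_labels(spec_j, effect=g)
            samples.append(
                CohortSample(
                    sample_id=f"{cohort.time_point}{g.label}-{j:02d}",
                    group=g.label,
                    time_point=cohort.time_point,
                    labels=labels,
                    truth=truth,
                    spec=spec_j,
                )
            )
            idx += 1
    return samples
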