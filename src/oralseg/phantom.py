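"""Procedural dental phantom: seeded synthetic CBCT-like volumes with
ground-truth instance labels.

The phantom emulates the structure of a clinical dental CBCT study: two dental
arches of up to 32 individually labelled teeth placed on elliptical arch curves
(crowns are truncated ellipsoids, roots tapered cones penetrating the jaw, with
root count depending on tooth type), a maxillary and a mandibular bone slab,
and two tubular mandibular canals inside the mandible.  Intensities are drawn
per structure (bone brighter than background, enamel/dentin brightest, canal
lumen dark) with additive Gaussian noise; optional metal-streak spokes and
motion blur mimic the artifact modes that plague clinical scans.  Geometry is
parametric-analytic, so generation is a pure function of the spec and seed.

Default desk-scale grid is 128 x 128 x 96 voxels at 0.3 mm isotropic spacing;
the clinical 440 x 440 x 344 grid remains a configuration choice.  Axes follow
the package's RAS convention: +x patient-right, +y anterior, +z superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .label_scheme import LabelScheme, default_scheme
from .volume_io import LabelVolume, Volume

__all__ = ["PhantomSpec", "ArchParams", "ToothParams", "JawParams",
           "CanalParams", "IntensityModel", "ArtifactParams",
           "generate_phantom", "generate_cohort", "perturb_annotation",
           "PhantomSizingError"]


class PhantomSizingError(ValueError):
    """Tooth or jaw geometry does not fit the requested grid."""


_TOOTH_TYPES = {1: "incisor", 2: "incisor", 3: "canine", 4: "premolar",
                5: "premolar", 6: "molar", 7: "molar", 8: "molar"}

# crown semi-axes (lateral, antero-posterior, occluso-cervical) in mm
_CROWN_AXES = {"incisor": (1.7, 1.2, 2.4), "canine": (1.9, 1.7, 2.6),
               "premolar": (2.2, 2.1, 2.2), "molar": (2.9, 2.6, 2.1)}


@dataclass(frozen=True)
class ArchParams:
    radius_mm: float = 13.5          # lateral semi-axis of the arch ellipse
    depth_mm: float = 11.0           # antero-posterior semi-axis
    tooth_spacing_deg: tuple[float, ...] = (6.0, 11.0, 11.5, 11.0, 11.0, 12.5, 13.5, 13.0)
    # cumulative angular positions from the midline, per FDI position 1..8


@dataclass(frozen=True)
class ToothParams:
    crown_scale_range: tuple[float, float] = (0.9, 1.1)
    root_length_range: tuple[float, float] = (3.5, 5.0)
    root_radius_mm: float = 1.0
    root_count: dict = field(default_factory=lambda: {
        "incisor": 1, "canine": 1, "premolar": 2, "molar": 3})


@dataclass(frozen=True)
class JawParams:
    slab_thickness_mm: float = 7.0       # vertical extent of each bone slab
    band_width_mm: float = 7.5           # radial half-width of bone around the arch
    occlusal_gap_mm: float = 1.0         # gap between upper and lower crowns
    crown_height_mm: float = 5.0         # occlusal band occupied by crowns
    cortical_fraction: float = 0.25      # outer shell fraction of slab thickness


@dataclass(frozen=True)
class CanalParams:
    radius_mm: float = 1.1
    depth_mm: float = 3.5                # below the mandible slab top
    arc_deg: tuple[float, float] = (25.0, 80.0)


@dataclass(frozen=True)
class IntensityModel:
    background: float = 0.05
    bone_trabecular: float = 0.38
    bone_cortical: float = 0.55
    tooth: float = 0.85
    canal: float = 0.12
    noise_sd: float = 0.03


@dataclass(frozen=True)
class ArtifactParams:
    metal_streak: bool = False
    streak_fdi: int = 16                 # crown seeding the streaks
    streak_intensity: float = 1.5
    n_spokes: int = 12
    motion_blur_sigma: float = 0.0       # voxels; 0 disables


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (128, 128, 96)
    spacing_mm: float = 0.3
    teeth_present: dict = field(default_factory=dict)  # fdi -> bool, default all True
    arch_params: ArchParams = field(default_factory=ArchParams)
    tooth_params: ToothParams = field(default_factory=ToothParams)
    jaw_params: JawParams = field(default_factory=JawParams)
    canal_params: CanalParams = field(default_factory=CanalParams)
    intensity_model: IntensityModel = field(default_factory=IntensityModel)
    artifacts: ArtifactParams = field(default_factory=ArtifactParams)
    seed: int = 0

    def __post_init__(self):
        if any(s < 32 for s in self.grid_shape):
            raise ValueError("grid_shape components must be >= 32")
        extra = set(self.teeth_present) - set(_all_fdi())
        if extra:
            raise ValueError(f"unknown FDI codes in teeth_present: {sorted(extra)}")

    def present(self, fdi: int) -> bool:
        return bool(self.teeth_present.get(fdi, True))


def _all_fdi() -> list[int]:
    return [q * 10 + p for q in (1, 2, 3, 4) for p in range(1, 9)]


def _tooth_geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Centre, crown axes, root specs for every present tooth, in mm (grid
    coordinates with origin at the volume centre)."""
    arch, tp, jp = spec.arch_params, spec.tooth_params, spec.jaw_params
    out = []
    angles = np.cumsum(arch.tooth_spacing_deg)
    for fdi in _all_fdi():
        q, pos = divmod(fdi, 10)
        ttype = _TOOTH_TYPES[pos]
        scale = float(rng.uniform(*tp.crown_scale_range))
        root_len = float(rng.uniform(*tp.root_length_range))
        if not spec.present(fdi):
            continue
        theta = np.deg2rad(angles[pos - 1])
        sx = 1.0 if q in (1, 4) else -1.0       # quadrants 1/4 are patient-right (+x)
        upper = q in (1, 2)
        x = sx * arch.radius_mm * np.sin(theta)
        y = arch.depth_mm * np.cos(theta) - 0.25 * arch.depth_mm
        ax = tuple(a * scale for a in _CROWN_AXES[ttype])
        zdir = 1.0 if upper else -1.0            # roots run away from the occlusal plane
        z_crown = zdir * (jp.occlusal_gap_mm / 2.0 + ax[2])
        n_roots = int(tp.root_count[ttype])
        out.append({"fdi": fdi, "type": ttype, "upper": upper,
                    "center": np.array([x, y, z_crown]),
                    "axes": ax, "root_len": root_len, "n_roots": n_roots,
                    "zdir": zdir})
    return out


def _paint_tooth(labels, claimed, geom, idx, spec: PhantomSpec):
    sp = spec.spacing_mm
    shape = np.array(spec.grid_shape)
    center_vox = (np.asarray(geom["center"]) / sp) + shape / 2.0
    ax_vox = np.asarray(geom["axes"]) / sp
    root_len_vox = geom["root_len"] / sp
    rr_vox = spec.tooth_params.root_radius_mm / sp

    # geometric extent (mm, voxel units) of crown + roots along each axis
    extent = np.array([max(ax_vox[0], rr_vox + 0.6 * ax_vox[0]),
                       max(ax_vox[1], rr_vox + 0.6 * ax_vox[1]),
                       ax_vox[2] + root_len_vox])
    if np.any(center_vox - extent < -0.5) or np.any(center_vox + extent > shape + 0.5):
        raise PhantomSizingError(
            f"tooth {geom['fdi']} does not fit the grid {tuple(shape)}; "
            f"enlarge the grid or shrink the arch")
    half = np.ceil(extent).astype(int) + 2
    lo_c = np.maximum(np.floor(center_vox - half).astype(int), 0)
    hi_c = np.minimum(np.ceil(center_vox + half).astype(int) + 1, shape)

    ii, jj, kk = np.meshgrid(*[np.arange(lo_c[a], hi_c[a]) for a in range(3)],
                             indexing="ij")
    # local mm coordinates relative to the crown centre
    px = (ii + 0.5 - center_vox[0]) * sp
    py = (jj + 0.5 - center_vox[1]) * sp
    pz = (kk + 0.5 - center_vox[2]) * sp
    axes = np.asarray(geom["axes"])
    mask = (px / axes[0]) ** 2 + (py / axes[1]) ** 2 + (pz / axes[2]) ** 2 <= 1.0
    # truncate the occlusal tip slightly (flat wear facet)
    mask &= geom["zdir"] * pz > -0.92 * axes[2]

    # roots: tapered cones from the crown centre into the jaw
    n = geom["n_roots"]
    offsets = {1: [(0.0, 0.0)],
               2: [(-0.45, 0.0), (0.45, 0.0)],
               3: [(-0.5, -0.35), (0.5, -0.35), (0.0, 0.45)]}[min(n, 3)]
    rr = spec.tooth_params.root_radius_mm
    for ox, oy in offsets:
        cx, cy = ox * axes[0], oy * axes[1]
        t = (geom["zdir"] * pz) / (axes[2] + geom["root_len"])  # 0 at centre, 1 at apex
        # taper floor scales with spacing so coarse grids keep roots connected
        with np.errstate(invalid="ignore"):
            taper = rr * (1.0 - np.clip(t, 0.0, 1.0)) + max(0.25, 0.8 * sp)
        root = (((px - cx) ** 2 + (py - cy) ** 2) <= taper ** 2) & (t >= 0) & (t <= 1.0)
        mask |= root

    region = (slice(lo_c[0], hi_c[0]), slice(lo_c[1], hi_c[1]), slice(lo_c[2], hi_c[2]))
    free = mask & ~claimed[region]
    labels[region][free] = idx
    claimed[region] |= mask


def _grid_mm(spec: PhantomSpec):
    shape = spec.grid_shape
    sp = spec.spacing_mm
    coords = [(np.arange(n) + 0.5 - n / 2.0) * sp for n in shape]
    return np.meshgrid(*coords, indexing="ij")


def generate_phantom(spec: PhantomSpec,
                     scheme: LabelScheme | None = None) -> tuple[Volume, LabelVolume]:
    """Render one phantom; fully reproducible from ``spec`` (incl. its seed)."""
    scheme = scheme or default_scheme()
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    sp = spec.spacing_mm
    jp, arch, cp, im = (spec.jaw_params, spec.arch_params, spec.canal_params,
                        spec.intensity_model)

    X, Y, Z = _grid_mm(spec)
    labels = np.zeros(shape, dtype=np.int16)

    # --- jaw slabs: elliptical band around the arch curve ------------------
    yc = -0.25 * arch.depth_mm
    r_norm = np.sqrt((X / arch.radius_mm) ** 2 + ((Y - yc) / arch.depth_mm) ** 2)
    band = np.abs(r_norm - 1.0) * min(arch.radius_mm, arch.depth_mm) <= jp.band_width_mm / 2.0
    z0 = jp.occlusal_gap_mm / 2.0 + jp.crown_height_mm
    maxilla = band & (Z >= z0) & (Z <= z0 + jp.slab_thickness_mm)
    mandible = band & (Z <= -z0) & (Z >= -z0 - jp.slab_thickness_mm)
    if not maxilla.any() or not mandible.any():
        raise PhantomSizingError("jaw slabs do not fit the grid; enlarge the "
                                 "grid or reduce jaw_params")
    labels[maxilla] = 33
    labels[mandible] = 34

    # --- mandibular canals: tubes following the arch inside the mandible ---
    z_canal = -(z0 + cp.depth_mm)
    t = np.linspace(np.deg2rad(cp.arc_deg[0]), np.deg2rad(cp.arc_deg[1]), 60)
    for side, idx in ((+1.0, 36), (-1.0, 35)):     # +x patient-right, 35 = left
        dist2 = np.full(shape, np.inf)
        for th in t:
            cx = side * arch.radius_mm * np.sin(th)
            cy = arch.depth_mm * np.cos(th) + yc
            d2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - z_canal) ** 2
            np.minimum(dist2, d2, out=dist2)
        canal = (dist2 <= cp.radius_mm ** 2) & mandible
        labels[canal] = idx

    # --- teeth --------------------------------------------------------------
    backdrop = labels.copy()
    claimed = np.zeros(shape, dtype=bool)
    tooth_indices = []
    for geom in _tooth_geometry(spec, rng):
        idx = scheme.fdi_to_index(geom["fdi"])
        tooth_indices.append(idx)
        _paint_tooth(labels, claimed, geom, idx, spec)
    # voxelisation of thin root cones can shed satellite fragments; revert
    # them to the backdrop so every tooth is exactly one connected component
    for idx in tooth_indices:
        comp, n = ndimage.label(labels == idx)
        if n > 1:
            sizes = np.bincount(comp.ravel())[1:]
            keep = int(np.argmax(sizes)) + 1
            satellite = (comp != 0) & (comp != keep)
            labels[satellite] = backdrop[satellite]

    # --- intensities --------------------------------------------------------
    img = np.full(shape, im.background, dtype=np.float32)
    bone = (labels == 33) | (labels == 34)
    img[bone] = im.bone_trabecular
    # cortical shell: outer rim of the slabs
    shell_vox = max(1, int(round(jp.cortical_fraction * jp.slab_thickness_mm / sp / 2)))
    eroded = ndimage.binary_erosion(bone, iterations=shell_vox)
    img[bone & ~eroded] = im.bone_cortical
    img[(labels >= 1) & (labels <= 32)] = im.tooth
    img[(labels == 35) | (labels == 36)] = im.canal
    img += rng.normal(0.0, im.noise_sd, size=shape).astype(np.float32)

    # --- artifacts ----------------------------------------------------------
    art = spec.artifacts
    if art.metal_streak and spec.present(art.streak_fdi):
        tooth_idx = scheme.fdi_to_index(art.streak_fdi)
        where = np.argwhere(labels == tooth_idx)
        if where.size:
            c = where.mean(axis=0)
            zs = slice(max(0, int(c[2]) - 3), min(shape[2], int(c[2]) + 4))
            diag = int(np.ceil(np.hypot(*shape[:2])))
            for a in np.linspace(0.0, np.pi, art.n_spokes, endpoint=False):
                s_arr = np.arange(-diag, diag)
                xi = np.round(c[0] + s_arr * np.cos(a)).astype(int)
                yi = np.round(c[1] + s_arr * np.sin(a)).astype(int)
                ok = (xi >= 0) & (xi < shape[0]) & (yi >= 0) & (yi < shape[1])
                img[xi[ok], yi[ok], zs] = art.streak_intensity
    if art.motion_blur_sigma > 0:
        img = ndimage.gaussian_filter(img, art.motion_blur_sigma)

    spacing = (sp, sp, sp)
    vol = Volume(data=img, spacing=spacing)
    lv = LabelVolume(labels=labels, spacing=spacing, scheme=scheme)
    return vol, lv


def generate_cohort(n: int, missing_rate: float = 0.0, seed: int = 0,
                    base_spec: PhantomSpec | None = None
                    ) -> list[tuple[Volume, LabelVolume]]:
    """Generate ``n`` independent phantoms with per-tooth Bernoulli(missing_rate)
    absence; per-case seeds are derived deterministically from ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    base = base_spec or PhantomSpec()
    master = np.random.default_rng(seed)
    cohort = []
    for _ in range(n):
        case_seed = int(master.integers(0, 2 ** 31 - 1))
        miss_rng = np.random.default_rng(case_seed + 1)
        present = {fdi: bool(miss_rng.random() >= missing_rate)
                   for fdi in _all_fdi()}
        spec = replace(base, teeth_present=present, seed=case_seed)
        cohort.append(generate_phantom(spec))
    return cohort


def perturb_annotation(lv: LabelVolume, boundary_flip_prob: float,
                       seed: int = 0) -> LabelVolume:
    """Simulate a second rater: voxels on label boundaries are reassigned to a
    random 6-neighbour's (differing) label with the given probability; interior
    voxels are untouched."""
    if not 0.0 <= boundary_flip_prob <= 1.0:
        raise ValueError("boundary_flip_prob must be in [0, 1]")
    labels = lv.labels
    rng = np.random.default_rng(seed)
    shifts = [(1, 0), (-1, 0), (1, 1), (-1, 1), (1, 2), (-1, 2)]
    neigh = np.stack([np.roll(labels, s, axis=a) for s, a in shifts])
    # edge rolls wrap; mark wrapped entries as "same" so they are never chosen
    for i, (s, a) in enumerate(shifts):
        sl = [slice(None)] * 3
        sl[a] = 0 if s == 1 else -1
        neigh[(i, *tuple(sl))] = labels[tuple(sl)]
    differs = neigh != labels[None]
    boundary = differs.any(axis=0)
    flip = boundary & (rng.random(labels.shape) < boundary_flip_prob)
    if not flip.any():
        return replace(lv, labels=labels.copy())
    # choose uniformly among the differing neighbours of each flipped voxel
    counts = differs[:, flip].astype(np.int64)            # (6, m)
    cum = counts.cumsum(axis=0)
    r = rng.integers(0, cum[-1])                          # (m,)
    pick = (cum > r[None]).argmax(axis=0)                 # first index past r
    out = labels.copy()
    out[flip] = neigh[:, flip][pick, np.arange(pick.size)]
    return replace(lv, labels=out)
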