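"""Seeded synthetic thorax CT phantoms with full ground truth.

A phantom emulates the geometry a lung-segmentation pipeline must cope with:
an air background, an elliptical body with a bone ring, two low-intensity
lung ellipsoids, a vertical trachea tube branching into two bronchi, bright
spherical nodules, and optionally a soft-tissue-free bridge fusing the two
lungs or a wall-adjacent notch (the footprint of a juxtapleural mass pushed
out of the dark lung class, which the rolling-ball repair should restore).

Phantoms are generated at 1 mm isotropic spacing by default so radii in mm
map 1:1 to voxels.  All randomness flows from ``spec.seed``; per-phantom
streams in :func:`generate_dataset` are spawned from the master seed so the
dataset is reproducible and order-independent.

Not emulated: anatomically realistic airway trees, lung texture, and
ground-glass (non-solid) nodules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from pulmocad.volume_io import CTVolume

__all__ = [
    "NoduleSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "generate_dataset",
]


class PhantomSpecError(ValueError):
    """Raised when a phantom spec is geometrically invalid."""


@dataclass
class NoduleSpec:
    """A single synthetic nodule.

    center is world mm (x, y, z); diameter must lie in the 3-30 mm
    annotation range; kind 'solid' is interior, 'pleural' is tangent to the
    lung wall; contrast is the intensity offset above lung background.
    """

    center: tuple  # (x, y, z) world mm
    diameter_mm: float
    kind: str = "solid"
    contrast: float = 700.0

    def __post_init__(self) -> None:
        self.center = tuple(float(c) for c in self.center)
        if not (3.0 <= float(self.diameter_mm) <= 30.0):
            raise PhantomSpecError(
                f"nodule diameter {self.diameter_mm} outside the 3-30 mm range"
            )
        if self.kind not in ("solid", "pleural"):
            raise PhantomSpecError(f"unknown nodule kind {self.kind!r}")


@dataclass
class PhantomSpec:
    """Geometry, intensity levels and noise of a synthetic thorax.

    Defaults describe a 150x120 mm axial section over 60 slices at 1 mm
    isotropic spacing, with lung ellipsoids of semi-axes (24, 30, 24) mm in
    (x, y, z) and a 3 mm-radius trachea.  Intensity levels follow HU:
    air -1000, lung -800, soft tissue +40, bone +700.
    """

    shape: tuple = (60, 120, 150)  # (z, y, x)
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    # body ellipse (axial plane), in voxel units of the default 1 mm grid
    body_center_xy: tuple = (75.0, 62.0)
    body_semiaxes_xy: tuple = (65.0, 45.0)
    bone_ring_fractions: tuple = (0.86, 0.95)
    # lungs: two ellipsoids, mirrored in x
    lung_centers_x: tuple = (45.0, 105.0)
    lung_center_yz: tuple = (60.0, 30.0)  # (y, z)
    lung_semiaxes: tuple = (24.0, 30.0, 24.0)  # (x, y, z)
    # airway (lumen radii; a soft-tissue wall of airway_wall_mm surrounds
    # the lumen so the airway is a separate dark structure from the lungs)
    trachea_radius: float = 3.0
    bronchus_radius: float = 2.0
    airway_wall_mm: float = 2.0
    carina_z: float = 32.0
    nodules: list = field(default_factory=list)
    fused: bool = False
    pleural_notch: bool = False
    notch_radius_mm: float = 5.0
    noise_sigma: float = 0.0
    # intensity levels
    air_hu: float = -1000.0
    lung_hu: float = -800.0
    body_hu: float = 40.0
    bone_hu: float = 700.0
    seed: int = 0


@dataclass
class PhantomTruth:
    """Ground truth for a generated phantom.

    ``lung_mask`` is the full parenchyma region (nodules included, airways
    and notch excluded; when ``fused`` it also includes the bridge).
    ``left_lung_mask``/``right_lung_mask`` are the clean per-lung ellipsoid
    regions without the bridge.  ``notch_mask`` marks the carved wall
    concavity the boundary repair is expected to restore.
    """

    lung_mask: np.ndarray
    left_lung_mask: np.ndarray
    right_lung_mask: np.ndarray
    trachea_mask: np.ndarray
    bronchi_mask: np.ndarray
    nodule_mask: np.ndarray
    notch_mask: np.ndarray
    nodules: list  # of NoduleSpec


# ---------------------------------------------------------------------------
# geometry helpers (all in voxel coordinates, (z, y, x) arrays)
# ---------------------------------------------------------------------------

def _ellipse_mask_2d(shape_yx, center_xy, semiaxes_xy, scale=1.0):
    yy, xx = np.ogrid[: shape_yx[0], : shape_yx[1]]
    cx, cy = center_xy
    ax, ay = semiaxes_xy[0] * scale, semiaxes_xy[1] * scale
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def _ellipsoid_mask(shape, center_zyx, semiaxes_zyx):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center_zyx
    az, ay, ax = semiaxes_zyx
    return (
        ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    )


def _sphere_mask(shape, center_zyx, radius):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center_zyx
    return (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _tube_mask(shape, p0_zyx, p1_zyx, radius):
    """Voxels within ``radius`` of the segment p0-p1 (capsule)."""
    p0 = np.asarray(p0_zyx, dtype=float)
    p1 = np.asarray(p1_zyx, dtype=float)
    lo = np.maximum(np.floor(np.minimum(p0, p1) - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + radius + 1).astype(int) + 1, shape)
    out = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        return out
    grids = np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)], indexing="ij")
    pts = np.stack([g.astype(float) for g in grids], axis=-1)
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0:
        t = np.zeros(pts.shape[:-1])
    else:
        t = np.clip(((pts - p0) @ d) / denom, 0.0, 1.0)
    closest = p0 + t[..., None] * d
    dist2 = np.sum((pts - closest) ** 2, axis=-1)
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = dist2 <= radius**2
    return out


def _world_to_voxel_zyx(spec: PhantomSpec, center_xyz) -> tuple:
    world_zyx = (center_xyz[2], center_xyz[1], center_xyz[0])
    return tuple(
        (w - o) / s for w, o, s in zip(world_zyx, spec.origin, spec.spacing)
    )


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> tuple:
    """Render a phantom volume and its ground truth.

    Deterministic for a fixed ``spec.seed``.  Raises PhantomSpecError when a
    nodule does not fit inside a lung (pleural nodules may be tangent).
    """
    shape = tuple(int(s) for s in spec.shape)
    cy, cz = spec.lung_center_yz
    ax, ay, az = spec.lung_semiaxes

    body2d = _ellipse_mask_2d(shape[1:], spec.body_center_xy, spec.body_semiaxes_xy)
    inner = _ellipse_mask_2d(
        shape[1:], spec.body_center_xy, spec.body_semiaxes_xy, spec.bone_ring_fractions[0]
    )
    outer = _ellipse_mask_2d(
        shape[1:], spec.body_center_xy, spec.body_semiaxes_xy, spec.bone_ring_fractions[1]
    )
    bone2d = outer & ~inner

    lungs = []
    for cx in spec.lung_centers_x:
        lungs.append(_ellipsoid_mask(shape, (cz, cy, cx), (az, ay, ax)))
        if not np.all(body2d[np.any(lungs[-1], axis=0)]):
            raise PhantomSpecError("lung ellipsoid extends outside the body ellipse")
    left_lung, right_lung = lungs  # left = smaller x

    # airway: vertical trachea from the top slice down to the carina, then
    # two bronchi descending laterally into each lung
    mid_x = 0.5 * (spec.lung_centers_x[0] + spec.lung_centers_x[1])
    wall = spec.airway_wall_mm
    trachea = _tube_mask(
        shape, (0.0, cy - 5.0, mid_x), (spec.carina_z, cy - 5.0, mid_x), spec.trachea_radius
    )
    airway_outer = _tube_mask(
        shape, (0.0, cy - 5.0, mid_x), (spec.carina_z, cy - 5.0, mid_x),
        spec.trachea_radius + wall,
    )
    carina = np.array([spec.carina_z, cy - 5.0, mid_x])
    bronchi = np.zeros(shape, dtype=bool)
    for cx in spec.lung_centers_x:
        tip = np.array([cz + 0.6 * az, cy, cx + (0.25 * ax if cx < mid_x else -0.25 * ax)])
        bronchi |= _tube_mask(shape, carina, tip, spec.bronchus_radius)
        airway_outer |= _tube_mask(shape, carina, tip, spec.bronchus_radius + wall)
    bronchi &= ~trachea
    airway_wall = airway_outer & ~(trachea | bronchi)

    lung_region = left_lung | right_lung

    # nodules
    nodule_mask = np.zeros(shape, dtype=bool)
    for i, nod in enumerate(spec.nodules):
        c_zyx = _world_to_voxel_zyx(spec, nod.center)
        r_vox = 0.5 * nod.diameter_mm / spec.spacing[0]
        sphere = _sphere_mask(shape, c_zyx, r_vox)
        inside = sphere & lung_region & ~airway_outer
        if nod.kind == "solid":
            if not np.array_equal(sphere, sphere & lung_region):
                raise PhantomSpecError(f"nodule {i} (solid) not fully inside a lung")
        else:  # pleural: tangent allowed, but the centre must be in lung
            ci = tuple(int(round(c)) for c in c_zyx)
            if not (all(0 <= ci[a] < shape[a] for a in range(3)) and lung_region[ci]):
                raise PhantomSpecError(f"nodule {i} (pleural) centre not inside a lung")
        nodule_mask |= inside

    # fusion bridge: lung-intensity tissue joining the two lungs
    bridge = np.zeros(shape, dtype=bool)
    if spec.fused:
        x0 = spec.lung_centers_x[0] + 0.7 * ax
        x1 = spec.lung_centers_x[1] - 0.7 * ax
        bridge[
            int(cz - 6) : int(cz + 6),
            int(cy - 6) : int(cy + 6),
            int(np.floor(x0)) : int(np.ceil(x1)) + 1,
        ] = True
        bridge &= ~(trachea | bronchi)

    # pleural notch: the pocket a juxtapleural mass carves out of the lung
    # wall, modelled as a sphere embedded 0.8 radii into the lateral lung
    # boundary (a mostly-embedded mass touching the pleura).  Its mouth
    # (~1.2 radii wide) is much narrower than the rolling-ball diameter, so
    # the boundary repair can fill it.
    notch = np.zeros(shape, dtype=bool)
    if spec.pleural_notch:
        r_n = spec.notch_radius_mm / spec.spacing[0]
        wall_x = spec.lung_centers_x[0] - ax + 0.85 * r_n
        notch = _sphere_mask(shape, (cz, cy, wall_x), r_n)
        notch &= lung_region

    lung_mask = (lung_region | bridge) & ~airway_outer & ~notch

    # paint the volume
    vol = np.full(shape, spec.air_hu, dtype=np.float64)
    vol[:, body2d] = spec.body_hu
    vol[:, bone2d] = spec.bone_hu
    vol[lung_region | bridge] = spec.lung_hu
    vol[airway_wall] = spec.body_hu
    vol[trachea | bronchi] = spec.air_hu
    vol[notch] = spec.body_hu
    for nod in spec.nodules:
        c_zyx = _world_to_voxel_zyx(spec, nod.center)
        r_vox = 0.5 * nod.diameter_mm / spec.spacing[0]
        sphere = _sphere_mask(shape, c_zyx, r_vox) & lung_region & ~airway_outer
        vol[sphere] = spec.lung_hu + nod.contrast

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=shape)

    volume = CTVolume(
        voxels=vol,
        spacing=spec.spacing,
        origin=spec.origin,
        series_id=f"phantom-{spec.seed:08d}",
    )
    truth = PhantomTruth(
        lung_mask=lung_mask,
        left_lung_mask=left_lung & lung_mask,
        right_lung_mask=right_lung & lung_mask,
        trachea_mask=trachea,
        bronchi_mask=bronchi,
        nodule_mask=nodule_mask,
        notch_mask=notch,
        nodules=list(spec.nodules),
    )
    return volume, truth


def default_nodule_center(spec: PhantomSpec, side: int = 0) -> tuple:
    """World-mm (x, y, z) centre of lung ``side`` (0 = left, 1 = right)."""
    cx = spec.lung_centers_x[side]
    cy, cz = spec.lung_center_yz
    vox_zyx = (cz, cy, cx)
    world = [o + v * s for o, v, s in zip(spec.origin, vox_zyx, spec.spacing)]
    return (world[2], world[1], world[0])


def default_phantom_spec(**overrides) -> PhantomSpec:
    """The study-default phantom: noiseless, not fused, one interior 10 mm nodule."""
    spec = PhantomSpec(**{k: v for k, v in overrides.items() if k != "nodules"})
    if "nodules" in overrides:
        spec.nodules = list(overrides["nodules"])
    else:
        spec.nodules = [NoduleSpec(center=default_nodule_center(spec, 0), diameter_mm=10.0)]
    return spec


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _sample_nodule(rng: np.random.Generator, spec: PhantomSpec, diameter: float) -> NoduleSpec:
    """Place one solid nodule uniformly inside a randomly chosen lung."""
    side = int(rng.integers(0, 2))
    cx = spec.lung_centers_x[side]
    cy, cz = spec.lung_center_yz
    ax, ay, az = spec.lung_semiaxes
    r = 0.5 * diameter
    for _ in range(200):
        u = rng.uniform(-1.0, 1.0, size=3)  # (x, y, z) fractional offsets
        # shrink each semi-axis so the whole sphere fits inside the ellipsoid
        sx, sy, sz = (max(ax - r - 1, 0), max(ay - r - 1, 0), max(az - r - 1, 0))
        if (u[0]) ** 2 + (u[1]) ** 2 + (u[2]) ** 2 > 1.0:
            continue
        vox_zyx = (cz + u[2] * sz, cy + u[1] * sy, cx + u[0] * sx)
        world = [o + v * s for o, v, s in zip(spec.origin, vox_zyx, spec.spacing)]
        return NoduleSpec(center=(world[2], world[1], world[0]), diameter_mm=diameter)
    raise PhantomSpecError(f"could not place a {diameter} mm nodule inside the lung")


def generate_dataset(
    n: int,
    base_spec: Optional[PhantomSpec] = None,
    diameter_sampler: Optional[Callable[[np.random.Generator], float]] = None,
    seed: int = 0,
    nodules_per_item: int = 1,
) -> list:
    """Generate ``n`` phantoms with i.i.d. nodule diameters.

    ``diameter_sampler`` maps a numpy Generator to a diameter in mm; the
    default is uniform on [3, 30].  Per-item seeds are spawned from the
    master ``seed`` with ``np.random.SeedSequence`` so each item is
    reproducible independently of the others.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if base_spec is None:
        base_spec = PhantomSpec()
    if diameter_sampler is None:
        diameter_sampler = lambda rng: float(rng.uniform(3.0, 30.0))  # noqa: E731

    children = np.random.SeedSequence(seed).spawn(n)
    out = []
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        item_seed = int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
        nodules = [
            _sample_nodule(rng, base_spec, float(diameter_sampler(rng)))
            for _ in range(nodules_per_item)
        ]
        spec = replace(base_spec, nodules=nodules, seed=item_seed)
        vol, truth = generate_phantom(spec)
        vol.series_id = f"phantom-{seed:04d}-{i:04d}"
        out.append((vol, truth))
    return out
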