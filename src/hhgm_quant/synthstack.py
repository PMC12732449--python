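"""Synthetic two-channel harmonic-microscopy stacks with full ground truth.

This module fabricates z-stacks that mimic the statistical structure of
label-free harmonic-generation imaging of 3D fibroblast cultures:

* an "SHG" channel of bright curvilinear collagen fibers with Gaussian radial
  cross-section (sub-micron diameters),
* a "THG" channel of interface-bright ellipsoidal cells — hollow shells with a
  bright outer membrane, an inner nucleus rim and dark interiors, matching the
  interface sensitivity of third-harmonic contrast,
* a depth-dependent counterclockwise rotation of the dominant in-plane
  orientation, and a tunable coupling between each cell's long axis and the
  local fiber orientation,
* Poisson shot noise on (signal + background) plus optional Gaussian read
  noise.

Every generated stack comes with a :class:`SceneTruth` that records the exact
fiber centerlines/diameters/angles, cell ellipsoid parameters and the rotation
rate, so that each downstream operator (diametry, segmentation, orientation)
can be validated by parameter recovery.

Angle conventions: the in-plane (azimuthal) angle θ is axial on [0°, 180°),
measured counterclockwise from the +x axis with y pointing up when the image
is displayed conventionally (arrays store y downward). The polar angle φ is
measured from the +z (optical) axis, φ = 90° meaning in-plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .volume import VolumeStack

__all__ = [
    "FiberSpec",
    "CellSpec",
    "SceneTruth",
    "CellPlacementError",
    "generate_fibers",
    "generate_cells",
    "generate_culture",
    "render_fibers",
    "render_cells",
    "wrap_theta",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.3548


def wrap_theta(theta_deg):
    """Wrap an axial angle to [0, 180)."""
    # double mod: np.mod(-tiny, 180) rounds to exactly 180.0 in floats
    return np.mod(np.mod(theta_deg, 180.0), 180.0)


class CellPlacementError(RuntimeError):
    """Non-overlapping cell placement infeasible; carries the count placed."""

    def __init__(self, requested: int, placed: int):
        self.requested = requested
        self.placed = placed
        super().__init__(
            f"placed only {placed}/{requested} non-overlapping cells "
            "within the retry budget"
        )


@dataclass
class FiberSpec:
    """One collagen fiber: polyline centerline plus radial Gaussian profile.

    ``centerline`` is an (N, 3) array of (z, y, x) points in µm;
    ``diameter_fwhm`` is the full width at half maximum of the transverse
    intensity profile, taken as the fiber diameter.
    """

    centerline: np.ndarray
    diameter_fwhm: float
    intensity_peak: float
    theta_deg: float
    phi_deg: float = 90.0

    def __post_init__(self):
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if self.diameter_fwhm <= 0:
            raise ValueError("diameter_fwhm must be positive")
        if not (0.0 <= self.theta_deg < 180.0):
            raise ValueError("theta_deg must lie in [0, 180)")
        if not (0.0 <= self.phi_deg <= 90.0):
            raise ValueError("phi_deg must lie in [0, 90]")


@dataclass
class CellSpec:
    """One cell: oriented ellipsoidal shell with a nucleus rim.

    ``center`` is (z, y, x) in µm; ``semi_axes`` = (a, b, c) with a ≥ b ≥ c,
    a along the in-plane long axis at ``long_axis_theta_deg``, c along z.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    long_axis_theta_deg: float
    rim_intensity: float = 50.0
    nucleus_rim_intensity: float = 40.0

    def __post_init__(self):
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise ValueError("semi_axes must satisfy a >= b >= c > 0")

    @property
    def width_to_length(self) -> float:
        a, b, _ = self.semi_axes
        return b / a


@dataclass
class SceneTruth:
    """Ground truth for a synthetic stack."""

    fibers: list[FiberSpec] = field(default_factory=list)
    cells: list[CellSpec] = field(default_factory=list)
    rotation_rate_deg_per_um: float = 0.0
    base_theta_deg: float = 0.0
    coupling_kappa: float = 1.0
    seed: int = 0

    def layer_mean_theta(self, z_um) -> np.ndarray:
        """Nominal dominant in-plane angle at depth ``z_um`` (µm)."""
        return wrap_theta(self.base_theta_deg
                          + self.rotation_rate_deg_per_um * np.asarray(z_um, float))

    def merged_with(self, other: "SceneTruth") -> "SceneTruth":
        return SceneTruth(
            fibers=self.fibers + other.fibers,
            cells=self.cells + other.cells,
            rotation_rate_deg_per_um=self.rotation_rate_deg_per_um
            or other.rotation_rate_deg_per_um,
            base_theta_deg=self.base_theta_deg or other.base_theta_deg,
            coupling_kappa=other.coupling_kappa
            if other.cells else self.coupling_kappa,
            seed=self.seed,
        )

    # --- sidecar (JSON) serialization -------------------------------------
    def to_json(self) -> str:
        def enc(o):
            d = asdict(o)
            for k, v in d.items():
                if isinstance(v, np.ndarray):
                    d[k] = v.tolist()
            return d

        return json.dumps(
            {
                "fibers": [enc(f) for f in self.fibers],
                "cells": [enc(c) for c in self.cells],
                "rotation_rate_deg_per_um": self.rotation_rate_deg_per_um,
                "base_theta_deg": self.base_theta_deg,
                "coupling_kappa": self.coupling_kappa,
                "seed": self.seed,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SceneTruth":
        d = json.loads(text)
        fibers = [FiberSpec(**f) for f in d["fibers"]]
        cells = [CellSpec(center=tuple(c["center"]),
                          semi_axes=tuple(c["semi_axes"]),
                          long_axis_theta_deg=c["long_axis_theta_deg"],
                          rim_intensity=c["rim_intensity"],
                          nucleus_rim_intensity=c["nucleus_rim_intensity"])
                 for c in d["cells"]]
        return cls(fibers, cells, d["rotation_rate_deg_per_um"],
                   d["base_theta_deg"], d["coupling_kappa"], d["seed"])


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _check_dims(shape):
    nz, ny, nx = shape
    if nz < 1 or ny < 32 or nx < 32 or (ny * nx * nz) == 0:
        raise ValueError(f"volume dimensions too small: {shape} (need >= 32x32 in plane)")


def render_fibers(specs, shape, voxel_xy, voxel_z) -> np.ndarray:
    """Render fibers additively into a float64 (z, y, x) volume.

    Each fiber contributes ``peak * exp(-d^2 / 2σ^2)`` where ``d`` is the
    physical (µm) distance of the voxel center to the fiber centerline and
    σ = diameter_fwhm / (2√(2 ln 2)). Superposition holds exactly: the sum of
    the rendered volume equals the sum of individually rendered fibers.
    """
    _check_dims(shape)
    nz, ny, nx = shape
    vol = np.zeros(shape, dtype=np.float64)
    scale = np.array([voxel_z, voxel_xy, voxel_xy])
    for spec in specs:
        if spec.diameter_fwhm < 2.0 * voxel_xy:
            raise ValueError(
                f"fiber diameter {spec.diameter_fwhm} µm below 2 voxels "
                f"({2 * voxel_xy} µm): unresolvable"
            )
        sigma = spec.diameter_fwhm / FWHM_TO_SIGMA
        reach = 4.0 * sigma
        pts = spec.centerline / scale  # voxel units per axis
        reach_vox = reach / scale
        for p0, p1 in zip(pts[:-1], pts[1:]) if len(pts) > 1 else [(pts[0], pts[0])]:
            lo = np.maximum(np.floor(np.minimum(p0, p1) - reach_vox), 0).astype(int)
            hi = np.minimum(np.ceil(np.maximum(p0, p1) + reach_vox) + 1,
                            [nz, ny, nx]).astype(int)
            if np.any(lo >= hi):
                continue
            zz, yy, xx = np.meshgrid(
                np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]),
                np.arange(lo[2], hi[2]), indexing="ij",
            )
            # physical coordinates of voxel centers in the box
            q = np.stack([zz * voxel_z, yy * voxel_xy, xx * voxel_xy], axis=-1)
            a = p0 * scale
            b = p1 * scale
            ab = b - a
            denom = float(ab @ ab)
            if denom == 0.0:
                d2 = np.sum((q - a) ** 2, axis=-1)
            else:
                t = np.clip(((q - a) @ ab) / denom, 0.0, 1.0)
                proj = a + t[..., None] * ab
                d2 = np.sum((q - proj) ** 2, axis=-1)
            vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
                spec.intensity_peak * np.exp(-d2 / (2.0 * sigma**2))
            )
    return vol


def render_cells(specs, shape, voxel_xy, voxel_z,
                 shell_sigma_m: float = 0.12,
                 nucleus_m: float = 0.35,
                 nucleus_sigma_m: float = 0.10) -> np.ndarray:
    """Render cells as hollow ellipsoidal shells (bright interfaces).

    Intensity is a Gaussian band around the normalized ellipsoid radius
    m = 1 (outer membrane) plus a band around ``m = nucleus_m`` (nucleus rim);
    the space between and inside is dark, as for interface-sensitive contrast.
    """
    _check_dims(shape)
    nz, ny, nx = shape
    vol = np.zeros(shape, dtype=np.float64)
    for spec in specs:
        a, b, c = spec.semi_axes
        cz, cy, cx = spec.center
        th = np.deg2rad(spec.long_axis_theta_deg)
        # in-plane long-axis direction in array coords (y down)
        ex, ey = np.cos(th), -np.sin(th)
        pad = 1.0 + 4.0 * shell_sigma_m
        lo_z = max(int(np.floor((cz - c * pad) / voxel_z)), 0)
        hi_z = min(int(np.ceil((cz + c * pad) / voxel_z)) + 1, nz)
        lo_y = max(int(np.floor((cy - a * pad) / voxel_xy)), 0)
        hi_y = min(int(np.ceil((cy + a * pad) / voxel_xy)) + 1, ny)
        lo_x = max(int(np.floor((cx - a * pad) / voxel_xy)), 0)
        hi_x = min(int(np.ceil((cx + a * pad) / voxel_xy)) + 1, nx)
        if lo_z >= hi_z or lo_y >= hi_y or lo_x >= hi_x:
            continue
        zz = np.arange(lo_z, hi_z) * voxel_z - cz
        yy = np.arange(lo_y, hi_y) * voxel_xy - cy
        xx = np.arange(lo_x, hi_x) * voxel_xy - cx
        dz, dy, dx = np.meshgrid(zz, yy, xx, indexing="ij")
        u = dx * ex + dy * ey            # along long axis
        v = -dx * ey + dy * ex           # in-plane perpendicular
        m = np.sqrt((u / a) ** 2 + (v / b) ** 2 + (dz / c) ** 2)
        band = spec.rim_intensity * np.exp(-((m - 1.0) ** 2) / (2 * shell_sigma_m**2))
        nuc = spec.nucleus_rim_intensity * np.exp(
            -((m - nucleus_m) ** 2) / (2 * nucleus_sigma_m**2)
        )
        vol[lo_z:hi_z, lo_y:hi_y, lo_x:hi_x] += band + nuc
    return vol


def truth_cell_mask(truth: "SceneTruth", shape, voxel_xy, voxel_z,
                    level: float = 0.5) -> np.ndarray:
    """Half-maximum footprint of every cell's interface bands, per layer.

    For each cell the noiseless render is thresholded at ``level`` of its own
    rim intensity, giving the reference foreground (membrane and nucleus
    bands) that a cell-material segmentation is scored against.
    """
    mask = np.zeros(shape, dtype=bool)
    for cell in truth.cells:
        r = render_cells([cell], shape, voxel_xy, voxel_z)
        mask |= r >= level * cell.rim_intensity
    return mask


def _apply_noise(signal, background, rng, read_noise_sd):
    noisy = rng.poisson(signal + background).astype(np.float64)
    if read_noise_sd > 0:
        noisy = noisy + rng.normal(0.0, read_noise_sd, size=noisy.shape)
    return np.clip(noisy, 0.0, None)


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def generate_fibers(
    *,
    shape=(15, 512, 512),
    voxel_xy: float = 0.2,
    voxel_z: float = 2.0,
    n_fibers: int = 60,
    diameter_mean_um: float = 0.9,
    diameter_sd_um: float = 0.2,
    diameter_range=(0.5, 1.5),
    base_theta_deg: float = 30.0,
    theta_spread_deg: float = 8.0,
    rotation_rate_deg_per_um: float = 0.25,
    peak_range=(30.0, 60.0),
    background: float = 5.0,
    noise: bool = True,
    read_noise_sd: float = 1.0,
    z_jitter_um: float = 0.3,
    seed: int = 0,
    stack_id: str = "fibers",
    group: str = "",
):
    """Generate a single-channel ("SHG") fiber stack with truth.

    Fibers are straight chords across the field. Each fiber is assigned a
    home layer; its nominal in-plane angle is the layer's rotating mean angle
    (base + rotation_rate × depth) plus a Gaussian spread, so the dominant
    orientation advances counterclockwise with depth.

    Returns ``(VolumeStack with channel "SHG", SceneTruth)``.
    """
    _check_dims(shape)
    if shape[0] < 4:
        raise ValueError("fiber scenes require at least 4 layers")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    fy, fx = ny * voxel_xy, nx * voxel_xy
    diag = float(np.hypot(fy, fx))
    fibers: list[FiberSpec] = []
    for _ in range(int(n_fibers)):
        layer = int(rng.integers(0, nz))
        z = layer * voxel_z + rng.normal(0.0, z_jitter_um)
        z = float(np.clip(z, 0.0, (nz - 1) * voxel_z))
        mean_theta = base_theta_deg + rotation_rate_deg_per_um * z
        theta = wrap_theta(mean_theta + rng.normal(0.0, theta_spread_deg))
        d = float(np.clip(rng.normal(diameter_mean_um, diameter_sd_um),
                          *diameter_range))
        d = max(d, 2.0 * voxel_xy)
        peak = float(rng.uniform(*peak_range))
        cy = rng.uniform(0, fy)
        cx = rng.uniform(0, fx)
        th = np.deg2rad(theta)
        # direction in (z, y_array, x): y_array points down
        direc = np.array([0.0, -np.sin(th), np.cos(th)])
        half = diag  # long enough to cross the field
        p0 = np.array([z, cy, cx]) - half * direc
        p1 = np.array([z, cy, cx]) + half * direc
        fibers.append(FiberSpec(np.stack([p0, p1]), d, peak, float(theta)))

    clean = render_fibers(fibers, shape, voxel_xy, voxel_z)
    if noise:
        img = _apply_noise(clean, background, rng, read_noise_sd)
    else:
        img = clean + background
    stack = VolumeStack({"SHG": img}, voxel_xy, voxel_z, stack_id, group)
    truth = SceneTruth(fibers=fibers,
                       rotation_rate_deg_per_um=rotation_rate_deg_per_um,
                       base_theta_deg=base_theta_deg, seed=seed)
    return stack, truth


def slab_centers_um(nz: int, voxel_z: float) -> np.ndarray:
    """Physical z-centers of the pairwise-projection slabs of an nz-layer stack.

    Slab k covers layers (2k, 2k+1); an odd trailing layer forms its own slab.
    """
    centers = []
    k = 0
    while 2 * k < nz:
        if 2 * k + 1 < nz:
            centers.append((2 * k + 0.5) * voxel_z)
        else:
            centers.append(2 * k * voxel_z)
        k += 1
    return np.asarray(centers)


def _capsule_distance(p0, p1, q0, q1):
    """Minimum distance between two 3D segments (numerically robust enough
    for overlap rejection; exact for non-degenerate segments)."""
    d1 = p1 - p0
    d2 = q1 - q0
    r = p0 - q0
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r
    eps = 1e-12
    if a <= eps and e <= eps:
        return float(np.linalg.norm(r))
    if a <= eps:
        t = np.clip(f / e, 0, 1)
        return float(np.linalg.norm(p0 - (q0 + t * d2)))
    c = d1 @ r
    if e <= eps:
        s = np.clip(-c / a, 0, 1)
        return float(np.linalg.norm(p0 + s * d1 - q0))
    b = d1 @ d2
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0, 1) if denom > eps else 0.0
    t = (b * s + f) / e
    if t < 0:
        t = 0.0
        s = np.clip(-c / a, 0, 1)
    elif t > 1:
        t = 1.0
        s = np.clip((b - c) / a, 0, 1)
    return float(np.linalg.norm((p0 + s * d1) - (q0 + t * d2)))


def generate_cells(
    *,
    shape=(15, 512, 512),
    voxel_xy: float = 0.2,
    voxel_z: float = 2.0,
    n_cells: int = 50,
    a_range=(8.0, 13.0),
    b_range=(2.5, 4.5),
    c_range=(1.8, 2.2),
    rim_range=(40.0, 70.0),
    nucleus_rim_frac: float = 0.8,
    coupling_kappa: float = 0.9,
    fiber_truth: SceneTruth | None = None,
    background: float = 2.0,
    noise: bool = True,
    read_noise_sd: float = 1.0,
    overlap_fraction: float = 0.0,
    max_tries: int = 100000,
    margin_um: float = 2.0,
    clearance_um: float = 1.25,
    seed: int = 0,
    stack_id: str = "cells",
    group: str = "",
):
    """Generate a single-channel ("THG") cell stack with truth.

    Cells are hollow ellipsoidal shells whose z-centers sit on the centers of
    pairwise-projection slabs (cultured cells form discrete contiguous
    layers); their in-plane long axes follow the local fiber orientation with
    strength ``coupling_kappa``: θ_cell = θ_fiber(z) + (1 − κ)·U(−90°, 90°).
    With κ=0 the orientation is uniform; with κ=1 it equals the local fiber
    mean. Placement is rejection-sampled to be non-overlapping (capsule
    approximation along the long axis) unless ``overlap_fraction`` > 0.
    """
    _check_dims(shape)
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    fy, fx = ny * voxel_xy, nx * voxel_xy
    # cells sit on the centers of full layer-pairs only: a trailing odd
    # layer has its slab center on the layer itself, which would put the
    # cell's z-shell exactly onto the neighboring slab
    slabs = slab_centers_um(nz, voxel_z)[: nz // 2]
    cells: list[CellSpec] = []
    segs: list[tuple[np.ndarray, np.ndarray, float]] = []
    slab_counts = np.zeros(len(slabs), dtype=int)
    tries = 0
    while len(cells) < n_cells and tries < max_tries:
        tries += 1
        a = rng.uniform(*a_range)
        b = rng.uniform(*b_range)
        c = rng.uniform(*c_range)
        a, b, c = sorted((a, b, c), reverse=True)
        # fill the least-occupied slab (ties broken randomly): cultured cell
        # layers are roughly balanced, and balance maximizes packing headroom
        least = np.flatnonzero(slab_counts == slab_counts.min())
        slab_idx = int(least[rng.integers(0, len(least))])
        zc = float(slabs[slab_idx])
        if fiber_truth is not None:
            base = float(fiber_truth.layer_mean_theta(zc))
        else:
            base = 0.0
        offset = rng.uniform(-90.0, 90.0)
        theta = float(wrap_theta(base + (1.0 - coupling_kappa) * offset))
        th = np.deg2rad(theta)
        # bounding half-extents of the rotated ellipse keep cells inside
        ext_x = float(np.hypot(a * np.cos(th), b * np.sin(th)))
        ext_y = float(np.hypot(a * np.sin(th), b * np.cos(th)))
        if (ext_y + margin_um >= fy - ext_y - margin_um
                or ext_x + margin_um >= fx - ext_x - margin_um):
            continue
        cy = rng.uniform(ext_y + margin_um, fy - ext_y - margin_um)
        cx = rng.uniform(ext_x + margin_um, fx - ext_x - margin_um)
        direc = np.array([0.0, -np.sin(th), np.cos(th)])
        ctr = np.array([zc, cy, cx])
        half = max(a - b, 0.0)
        p0, p1 = ctr - half * direc, ctr + half * direc
        ok = True
        if overlap_fraction == 0.0:
            # shells have finite band width beyond the nominal semi-axis,
            # so keep an extra clearance or rendered rings would touch
            for q0, q1, rad in segs:
                if _capsule_distance(p0, p1, q0, q1) < (b + rad + clearance_um):
                    ok = False
                    break
        if not ok:
            continue
        rim = float(rng.uniform(*rim_range))
        cells.append(CellSpec((zc, cy, cx), (a, b, c), theta, rim,
                              nucleus_rim_frac * rim))
        segs.append((p0, p1, b))
        slab_counts[slab_idx] += 1
    if len(cells) < n_cells:
        raise CellPlacementError(n_cells, len(cells))

    clean = render_cells(cells, shape, voxel_xy, voxel_z)
    if noise:
        img = _apply_noise(clean, background, rng, read_noise_sd)
    else:
        img = clean + background
    stack = VolumeStack({"THG": img}, voxel_xy, voxel_z, stack_id, group)
    truth = SceneTruth(cells=cells, coupling_kappa=coupling_kappa, seed=seed)
    if fiber_truth is not None:
        truth.rotation_rate_deg_per_um = fiber_truth.rotation_rate_deg_per_um
        truth.base_theta_deg = fiber_truth.base_theta_deg
    return stack, truth


def generate_culture(
    *,
    shape=(15, 512, 512),
    voxel_xy: float = 0.2,
    voxel_z: float = 2.0,
    seed: int = 0,
    stack_id: str = "culture",
    group: str = "",
    fiber_kwargs: dict | None = None,
    cell_kwargs: dict | None = None,
):
    """Generate a two-channel culture stack (SHG fibers + THG cells).

    Both channels share the voxel grid, the depth-rotation of the dominant
    angle, and the fiber/cell orientation coupling. Sub-seeds for the two
    channels are derived deterministically from ``seed``.
    """
    fiber_kwargs = dict(fiber_kwargs or {})
    cell_kwargs = dict(cell_kwargs or {})
    common = dict(shape=shape, voxel_xy=voxel_xy, voxel_z=voxel_z)
    shg, fiber_truth = generate_fibers(
        seed=seed * 2 + 1, stack_id=stack_id, group=group,
        **common, **fiber_kwargs,
    )
    thg, cell_truth = generate_cells(
        seed=seed * 2 + 2, stack_id=stack_id, group=group,
        fiber_truth=fiber_truth, **common, **cell_kwargs,
    )
    stack = VolumeStack(
        {"SHG": shg.channel("SHG"), "THG": thg.channel("THG")},
        voxel_xy, voxel_z, stack_id, group,
    )
    truth = fiber_truth.merged_with(cell_truth)
    truth.seed = seed
    return stack, truth
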