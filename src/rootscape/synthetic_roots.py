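"""Stochastic 3D root-system simulator and turntable renderer.

Training a pixel segmenter and validating shape descriptors both need
images with known vector ground truth, which real root photographs never
carry. This module grows a root system as a set of 3D polyline axes —
adventitious primaries emerging below a short vertical stem, each axis a
biased random walk (Gaussian direction noise = tortuosity, a pull toward
the downward vertical = gravitropism), with lateral branches arising as
a Poisson process along the parent — then renders the system the way the
turntable sees it: rotated about the vertical axis by each requested
angle, orthographically projected, and rasterized with per-axis stroke
radius. Optional Gaussian blur and additive noise emulate the camera;
polarity can be bright-on-dark or dark-on-bright.

Because an orthographic projection foreshortens out-of-plane segments,
each rendered view records its own *projected* ground truth (projected
polyline length, tip count, crossing counts) next to the 3D totals; the
projected values are the correct oracle for anything measured on a 2D
view.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.draw import disk

from rootscape.errors import ParameterError, RootscapeError
from rootscape.image_io import RasterImage, write_manifest
from rootscape.segmentation import RootMask

_DOWN = np.array([0.0, 1.0, 0.0])  # +y is depth (image row)


@dataclass(frozen=True)
class SyntheticRootSpec:
    """Parameters of the stochastic root-system generator.

    Distances are in pixels, angles in the stated units. Defaults emulate
    a 40-day cutting in a transparent tube: a handful of adventitious
    axes, moderate gravitropic pull, about one lateral per 100 px of
    parent axis.
    """

    seed: int = 0
    n_primary: int = 3
    step_len: float = 4.0
    n_steps: int = 40
    tortuosity: float = 0.15          # σ of direction noise, rad/step
    gravitropism: float = 0.3         # blend weight toward vertical, [0, 1]
    branch_rate: float = 1.0          # expected branches per 100 px of parent
    branch_angle_mean: float = 50.0   # degrees off the parent direction
    branch_angle_sd: float = 12.0
    taper: float = 0.7                # radius decay per branch order
    base_radius: float = 2.0
    canvas: tuple[int, int] = (256, 256)   # (width, height)
    noise_sigma: float = 0.05
    blur_sigma: float = 1.0
    polarity: str = "bright_roots"
    stem_len: float = 10.0
    max_order: int = 3
    planar: bool = False
    no_overlap: bool = False
    no_overlap_angles: tuple[float, ...] = (0.0,)

    def validate(self) -> None:
        if self.seed < 0:
            raise ParameterError("seed must be non-negative")
        if self.n_primary < 1:
            raise ParameterError("n_primary must be >= 1")
        if self.step_len <= 0 or self.n_steps < 1:
            raise ParameterError("step_len must be > 0 and n_steps >= 1")
        for name in ("tortuosity", "branch_rate", "branch_angle_sd",
                     "noise_sigma", "blur_sigma", "stem_len"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0.0 <= self.gravitropism <= 1.0:
            raise ParameterError("gravitropism must be in [0, 1]")
        if self.base_radius < 0.5:
            raise ParameterError("base_radius must be >= 0.5")
        if not 0.0 < self.taper <= 1.0:
            raise ParameterError("taper must be in (0, 1]")
        if self.polarity not in ("bright_roots", "dark_roots"):
            raise ParameterError(f"unknown polarity {self.polarity!r}")
        w, h = self.canvas
        if w < 32 or h < 32 or h <= self.stem_len + 16:
            raise ParameterError("canvas too small to contain the crown")


@dataclass
class Axis:
    """One root axis: a 3D polyline with a stroke radius and lineage."""

    points: np.ndarray          # (n, 3): x (lateral), y (depth), z (out-of-plane)
    radius: float
    order: int                  # 0 = stem, 1 = primary, 2+ = laterals
    parent: int | None = None   # index into the axis list
    is_stem: bool = False

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class GroundTruth:
    """Exact quantities the generator knows about its own output."""

    total_length: float          # 3D arclength over all axes incl. stem
    tip_count: int               # distal tips (one per non-stem axis)
    polylines: list[np.ndarray]  # 3D points per axis


@dataclass
class ViewGroundTruth:
    """Projected ground truth for one rendered view."""

    angle_deg: float
    projected_length: float
    tip_count: int
    hori_row_counts: np.ndarray  # crossing count per bounding-box row
    cross_hori_mean: float
    cross_hori_max: int


@dataclass
class RenderedView:
    angle_deg: float
    image: RasterImage
    mask: RootMask
    ground_truth: ViewGroundTruth


def _perp_unit(d: np.ndarray, rng: np.random.Generator, planar: bool) -> np.ndarray:
    """A random unit vector perpendicular to d (in-plane when planar)."""
    if planar:
        u = np.array([-d[1], d[0], 0.0])
        n = np.linalg.norm(u)
        if n < 1e-9:  # d points out of plane; cannot happen for planar growth
            u, n = np.array([1.0, 0.0, 0.0]), 1.0
        return float(rng.choice([-1.0, 1.0])) * u / n
    while True:
        r = rng.normal(size=3)
        u = r - np.dot(r, d) * d
        n = np.linalg.norm(u)
        if n > 1e-9:
            return u / n


def _rotate_toward(
    d: np.ndarray, angle: float, rng: np.random.Generator, planar: bool = False
) -> np.ndarray:
    """Rotate d by `angle` radians about a random perpendicular axis."""
    u = _perp_unit(d, rng, planar)
    out = d * math.cos(angle) + u * math.sin(angle)
    return out / np.linalg.norm(out)


def _grow_axis(
    start: np.ndarray,
    direction: np.ndarray,
    n_steps: int,
    spec: SyntheticRootSpec,
    rng: np.random.Generator,
    radial_bound: float,
    depth_bound: float,
) -> tuple[np.ndarray, list[tuple[int, np.ndarray]]]:
    """Grow one axis; returns points and (vertex index, direction) branch seeds."""
    pts = [start.copy()]
    d = direction / np.linalg.norm(direction)
    branch_seeds: list[tuple[int, np.ndarray]] = []
    p_branch = min(1.0, spec.branch_rate * spec.step_len / 100.0)
    for _ in range(n_steps):
        if spec.tortuosity > 0:
            d = _rotate_toward(d, rng.normal(0.0, spec.tortuosity), rng, spec.planar)
        d = (1.0 - spec.gravitropism) * d + spec.gravitropism * _DOWN
        d = d / np.linalg.norm(d)
        nxt = pts[-1] + spec.step_len * d
        if math.hypot(nxt[0], nxt[2]) > radial_bound or nxt[1] > depth_bound:
            break  # truncate at the canvas so every rotation stays in frame
        pts.append(nxt)
        if rng.random() < p_branch:
            beta = math.radians(
                max(5.0, rng.normal(spec.branch_angle_mean, spec.branch_angle_sd))
            )
            branch_seeds.append((len(pts) - 1, _rotate_toward(d, beta, rng, spec.planar)))
    return np.array(pts), branch_seeds


def _generate_once(spec: SyntheticRootSpec, rng: np.random.Generator) -> list[Axis]:
    w, h = spec.canvas
    margin = max(4.0, spec.base_radius + 2.0)
    radial_bound = w / 2.0 - margin
    depth_bound = h - margin
    crown_top = np.array([0.0, margin, 0.0])
    crown_base = crown_top + np.array([0.0, spec.stem_len, 0.0])
    axes: list[Axis] = [
        Axis(points=np.vstack([crown_top, crown_base]), radius=spec.base_radius,
             order=0, is_stem=True)
    ]
    # primaries leave the crown at a random downward tilt and azimuth
    queue: list[tuple[np.ndarray, np.ndarray, int, int, int]] = []
    for _ in range(spec.n_primary):
        tilt = rng.uniform(0.0, math.radians(40.0))
        azim = rng.uniform(0.0, 2.0 * math.pi)
        if spec.planar:
            u = np.array([math.copysign(1.0, math.cos(azim)), 0.0, 0.0])
        else:
            u = np.array([math.cos(azim), 0.0, math.sin(azim)])
        d0 = _DOWN * math.cos(tilt) + u * math.sin(tilt)
        queue.append((crown_base.copy(), d0, 1, spec.n_steps, 0))

    while queue:
        start, d0, order, n_steps, parent = queue.pop(0)
        radius = max(0.5, spec.base_radius * spec.taper ** (order - 1))
        pts, seeds = _grow_axis(start, d0, n_steps, spec, rng, radial_bound, depth_bound)
        if len(pts) < 2:
            continue
        axes.append(Axis(points=pts, radius=radius, order=order, parent=parent))
        idx = len(axes) - 1
        if order < spec.max_order:
            child_steps = max(3, n_steps // 2)
            for vtx, bd in seeds:
                queue.append((pts[vtx].copy(), bd, order + 1, child_steps, idx))
    return axes


def _project(points: np.ndarray, angle_deg: float, canvas: tuple[int, int]) -> np.ndarray:
    """Rotate about the vertical axis and project to (row, col)."""
    theta = math.radians(angle_deg)
    x = points[:, 0] * math.cos(theta) + points[:, 2] * math.sin(theta)
    w, _ = canvas
    # center on (w-1)/2 so views at θ and θ+180° rasterize as exact mirrors
    return np.column_stack([points[:, 1], x + (w - 1) / 2.0])


def _densify(poly: np.ndarray, max_step: float = 0.75) -> np.ndarray:
    """Resample a polyline so consecutive points are <= max_step apart."""
    out = [poly[:1]]
    for a, b in zip(poly[:-1], poly[1:]):
        seg = np.linalg.norm(b - a)
        n = max(1, int(math.ceil(seg / max_step)))
        t = np.linspace(0.0, 1.0, n + 1)[1:]
        out.append(a[None, :] + t[:, None] * (b - a)[None, :])
    return np.vstack(out)


def _attachment_point(a: Axis, b: Axis) -> np.ndarray | None:
    """3D point where axes a and b legitimately touch, or None.

    Parent/child pairs touch at the child's start; the stem and a primary
    at the primary's start; sibling axes emerging from the same point
    (e.g. two primaries at the crown base) at that shared start.
    """
    if np.allclose(a.points[0], b.points[0]):
        return a.points[0]
    if a.is_stem and b.order == 1:
        return b.points[0]
    if b.is_stem and a.order == 1:
        return a.points[0]
    # parent-child: the child's first point lies on the parent polyline
    for child in (a, b):
        if child.parent is not None:
            parent = b if child is a else a
            d = np.linalg.norm(parent.points - child.points[0], axis=1)
            if d.min() < 1e-6:
                return child.points[0]
    return None


def _overlap_free(axes: list[Axis], spec: SyntheticRootSpec) -> bool:
    """True when projected strokes of distinct axes never merge.

    Pairs with a legitimate attachment (parent/child, stem/primary,
    siblings sharing a start point) may touch near that attachment; any
    other proximity below the combined stroke radii (plus a 2 px guard)
    at any checked angle rejects the sample. Self-contact of a tortuous
    axis is rejected the same way.
    """
    for angle in spec.no_overlap_angles:
        projs = [_densify(_project(a.points, angle, spec.canvas)) for a in axes]
        trees = [cKDTree(p) for p in projs]
        for i in range(len(axes)):
            # self-overlap: far-apart arclength positions must not touch
            pi = projs[i]
            if len(pi) > 8:
                touch = 2.0 * axes[i].radius + 1.5
                arclen = np.concatenate(
                    [[0.0], np.cumsum(np.linalg.norm(np.diff(pi, axis=0), axis=1))]
                )
                pairs = trees[i].query_pairs(touch, output_type="ndarray")
                if len(pairs):
                    sep = np.abs(arclen[pairs[:, 0]] - arclen[pairs[:, 1]])
                    if (sep > 3.0 * touch).any():
                        return False
            for j in range(i + 1, len(axes)):
                guard = axes[i].radius + axes[j].radius + 2.0
                attach3d = _attachment_point(axes[i], axes[j])
                dists, _ = trees[i].query(projs[j], k=1)
                if attach3d is None:
                    if (dists < guard).any():
                        return False
                else:
                    attach = _project(attach3d[None, :], angle, spec.canvas)[0]
                    far = np.linalg.norm(projs[j] - attach, axis=1) > 4.0 * guard
                    if (dists[far] < guard).any():
                        return False
                    # distal tips must emerge from the contact zone, or the
                    # thinned skeleton loses an endpoint
                    tip_j = dists[-1]
                    tip_i, _ = trees[j].query(projs[i][-1], k=1)
                    if (not axes[j].is_stem and tip_j < guard) or (
                        not axes[i].is_stem and tip_i < guard
                    ):
                        return False
    return True


def simulate_root_system(
    spec: SyntheticRootSpec, max_attempts: int = 300
) -> tuple[list[Axis], GroundTruth]:
    """Grow a root system; deterministic given ``spec.seed``.

    With ``spec.no_overlap`` set, candidate systems are resampled (with
    seeds derived from ``spec.seed``) until no two distinct axes merge in
    projection at the checked angles — the regime in which tip counts and
    crossing counts are exactly recoverable from a rendered view.
    """
    spec.validate()
    attempts = max_attempts if spec.no_overlap else 1
    for attempt in range(attempts):
        rng = np.random.default_rng([spec.seed, attempt])
        axes = _generate_once(spec, rng)
        if not spec.no_overlap or _overlap_free(axes, spec):
            gt = GroundTruth(
                total_length=float(sum(a.length for a in axes)),
                tip_count=sum(1 for a in axes if not a.is_stem),
                polylines=[a.points for a in axes],
            )
            return axes, gt
    raise RootscapeError(
        f"no overlap-free root system found in {max_attempts} attempts "
        f"(seed {spec.seed}); relax branch_rate or enlarge the canvas"
    )


def _row_run_counts(mask: np.ndarray) -> np.ndarray:
    """Per-row crossing counts of the bounding box, by explicit run walking.

    Kept as a plain loop, independent of the vectorized descriptor route,
    so rendered views carry a ground truth that does not share code with
    the measurement under test.
    """
    rows = np.nonzero(mask.any(axis=1))[0]
    counts = []
    for r in range(rows.min(), rows.max() + 1):
        inside = False
        n = 0
        for v in mask[r]:
            if v and not inside:
                n += 1
            inside = bool(v)
        counts.append(n)
    return np.array(counts)


def render_views(
    axes: list[Axis],
    spec: SyntheticRootSpec,
    angles: Sequence[float] = (0.0,),
) -> list[RenderedView]:
    """Render the system at each turntable angle.

    Each view rotates the polylines about the vertical axis, projects
    orthographically, and stamps discs of the axis stroke radius along the
    densified projected polyline; the mask is this exact rasterization and
    the image adds polarity, Gaussian blur and seeded additive noise.
    """
    if not axes:
        raise ParameterError("no polylines to render")
    spec.validate()
    w, h = spec.canvas
    views = []
    for vi, angle in enumerate(angles):
        if not 0 <= angle % 360 < 360:  # pragma: no cover - arithmetic guard
            raise ParameterError(f"bad angle {angle}")
        mask = np.zeros((h, w), dtype=bool)
        projected_length = 0.0
        for a in axes:
            proj = _project(a.points, angle, spec.canvas)
            projected_length += float(
                np.linalg.norm(np.diff(proj, axis=0), axis=1).sum()
            )
            for r, c in _densify(proj, max_step=0.5):
                rr, cc = disk((r, c), a.radius, shape=mask.shape)
                mask[rr, cc] = True
        image = mask.astype(float)
        if spec.blur_sigma > 0:
            image = ndi.gaussian_filter(image, spec.blur_sigma)
        if spec.noise_sigma > 0:
            noise_rng = np.random.default_rng([spec.seed, 7919, vi])
            image = image + noise_rng.normal(0.0, spec.noise_sigma, image.shape)
        image = np.clip(image, 0.0, 1.0)
        if spec.polarity == "dark_roots":
            image = 1.0 - image
        row_counts = _row_run_counts(mask)
        gt = ViewGroundTruth(
            angle_deg=float(angle),
            projected_length=projected_length,
            tip_count=sum(1 for a in axes if not a.is_stem),
            hori_row_counts=row_counts,
            cross_hori_mean=float(row_counts.mean()),
            cross_hori_max=int(row_counts.max()),
        )
        views.append(
            RenderedView(angle_deg=float(angle), image=RasterImage(values=image),
                         mask=RootMask(values=mask), ground_truth=gt)
        )
    return views


DEFAULT_SPEC_RANGES: dict[str, tuple[float, float]] = {
    "n_primary": (2, 5),
    "n_steps": (30, 50),
    "tortuosity": (0.05, 0.25),
    "gravitropism": (0.2, 0.6),
    "branch_rate": (0.5, 2.0),
    "base_radius": (1.5, 2.5),
}

_INT_FIELDS = {"n_primary", "n_steps", "seed"}


def sample_spec(
    rng: np.random.Generator,
    spec_ranges: dict[str, tuple[float, float]] | None = None,
    base: SyntheticRootSpec | None = None,
) -> SyntheticRootSpec:
    """Draw one spec uniformly within per-field (low, high) ranges."""
    ranges = dict(DEFAULT_SPEC_RANGES if spec_ranges is None else spec_ranges)
    base = base if base is not None else SyntheticRootSpec()
    updates = {}
    for name, (lo, hi) in ranges.items():
        if not hasattr(base, name):
            raise ParameterError(f"unknown spec field {name!r}")
        if hi < lo:
            raise ParameterError(f"invalid range for {name}: ({lo}, {hi})")
        if name in _INT_FIELDS:
            updates[name] = int(rng.integers(int(lo), int(hi) + 1))
        else:
            updates[name] = float(rng.uniform(lo, hi))
    updates["seed"] = int(rng.integers(0, 2**31 - 1))
    return replace(base, **updates)


def make_library(
    n_images: int,
    spec_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    angle: float = 0.0,
    base_spec: SyntheticRootSpec | None = None,
) -> list[dict]:
    """Build a synthetic training library: image/mask pairs + manifest.

    Samples ``n_images`` specs uniformly within ``spec_ranges`` (seeded),
    renders one view each, and — when ``out_dir`` is given — writes
    ``img_####.png``, ``mask_####.png`` and a ``manifest.json`` recording
    every spec and its ground-truth summary. Returns the records, each
    with the in-memory image, mask and ground truth attached.
    """
    if n_images < 1:
        raise ParameterError("n_images must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_images):
        spec = sample_spec(rng, spec_ranges, base=base_spec)
        axes, gt = simulate_root_system(spec)
        view = render_views(axes, spec, angles=(angle,))[0]
        records.append(
            {
                "index": i,
                "spec": spec,
                "image": view.image,
                "mask": view.mask,
                "ground_truth": gt,
                "view_ground_truth": view.ground_truth,
            }
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {"seed": seed, "n_images": n_images, "entries": []}
        for rec in records:
            i = rec["index"]
            img8 = (np.round(rec["image"].values * 255)).astype(np.uint8)
            Image.fromarray(img8).save(out_dir / f"img_{i:04d}.png")
            Image.fromarray(
                np.where(rec["mask"].values, 255, 0).astype(np.uint8)
            ).save(out_dir / f"mask_{i:04d}.png")
            spec_dict = asdict(rec["spec"])
            spec_dict["canvas"] = list(spec_dict["canvas"])
            spec_dict["no_overlap_angles"] = list(spec_dict["no_overlap_angles"])
            manifest["entries"].append(
                {
                    "image": f"img_{i:04d}.png",
                    "mask": f"mask_{i:04d}.png",
                    "spec": spec_dict,
                    "total_length": rec["ground_truth"].total_length,
                    "tip_count": rec["ground_truth"].tip_count,
                    "projected_length": rec["view_ground_truth"].projected_length,
                    "cross_hori_max": rec["view_ground_truth"].cross_hori_max,
                }
            )
        write_manifest(manifest, out_dir / "manifest.json")
    return records
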