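"""Layered root-shape descriptors: 16 macrophenotypes, 96 microphenotypes.

The trait set summarizes a segmented root system at two resolutions.
Macrophenotypes are whole-image scalars, split into 7 structural
descriptors (center of mass ``com_x``/``com_y``, ellipse-coverage
``ellips``, depth-strata ``rect``, ``convexhull`` area, per-layer shape
coordinate ``coord_x`` and its difference ``diff_x``) and 9 morphological
ones (``diam_mean``, ``length``, ``area``, ``directionality``,
``tip_count`` and the horizontal/vertical line-scan crossing statistics
``cross_{hori,vert}_{mean,max}``). Microphenotypes resolve six of these
along depth/width/size ladders — 30 horizontal and 30 vertical crossing
layers, 10 ``coord_x`` and 10 ``diff_x`` layers, 4 ``rect`` strata and a
12-rung ellipse ladder — giving fixed-length, GWAS-ready vectors.

All banded descriptors are computed over the root bounding box (not the
full frame) so they are invariant to framing and zoom; empty bands
report 0 so vector length never varies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from rootscape.errors import MeasurementError, ParameterError, ValidationError
from rootscape.segmentation import as_mask_array
from rootscape.skeleton_graph import (
    SkeletonGraph,
    count_tips,
    directionality,
    mean_diameter,
    measure_length,
    skeletonize,
)

STRUCTURAL = "structural"
MORPHOLOGICAL = "morphological"

#: Default ladder sizes, chosen so the registry totals 16 macro + 96 micro.
DEFAULT_CROSS_LAYERS = 30
DEFAULT_COORD_LAYERS = 10
DEFAULT_RECT_LAYERS = 4
DEFAULT_ELLIPS_LADDER = 12


@dataclass(frozen=True)
class TraitDescriptor:
    """One named trait channel block.

    ``layering="none"`` is a scalar macrophenotype; otherwise the block
    holds ``channels`` layer-resolved microphenotype channels.
    """

    name: str
    kind: str
    channels: int = 1
    layering: str = "none"  # none | horizontal_bands | vertical_bands | ellipse_ladder

    def __post_init__(self) -> None:
        if self.kind not in (STRUCTURAL, MORPHOLOGICAL):
            raise ParameterError(f"unknown trait kind {self.kind!r}")
        if self.channels < 1:
            raise ParameterError("channels must be >= 1")
        if self.layering == "none" and self.channels != 1:
            raise ParameterError("unlayered descriptors are scalar")

    def channel_names(self) -> list[str]:
        if self.layering == "none":
            return [self.name]
        base = self.name.removesuffix("_layers")
        if base.startswith("cross_"):
            # cross_hori_mean -> cross_hori_0_mean ... (published naming)
            prefix, stat = base.rsplit("_", 1)
            return [f"{prefix}_{i}_{stat}" for i in range(self.channels)]
        return [f"{base}_{i}" for i in range(self.channels)]


@dataclass(frozen=True)
class TraitRegistry:
    """Ordered trait channel layout shared by every vector and table."""

    descriptors: tuple[TraitDescriptor, ...]

    def __post_init__(self) -> None:
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ValidationError("descriptor names must be unique")

    @property
    def macro_count(self) -> int:
        return sum(d.channels for d in self.descriptors if d.layering == "none")

    @property
    def micro_count(self) -> int:
        return sum(d.channels for d in self.descriptors if d.layering != "none")

    @property
    def channel_count(self) -> int:
        return self.macro_count + self.micro_count

    @property
    def channel_names(self) -> tuple[str, ...]:
        out: list[str] = []
        for d in self.descriptors:
            out.extend(d.channel_names())
        return tuple(out)

    def get(self, name: str) -> TraitDescriptor:
        for d in self.descriptors:
            if d.name == name:
                return d
        raise KeyError(name)

    def to_json(self, path: str | Path) -> None:
        payload = [
            {"name": d.name, "kind": d.kind, "channels": d.channels,
             "layering": d.layering}
            for d in self.descriptors
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "TraitRegistry":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(tuple(TraitDescriptor(**d) for d in payload))


def default_registry(
    cross_layers: int = DEFAULT_CROSS_LAYERS,
    coord_layers: int = DEFAULT_COORD_LAYERS,
    rect_layers: int = DEFAULT_RECT_LAYERS,
    ellips_ladder: int = DEFAULT_ELLIPS_LADDER,
) -> TraitRegistry:
    """The default 16-macro / 96-micro registry."""
    S, M = STRUCTURAL, MORPHOLOGICAL
    macros = [
        TraitDescriptor("com_x", S), TraitDescriptor("com_y", S),
        TraitDescriptor("ellips", S), TraitDescriptor("rect", S),
        TraitDescriptor("convexhull", S), TraitDescriptor("coord_x", S),
        TraitDescriptor("diff_x", S),
        TraitDescriptor("diam_mean", M), TraitDescriptor("length", M),
        TraitDescriptor("area", M), TraitDescriptor("directionality", M),
        TraitDescriptor("tip_count", M),
        TraitDescriptor("cross_hori_mean", M), TraitDescriptor("cross_hori_max", M),
        TraitDescriptor("cross_vert_mean", M), TraitDescriptor("cross_vert_max", M),
    ]
    micros = [
        TraitDescriptor("ellips_layers", S, ellips_ladder, "ellipse_ladder"),
        TraitDescriptor("rect_layers", S, rect_layers, "horizontal_bands"),
        TraitDescriptor("coord_x_layers", S, coord_layers, "horizontal_bands"),
        TraitDescriptor("diff_x_layers", S, coord_layers, "horizontal_bands"),
        TraitDescriptor("cross_hori_mean_layers", M, cross_layers, "horizontal_bands"),
        TraitDescriptor("cross_vert_mean_layers", M, cross_layers, "vertical_bands"),
    ]
    return TraitRegistry(tuple(macros + micros))


@dataclass
class TraitVector:
    """One measured trait vector: registry layout + values + provenance."""

    registry: TraitRegistry
    values: np.ndarray
    provenance: object | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).ravel()
        if vals.size != self.registry.channel_count:
            raise ValidationError(
                f"vector length {vals.size} != registry channel count "
                f"{self.registry.channel_count}"
            )
        self.values = vals

    def __getitem__(self, name: str) -> float | np.ndarray:
        names = self.registry.channel_names
        start = 0
        for d in self.registry.descriptors:
            if d.name == name:
                block = self.values[start : start + d.channels]
                return float(block[0]) if d.channels == 1 else block
            start += d.channels
        if name in names:
            return float(self.values[names.index(name)])
        raise KeyError(name)


# --------------------------------------------------------------------------
# banding helpers

def _bbox(vals: np.ndarray):
    rows, cols = np.nonzero(vals)
    return rows.min(), rows.max(), cols.min(), cols.max()


def _band_edges(extent: int, layers: int) -> list[tuple[int, int]]:
    """Half-open equal bands over [0, extent); last band absorbs remainder."""
    base = extent // layers
    edges = []
    for i in range(layers):
        lo = i * base
        hi = (i + 1) * base if i < layers - 1 else extent
        edges.append((lo, hi))
    return edges


def _require_nonempty(vals: np.ndarray) -> None:
    if not vals.any():
        raise MeasurementError("descriptor requested on an empty mask")


# --------------------------------------------------------------------------
# structural descriptors

def center_of_mass(mask) -> tuple[float, float]:
    """Foreground centroid normalized by the root bounding box.

    Returns ``(com_x, com_y)`` in [0, 1]; a degenerate 1-px-wide box
    reports 0.5 on that axis.
    """
    vals = as_mask_array(mask)
    _require_nonempty(vals)
    rows, cols = np.nonzero(vals)
    r0, r1, c0, c1 = _bbox(vals)
    com_x = 0.5 if c1 == c0 else (cols.mean() - c0) / (c1 - c0)
    com_y = 0.5 if r1 == r0 else (rows.mean() - r0) / (r1 - r0)
    return float(com_x), float(com_y)


def convex_hull_area(mask) -> float:
    """Shoelace area of the convex hull of foreground pixel centers.

    Degenerate (collinear or single-point) masks report 0.
    """
    vals = as_mask_array(mask)
    _require_nonempty(vals)
    pts = np.argwhere(vals).astype(float)
    if len(pts) < 3:
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0  # collinear point set
    return float(hull.volume)  # in 2D, .volume is the polygon area


def rect_profile(mask, layers: int = DEFAULT_RECT_LAYERS) -> np.ndarray:
    """Fraction of root area in each of ``layers`` depth strata; sums to 1."""
    vals = as_mask_array(mask)
    _require_nonempty(vals)
    if layers < 1:
        raise ParameterError("layers must be >= 1")
    r0, r1, _, _ = _bbox(vals)
    counts = vals.sum(axis=1)[r0 : r1 + 1].astype(float)
    total = counts.sum()
    return np.array(
        [counts[lo:hi].sum() / total for lo, hi in _band_edges(len(counts), layers)]
    )


def ellips_profile(mask, ladder: int = DEFAULT_ELLIPS_LADDER) -> np.ndarray:
    """Fraction of root area inside a ladder of apex-centered ellipses.

    The apex is the centroid of the topmost foreground row; ellipse k of K
    has semi-axes ``(k/K) * s_max`` times the base shape (half the
    bounding-box width horizontally, its full depth vertically), where
    ``s_max`` normalizes so the final ellipse just covers the root. The
    profile is non-decreasing and ends at exactly 1.
    """
    vals = as_mask_array(mask)
    _require_nonempty(vals)
    if ladder < 1:
        raise ParameterError("ladder must be >= 1")
    rows, cols = np.nonzero(vals)
    r0, r1, c0, c1 = _bbox(vals)
    apex_r = float(r0)
    apex_c = float(cols[rows == r0].mean())
    a0 = max((c1 - c0 + 1) / 2.0, 1.0)
    b0 = max(float(r1 - r0 + 1), 1.0)
    s = np.sqrt(((cols - apex_c) / a0) ** 2 + ((rows - apex_r) / b0) ** 2)
    s_max = s.max()
    thresholds = (np.arange(1, ladder + 1) / ladder) * s_max
    return np.array([(s <= t).mean() for t in thresholds])


def coord_x_profile(mask, layers: int = DEFAULT_COORD_LAYERS) -> np.ndarray:
    """Normalized root width per depth layer.

    Layer i reports ``(max_col - min_col + 1) / W`` over the foreground in
    that band of the bounding box (W = bounding-box width); empty bands
    report 0.
    """
    vals = as_mask_array(mask)
    _require_nonempty(vals)
    if layers < 1:
        raise ParameterError("layers must be >= 1")
    r0, r1, c0, c1 = _bbox(vals)
    W = c1 - c0 + 1
    box = vals[r0 : r1 + 1, :]
    out = np.zeros(layers)
    for i, (lo, hi) in enumerate(_band_edges(box.shape[0], layers)):
        band_cols = np.nonzero(box[lo:hi].any(axis=0))[0]
        if band_cols.size:
            out[i] = (band_cols.max() - band_cols.min() + 1) / W
    return out


def diff_x_profile(coord_x: np.ndarray) -> np.ndarray:
    """Layer-to-layer difference of ``coord_x``; larger values mean a
    faster-opening root system at that depth. Layer 0 repeats coord_x_0."""
    coord_x = np.asarray(coord_x, dtype=float)
    out = np.empty_like(coord_x)
    out[0] = coord_x[0]
    out[1:] = np.diff(coord_x)
    return out


class CrossingProfile(NamedTuple):
    """Per-layer mean crossing counts plus global (mean, max)."""

    layer_means: np.ndarray
    mean: float
    max: int


def _run_counts(lines: np.ndarray) -> np.ndarray:
    """Count maximal foreground runs along axis 1 for each line (row)."""
    padded = np.pad(lines.astype(np.int8), ((0, 0), (1, 0)))
    starts = (np.diff(padded, axis=1) == 1).sum(axis=1)
    return starts


def crossing_counts(mask, axis: str = "horizontal", layers: int = DEFAULT_CROSS_LAYERS) -> CrossingProfile:
    """Line-scan crossing counts: disjoint root runs per scan line.

    ``axis="horizontal"`` scans every row of the root bounding box with a
    horizontal line (the classic lateral-root-count proxy);
    ``axis="vertical"`` scans columns. Layer channels average the counts
    within equal bands of the bounding box.
    """
    vals = as_mask_array(mask)
    _require_nonempty(vals)
    if layers < 1:
        raise ParameterError("layers must be >= 1")
    if axis not in ("horizontal", "vertical"):
        raise ParameterError(f"axis must be horizontal or vertical, got {axis!r}")
    r0, r1, c0, c1 = _bbox(vals)
    if axis == "horizontal":
        lines = vals[r0 : r1 + 1, c0 : c1 + 1]
    else:
        lines = vals[r0 : r1 + 1, c0 : c1 + 1].T
    counts = _run_counts(lines).astype(float)
    layer_means = np.zeros(layers)
    for i, (lo, hi) in enumerate(_band_edges(len(counts), layers)):
        if hi > lo:
            layer_means[i] = counts[lo:hi].mean()
    return CrossingProfile(
        layer_means=layer_means, mean=float(counts.mean()), max=int(counts.max())
    )


# --------------------------------------------------------------------------
# full vector

def _validate_pair(vals: np.ndarray, graph: SkeletonGraph) -> None:
    if graph.mask_shape is not None and tuple(graph.mask_shape) != vals.shape:
        raise ValidationError("skeleton graph was built from a different mask (shape)")
    if graph.skeleton is not None and not vals[graph.skeleton].all():
        raise ValidationError("skeleton graph is not contained in the mask")
    if vals.any() and graph.is_empty():
        raise ValidationError("nonempty mask but empty skeleton graph")


def compute_trait_vector(
    mask, graph: SkeletonGraph | None = None, registry: TraitRegistry | None = None,
    provenance=None,
) -> TraitVector:
    """Fill every registry channel from a mask and its skeleton graph.

    Macro summaries of the layered blocks: ``ellips`` is the coverage of
    the mid-ladder ellipse (rung ceil(K/2)), ``rect`` the top-stratum
    share, ``coord_x`` the mean over layers, ``diff_x`` the mean over
    layers 1..L-1. ``directionality`` reports 0 for a skeleton with no
    edges (single-pixel root). Deterministic.
    """
    vals = as_mask_array(mask)
    _require_nonempty(vals)
    if registry is None:
        registry = default_registry()
    if graph is None:
        graph = skeletonize(vals)
    _validate_pair(vals, graph)

    sizes = {d.name: d.channels for d in registry.descriptors}
    K = sizes.get("ellips_layers", DEFAULT_ELLIPS_LADDER)
    L_rect = sizes.get("rect_layers", DEFAULT_RECT_LAYERS)
    L_coord = sizes.get("coord_x_layers", DEFAULT_COORD_LAYERS)
    L_cross = sizes.get("cross_hori_mean_layers", DEFAULT_CROSS_LAYERS)

    com_x, com_y = center_of_mass(vals)
    ellips = ellips_profile(vals, K)
    rect = rect_profile(vals, L_rect)
    coord_x = coord_x_profile(vals, L_coord)
    diff_x = diff_x_profile(coord_x)
    hori = crossing_counts(vals, "horizontal", L_cross)
    vert = crossing_counts(vals, "vertical", L_cross)
    try:
        direction = directionality(graph)
    except MeasurementError:
        direction = 0.0

    blocks = {
        "com_x": com_x,
        "com_y": com_y,
        "ellips": float(ellips[int(np.ceil(K / 2)) - 1]),
        "rect": float(rect[0]),
        "convexhull": convex_hull_area(vals),
        "coord_x": float(coord_x.mean()),
        "diff_x": float(diff_x[1:].mean()) if L_coord > 1 else float(diff_x[0]),
        "diam_mean": mean_diameter(graph),
        "length": measure_length(graph),
        "area": float(vals.sum()),
        "directionality": direction,
        "tip_count": float(count_tips(graph)),
        "cross_hori_mean": hori.mean,
        "cross_hori_max": float(hori.max),
        "cross_vert_mean": vert.mean,
        "cross_vert_max": float(vert.max),
        "ellips_layers": ellips,
        "rect_layers": rect,
        "coord_x_layers": coord_x,
        "diff_x_layers": diff_x,
        "cross_hori_mean_layers": hori.layer_means,
        "cross_vert_mean_layers": vert.layer_means,
    }
    out = []
    for d in registry.descriptors:
        if d.name not in blocks:
            raise ValidationError(f"registry descriptor {d.name!r} is not computable")
        block = np.atleast_1d(np.asarray(blocks[d.name], dtype=float))
        if block.size != d.channels:
            raise ValidationError(
                f"descriptor {d.name!r} produced {block.size} channels, "
                f"registry expects {d.channels}"
            )
        out.append(block)
    return TraitVector(registry=registry, values=np.concatenate(out), provenance=provenance)


class TraitExtractor:
    """Transformer-style front end: masks in, trait matrix out.

    ``transform`` accepts a sequence of RootMasks (or boolean arrays),
    skeletonizes each and returns an (n_masks, n_channels) array in the
    registry's column order. Stateless; ``fit`` is a no-op for pipeline
    compatibility.
    """

    def __init__(self, registry: TraitRegistry | None = None):
        self.registry = registry if registry is not None else default_registry()

    def get_params(self, deep: bool = True) -> dict:
        return {"registry": self.registry}

    def set_params(self, **params) -> "TraitExtractor":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "TraitExtractor":
        return self

    def transform(self, masks: Sequence) -> np.ndarray:
        rows = [compute_trait_vector(m, registry=self.registry).values for m in masks]
        return np.vstack(rows) if rows else np.zeros((0, self.registry.channel_count))

    def fit_transform(self, masks: Sequence, y=None) -> np.ndarray:
        return self.fit().transform(masks)
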