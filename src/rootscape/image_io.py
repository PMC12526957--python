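"""Image, mask and table I/O plus filename metadata parsing.

The acquisition protocol this package targets photographs each plant on a
turntable in fixed angular steps (15° by default, i.e. 24 views), with
several biological replicates per accession. Nothing about the accession,
replicate or camera angle is stored inside the image files, so the view
key is carried by the filename and recovered with a user-supplied pattern
such as ``"{accession}_r{replicate}_a{angle}.png"``.

Conventions used throughout the package:

* images are normalized to float intensities in ``[0, 1]``
  (8-bit values divided by 255, 16-bit by 65535);
* RGB is collapsed to ITU-R 601 luminance ``0.299 R + 0.587 G + 0.114 B``;
* pixel indexing is 0-based ``(row, col)`` with the origin at the top-left,
  so the row index increases with depth below the crown.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from rootscape.errors import FormatError, ParseError, SchemaError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from rootscape.descriptors import TraitRegistry

#: ITU-R 601 luminance weights for RGB→gray conversion.
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)

KEY_COLUMNS = ("accession", "replicate", "angle")


@dataclass(frozen=True)
class RasterImage:
    """A grayscale raster normalized to ``[0, 1]``.

    Attributes
    ----------
    values : ndarray, shape (height, width)
        Float intensities in ``[0, 1]``; row index = depth.
    bit_depth_source : int
        Bit depth of the source file (8 or 16).
    channels_source : str
        ``"gray"`` or ``"rgb"``.
    """

    values: np.ndarray
    bit_depth_source: int = 8
    channels_source: str = "gray"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] < 1 or vals.shape[1] < 1:
            raise ValidationError("image must be a 2D grid with width, height >= 1")
        if vals.min() < 0.0 or vals.max() > 1.0:
            raise ValidationError("image values must lie in [0, 1]")
        object.__setattr__(self, "values", vals)

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def height(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True, order=True)
class ViewKey:
    """Identity of one view: accession, biological replicate, turntable angle."""

    accession_id: str
    replicate: int
    angle_deg: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if not 0 <= self.angle_deg < 360:
            raise ValidationError(f"angle_deg must be in [0, 360), got {self.angle_deg}")


def load_image(path: str | Path) -> RasterImage:
    """Read a PNG or TIFF image as a normalized grayscale :class:`RasterImage`.

    8-bit values are divided by 255 and 16-bit by 65535; RGB is converted to
    ITU-R 601 luminance before normalization. Raises ``FileNotFoundError``
    for a missing file and :class:`FormatError` for unsupported formats or
    bit depths, naming the offending path.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if path.suffix.lower() not in {".png", ".tif", ".tiff"}:
        raise FormatError(f"unsupported image format (expect PNG/TIFF): {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except UnidentifiedImageError as exc:
        raise FormatError(f"cannot decode image: {path}") from exc

    if arr.ndim == 3:
        if arr.shape[2] < 3:
            raise FormatError(f"unsupported channel count {arr.shape[2]}: {path}")
        channels = "rgb"
        rgb = arr[:, :, :3].astype(float)
        gray = (
            LUMINANCE_WEIGHTS[0] * rgb[:, :, 0]
            + LUMINANCE_WEIGHTS[1] * rgb[:, :, 1]
            + LUMINANCE_WEIGHTS[2] * rgb[:, :, 2]
        )
        source_dtype = arr.dtype
    elif arr.ndim == 2:
        channels = "gray"
        gray = arr.astype(float)
        source_dtype = arr.dtype
    else:
        raise FormatError(f"unsupported image dimensionality {arr.ndim}: {path}")

    if source_dtype == np.uint8:
        bit_depth, scale = 8, 255.0
    elif source_dtype in (np.uint16, np.int32):  # PIL reads 16-bit PNG as int32
        bit_depth, scale = 16, 65535.0
    else:
        raise FormatError(f"unsupported bit depth {source_dtype}: {path}")

    values = np.clip(gray / scale, 0.0, 1.0)
    return RasterImage(values=values, bit_depth_source=bit_depth, channels_source=channels)


def load_mask(path: str | Path):
    """Read a binary mask image (background 0, foreground 255) as a RootMask."""
    from rootscape.segmentation import RootMask

    img = load_image(path)
    return RootMask(values=img.values >= 0.5)


_FIELD_PATTERNS = {
    "accession": r"(?P<accession>[A-Za-z0-9.\-]+?)",
    "replicate": r"(?P<replicate>\d+)",
    "angle": r"(?P<angle>-?\d+)",
}


def _compile_pattern(pattern: str) -> re.Pattern:
    out = []
    pos = 0
    for m in re.finditer(r"\{(accession|replicate|angle)\}", pattern):
        out.append(re.escape(pattern[pos : m.start()]))
        out.append(_FIELD_PATTERNS[m.group(1)])
        pos = m.end()
    out.append(re.escape(pattern[pos:]))
    regex = "".join(out)
    for name in ("accession", "replicate", "angle"):
        if f"(?P<{name}>" not in regex:
            raise ParseError(f"pattern is missing the {{{name}}} field: {pattern!r}")
    return re.compile(regex)


def parse_view_metadata(filename: str, pattern: str, step_deg: int = 15) -> ViewKey:
    """Parse accession/replicate/angle from a filename.

    ``pattern`` is a template with ``{accession}``, ``{replicate}`` and
    ``{angle}`` placeholders. The angle is normalized to ``[0, 360)`` and
    must be a multiple of ``step_deg``.
    """
    name = Path(filename).name
    m = _compile_pattern(pattern).fullmatch(name)
    if m is None:
        raise ParseError(f"filename {name!r} does not match pattern {pattern!r}")
    angle = int(m.group("angle")) % 360
    if step_deg >= 1 and angle % step_deg != 0:
        raise ValidationError(
            f"angle {angle} is not a multiple of the {step_deg}° step in {name!r}"
        )
    return ViewKey(accession_id=m.group("accession"), replicate=int(m.group("replicate")), angle_deg=angle)


@dataclass
class TraitTable:
    """Rows of (view key, trait vector) sharing one registry's column order."""

    registry: "TraitRegistry"
    keys: list[ViewKey] = field(default_factory=list)
    values: np.ndarray | None = None  # (n_rows, n_channels)

    def __post_init__(self) -> None:
        n = len(self.keys)
        if self.values is None:
            self.values = np.zeros((0, self.registry.channel_count), dtype=float)
        self.values = np.asarray(self.values, dtype=float).reshape(
            n, self.registry.channel_count
        )
        if len({(k.accession_id, k.replicate, k.angle_deg) for k in self.keys}) != n:
            raise ValidationError("duplicate (accession, replicate, angle) keys")

    def __len__(self) -> int:
        return len(self.keys)

    def append(self, key: ViewKey, vector) -> None:
        vals = np.asarray(getattr(vector, "values", vector), dtype=float)
        if vals.shape != (self.registry.channel_count,):
            raise ValidationError(
                f"vector length {vals.size} != registry channel count "
                f"{self.registry.channel_count}"
            )
        self.keys.append(key)
        self.values = np.vstack([self.values, vals[None, :]])
        if len({(k.accession_id, k.replicate, k.angle_deg) for k in self.keys}) != len(self.keys):
            raise ValidationError("duplicate (accession, replicate, angle) keys")

    def to_frame(self) -> pd.DataFrame:
        keys = pd.DataFrame(
            {
                "accession": [k.accession_id for k in self.keys],
                "replicate": [k.replicate for k in self.keys],
                "angle": [k.angle_deg for k in self.keys],
            }
        )
        vals = pd.DataFrame(self.values, columns=list(self.registry.channel_names))
        return pd.concat([keys, vals], axis=1)


def write_trait_table(
    table: TraitTable, path: str | Path, header_comments: Sequence[str] = ()
) -> None:
    """Write a trait table as UTF-8 CSV: key columns, then registry channels.

    Optional ``header_comments`` are emitted as ``#``-prefixed lines before
    the header (used by the CLI for provenance). Values are written with 17
    significant digits so a read→write round trip is lossless.
    """
    path = Path(path)
    df = table.to_frame()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_trait_table(path: str | Path, registry: "TraitRegistry | None" = None) -> TraitTable:
    """Read a CSV trait table, validating the header against the registry."""
    if registry is None:
        from rootscape.descriptors import default_registry

        registry = default_registry()
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    expected = list(KEY_COLUMNS) + list(registry.channel_names)
    if list(df.columns) != expected:
        missing = [c for c in expected if c not in df.columns]
        extra = [c for c in df.columns if c not in expected]
        raise SchemaError(
            f"trait table header does not match registry at {path}: "
            f"missing={missing[:5]}, unexpected={extra[:5]}"
        )
    keys = [
        ViewKey(str(a), int(r), int(g))
        for a, r, g in zip(df["accession"], df["replicate"], df["angle"])
    ]
    values = df[list(registry.channel_names)].to_numpy(dtype=float)
    return TraitTable(registry=registry, keys=keys, values=values)


def write_manifest(manifest: dict, path: str | Path) -> None:
    """Write a JSON manifest (specs, ground truth, provenance)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
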