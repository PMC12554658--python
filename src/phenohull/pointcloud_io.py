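"""Colored point-cloud I/O for single plants.

Two plain-text interchange formats are supported:

* **ASCII PLY** — ``element vertex N`` with float properties ``x y z`` and
  uchar (or float-in-[0,1]) properties ``red green blue``.  Binary PLY is
  rejected: every fixture in the test suite must stay diffable text.
* **XYZRGB** — whitespace-delimited, one point per line
  (``x y z [r g b]``), ``#`` comment lines ignored.  Missing color columns
  default to black.

Colors are held internally as 8-bit integers; float PLY colors in [0, 1]
are scaled by 255 and rounded on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "PointCloud",
    "PointCloudParseError",
    "read_point_cloud",
    "write_point_cloud",
]

Format = Literal["ply_ascii", "xyzrgb"]


class PointCloudParseError(ValueError):
    """Malformed point-cloud file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class PointCloud:
    """N colored 3D points in model units.

    Parameters
    ----------
    coords
        ``(N, 3)`` float array of positions.
    colors
        ``(N, 3)`` uint8 array of RGB values.
    name
        Free-text identifier (defaults to empty).
    """

    coords: np.ndarray
    colors: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.colors = np.asarray(self.colors).reshape(-1, 3)
        if len(self.coords) != len(self.colors):
            raise ValueError(
                f"coords ({len(self.coords)}) and colors ({len(self.colors)}) "
                "must have equal length"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.colors.size and (
            self.colors.min() < 0 or self.colors.max() > 255
        ):
            raise ValueError("color channels must be in [0, 255]")
        self.colors = self.colors.astype(np.uint8)

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_points(self) -> int:
        return len(self.coords)

    def replace(self, coords=None, colors=None, name=None) -> "PointCloud":
        return PointCloud(
            coords=self.coords if coords is None else coords,
            colors=self.colors if colors is None else colors,
            name=self.name if name is None else name,
        )


def _sniff_format(path: str | os.PathLike) -> Format:
    with open(path, "rb") as fh:
        magic = fh.read(3)
    return "ply_ascii" if magic == b"ply" else "xyzrgb"


def read_point_cloud(
    path: str | os.PathLike, format: Format | None = None
) -> PointCloud:
    """Read a colored point cloud from an ASCII PLY or XYZRGB text file.

    ``format=None`` sniffs the format from the file's magic bytes.  The
    returned cloud has one entry per file record, in file order; records
    without color columns get ``(0, 0, 0)``.

    Raises
    ------
    PointCloudParseError
        On a malformed header, a non-numeric field, a color channel out of
        range, or a record count that disagrees with the header.
    """
    path = Path(path)
    if format is None:
        format = _sniff_format(path)
    if format == "ply_ascii":
        cloud = _read_ply_ascii(path)
    elif format == "xyzrgb":
        cloud = _read_xyzrgb(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return cloud.replace(name=path.stem)


def write_point_cloud(
    cloud: PointCloud, path: str | os.PathLike, format: Format = "ply_ascii"
) -> None:
    """Write a cloud so that reading it back reproduces coords within 1e-6
    and colors exactly (coordinates are printed with 9 significant digits)."""
    path = Path(path)
    if format == "ply_ascii":
        _write_ply_ascii(cloud, path)
    elif format == "xyzrgb":
        _write_xyzrgb(cloud, path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------- XYZRGB


def _read_xyzrgb(path: Path) -> PointCloud:
    coords: list[list[float]] = []
    colors: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) not in (3, 6):
                raise PointCloudParseError(
                    f"expected 3 or 6 columns, got {len(fields)}", lineno
                )
            try:
                values = [float(f) for f in fields]
            except ValueError:
                raise PointCloudParseError(
                    f"non-numeric field in {fields!r}", lineno
                ) from None
            coords.append(values[:3])
            rgb = values[3:] if len(values) == 6 else [0.0, 0.0, 0.0]
            for c in rgb:
                if not 0 <= c <= 255:
                    raise PointCloudParseError(
                        f"color channel {c} out of [0, 255]", lineno
                    )
            colors.append(rgb)
    return PointCloud(
        coords=np.array(coords, dtype=float).reshape(-1, 3),
        colors=np.rint(np.array(colors, dtype=float).reshape(-1, 3)),
    )


def _write_xyzrgb(cloud: PointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        for (x, y, z), (r, g, b) in zip(cloud.coords, cloud.colors):
            fh.write(f"{x:.9g} {y:.9g} {z:.9g} {r:d} {g:d} {b:d}\n")


# ---------------------------------------------------------------- ASCII PLY

_PLY_FLOAT_TYPES = {"float", "float32", "float64", "double"}
_PLY_UCHAR_TYPES = {"uchar", "uint8", "char", "int8"}
_COLOR_ALIASES = {
    "red": "red", "green": "green", "blue": "blue",
    "r": "red", "g": "green", "b": "blue",
    "diffuse_red": "red", "diffuse_green": "green", "diffuse_blue": "blue",
}


def _read_ply_ascii(path: Path) -> PointCloud:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise PointCloudParseError("missing 'ply' magic", 1)

    n_vertices = None
    properties: list[tuple[str, str]] = []  # (type, name), vertex element only
    in_vertex_element = False
    element_seen_other = False
    body_start = None
    lineno = 1
    for lineno, line in enumerate(lines[1:], start=2):
        tokens = line.split()
        if not tokens or tokens[0] == "comment":
            continue
        if tokens[0] == "format":
            if len(tokens) < 2 or tokens[1] != "ascii":
                raise PointCloudParseError(
                    "only 'format ascii 1.0' PLY is supported "
                    "(binary PLY rejected)",
                    lineno,
                )
        elif tokens[0] == "element":
            if len(tokens) != 3:
                raise PointCloudParseError("malformed element line", lineno)
            if tokens[1] == "vertex":
                try:
                    n_vertices = int(tokens[2])
                except ValueError:
                    raise PointCloudParseError(
                        f"bad vertex count {tokens[2]!r}", lineno
                    ) from None
                in_vertex_element = True
            else:
                in_vertex_element = False
                element_seen_other = True
        elif tokens[0] == "property":
            if in_vertex_element:
                if len(tokens) != 3:
                    raise PointCloudParseError(
                        "only scalar vertex properties supported", lineno
                    )
                properties.append((tokens[1], tokens[2]))
        elif tokens[0] == "end_header":
            body_start = lineno
            break
        else:
            raise PointCloudParseError(
                f"unexpected header keyword {tokens[0]!r}", lineno
            )
    if body_start is None:
        raise PointCloudParseError("missing end_header", lineno)
    if n_vertices is None:
        raise PointCloudParseError("no 'element vertex' in header", body_start)
    if element_seen_other:
        raise PointCloudParseError(
            "non-vertex elements are not supported", body_start
        )

    names = [name for _, name in properties]
    for axis in ("x", "y", "z"):
        if axis not in names:
            raise PointCloudParseError(
                f"vertex element lacks property {axis!r}", body_start
            )
    col_idx = {name: i for i, (_, name) in enumerate(properties)}
    color_types = {
        _COLOR_ALIASES[name]: typ
        for typ, name in properties
        if name in _COLOR_ALIASES
    }
    has_color = set(color_types) == {"red", "green", "blue"}

    body = [
        (body_start + 1 + i, line)
        for i, line in enumerate(lines[body_start:])
        if line.strip()
    ]
    if len(body) != n_vertices:
        raise PointCloudParseError(
            f"header declares {n_vertices} vertices but body has {len(body)}",
            body[-1][0] if body else body_start,
        )

    coords = np.empty((n_vertices, 3), dtype=float)
    colors = np.zeros((n_vertices, 3), dtype=float)
    for row, (lineno, line) in enumerate(body):
        fields = line.split()
        if len(fields) != len(properties):
            raise PointCloudParseError(
                f"expected {len(properties)} fields, got {len(fields)}", lineno
            )
        try:
            values = [float(f) for f in fields]
        except ValueError:
            raise PointCloudParseError(
                f"non-numeric field in {fields!r}", lineno
            ) from None
        coords[row] = [values[col_idx[a]] for a in ("x", "y", "z")]
        if has_color:
            rgb = []
            for channel in ("red", "green", "blue"):
                idx = next(
                    col_idx[n] for n in names
                    if _COLOR_ALIASES.get(n) == channel
                )
                v = values[idx]
                if color_types[channel] in _PLY_FLOAT_TYPES:
                    if not 0.0 <= v <= 1.0:
                        raise PointCloudParseError(
                            f"float color {v} out of [0, 1]", lineno
                        )
                    v = round(v * 255)
                elif not 0 <= v <= 255:
                    raise PointCloudParseError(
                        f"color channel {v} out of [0, 255]", lineno
                    )
                rgb.append(v)
            colors[row] = rgb
    return PointCloud(coords=coords, colors=np.rint(colors))


def _write_ply_ascii(cloud: PointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(cloud)}\n")
        fh.write(
            "property float x\nproperty float y\nproperty float z\n"
            "property uchar red\nproperty uchar green\nproperty uchar blue\n"
        )
        fh.write("end_header\n")
        for (x, y, z), (r, g, b) in zip(cloud.coords, cloud.colors):
            fh.write(f"{x:.9g} {y:.9g} {z:.9g} {r:d} {g:d} {b:d}\n")
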