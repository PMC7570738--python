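"""Readers and writers for the pipeline's file formats, plus species tables.

Two formats matter: PTS (plain-text colored point clouds, the scanner's raw
export) and STL (triangle surface models, ASCII or binary). Everything is
normalised on read to the package's canonical unit, centimetres, with the
z axis pointing up.

PTS dialects vary between exporters; both the 6-column ``x y z r g b`` and
the 7-column ``x y z intensity r g b`` layouts are accepted, with an
optional leading point-count header. The intensity column is discarded.
"""

from __future__ import annotations

import configparser
import io
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import trimesh

__all__ = [
    "ColoredPointCloud",
    "TriangleMesh",
    "RGBGate",
    "SpeciesParams",
    "PTSParseError",
    "STLFormatError",
    "SpeciesConfigError",
    "read_pts",
    "write_pts",
    "read_stl",
    "write_stl",
    "load_species_config",
    "default_species",
]

#: multiplicative factor taking a coordinate in `unit` to centimetres
_UNIT_TO_CM = {"mm": 0.1, "cm": 1.0, "m": 100.0}


class PTSParseError(ValueError):
    """A PTS file row or header could not be parsed."""


class STLFormatError(ValueError):
    """An STL file is neither valid ASCII nor a consistent binary body."""


class SpeciesConfigError(ValueError):
    """A species config block is missing a field or holds an invalid value."""


@dataclass
class ColoredPointCloud:
    """A set of 3D points with per-point RGB color.

    Parameters
    ----------
    points : (N, 3) float array
        XYZ coordinates in centimetres, z-up.
    colors : (N, 3) int array
        RGB channel values, each in [0, 255].
    source_unit : {"mm", "cm", "m"}
        Unit the coordinates were originally expressed in (bookkeeping
        only; `points` is always cm).
    """

    points: np.ndarray
    colors: np.ndarray
    source_unit: str = "cm"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.colors = np.asarray(self.colors, dtype=np.int64).reshape(-1, 3)
        if self.points.shape[0] != self.colors.shape[0]:
            raise ValueError(
                f"points ({self.points.shape[0]}) and colors "
                f"({self.colors.shape[0]}) must have equal row counts"
            )
        if self.source_unit not in _UNIT_TO_CM:
            raise ValueError(f"unknown unit {self.source_unit!r}")
        if self.points.size and not np.isfinite(self.points).all():
            raise ValueError("point coordinates must be finite")
        if self.colors.size and (
            self.colors.min() < 0 or self.colors.max() > 255
        ):
            raise ValueError("color channels must lie in [0, 255]")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class TriangleMesh:
    """A triangle soup: shared vertex table plus per-triangle vertex indices.

    Coordinates are centimetres, z-up. Connectivity is whatever the source
    provided; surface-area integration needs none.
    """

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.vertices.size and not np.isfinite(self.vertices).all():
            raise ValueError("vertex coordinates must be finite")
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
                raise ValueError("triangle indices out of range")
            t = self.triangles
            if ((t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])).any():
                raise ValueError("a triangle repeats a vertex index")

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def triangle_vertices(self) -> np.ndarray:
        """Return a (T, 3, 3) array of the corner coordinates per triangle."""
        return self.vertices[self.triangles]


@dataclass(frozen=True)
class RGBGate:
    """Per-channel color bounds; all stated bounds are strict inequalities.

    A point passes when every stated bound holds: channel > min and
    channel < max. ``None`` leaves that side unbounded.
    """

    r_min: Optional[int] = None
    r_max: Optional[int] = None
    g_min: Optional[int] = None
    g_max: Optional[int] = None
    b_min: Optional[int] = None
    b_max: Optional[int] = None

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.r_min, self.r_max, "R"),
            (self.g_min, self.g_max, "G"),
            (self.b_min, self.b_max, "B"),
        ):
            for v in (lo, hi):
                if v is not None and not 0 <= v <= 255:
                    raise ValueError(f"{name} bound {v} outside [0, 255]")
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"{name} bounds inverted: {lo} > {hi}")

    def mask(self, colors: np.ndarray) -> np.ndarray:
        """Boolean pass mask for an (N, 3) RGB array. Bounds are strict."""
        colors = np.asarray(colors)
        keep = np.ones(len(colors), dtype=bool)
        bounds = (
            (0, self.r_min, self.r_max),
            (1, self.g_min, self.g_max),
            (2, self.b_min, self.b_max),
        )
        for ch, lo, hi in bounds:
            if lo is not None:
                keep &= colors[:, ch] > lo
            if hi is not None:
                keep &= colors[:, ch] < hi
        return keep


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species constants used across the pipeline.

    ``allometric_a`` is the dimensionless coefficient in
    leaf area = a × leaf length × leaf width. ``fruit_density`` (g/cm³)
    and ``rgb_gate`` are optional: species that were never yield-scanned
    (cucumber) ship without them.
    """

    name: str
    allometric_a: float
    fruit_density: Optional[float] = None
    rgb_gate: Optional[RGBGate] = None

    def __post_init__(self) -> None:
        if not self.allometric_a > 0:
            raise SpeciesConfigError(
                f"species {self.name!r}: allometric_a must be > 0, "
                f"got {self.allometric_a}"
            )
        if self.fruit_density is not None and not self.fruit_density > 0:
            raise SpeciesConfigError(
                f"species {self.name!r}: fruit_density must be > 0, "
                f"got {self.fruit_density}"
            )


def default_species() -> dict[str, SpeciesParams]:
    """The shipped species table for tomato, cucumber, and paprika.

    Allometric coefficients: tomato 0.25, cucumber 0.87, paprika 0.59.
    Fruit densities (g/cm³): tomato 0.84, paprika 0.59; cucumber was
    measured for growth only and carries no fruit parameters. The gates
    select mature-fruit colors: tomato R>140, G<100, B<100; paprika
    R>150, G>110, B<50.
    """
    return {
        "tomato": SpeciesParams(
            name="tomato",
            allometric_a=0.25,
            fruit_density=0.84,
            rgb_gate=RGBGate(r_min=140, g_max=100, b_max=100),
        ),
        "cucumber": SpeciesParams(name="cucumber", allometric_a=0.87),
        "paprika": SpeciesParams(
            name="paprika",
            allometric_a=0.59,
            fruit_density=0.59,
            rgb_gate=RGBGate(r_min=150, g_min=110, b_max=50),
        ),
    }


# ---------------------------------------------------------------------------
# PTS
# ---------------------------------------------------------------------------

def read_pts(
    path: Union[str, Path], source_unit: str = "m"
) -> ColoredPointCloud:
    """Read a PTS colored point cloud, converting coordinates to cm.

    Rows may carry 6 columns (``x y z r g b``) or 7 (``x y z intensity
    r g b``); the intensity is dropped. A single-integer first line, if
    present, is treated as a point-count header and must match the number
    of data rows.

    Parameters
    ----------
    path : path-like
        File to read.
    source_unit : {"mm", "cm", "m"}
        Unit of the coordinates in the file. Scanners conventionally
        export metres, hence the default.
    """
    if source_unit not in _UNIT_TO_CM:
        raise ValueError(f"unknown source_unit {source_unit!r}")
    factor = _UNIT_TO_CM[source_unit]

    path = Path(path)
    lines = path.read_text().splitlines()

    header_count: Optional[int] = None
    start = 0
    # optional count header: a first line holding exactly one integer token
    for i, line in enumerate(lines):
        if line.strip():
            tokens = line.split()
            if len(tokens) == 1:
                try:
                    header_count = int(tokens[0])
                except ValueError as exc:
                    raise PTSParseError(
                        f"line {i + 1}: single-token line is not an "
                        f"integer header: {tokens[0]!r}"
                    ) from exc
                start = i + 1
            else:
                start = i
            break

    coords: list[tuple[float, float, float]] = []
    colors: list[tuple[int, int, int]] = []
    n_rows = 0
    for lineno0 in range(start, len(lines)):
        line = lines[lineno0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) == 6:
            xyz, rgb = tokens[:3], tokens[3:]
        elif len(tokens) == 7:
            xyz, rgb = tokens[:3], tokens[4:]  # drop intensity
        else:
            raise PTSParseError(
                f"line {lineno0 + 1}: expected 6 or 7 columns, "
                f"got {len(tokens)}"
            )
        try:
            x, y, z = (float(v) for v in xyz)
            r, g, b = (int(float(v)) for v in rgb)
        except ValueError as exc:
            raise PTSParseError(
                f"line {lineno0 + 1}: non-numeric value in {line!r}"
            ) from exc
        if not all(0 <= c <= 255 for c in (r, g, b)):
            raise PTSParseError(
                f"line {lineno0 + 1}: color channel outside [0, 255] "
                f"in {line!r}"
            )
        coords.append((x, y, z))
        colors.append((r, g, b))
        n_rows += 1

    if header_count is not None and header_count != n_rows:
        raise PTSParseError(
            f"header declares {header_count} points but file has "
            f"{n_rows} data rows"
        )

    pts = np.asarray(coords, dtype=np.float64).reshape(-1, 3) * factor
    cols = np.asarray(colors, dtype=np.int64).reshape(-1, 3)
    return ColoredPointCloud(points=pts, colors=cols, source_unit=source_unit)


def write_pts(cloud: ColoredPointCloud, path: Union[str, Path]) -> None:
    """Write a point cloud as PTS: a count header then ``x y z r g b`` rows.

    Coordinates are written in cm with six decimals, so a round trip
    reproduces them to well under 1e-4 cm.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{len(cloud)}\n")
        for (x, y, z), (r, g, b) in zip(cloud.points, cloud.colors):
            fh.write(f"{x:.6f} {y:.6f} {z:.6f} {r:d} {g:d} {b:d}\n")


# ---------------------------------------------------------------------------
# STL
# ---------------------------------------------------------------------------

def _looks_ascii_stl(data: bytes) -> bool:
    head = data[:512].lstrip()
    return head.startswith(b"solid") and b"facet" in data[:4096].lower()


def read_stl(
    path: Union[str, Path],
    source_unit: str = "cm",
    deduplicate: bool = False,
) -> TriangleMesh:
    """Read an ASCII or binary STL surface model.

    The dialect is sniffed: a file opening with ``solid`` and containing
    ``facet`` parses as ASCII; otherwise the binary layout (80-byte
    header, uint32 facet count, 50-byte facet records) must be
    self-consistent. Stored facet normals are ignored. Each facet
    contributes its own three vertices unless ``deduplicate`` merges
    exactly coincident coordinates.

    Parameters
    ----------
    path : path-like
    source_unit : {"mm", "cm", "m"}
        Unit of the file's coordinates; converted to cm. STL files carry
        no unit, so the caller must know.
    deduplicate : bool
        Merge vertices with bit-identical coordinates (no tolerance
        welding).
    """
    if source_unit not in _UNIT_TO_CM:
        raise ValueError(f"unknown source_unit {source_unit!r}")
    factor = _UNIT_TO_CM[source_unit]

    data = Path(path).read_bytes()
    if len(data) == 0:
        raise STLFormatError(f"{path}: empty file")

    if _looks_ascii_stl(data):
        pass  # trimesh parses the ASCII dialect below
    elif len(data) >= 84:
        (declared,) = struct.unpack("<I", data[80:84])
        expected = 84 + 50 * declared
        if len(data) != expected:
            have = (len(data) - 84) // 50
            raise STLFormatError(
                f"{path}: binary STL declares {declared} facets but the "
                f"body holds {have}"
            )
    else:
        raise STLFormatError(
            f"{path}: not ASCII STL and too short for a binary header"
        )

    try:
        loaded = trimesh.load(
            io.BytesIO(data), file_type="stl", process=False
        )
    except Exception as exc:  # noqa: BLE001 - any loader failure is a format error
        raise STLFormatError(f"{path}: unreadable STL ({exc})") from exc
    if not hasattr(loaded, "faces"):
        raise STLFormatError(f"{path}: no triangles recognised")

    vertices = np.asarray(loaded.vertices, dtype=np.float64) * factor
    triangles = np.asarray(loaded.faces, dtype=np.int64)

    if deduplicate and len(vertices):
        uniq, inverse = np.unique(vertices, axis=0, return_inverse=True)
        vertices = uniq
        triangles = inverse[triangles]

    return TriangleMesh(vertices=vertices, triangles=triangles)


def write_stl(
    mesh: TriangleMesh, path: Union[str, Path], dialect: str = "binary"
) -> None:
    """Write a mesh as STL in the requested dialect (coordinates in cm)."""
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"dialect must be 'binary' or 'ascii', got {dialect!r}")
    tm = trimesh.Trimesh(
        vertices=mesh.vertices, faces=mesh.triangles, process=False
    )
    file_type = "stl" if dialect == "binary" else "stl_ascii"
    out = tm.export(file_type=file_type)
    path = Path(path)
    if isinstance(out, bytes):
        path.write_bytes(out)
    else:
        path.write_text(out)


# ---------------------------------------------------------------------------
# Species config
# ---------------------------------------------------------------------------

_GATE_KEYS = ("r_min", "r_max", "g_min", "g_max", "b_min", "b_max")


def load_species_config(
    path: Optional[Union[str, Path]] = None,
) -> dict[str, SpeciesParams]:
    """Load a species parameter table from an INI-style config file.

    Each section names a species and may set ``allometric_a`` (required),
    ``fruit_density``, and any of the six gate bounds ``r_min``/``r_max``/
    ``g_min``/``g_max``/``b_min``/``b_max``. With no path, the shipped
    defaults for tomato, cucumber, and paprika are returned.

    Example config::

        [tomato]
        allometric_a = 0.25
        fruit_density = 0.84
        r_min = 140
        g_max = 100
        b_max = 100
    """
    if path is None:
        return default_species()

    parser = configparser.ConfigParser()
    read = parser.read(str(path))
    if not read:
        raise SpeciesConfigError(f"cannot read species config {path}")

    table: dict[str, SpeciesParams] = {}
    for species in parser.sections():
        section = parser[species]
        if "allometric_a" not in section:
            raise SpeciesConfigError(
                f"species {species!r}: missing required field 'allometric_a'"
            )
        try:
            a = float(section["allometric_a"])
        except ValueError as exc:
            raise SpeciesConfigError(
                f"species {species!r}: allometric_a is not a number"
            ) from exc
        density = None
        if "fruit_density" in section:
            try:
                density = float(section["fruit_density"])
            except ValueError as exc:
                raise SpeciesConfigError(
                    f"species {species!r}: fruit_density is not a number"
                ) from exc
        gate_kwargs = {}
        for key in _GATE_KEYS:
            if key in section:
                try:
                    gate_kwargs[key] = int(section[key])
                except ValueError as exc:
                    raise SpeciesConfigError(
                        f"species {species!r}: {key} is not an integer"
                    ) from exc
        gate = None
        if gate_kwargs:
            try:
                gate = RGBGate(**gate_kwargs)
            except ValueError as exc:
                raise SpeciesConfigError(
                    f"species {species!r}: {exc}"
                ) from exc
        table[species] = SpeciesParams(
            name=species, allometric_a=a, fruit_density=density, rgb_gate=gate
        )
    return table
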