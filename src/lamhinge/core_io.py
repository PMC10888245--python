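"""Domain types and file I/O for AFM topographs, movies and atomistic structures.

Conventions, stated once and asserted in the tests:

* All lateral and vertical image quantities are in **nm**.  Structure
  coordinates are kept in **Å** internally and converted to nm only at the
  rendering boundary (0.1 nm/Å), matching the PDB and AFM conventions
  respectively.
* Image arrays are row-major with the origin at the top-left corner; ``x`` is
  the column axis, ``y`` the row axis.  Reported molecule coordinates are in
  nm with ``(0, 0)`` at the image origin.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("lamhinge")

ANGSTROM_PER_NM = 10.0

#: Fallback van der Waals radius (Å) for elements missing from the table.
DEFAULT_VDW_RADIUS = 1.7


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# image types
# ---------------------------------------------------------------------------


@dataclass
class Topograph:
    """A single AFM height image.

    Parameters
    ----------
    heights
        2-D array of surface heights in nm (row-major, origin top-left).
    pixel_size
        Lateral sampling in nm per pixel; pixels are square.
    time
        Acquisition time of the frame in seconds (optional).
    frame_index
        Index of the frame within a movie (``0`` for stills).
    """

    heights: np.ndarray
    pixel_size: float
    time: float | None = None
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D array")
        if self.heights.shape[0] < 8 or self.heights.shape[1] < 8:
            raise ValueError("topograph must be at least 8x8 pixels")
        if not np.all(np.isfinite(self.heights)):
            n_bad = int(np.sum(~np.isfinite(self.heights)))
            raise ValueError(f"heights contain {n_bad} non-finite pixels")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be positive")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def extent_nm(self) -> tuple[float, float]:
        """(width, height) of the imaged area in nm."""
        return (
            self.heights.shape[1] * self.pixel_size,
            self.heights.shape[0] * self.pixel_size,
        )

    def plane_subtract(self) -> "Topograph":
        """Return a copy with the least-squares background plane removed.

        A simple first-order flatten: heights are fitted with
        ``z = a·x + b·y + c`` over all pixels and the plane is subtracted.
        """
        ny, nx = self.heights.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        a = np.column_stack([xx.ravel(), yy.ravel(), np.ones(nx * ny)])
        coef, *_ = np.linalg.lstsq(a, self.heights.ravel(), rcond=None)
        plane = (a @ coef).reshape(ny, nx)
        return Topograph(
            self.heights - plane,
            self.pixel_size,
            time=self.time,
            frame_index=self.frame_index,
        )


@dataclass
class MovieStack:
    """An ordered stack of topographs sharing shape and pixel size."""

    frames: list[Topograph]
    frame_interval: float

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("movie must contain at least one frame")
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be positive")
        shape0 = self.frames[0].shape
        px0 = self.frames[0].pixel_size
        bad = [
            i
            for i, f in enumerate(self.frames)
            if f.shape != shape0 or not math.isclose(f.pixel_size, px0)
        ]
        if bad:
            raise ValueError(f"frames {bad} differ in shape or pixel size")
        times = [f.time for f in self.frames if f.time is not None]
        if len(times) == len(self.frames) and len(times) > 1:
            if not all(t1 > t0 for t0, t1 in zip(times, times[1:])):
                raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def pixel_size(self) -> float:
        return self.frames[0].pixel_size


# ---------------------------------------------------------------------------
# structure types
# ---------------------------------------------------------------------------


@dataclass
class AtomisticStructure:
    """A flat table of atoms from a PDB file (coordinates in Å).

    Arrays are parallel, one entry per atom.  van der Waals radii are
    assigned from the element table at read time (:data:`DEFAULT_VDW_RADIUS`
    for unknown elements) and may be overridden, e.g. for pseudo-atom models.
    """

    chain_ids: np.ndarray  # dtype=str
    res_numbers: np.ndarray  # dtype=int
    res_names: np.ndarray  # dtype=str
    atom_names: np.ndarray  # dtype=str
    elements: np.ndarray  # dtype=str
    coords: np.ndarray  # (n, 3) float, Å
    vdw_radii: np.ndarray  # (n,) float, Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.coords)
        if n == 0:
            raise ValueError("structure must contain at least one atom")
        for name in ("chain_ids", "res_numbers", "res_names", "atom_names",
                     "elements", "vdw_radii"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != atom count {n}")
            setattr(self, name, arr)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must have shape (n, 3)")
        if not np.all(self.vdw_radii > 0):
            raise ValueError("every atom needs a positive vdW radius")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c), None)
        return list(seen)

    def select(self, mask: np.ndarray) -> "AtomisticStructure":
        return AtomisticStructure(
            self.chain_ids[mask], self.res_numbers[mask], self.res_names[mask],
            self.atom_names[mask], self.elements[mask], self.coords[mask],
            self.vdw_radii[mask],
        )

    def ca_mask(self) -> np.ndarray:
        return np.char.strip(self.atom_names.astype(str)) == "CA"

    def range_mask(self, rr: "ResidueRange") -> np.ndarray:
        return (
            (self.chain_ids.astype(str) == rr.chain_id)
            & (self.res_numbers >= rr.first)
            & (self.res_numbers <= rr.last)
        )

    def transformed(
        self, rotation: np.ndarray | None = None, translation: np.ndarray | None = None
    ) -> "AtomisticStructure":
        """Return a rigidly transformed copy (``x' = R x + t``, Å)."""
        coords = self.coords
        if rotation is not None:
            coords = coords @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            coords = coords + np.asarray(translation, dtype=float)
        out = AtomisticStructure(
            self.chain_ids, self.res_numbers, self.res_names,
            self.atom_names, self.elements, coords.copy(), self.vdw_radii,
        )
        return out


@dataclass(frozen=True)
class TipModel:
    """Sphere-capped-cone AFM tip: apex sphere radius (nm) and cone
    half-angle (degrees, measured from the tip axis)."""

    sphere_radius: float = 1.0
    cone_half_angle: float = 5.0

    def __post_init__(self) -> None:
        if not (self.sphere_radius > 0):
            raise ValueError("sphere_radius must be positive")
        if not (0 < self.cone_half_angle < 90):
            raise ValueError("cone_half_angle must lie in (0, 90) degrees")


@dataclass(frozen=True)
class ResidueRange:
    """Inclusive residue-number range on one chain."""

    chain_id: str
    first: int
    last: int

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValueError("first residue must be <= last residue")

    def __len__(self) -> int:
        return self.last - self.first + 1


# ---------------------------------------------------------------------------
# structure I/O
# ---------------------------------------------------------------------------

# vdW radii (Å) for the elements that occur in protein PDB files; anything
# else falls back to DEFAULT_VDW_RADIUS (logged).
_VDW_TABLE = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "FE": 2.00, "ZN": 1.39, "MG": 1.73,
    "CA": 2.31, "NA": 2.27, "CL": 1.75, "K": 2.75, "MN": 2.00,
}


def vdw_radius(element: str) -> float:
    """van der Waals radius in Å for an element symbol (fallback 1.7 Å)."""
    r = _VDW_TABLE.get(element.strip().upper())
    if r is None:
        logger.warning("unknown element %r: using fallback vdW radius %.2f A",
                       element, DEFAULT_VDW_RADIUS)
        return DEFAULT_VDW_RADIUS
    return r


def read_structure(path: str | Path) -> AtomisticStructure:
    """Read the ATOM records of a PDB file into an :class:`AtomisticStructure`.

    HETATM records (waters, ligands) are ignored.  Coordinates are kept in Å;
    vdW radii are assigned per element.  Raises :class:`FormatError` when the
    file contains no ATOM records or a coordinate field cannot be parsed.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the bad line
        raise FormatError(f"{path}: unparseable PDB file: {exc}") from exc

    chain_ids, res_numbers, res_names = [], [], []
    atom_names, elements, coords = [], [], []
    for model in st:
        for chain in model:
            for residue in chain:
                if residue.het_flag != "A":  # ATOM records only
                    continue
                for atom in residue:
                    chain_ids.append(chain.name)
                    res_numbers.append(residue.seqid.num)
                    res_names.append(residue.name)
                    atom_names.append(atom.name)
                    elements.append(atom.element.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break  # first model only
    if not coords:
        raise FormatError(f"{path}: no ATOM records")
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        bad = int(np.argmax(~np.all(np.isfinite(coords), axis=1)))
        raise FormatError(f"{path}: non-finite coordinates at atom {bad}")
    radii = np.array([vdw_radius(e) for e in elements])
    return AtomisticStructure(
        np.array(chain_ids), np.array(res_numbers, dtype=int),
        np.array(res_names), np.array(atom_names), np.array(elements),
        coords, radii,
    )


def write_structure(structure: AtomisticStructure, path: str | Path) -> None:
    """Write a minimal PDB file (ATOM records only)."""
    path = Path(path)
    lines = []
    for i in range(len(structure)):
        x, y, z = structure.coords[i]
        lines.append(
            "ATOM  {serial:>5d} {name:^4s} {res:<3s} {chain:1s}{resnum:>4d}    "
            "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}".format(
                serial=(i + 1) % 100000,
                name=str(structure.atom_names[i])[:4],
                res=str(structure.res_names[i])[:3],
                chain=str(structure.chain_ids[i])[:1],
                resnum=int(structure.res_numbers[i]),
                x=x, y=y, z=z, occ=1.0, b=0.0,
                el=str(structure.elements[i])[:2],
            )
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# topograph I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_topograph(topo: Topograph, path: str | Path) -> None:
    """Write a topograph as 32-bit float TIFF (nm) plus a JSON metadata
    sidecar ``<name>.tif.json`` holding pixel size and time."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(str(path), topo.heights.astype(np.float32))
    meta = {
        "pixel_size_nm": topo.pixel_size,
        "time_s": topo.time,
        "frame_index": topo.frame_index,
    }
    _sidecar_path(path).write_text(json.dumps(meta))


def read_topograph(
    path: str | Path, pixel_size: float | None = None
) -> Topograph:
    """Read a topograph from TIFF (+JSON sidecar) or an ASCII matrix.

    TIFF files require the sidecar written by :func:`write_topograph`; a
    missing sidecar is an error, never a guessed pixel size.  ASCII matrices
    (whitespace-delimited heights in nm) require ``pixel_size`` explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        heights = np.asarray(tifffile.imread(str(path)), dtype=float)
        sidecar = _sidecar_path(path)
        if pixel_size is None:
            if not sidecar.exists():
                raise FormatError(f"{path}: pixel size unknown (no JSON sidecar)")
            meta = json.loads(sidecar.read_text())
            pixel_size = meta.get("pixel_size_nm")
            if pixel_size is None:
                raise FormatError(f"{sidecar}: pixel size unknown")
            time = meta.get("time_s")
            frame_index = int(meta.get("frame_index", 0))
        else:
            time, frame_index = None, 0
    else:
        if pixel_size is None:
            raise FormatError(f"{path}: pixel size unknown (required for ASCII)")
        heights = np.atleast_2d(np.loadtxt(path))
        time, frame_index = None, 0
    if np.any(~np.isfinite(heights)):
        n_bad = int(np.sum(~np.isfinite(heights)))
        raise FormatError(f"{path}: {n_bad} NaN/inf pixels")
    return Topograph(heights, float(pixel_size), time=time, frame_index=frame_index)


def read_movie(path: str | Path) -> MovieStack:
    """Read a movie from a directory of ``frame_*.tif`` files (with sidecars).

    Frames are ordered by their file names; all frames must share shape and
    pixel size, and carry strictly increasing times.  The frame interval is
    the median of the time differences.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"{path} is not a directory")
    files = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
    if not files:
        raise FormatError(f"{path}: no TIFF frames found")
    frames = [read_topograph(f) for f in files]
    shape0, px0 = frames[0].shape, frames[0].pixel_size
    bad = [
        i for i, f in enumerate(frames)
        if f.shape != shape0 or not math.isclose(f.pixel_size, px0)
    ]
    if bad:
        raise FormatError(
            f"{path}: frames {bad} ({[files[i].name for i in bad]}) "
            "differ in shape or pixel size"
        )
    times = [f.time for f in frames]
    if len(frames) > 1 and all(t is not None for t in times):
        dts = np.diff(times)
        if np.any(dts <= 0):
            raise FormatError(f"{path}: frame times not strictly increasing")
        interval = float(np.median(dts))
    else:
        interval = 1.0
    for i, f in enumerate(frames):
        f.frame_index = i
    return MovieStack(frames, frame_interval=interval)


def write_movie(movie: MovieStack, out_dir: str | Path) -> list[Path]:
    """Write a movie as numbered TIFF frames with sidecars; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(movie.frames):
        p = out_dir / f"frame_{i:05d}.tif"
        write_topograph(frame, p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def load_config(path: str | Path, defaults: dict | None = None) -> dict:
    """Load a flat JSON configuration, validate keys against ``defaults``.

    Unknown keys raise; missing keys take their default.  The merged
    configuration is logged at run start.
    """
    path = Path(path)
    user = json.loads(path.read_text())
    if not isinstance(user, dict):
        raise FormatError(f"{path}: config must be a flat JSON object")
    merged = dict(defaults or {})
    for key, value in user.items():
        if defaults is not None and key not in defaults:
            raise FormatError(f"{path}: unknown config key {key!r}")
        merged[key] = value
    logger.info("config: %s", merged)
    return merged
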