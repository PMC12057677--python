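"""Trajectory input/output and periodic-geometry primitives.

Supported formats are plain XYZ, extended XYZ (``Lattice=...`` comment lines)
and LAMMPS text dumps.  Only orthorhombic cells are accepted; coordinates are
stored exactly as read (never auto-wrapped) and all geometry downstream goes
through the minimum-image displacement helpers defined here.  A separate
reader handles auxiliary XYZ streams of maximally localized Wannier-function
centers (species tag ``X``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

ALLOWED_SPECIES = frozenset({"C", "O", "H", "X"})


class TrajectoryParseError(ValueError):
    """Malformed trajectory file (carries the offending line number)."""


class TrajectoryStructureError(ValueError):
    """Structurally inconsistent trajectory (atom counts, ordering...)."""


class UnsupportedFormatError(ValueError):
    """Recognized but unsupported input (e.g. triclinic cells)."""


@dataclass(frozen=True)
class CellSpec:
    """Orthorhombic simulation cell.

    Parameters
    ----------
    lengths : sequence of 3 floats
        Box edge lengths in Angstrom; all strictly positive.
    periodic : tuple of 3 bools
        Periodicity flags per axis.
    """

    lengths: tuple[float, float, float]
    periodic: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        lengths = tuple(float(x) for x in self.lengths)
        if len(lengths) != 3 or any(x <= 0 for x in lengths):
            raise ValueError(f"cell lengths must be 3 positive floats, got {self.lengths!r}")
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "periodic", tuple(bool(b) for b in self.periodic))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)

    @property
    def volume(self) -> float:
        return float(np.prod(self.array))


@dataclass
class Frame:
    """A single trajectory snapshot."""

    index: int
    time: float  # ps
    species: np.ndarray  # (n,) of str
    coords: np.ndarray  # (n, 3) Angstrom
    cell: CellSpec

    def __post_init__(self) -> None:
        self.species = np.asarray(self.species, dtype="U2")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if len(self.species) != len(self.coords):
            raise ValueError("species and coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates in frame {self.index}")

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    def indices_of(self, element: str) -> np.ndarray:
        return np.flatnonzero(self.species == element)


class Trajectory:
    """Ordered sequence of frames with constant atom count and species.

    Stored columnar (one ``(n_frames, n_atoms, 3)`` coordinate array) for
    speed; :meth:`frame` / iteration yield lightweight :class:`Frame` views.
    """

    def __init__(
        self,
        species: Sequence[str],
        coords: np.ndarray,
        cell: CellSpec | Sequence[CellSpec],
        times: Sequence[float] | None = None,
        dt: float = 1.0,
    ) -> None:
        self.species = np.asarray(species, dtype="U2")
        self.coords = np.asarray(coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.species):
            raise ValueError("coords second axis must match species length")
        self.dt = float(dt)
        n_frames = self.coords.shape[0]
        if times is None:
            times = np.arange(n_frames) * self.dt
        self.times = np.asarray(times, dtype=float)
        if len(self.times) != n_frames:
            raise ValueError("times length must match frame count")
        if n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryStructureError("frame times must be strictly increasing")
        if isinstance(cell, CellSpec):
            self.cells: list[CellSpec] = [cell] * n_frames
        else:
            self.cells = list(cell)
            if len(self.cells) != n_frames:
                raise ValueError("need one cell per frame")
        unknown = set(self.species) - ALLOWED_SPECIES
        if unknown:
            raise TrajectoryParseError(f"unknown element symbols {sorted(unknown)}")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def cell(self) -> CellSpec:
        """The cell of the first frame (constant-cell convenience)."""
        return self.cells[0]

    def frame(self, i: int) -> Frame:
        i = int(i)
        return Frame(
            index=i,
            time=float(self.times[i]),
            species=self.species,
            coords=self.coords[i],
            cell=self.cells[i],
        )

    def __iter__(self) -> Iterator[Frame]:
        for i in range(len(self)):
            yield self.frame(i)

    @classmethod
    def from_frames(cls, frames: Sequence[Frame], dt: float = 1.0) -> "Trajectory":
        if not frames:
            raise ValueError("empty frame list")
        ref = frames[0]
        for f in frames[1:]:
            if f.n_atoms != ref.n_atoms:
                raise TrajectoryStructureError(
                    f"frame {f.index} has {f.n_atoms} atoms, expected {ref.n_atoms}"
                )
            if not np.array_equal(f.species, ref.species):
                raise TrajectoryStructureError(f"frame {f.index} changes species ordering")
        coords = np.stack([f.coords for f in frames])
        times = [f.time for f in frames]
        cells = [f.cell for f in frames]
        return cls(ref.species, coords, cells, times=times, dt=dt)


# ---------------------------------------------------------------------------
# minimum-image geometry
# ---------------------------------------------------------------------------

def min_image_vec(a, b, cell: CellSpec) -> np.ndarray:
    """Minimum-image displacement ``b - a`` under an orthorhombic cell.

    Each component is shifted by integer multiples of the box length into
    ``(-L/2, L/2]``.  Non-periodic axes are returned unshifted.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    L = cell.array
    shift = np.ceil(d / L - 0.5)
    shift = np.where(np.asarray(cell.periodic), shift, 0.0)
    return d - shift * L


def min_image_displacements(a: np.ndarray, b: np.ndarray, cell: CellSpec) -> np.ndarray:
    """Vectorized minimum-image displacements between coordinate arrays.

    ``a`` of shape (..., 3) and ``b`` broadcastable against it; returns
    ``b - a`` wrapped per component into ``(-L/2, L/2]``.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    L = cell.array
    shift = np.ceil(d / L - 0.5)
    shift = np.where(np.asarray(cell.periodic), shift, 0.0)
    return d - shift * L


def min_image_distance_matrix(a: np.ndarray, b: np.ndarray, cell: CellSpec) -> np.ndarray:
    """All-pairs minimum-image distances: (n, m) for a (n,3) and b (m,3)."""
    d = min_image_displacements(a[:, None, :], b[None, :, :], cell)
    return np.linalg.norm(d, axis=-1)


# ---------------------------------------------------------------------------
# XYZ / extended XYZ
# ---------------------------------------------------------------------------

_LATTICE_RE = re.compile(r'Lattice\s*=\s*"([^"]+)"')
_TIME_RE = re.compile(r'[Tt]ime\s*=\s*([0-9eE.+-]+)')


def _parse_lattice(comment: str, lineno: int) -> CellSpec | None:
    m = _LATTICE_RE.search(comment)
    if m is None:
        return None
    vals = [float(x) for x in m.group(1).split()]
    if len(vals) != 9:
        raise TrajectoryParseError(f"line {lineno}: Lattice must have 9 entries")
    M = np.array(vals).reshape(3, 3)
    off = M - np.diag(np.diag(M))
    if np.any(np.abs(off) > 1e-10):
        raise UnsupportedFormatError(f"line {lineno}: non-orthorhombic lattice not supported")
    return CellSpec(tuple(np.diag(M)))


def read_xyz(
    path: str | Path,
    cell: CellSpec | None = None,
    dt: float = 1.0,
    allowed_species: frozenset[str] = ALLOWED_SPECIES,
) -> Trajectory:
    """Read a plain or extended XYZ trajectory.

    For plain XYZ files a ``cell`` must be supplied; extended-XYZ
    ``Lattice`` comment entries override it frame by frame.  Frame times are
    taken from a ``Time=`` comment tag when present, else ``index * dt``.
    """
    path = Path(path)
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    lineno = 0
    frame_index = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        header_line = i + 1
        try:
            n_atoms = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise TrajectoryParseError(
                f"line {header_line}: expected atom count, got {lines[i]!r}"
            ) from None
        if i + 1 >= len(lines):
            raise TrajectoryParseError(f"line {header_line + 1}: missing comment line")
        comment = lines[i + 1]
        frame_cell = _parse_lattice(comment, header_line + 1) or cell
        if frame_cell is None:
            raise ValueError(
                f"frame {frame_index}: plain XYZ without Lattice requires an explicit cell"
            )
        m = _TIME_RE.search(comment)
        time = float(m.group(1)) if m else frame_index * dt
        body = lines[i + 2 : i + 2 + n_atoms]
        if len(body) < n_atoms:
            raise TrajectoryStructureError(
                f"frame {frame_index}: header declares {n_atoms} atoms, "
                f"file has only {len(body)} left"
            )
        species = []
        coords = np.empty((n_atoms, 3))
        for j, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise TrajectoryParseError(
                    f"line {header_line + 2 + j}: expected 'symbol x y z', got {line!r}"
                )
            sym = parts[0]
            if sym not in allowed_species:
                raise TrajectoryParseError(
                    f"line {header_line + 2 + j}: unknown element symbol {sym!r}"
                )
            species.append(sym)
            try:
                coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise TrajectoryParseError(
                    f"line {header_line + 2 + j}: non-numeric coordinate in {line!r}"
                ) from None
        # catch over-long frames: next non-blank line must be a bare int header
        frames.append(Frame(frame_index, time, np.array(species), coords, frame_cell))
        i += 2 + n_atoms
        frame_index += 1
    if not frames:
        raise TrajectoryParseError(f"{path}: no frames found")
    try:
        return Trajectory.from_frames(frames, dt=dt)
    except TrajectoryStructureError as exc:
        raise TrajectoryStructureError(f"{path}: {exc}") from None


def write_xyz(traj: Trajectory, path: str | Path, precision: int = 8) -> None:
    """Write an extended-XYZ trajectory (Lattice + Time comment tags)."""
    path = Path(path)
    fmt = f"{{:.{precision}f}}"
    with open(path, "w") as fh:
        for f in traj:
            L = f.cell.lengths
            lattice = f"{L[0]} 0.0 0.0 0.0 {L[1]} 0.0 0.0 0.0 {L[2]}"
            fh.write(f"{f.n_atoms}\n")
            fh.write(f'Lattice="{lattice}" Properties=species:S:1:pos:R:3 Time={f.time}\n')
            for sym, xyz in zip(f.species, f.coords):
                fh.write(
                    f"{sym} {fmt.format(xyz[0])} {fmt.format(xyz[1])} {fmt.format(xyz[2])}\n"
                )


# ---------------------------------------------------------------------------
# LAMMPS text dump
# ---------------------------------------------------------------------------

def read_lammps_dump(
    path: str | Path,
    element_map: dict[int, str],
    dt: float = 1.0,
    time_per_step: float | None = None,
) -> Trajectory:
    """Read a LAMMPS text dump (``ITEM: TIMESTEP/BOX BOUNDS/ATOMS``).

    Atoms are re-ordered by id and types mapped to element symbols through
    ``element_map``.  Wrapped (``x``), scaled (``xs``) and unwrapped (``xu``)
    coordinate columns are supported; triclinic tilt factors are rejected.
    Frame times are ``index * dt`` unless ``time_per_step`` converts the
    dump's TIMESTEP values directly.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: list[Frame] = []
    i = 0
    frame_index = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith("ITEM: TIMESTEP"):
            raise TrajectoryParseError(f"line {i + 1}: expected 'ITEM: TIMESTEP'")
        step = int(lines[i + 1])
        i += 2
        if not lines[i].startswith("ITEM: NUMBER OF ATOMS"):
            raise TrajectoryParseError(f"line {i + 1}: expected 'ITEM: NUMBER OF ATOMS'")
        n_atoms = int(lines[i + 1])
        i += 2
        if not lines[i].startswith("ITEM: BOX BOUNDS"):
            raise TrajectoryParseError(f"line {i + 1}: expected 'ITEM: BOX BOUNDS'")
        if any(tag in lines[i] for tag in ("xy", "xz", "yz")):
            raise UnsupportedFormatError(f"line {i + 1}: triclinic tilt factors not supported")
        lo = np.empty(3)
        hi = np.empty(3)
        for ax in range(3):
            parts = lines[i + 1 + ax].split()
            if len(parts) > 2:
                raise UnsupportedFormatError(
                    f"line {i + 2 + ax}: triclinic tilt factors not supported"
                )
            lo[ax], hi[ax] = float(parts[0]), float(parts[1])
        i += 4
        if not lines[i].startswith("ITEM: ATOMS"):
            raise TrajectoryParseError(f"line {i + 1}: expected 'ITEM: ATOMS'")
        columns = lines[i].split()[2:]
        col = {name: k for k, name in enumerate(columns)}
        if "id" not in col or "type" not in col:
            raise TrajectoryParseError(f"line {i + 1}: dump must provide id and type columns")
        if all(c in col for c in ("x", "y", "z")):
            xyz_cols, scaled = ("x", "y", "z"), False
        elif all(c in col for c in ("xs", "ys", "zs")):
            xyz_cols, scaled = ("xs", "ys", "zs"), True
        elif all(c in col for c in ("xu", "yu", "zu")):
            xyz_cols, scaled = ("xu", "yu", "zu"), False
        else:
            raise TrajectoryParseError(
                f"line {i + 1}: missing coordinate columns (x/xs/xu y z ...)"
            )
        i += 1
        lengths = hi - lo
        cell = CellSpec(tuple(lengths))
        ids = np.empty(n_atoms, dtype=int)
        types = np.empty(n_atoms, dtype=int)
        coords = np.empty((n_atoms, 3))
        for j in range(n_atoms):
            parts = lines[i + j].split()
            ids[j] = int(parts[col["id"]])
            types[j] = int(parts[col["type"]])
            coords[j] = [float(parts[col[c]]) for c in xyz_cols]
        i += n_atoms
        if scaled:
            coords = lo + coords * lengths
        order = np.argsort(ids, kind="stable")
        ids, types, coords = ids[order], types[order], coords[order]
        try:
            species = np.array([element_map[t] for t in types], dtype="U2")
        except KeyError as exc:
            raise TrajectoryParseError(
                f"frame {frame_index}: atom type {exc.args[0]} missing from element_map"
            ) from None
        time = step * time_per_step if time_per_step is not None else frame_index * dt
        frames.append(Frame(frame_index, time, species, coords, cell))
        frame_index += 1
    if not frames:
        raise TrajectoryParseError(f"{path}: no frames found")
    return Trajectory.from_frames(frames, dt=dt)


# ---------------------------------------------------------------------------
# Wannier-center streams
# ---------------------------------------------------------------------------

@dataclass
class WannierStream:
    """Per-frame lists of Wannier-center coordinates (species tag ``X``).

    ``stride`` records how many trajectory frames each center frame spans;
    it is filled in by :func:`match_stride`.
    """

    frames: list[np.ndarray] = field(default_factory=list)
    stride: int | None = None

    def __len__(self) -> int:
        return len(self.frames)


def read_wannier_stream(path: str | Path) -> WannierStream:
    """Read an XYZ-style stream whose records are Wannier centers."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: list[np.ndarray] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise TrajectoryParseError(
                f"line {i + 1}: expected center count, got {lines[i]!r}"
            ) from None
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise TrajectoryStructureError(
                f"frame {len(frames)}: header declares {n} centers, file has {len(body)} left"
            )
        coords = np.empty((n, 3))
        for j, line in enumerate(body):
            parts = line.split()
            if parts[0] != "X":
                raise TrajectoryParseError(
                    f"line {i + 3 + j}: Wannier stream must use species 'X', got {parts[0]!r}"
                )
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        i += 2 + n
    if not frames:
        logger.warning("%s: empty Wannier stream", path)
    return WannierStream(frames=frames)


def match_stride(stream: WannierStream, traj: Trajectory) -> int:
    """Record and return the stream's stride relative to a trajectory.

    The stream's frame count must equal or divide the trajectory's.
    """
    if len(stream) == 0:
        raise ValueError("cannot match an empty Wannier stream")
    n_traj, n_stream = len(traj), len(stream)
    if n_traj % n_stream != 0:
        raise TrajectoryStructureError(
            f"Wannier stream frame count {n_stream} does not divide "
            f"trajectory frame count {n_traj}"
        )
    stream.stride = n_traj // n_stream
    return stream.stride
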