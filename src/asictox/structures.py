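"""Multi-frame structure container and file IO.

The trajectory interchange format is multi-model PDB (MODEL/ENDMDL records,
one chain id per molecule); reading and writing go through biotite.
Coordinates are in Angstrom throughout, author residue numbering is
preserved verbatim, and no periodic-boundary handling is performed (real MD
input is assumed pre-imaged and whole).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONTACT_TYPES = ("H", "I", "D", "P", "S", "M")


class TrajectoryError(ValueError):
    """Raised for malformed multi-frame structure input."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom in one frame (author numbering, Angstrom coordinates)."""

    chain_id: str
    res_id: int
    res_name: str
    atom_name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass
class Frame:
    """A view of one trajectory frame sharing the trajectory topology."""

    index: int
    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray  # (n_atoms, 3)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def atom_records(self) -> list[AtomRecord]:
        return [
            AtomRecord(
                chain_id=str(self.chain_ids[i]),
                res_id=int(self.res_ids[i]),
                res_name=str(self.res_names[i]),
                atom_name=str(self.atom_names[i]),
                element=str(self.elements[i]),
                xyz=tuple(float(x) for x in self.coords[i]),
            )
            for i in range(self.n_atoms)
        ]


class Trajectory:
    """Multi-frame structure with a constant topology.

    Parameters
    ----------
    chain_ids, res_ids, res_names, atom_names, elements
        Per-atom topology arrays (length ``n_atoms``), identical in every
        frame.
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Angstrom.
    """

    def __init__(
        self,
        chain_ids: Sequence[str],
        res_ids: Sequence[int],
        res_names: Sequence[str],
        atom_names: Sequence[str],
        elements: Sequence[str],
        coords: np.ndarray,
    ):
        self.chain_ids = np.asarray(chain_ids, dtype="U4")
        self.res_ids = np.asarray(res_ids, dtype=int)
        self.res_names = np.asarray(res_names, dtype="U4")
        self.atom_names = np.asarray(atom_names, dtype="U6")
        self.elements = np.asarray(elements, dtype="U2")
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise TrajectoryError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[0] < 1:
            raise TrajectoryError("a trajectory needs at least one frame")
        n_atoms = coords.shape[1]
        for arr, label in (
            (self.chain_ids, "chain_ids"),
            (self.res_ids, "res_ids"),
            (self.res_names, "res_names"),
            (self.atom_names, "atom_names"),
            (self.elements, "elements"),
        ):
            if len(arr) != n_atoms:
                raise TrajectoryError(f"{label} length does not match coords")
        if np.any(self.elements == ""):
            raise TrajectoryError("every atom needs a non-empty element")
        if not np.all(np.isfinite(coords)):
            raise TrajectoryError("coordinates must be finite")
        self.coords = coords

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c))
        return list(seen)

    def residue_range(self, chain_id: str) -> tuple[int, int]:
        mask = self.chain_ids == chain_id
        if not mask.any():
            raise KeyError(f"no chain {chain_id!r} in trajectory")
        res = self.res_ids[mask]
        return int(res.min()), int(res.max())

    def frame(self, index: int) -> Frame:
        return Frame(
            index=index,
            chain_ids=self.chain_ids,
            res_ids=self.res_ids,
            res_names=self.res_names,
            atom_names=self.atom_names,
            elements=self.elements,
            coords=self.coords[index],
        )

    def frames(self) -> Iterable[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)


# ---------------------------------------------------------------------------
# multi-model PDB IO (biotite-backed)
# ---------------------------------------------------------------------------


def _scan_model_atom_counts(path: Path) -> list[int]:
    counts: list[int] = []
    current = 0
    in_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                current += 1
        if in_model or (not counts and current):
            counts.append(current)
    return counts


def read_multimodel_pdb(path: str | Path) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    Frames are ordered by MODEL number; a file without MODEL records is a
    single-frame trajectory.  Models with inconsistent atom counts raise a
    :class:`TrajectoryError` naming the offending frame.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:
        counts = _scan_model_atom_counts(path)
        if not counts or all(c == 0 for c in counts):
            raise TrajectoryError(f"{path} contains no atoms") from exc
        if len(set(counts)) > 1:
            bad = next(i for i, c in enumerate(counts) if c != counts[0])
            raise TrajectoryError(
                f"{path}: model {bad + 1} has {counts[bad]} atoms, "
                f"model 1 has {counts[0]}"
            ) from exc
        raise TrajectoryError(f"could not parse {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise TrajectoryError(f"{path} contains no atoms")
    elements = np.asarray(stack.element, dtype="U2")
    if np.any(elements == ""):
        from .chemistry import element_from_name

        names = np.asarray(stack.atom_name)
        elements = np.array(
            [
                e if e else element_from_name(str(n))
                for e, n in zip(elements, names)
            ],
            dtype="U2",
        )
    return Trajectory(
        chain_ids=np.asarray(stack.chain_id),
        res_ids=np.asarray(stack.res_id),
        res_names=np.asarray(stack.res_name),
        atom_names=np.asarray(stack.atom_name),
        elements=elements,
        coords=np.asarray(stack.coord, dtype=float),
    )


def write_multimodel_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write a :class:`Trajectory` as a multi-model PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = trajectory.n_atoms
    stack = struc.AtomArrayStack(trajectory.n_frames, n)
    stack.chain_id = trajectory.chain_ids.astype("U4")
    stack.res_id = trajectory.res_ids.astype(int)
    stack.res_name = trajectory.res_names.astype("U5")
    stack.atom_name = trajectory.atom_names.astype("U6")
    stack.element = trajectory.elements.astype("U2")
    stack.hetero = np.zeros(n, dtype=bool)
    stack.coord = trajectory.coords.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# lifetime CSV IO
# ---------------------------------------------------------------------------

LIFETIME_COLUMNS = [
    "chain_a",
    "res_a",
    "resname_a",
    "chain_b",
    "res_b",
    "resname_b",
    "type",
    "lifetime",
]


def write_lifetime_csv(table, path: str | Path) -> None:
    """Write a lifetime table to CSV (UTF-8, '.' decimal separator)."""
    df = table.data[LIFETIME_COLUMNS]
    df.to_csv(path, index=False)


def read_lifetime_csv(path: str | Path, n_frames: int | None = None):
    """Read a lifetime CSV written by :func:`write_lifetime_csv`.

    Lifetimes outside [0, 1] or unknown contact type letters are rejected.
    """
    from .lifetimes import LifetimeTable

    df = pd.read_csv(path)
    missing = [c for c in LIFETIME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"lifetime CSV {path} lacks columns {missing}")
    return LifetimeTable(df[LIFETIME_COLUMNS], n_frames=n_frames)
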