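"""Structures, trajectories, filament annotations, and file I/O.

In-memory containers are thin ``numpy``-backed dataclasses; multi-model PDB
reading/writing goes through :mod:`biotite.structure.io.pdb`.  A filament
annotation (:class:`FilamentModel`) maps atoms to subunits (bottom → top)
and each subunit's residues to its N-/C-terminal domain; it is loadable
from a YAML config because domain boundaries are experimental knowledge,
never inferred from coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import FormatError, InvalidSpecificationError, SelectionError

logger = logging.getLogger(__name__)

__all__ = [
    "Structure",
    "Trajectory",
    "SubunitDef",
    "FilamentModel",
    "read_pdb_trajectory",
    "write_pdb_trajectory",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "select",
]


@dataclass
class Structure:
    """A set of atom records with coordinates in Å.

    (chain, residue number, atom name) triples must be unique and
    coordinates finite.
    """

    coords: np.ndarray          # (N, 3) float64, Å
    atom_name: np.ndarray       # (N,) str
    res_name: np.ndarray        # (N,) str
    res_id: np.ndarray          # (N,) int, 1-based
    chain_id: np.ndarray        # (N,) str
    occupancy: np.ndarray | None = None
    b_factor: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise FormatError(f"coords must be (N, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates")
        n = len(self.coords)
        for name in ("atom_name", "res_name", "res_id", "chain_id"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise FormatError(f"{name} length {arr.shape} != atom count {n}")
            setattr(self, name, arr)
        keys = list(zip(self.chain_id, self.res_id, self.atom_name))
        if len(set(keys)) != n:
            raise FormatError("(chain, residue, atom name) triples are not unique")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure carrying new coordinates."""
        return Structure(
            coords=np.array(coords, dtype=np.float64),
            atom_name=self.atom_name,
            res_name=self.res_name,
            res_id=self.res_id,
            chain_id=self.chain_id,
            occupancy=self.occupancy,
            b_factor=self.b_factor,
        )

    def subset(self, indices: np.ndarray) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            coords=self.coords[idx],
            atom_name=self.atom_name[idx],
            res_name=self.res_name[idx],
            res_id=self.res_id[idx],
            chain_id=self.chain_id[idx],
            occupancy=None if self.occupancy is None else self.occupancy[idx],
            b_factor=None if self.b_factor is None else self.b_factor[idx],
        )


@dataclass
class Trajectory:
    """Ordered coordinate frames over a shared atom list.

    ``frame_dt`` is the time step between frames in ns.
    """

    reference: Structure
    frames: np.ndarray          # (F, N, 3) float64, Å
    frame_dt: float = 0.1       # ns

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise FormatError(f"frames must be (F, N, 3), got {self.frames.shape}")
        if self.frames.shape[1] != self.reference.n_atoms:
            raise FormatError(
                f"frame atom count {self.frames.shape[1]} != reference "
                f"{self.reference.n_atoms}"
            )
        if not self.frame_dt > 0:
            raise InvalidSpecificationError(f"frame_dt must be > 0, got {self.frame_dt}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_dt

    def frame_structure(self, i: int) -> Structure:
        return self.reference.with_coords(self.frames[i])


@dataclass
class SubunitDef:
    """One subunit: a chain plus an inclusive 1-based residue range and its
    partition into N-/C-terminal domain residue sets."""

    label: str
    chain: str
    residues: tuple[int, int]           # inclusive range
    n_domain: frozenset[int] = field(default_factory=frozenset)
    c_domain: frozenset[int] = field(default_factory=frozenset)

    def residue_set(self) -> frozenset[int]:
        lo, hi = self.residues
        return frozenset(range(lo, hi + 1))


@dataclass
class FilamentModel:
    """Maps atoms → subunits (ordered bottom → top) → domains."""

    subunits: list[SubunitDef]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for su in self.subunits:
            lo, hi = su.residues
            if hi < lo:
                raise InvalidSpecificationError(f"subunit {su.label}: empty residue range")
            res = su.residue_set()
            keyed = {(su.chain, r) for r in res}
            if keyed & seen:
                raise InvalidSpecificationError("subunit residue sets overlap")
            seen |= keyed
            if su.n_domain or su.c_domain:
                if su.n_domain & su.c_domain:
                    raise InvalidSpecificationError(
                        f"subunit {su.label}: domain sets overlap"
                    )
                if (su.n_domain | su.c_domain) != res:
                    raise InvalidSpecificationError(
                        f"subunit {su.label}: domains do not partition the residues"
                    )

    @property
    def labels(self) -> list[str]:
        return [su.label for su in self.subunits]

    def subunit(self, label: str) -> SubunitDef:
        for su in self.subunits:
            if su.label == label:
                return su
        raise SelectionError(f"unknown subunit label {label!r}; have {self.labels}")

    @property
    def interfaces(self) -> list[tuple[str, str, str]]:
        """(name, lower label, upper label) for consecutive subunit pairs.

        With the canonical bottom/middle/top labels the bottom–middle pair is
        the "bottom" interface and middle–top the "top" interface.
        """
        out = []
        for i, (lower, upper) in enumerate(zip(self.subunits[:-1], self.subunits[1:])):
            name = lower.label if i == 0 else upper.label
            out.append((name, lower.label, upper.label))
        return out

    # -- config round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "subunits": [
                {
                    "label": su.label,
                    "chain": su.chain,
                    "residues": list(su.residues),
                    "n_domain": sorted(su.n_domain),
                    "c_domain": sorted(su.c_domain),
                }
                for su in self.subunits
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilamentModel":
        subs = [
            SubunitDef(
                label=e["label"],
                chain=e["chain"],
                residues=tuple(e["residues"]),
                n_domain=frozenset(e.get("n_domain", [])),
                c_domain=frozenset(e.get("c_domain", [])),
            )
            for e in d["subunits"]
        ]
        return cls(subunits=subs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "FilamentModel":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _structure_to_atom_array(s: Structure) -> struc.AtomArray:
    arr = struc.AtomArray(s.n_atoms)
    arr.coord = s.coords
    arr.chain_id = s.chain_id.astype("U4")
    arr.res_id = s.res_id.astype(int)
    arr.res_name = s.res_name.astype("U5")
    arr.atom_name = s.atom_name.astype("U6")
    arr.element = np.array(["C"] * s.n_atoms)
    arr.hetero = np.zeros(s.n_atoms, dtype=bool)
    if s.occupancy is not None:
        arr.set_annotation("occupancy", s.occupancy.astype(float))
    if s.b_factor is not None:
        arr.set_annotation("b_factor", s.b_factor.astype(float))
    return arr


def write_pdb_trajectory(path: str | Path, traj: Trajectory) -> None:
    """Write a multi-model PDB (MODEL/ENDMDL per frame)."""
    template = _structure_to_atom_array(traj.reference)
    stack = struc.from_template(template, traj.frames)
    f = PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def write_pdb_structure(path: str | Path, s: Structure) -> None:
    f = PDBFile()
    f.set_structure(_structure_to_atom_array(s))
    f.write(str(path))


def _atom_array_to_structure(arr: struc.AtomArray) -> Structure:
    return Structure(
        coords=np.asarray(arr.coord, dtype=np.float64),
        atom_name=np.asarray(arr.atom_name),
        res_name=np.asarray(arr.res_name),
        res_id=np.asarray(arr.res_id, dtype=int),
        chain_id=np.asarray(arr.chain_id),
        occupancy=(np.asarray(arr.occupancy) if "occupancy" in arr.get_annotation_categories() else None),
        b_factor=(np.asarray(arr.b_factor) if "b_factor" in arr.get_annotation_categories() else None),
    )


def read_pdb_trajectory(path: str | Path, frame_dt: float = 0.1) -> Trajectory:
    """Read a (multi-model) PDB into a Trajectory.

    Models must be congruent (same atom count in the same order); a
    mismatch raises :class:`FormatError` naming the offending model.
    Alternate locations keep the highest-occupancy conformer (first on
    ties).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            obj = pdb.get_structure(altloc="occupancy")
    except Exception:
        # diagnose which model breaks congruence
        counts = []
        for m in range(1, n_models + 1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                counts.append(pdb.get_structure(model=m, altloc="occupancy").array_length())
        for m, c in enumerate(counts[1:], start=2):
            if c != counts[0]:
                raise FormatError(
                    f"model {m} has {c} atoms but model 1 has {counts[0]}"
                ) from None
        raise FormatError(f"inconsistent models in {path}") from None

    if isinstance(obj, struc.AtomArray):        # single model
        ref = _atom_array_to_structure(obj)
        frames = ref.coords[None]
    else:
        ref = _atom_array_to_structure(obj[0])
        frames = np.asarray(obj.coord, dtype=np.float64)
    return Trajectory(reference=ref, frames=frames, frame_dt=frame_dt)


# ---------------------------------------------------------------------------
# XYZ dialect (element x y z per line, frame blocks) — no installed package
# reads topology-free multi-frame XYZ, so this minimal reader is local.
# ---------------------------------------------------------------------------

def write_xyz_trajectory(path: str | Path, traj: Trajectory) -> None:
    ref = traj.reference
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{ref.n_atoms}\nframe {f}\n")
            for name, xyz in zip(ref.atom_name, traj.frames[f]):
                fh.write(f"{name:<4s} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}\n")


def read_xyz_trajectory(path: str | Path, frame_dt: float = 0.1) -> Trajectory:
    """Read the plain XYZ dialect; atoms become single-point residues on
    chain A unless a reference Structure is attached afterwards."""
    lines = Path(path).read_text().splitlines()
    frames: list[np.ndarray] = []
    names: list[str] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as e:
            raise FormatError(f"expected atom count at line {i + 1}") from e
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise FormatError(f"truncated frame starting at line {i + 1}")
        coords = np.empty((n, 3))
        frame_names = []
        for j, ln in enumerate(block):
            parts = ln.split()
            frame_names.append(parts[0])
            coords[j] = [float(x) for x in parts[1:4]]
        if frames and n != frames[0].shape[0]:
            raise FormatError(
                f"frame {len(frames) + 1} has {n} atoms but frame 1 has "
                f"{frames[0].shape[0]}"
            )
        frames.append(coords)
        names = frame_names
        i += 2 + n
    if not frames:
        raise FormatError(f"no frames in {path}")
    n = frames[0].shape[0]
    ref = Structure(
        coords=frames[0],
        atom_name=np.array(names),
        res_name=np.array(["GLY"] * n),
        res_id=np.arange(1, n + 1),
        chain_id=np.array(["A"] * n),
    )
    return Trajectory(reference=ref, frames=np.stack(frames), frame_dt=frame_dt)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def select(
    obj: Structure | Trajectory,
    model: FilamentModel,
    subunit: str | None = None,
    domain: str | None = None,
    atom_name: str | None = None,
) -> np.ndarray:
    """Resolve a (subunit, domain, atom-name) filter to sorted atom indices.

    Filters intersect; ``domain`` is "N" or "C" and requires ``subunit``.
    """
    s = obj.reference if isinstance(obj, Trajectory) else obj
    mask = np.ones(s.n_atoms, dtype=bool)
    if subunit is not None:
        su = model.subunit(subunit)
        res = su.residue_set()
        mask &= (s.chain_id == su.chain) & np.isin(s.res_id, list(res))
        if domain is not None:
            dset = {"N": su.n_domain, "C": su.c_domain}.get(domain.upper())
            if dset is None:
                raise SelectionError(f"domain must be 'N' or 'C', got {domain!r}")
            if not dset:
                raise SelectionError(f"subunit {subunit!r} has no domain split")
            mask &= np.isin(s.res_id, list(dset))
    elif domain is not None:
        raise SelectionError("domain filter requires a subunit label")
    if atom_name is not None:
        mask &= s.atom_name == atom_name
    return np.flatnonzero(mask)
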