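"""Domain types for peptide systems and trajectory frames, plus multi-model PDB I/O.

A :class:`SystemModel` is the immutable topology (sequence, chains, atoms) shared
by every frame of a :class:`Trajectory`.  Coordinates are stored in Angstrom
throughout the package; nanometre conversion happens only in reports.

Residue numbering: internal residue indices are 0-based per chain; reported
labels add :attr:`SystemModel.residue_numbering_offset` (105 for the
transthyretin 105-115 fragment this package was written around).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

__all__ = [
    "Atom",
    "SystemModel",
    "Frame",
    "Trajectory",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "select",
    "SELECTORS",
]

#: three-letter codes for the twenty standard amino acids, keyed by one-letter code
THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


def element_from_name(name: str) -> str:
    """Infer the element from a PDB atom name (peptide atoms only)."""
    stripped = name.strip()
    if not stripped:
        raise ValueError("empty atom name")
    # hydrogen names may start with a digit (e.g. 1HB) or with H
    if stripped[0].isdigit():
        stripped = stripped[1:]
    return stripped[0].upper()


@dataclass(frozen=True)
class Atom:
    """One atom of the topology: name, element, residue index (0-based, per chain), chain id."""

    name: str
    element: str
    residue_index: int
    chain_id: str


@dataclass(frozen=True)
class SystemModel:
    """Immutable topology of a multi-chain peptide system.

    All chains carry the same sequence (identical peptide copies), matching the
    homo-oligomer systems this package targets.
    """

    sequence: str
    chains: tuple[str, ...]
    atoms: tuple[Atom, ...]
    residue_numbering_offset: int = 105

    def __post_init__(self):
        n = len(self.sequence)
        for a in self.atoms:
            if not (0 <= a.residue_index < n):
                raise ValueError(
                    f"atom {a.name} residue index {a.residue_index} outside sequence length {n}"
                )
            if a.chain_id not in self.chains:
                raise ValueError(f"atom {a.name} references unknown chain {a.chain_id!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def residue_label(self, residue_index: int) -> int:
        """Author-style residue number (105-based by default)."""
        return residue_index + self.residue_numbering_offset

    def atom_index(self, chain_id: str, residue_index: int, name: str) -> int | None:
        """Index of a named atom, or None if absent (O(n); cached tables live in callers)."""
        for i, a in enumerate(self.atoms):
            if a.chain_id == chain_id and a.residue_index == residue_index and a.name == name:
                return i
        return None


@dataclass(frozen=True)
class Frame:
    """A single coordinate set (Angstrom) bound to a SystemModel; time in ns if known."""

    coordinates: np.ndarray
    time: float | None = None

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates contain non-finite values")
        object.__setattr__(self, "coordinates", coords)


@dataclass(frozen=True)
class Trajectory:
    """An ordered sequence of frames sharing one topology."""

    model: SystemModel
    frames: tuple[Frame, ...]
    frame_interval: float | None = None

    def __post_init__(self):
        if len(self.frames) == 0:
            raise ValueError("trajectory must contain at least one frame")
        for i, f in enumerate(self.frames):
            if f.coordinates.shape[0] != self.model.n_atoms:
                raise ValueError(
                    f"frame {i}: {f.coordinates.shape[0]} coordinates for "
                    f"{self.model.n_atoms} atoms"
                )
        times = [f.time for f in self.frames if f.time is not None]
        if len(times) > 1 and not all(b > a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def window(self, start: int | None = None, stop: int | None = None) -> "Trajectory":
        """Sub-trajectory by frame index (half-open slice)."""
        frames = self.frames[slice(start, stop)]
        if not frames:
            raise ValueError("window selects no frames")
        return replace(self, frames=frames)

    def coordinates_array(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates."""
        return np.stack([f.coordinates for f in self.frames])


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def read_multimodel_pdb(path, frame_interval: float | None = None) -> Trajectory:
    """Read a (multi-)MODEL PDB file into a Trajectory.

    One Frame per MODEL record; a bare ATOM-record file yields one frame.
    Insertion codes are rejected; for alternate locations the first altLoc is
    kept (Biopython's default).  Raises ValueError when atom counts differ
    between models.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(path))

    bio_models = list(structure)
    if not bio_models:
        raise ValueError(f"{path}: no models found")

    # topology from the first model
    first = bio_models[0]
    chain_ids: list[str] = []
    atoms: list[Atom] = []
    sequence_by_chain: dict[str, list[tuple[int, str]]] = {}
    offset: int | None = None

    for chain in first:
        chain_ids.append(chain.id)
        sequence_by_chain[chain.id] = []
        for residue in chain:
            het, resseq, icode = residue.id
            if het.strip():
                continue  # skip waters / heteroatoms
            if icode.strip():
                raise ValueError(f"{path}: insertion code {icode!r} at residue {resseq} not supported")
            if offset is None:
                offset = resseq
            resname = residue.get_resname()
            one = ONE_LETTER.get(resname)
            if one is None:
                raise ValueError(f"{path}: unknown residue {resname}")
            chain_start = sequence_by_chain[chain.id][0][0] if sequence_by_chain[chain.id] else resseq
            ridx = resseq - chain_start
            sequence_by_chain[chain.id].append((resseq, one))
            for atom in residue:
                if atom.is_disordered():
                    atom = atom.disordered_get()
                name = atom.get_name()
                atoms.append(Atom(name, element_from_name(name), ridx, chain.id))

    sequences = {"".join(one for _, one in v) for v in sequence_by_chain.values()}
    if len(sequences) != 1:
        raise ValueError(f"{path}: chains carry different sequences {sequences}")
    sequence = sequences.pop()

    model = SystemModel(
        sequence=sequence,
        chains=tuple(chain_ids),
        atoms=tuple(atoms),
        residue_numbering_offset=offset if offset is not None else 1,
    )

    frames = []
    for mi, bio_model in enumerate(bio_models):
        coords = []
        for chain in bio_model:
            for residue in chain:
                if residue.id[0].strip():
                    continue
                for atom in residue:
                    if atom.is_disordered():
                        atom = atom.disordered_get()
                    coords.append(atom.get_coord())
        if len(coords) != model.n_atoms:
            raise ValueError(
                f"{path}: model {mi + 1} has {len(coords)} atoms, expected {model.n_atoms}"
            )
        time = mi * frame_interval if frame_interval is not None else None
        frames.append(Frame(np.asarray(coords, dtype=float), time=time))

    return Trajectory(model=model, frames=tuple(frames), frame_interval=frame_interval)


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write a Trajectory as a fixed-column multi-MODEL PDB (MODEL/ENDMDL, TER per chain)."""
    model = traj.model
    lines: list[str] = []
    multi = traj.n_frames > 1
    for mi, frame in enumerate(traj.frames):
        if multi:
            lines.append(f"MODEL     {mi + 1:4d}")
        serial = 1
        prev_chain = None
        coords = frame.coordinates
        for ai, atom in enumerate(model.atoms):
            if prev_chain is not None and atom.chain_id != prev_chain:
                lines.append("TER")
            prev_chain = atom.chain_id
            x, y, z = coords[ai]
            if not (-999.999 <= x <= 9999.999 and -999.999 <= y <= 9999.999 and -999.999 <= z <= 9999.999):
                raise ValueError(f"coordinate {coords[ai]} exceeds PDB column width")
            resname = THREE_LETTER[model.sequence[atom.residue_index]]
            resseq = atom.residue_index + model.residue_numbering_offset
            name = atom.name
            # PDB alignment: element-aligned names start in column 14 unless 4 chars
            fname = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {fname}{'':1s}{resname:>3s} {atom.chain_id}{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {atom.element:>2s}"
            )
            serial += 1
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# atom selections
# ---------------------------------------------------------------------------

def _sel_all(a: Atom) -> bool:
    return True


def _sel_heavy(a: Atom) -> bool:
    return a.element != "H"


def _sel_backbone(a: Atom) -> bool:
    return a.name in _BACKBONE_NAMES


def _sel_calpha(a: Atom) -> bool:
    return a.name == "CA"


SELECTORS = {
    "all": _sel_all,
    "heavy": _sel_heavy,
    "backbone": _sel_backbone,
    "calpha": _sel_calpha,
    "ca": _sel_calpha,
}


def select(model: SystemModel, predicate: str, chain: str | None = None) -> np.ndarray:
    """Deterministic, order-preserving atom index set for a named selector.

    Supported selectors: ``all``, ``heavy``, ``backbone`` (N/CA/C/O + OXT),
    ``calpha``/``ca``.  Restrict to a single chain with ``chain=``.
    """
    key = predicate.lower()
    if key not in SELECTORS:
        raise ValueError(f"unknown selector {predicate!r}; choose from {sorted(SELECTORS)}")
    fn = SELECTORS[key]
    idx = [
        i
        for i, a in enumerate(model.atoms)
        if fn(a) and (chain is None or a.chain_id == chain)
    ]
    return np.asarray(idx, dtype=int)
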