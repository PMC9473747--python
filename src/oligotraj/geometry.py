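"""Frame-level geometric observables: hydrogen bonds, residue contacts, Rg, SASA.

The hydrogen-bond criterion is purely geometric: donor N to acceptor O distance
within ``hbond_max_dist`` (3.5 A) and N-H...O angle at the hydrogen of at least
``hbond_min_angle`` (120 deg).  Residue contacts use the minimum heavy-atom
distance rule at 5.4 A, excluding sequence neighbours (|i-j| < 2) within a
chain; interchain pairs are never excluded.  Both cutoffs are the conventional
choices for amyloid-oligomer trajectory analysis and are tunable through
:class:`AnalysisParameters`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .model_io import Atom, Frame, SystemModel, select

__all__ = [
    "AnalysisParameters",
    "HBond",
    "ContactMap",
    "detect_hbonds",
    "residue_contacts",
    "radius_of_gyration",
    "sasa",
    "ATOMIC_MASSES",
    "VDW_RADII",
]

#: atomic masses (u) for the elements occurring in peptides
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

#: Bondi van der Waals radii (A)
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}


@dataclass(frozen=True)
class AnalysisParameters:
    """Tunable thresholds for all geometric detectors.

    Defaults follow the standard conventions for peptide-aggregation MD
    analysis: 3.5 A / 120 deg hydrogen bonds, 5.4 A heavy-atom contacts between
    discontinuous residues, 0.4 nm gromos clustering cutoff, 310 K.
    """

    hbond_max_dist: float = 3.5       # A, donor N to acceptor O
    hbond_min_angle: float = 120.0    # deg, N-H...O at the hydrogen
    contact_max_dist: float = 5.4     # A, minimum heavy-atom distance
    min_seq_separation: int = 2       # residues, intrachain contact exclusion
    cluster_cutoff: float = 4.0       # A, gromos RMSD cutoff (0.4 nm)
    temperature: float = 310.0        # K
    sheet_min_run: int = 2            # residues per beta strand
    sheet_min_hbonds: int = 2         # backbone H-bonds per sheet pairing

    def __post_init__(self):
        if min(self.hbond_max_dist, self.contact_max_dist, self.cluster_cutoff) <= 0:
            raise ValueError("distance thresholds must be positive")
        if not (0 < self.hbond_min_angle <= 180):
            raise ValueError("hbond_min_angle must lie in (0, 180]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class HBond:
    """One detected hydrogen bond between backbone/polar groups of two residues."""

    donor_chain: str
    donor_residue: int
    acceptor_chain: str
    acceptor_residue: int
    distance: float     # N-O, A
    angle: float        # N-H...O, deg
    interchain: bool


@dataclass(frozen=True)
class ContactMap:
    """Square residue-pair matrix over all (chain, residue) pairs of a system.

    ``matrix`` is boolean for a single frame or a probability in [0, 1] for an
    ensemble.  ``labels`` gives the (chain, residue_index) pair behind each row.
    """

    matrix: np.ndarray
    labels: tuple[tuple[str, int], ...]

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("contact matrix must be square and match labels")
        if not np.allclose(m, m.T):
            raise ValueError("contact matrix must be symmetric")
        object.__setattr__(self, "matrix", m)

    def submap(self, interchain: bool) -> np.ndarray:
        """Interchain (True) or intrachain (False) entries; others zeroed."""
        chains = np.array([c for c, _ in self.labels])
        inter = chains[:, None] != chains[None, :]
        mask = inter if interchain else ~inter
        return np.where(mask, self.matrix, 0)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _residue_atom_table(model: SystemModel) -> dict[tuple[str, int], dict[str, int]]:
    table: dict[tuple[str, int], dict[str, int]] = {}
    for i, a in enumerate(model.atoms):
        table.setdefault((a.chain_id, a.residue_index), {})[a.name] = i
    return table


def reconstruct_amide_h(n_pos: np.ndarray, ca_pos: np.ndarray, cprev_pos: np.ndarray) -> np.ndarray:
    """Planar amide hydrogen: 1.01 A from N, opposite the C(prev)-N-CA bisector."""
    u1 = cprev_pos - n_pos
    u2 = ca_pos - n_pos
    u1 = u1 / np.linalg.norm(u1)
    u2 = u2 / np.linalg.norm(u2)
    bisector = u1 + u2
    norm = np.linalg.norm(bisector)
    if norm < 1e-8:  # collinear C-N-CA, no defined plane
        raise ValueError("degenerate amide geometry")
    return n_pos - 1.01 * bisector / norm


def detect_hbonds(
    frame: Frame,
    model: SystemModel,
    params: AnalysisParameters = AnalysisParameters(),
    scope: str = "backbone",
) -> list[HBond]:
    """Geometric hydrogen-bond detection.

    ``scope='backbone'`` restricts donors to backbone amide N-H and acceptors
    to carbonyl O (incl. OXT); ``scope='all-NO'`` additionally admits side-chain
    N donors and O acceptors.  Proline contributes no donor (no amide H).  When
    the amide hydrogen is absent from the topology it is reconstructed from
    standard planar geometry; the first residue of a chain (no preceding
    carbonyl C) is then skipped as a donor with a warning.

    Covalently linked N/O pairs (same residue, or donor N with the carbonyl O
    of its preceding residue) are never counted.
    """
    if scope not in ("backbone", "all-NO"):
        raise ValueError(f"unknown scope {scope!r}")
    table = _residue_atom_table(model)
    coords = frame.coordinates

    donors = []  # (chain, ridx, N index, H position)
    acceptors = []  # (chain, ridx, O index)
    skipped = 0
    for (chain, ridx), names in table.items():
        aa = model.sequence[ridx]
        for name, ai in names.items():
            atom = model.atoms[ai]
            if atom.element == "O":
                if scope == "backbone" and name not in ("O", "OXT"):
                    continue
                acceptors.append((chain, ridx, ai))
        if aa == "P":
            continue
        n_idx = names.get("N")
        if n_idx is None:
            continue
        h_idx = names.get("H") or names.get("HN") or names.get("H1")
        if h_idx is not None:
            donors.append((chain, ridx, n_idx, coords[h_idx]))
        else:
            prev = table.get((chain, ridx - 1))
            ca_idx = names.get("CA")
            if prev is None or "C" not in prev or ca_idx is None:
                skipped += 1
                continue
            h_pos = reconstruct_amide_h(coords[n_idx], coords[ca_idx], coords[prev["C"]])
            donors.append((chain, ridx, n_idx, h_pos))
    if skipped:
        warnings.warn(f"{skipped} residue(s) skipped as H-bond donors (no amide H reconstructible)")

    bonds: list[HBond] = []
    seen: set[tuple] = set()
    for d_chain, d_res, n_idx, h_pos in donors:
        n_pos = coords[n_idx]
        for a_chain, a_res, o_idx in acceptors:
            if d_chain == a_chain and a_res in (d_res, d_res - 1):
                continue  # covalent neighbours, not hydrogen bonds
            o_pos = coords[o_idx]
            dist = float(np.linalg.norm(n_pos - o_pos))
            if dist > params.hbond_max_dist:
                continue
            v1 = n_pos - h_pos
            v2 = o_pos - h_pos
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle < params.hbond_min_angle:
                continue
            key = (d_chain, d_res, a_chain, a_res, o_idx)
            if key in seen:
                continue
            seen.add(key)
            bonds.append(
                HBond(d_chain, d_res, a_chain, a_res, dist, angle, interchain=d_chain != a_chain)
            )
    return bonds


# ---------------------------------------------------------------------------
# residue contacts
# ---------------------------------------------------------------------------

def residue_contacts(
    frame: Frame,
    model: SystemModel,
    params: AnalysisParameters = AnalysisParameters(),
) -> ContactMap:
    """Boolean residue-residue contact map by the minimum heavy-atom distance rule."""
    labels: list[tuple[str, int]] = []
    groups: list[np.ndarray] = []
    heavy = select(model, "heavy")
    by_res: dict[tuple[str, int], list[int]] = {}
    for ai in heavy:
        a = model.atoms[ai]
        by_res.setdefault((a.chain_id, a.residue_index), []).append(ai)
    for chain in model.chains:
        for ridx in range(model.n_residues):
            key = (chain, ridx)
            if key in by_res:
                labels.append(key)
                groups.append(frame.coordinates[by_res[key]])

    n = len(labels)
    mat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            ci, ri = labels[i]
            cj, rj = labels[j]
            if ci == cj and abs(ri - rj) < params.min_seq_separation:
                continue
            if cdist(groups[i], groups[j]).min() <= params.contact_max_dist:
                mat[i, j] = mat[j, i] = True
    return ContactMap(mat, tuple(labels))


# ---------------------------------------------------------------------------
# radius of gyration
# ---------------------------------------------------------------------------

def radius_of_gyration(
    frame: Frame,
    model: SystemModel,
    selection: np.ndarray | None = None,
    mass_weighted: bool = True,
) -> float:
    """Rg in Angstrom: sqrt(sum m_i |r_i - rbar|^2 / sum m_i).

    Default selection is all heavy atoms of all chains, mass-weighted.
    """
    if selection is None:
        selection = select(model, "heavy")
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    coords = frame.coordinates[selection]
    if mass_weighted:
        masses = np.array([ATOMIC_MASSES[model.atoms[i].element] for i in selection])
    else:
        masses = np.ones(len(selection))
    centroid = np.average(coords, axis=0, weights=masses)
    sq = np.sum((coords - centroid) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(
    frame: Frame,
    model: SystemModel,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> tuple[np.ndarray, float, float]:
    """Shrake-Rupley SASA over heavy atoms.

    Returns (per-atom areas in A^2 indexed like the topology — hydrogens get 0 —
    hydrophobic total over C/S atoms, hydrophilic total over N/O atoms).
    """
    heavy = select(model, "heavy")
    for ai in heavy:
        if model.atoms[ai].element not in VDW_RADII:
            raise ValueError(f"unknown element for atom {model.atoms[ai]}")
    radii = np.array([VDW_RADII[model.atoms[i].element] for i in heavy]) + probe_radius
    coords = frame.coordinates[heavy]
    unit = _sphere_points(n_sphere_points)

    n = len(heavy)
    dists = cdist(coords, coords)
    areas_heavy = np.zeros(n)
    for i in range(n):
        neighbours = np.where((dists[i] < radii[i] + radii) & (np.arange(n) != i))[0]
        pts = coords[i] + radii[i] * unit
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbours:
            accessible &= np.sum((pts - coords[j]) ** 2, axis=1) > radii[j] ** 2
            if not accessible.any():
                break
        areas_heavy[i] = accessible.sum() / n_sphere_points * 4 * np.pi * radii[i] ** 2

    areas = np.zeros(model.n_atoms)
    areas[heavy] = areas_heavy
    elements = np.array([model.atoms[i].element for i in heavy])
    hydrophobic = float(areas_heavy[np.isin(elements, ["C", "S"])].sum())
    hydrophilic = float(areas_heavy[np.isin(elements, ["N", "O"])].sum())
    return areas, hydrophobic, hydrophilic
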