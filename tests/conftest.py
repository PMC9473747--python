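"""Shared fixtures and independent oracles for the test suite."""

import warnings

import numpy as np
import pytest

from oligotraj.model_io import Atom, Frame, SystemModel


@pytest.fixture(autouse=True)
def _quiet_donor_warnings():
    """Chain-start residues without amide H always warn; keep test output clean."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*skipped as H-bond donors.*")
        yield


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def quaternion_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Optimal-superposition RMSD via the quaternion characteristic polynomial
    (Horn's method): independent of the SVD route used by the package."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    ga = np.sum(a * a)
    gb = np.sum(b * b)
    msd = max(0.0, (ga + gb - 2.0 * lam) / len(a))
    return float(np.sqrt(msd))


def daura_reference(dist: np.ndarray, cutoff: float):
    """Naive loop implementation of gromos clustering (greedy max-neighbour,
    strict < cutoff, ties to the lowest frame index)."""
    n = dist.shape[0]
    remaining = set(range(n))
    clusters = []
    while remaining:
        best, best_count = None, -1
        for i in sorted(remaining):
            count = sum(1 for j in remaining if j != i and dist[i, j] < cutoff)
            if count > best_count:
                best, best_count = i, count
        members = sorted({best} | {j for j in remaining if dist[best, j] < cutoff})
        clusters.append((best, tuple(members)))
        remaining -= set(members)
    return clusters


def two_sphere_sasa(r1: float, r2: float, d: float) -> tuple[float, float]:
    """Closed-form accessible areas of two intersecting spheres (probe-expanded
    radii r1, r2, centre distance d): full sphere minus the buried cap."""
    areas = []
    for ra, rb in ((r1, r2), (r2, r1)):
        if d >= ra + rb:
            areas.append(4 * np.pi * ra**2)
            continue
        if d + ra <= rb:
            areas.append(0.0)
            continue
        cos_t = (d**2 + ra**2 - rb**2) / (2 * d * ra)
        cap = 2 * np.pi * ra**2 * (1 - cos_t)
        areas.append(4 * np.pi * ra**2 - cap)
    return areas[0], areas[1]


def to_mdtraj(model: SystemModel, frame: Frame):
    """Convert a system + frame to an mdtraj Trajectory (nm) for reference DSSP."""
    import mdtraj as md
    from mdtraj.core.element import get_by_symbol

    from oligotraj.model_io import THREE_LETTER

    top = md.Topology()
    order = []
    for cid in model.chains:
        ch = top.add_chain()
        res, last = None, -1
        for i, a in enumerate(model.atoms):
            if a.chain_id != cid:
                continue
            if a.residue_index != last:
                res = top.add_residue(
                    THREE_LETTER[model.sequence[a.residue_index]],
                    ch,
                    resSeq=a.residue_index + model.residue_numbering_offset,
                )
                last = a.residue_index
            top.add_atom(a.name, get_by_symbol(a.element), res)
            order.append(i)
    xyz = frame.coordinates[order][None] / 10.0
    return md.Trajectory(xyz, top)


def reference_dssp(model: SystemModel, frame: Frame) -> np.ndarray:
    """Reference Kabsch-Sander codes via mdtraj ('-' for loop)."""
    import mdtraj as md

    codes = md.compute_dssp(to_mdtraj(model, frame), simplified=False)[0]
    return np.array(["-" if c in (" ", "") else c for c in codes])


@pytest.fixture(scope="session")
def oracles():
    return dict(
        quaternion_rmsd=quaternion_rmsd,
        daura_reference=daura_reference,
        two_sphere_sasa=two_sphere_sasa,
        reference_dssp=reference_dssp,
    )


# ---------------------------------------------------------------------------
# small hand-built systems
# ---------------------------------------------------------------------------

@pytest.fixture
def donor_acceptor_factory():
    """Two single-residue chains: donor N-H on chain A, acceptor O on chain B.

    The factory takes the N-O target distance and the N-H...O angle (deg) and
    returns (model, frame) with that exact geometry.
    """

    def build(no_dist: float, angle_deg: float):
        from scipy.optimize import brentq

        n = np.array([0.0, 0.0, 0.0])
        h = np.array([1.01, 0.0, 0.0])
        theta = np.radians(180.0 - angle_deg)
        v = np.array([np.cos(theta), np.sin(theta), 0.0])  # H->O direction

        def f(r):
            o = h + r * v
            return np.linalg.norm(o - n) - no_dist

        r = brentq(f, 1e-6, no_dist + 2.5)
        o = h + r * v
        model = SystemModel(
            sequence="A",
            chains=("A", "B"),
            atoms=(
                Atom("N", "N", 0, "A"),
                Atom("H", "H", 0, "A"),
                Atom("CA", "C", 0, "A"),
                Atom("O", "O", 0, "B"),
                Atom("C", "C", 0, "B"),
            ),
            residue_numbering_offset=1,
        )
        coords = np.array([n, h, [0.5, 1.3, 0.0], o, o + [1.23, 0, 0]])
        return model, Frame(coords)

    return build


@pytest.fixture(scope="session")
def sheet_dimer():
    from oligotraj.synthetic_data import assemble_state

    model, frame, label = assemble_state("sheet", n_chains=2, seed=42)
    return model, frame, label


@pytest.fixture(scope="session")
def mixed_trajectory():
    """20-frame coil -> 4-strand sheet trajectory with ground-truth labels."""
    from oligotraj.synthetic_data import make_trajectory

    traj, labels = make_trajectory(
        [
            (dict(kind="coil", n_chains=4), 10),
            (dict(kind="sheet", n_chains=4, noise_sigma=0.2), 10),
        ],
        seed=11,
    )
    return traj, labels
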