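"""Hydrogen bonds, residue contacts, radius of gyration and SASA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oligotraj.geometry import (
    AnalysisParameters,
    detect_hbonds,
    radius_of_gyration,
    residue_contacts,
    sasa,
)
from oligotraj.model_io import Atom, Frame, SystemModel, select
from oligotraj.synthetic_data import assemble_state, build_peptide, PHI_PSI


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "dist,angle,expected",
    [
        (3.0, 165.0, 1),    # comfortably inside both criteria
        (3.4999, 170.0, 1),  # just inside the inclusive 3.5 A cutoff
        (3.5001, 170.0, 0),  # just outside
        (3.6, 170.0, 0),     # too long, however linear
        (2.9, 100.0, 0),     # short but bent well below the 120 deg floor
        (2.9, 119.99, 0),    # just under the angle floor
        (2.9, 120.01, 1),    # just over
    ],
)
def test_hbond_criterion_boundaries(donor_acceptor_factory, dist, angle, expected):
    model, frame = donor_acceptor_factory(dist, angle)
    bonds = detect_hbonds(frame, model)
    assert len(bonds) == expected
    if expected:
        (b,) = bonds
        assert b.interchain
        assert b.distance == pytest.approx(dist, abs=1e-6)
        assert b.angle == pytest.approx(angle, abs=1e-6)


def test_hbond_set_shrinks_with_tighter_criteria(sheet_dimer):
    model, frame, _ = sheet_dimer
    loose = detect_hbonds(frame, model, AnalysisParameters())
    tight_d = detect_hbonds(frame, model, AnalysisParameters(hbond_max_dist=3.0))
    tight_a = detect_hbonds(frame, model, AnalysisParameters(hbond_min_angle=150.0))

    def keys(bonds):
        return {(b.donor_chain, b.donor_residue, b.acceptor_chain, b.acceptor_residue) for b in bonds}

    assert keys(tight_d) <= keys(loose)
    assert keys(tight_a) <= keys(loose)


def test_proline_never_donates(sheet_dimer):
    model, frame, _ = sheet_dimer
    pro = model.sequence.index("P")
    assert all(b.donor_residue != pro for b in detect_hbonds(frame, model))


def test_covalent_neighbours_not_counted():
    model, frame = build_peptide("AAAA", PHI_PSI["extended"])
    # extended chain: the only N/O pairs within 3.5 A are covalent neighbours
    assert detect_hbonds(frame, model) == []


# ---------------------------------------------------------------------------
# residue contacts
# ---------------------------------------------------------------------------

def test_sequence_neighbours_excluded_interchain_kept(sheet_dimer):
    model, frame, _ = sheet_dimer
    cm = residue_contacts(frame, model)
    idx = {lab: k for k, lab in enumerate(cm.labels)}
    n = model.n_residues
    for r in range(n - 1):
        assert not cm.matrix[idx[("A", r)], idx[("A", r + 1)]]
        assert not cm.matrix[idx[("A", r)], idx[("A", r)]]
    # paired antiparallel strands touch across chains
    assert cm.submap(interchain=True).sum() > 0


def test_contact_monotone_in_cutoff(sheet_dimer):
    model, frame, _ = sheet_dimer
    small = residue_contacts(frame, model, AnalysisParameters(contact_max_dist=4.5))
    large = residue_contacts(frame, model, AnalysisParameters(contact_max_dist=6.5))
    assert np.all(large.matrix[small.matrix])  # raising the cutoff never removes one


def test_contact_map_symmetry(sheet_dimer):
    model, frame, _ = sheet_dimer
    cm = residue_contacts(frame, model)
    assert np.array_equal(cm.matrix, cm.matrix.T)


# ---------------------------------------------------------------------------
# radius of gyration
# ---------------------------------------------------------------------------

def _point_model(positions, elements):
    atoms = tuple(Atom(f"C{i}", el, 0, "A") for i, el in enumerate(elements))
    model = SystemModel(sequence="A", chains=("A",), atoms=atoms, residue_numbering_offset=1)
    return model, Frame(np.asarray(positions, dtype=float))


def test_rg_closed_forms():
    m, f = _point_model([[5.0, -2.0, 7.0]], ["C"])
    assert radius_of_gyration(f, m) == pytest.approx(0.0, abs=1e-12)

    corners = [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    m, f = _point_model(corners, ["C"] * 8)
    assert radius_of_gyration(f, m, mass_weighted=False) == pytest.approx(np.sqrt(3), abs=1e-12)

    # mass ratio 1:3 via one atom against three co-located: centroid 3, Rg^2 = 12/4
    m, f = _point_model([[0, 0, 0], [4, 0, 0], [4, 0, 0], [4, 0, 0]], ["C"] * 4)
    assert radius_of_gyration(f, m, mass_weighted=False) == pytest.approx(np.sqrt(3), abs=1e-12)


def test_rg_empty_selection_rejected(sheet_dimer):
    model, frame, _ = sheet_dimer
    with pytest.raises(ValueError):
        radius_of_gyration(frame, model, selection=np.array([], dtype=int))


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def test_sasa_isolated_sphere_matches_closed_form():
    m, f = _point_model([[0, 0, 0]], ["C"])  # r = 1.70
    areas, phob, phil = sasa(f, m, probe_radius=1.4)
    exact = 4 * np.pi * (1.70 + 1.4) ** 2
    assert areas[0] == pytest.approx(exact, rel=5e-3)
    assert phob == pytest.approx(exact, rel=5e-3)
    assert phil == 0.0


def test_sasa_enclosed_atom_is_zero():
    rng = np.random.default_rng(0)
    shell = []
    for _ in range(80):
        v = rng.normal(size=3)
        shell.append(2.2 * v / np.linalg.norm(v))
    m, f = _point_model([[0, 0, 0]] + shell, ["C"] * 81)
    areas, *_ = sasa(f, m)
    assert areas[0] == 0.0


def test_sasa_two_spheres_match_analytic_caps(oracles):
    d = 2.5
    m, f = _point_model([[0, 0, 0], [d, 0, 0]], ["C", "O"])
    areas, *_ = sasa(f, m, probe_radius=1.4)
    a1, a2 = oracles["two_sphere_sasa"](1.70 + 1.4, 1.52 + 1.4, d)
    assert areas[0] == pytest.approx(a1, rel=0.02)
    assert areas[1] == pytest.approx(a2, rel=0.02)


def test_sasa_rigid_motion_invariant(sheet_dimer):
    model, frame, _ = sheet_dimer
    _, phob, phil = sasa(frame, model, n_sphere_points=240)
    theta = 0.7
    rot = np.array(
        [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
    )
    moved = Frame(frame.coordinates @ rot.T + np.array([3.0, -7.0, 11.0]))
    _, phob2, phil2 = sasa(moved, model, n_sphere_points=240)
    assert phob2 == pytest.approx(phob, rel=0.02)
    assert phil2 == pytest.approx(phil, rel=0.02)


def test_sasa_unknown_element_rejected():
    m, f = _point_model([[0, 0, 0]], ["X"])
    with pytest.raises(ValueError, match="unknown element"):
        sasa(f, m)


def test_hydrophobic_exceeds_hydrophilic_for_oligomer(sheet_dimer):
    """The fragment is hydrophobe-rich; C/S area should dominate N/O area."""
    model, frame, _ = sheet_dimer
    _, phob, phil = sasa(frame, model, n_sphere_points=240)
    assert phob > phil


# ---------------------------------------------------------------------------
# parameter validation
# ---------------------------------------------------------------------------

@given(
    st.floats(min_value=-5, max_value=0),
    st.sampled_from(["hbond_max_dist", "contact_max_dist", "cluster_cutoff", "temperature"]),
)
@settings(deadline=None, derandomize=True, max_examples=20)
def test_nonpositive_parameters_rejected(value, field):
    with pytest.raises(ValueError):
        AnalysisParameters(**{field: value})
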