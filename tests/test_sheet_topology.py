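"""Strand segmentation, pairing graph, beta-sheet contacts, oligomer classes."""

import numpy as np
import pytest

from oligotraj.geometry import AnalysisParameters, detect_hbonds
from oligotraj.model_io import Frame
from oligotraj.secondary_structure import SSAssignment, assign_ss
from oligotraj.sheet_topology import (
    beta_sheet_contacts,
    build_sheet_graph,
    classify_oligomer,
    find_strands,
)
from oligotraj.synthetic_data import assemble_state

PARAMS = AnalysisParameters()


def _analyze(model, frame, params=PARAMS):
    ss = assign_ss(frame, model)
    strands = find_strands(ss, frame, model, params.sheet_min_run)
    hbonds = detect_hbonds(frame, model, params)
    graph = build_sheet_graph(strands, hbonds, params)
    return ss, strands, hbonds, graph


# ---------------------------------------------------------------------------
# strand segmentation
# ---------------------------------------------------------------------------

def _fake_assignment(codes_per_chain):
    flat = "".join(codes_per_chain)
    return SSAssignment(tuple(flat), (), len(codes_per_chain), len(codes_per_chain[0]))


def test_find_strands_runs(sheet_dimer):
    model, frame, _ = sheet_dimer
    ss = _fake_assignment(["--EEEEE----", "-----------"])
    (seg,) = find_strands(ss, frame, model)
    assert (seg.chain_id, seg.start, seg.end) == ("A", 2, 6)
    assert len(seg) == 5
    assert np.isclose(np.linalg.norm(seg.direction), 1.0)

    # a lone E residue is not a strand; an all-coil frame has none
    ss = _fake_assignment(["----E------", "-----------"])
    assert find_strands(ss, frame, model) == []
    ss = _fake_assignment(["-----------", "-----------"])
    assert find_strands(ss, frame, model) == []


def test_two_strands_per_chain_allowed(sheet_dimer):
    model, frame, _ = sheet_dimer
    ss = _fake_assignment(["-EE----EE--", "-----------"])
    segs = find_strands(ss, frame, model)
    assert [(s.start, s.end) for s in segs] == [(1, 2), (7, 8)]


# ---------------------------------------------------------------------------
# sheet graph
# ---------------------------------------------------------------------------

def test_ideal_dimer_gives_one_antiparallel_edge(sheet_dimer):
    model, frame, _ = sheet_dimer
    _, strands, hbonds, graph = _analyze(model, frame)
    assert len(strands) == 2
    assert len(graph.edges) == 1
    (orient, nhb), = graph.edges.values()
    assert orient == "antiparallel"
    assert nhb >= 4


def test_single_hbond_is_not_a_sheet(sheet_dimer):
    model, frame, _ = sheet_dimer
    _, strands, hbonds, _ = _analyze(model, frame)
    inter = [b for b in hbonds if b.interchain]
    graph = build_sheet_graph(strands, inter[:1], PARAMS)
    assert graph.edges == {}
    assert build_sheet_graph(strands, [], PARAMS).edges == {}


def test_parallel_orientation_label():
    model, frame, _ = assemble_state("sheet", n_chains=2, orientation="parallel", seed=9)
    _, _, _, graph = _analyze(model, frame)
    (orient, _), = graph.edges.values()
    assert orient == "parallel"


# ---------------------------------------------------------------------------
# beta-sheet contacts
# ---------------------------------------------------------------------------

def test_contact_count_bounded_by_interchain_hbonds():
    for seed in range(6):
        model, frame, _ = assemble_state("sheet", n_chains=3, noise_sigma=0.25, seed=seed)
        _, _, hbonds, graph = _analyze(model, frame)
        count = beta_sheet_contacts(graph, hbonds)
        inter = sum(1 for b in hbonds if b.interchain)
        assert 0 <= count <= inter


def test_contact_modes_and_coil_zero(sheet_dimer):
    model, frame, _ = sheet_dimer
    _, _, hbonds, graph = _analyze(model, frame)
    linked = beta_sheet_contacts(graph, hbonds)
    allpairs = beta_sheet_contacts(graph, hbonds, mode="all-paired")
    assert 0 < linked <= allpairs

    cmodel, cframe, _ = assemble_state("coil", n_chains=2, seed=3)
    _, _, chb, cgraph = _analyze(cmodel, cframe)
    assert beta_sheet_contacts(cgraph, chb) == 0
    with pytest.raises(ValueError):
        beta_sheet_contacts(graph, hbonds, mode="bogus")


# ---------------------------------------------------------------------------
# oligomer classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kind,kwargs,label,strands",
    [
        ("closed_barrel", dict(n_chains=6), "closed_barrel", (6,)),
        ("open_barrel", dict(n_chains=5, noise_sigma=0.3), "open_barrel", (5,)),
        ("bilayer", dict(layers=(3, 2), n_chains=5), "bilayer", (3, 2)),
        ("sheet", dict(n_chains=4), "single_sheet", (4,)),
        ("coil", dict(n_chains=4), "disordered", ()),
    ],
)
def test_classifier_recovers_construction(kind, kwargs, label, strands):
    model, frame, gt = assemble_state(kind, seed=21, **kwargs)
    _, _, _, graph = _analyze(model, frame)
    oc = classify_oligomer(graph, frame, model, PARAMS)
    assert oc.label == label == gt.label
    assert tuple(oc.strands) == strands == tuple(gt.strands)


def test_classification_invariant_under_rigid_motion_and_relabeling():
    model, frame, _ = assemble_state("open_barrel", n_chains=4, seed=2)
    _, _, _, graph = _analyze(model, frame)
    base = classify_oligomer(graph, frame, model, PARAMS)

    rng = np.random.default_rng(0)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    moved = Frame(frame.coordinates @ rot.T + np.array([5.0, -3.0, 8.0]))
    _, _, _, g2 = _analyze(model, moved)
    oc2 = classify_oligomer(g2, moved, model, PARAMS)
    assert (oc2.label, oc2.strands) == (base.label, base.strands)

    # relabel chains by reversing the coordinate blocks
    n_per = model.n_atoms // model.n_chains
    blocks = [frame.coordinates[k * n_per:(k + 1) * n_per] for k in range(model.n_chains)]
    relabeled = Frame(np.concatenate(blocks[::-1]))
    _, _, _, g3 = _analyze(model, relabeled)
    oc3 = classify_oligomer(g3, relabeled, model, PARAMS)
    assert (oc3.label, oc3.strands) == (base.label, base.strands)


def test_mixed_orientation_flag():
    model, frame, _ = assemble_state("sheet", n_chains=4, orientation="mixed", seed=13)
    _, _, _, graph = _analyze(model, frame)
    assert graph.mixed_orientation
    oc = classify_oligomer(graph, frame, model, PARAMS)
    assert oc.mixed_orientation


def test_sheet_with_coil_spectator_counts_only_strands():
    """A three-stranded sheet plus one coil chain is single_sheet(3)."""
    model, frame, gt = assemble_state("sheet", n_chains=4, n_strands=3, seed=17)
    assert model.n_chains == 4
    _, _, _, graph = _analyze(model, frame)
    oc = classify_oligomer(graph, frame, model, PARAMS)
    assert (oc.label, tuple(oc.strands)) == ("single_sheet", (3,)) == (gt.label, tuple(gt.strands))
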