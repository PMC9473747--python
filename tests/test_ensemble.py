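"""PDFs, free-energy landscapes, contact maps, time series and bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oligotraj.ensemble_analysis import (
    GAS_CONSTANT_KJ,
    SimulationPlan,
    contact_probability_map,
    convergence_overlap,
    interaction_timeseries,
    ion_count,
    pdf1d,
    plan_totals,
    pmf2d,
)
from oligotraj.geometry import detect_hbonds
from oligotraj.model_io import Trajectory
from oligotraj.synthetic_data import assemble_state, make_trajectory


# ---------------------------------------------------------------------------
# pdf1d / pmf2d
# ---------------------------------------------------------------------------

def test_pdf_normalization_and_errors():
    rng = np.random.default_rng(0)
    dens, edges = pdf1d(rng.normal(size=2000), bins=40)
    assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0, abs=1e-9)

    dens, edges = pdf1d([3.0, 3.0, 3.0])
    assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0, abs=1e-9)
    assert (dens > 0).sum() == 1  # constant series fills a single bin
    with pytest.raises(ValueError):
        pdf1d([])


def test_uniform_samples_give_flat_density():
    rng = np.random.default_rng(1)
    dens, edges = pdf1d(rng.uniform(size=60_000), bins=np.linspace(0, 1, 11))
    assert np.abs(dens - 1.0).max() < 0.08  # sampling error at n = 60k


def test_pmf_two_bin_closed_form():
    # counts 4:1 in two x bins at 310 K -> delta PMF = RT ln 4
    x = np.array([0.0] * 4 + [1.0])
    y = np.zeros(5)
    land = pmf2d(x, y, bins=(np.array([-0.5, 0.5, 1.5]), np.array([-0.5, 0.5])), temperature=310.0)
    delta = land.pmf[1, 0] - land.pmf[0, 0]
    expected = GAS_CONSTANT_KJ * 310.0 * np.log(4.0)
    assert delta == pytest.approx(expected, abs=1e-9)
    assert expected == pytest.approx(3.5733, abs=2e-3)
    assert land.pmf.min() == 0.0
    assert land.histogram.sum() == pytest.approx(1.0, abs=1e-12)


def test_uniform_histogram_gives_zero_pmf():
    x = np.repeat([0.0, 1.0, 2.0], 5)
    y = np.zeros(15)
    land = pmf2d(x, y, bins=(np.array([-0.5, 0.5, 1.5, 2.5]), np.array([-0.5, 0.5])))
    assert np.allclose(land.pmf, 0.0)


def test_empty_bins_are_infinite():
    land = pmf2d([0.0, 2.0], [0.0, 0.0],
                 bins=(np.array([-0.5, 0.5, 1.5, 2.5]), np.array([-0.5, 0.5])))
    assert np.isinf(land.pmf[1, 0])


@given(st.integers(min_value=0, max_value=10_000))
@settings(deadline=None, derandomize=True, max_examples=30)
def test_pmf_differences_depend_only_on_count_ratio(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(1, 50, size=6)
    x = np.repeat(np.arange(6, dtype=float), counts)
    y = np.zeros(len(x))
    land = pmf2d(x, y, bins=(np.arange(-0.5, 6.5), np.array([-0.5, 0.5])), temperature=310.0)
    h = land.histogram[:, 0]
    pmf = land.pmf[:, 0]
    rt = GAS_CONSTANT_KJ * 310.0
    for i in range(6):
        for j in range(6):
            assert pmf[i] - pmf[j] == pytest.approx(-rt * np.log(h[i] / h[j]), abs=1e-9)


def test_pmf_mismatched_lengths_rejected():
    with pytest.raises(ValueError):
        pmf2d([1.0, 2.0], [1.0])


# ---------------------------------------------------------------------------
# contact maps and time series
# ---------------------------------------------------------------------------

def test_frozen_dimer_contact_probabilities_are_binary(sheet_dimer):
    model, frame, _ = sheet_dimer
    traj = Trajectory(model, (frame, frame, frame))
    inter, intra = contact_probability_map(traj)
    assert inter.shape == intra.shape == (11, 11)
    assert np.array_equal(inter, inter.T)
    assert set(np.unique(inter)) <= {0.0, 0.5, 1.0}  # two ordered chain pairs
    assert inter.max() == 1.0


def test_interaction_timeseries_consistency(sheet_dimer):
    model, frame, _ = sheet_dimer
    traj = Trajectory(model, (frame,))
    df = interaction_timeseries(traj)
    row = df.iloc[0]
    assert row.hbonds_total == row.hbonds_intrachain + row.hbonds_interchain
    assert row.contacts_total == row.contacts_intrachain + row.contacts_interchain
    assert row.hbonds_interchain == sum(1 for b in detect_hbonds(frame, model) if b.interchain)


def test_single_chain_has_no_interchain_interactions():
    model, frame, _ = assemble_state("helix", n_chains=1, seed=0)
    traj = Trajectory(model, (frame,))
    df = interaction_timeseries(traj)
    assert df.hbonds_interchain.iloc[0] == 0
    assert df.contacts_interchain.iloc[0] == 0


def test_timeseries_tracks_schedule_switch(mixed_trajectory):
    traj, _ = mixed_trajectory
    df = interaction_timeseries(traj)
    # sheet frames carry far more interchain H-bonds than scattered coils
    assert df.hbonds_interchain[10:].mean() > df.hbonds_interchain[:10].mean() + 5


# ---------------------------------------------------------------------------
# convergence overlap
# ---------------------------------------------------------------------------

def test_overlap_extremes_and_closed_form():
    rng = np.random.default_rng(0)
    a = rng.normal(size=4000)
    assert convergence_overlap(a, a) == pytest.approx(1.0, abs=1e-12)
    assert convergence_overlap([0.0] * 10, [100.0] * 10, bins=5) == 0.0
    # hand-built histograms {0.5, 0.5} vs {0.25, 0.75} -> 0.75
    a = [0.0, 0.0, 1.0, 1.0]
    b = [0.0, 1.0, 1.0, 1.0]
    assert convergence_overlap(a, b, bins=2) == pytest.approx(0.75, abs=1e-12)
    assert convergence_overlap(b, a, bins=2) == pytest.approx(0.75, abs=1e-12)  # symmetric
    with pytest.raises(ValueError):
        convergence_overlap([], [1.0])


# ---------------------------------------------------------------------------
# simulation bookkeeping
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "box_nm,expected",
    [(4.757, 10), (5.873, 18), (7.060, 32)],
)
def test_physiological_ion_counts(box_nm, expected):
    """0.15 mol/L NaCl in the three oligomer boxes."""
    assert ion_count(0.15, box_nm) == expected


def test_ion_count_edge_cases():
    assert ion_count(0.0, 5.0) == 0
    with pytest.raises(ValueError):
        ion_count(-0.1, 5.0)
    with pytest.raises(ValueError):
        ion_count(0.15, 0.0)


def test_plan_totals():
    rows = tuple(
        dict(system=s, box_edge_nm=b, n_peptides=p, time_per_run_us=1.5, n_runs=7)
        for s, b, p in [("two", 4.757, 2), ("four", 5.873, 4), ("six", 7.060, 6)]
    )
    plan = SimulationPlan(rows)
    assert plan_totals(plan) == pytest.approx(31.5, abs=1e-12)
    single = SimulationPlan((dict(system="x", box_edge_nm=5, n_peptides=2,
                                  time_per_run_us=1.5, n_runs=1),))
    assert plan_totals(single) == pytest.approx(1.5)
    assert plan_totals(SimulationPlan(())) == 0.0
    with pytest.raises(ValueError):
        SimulationPlan((dict(system="bad", box_edge_nm=-1, n_peptides=2,
                             time_per_run_us=1.5, n_runs=7),))
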