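"""Ensemble statistics: 1D PDFs, 2D free-energy landscapes, contact-probability
maps, interaction time series, convergence overlap, and simulation bookkeeping.

The landscape is the standard histogram estimate of a potential of mean force:
PMF(x, y) = -R T ln H(x, y) with H the normalized 2D probability over the two
reaction coordinates (here: beta-sheet contact count and radius of gyration),
shifted so the occupied minimum sits at zero; empty bins are +inf.  R is the
molar gas constant in kJ/(mol K), so at 310 K the prefactor RT is 2.5775
kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import AnalysisParameters, ContactMap, detect_hbonds, residue_contacts
from .model_io import SystemModel, Trajectory

__all__ = [
    "GAS_CONSTANT_KJ",
    "AVOGADRO",
    "Landscape",
    "SimulationPlan",
    "pdf1d",
    "pmf2d",
    "contact_probability_map",
    "interaction_timeseries",
    "convergence_overlap",
    "ion_count",
    "plan_totals",
]

GAS_CONSTANT_KJ = 8.314462e-3  # kJ / (mol K)
AVOGADRO = 6.02214076e23  # 1 / mol


@dataclass(frozen=True)
class Landscape:
    """2D probability histogram and derived free-energy surface.

    ``pmf`` is -RT ln H shifted to min 0 over occupied bins; empty bins +inf.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    histogram: np.ndarray  # normalized probability, sums to 1
    pmf: np.ndarray        # kJ/mol
    temperature: float

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: x center, y center, probability, pmf."""
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        rows = []
        for i, x in enumerate(xc):
            for j, y in enumerate(yc):
                rows.append((x, y, self.histogram[i, j], self.pmf[i, j]))
        return pd.DataFrame(rows, columns=["x", "y", "probability", "pmf_kj_mol"])


@dataclass(frozen=True)
class SimulationPlan:
    """Bookkeeping of an MD campaign: one row per system."""

    rows: tuple[dict, ...]  # keys: system, box_edge_nm, n_peptides, time_per_run_us, n_runs
    salt_mol_per_l: float = 0.15

    def __post_init__(self):
        for r in self.rows:
            if min(r["box_edge_nm"], r["n_peptides"], r["time_per_run_us"], r["n_runs"]) <= 0:
                raise ValueError(f"non-positive entry in plan row {r}")


def pdf1d(series, bins=50) -> tuple[np.ndarray, np.ndarray]:
    """Normalized density over a numeric series: (density, bin edges); integral 1."""
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("empty series")
    density, edges = np.histogram(arr, bins=bins, density=True)
    return density, edges


def pmf2d(
    x,
    y,
    bins=(None, None),
    temperature: float = 310.0,
) -> Landscape:
    """Free-energy landscape -RT ln H(x, y) from two equal-length series.

    Default binning: integer bins on x (a count coordinate) and 0.25 A
    (0.025 nm) bins on y spanning the observed range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y series must have equal length")
    if x.size == 0:
        raise ValueError("empty series")
    x_bins, y_bins = bins if isinstance(bins, tuple) else (bins, bins)
    if x_bins is None:
        lo, hi = np.floor(x.min()), np.ceil(x.max())
        x_bins = np.arange(lo - 0.5, hi + 1.5)
    if y_bins is None:
        width = 0.25
        lo = np.floor(y.min() / width) * width
        hi = np.ceil(y.max() / width) * width + width
        y_bins = np.arange(lo, hi + width / 2, width)

    counts, xe, ye = np.histogram2d(x, y, bins=(x_bins, y_bins))
    h = counts / counts.sum()
    with np.errstate(divide="ignore"):
        pmf = -GAS_CONSTANT_KJ * temperature * np.log(h)
    occupied = h > 0
    pmf[occupied] -= pmf[occupied].min()
    pmf[~occupied] = np.inf
    return Landscape(xe, ye, h, pmf, temperature)


def contact_probability_map(
    traj: Trajectory,
    window: tuple[int | None, int | None] = (None, None),
    params: AnalysisParameters = AnalysisParameters(),
) -> tuple[np.ndarray, np.ndarray]:
    """(interchain, intrachain) residue-pair contact probabilities.

    Both maps are n_residues x n_residues over sequence positions, averaged
    over frames and over all ordered chain pairs (interchain) or chains
    (intrachain); symmetric with values in [0, 1].
    """
    sub = traj.window(*window)
    model = sub.model
    n_res = model.n_residues
    n_chains = model.n_chains
    inter = np.zeros((n_res, n_res))
    intra = np.zeros((n_res, n_res))
    n_pairs = n_chains * (n_chains - 1)  # ordered chain pairs
    for frame in sub.frames:
        cm = residue_contacts(frame, model, params)
        idx = {lab: k for k, lab in enumerate(cm.labels)}
        for ci, ca in enumerate(model.chains):
            for cj, cb in enumerate(model.chains):
                for ri in range(n_res):
                    for rj in range(n_res):
                        if cm.matrix[idx[(ca, ri)], idx[(cb, rj)]]:
                            if ci == cj:
                                intra[ri, rj] += 1
                            else:
                                inter[ri, rj] += 1
    intra /= sub.n_frames * n_chains
    if n_pairs:
        inter /= sub.n_frames * n_pairs
    return inter, intra


def interaction_timeseries(
    traj: Trajectory,
    params: AnalysisParameters = AnalysisParameters(),
    scope: str = "backbone",
) -> pd.DataFrame:
    """Per-frame interaction counts: intra/inter/total H-bonds and heavy-atom contacts."""
    rows = []
    model = traj.model
    for fi, frame in enumerate(traj.frames):
        hbonds = detect_hbonds(frame, model, params, scope=scope)
        hb_inter = sum(1 for b in hbonds if b.interchain)
        hb_intra = len(hbonds) - hb_inter
        cm = residue_contacts(frame, model, params)
        inter_mask = cm.submap(interchain=True)
        intra_mask = cm.submap(interchain=False)
        c_inter = int(inter_mask.sum()) // 2
        c_intra = int(intra_mask.sum()) // 2
        rows.append(
            dict(
                frame=fi,
                time_ns=frame.time,
                hbonds_intrachain=hb_intra,
                hbonds_interchain=hb_inter,
                hbonds_total=len(hbonds),
                contacts_intrachain=c_intra,
                contacts_interchain=c_inter,
                contacts_total=c_intra + c_inter,
            )
        )
    return pd.DataFrame(rows)


def convergence_overlap(series_a, series_b, bins=30) -> float:
    """Histogram overlap coefficient sum(min(pA, pB)) in [0, 1] over shared bins."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty window")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        return 1.0
    edges = np.linspace(lo, hi, (bins if isinstance(bins, int) else len(bins)) + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(np.minimum(pa, pb).sum())


def ion_count(concentration_mol_per_l: float, box_edge_nm: float) -> int:
    """Ions per species for a cubic box: round(c * V * N_A), V in litres."""
    if concentration_mol_per_l < 0 or box_edge_nm <= 0:
        raise ValueError("concentration must be >= 0 and box edge > 0")
    volume_l = (box_edge_nm * 1e-8) ** 3  # nm -> dm (1 nm = 1e-8 dm); dm^3 = L
    return int(round(concentration_mol_per_l * volume_l * AVOGADRO))


def plan_totals(plan: SimulationPlan) -> float:
    """Accumulated simulation time in microseconds: sum of time-per-run x runs."""
    return float(sum(r["time_per_run_us"] * r["n_runs"] for r in plan.rows))
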