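"""Beta-sheet topology: strand segments, pairing graph, and oligomer classification.

A chain contributes a strand for every maximal run of >= 2 residues assigned E.
Two strands are sheet-paired when at least two backbone hydrogen bonds connect
their residues; the pairing orientation comes from the sign of the dot product
of the strand direction vectors (first-CA -> last-CA), with an explicit
``indeterminate`` label inside the +-0.5 dead zone.

The oligomer classifier reads the pairing graph:

1. a component whose pairing graph contains a simple cycle through >= 3
   strands is a closed barrel (n = strands in the component);
2. an acyclic component of >= 3 strands that curls toward closure — terminal
   strands within 8 A (min CA-CA), or successive strand-pair planes turning by
   >= 90 deg accumulated — is an open barrel;
3. two sheets stacked face-to-face (>= 3 inter-component residue contacts,
   no pairing edge between them) form a bilayer [m, n];
4. a single flat component is a single sheet; anything else is disordered.

Precedence follows that order; chains with no strands never block a call
(the four-peptide "three-stranded sheet + one coil chain" cluster is a
single_sheet(3)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import networkx as nx

from .geometry import AnalysisParameters, ContactMap, HBond, residue_contacts
from .model_io import Frame, SystemModel
from .secondary_structure import SSAssignment

__all__ = [
    "StrandSegment",
    "SheetGraph",
    "OligomerClass",
    "find_strands",
    "build_sheet_graph",
    "beta_sheet_contacts",
    "classify_oligomer",
]


@dataclass(frozen=True)
class StrandSegment:
    """A maximal run of E residues in one chain; residue range inclusive, 0-based."""

    chain_id: str
    chain_index: int
    start: int
    end: int
    direction: np.ndarray  # unit vector first-CA -> last-CA

    @property
    def residues(self) -> range:
        return range(self.start, self.end + 1)

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SheetGraph:
    """Strand pairing graph for one frame.

    ``edges`` maps (strand index a, strand index b) with a < b to
    (orientation, hbond count); orientation in {parallel, antiparallel,
    indeterminate}.
    """

    strands: tuple[StrandSegment, ...]
    edges: dict[tuple[int, int], tuple[str, int]]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.strands)))
        for (a, b), (orient, nhb) in self.edges.items():
            g.add_edge(a, b, orientation=orient, hbonds=nhb)
        return g

    @property
    def mixed_orientation(self) -> bool:
        orients = {o for o, _ in self.edges.values()}
        return "parallel" in orients and "antiparallel" in orients


@dataclass(frozen=True)
class OligomerClass:
    """Topology label of one frame's strand arrangement."""

    label: str  # disordered | single_sheet | bilayer | open_barrel | closed_barrel
    strands: tuple[int, ...]  # (n,) or layer sizes (m, n) sorted descending
    mixed_orientation: bool = False

    def __str__(self) -> str:
        if self.label == "bilayer":
            return f"bilayer[{'+'.join(map(str, self.strands))}]"
        if self.strands:
            return f"{self.label}({self.strands[0]})"
        return self.label


def find_strands(
    ss: SSAssignment,
    frame: Frame,
    model: SystemModel,
    min_run: int = 2,
) -> list[StrandSegment]:
    """Maximal runs of E of length >= min_run, per chain."""
    n_res = model.n_residues
    ca_index = {}
    for i, a in enumerate(model.atoms):
        if a.name == "CA":
            ca_index[(a.chain_id, a.residue_index)] = i

    strands: list[StrandSegment] = []
    for ci, chain in enumerate(model.chains):
        run_start = None
        for r in range(n_res + 1):
            is_e = r < n_res and ss.code(ci, r) == "E"
            if is_e and run_start is None:
                run_start = r
            elif not is_e and run_start is not None:
                if r - run_start >= min_run:
                    first = frame.coordinates[ca_index[(chain, run_start)]]
                    last = frame.coordinates[ca_index[(chain, r - 1)]]
                    d = last - first
                    d = d / np.linalg.norm(d)
                    strands.append(StrandSegment(chain, ci, run_start, r - 1, d))
                run_start = None
    return strands


def build_sheet_graph(
    strands: list[StrandSegment],
    hbonds: list[HBond],
    params: AnalysisParameters = AnalysisParameters(),
) -> SheetGraph:
    """Pair strands sharing >= sheet_min_hbonds backbone hydrogen bonds."""
    membership: dict[tuple[str, int], int] = {}
    for si, s in enumerate(strands):
        for r in s.residues:
            membership[(s.chain_id, r)] = si

    counts: dict[tuple[int, int], int] = {}
    for hb in hbonds:
        a = membership.get((hb.donor_chain, hb.donor_residue))
        b = membership.get((hb.acceptor_chain, hb.acceptor_residue))
        if a is None or b is None or a == b:
            continue
        key = (min(a, b), max(a, b))
        counts[key] = counts.get(key, 0) + 1

    edges: dict[tuple[int, int], tuple[str, int]] = {}
    for (a, b), n in counts.items():
        if n < params.sheet_min_hbonds:
            continue
        dot = float(np.dot(strands[a].direction, strands[b].direction))
        if dot > 0.5:
            orient = "parallel"
        elif dot < -0.5:
            orient = "antiparallel"
        else:
            orient = "indeterminate"
        edges[(a, b)] = (orient, n)
    return SheetGraph(tuple(strands), edges)


def beta_sheet_contacts(
    graph: SheetGraph,
    hbonds: list[HBond],
    mode: str = "hbond-linked",
) -> int:
    """Count beta-sheet contacts: residue pairs knitting paired strands together.

    ``hbond-linked`` (default): pairs of E residues in sheet-paired strands
    joined by >= 1 backbone hydrogen bond.  ``all-paired``: every E-residue
    pair belonging to a paired strand couple, H-bonded or not.  The count is
    the x reaction coordinate of the free-energy landscape.
    """
    if mode not in ("hbond-linked", "all-paired"):
        raise ValueError(f"unknown mode {mode!r}")
    membership: dict[tuple[str, int], int] = {}
    for si, s in enumerate(graph.strands):
        for r in s.residues:
            membership[(s.chain_id, r)] = si

    if mode == "all-paired":
        total = 0
        for (a, b) in graph.edges:
            total += len(graph.strands[a]) * len(graph.strands[b])
        return total

    pairs: set[frozenset] = set()
    for hb in hbonds:
        a = membership.get((hb.donor_chain, hb.donor_residue))
        b = membership.get((hb.acceptor_chain, hb.acceptor_residue))
        if a is None or b is None or a == b:
            continue
        if (min(a, b), max(a, b)) not in graph.edges:
            continue
        pairs.add(
            frozenset(
                (
                    (hb.donor_chain, hb.donor_residue),
                    (hb.acceptor_chain, hb.acceptor_residue),
                )
            )
        )
    return len(pairs)


# ---------------------------------------------------------------------------
# oligomer classification
# ---------------------------------------------------------------------------

def _strand_ca_coords(strand: StrandSegment, frame: Frame, model: SystemModel) -> np.ndarray:
    idx = [
        i
        for i, a in enumerate(model.atoms)
        if a.name == "CA" and a.chain_id == strand.chain_id and a.residue_index in strand.residues
    ]
    return frame.coordinates[idx]


def _pair_plane_normal(ca_a: np.ndarray, ca_b: np.ndarray) -> np.ndarray:
    pts = np.vstack([ca_a, ca_b])
    pts = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    return vt[2]


def _is_curled(
    component: list[int],
    graph: SheetGraph,
    frame: Frame,
    model: SystemModel,
    terminal_dist_cutoff: float = 8.0,
    accumulated_angle_cutoff: float = 90.0,
) -> bool:
    """Open-barrel curl test on an acyclic sheet component of >= 3 strands."""
    g = graph.graph().subgraph(component)
    # order strands along the sheet: longest simple path between degree-1 nodes
    term = [n for n in g.nodes if g.degree(n) == 1]
    if len(term) < 2:
        return False
    best_path: list[int] = []
    for a, b in combinations(term, 2):
        for path in nx.all_simple_paths(g, a, b):
            if len(path) > len(best_path):
                best_path = path
    if len(best_path) < 3:
        return False

    cas = [_strand_ca_coords(graph.strands[s], frame, model) for s in best_path]
    # terminal-strand approach
    from scipy.spatial.distance import cdist

    if cdist(cas[0], cas[-1]).min() <= terminal_dist_cutoff:
        return True
    # accumulated turning of successive strand-pair planes
    normals = [
        _pair_plane_normal(cas[k], cas[k + 1]) for k in range(len(cas) - 1)
    ]
    total = 0.0
    for n1, n2 in zip(normals, normals[1:]):
        cosang = abs(float(np.dot(n1, n2)))  # plane angle, sign-free
        total += np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
    return total >= accumulated_angle_cutoff


def classify_oligomer(
    graph: SheetGraph,
    frame: Frame,
    model: SystemModel,
    params: AnalysisParameters = AnalysisParameters(),
    contacts: ContactMap | None = None,
    bilayer_min_contacts: int = 3,
) -> OligomerClass:
    """Classify a frame's strand arrangement (see module docstring for the rules)."""
    g = graph.graph()
    mixed = graph.mixed_orientation
    sheets = [sorted(c) for c in nx.connected_components(g) if len(c) >= 2]
    sheets.sort(key=len, reverse=True)

    # (1) closed barrel: cycle through >= 3 strands
    for comp in sheets:
        sub = g.subgraph(comp)
        if any(len(cyc) >= 3 for cyc in nx.cycle_basis(sub)):
            return OligomerClass("closed_barrel", (len(comp),), mixed)

    # (2) open barrel: curled acyclic sheet of >= 3 strands
    for comp in sheets:
        if len(comp) >= 3 and _is_curled(comp, graph, frame, model):
            return OligomerClass("open_barrel", (len(comp),), mixed)

    # (3) bilayer: two sheets stacked via residue contacts, no pairing edge
    if len(sheets) >= 2:
        if contacts is None:
            contacts = residue_contacts(frame, model, params)
        label_index = {lab: k for k, lab in enumerate(contacts.labels)}
        for compA, compB in combinations(sheets, 2):
            resA = [
                (graph.strands[s].chain_id, r)
                for s in compA
                for r in graph.strands[s].residues
            ]
            resB = [
                (graph.strands[s].chain_id, r)
                for s in compB
                for r in graph.strands[s].residues
            ]
            ia = [label_index[x] for x in resA]
            ib = [label_index[x] for x in resB]
            n_contacts = int(contacts.matrix[np.ix_(ia, ib)].sum())
            if n_contacts >= bilayer_min_contacts:
                sizes = tuple(sorted((len(compA), len(compB)), reverse=True))
                return OligomerClass("bilayer", sizes, mixed)

    # (4) single flat sheet
    if sheets:
        return OligomerClass("single_sheet", (len(sheets[0]),), mixed)

    return OligomerClass("disordered", ())
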