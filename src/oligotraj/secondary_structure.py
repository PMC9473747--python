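"""Kabsch-Sander (DSSP) secondary-structure assignment and category statistics.

The assignment follows the published Kabsch-Sander algorithm: backbone hydrogen
bonds are scored with the electrostatic model

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol

with a bond whenever E < -0.5 kcal/mol; n-turns give helices (G/H/I), bridge
patterns give ladders and sheets (B/E), remaining turns give T, and a bend in
the chain (kappa > 70 deg) gives S.  Inter-chain bridges are permitted — they
are what interpeptide beta-sheets are made of — while turns and helices never
span a chain terminus.

Assignment precedence mirrors the reference DSSP implementation: four-turn
helices overwrite strands; 3-10 and pi helices, turns and bends only fill
residues still unassigned.

For reporting, the eight DSSP states collapse to five categories
(coil, beta-sheet, alpha-helix, bend, turn).  By default isolated beta bridges
(B) and the 3-10/pi helices (G/I) count as coil: the beta-sheet bookkeeping
downstream requires two or more coherent strand residues, which a single
bridge cannot supply, and the alpha-helix category is reserved for genuine
4-turn helices.  The table is a plain dict and can be remapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model_io import Frame, SystemModel, Trajectory

__all__ = [
    "SSAssignment",
    "DEFAULT_CATEGORY_TABLE",
    "CATEGORIES",
    "assign_ss",
    "collapse_categories",
    "ss_statistics",
    "ss_timeline",
]

#: reporting categories, in the conventional order
CATEGORIES = ("coil", "beta-sheet", "alpha-helix", "bend", "turn")

#: default DSSP code -> category mapping
DEFAULT_CATEGORY_TABLE = {
    "H": "alpha-helix",
    "G": "coil",
    "I": "coil",
    "E": "beta-sheet",
    "B": "coil",
    "T": "turn",
    "S": "bend",
    "-": "coil",
}

_Q = 0.084 * 332.0  # kcal/mol * A, Kabsch-Sander coupling constant
_HBOND_CUTOFF = -0.5  # kcal/mol
_CA_CUTOFF = 9.0  # A, pairs farther apart cannot hydrogen-bond


@dataclass(frozen=True)
class SSAssignment:
    """Per-residue DSSP codes for one frame.

    ``codes[g]`` is the code of global residue ``g`` (chain-major ordering:
    chain index * n_residues + residue index).  ``bridges`` lists
    (g_i, g_j, orientation) beta bridges with orientation 'parallel' or
    'antiparallel'.
    """

    codes: tuple[str, ...]
    bridges: tuple[tuple[int, int, str], ...]
    n_chains: int
    n_residues: int  # per chain

    def code(self, chain_index: int, residue_index: int) -> str:
        return self.codes[chain_index * self.n_residues + residue_index]

    def as_array(self) -> np.ndarray:
        return np.array(self.codes)


def _backbone_indices(model: SystemModel) -> list[dict[str, int]]:
    """Per global residue: dict of backbone atom name -> atom index."""
    n_res = model.n_residues
    table: list[dict[str, int]] = [dict() for _ in range(model.n_chains * n_res)]
    chain_pos = {c: k for k, c in enumerate(model.chains)}
    for i, a in enumerate(model.atoms):
        if a.name in ("N", "CA", "C", "O", "H", "HN"):
            g = chain_pos[a.chain_id] * n_res + a.residue_index
            table[g].setdefault("H" if a.name == "HN" else a.name, i)
    return table


def _hbond_energy(n, h, c, o) -> float:
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9
    return _Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_ss(frame: Frame, model: SystemModel) -> SSAssignment:
    """Kabsch-Sander assignment for one frame (codes H/G/I/E/B/T/S/-)."""
    n_res = model.n_residues
    n_chains = model.n_chains
    n_tot = n_chains * n_res
    coords = frame.coordinates
    bb = _backbone_indices(model)

    def chain_of(g: int) -> int:
        return g // n_res

    def same_chain(a: int, b: int) -> bool:
        return 0 <= a < n_tot and 0 <= b < n_tot and chain_of(a) == chain_of(b)

    for k, c in enumerate(model.chains):
        if n_res < 3:
            warnings.warn(f"chain {c} shorter than 3 residues; assigned all '-'")
            return SSAssignment(tuple("-" * n_tot), (), n_chains, n_res)

    # backbone positions; amide H reconstructed when absent
    N = np.full((n_tot, 3), np.nan)
    CA = np.full((n_tot, 3), np.nan)
    C = np.full((n_tot, 3), np.nan)
    O = np.full((n_tot, 3), np.nan)
    H = np.full((n_tot, 3), np.nan)
    has_donor = np.zeros(n_tot, dtype=bool)
    for g in range(n_tot):
        names = bb[g]
        for arr, nm in ((N, "N"), (CA, "CA"), (C, "C"), (O, "O")):
            if nm not in names:
                raise ValueError(f"residue {g}: backbone atom {nm} missing")
            arr[g] = coords[names[nm]]
    for g in range(n_tot):
        ridx = g % n_res
        if model.sequence[ridx] == "P":
            continue  # proline: no amide hydrogen
        if same_chain(g - 1, g):
            # Kabsch-Sander convention: H sits 1 A from N along the previous
            # C=O direction, regardless of any explicit hydrogen in the file
            co = C[g - 1] - O[g - 1]
            H[g] = N[g] + co / np.linalg.norm(co)
            has_donor[g] = True
        # first residue of a chain: no amide H, no donor

    # donates[d] = set of acceptors a with E(NH(d) -> CO(a)) < cutoff
    donates: list[set[int]] = [set() for _ in range(n_tot)]
    ca_dist = np.linalg.norm(CA[:, None, :] - CA[None, :, :], axis=-1)
    for d in range(n_tot):
        if not has_donor[d]:
            continue
        for a in range(n_tot):
            if a == d or ca_dist[d, a] > _CA_CUTOFF:
                continue
            if same_chain(a, d) and abs(a - d) == 1:
                continue  # peptide-bonded neighbours
            if _hbond_energy(N[d], H[d], C[a], O[a]) < _HBOND_CUTOFF:
                donates[d].add(a)

    def hbond(i: int, j: int) -> bool:
        """K&S Hbond(i, j): CO of residue i accepts from NH of residue j."""
        if not (0 <= i < n_tot and 0 <= j < n_tot):
            return False
        return i in donates[j]

    ss = ["-"] * n_tot

    # ---- beta bridges, ladders and sheets -------------------------------
    bridges: list[tuple[int, int, str]] = []
    for i in range(n_tot):
        if not (same_chain(i - 1, i) and same_chain(i, i + 1)):
            continue  # bridge partners must be interior residues of their chain
        for j in range(i + 1, n_tot):
            if not (same_chain(j - 1, j) and same_chain(j, j + 1)):
                continue
            if same_chain(i, j) and j - i < 3:
                continue
            par = (hbond(i - 1, j) and hbond(j, i + 1)) or (
                hbond(j - 1, i) and hbond(i, j + 1)
            )
            anti = (hbond(i, j) and hbond(j, i)) or (
                hbond(i - 1, j + 1) and hbond(j - 1, i + 1)
            )
            if par:
                bridges.append((i, j, "parallel"))
            elif anti:
                bridges.append((i, j, "antiparallel"))

    # group bridges into ladders (runs of consecutive bridges of one type)
    ladders: list[list[tuple[int, int, str]]] = []
    used = [False] * len(bridges)
    bridge_set = {(b[0], b[1], b[2]) for b in bridges}
    for bi, (i, j, typ) in enumerate(bridges):
        if used[bi]:
            continue
        run = [(i, j, typ)]
        used[bi] = True
        step = 1 if typ == "parallel" else -1
        ii, jj = i + 1, j + step
        while same_chain(ii - 1, ii) and same_chain(min(jj, jj - step), max(jj, jj - step)) and (
            (ii, jj, typ) in bridge_set or (jj, ii, typ) in bridge_set
        ):
            key = (ii, jj, typ) if (ii, jj, typ) in bridge_set else (jj, ii, typ)
            kidx = bridges.index(key)
            if used[kidx]:
                break
            run.append(key)
            used[kidx] = True
            ii, jj = ii + 1, jj + step
        ladders.append(run)

    # bulge linkage: two same-type ladders joined by a short gap share a sheet
    # (<=1 missing residue on one strand, <=4 on the other) and count as E
    def ladder_res(run):
        a = sorted({b[0] for b in run})
        b = sorted({b[1] for b in run})
        return a, b

    extended = [len(run) > 1 for run in ladders]
    for x in range(len(ladders)):
        for y in range(len(ladders)):
            if x == y or ladders[x][0][2] != ladders[y][0][2]:
                continue
            ax, bx = ladder_res(ladders[x])
            ay, by = ladder_res(ladders[y])
            # try linking strand-wise: x's first strand continues into y's first strand
            for (sx, sy, tx, ty) in ((ax, ay, bx, by), (ax, by, bx, ay)):
                if not (same_chain(sx[-1], sy[0]) and same_chain(tx[-1], ty[0])):
                    continue
                g1 = sy[0] - sx[-1] - 1
                g2 = min(abs(ty[0] - tx[-1]), abs(ty[-1] - tx[0])) - 1
                if 0 <= g1 and 0 <= g2 and ((g1 <= 1 and g2 <= 4) or (g1 <= 4 and g2 <= 1)):
                    extended[x] = extended[y] = True

    for run, ext in zip(ladders, extended):
        code = "E" if ext else "B"
        for (i, j, _) in run:
            for g in (i, j):
                if ss[g] == "-" or (code == "E" and ss[g] == "B"):
                    ss[g] = code

    # ---- helices --------------------------------------------------------
    # helix_start[stride][i] true when an n-turn starts at i (CO(i) <- NH(i+n))
    helix_start = {s: np.zeros(n_tot, dtype=bool) for s in (3, 4, 5)}
    for stride in (3, 4, 5):
        for i in range(n_tot):
            if same_chain(i, i + stride) and hbond(i, i + stride):
                helix_start[stride][i] = True

    for i in range(1, n_tot):
        if helix_start[4][i] and helix_start[4][i - 1] and same_chain(i - 1, i):
            for g in range(i, min(i + 4, n_tot)):
                ss[g] = "H"
    for stride, code in ((3, "G"), (5, "I")):
        for i in range(1, n_tot):
            if helix_start[stride][i] and helix_start[stride][i - 1] and same_chain(i - 1, i):
                span = range(i, min(i + stride, n_tot))
                if all(ss[g] in ("-", code, "T", "S") for g in span):
                    for g in span:
                        ss[g] = code

    # ---- turns ----------------------------------------------------------
    for g in range(n_tot):
        if ss[g] != "-":
            continue
        for stride in (3, 4, 5):
            for k in range(1, stride):
                if g - k >= 0 and same_chain(g - k, g) and helix_start[stride][g - k]:
                    ss[g] = "T"
                    break
            if ss[g] == "T":
                break

    # ---- bends ----------------------------------------------------------
    for g in range(n_tot):
        if ss[g] != "-":
            continue
        if same_chain(g - 2, g) and same_chain(g, g + 2):
            u = CA[g] - CA[g - 2]
            v = CA[g + 2] - CA[g]
            cosk = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            kappa = np.degrees(np.arccos(np.clip(cosk, -1, 1)))
            if kappa > 70.0:
                ss[g] = "S"

    return SSAssignment(tuple(ss), tuple(bridges), n_chains, n_res)


# ---------------------------------------------------------------------------
# category statistics
# ---------------------------------------------------------------------------

def collapse_categories(
    ss: SSAssignment, table: dict[str, str] = DEFAULT_CATEGORY_TABLE
) -> np.ndarray:
    """Map DSSP codes to the five reporting categories (array of category names)."""
    out = []
    for c in ss.codes:
        if c not in table:
            raise KeyError(f"code {c!r} missing from category table")
        out.append(table[c])
    return np.array(out)


def ss_statistics(
    traj: Trajectory,
    window: tuple[int | None, int | None] = (None, None),
    table: dict[str, str] = DEFAULT_CATEGORY_TABLE,
) -> tuple[dict[str, float], "pd.DataFrame"]:
    """Ensemble secondary-structure statistics over a frame window.

    Returns (overall category probabilities, per-residue profile DataFrame with
    one row per sequence position — 105-based labels — averaged over chains and
    frames).  Probabilities over the five categories sum to 1.
    """
    import pandas as pd

    sub = traj.window(*window)
    model = sub.model
    n_res = model.n_residues
    counts = np.zeros((n_res, len(CATEGORIES)))
    cat_idx = {c: k for k, c in enumerate(CATEGORIES)}
    for frame in sub.frames:
        cats = collapse_categories(assign_ss(frame, model), table)
        for g, cat in enumerate(cats):
            counts[g % n_res, cat_idx[cat]] += 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    profile = pd.DataFrame(
        probs, columns=list(CATEGORIES),
        index=[model.residue_label(r) for r in range(n_res)],
    )
    profile.index.name = "residue"
    overall = {c: float(probs[:, k].mean()) for c, k in cat_idx.items()}
    return overall, profile


def ss_timeline(
    traj: Trajectory, table: dict[str, str] = DEFAULT_CATEGORY_TABLE
) -> "pd.DataFrame":
    """Per-residue category raster: rows = frames, columns = chain:residue."""
    import pandas as pd

    model = traj.model
    cols = [
        f"{c}:{model.residue_label(r)}"
        for c in model.chains
        for r in range(model.n_residues)
    ]
    rows = []
    for frame in traj.frames:
        rows.append(collapse_categories(assign_ss(frame, model), table))
    df = pd.DataFrame(rows, columns=cols)
    df.index.name = "frame"
    return df
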