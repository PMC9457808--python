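"""The ten descriptors of the carbamate toxicity model.

Two electronic descriptors (EA, qC) are ingested as data; the other eight
are computed here from structure:

* ``LOC`` — lopping centric index: Shannon entropy (bits) of the partition
  of heavy atoms by the pruning round in which iterative removal of
  terminal vertices deletes them.
* ``SpPosA_RG`` — normalised positive spectral sum of the reciprocal
  squared geometry matrix.
* ``H4m`` — GETAWAY H autocorrelation of lag 4, mass-weighted: positive
  elements of the molecular influence matrix summed over atom pairs four
  bonds apart.
* ``nCt`` — number of tertiary sp3 carbons (three carbon neighbours, one H).
* ``nROCON`` — presence of an aliphatic substituent on the sp3 oxygen of
  the carbamate group C-O-C(=O)-N.
* ``B05[C-N]``, ``B05[N-O]`` — presence of an element pair at topological
  distance exactly five bonds.
* ``DLS_05`` — two-rule drug-like score from the heteroatom ratio nNO/nC3
  and the unsaturation ratio Unsat-p.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from qstrtox.config import Conventions
from qstrtox.molecule_io import CARBON_MASS, HALOGENS, HeavyGraph, Molecule, heavy_graph

logger = logging.getLogger(__name__)

#: model descriptor columns in canonical order
DESCRIPTOR_COLUMNS = [
    "EA", "qC", "LOC", "SpPosA_RG", "H4m",
    "nCt", "nROCON", "B05_CN", "B05_NO", "DLS_05",
]

_EIG_POSITIVE_RTOL = 1e-10   # eigenvalue counts as positive if > rtol * max|lambda|
_COINCIDENT_TOL = 1e-6       # Angstrom; closer atom pairs are a geometry error


@dataclass
class DescriptorRow:
    id: str
    EA: float
    qC: float
    LOC: float
    SpPosA_RG: Optional[float]
    H4m: Optional[float]
    nCt: int
    nROCON: int
    B05_CN: int
    B05_NO: int
    DLS_05: float

    def __post_init__(self) -> None:
        for name in ("nROCON", "B05_CN", "B05_NO"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{self.id}: {name} must be 0 or 1")
        if self.DLS_05 not in (0.0, 0.5, 1.0):
            raise ValueError(f"{self.id}: DLS_05 must be 0, 0.5 or 1")
        if self.nCt < 0:
            raise ValueError(f"{self.id}: nCt must be >= 0")
        for name in ("EA", "qC", "LOC"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{self.id}: {name} must be finite")


@dataclass
class UnsatBreakdown:
    """Unsaturation bookkeeping behind Unsat, Unsat-p and DLS_05."""

    nrg567: int      # 5-, 6-, 7-membered rings (smallest set of smallest rings)
    nDB: int         # double bonds (non-aromatic)
    nTB: int         # triple bonds
    nAB: int         # aromatic bonds
    unsat: float
    unsat_p: Optional[float]   # unsat / D; None when the denominator is 0
    nNO: int
    nC3: int


# ---------------------------------------------------------------------------
# atom-level helpers

def _is_sp3_carbon(mol: Molecule, i: int) -> bool:
    """Carbon with only single, non-aromatic bonds."""
    if mol.atoms[i].symbol != "C":
        return False
    return all(b.order == 1 and not b.aromatic for b in mol.bonds_of(i))


def nct(mol: Molecule) -> int:
    """Tertiary sp3 carbons: bonded to exactly three carbons and one hydrogen."""
    count = 0
    for i, atom in enumerate(mol.atoms):
        if not _is_sp3_carbon(mol, i):
            continue
        heavy_nb = [j for j in mol.neighbors(i) if mol.atoms[j].symbol != "H"]
        n_h = atom.n_h + sum(1 for j in mol.neighbors(i) if mol.atoms[j].symbol == "H")
        if n_h == 1 and len(heavy_nb) == 3 and all(
            mol.atoms[j].symbol == "C" for j in heavy_nb
        ):
            count += 1
    return count


def nrocon(mol: Molecule) -> int:
    """1 iff an aliphatic (non-aromatic) carbon is bonded to the sp3 oxygen
    of a carbamate fragment C-O-C(=O)-N; 0 otherwise (O-aryl carbamates,
    carbamic acids and non-carbamates score 0)."""
    for i, atom in enumerate(mol.atoms):
        if atom.symbol != "O" or mol.is_aromatic_atom(i):
            continue
        if any(b.order != 1 for b in mol.bonds_of(i)):
            continue  # not the sp3 ester oxygen
        nbrs = [j for j in mol.neighbors(i) if mol.atoms[j].symbol == "C"]
        carbonyl = [j for j in nbrs if _is_carbamoyl_carbon(mol, j)]
        substituents = [j for j in nbrs if j not in carbonyl]
        for c in carbonyl:
            for s in substituents:
                if not mol.is_aromatic_atom(s):
                    return 1
    return 0


def _is_carbamoyl_carbon(mol: Molecule, i: int) -> bool:
    """Carbon double-bonded to O and single-bonded to N: the C of O-C(=O)-N."""
    if mol.atoms[i].symbol != "C":
        return False
    has_carbonyl_o = any(
        b.order == 2 and not b.aromatic
        and mol.atoms[b.j if b.i == i else b.i].symbol == "O"
        for b in mol.bonds_of(i)
    )
    has_n = any(
        b.order == 1 and mol.atoms[b.j if b.i == i else b.i].symbol == "N"
        for b in mol.bonds_of(i)
    )
    return has_carbonyl_o and has_n


# ---------------------------------------------------------------------------
# topological descriptors

def loc_index(g: HeavyGraph) -> float:
    """Lopping centric index in bits.

    Terminal (degree-1) vertices are removed in simultaneous rounds; the
    class sizes of the removal rounds, plus the surviving core if any, form
    a partition of the heavy atoms whose Shannon entropy is returned.
    """
    if g.n == 0:
        raise ValueError("empty graph")
    if not g.is_connected():
        raise ValueError("loc_index requires a connected graph "
                         "(extract the largest fragment upstream)")
    adj = g.adjacency.copy()
    alive = np.ones(g.n, dtype=bool)
    classes: list[int] = []
    while True:
        deg = adj[alive][:, alive].sum(axis=1)
        alive_idx = np.flatnonzero(alive)
        if alive_idx.size == 0:
            break
        terminals = alive_idx[deg == 1]
        if terminals.size == 0:
            classes.append(int(alive_idx.size))  # surviving cycle core / center
            break
        classes.append(int(terminals.size))
        alive[terminals] = False
    a = float(g.n)
    return -sum((c / a) * math.log2(c / a) for c in classes)


def b05_pair(g: HeavyGraph, elem_a: str, elem_b: str) -> int:
    """1 iff some atom of element ``elem_a`` and some atom of ``elem_b``
    sit at shortest-path distance exactly 5 bonds."""
    ia = [k for k, e in enumerate(g.elements) if e == elem_a]
    ib = [k for k, e in enumerate(g.elements) if e == elem_b]
    if not ia or not ib:
        return 0
    sub = g.topo_dist[np.ix_(ia, ib)]
    return int(bool(np.any(sub == 5)))


def unsat_breakdown(mol: Molecule, conv: Conventions | None = None) -> UnsatBreakdown:
    """Ring/multiple-bond counts and the unsaturation indices.

    Unsat = NRG567 + nDB + 2*nTB + (nAB + 1)/2, with the aromatic term
    taken as 0 when nAB = 0 unless ``conv.unsat_literal`` (the literal
    formula gives every saturated molecule a spurious 0.5).
    Unsat-p divides by the number of heavy atoms that are not halogens and
    carry no hydrogens; None when that denominator is zero.
    """
    conv = conv or Conventions()
    nrg567 = sum(1 for ring in mol.rings if len(ring) in (5, 6, 7))
    nDB = sum(1 for b in mol.bonds if b.order == 2 and not b.aromatic)
    nTB = sum(1 for b in mol.bonds if b.order == 3)
    nAB = sum(1 for b in mol.bonds if b.aromatic)
    if nAB == 0 and not conv.unsat_literal:
        aromatic_term = 0.0
    else:
        aromatic_term = (nAB + 1) / 2.0
    unsat = nrg567 + nDB + 2 * nTB + aromatic_term

    d = sum(
        1 for a in mol.atoms
        if a.symbol != "H" and a.symbol not in HALOGENS and a.n_h == 0
    )
    unsat_p = unsat / d if d > 0 else None

    n_no = sum(1 for a in mol.atoms if a.symbol in ("N", "O"))
    n_c3 = sum(1 for i in range(mol.n_atoms) if _is_sp3_carbon(mol, i))
    return UnsatBreakdown(nrg567=nrg567, nDB=nDB, nTB=nTB, nAB=nAB,
                          unsat=unsat, unsat_p=unsat_p, nNO=n_no, nC3=n_c3)


def dls05(mol: Molecule, conv: Conventions | None = None) -> float:
    """Fifth drug-like score: fraction of two rules satisfied.

    Rule 1: heteroatom ratio nNO/nC3 in [0.10, 1.80] (inclusive).
    Rule 2: Unsat-p <= 0.43.
    A rule whose ratio is undefined (zero denominator) counts as failed.
    """
    ub = unsat_breakdown(mol, conv)
    rule1 = ub.nC3 > 0 and 0.10 <= ub.nNO / ub.nC3 <= 1.80
    rule2 = ub.unsat_p is not None and ub.unsat_p <= 0.43
    return (int(rule1) + int(rule2)) / 2.0


# ---------------------------------------------------------------------------
# geometric descriptors

def _atom_set(mol: Molecule, include_h: bool) -> list[int]:
    return list(range(mol.n_atoms)) if include_h else mol.heavy_indices()


def sp_pos_a_rg(mol: Molecule, conv: Conventions | None = None) -> float:
    """Normalised positive spectral sum of the reciprocal squared geometry
    matrix: sum of positive eigenvalues of G (G_ij = 1/r_ij^2, Angstrom^-2,
    zero diagonal) divided by the atom count of the chosen set."""
    conv = conv or Conventions()
    if mol.coords is None:
        raise ValueError(f"{mol.id}: SpPosA_RG requires 3D coordinates")
    idx = _atom_set(mol, conv.sppos_include_h)
    if len(idx) < 2:
        raise ValueError(f"{mol.id}: SpPosA_RG requires >= 2 atoms in the atom set")
    pts = mol.coords[idx]
    diff = pts[:, None, :] - pts[None, :, :]
    r2 = np.sum(diff * diff, axis=-1)
    n = len(idx)
    off = ~np.eye(n, dtype=bool)
    if np.any(r2[off] < _COINCIDENT_TOL**2):
        raise ValueError(f"{mol.id}: coincident atom positions in geometry matrix")
    g = np.zeros_like(r2)
    g[off] = 1.0 / r2[off]
    eig = np.linalg.eigvalsh(g)
    thresh = _EIG_POSITIVE_RTOL * np.max(np.abs(eig))
    return float(eig[eig > thresh].sum() / n)


def influence_matrix(coords: np.ndarray) -> np.ndarray:
    """Molecular influence matrix H = M (M^T M)^-1 M^T of centered coords.

    Uses the pseudo-inverse, so planar and linear geometries (rank-deficient
    M^T M) are handled; trace(H) = rank(M)."""
    m = np.asarray(coords, dtype=float)
    m = m - m.mean(axis=0)
    gram = m.T @ m
    if np.linalg.matrix_rank(gram) < 3:
        logger.info("influence_matrix: rank-deficient geometry (planar/linear); "
                    "using pseudo-inverse")
    return m @ np.linalg.pinv(gram) @ m.T


def h4m(mol: Molecule, conv: Conventions | None = None) -> float:
    """GETAWAY H autocorrelation of lag 4, weighted by carbon-scaled mass.

    Sum of H_ij * w_i * w_j over unordered atom pairs at topological
    distance 4 with positive influence-matrix element H_ij; weights are
    atomic mass / mass of carbon.  Atom set is heavy atoms by default
    (``conv.getaway_include_h`` adds hydrogens); topological distances are
    measured on the same atom set.  Returns 0 when no lag-4 pair exists.
    """
    conv = conv or Conventions()
    if mol.coords is None:
        raise ValueError(f"{mol.id}: H4m requires 3D coordinates")
    idx = _atom_set(mol, conv.getaway_include_h)
    if len(idx) <= 4:
        return 0.0
    g = heavy_graph(mol, include_h=conv.getaway_include_h)
    assert g.nodes == idx
    h = influence_matrix(mol.coords[idx])
    w = np.array([mol.atoms[a].mass for a in idx]) / CARBON_MASS
    total = 0.0
    n = len(idx)
    for i in range(n):
        for j in range(i + 1, n):
            if g.topo_dist[i, j] == 4 and h[i, j] > 0:
                total += h[i, j] * w[i] * w[j]
    return float(total)


# ---------------------------------------------------------------------------
# table assembly

def compute_descriptor_table(
    mols: Sequence[Molecule],
    electronic: pd.DataFrame,
    conv: Conventions | None = None,
) -> pd.DataFrame:
    """Assemble the full descriptor matrix, one row per molecule.

    ``electronic`` must be indexed (or carry an ``id`` column) covering
    every molecule id and provide columns ``EA`` and ``qC``.  Geometric
    descriptors of molecules without 3D coordinates are left as missing
    values (NaN), never silent zeros.
    """
    conv = conv or Conventions()
    elec = electronic.set_index("id") if "id" in electronic.columns else electronic
    for col in ("EA", "qC"):
        if col not in elec.columns:
            raise ValueError(f"electronic table missing required column {col!r}")
    missing = [m.id for m in mols if m.id not in elec.index]
    if missing:
        raise ValueError(f"electronic data missing for ids: {missing}")

    rows = []
    for mol in mols:
        g = heavy_graph(mol)
        row: dict = {"id": mol.id}
        row["EA"] = float(elec.loc[mol.id, "EA"])
        row["qC"] = float(elec.loc[mol.id, "qC"])
        row["LOC"] = loc_index(g)
        if mol.coords is not None:
            row["SpPosA_RG"] = sp_pos_a_rg(mol, conv)
            row["H4m"] = h4m(mol, conv)
        else:
            row["SpPosA_RG"] = np.nan
            row["H4m"] = np.nan
            logger.warning("%s: no 3D coordinates; SpPosA_RG and H4m flagged missing",
                           mol.id)
        row["nCt"] = nct(mol)
        row["nROCON"] = nrocon(mol)
        row["B05_CN"] = b05_pair(g, "C", "N")
        row["B05_NO"] = b05_pair(g, "N", "O")
        row["DLS_05"] = dls05(mol, conv)
        rows.append(row)
    return pd.DataFrame(rows, columns=["id"] + DESCRIPTOR_COLUMNS)


def write_descriptor_csv(table: pd.DataFrame, path) -> None:
    """Serialise a descriptor table with the canonical column order.

    Header: id,set,log_inv_c,EA,...,DLS_05 (set and log_inv_c included only
    when present); missing values are empty cells.
    """
    cols = ["id"]
    for opt in ("set", "log_inv_c"):
        if opt in table.columns:
            cols.append(opt)
    cols += DESCRIPTOR_COLUMNS
    table.to_csv(path, columns=cols, index=False)
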