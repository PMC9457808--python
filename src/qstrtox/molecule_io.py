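"""Structure input, hydrogen-depleted graphs, and the toxicity response.

Molecules arrive as SMILES (topology only) or SDF (with 3D coordinates from
an external geometry optimisation).  RDKit does the parsing, aromaticity and
ring perception; the result is frozen into a plain :class:`Molecule`
container so that every descriptor downstream is a pure function of the
stored atoms, bonds, rings and coordinates.

Acute oral toxicity enters as an LD50 in mg/kg and is converted to the
modeling response log(1/C), the negative decadic logarithm of the lethal
dose on the mmol/kg scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger(__name__)

CARBON_MASS = 12.011  # standard atomic weight of C, u
HALOGENS = frozenset({"F", "Cl", "Br", "I", "At"})


@dataclass(frozen=True)
class Atom:
    symbol: str
    mass: float           # standard atomic weight, u
    formal_charge: int
    n_h: int              # total attached hydrogens (implicit + explicit)


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: int            # 1, 2 or 3; aromatic bonds carry order 1
    aromatic: bool


@dataclass
class Molecule:
    """Plain container for a parsed structure.

    ``rings`` holds the smallest set of smallest rings as tuples of atom
    indices; ``coords`` (n_atoms x 3, Angstrom) is present only for
    structures read with 3D geometry.
    """

    id: str
    atoms: list[Atom]
    bonds: list[Bond]
    coords: Optional[np.ndarray] = None
    rings: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise ValueError(f"{self.id}: bond ({b.i},{b.j}) has invalid endpoints")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"{self.id}: duplicate bond {key}")
            seen.add(key)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 3):
                raise ValueError(f"{self.id}: coords shape {self.coords.shape} != ({n}, 3)")
            if not np.all(np.isfinite(self.coords)):
                raise ValueError(f"{self.id}: non-finite coordinates")
            if n >= 2 and np.allclose(self.coords, self.coords[0]):
                raise ValueError(f"{self.id}: all atom positions identical")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.symbol != "H"]

    def neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == i:
                out.append(b.j)
            elif b.j == i:
                out.append(b.i)
        return out

    def bonds_of(self, i: int) -> list[Bond]:
        return [b for b in self.bonds if i in (b.i, b.j)]

    def is_aromatic_atom(self, i: int) -> bool:
        return any(b.aromatic for b in self.bonds_of(i))


@dataclass
class HeavyGraph:
    """Hydrogen-depleted molecular graph with all-pairs bond distances.

    ``topo_dist[i][j]`` is the shortest-path bond count between heavy atoms
    (``inf`` for disconnected pairs); indices refer to positions in
    ``nodes``, which map back to atom indices of the source Molecule.
    """

    nodes: list[int]
    elements: list[str]
    adjacency: np.ndarray   # boolean, symmetric
    topo_dist: np.ndarray   # float, inf for unreachable

    @property
    def n(self) -> int:
        return len(self.nodes)

    def is_connected(self) -> bool:
        return bool(np.all(np.isfinite(self.topo_dist)))

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


@dataclass
class ToxicityRecord:
    """Compound toxicity: LD50 (mg/kg), molecular weight (g/mol), log(1/C)."""

    id: str
    ld50: Optional[float] = None
    mw: Optional[float] = None
    log_inv_c: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ld50 is not None and self.ld50 <= 0:
            raise ValueError(f"{self.id}: ld50 must be > 0")
        if self.mw is not None and self.mw <= 0:
            raise ValueError(f"{self.id}: mw must be > 0")
        if self.ld50 is not None and self.mw is not None:
            expected = log_inv_c(self.ld50, self.mw)
            if self.log_inv_c is None:
                self.log_inv_c = expected
            elif abs(self.log_inv_c - expected) > 1e-9:
                raise ValueError(
                    f"{self.id}: log_inv_c {self.log_inv_c} inconsistent with "
                    f"-log10(ld50/mw) = {expected}"
                )


def log_inv_c(ld50: float, mw: float) -> float:
    """log(1/C) response from LD50 in mg/kg and molecular weight in g/mol.

    ld50[mg/kg] / mw[g/mol] is numerically the molar dose C in mmol/kg, so
    the response is -log10(ld50/mw).  Larger values mean higher toxicity.
    """
    if ld50 <= 0 or mw <= 0:
        raise ValueError(f"ld50 and mw must be positive, got ld50={ld50}, mw={mw}")
    return -math.log10(ld50 / mw)


def _from_rdkit(rdmol: Chem.Mol, mol_id: str, take_coords: bool) -> Molecule:
    atoms = [
        Atom(
            symbol=a.GetSymbol(),
            mass=a.GetMass(),
            formal_charge=a.GetFormalCharge(),
            n_h=a.GetTotalNumHs(),
        )
        for a in rdmol.GetAtoms()
    ]
    order_map = {
        Chem.BondType.SINGLE: 1,
        Chem.BondType.DOUBLE: 2,
        Chem.BondType.TRIPLE: 3,
        Chem.BondType.AROMATIC: 1,
    }
    bonds = []
    for b in rdmol.GetBonds():
        bt = b.GetBondType()
        if bt not in order_map:
            raise ValueError(f"{mol_id}: unsupported bond type {bt}")
        bonds.append(
            Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order_map[bt], b.GetIsAromatic())
        )
    rings = [tuple(r) for r in rdmol.GetRingInfo().AtomRings()]
    coords = None
    if take_coords and rdmol.GetNumConformers() > 0:
        coords = np.array(rdmol.GetConformer().GetPositions(), dtype=float)
    return Molecule(id=mol_id, atoms=atoms, bonds=bonds, coords=coords, rings=rings)


def _largest_fragment(rdmol: Chem.Mol, mol_id: str) -> Chem.Mol:
    frags = Chem.GetMolFrags(rdmol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return rdmol
    logger.warning(
        "%s: %d disconnected fragments; keeping the largest heavy-atom fragment",
        mol_id, len(frags),
    )
    return max(frags, key=lambda m: m.GetNumHeavyAtoms())


def parse_smiles(smiles: str, mol_id: str | None = None,
                 largest_fragment: bool = True) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule` (no 3D coordinates).

    Aromaticity and rings are perceived with RDKit's default model.  For
    multi-fragment inputs (salts) only the largest heavy-atom fragment is
    kept unless ``largest_fragment=False``.
    """
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ValueError(f"malformed SMILES: {smiles!r}")
    if largest_fragment:
        rdmol = _largest_fragment(rdmol, mol_id or smiles)
    return _from_rdkit(rdmol, mol_id or smiles, take_coords=False)


def read_smiles_file(path: str | Path, largest_fragment: bool = True) -> list[Molecule]:
    """Read a SMILES list file: one molecule per line, optional tab-separated id."""
    mols = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smiles = parts[0].strip()
        mol_id = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"line{lineno}"
        mols.append(parse_smiles(smiles, mol_id, largest_fragment=largest_fragment))
    return mols


def read_sdf(path: str | Path, largest_fragment: bool = True) -> list[Molecule]:
    """Read an SDF file, keeping 3D coordinates from the atom block.

    Records that fail to parse are logged and skipped; records whose
    coordinates are all identical (2D placeholders) are kept with
    ``coords=None`` and flagged.  Raises if the file is unreadable or
    yields zero parseable records.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read SDF: {path}")
    try:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    except OSError as exc:
        raise ValueError(f"{path}: no parseable SDF records ({exc})") from exc
    mols: list[Molecule] = []
    n_failed = 0
    for idx, rdmol in enumerate(supplier):
        if rdmol is None:
            n_failed += 1
            logger.warning("%s: record %d failed to parse; skipped", path, idx)
            continue
        mol_id = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") and rdmol.GetProp("_Name") else f"record{idx}"
        if largest_fragment:
            rdmol = _largest_fragment(rdmol, mol_id)
        coords_ok = True
        if rdmol.GetNumConformers() > 0 and rdmol.GetNumAtoms() >= 2:
            pos = np.array(rdmol.GetConformer().GetPositions())
            if np.allclose(pos, pos[0]):
                coords_ok = False
                logger.warning("%s: record %d (%s): no 3D geometry (all positions identical)",
                               path, idx, mol_id)
        mols.append(_from_rdkit(rdmol, mol_id, take_coords=coords_ok))
    if n_failed:
        logger.info("%s: skipped %d unparseable records", path, n_failed)
    if not mols:
        raise ValueError(f"{path}: no parseable SDF records")
    return mols


def to_rdkit(mol: Molecule) -> Chem.Mol:
    """Rebuild an RDKit molecule (used for SDF writing and round-trips)."""
    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.symbol)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNumExplicitHs(a.n_h)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    type_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    for b in mol.bonds:
        bt = Chem.BondType.AROMATIC if b.aromatic else type_map[b.order]
        rw.AddBond(b.i, b.j, bt)
        if b.aromatic:
            rw.GetAtomWithIdx(b.i).SetIsAromatic(True)
            rw.GetAtomWithIdx(b.j).SetIsAromatic(True)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    out.SetProp("_Name", mol.id)
    if mol.coords is not None:
        conf = Chem.Conformer(out.GetNumAtoms())
        for i, xyz in enumerate(mol.coords):
            conf.SetAtomPosition(i, [float(x) for x in xyz])
        out.AddConformer(conf)
    return out


def write_sdf(mols: Sequence[Molecule], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    for mol in mols:
        rdmol = to_rdkit(mol)
        if rdmol.GetNumConformers() == 0:
            conf = Chem.Conformer(rdmol.GetNumAtoms())
            rdmol.AddConformer(conf)
        writer.write(rdmol)
    writer.close()


def heavy_graph(mol: Molecule, include_h: bool = False) -> HeavyGraph:
    """Build the (by default hydrogen-depleted) graph with BFS bond distances."""
    if include_h:
        nodes = list(range(mol.n_atoms))
    else:
        nodes = mol.heavy_indices()
    if not nodes:
        raise ValueError(f"{mol.id}: no heavy atoms")
    pos = {a: k for k, a in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for b in mol.bonds:
        if b.i in pos and b.j in pos:
            adj[pos[b.i], pos[b.j]] = True
            adj[pos[b.j], pos[b.i]] = True
    dist = shortest_path(adj.astype(np.int8), method="D", unweighted=True, directed=False)
    return HeavyGraph(
        nodes=nodes,
        elements=[mol.atoms[a].symbol for a in nodes],
        adjacency=adj,
        topo_dist=dist,
    )


def permute_atoms(mol: Molecule, perm: Sequence[int]) -> Molecule:
    """Relabel atoms by ``perm`` (new index = perm[old index]); for invariance tests."""
    perm = list(perm)
    if sorted(perm) != list(range(mol.n_atoms)):
        raise ValueError("perm must be a permutation of atom indices")
    new_atoms: list[Atom] = [None] * mol.n_atoms  # type: ignore[list-item]
    for old, new in enumerate(perm):
        new_atoms[new] = mol.atoms[old]
    new_bonds = [Bond(perm[b.i], perm[b.j], b.order, b.aromatic) for b in mol.bonds]
    new_coords = None
    if mol.coords is not None:
        new_coords = np.empty_like(mol.coords)
        for old, new in enumerate(perm):
            new_coords[new] = mol.coords[old]
    new_rings = [tuple(perm[a] for a in ring) for ring in mol.rings]
    return Molecule(id=mol.id, atoms=new_atoms, bonds=new_bonds,
                    coords=new_coords, rings=new_rings)
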