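"""Pharmacophore points and fragment centres from bound ligand poses.

Each ligand pose is abstracted into typed 3-D pharmacophore points using
SMARTS rules in the style of the standard RDKit feature definitions, plus two
medicinal-chemistry extensions: halogens and ring methyls.  A "Hydrophobe" is
a singly substituted non-polar carbon.  Aromatic points sit at the ring
centroid; all other kinds sit on the matched atom.

Fragments are generated by cutting acyclic single bonds between heavy atoms
(single cuts, plus double-cut core fragments), matched-molecular-pair style;
each fragment is summarised by the unweighted centroid of its atoms in the
bound pose, so fragments can be clustered in space alongside waters and
pharmacophores.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from rdkit import Chem

from .io_model import LigandPose

#: The closed set of pharmacophore kinds.
KINDS = ("Donor", "Acceptor", "Aromatic", "Hydrophobe", "Halogen", "RingMethyl")

# Atom-centred SMARTS rules.  Donor/Acceptor mirror the standard RDKit
# BaseFeatures definitions; Halogen and RingMethyl are the medicinal-chemistry
# extensions; Hydrophobe is additionally restricted (below) to carbons with
# exactly one heavy neighbour, i.e. singly substituted non-polar carbons.
_SMARTS = {
    "Donor": "[$([N;!H0;v3,v4&+1]),$([O,S;H1;+0]),n&H1&+0]",
    "Acceptor": (
        "[$([O,S;H1;v2;!$(*-*=[O,N,P,S])]),$([O,S;H0;v2]),$([O,S;-]),"
        "$([N;v3;!$(N-*=[O,N,P,S])]),n&H0&+0,"
        "$([o,s;+0;!$([o,s]:n);!$([o,s]:c:n)])]"
    ),
    "Halogen": "[F,Cl,Br,I]",
    "RingMethyl": "[CH3;!$(C=*)]-[R]",
    "Hydrophobe": "[CX4H3,CX4H2;$([#6]~[#6])]",
}
_PATTERNS = {kind: Chem.MolFromSmarts(s) for kind, s in _SMARTS.items()}


class FeaturisationError(ValueError):
    pass


@dataclass
class PharmacophorePoint:
    kind: str
    position: np.ndarray
    source_model: str
    source_atoms: tuple[int, ...]


@dataclass
class FragmentPose:
    atom_indices: tuple[int, ...]
    n_attachment_points: int
    position: np.ndarray
    source_model: str


def detect_pharmacophores(ligand: LigandPose) -> list[PharmacophorePoint]:
    """Typed 3-D pharmacophore points for one bound ligand.

    Matches are de-duplicated within a kind by source-atom set; an atom may
    carry points of several kinds (a ring methyl is also a hydrophobe).
    """
    mol = ligand.rdkit_mol
    if mol is None:
        raise FeaturisationError(
            f"ligand of model {ligand.model_id!r} has no assigned chemistry"
        )
    coords = ligand.coords()
    points: list[PharmacophorePoint] = []

    for kind in ("Donor", "Acceptor", "Halogen"):
        for atom_set in _atom_matches(mol, kind):
            points.append(_point(kind, atom_set, coords, ligand.model_id))

    # RingMethyl: the match covers (methyl C, ring atom); the point sits on
    # the methyl carbon.
    seen: set[tuple[int, ...]] = set()
    for match in mol.GetSubstructMatches(_PATTERNS["RingMethyl"]):
        atom_set = (match[0],)
        if atom_set not in seen:
            seen.add(atom_set)
            points.append(_point("RingMethyl", atom_set, coords, ligand.model_id))

    # Hydrophobe: singly substituted non-polar carbon.
    seen = set()
    for match in mol.GetSubstructMatches(_PATTERNS["Hydrophobe"]):
        idx = match[0]
        atom = mol.GetAtomWithIdx(idx)
        heavy_neighbours = sum(
            1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1
        )
        if heavy_neighbours == 1 and (idx,) not in seen:
            seen.add((idx,))
            points.append(_point("Hydrophobe", (idx,), coords, ligand.model_id))

    # Aromatic: one point per aromatic SSSR ring, at the ring centroid.
    ring_info = mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            points.append(
                _point("Aromatic", tuple(sorted(ring)), coords, ligand.model_id)
            )
    return points


def _atom_matches(mol: Chem.Mol, kind: str) -> list[tuple[int, ...]]:
    matches = mol.GetSubstructMatches(_PATTERNS[kind])
    out, seen = [], set()
    for match in matches:
        atom_set = tuple(sorted(match))
        if atom_set not in seen:
            seen.add(atom_set)
            out.append(atom_set)
    return out


def _point(kind, atom_set, coords, model_id) -> PharmacophorePoint:
    return PharmacophorePoint(
        kind=kind,
        position=coords[list(atom_set)].mean(axis=0),
        source_model=model_id,
        source_atoms=tuple(atom_set),
    )


def _cuttable_bonds(mol: Chem.Mol) -> list[tuple[int, int]]:
    """Acyclic single bonds between heavy atoms.

    A bond is skipped only when both resulting sides would be single atoms
    (the two-atom molecule), where cutting is vacuous.
    """
    bonds = []
    for bond in mol.GetBonds():
        if bond.IsInRing():
            continue
        if bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        if mol.GetNumAtoms() == 2:
            continue
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
    return bonds


def _components(n_atoms: int, bonds: list[tuple[int, int]], cut: set[tuple[int, int]]):
    adj: list[list[int]] = [[] for _ in range(n_atoms)]
    for i, j in bonds:
        if (i, j) in cut or (j, i) in cut:
            continue
        adj[i].append(j)
        adj[j].append(i)
    seen = [False] * n_atoms
    comps = []
    for start in range(n_atoms):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(sorted(comp))
    return comps


def fragment_ligand(ligand: LigandPose) -> list[FragmentPose]:
    """Single- and double-cut fragments of a bound ligand.

    Every acyclic single bond is cut once, emitting both sides; every
    unordered pair of such bonds is cut simultaneously, emitting the core
    fragment carrying both attachment points.  A ligand with no cuttable bond
    yields a single fragment covering the whole molecule.  Fragments are
    de-duplicated by atom set and attachment count.
    """
    mol = ligand.rdkit_mol
    if mol is None:
        raise FeaturisationError(
            f"ligand of model {ligand.model_id!r} has no assigned chemistry"
        )
    coords = ligand.coords()
    n = mol.GetNumAtoms()
    all_bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
    ]
    cuttable = _cuttable_bonds(mol)

    def pose(atom_idx: list[int], n_attach: int) -> FragmentPose:
        return FragmentPose(
            atom_indices=tuple(atom_idx),
            n_attachment_points=n_attach,
            position=coords[atom_idx].mean(axis=0),
            source_model=ligand.model_id,
        )

    if not cuttable:
        return [pose(list(range(n)), 0)]

    fragments: list[FragmentPose] = []
    seen: set[tuple[tuple[int, ...], int]] = set()

    def emit(atom_idx: list[int], n_attach: int) -> None:
        key = (tuple(atom_idx), n_attach)
        if key not in seen:
            seen.add(key)
            fragments.append(pose(atom_idx, n_attach))

    for cut_bond in cuttable:
        for comp in _components(n, all_bonds, {cut_bond}):
            emit(comp, 1)

    if len(cuttable) >= 2:
        for b1, b2 in combinations(cuttable, 2):
            comps = _components(n, all_bonds, {b1, b2})
            for comp in comps:
                members = set(comp)
                n_attach = sum(
                    1 for cut in (b1, b2)
                    if (cut[0] in members) != (cut[1] in members)
                    and (cut[0] in members or cut[1] in members)
                )
                if n_attach == 2:  # the core between the two cuts
                    emit(comp, 2)
    return fragments
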