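"""Manifest and PDB parsing into the ensemble data model.

An ensemble is described by one CSV manifest: the header row names the
columns, and every subsequent row is one ligand-bound protein chain.  Required
columns are ``pdb_path`` and ``smiles`` (the ligand's SMILES with tautomer and
charge state already assigned); ``compound_id``, ``model_id`` and ``chain``
are recognised when present and all remaining columns are carried through
untouched.  The referenced PDB files must be pre-superposed onto a common
template chain with consistent residue numbering — no alignment is performed
here.

Parsing a row produces a :class:`StructureModel`: the chain's protein residues
(heavy atoms only), its water oxygen positions, and exactly one ligand pose
whose bond orders, charges and aromaticity are transferred from the template
SMILES onto the crystallographic coordinates.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

#: Residue names treated as water; only the oxygen position is used.
WATER_RESIDUE_NAMES = {"HOH", "WAT", "DOD"}

#: Elements dropped everywhere (deuterium is treated as hydrogen).
_HYDROGEN_ELEMENTS = {"H", "D"}

#: Tolerance added to the sum of covalent radii when inferring ligand
#: connectivity from interatomic distances (PDB files may lack CONECT).
COVALENT_TOLERANCE = 0.45


class ManifestError(ValueError):
    """Malformed or incomplete CSV manifest."""


class StructureError(ValueError):
    """A PDB file could not be interpreted as one ligand-bound chain."""


class LigandMatchingError(StructureError):
    """No (or no unambiguous) hetero group matches the template SMILES."""


@dataclass
class InputRecord:
    """One manifest row: a ligand-bound protein chain."""

    pdb_path: str
    ligand_smiles: str
    compound_id: str | None = None
    model_id: str | None = None
    chain: str | None = None
    extra: dict[str, str] = field(default_factory=dict)


@dataclass
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def is_heavy(self) -> bool:
        return self.element not in _HYDROGEN_ELEMENTS


@dataclass
class ResidueConformation:
    """Heavy atoms of one residue in one model.

    ``identity`` is ``(chain_id, residue_number, insertion_code, residue_name)``
    and is shared across models thanks to the consistent-numbering input
    requirement.
    """

    identity: tuple[str, int, str, str]
    atoms: list[AtomRecord]
    model_id: str


@dataclass
class WaterSite:
    position: np.ndarray
    model_id: str


@dataclass
class LigandPose:
    """A crystallographic ligand with chemistry from its template SMILES."""

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int, float]]
    smiles: str
    centroid: np.ndarray
    model_id: str
    compound_id: str | None = None
    rdkit_mol: Chem.Mol | None = None

    def coords(self) -> np.ndarray:
        return np.asarray([a.coords for a in self.atoms], dtype=float)


@dataclass
class StructureModel:
    """One ligand-bound protein chain: the unit of conservation counting."""

    model_id: str
    chain_id: str
    residues: list[ResidueConformation]
    waters: list[WaterSite]
    ligand: LigandPose


def parse_input_csv(path: str | Path) -> list[InputRecord]:
    """Read the manifest into :class:`InputRecord` rows, in file order.

    Missing ``model_id`` values default deterministically to
    ``m<row index>_<pdb file stem>``.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        fields = [f.strip() for f in reader.fieldnames]
        for required in ("pdb_path", "smiles"):
            if required not in fields:
                raise ManifestError(
                    f"manifest {path} is missing required column '{required}'"
                )
        records = []
        for i, row in enumerate(reader):
            row = {(k or "").strip(): (v or "").strip() for k, v in row.items()}
            pdb_path = row.pop("pdb_path", "")
            smiles = row.pop("smiles", "")
            if not pdb_path:
                raise ManifestError(f"row {i + 1}: empty pdb_path")
            mol = Chem.MolFromSmiles(smiles) if smiles else None
            if mol is None or mol.GetNumHeavyAtoms() < 1:
                raise ManifestError(
                    f"row {i + 1}: SMILES {smiles!r} does not parse to a "
                    "molecule with at least one heavy atom"
                )
            compound_id = row.pop("compound_id", "") or None
            model_id = row.pop("model_id", "") or f"m{i}_{Path(pdb_path).stem}"
            chain = row.pop("chain", "") or None
            records.append(
                InputRecord(
                    pdb_path=pdb_path,
                    ligand_smiles=smiles,
                    compound_id=compound_id,
                    model_id=model_id,
                    chain=chain,
                    extra=row,
                )
            )
    return records


def select_altloc(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Resolve alternate locations within one residue.

    For each atom name with several altlocs the highest-occupancy record is
    kept; occupancy ties break toward the lexicographically smallest altloc
    character.  Atom names are unique in the result.
    """
    best: dict[str, AtomRecord] = {}
    order: list[str] = []
    for atom in atoms:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            order.append(atom.name)
        elif (atom.occupancy, _altloc_rank(atom.altloc)) > (
            prev.occupancy,
            _altloc_rank(prev.altloc),
        ):
            best[atom.name] = atom
    return [best[name] for name in order]


def _altloc_rank(altloc: str) -> float:
    # higher rank = preferred on occupancy ties; blank beats any letter,
    # otherwise lexicographically smallest wins
    return -ord(altloc) if altloc else 1.0


def _smiles_composition(smiles: str) -> Counter:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ManifestError(f"SMILES {smiles!r} does not parse")
    return Counter(a.GetSymbol() for a in mol.GetAtoms())


def load_structure(record: InputRecord, base_dir: str | Path | None = None) -> StructureModel:
    """Parse one PDB file into a :class:`StructureModel`.

    Protein residues come from the stated chain (hydrogens dropped, altlocs
    resolved by :func:`select_altloc` first), waters from HETATM residues
    named HOH/WAT/DOD, and the ligand is the hetero group whose heavy-atom
    element multiset matches the template SMILES.  When no ``chain`` is given,
    the first chain containing a matching hetero group is used.
    """
    pdb_path = Path(record.pdb_path)
    if base_dir is not None and not pdb_path.is_absolute():
        pdb_path = Path(base_dir) / pdb_path
    if not pdb_path.exists():
        raise StructureError(f"PDB file not found: {pdb_path}")
    structure = gemmi.read_structure(str(pdb_path))
    if len(structure) == 0:
        raise StructureError(f"{pdb_path}: no models in file")
    model = structure[0]

    template_comp = _smiles_composition(record.ligand_smiles)

    chains = []
    if record.chain is not None:
        chain = model.find_chain(record.chain)
        if chain is None:
            raise StructureError(
                f"{pdb_path}: chain {record.chain!r} absent from structure"
            )
        chains = [chain]
    else:
        chains = list(model)

    chosen = None
    all_candidates: list[str] = []
    for chain in chains:
        residues, waters, hetero = _partition_chain(chain, record.model_id)
        matches = [
            (res_id, atoms)
            for res_id, atoms in hetero
            if Counter(a.element for a in atoms) == template_comp
        ]
        all_candidates.extend(f"{chain.name}/{rid}" for rid, _ in hetero)
        if matches and chosen is None:
            if len(matches) > 1:
                raise LigandMatchingError(
                    f"{pdb_path}: chain {chain.name} contains "
                    f"{len(matches)} hetero groups matching the ligand "
                    f"composition ({', '.join(m[0] for m in matches)}); "
                    "one ligand per row is required"
                )
            chosen = (chain.name, residues, waters, matches[0][1])
            if record.chain is not None:
                break
    if chosen is None:
        raise LigandMatchingError(
            f"{pdb_path}: no hetero group matches the SMILES composition "
            f"{dict(template_comp)}; candidates: {all_candidates or 'none'}"
        )
    chain_id, residues, waters, ligand_atoms = chosen
    ligand = assign_bond_orders(ligand_atoms, record.ligand_smiles)
    ligand.model_id = record.model_id or ""
    ligand.compound_id = record.compound_id
    return StructureModel(
        model_id=record.model_id or "",
        chain_id=chain_id,
        residues=residues,
        waters=waters,
        ligand=ligand,
    )


def _partition_chain(chain: gemmi.Chain, model_id: str | None):
    """Split a chain into (protein residues, waters, hetero candidate groups)."""
    residues: list[ResidueConformation] = []
    waters: list[WaterSite] = []
    hetero: list[tuple[str, list[AtomRecord]]] = []
    for res in chain:
        atoms = select_altloc(
            [
                AtomRecord(
                    name=atom.name,
                    element=atom.element.name,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=atom.occ,
                    altloc=atom.altloc if atom.altloc != "\x00" else "",
                )
                for atom in res
            ]
        )
        heavy = [a for a in atoms if a.is_heavy]
        if res.name in WATER_RESIDUE_NAMES:
            for atom in heavy:
                if atom.element == "O":
                    waters.append(
                        WaterSite(position=atom.coords, model_id=model_id or "")
                    )
        elif res.het_flag == "H":
            hetero.append((f"{res.name} {res.seqid.num}", heavy))
        else:
            if heavy:
                residues.append(
                    ResidueConformation(
                        identity=(
                            chain.name,
                            res.seqid.num,
                            res.seqid.icode.strip() or "",
                            res.name,
                        ),
                        atoms=heavy,
                        model_id=model_id or "",
                    )
                )
    return residues, waters, hetero


def _infer_bonds(atoms: list[AtomRecord]) -> list[tuple[int, int]]:
    """Connectivity from interatomic distances with covalent-radius tolerance."""
    bonds = []
    radii = [gemmi.Element(a.element).covalent_r for a in atoms]
    coords = np.asarray([a.coords for a in atoms])
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            cutoff = radii[i] + radii[j] + COVALENT_TOLERANCE
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                bonds.append((i, j))
    return bonds


def assign_bond_orders(
    ligand_atoms: list[AtomRecord], smiles: str
) -> LigandPose:
    """Transfer template chemistry onto crystallographic heavy atoms.

    Connectivity of the PDB atoms is inferred from distances, matched as a
    graph against the single-bond skeleton of the template SMILES, and bond
    orders, formal charges and aromaticity are copied over.  Coordinates are
    preserved bit-exactly.
    """
    template = Chem.MolFromSmiles(smiles)
    if template is None:
        raise ManifestError(f"SMILES {smiles!r} does not parse")
    heavy = [a for a in ligand_atoms if a.is_heavy]
    comp = Counter(a.element for a in heavy)
    template_comp = Counter(a.GetSymbol() for a in template.GetAtoms())
    if comp != template_comp:
        raise LigandMatchingError(
            f"element multiset mismatch: PDB {dict(comp)} vs "
            f"template {dict(template_comp)}"
        )

    rw = Chem.RWMol()
    for atom in heavy:
        a = Chem.Atom(atom.element)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for i, j in _infer_bonds(heavy):
        rw.AddBond(i, j, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, atom in enumerate(heavy):
        conf.SetAtomPosition(i, [float(x) for x in atom.coords])
    mol.AddConformer(conf)
    try:
        mol = AllChem.AssignBondOrdersFromTemplate(template, mol)
    except ValueError as exc:
        raise LigandMatchingError(
            "no graph isomorphism between distance-inferred PDB connectivity "
            f"and template {smiles!r}: {exc}"
        ) from exc
    # the crystallographic atoms carry no hydrogens; once the template
    # chemistry is in place, let RDKit restore implicit H counts so that
    # H-dependent SMARTS (donors, methyls) match
    for atom in mol.GetAtoms():
        atom.SetNoImplicit(False)
        atom.SetNumRadicalElectrons(0)
    mol.UpdatePropertyCache()
    Chem.SanitizeMol(mol)

    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in mol.GetBonds()
    ]
    coords = np.asarray([a.coords for a in heavy], dtype=float)
    return LigandPose(
        atoms=heavy,
        bonds=bonds,
        smiles=Chem.MolToSmiles(template),
        centroid=coords.mean(axis=0),
        model_id="",
        compound_id=None,
        rdkit_mol=mol,
    )


def write_model_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel back out as a minimal PDB v3.3 file."""
    lines = []
    serial = 1

    def fmt(record, name, resname, chain, resseq, coords, element):
        nonlocal serial
        # PDB columns: name left-padded for 4-char names, else 1 leading space
        atom_name = name if len(name) == 4 else f" {name:<3s}"
        line = (
            f"{record:<6s}{serial:5d} {atom_name:<4s}{'':1s}{resname:<3s} "
            f"{chain:1s}{resseq:4d}{'':1s}   "
            f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
        )
        serial += 1
        return line

    for res in model.residues:
        chain, num, _icode, name = res.identity
        for atom in res.atoms:
            lines.append(fmt("ATOM", atom.name, name, chain, num, atom.coords, atom.element))
    water_seq = 900
    for water in model.waters:
        lines.append(fmt("HETATM", "O", "HOH", model.chain_id, water_seq, water.position, "O"))
        water_seq += 1
    for atom in model.ligand.atoms:
        lines.append(fmt("HETATM", atom.name, "LIG", model.chain_id, 800, atom.coords, atom.element))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
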