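"""Seeded synthetic ensembles with machine-readable planted ground truth.

The generator emits exactly what the loader consumes — a CSV manifest plus
pre-aligned PDB files — for an idealised protein pocket, so that every stage
of the analysis can be exercised without external crystal structures.  All
models share a rigid scaffold (alignment is exact by construction) and carry:

* planted water sites, each occupied in a conservation-fraction-sized subset
  of models with small Gaussian positional jitter, plus far-away decoy waters;
* one bi-rotameric tyrosine whose side chain flips between two conformations
  according to a per-model state assignment;
* one ligand per model, built by embedding a template SMILES once per
  chemotype and rigidly placing the benzene ring of the conformer at the
  pocket anchor (translation-only per-model jitter).

The generator is deterministic given the seed, and the geometry is chosen so
that under the default distance parameters the analysis recovers the planted
truth exactly: planted sites are separated by more than 3 A, jitter is
clipped well below the water clustering distance, decoys stay at least twice
that distance from planted sites, and the rotamer flip moves the side chain
far beyond the residue clustering distance.

The planted truth is serialised alongside the manifest as ``truth.json``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .ensemble_summary import LAMBDA_LIGAND, LAMBDA_WATER

#: Jitter applied to planted waters is clipped at this multiple of sigma so
#: that cluster recovery is guaranteed, not merely probable.
_JITTER_CLIP_SIGMAS = 2.0

#: Pharmacophore kinds presented by each built-in chemotype (derived from the
#: SMARTS rules in :mod:`plens.features`).
CHEMOTYPE_KINDS = {
    "Oc1ccccc1": ("Donor", "Acceptor", "Aromatic"),
    "Cc1ccc(Cl)cc1": ("Aromatic", "Hydrophobe", "Halogen", "RingMethyl"),
}


#: Embedding seed for chemotype k is this base plus k.
_CHEMOTYPE_SEED_BASE = 1000


class SpecError(ValueError):
    """Infeasible ensemble specification; nothing was written."""


@dataclass
class WaterSiteSpec:
    position: np.ndarray
    conservation: float
    jitter_sigma: float = 0.3
    required_contributors: tuple[int, ...] = ()
    required_absentees: tuple[int, ...] = ()


@dataclass
class EnsembleSpec:
    """Parameters of a synthetic pre-aligned ensemble."""

    n_models: int
    water_sites: list[WaterSiteSpec]
    rotamer_states: list[int]          # per model: 0 or 1
    chemotypes: list[str]              # template SMILES, one 3-D embedding each
    ligand_assignment: list[tuple[int, int]]  # per model: (chemotype, site)
    site_anchors: list[np.ndarray]
    decoy_waters: int = 3
    ligand_jitter: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_models < 1:
            raise SpecError("n_models must be >= 1")
        if len(self.rotamer_states) != self.n_models:
            raise SpecError("rotamer_states must have one entry per model")
        if len(self.ligand_assignment) != self.n_models:
            raise SpecError("ligand_assignment must have one entry per model")
        for site in self.water_sites:
            if not (0.0 < site.conservation <= 1.0):
                raise SpecError(
                    f"water-site conservation {site.conservation} outside (0, 1]"
                )
            if site.jitter_sigma >= LAMBDA_WATER / 3:
                raise SpecError(
                    f"water jitter sigma {site.jitter_sigma} too large to "
                    f"resolve sites at lambda {LAMBDA_WATER}"
                )
            required = set(site.required_contributors)
            forbidden = set(site.required_absentees)
            n_contrib = round(site.conservation * self.n_models)
            if required & forbidden:
                raise SpecError(
                    "a model cannot be both a required contributor and a "
                    "required absentee of one water site"
                )
            if len(required) > n_contrib or self.n_models - len(forbidden) < n_contrib:
                raise SpecError(
                    "water-site contributor constraints are infeasible for "
                    f"conservation {site.conservation}"
                )
        positions = [np.asarray(s.position, dtype=float) for s in self.water_sites]
        for i in range(len(positions)):
            for j in range(i + 1, len(positions)):
                if np.linalg.norm(positions[i] - positions[j]) <= 3.0:
                    raise SpecError(
                        f"planted water sites {i} and {j} closer than 3 A"
                    )
        anchors = [np.asarray(a, dtype=float) for a in self.site_anchors]
        for i in range(len(anchors)):
            for j in range(i + 1, len(anchors)):
                if np.linalg.norm(anchors[i] - anchors[j]) <= 2 * LAMBDA_LIGAND:
                    raise SpecError(
                        f"site anchors {i} and {j} closer than twice the "
                        f"ligand clustering distance ({2 * LAMBDA_LIGAND} A)"
                    )


@dataclass
class PlantedTruth:
    """Ground truth implied by an :class:`EnsembleSpec`, by construction."""

    model_ids: list[str]
    site_members: dict[int, list[str]]
    water_sites: list[dict]            # position, conservation, contributors
    displacement: list[list[str]]      # per conservation rank: absent models
    unique_displacement: dict | None
    residue_identity: list
    residue_clusters: list[list[str]]  # size-descending member lists
    residue_max_rmsd: float
    pharmacophore_kinds: dict[str, list[str]]
    pharmacophore_clusters: dict[str, list[str]]

    def to_json_dict(self) -> dict:
        return {
            "model_ids": self.model_ids,
            "site_members": {str(k): v for k, v in self.site_members.items()},
            "water_sites": [
                {
                    "position": [round(float(x), 6) for x in w["position"]],
                    "conservation": w["conservation"],
                    "contributors": w["contributors"],
                }
                for w in self.water_sites
            ],
            "displacement": self.displacement,
            "unique_displacement": self.unique_displacement,
            "residue_identity": list(self.residue_identity),
            "residue_clusters": self.residue_clusters,
            "residue_max_rmsd": self.residue_max_rmsd,
            "pharmacophore_kinds": self.pharmacophore_kinds,
            "pharmacophore_clusters": self.pharmacophore_clusters,
        }


# ---------------------------------------------------------------------------
# scaffold geometry (angstroms); chain A, residues numbered 1..13

_BACKBONE_OFFSETS = {
    "N": np.array([-1.2, 0.5, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.2, 0.5, 0.0]),
    "O": np.array([1.3, 1.7, 0.0]),
}
_ALA_CB = np.array([-0.1, -1.0, 1.0])

_TYR_CA = np.array([1.5, 0.0, 0.0])
_TYR_SIDE_A = {
    "CB": np.array([1.5, 1.5, 0.0]),
    "CG": np.array([1.5, 2.9, 0.0]),
    "CD1": np.array([0.3, 3.6, 0.0]),
    "CD2": np.array([2.7, 3.6, 0.0]),
    "CE1": np.array([0.3, 5.0, 0.0]),
    "CE2": np.array([2.7, 5.0, 0.0]),
    "CZ": np.array([1.5, 5.7, 0.0]),
    "OH": np.array([1.5, 7.1, 0.0]),
}
_TYR_FLIP_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH")
_TYR_RESSEQ = 6
_POCKET_ANCHOR = np.array([1.5, 10.5, 0.0])

_SER_CA = np.array([-1.5, 9.0, 2.5])
_SER_SIDE = {"CB": np.array([0.0, -1.2, -0.8]), "OG": np.array([0.8, -2.2, -1.2])}
_THR_CA = np.array([4.5, 9.0, 2.5])
_THR_SIDE = {
    "CB": np.array([0.0, -1.2, -0.8]),
    "OG1": np.array([0.9, -2.1, -1.0]),
    "CG2": np.array([-1.2, -1.9, -1.1]),
}


def _scaffold_residues(rotamer_state: int):
    """(resname, resseq, {atom name: position}) for the rigid scaffold."""
    residues = []
    for i in range(1, 12):
        ca = np.array([-7.5 + 1.5 * i, 0.0, 0.0])
        if i == _TYR_RESSEQ:
            atoms = {k: ca + v for k, v in _BACKBONE_OFFSETS.items()}
            side = {k: v.copy() for k, v in _TYR_SIDE_A.items()}
            if rotamer_state == 1:
                for name in _TYR_FLIP_ATOMS:
                    side[name] = side[name] * np.array([1.0, -1.0, 1.0])
            atoms.update(side)
            residues.append(("TYR", i, atoms))
        else:
            atoms = {k: ca + v for k, v in _BACKBONE_OFFSETS.items()}
            atoms["CB"] = ca + _ALA_CB
            residues.append(("ALA", i, atoms))
    for resname, resseq, ca, side in (
        ("SER", 12, _SER_CA, _SER_SIDE),
        ("THR", 13, _THR_CA, _THR_SIDE),
    ):
        atoms = {k: ca + v for k, v in _BACKBONE_OFFSETS.items()}
        atoms.update({k: ca + v for k, v in side.items()})
        residues.append((resname, resseq, atoms))
    return residues


def tyr_rotamer_rmsd() -> float:
    """Heavy-atom RMSD between the two planted tyrosine rotamers."""
    a = _scaffold_residues(0)[_TYR_RESSEQ - 1][2]
    b = _scaffold_residues(1)[_TYR_RESSEQ - 1][2]
    names = sorted(a)
    pa = np.asarray([a[n] for n in names])
    pb = np.asarray([b[n] for n in names])
    return float(np.sqrt(((pa - pb) ** 2).sum(axis=1).mean()))


def _embed_chemotype(smiles: str, seed: int) -> tuple[Chem.Mol, np.ndarray]:
    """One 3-D conformer per chemotype, benzene ring centred in the xy-plane."""
    mol = Chem.MolFromSmiles(smiles)
    molh = Chem.AddHs(mol)
    if AllChem.EmbedMolecule(molh, randomSeed=seed) != 0:
        raise SpecError(f"could not embed chemotype {smiles!r}")
    mol3d = Chem.RemoveHs(molh)
    conf = mol3d.GetConformer()
    coords = np.asarray(
        [list(conf.GetAtomPosition(i)) for i in range(mol3d.GetNumAtoms())]
    )
    aromatic_rings = [
        r for r in mol3d.GetRingInfo().AtomRings()
        if all(mol3d.GetAtomWithIdx(i).GetIsAromatic() for i in r)
    ]
    # align on the first aromatic ring when there is one, else on all atoms
    ring = list(aromatic_rings[0]) if aromatic_rings else list(range(len(coords)))
    centre = coords[list(ring)].mean(axis=0)
    rel = coords[list(ring)] - centre
    _, _, vt = np.linalg.svd(rel)
    u, v, w = vt[0], np.cross(vt[2], vt[0]), vt[2]
    rot = np.vstack([u, v / np.linalg.norm(v), w])
    return mol3d, (coords - centre) @ rot.T


def _atom_names(mol: Chem.Mol) -> list[str]:
    counts: dict[str, int] = {}
    names = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol().upper()
        counts[sym] = counts.get(sym, 0) + 1
        names.append(f"{sym}{counts[sym]}")
    return names


def _pdb_line(serial, record, name, resname, chain, resseq, xyz, element):
    atom_name = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:5d} {atom_name:<4s}{'':1s}{resname:<3s} "
        f"{chain:1s}{resseq:4d}{'':1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def _clipped_jitter(rng: np.random.Generator, sigma: float) -> np.ndarray:
    v = rng.normal(0.0, sigma, 3)
    norm = np.linalg.norm(v)
    cap = _JITTER_CLIP_SIGMAS * sigma
    if norm > cap:
        v *= cap / norm
    return v


def _pick_contributors(
    rng: np.random.Generator, spec: EnsembleSpec, site: WaterSiteSpec
) -> list[int]:
    n_contrib = round(site.conservation * spec.n_models)
    required = set(site.required_contributors)
    forbidden = set(site.required_absentees)
    if required & forbidden:
        raise SpecError("a model cannot be both contributor and absentee")
    if len(required) > n_contrib or spec.n_models - len(forbidden) < n_contrib:
        raise SpecError("contributor constraints infeasible for conservation")
    pool = [
        i for i in range(spec.n_models) if i not in required and i not in forbidden
    ]
    extra = rng.choice(len(pool), size=n_contrib - len(required), replace=False)
    return sorted(required | {pool[i] for i in extra})


def generate_ensemble(
    spec: EnsembleSpec, out_dir: str | Path
) -> tuple[Path, list[Path], PlantedTruth]:
    """Write manifest + PDB files + truth.json; return their paths and truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    pdb_dir = out_dir / "pdbs"
    pdb_dir.mkdir(parents=True, exist_ok=True)

    model_ids = [f"m{i:02d}" for i in range(spec.n_models)]
    embeddings = [
        _embed_chemotype(smi, seed=_CHEMOTYPE_SEED_BASE + k)
        for k, smi in enumerate(spec.chemotypes)
    ]
    anchors = [np.asarray(a, dtype=float) for a in spec.site_anchors]

    # per-model ligand placement: translation-only jitter; the first model of
    # each (site, chemotype) pair is left unjittered so planted waters
    # provably pass the ligand-contact filter
    seen: set[tuple[int, int]] = set()
    ligand_offsets = []
    for i in range(spec.n_models):
        key = spec.ligand_assignment[i]
        if key not in seen:
            seen.add(key)
            ligand_offsets.append(np.zeros(3))
        else:
            v = rng.normal(0.0, 1.0, 3)
            v *= rng.uniform(0.0, spec.ligand_jitter) / np.linalg.norm(v)
            ligand_offsets.append(v)

    contributors = [_pick_contributors(rng, spec, s) for s in spec.water_sites]
    site_positions = [np.asarray(s.position, dtype=float) for s in spec.water_sites]

    # global decoy positions: a shell around each anchor, mutually separated
    # by > 2 * lambda_water and kept away from planted sites and ligands
    decoys: list[np.ndarray] = []
    decoy_per_model: list[list[np.ndarray]] = [[] for _ in range(spec.n_models)]
    for i in range(spec.n_models):
        _, site_idx = spec.ligand_assignment[i]
        anchor = anchors[site_idx]
        placed = 0
        attempts = 0
        while placed < spec.decoy_waters:
            attempts += 1
            if attempts > 10000:
                raise SpecError("could not place decoy waters; shell too crowded")
            direction = rng.normal(0.0, 1.0, 3)
            direction /= np.linalg.norm(direction)
            pos = anchor + direction * rng.uniform(8.0, 12.0)
            if any(np.linalg.norm(pos - p) <= 2 * LAMBDA_WATER for p in site_positions):
                continue
            if any(np.linalg.norm(pos - d) <= 2 * LAMBDA_WATER for d in decoys):
                continue
            decoys.append(pos)
            decoy_per_model[i].append(pos)
            placed += 1

    manifest_rows = []
    pdb_paths = []
    for i, model_id in enumerate(model_ids):
        chem_idx, site_idx = spec.ligand_assignment[i]
        mol3d, lig_coords = embeddings[chem_idx]
        names = _atom_names(mol3d)
        placed_coords = lig_coords + anchors[site_idx] + ligand_offsets[i]

        lines = []
        serial = 1
        for resname, resseq, atoms in _scaffold_residues(spec.rotamer_states[i]):
            for name, pos in atoms.items():
                lines.append(
                    _pdb_line(serial, "ATOM", name, resname, "A", resseq, pos, name[0])
                )
                serial += 1
        for j, name in enumerate(names):
            element = mol3d.GetAtomWithIdx(j).GetSymbol().upper()
            lines.append(
                _pdb_line(serial, "HETATM", name, "LIG", "A", 500, placed_coords[j], element)
            )
            serial += 1
        water_seq = 600
        for k, site in enumerate(spec.water_sites):
            if i in contributors[k]:
                pos = site_positions[k] + _clipped_jitter(rng, site.jitter_sigma)
                lines.append(
                    _pdb_line(serial, "HETATM", "O", "HOH", "A", water_seq, pos, "O")
                )
                serial += 1
                water_seq += 1
        for pos in decoy_per_model[i]:
            lines.append(
                _pdb_line(serial, "HETATM", "O", "HOH", "A", water_seq, pos, "O")
            )
            serial += 1
            water_seq += 1
        lines.append("END")

        pdb_path = pdb_dir / f"{model_id}.pdb"
        pdb_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        pdb_paths.append(pdb_path)
        manifest_rows.append(
            {
                "pdb_path": f"pdbs/{model_id}.pdb",
                "smiles": spec.chemotypes[chem_idx],
                "compound_id": f"CPD-{chem_idx}",
                "model_id": model_id,
                "chain": "A",
            }
        )

    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["pdb_path", "smiles", "compound_id", "model_id", "chain"]
        )
        writer.writeheader()
        writer.writerows(manifest_rows)

    truth = _build_truth(spec, model_ids, contributors, site_positions)
    (out_dir / "truth.json").write_text(
        json.dumps(truth.to_json_dict(), indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return manifest_path, pdb_paths, truth


def _build_truth(spec, model_ids, contributors, site_positions) -> PlantedTruth:
    site_members: dict[int, list[str]] = {}
    for i, (_, site_idx) in enumerate(spec.ligand_assignment):
        site_members.setdefault(site_idx, []).append(model_ids[i])

    rank = sorted(
        range(len(spec.water_sites)),
        key=lambda k: -spec.water_sites[k].conservation,
    )
    water_sites = [
        {
            "position": site_positions[k],
            "conservation": round(
                round(spec.water_sites[k].conservation * spec.n_models)
                / spec.n_models,
                6,
            ),
            "contributors": [model_ids[i] for i in contributors[k]],
        }
        for k in rank
    ]
    displacement = [
        sorted(set(model_ids) - set(w["contributors"])) for w in water_sites
    ]
    unique = None
    for r, absent in enumerate(displacement):
        for m in absent:
            if sum(m in other for other in displacement) == 1:
                unique = {"model": m, "water_rank": r}
                break
        if unique:
            break

    state_groups: dict[int, list[str]] = {}
    for i, state in enumerate(spec.rotamer_states):
        state_groups.setdefault(state, []).append(model_ids[i])
    residue_clusters = sorted(state_groups.values(), key=lambda g: (-len(g), g[0]))

    kinds = {
        model_ids[i]: sorted(CHEMOTYPE_KINDS[spec.chemotypes[c]])
        for i, (c, _) in enumerate(spec.ligand_assignment)
    }
    clusters: dict[str, list[str]] = {}
    for m, ks in kinds.items():
        for k in ks:
            clusters.setdefault(k, []).append(m)
    return PlantedTruth(
        model_ids=model_ids,
        site_members=site_members,
        water_sites=water_sites,
        displacement=displacement,
        unique_displacement=unique,
        residue_identity=("A", _TYR_RESSEQ, "", "TYR"),
        residue_clusters=residue_clusters,
        residue_max_rmsd=round(tyr_rotamer_rmsd(), 6)
        if len(state_groups) > 1
        else 0.0,
        pharmacophore_kinds=kinds,
        pharmacophore_clusters={k: sorted(v) for k, v in clusters.items()},
    )


def _demo_water_positions(anchor: np.ndarray, chemotype: str) -> list[np.ndarray]:
    """Four pocket water positions hugging the ligand envelope.

    Each position sits 0.8 A radially outward of an actual heavy atom of the
    placed chemotype (the two para substituent tips and the two most
    perpendicular ring carbons), which keeps every site within the 1.5 A
    ligand-contact cutoff while the four positions stay more than 3 A apart.
    """
    mol3d, coords = _embed_chemotype(chemotype, seed=_CHEMOTYPE_SEED_BASE + 1)
    ring = next(
        r for r in mol3d.GetRingInfo().AtomRings()
        if all(mol3d.GetAtomWithIdx(i).GetIsAromatic() for i in r)
    )
    symbols = [a.GetSymbol() for a in mol3d.GetAtoms()]
    tips = [i for i, s in enumerate(symbols) if s == "Cl"]
    tips += [
        i for i, s in enumerate(symbols)
        if s == "C" and i not in ring
    ]
    cl_axis = coords[tips[0]][:2]
    cl_axis = cl_axis / np.linalg.norm(cl_axis)
    perp = np.array([-cl_axis[1], cl_axis[0]])
    side = [float(coords[i][:2] @ perp) for i in ring]
    tips.append(ring[int(np.argmax(side))])
    tips.append(ring[int(np.argmin(side))])
    positions = []
    for idx in tips:
        atom = coords[idx]
        outward = atom / np.linalg.norm(atom)
        positions.append(anchor + atom + 0.8 * outward)
    return positions


def default_demo_spec(seed: int = 17) -> EnsembleSpec:
    """The fixed demo ensemble used by the documentation and the test suite.

    Twenty models in one binding site, four planted pocket water sites at
    conservations 1.00 / 0.90 / 0.60 / 0.30 (a conserved-water motif of four
    waters at the pocket floor), one bi-rotameric tyrosine split 6/14, and two
    ligand chemotypes.  Model ``m07`` is the designated displacer: it is
    absent from exactly one planted site (the second most conserved), so its
    displacement row carries exactly one mark.
    """
    n = 20
    anchor = _POCKET_ANCHOR
    chemotypes = ["Oc1ccccc1", "Cc1ccc(Cl)cc1"]
    positions = _demo_water_positions(anchor, chemotypes[1])
    water_sites = [
        WaterSiteSpec(position=positions[0], conservation=1.0),
        WaterSiteSpec(
            position=positions[1],
            conservation=0.9,
            required_absentees=(7, 13),
        ),
        WaterSiteSpec(
            position=positions[2],
            conservation=0.6,
            required_contributors=(7,),
            required_absentees=(13,),
        ),
        WaterSiteSpec(
            position=positions[3],
            conservation=0.3,
            required_contributors=(7,),
        ),
    ]
    flipped = {2, 5, 8, 11, 14, 17}
    rotamer_states = [1 if i in flipped else 0 for i in range(n)]
    ligand_assignment = [(0 if i < 12 else 1, 0) for i in range(n)]
    return EnsembleSpec(
        n_models=n,
        water_sites=water_sites,
        rotamer_states=rotamer_states,
        chemotypes=chemotypes,
        ligand_assignment=ligand_assignment,
        site_anchors=[anchor],
        decoy_waters=3,
        ligand_jitter=0.4,
        seed=seed,
    )
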