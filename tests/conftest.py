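"""Shared fixtures: ligand poses built from SMILES, and the demo ensemble."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from plens.cli_report import RunConfig, run_pipeline
from plens.fixtures import default_demo_spec, generate_ensemble
from plens.io_model import AtomRecord, LigandPose, StructureModel, assign_bond_orders

RDLogger.DisableLog("rdApp.warning")


def make_pose(
    smiles: str,
    seed: int = 1,
    model_id: str = "t",
    translate=(0.0, 0.0, 0.0),
) -> LigandPose:
    """Embed a SMILES once and wrap it as a crystallographic-style pose."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    assert AllChem.EmbedMolecule(mol, randomSeed=seed) == 0
    mol = Chem.RemoveHs(mol)
    conf = mol.GetConformer()
    records = []
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        counts[sym] = counts.get(sym, 0) + 1
        coords = np.array(list(conf.GetAtomPosition(atom.GetIdx()))) + np.asarray(
            translate, dtype=float
        )
        records.append(
            AtomRecord(name=f"{sym.upper()}{counts[sym]}", element=sym, coords=coords)
        )
    pose = assign_bond_orders(records, smiles)
    pose.model_id = model_id
    return pose


def make_model(
    model_id: str,
    ligand: LigandPose,
    waters=(),
    residues=(),
) -> StructureModel:
    from plens.io_model import WaterSite

    ligand.model_id = model_id
    return StructureModel(
        model_id=model_id,
        chain_id="A",
        residues=list(residues),
        waters=[WaterSite(position=np.asarray(w, dtype=float), model_id=model_id) for w in waters],
        ligand=ligand,
    )


@pytest.fixture
def pose_factory():
    return make_pose


@pytest.fixture
def model_factory():
    return make_model


@pytest.fixture(scope="session")
def demo_ensemble(tmp_path_factory):
    """The built-in demo ensemble, generated once per test session."""
    out = tmp_path_factory.mktemp("demo_ensemble")
    spec = default_demo_spec(seed=17)
    manifest, pdb_paths, truth = generate_ensemble(spec, out)
    return manifest, pdb_paths, truth


@pytest.fixture(scope="session")
def demo_run(demo_ensemble, tmp_path_factory):
    """Full pipeline output on the demo ensemble (bundle + output directory)."""
    manifest, _, truth = demo_ensemble
    out = tmp_path_factory.mktemp("demo_run")
    config = RunConfig(manifest=str(manifest), out_dir=str(out), seed=17)
    bundle = run_pipeline(config)
    return bundle, out, truth
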