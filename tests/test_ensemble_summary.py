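"""Site assignment, water conservation/displacement, presence grids, residues."""

import numpy as np
import pytest

from plens.clustering import PointCluster
from plens.ensemble_summary import (
    analyse_site,
    binding_site_residues,
    build_summary,
    cluster_ligand_sites,
    cluster_waters,
    filter_site_waters,
    main_site,
    order_compounds_chemically,
    pharmacophore_presence_matrix,
    water_displacement_matrix,
)
from plens.features import PharmacophorePoint, detect_pharmacophores, fragment_ligand
from plens.io_model import AtomRecord, ResidueConformation


class TestSites:
    def test_two_close_ligands_one_site(self, pose_factory, model_factory):
        models = [
            model_factory("m0", pose_factory("CCO", translate=(0, 0, 0))),
            model_factory("m1", pose_factory("CCO", translate=(3, 0, 0))),
        ]
        sites = cluster_ligand_sites(models)
        assert len(sites) == 1 and sites[0].is_main

    def test_majority_pocket_is_main(self, pose_factory, model_factory):
        models = [
            model_factory(f"m{i}", pose_factory("CCO", translate=(0.2 * i, 0, 0)))
            for i in range(5)
        ]
        models.append(model_factory("m9", pose_factory("CCO", translate=(25, 0, 0))))
        sites = cluster_ligand_sites(models)
        assert len(sites) == 2
        assert sorted(main_site(sites).members) == [f"m{i}" for i in range(5)]

    def test_single_model(self, pose_factory, model_factory):
        sites = cluster_ligand_sites([model_factory("m0", pose_factory("CCO"))])
        assert len(sites) == 1 and sites[0].is_main and sites[0].members == ["m0"]


class TestWaters:
    def test_full_conservation(self, pose_factory, model_factory):
        rng = np.random.default_rng(0)
        models = [
            model_factory(
                f"m{i}",
                pose_factory("CCO"),
                waters=[np.array([5.0, 5, 5]) + rng.normal(0, 0.1, 3)],
            )
            for i in range(10)
        ]
        (cluster,) = cluster_waters(models)
        assert cluster.conservation == pytest.approx(1.0)
        assert cluster.n_models == 10

    def test_distinct_model_counting(self, pose_factory, model_factory):
        # one model contributes two waters to the same cluster; three other
        # models contribute none
        models = [
            model_factory(
                "m0", pose_factory("CCO"),
                waters=[(5.0, 5, 5), (5.4, 5, 5)],
            )
        ] + [model_factory(f"m{i}", pose_factory("CCO")) for i in (1, 2, 3)]
        (cluster,) = cluster_waters(models)
        assert cluster.size == 2
        assert cluster.n_models == 1
        assert cluster.conservation == pytest.approx(0.25)

    def test_ranked_by_conservation(self, pose_factory, model_factory):
        rng = np.random.default_rng(1)
        positions = {(-5.0, 0, 0): 9, (5.0, 0, 0): 5, (0, 8.0, 0): 2}
        models = []
        for i in range(10):
            waters = [
                np.asarray(p) + rng.normal(0, 0.1, 3)
                for p, k in positions.items()
                if i < k
            ]
            models.append(model_factory(f"m{i}", pose_factory("CCO"), waters=waters))
        clusters = cluster_waters(models)
        assert [c.conservation for c in clusters] == pytest.approx([0.9, 0.5, 0.2])


def _cluster(centre, members, conservation, kind="water"):
    return PointCluster(
        kind=kind, lam=1.5, centre=np.asarray(centre, dtype=float),
        member_points=[(np.asarray(centre, dtype=float), m) for m in members],
        n_models=len(set(members)), conservation=conservation,
    )


class TestFilterAndDisplacement:
    def make_site_models(self, pose_factory, model_factory, n=4):
        models = [
            model_factory(f"m{i}", pose_factory("c1ccccc1")) for i in range(n)
        ]
        sites = cluster_ligand_sites(models)
        return models, sites[0]

    def test_contact_and_conservation_filter(self, pose_factory, model_factory):
        models, site = self.make_site_models(pose_factory, model_factory)
        atom = models[0].ligand.coords()[0]
        near = _cluster(atom + [1.4, 0, 0], ["m0"], 0.9)
        boundary = _cluster(atom + [1.4, 0, 0], ["m0"], 0.85)
        far = _cluster(atom + [6.0, 0, 0], ["m0", "m1"], 1.0)
        kept = filter_site_waters(
            [near, boundary, far], models, site, contact=1.5, min_conservation=0.85
        )
        assert kept == [near]  # 0.85 dropped by strict >, far dropped by contact

    def test_displacement_cells_mark_absence(self, pose_factory, model_factory):
        models, site = self.make_site_models(pose_factory, model_factory)
        full = _cluster((0, 0, 0), [m.model_id for m in models], 1.0)
        partial = _cluster((5, 0, 0), ["m0", "m2"], 0.5)
        matrix = water_displacement_matrix([full, partial], site)
        assert matrix.columns == ["m0", "m1", "m2", "m3"]
        assert matrix.cells[0] == [False, False, False, False]
        assert matrix.cells[1] == [False, True, False, True]

    def test_displacement_presence_duality(self, demo_run):
        bundle, _, _ = demo_run
        matrix = bundle.displacement
        for row, cells in zip(matrix.rows, matrix.cells):
            contributing = row.model_ids()
            for model, displaced in zip(matrix.columns, cells):
                assert displaced != (model in contributing)


class TestPresenceMatrix:
    def test_same_position_different_kinds_stay_separate(self):
        from plens.ensemble_summary import SiteAssignment

        site = SiteAssignment(
            site_id=0, members=["m0"], centre=np.zeros(3), is_main=True
        )
        points = [
            PharmacophorePoint("Donor", np.zeros(3), "m0", (0,)),
            PharmacophorePoint("Acceptor", np.zeros(3), "m0", (0,)),
        ]
        matrices = pharmacophore_presence_matrix(points, site)
        assert len(matrices["Donor"].rows) == 1
        assert len(matrices["Acceptor"].rows) == 1

    def test_missing_feature_leaves_one_false_cell(self, pose_factory, model_factory):
        # four phenols share the hydroxyl; one benzene lacks it
        models = [
            model_factory(f"m{i}", pose_factory("Oc1ccccc1")) for i in range(4)
        ] + [model_factory("m4", pose_factory("c1ccccc1"))]
        sites = cluster_ligand_sites(models)
        points = [
            p for m in models for p in detect_pharmacophores(m.ligand)
        ]
        matrices = pharmacophore_presence_matrix(points, sites[0])
        donor = matrices["Donor"]
        assert donor.columns == ["m0", "m1", "m2", "m3", "m4"]
        assert donor.cells[0] == [True, True, True, True, False]
        assert donor.rows[0].conservation == pytest.approx(0.8)

    def test_row_sums_equal_n_models(self, demo_run):
        bundle, _, _ = demo_run
        for matrix in bundle.pharmacophore_presence.values():
            for row, cells in zip(matrix.rows, matrix.cells):
                assert sum(cells) == row.n_models
            sizes = [r.n_models for r in matrix.rows]
            assert sizes == sorted(sizes, reverse=True)


def _residue(identity, coords_by_name, model_id):
    atoms = [
        AtomRecord(name=n, element=n[0], coords=np.asarray(c, dtype=float))
        for n, c in coords_by_name.items()
    ]
    return ResidueConformation(identity=identity, atoms=atoms, model_id=model_id)


class TestBindingSiteResidues:
    def build(self, pose_factory, model_factory, flip_models=(), far=False):
        models = []
        base_y = 3.0 if not far else 30.0
        for i in range(6):
            flipped = i in flip_models
            res = _residue(
                ("A", 1, "", "SER"),
                {
                    "CA": (0, base_y, 0),
                    "CB": (0, base_y + 1.0, 0),
                    "OG": (0, base_y + (8.0 if flipped else 2.0), 0),
                },
                f"m{i}",
            )
            models.append(
                model_factory(f"m{i}", pose_factory("c1ccccc1"), residues=[res])
            )
        sites = cluster_ligand_sites(models)
        return models, sites[0]

    def test_residue_beyond_cutoff_excluded(self, pose_factory, model_factory):
        models, site = self.build(pose_factory, model_factory, far=True)
        assert binding_site_residues(models, site) == []

    def test_identical_conformations_single_cluster(self, pose_factory, model_factory):
        models, site = self.build(pose_factory, model_factory)
        (entry,) = binding_site_residues(models, site)
        assert entry.max_rmsd == 0.0
        assert len(entry.cluster_set.clusters) == 1

    def test_rotamer_flip_splits_and_ranks_first(self, demo_run):
        bundle, _, truth = demo_run
        top = bundle.residue_ranking[0]
        assert list(top.identity) == list(truth.residue_identity)
        assert top.max_rmsd == pytest.approx(truth.residue_max_rmsd, abs=1e-4)
        sizes = sorted(len(m) for _, m in top.cluster_set.clusters)
        assert sizes == sorted(len(c) for c in truth.residue_clusters)
        ranking = [e.max_rmsd for e in bundle.residue_ranking]
        assert ranking == sorted(ranking, reverse=True)


class TestCompoundOrdering:
    def test_identical_smiles_order_by_model_id(self, pose_factory):
        ligands = []
        for i in (2, 0, 1):
            pose = pose_factory("CCO", model_id=f"m{i}")
            ligands.append(pose)
        assert order_compounds_chemically(ligands) == ["m0", "m1", "m2"]

    def test_larger_chemotype_first(self, pose_factory):
        ligands = [
            pose_factory("Oc1ccccc1", model_id=f"p{i}") for i in range(3)
        ] + [pose_factory("CCCCCCCC", model_id=f"a{i}") for i in range(2)]
        order = order_compounds_chemically(ligands)
        assert order == ["p0", "p1", "p2", "a0", "a1"]

    def test_singleton(self, pose_factory):
        assert order_compounds_chemically([pose_factory("CCO", model_id="x")]) == ["x"]


class TestAnalyseSite:
    def test_unknown_site_rejected(self, pose_factory, model_factory):
        models = [model_factory("m0", pose_factory("CCO"))]
        sites = cluster_ligand_sites(models)
        with pytest.raises(KeyError):
            analyse_site(models, [], [], sites, site_id=99)

    def test_site_restriction_idempotent(self, pose_factory, model_factory):
        rng = np.random.default_rng(5)
        models = []
        for i in range(4):
            models.append(
                model_factory(
                    f"m{i}",
                    pose_factory("Oc1ccccc1", translate=tuple(rng.normal(0, 0.2, 3))),
                    waters=[(3.0, 0, 0)],
                )
            )
        for i in (4, 5):
            models.append(
                model_factory(
                    f"m{i}",
                    pose_factory("CCO", translate=(30.0, 0, 0)),
                    waters=[(33.0, 0, 0)],
                )
            )
        feats = [p for m in models for p in detect_pharmacophores(m.ligand)]
        frags = [f for m in models for f in fragment_ligand(m.ligand)]
        sites = cluster_ligand_sites(models)
        main_id = main_site(sites).site_id
        full = analyse_site(models, feats, frags, sites, main_id)

        keep = set(main_site(sites).members)
        sub_models = [m for m in models if m.model_id in keep]
        sub_feats = [p for p in feats if p.source_model in keep]
        sub_frags = [f for f in frags if f.source_model in keep]
        sub = build_summary(sub_models, sub_feats, sub_frags)

        assert [c.conservation for c in full.water_clusters] == [
            c.conservation for c in sub.water_clusters
        ]
        assert full.displacement.columns == sub.displacement.columns
        assert full.displacement.cells == sub.displacement.cells
        for kind in full.pharmacophore_presence:
            assert (
                full.pharmacophore_presence[kind].cells
                == sub.pharmacophore_presence[kind].cells
            )

    def test_empty_site_after_filtering(self, pose_factory, model_factory):
        models = [model_factory("m0", pose_factory("CCO"))]
        sites = cluster_ligand_sites(models)
        bundle = analyse_site(models, [], [], sites, sites[0].site_id)
        assert bundle.filtered_waters == []
        assert all(not m.rows for m in bundle.pharmacophore_presence.values())
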