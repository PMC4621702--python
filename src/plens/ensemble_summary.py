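"""Ranked summary products over a structural ensemble.

Given the loaded models and their ligand features, this module builds the
tables a structure-based drug-design team reads off an ensemble:

* ligand binding **sites** (DP-means over ligand centroids, lambda 5.0 A),
  with the most populated site as the default "main" site;
* conserved **waters** (lambda 1.5 A) ranked by conservation, filtered to the
  ligand envelope, and a displacement matrix marking which main-site ligands
  contribute no water to each conserved cluster;
* **pharmacophore** presence grids per feature kind (lambda 2.0 A), rows in
  descending cluster-size order, one column per site ligand;
* binding-site **residues** within 5.0 A of any site ligand, ranked by
  maximum pairwise heavy-atom RMSD and clustered at lambda 2.5 A via the
  medoid variant;
* **fragment** clusters (lambda 2.0 A) and a chemistry-driven compound
  ordering (Morgan radius-2 fingerprints, Butina clustering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from rdkit.ML.Cluster import Butina
from scipy.spatial import cKDTree

from .clustering import (
    PointCluster,
    ResidueClusterSet,
    dp_means,
    dp_means_medoid,
    heavy_atom_rmsd,
)
from .features import KINDS, FragmentPose, PharmacophorePoint
from .io_model import LigandPose, StructureModel

logger = logging.getLogger(__name__)

# Field-validated default distance parameters (angstroms).
LAMBDA_WATER = 1.5
LAMBDA_PHARMACOPHORE = 2.0
LAMBDA_FRAGMENT = 2.0
LAMBDA_RESIDUE = 2.5
LAMBDA_LIGAND = 5.0
WATER_CONTACT = 1.5
RESIDUE_CONTACT = 5.0
BUTINA_DISTANCE_THRESHOLD = 0.4


@dataclass
class SiteAssignment:
    site_id: int
    members: list[str]
    centre: np.ndarray
    is_main: bool


@dataclass
class PresenceMatrix:
    """Boolean grid: rows are clusters (size-descending), columns are models."""

    rows: list[PointCluster]
    columns: list[str]
    cells: list[list[bool]]


@dataclass
class DisplacementMatrix:
    """True cell = the model contributes no water to that conserved cluster."""

    rows: list[PointCluster]
    columns: list[str]
    cells: list[list[bool]]


@dataclass
class ResidueRankingEntry:
    identity: tuple
    max_rmsd: float
    cluster_set: ResidueClusterSet


@dataclass
class SummaryBundle:
    sites: list[SiteAssignment]
    water_clusters: list[PointCluster]
    filtered_waters: list[PointCluster]
    displacement: DisplacementMatrix
    pharmacophore_presence: dict[str, PresenceMatrix]
    residue_ranking: list[ResidueRankingEntry]
    fragment_clusters: list[PointCluster]
    compound_order: list[str]
    site_id: int = 0
    parameters: dict = field(default_factory=dict)


def cluster_ligand_sites(
    models: list[StructureModel], lam: float = LAMBDA_LIGAND
) -> list[SiteAssignment]:
    """Group ligands into binding sites by clustering their centroids."""
    pts = sorted(
        ((m.ligand.centroid, m.model_id) for m in models), key=lambda t: t[1]
    )
    clusters = dp_means(pts, lam, kind="ligand", ensemble_size=len(models))
    sites = []
    # main site: most populated, ties toward the lexicographically smallest
    # member model_id
    best = None
    for k, cluster in enumerate(clusters):
        members = sorted(cluster.model_ids())
        sites.append(
            SiteAssignment(site_id=k, members=members, centre=cluster.centre, is_main=False)
        )
        key = (-len(members), members[0])
        if best is None or key < best[0]:
            best = (key, k)
    if best is not None:
        sites[best[1]].is_main = True
    return sites


def main_site(sites: list[SiteAssignment]) -> SiteAssignment:
    return next(s for s in sites if s.is_main)


def cluster_waters(
    models: list[StructureModel], lam: float = LAMBDA_WATER
) -> list[PointCluster]:
    """Cluster all water oxygens; rank clusters by conservation descending.

    Conservation counts distinct contributing models over the whole ensemble
    (two waters of one model in one cluster count once).
    """
    pts = []
    for model in sorted(models, key=lambda m: m.model_id):
        for water in model.waters:
            pts.append((water.position, model.model_id))
    clusters = dp_means(pts, lam, kind="water", ensemble_size=len(models))
    return sorted(clusters, key=lambda c: (-c.conservation, -c.size))


def filter_site_waters(
    clusters: list[PointCluster],
    models: list[StructureModel],
    site: SiteAssignment,
    contact: float = WATER_CONTACT,
    min_conservation: float = 0.0,
) -> list[PointCluster]:
    """Keep clusters near the site's ligands and above a conservation floor.

    A cluster survives when its centre is within ``contact`` of any heavy atom
    of any ligand bound in the site, and its conservation is strictly greater
    than ``min_conservation``.  Input order (conservation ranking) is kept.
    """
    site_models = {m.model_id: m for m in models if m.model_id in site.members}
    atoms = np.concatenate(
        [m.ligand.coords() for m in site_models.values()]
    ) if site_models else np.empty((0, 3))
    if len(atoms) == 0:
        return []
    tree = cKDTree(atoms)
    kept = []
    for cluster in clusters:
        if cluster.conservation <= min_conservation:
            continue
        dist, _ = tree.query(cluster.centre)
        if dist <= contact:
            kept.append(cluster)
    return kept


def water_displacement_matrix(
    clusters: list[PointCluster], site: SiteAssignment
) -> DisplacementMatrix:
    """Mark which main-site ligands contribute no water to each cluster."""
    columns = sorted(site.members)
    cells = []
    for cluster in clusters:
        contributing = cluster.model_ids()
        cells.append([m not in contributing for m in columns])
    return DisplacementMatrix(rows=clusters, columns=columns, cells=cells)


def pharmacophore_presence_matrix(
    points: list[PharmacophorePoint],
    site: SiteAssignment,
    lam: float = LAMBDA_PHARMACOPHORE,
) -> dict[str, PresenceMatrix]:
    """Per-kind presence grids over the site's ligands.

    Kinds never co-cluster.  Within a kind, rows are clusters in descending
    size order; a cell is true when that ligand contributes at least one point
    to the row's cluster.  Cluster conservation is the fraction of site
    ligands contributing.
    """
    columns = sorted(site.members)
    site_set = set(columns)
    out: dict[str, PresenceMatrix] = {}
    for kind in KINDS:
        kind_pts = sorted(
            (p for p in points if p.kind == kind and p.source_model in site_set),
            key=lambda p: (p.source_model, p.source_atoms),
        )
        clusters = dp_means(
            [(p.position, p.source_model) for p in kind_pts],
            lam,
            kind=kind,
            ensemble_size=len(columns),
        )
        clusters = sorted(clusters, key=lambda c: -c.n_models)
        cells = [
            [m in c.model_ids() for m in columns] for c in clusters
        ]
        out[kind] = PresenceMatrix(rows=clusters, columns=columns, cells=cells)
    return out


def cluster_fragments(
    fragments: list[FragmentPose],
    site: SiteAssignment,
    lam: float = LAMBDA_FRAGMENT,
) -> list[PointCluster]:
    site_set = set(site.members)
    pts = sorted(
        (f for f in fragments if f.source_model in site_set),
        key=lambda f: (f.source_model, f.atom_indices),
    )
    clusters = dp_means(
        [(f.position, f.source_model) for f in pts],
        lam,
        kind="fragment",
        ensemble_size=len(site.members),
    )
    return clusters


def binding_site_residues(
    models: list[StructureModel],
    site: SiteAssignment,
    contact: float = RESIDUE_CONTACT,
    lam: float = LAMBDA_RESIDUE,
) -> list[ResidueRankingEntry]:
    """Rank binding-site residues by conformational variability.

    A residue identity qualifies when, in any model, one of its heavy atoms
    lies within ``contact`` of a heavy atom of any site ligand (union over
    models: a residue pushed out of range by one ligand still counts).  For
    each qualifying residue the all-against-all heavy-atom RMSD matrix is
    clustered with the medoid DP-means variant; entries are sorted by maximum
    pairwise RMSD, descending.  Residues present in fewer than half of the
    models are excluded with a logged note.
    """
    site_models = [m for m in models if m.model_id in site.members]
    ligand_atoms = np.concatenate([m.ligand.coords() for m in site_models])
    tree = cKDTree(ligand_atoms)

    by_identity: dict[tuple, list] = {}
    for model in sorted(models, key=lambda m: m.model_id):
        for res in model.residues:
            by_identity.setdefault(res.identity, []).append(res)

    entries = []
    for identity, confs in sorted(by_identity.items()):
        if len(confs) <= len(models) / 2:
            logger.info(
                "residue %s present in only %d/%d models; excluded",
                identity, len(confs), len(models),
            )
            continue
        in_contact = any(
            np.any(tree.query(np.asarray([a.coords for a in conf.atoms]))[0] <= contact)
            for conf in confs
        )
        if not in_contact:
            continue
        n = len(confs)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = heavy_atom_rmsd(confs[i], confs[j])
        assignment, medoids = dp_means_medoid(D, lam)
        clusters: list[tuple[str, list[str]]] = []
        cluster_sizes = []
        for k, med in enumerate(medoids):
            members = [confs[i].model_id for i in range(n) if assignment[i] == k]
            clusters.append((confs[med].model_id, members))
            cluster_sizes.append(len(members))
        # largest conformational cluster first
        rank = sorted(range(len(clusters)), key=lambda k: (-cluster_sizes[k], k))
        remap = {old: new for new, old in enumerate(rank)}
        clusters = [clusters[k] for k in rank]
        cluster_set = ResidueClusterSet(
            identity=identity,
            clusters=clusters,
            max_rmsd=float(D.max()),
            assignment={
                confs[i].model_id: remap[assignment[i]] for i in range(n)
            },
        )
        entries.append(
            ResidueRankingEntry(
                identity=identity, max_rmsd=cluster_set.max_rmsd, cluster_set=cluster_set
            )
        )
    entries.sort(key=lambda e: (-e.max_rmsd, e.identity))
    return entries


def order_compounds_chemically(
    ligands: list[LigandPose],
    distance_threshold: float = BUTINA_DISTANCE_THRESHOLD,
) -> list[str]:
    """Chemistry-driven column ordering.

    Morgan fingerprints (radius 2, 2048 bits) are clustered with the Butina
    algorithm at the given Tanimoto-distance threshold; clusters are emitted
    in descending size order and members within a cluster by model_id.
    """
    ligands = sorted(ligands, key=lambda l: l.model_id)
    if not ligands:
        return []
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    fps = [gen.GetFingerprint(Chem.MolFromSmiles(l.smiles)) for l in ligands]
    n = len(fps)
    dists = []
    for i in range(1, n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        dists.extend(1.0 - s for s in sims)
    raw = Butina.ClusterData(dists, n, distance_threshold, isDistData=True)
    clusters = [sorted(ligands[i].model_id for i in cl) for cl in raw]
    clusters.sort(key=lambda cl: (-len(cl), cl[0]))
    return [m for cl in clusters for m in cl]


def analyse_site(
    models: list[StructureModel],
    pharmacophores: list[PharmacophorePoint],
    fragments: list[FragmentPose],
    sites: list[SiteAssignment],
    site_id: int,
    lam_water: float = LAMBDA_WATER,
    lam_pharmacophore: float = LAMBDA_PHARMACOPHORE,
    lam_fragment: float = LAMBDA_FRAGMENT,
    lam_residue: float = LAMBDA_RESIDUE,
    water_contact: float = WATER_CONTACT,
    residue_contact: float = RESIDUE_CONTACT,
    min_water_conservation: float = 0.0,
    order: str = "chem",
) -> SummaryBundle:
    """All summary products restricted to one binding site.

    Every analysis — water clustering and conservation denominators, the
    displacement and presence columns, residue contacts — runs over the
    site's models only, so analysing a site of the full ensemble coincides
    with analysing the sub-ensemble of that site's models.
    """
    matching = [s for s in sites if s.site_id == site_id]
    if not matching:
        raise KeyError(f"unknown site_id {site_id}")
    site = matching[0]
    member_set = set(site.members)
    site_models = [m for m in models if m.model_id in member_set]

    water_clusters = cluster_waters(site_models, lam_water)
    filtered = filter_site_waters(
        water_clusters, site_models, site, water_contact, min_water_conservation
    )
    displacement = water_displacement_matrix(filtered, site)
    presence = pharmacophore_presence_matrix(pharmacophores, site, lam_pharmacophore)
    residues = (
        binding_site_residues(site_models, site, residue_contact, lam_residue)
        if site_models
        else []
    )
    frag_clusters = cluster_fragments(fragments, site, lam_fragment)
    site_ligands = [m.ligand for m in models if m.model_id in set(site.members)]
    if order == "chem" and site_ligands:
        compound_order = order_compounds_chemically(site_ligands)
    else:
        compound_order = sorted(site.members)
    return SummaryBundle(
        sites=sites,
        water_clusters=water_clusters,
        filtered_waters=filtered,
        displacement=displacement,
        pharmacophore_presence=presence,
        residue_ranking=residues,
        fragment_clusters=frag_clusters,
        compound_order=compound_order,
        site_id=site_id,
        parameters={
            "lambda_water": lam_water,
            "lambda_pharmacophore": lam_pharmacophore,
            "lambda_fragment": lam_fragment,
            "lambda_residue": lam_residue,
            "water_contact": water_contact,
            "residue_contact": residue_contact,
            "min_water_conservation": min_water_conservation,
        },
    )


def build_summary(
    models: list[StructureModel],
    pharmacophores: list[PharmacophorePoint],
    fragments: list[FragmentPose],
    lam_ligand: float = LAMBDA_LIGAND,
    **kwargs,
) -> SummaryBundle:
    """Default analysis: cluster sites, then analyse the main site."""
    sites = cluster_ligand_sites(models, lam_ligand)
    bundle = analyse_site(
        models, pharmacophores, fragments, sites, main_site(sites).site_id, **kwargs
    )
    bundle.parameters["lambda_ligand"] = lam_ligand
    return bundle
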