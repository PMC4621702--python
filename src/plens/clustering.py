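"""Distance-thresholded DP-means clustering.

Two flavours are provided:

* :func:`dp_means` — hard clustering of 3-D points (waters, pharmacophore
  points, fragment centres, ligand centroids).  The single parameter ``lam``
  (lambda, in angstroms) is the maximum distance allowed between a member and
  its cluster centre; a point farther than ``lam`` from every existing centre
  spawns a new cluster, so the number of clusters is data-driven.
* :func:`dp_means_medoid` — the same pass structure driven by a precomputed
  dissimilarity matrix (heavy-atom RMSD between residue conformations), with
  the cluster centre replaced by the cluster medoid.

Both are deterministic: points are visited in input order, ties between
equidistant centres break toward the lowest cluster index, and convergence is
declared when a full assignment pass changes nothing.  At the fixed point every
member lies within ``lam`` of its centre/medoid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Safety cap on assignment passes; the fixed point is normally reached in a
#: handful of passes, the cap only guards against pathological oscillation.
MAX_PASSES = 100


@dataclass
class PointCluster:
    """One spatial cluster of 3-D feature points.

    ``conservation`` is the fraction of ensemble models contributing at least
    one member point (distinct-model counting: a model contributing two waters
    to the same cluster counts once).
    """

    kind: str
    lam: float
    centre: np.ndarray
    member_points: list[tuple[np.ndarray, str]]
    n_models: int
    conservation: float

    @property
    def size(self) -> int:
        return len(self.member_points)

    def model_ids(self) -> set[str]:
        return {m for _, m in self.member_points}


@dataclass
class ResidueClusterSet:
    """Conformational clusters of one residue identity across the ensemble."""

    identity: tuple
    clusters: list[tuple[str, list[str]]]  # (medoid model_id, member model_ids)
    max_rmsd: float
    assignment: dict[str, int] = field(default_factory=dict)


def unweighted_centroid(points: Sequence[np.ndarray]) -> np.ndarray:
    """Arithmetic mean of coordinates, with no mass weighting."""
    if len(points) == 0:
        raise ValueError("centroid of zero points is undefined")
    return np.asarray(points, dtype=float).mean(axis=0)


def dp_means(
    points: Sequence[tuple[np.ndarray, str]],
    lam: float,
    kind: str = "point",
    ensemble_size: int | None = None,
) -> list[PointCluster]:
    """Cluster labelled 3-D points with the distance-threshold spawn rule.

    Parameters
    ----------
    points:
        Sequence of ``(xyz, model_id)`` pairs, visited in the given order.
    lam:
        Maximum member-to-centre distance in angstroms; must be positive.
    kind:
        Label stored on the resulting clusters (e.g. ``"water"``).
    ensemble_size:
        Denominator for the conservation fraction.  Defaults to the number of
        distinct model_ids present in ``points``.

    Returns
    -------
    Clusters sorted by size descending, ties broken by first-member input
    order.  Every member is within ``lam`` of its cluster centre.
    """
    if not np.isfinite(lam) or lam <= 0:
        raise ValueError(f"lambda must be positive and finite, got {lam}")
    pts = list(points)
    if not pts:
        return []
    X = np.asarray([np.asarray(p, dtype=float) for p, _ in pts])
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite coordinates in clustering input")
    labels = [m for _, m in pts]
    n = len(pts)

    centres: np.ndarray = np.empty((0, X.shape[1]))
    assign = np.full(n, -1, dtype=int)

    for _pass in range(MAX_PASSES):
        changed = False
        centre_list = [c for c in centres]
        for i in range(n):
            if centre_list:
                C = np.asarray(centre_list)
                d = np.sqrt(((C - X[i]) ** 2).sum(axis=1))
                j = int(np.argmin(d))  # ties -> lowest index
                if d[j] > lam:
                    centre_list.append(X[i].copy())
                    j = len(centre_list) - 1
            else:
                centre_list.append(X[i].copy())
                j = 0
            if assign[i] != j:
                assign[i] = j
                changed = True
        # recompute centres as unweighted means; drop empty clusters
        new_centres = []
        remap = {}
        for k in range(len(centre_list)):
            idx = np.nonzero(assign == k)[0]
            if idx.size:
                remap[k] = len(new_centres)
                new_centres.append(X[idx].mean(axis=0))
        assign = np.asarray([remap[a] for a in assign])
        centres = np.asarray(new_centres)
        if not changed:
            break
    else:
        logger.warning(
            "dp_means did not converge in %d passes (n=%d, lam=%g); "
            "accepting current assignment", MAX_PASSES, n, lam,
        )

    if ensemble_size is None:
        ensemble_size = len(set(labels))

    clusters = []
    order = []  # first-member input index, for tie-breaking
    for k in range(len(centres)):
        idx = np.nonzero(assign == k)[0]
        members = [(X[i], labels[i]) for i in idx]
        models = {labels[i] for i in idx}
        clusters.append(
            PointCluster(
                kind=kind,
                lam=float(lam),
                centre=centres[k],
                member_points=members,
                n_models=len(models),
                conservation=len(models) / ensemble_size if ensemble_size else 0.0,
            )
        )
        order.append(int(idx[0]))
    ranked = sorted(range(len(clusters)), key=lambda k: (-clusters[k].size, order[k]))
    return [clusters[k] for k in ranked]


def dp_means_medoid(
    dissimilarity: np.ndarray, lam: float
) -> tuple[list[int], list[int]]:
    """DP-means over a precomputed dissimilarity matrix using medoid centres.

    The pass structure mirrors :func:`dp_means`: items are visited in index
    order, an item farther than ``lam`` from every current medoid spawns a new
    singleton cluster (itself the medoid), otherwise it joins the nearest
    medoid (ties toward the lowest cluster index).  After each pass the medoid
    of each cluster is recomputed as the member minimising the sum of
    dissimilarities to all members (ties toward the lowest item index).

    Returns ``(assignment, medoids)`` where ``assignment[i]`` is the cluster
    index of item ``i`` and ``medoids[k]`` is the item index of cluster ``k``'s
    medoid.
    """
    if not np.isfinite(lam) or lam <= 0:
        raise ValueError(f"lambda must be positive and finite, got {lam}")
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if np.any(D < 0):
        raise ValueError("dissimilarity entries must be non-negative")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("dissimilarity diagonal must be zero")
    n = D.shape[0]
    if n == 0:
        return [], []

    medoids: list[int] = []
    assign = np.full(n, -1, dtype=int)

    for _pass in range(MAX_PASSES):
        changed = False
        for i in range(n):
            if medoids:
                d = D[i, medoids]
                j = int(np.argmin(d))
                if d[j] > lam:
                    medoids.append(i)
                    j = len(medoids) - 1
            else:
                medoids.append(i)
                j = 0
            if assign[i] != j:
                assign[i] = j
                changed = True
        # recompute medoids; drop empty clusters
        new_medoids = []
        remap = {}
        for k in range(len(medoids)):
            idx = np.nonzero(assign == k)[0]
            if idx.size:
                sums = D[np.ix_(idx, idx)].sum(axis=1)
                med = int(idx[int(np.argmin(sums))])  # ties -> lowest index
                remap[k] = len(new_medoids)
                new_medoids.append(med)
        assign = np.asarray([remap[a] for a in assign])
        medoids = new_medoids
        if not changed:
            break
    else:
        logger.warning(
            "dp_means_medoid did not converge in %d passes (n=%d, lam=%g)",
            MAX_PASSES, n, lam,
        )
    return [int(a) for a in assign], [int(m) for m in medoids]


def heavy_atom_rmsd(a, b) -> float:
    """RMSD between two conformations of the same residue, paired by atom name.

    Structures are assumed pre-superposed, so no re-fitting is done.  Atoms
    present in only one conformation are excluded from the pairing.
    """
    if a.identity[3] != b.identity[3]:
        raise ValueError(
            f"residue name mismatch: {a.identity[3]} vs {b.identity[3]}"
        )
    pos_a = {atom.name: atom.coords for atom in a.atoms}
    pos_b = {atom.name: atom.coords for atom in b.atoms}
    common = sorted(pos_a.keys() & pos_b.keys())
    if not common:
        raise ValueError(
            f"no shared atom names between conformations of {a.identity}"
        )
    pa = np.asarray([pos_a[nm] for nm in common], dtype=float)
    pb = np.asarray([pos_b[nm] for nm in common], dtype=float)
    return float(np.sqrt(((pa - pb) ** 2).sum(axis=1).mean()))
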