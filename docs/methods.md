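# Methods

## The clustering model

All five analyses (waters, pharmacophores, fragments, residue conformations,
ligand sites) use one clustering primitive: a hard, threshold-driven DP-means.
The classical formulation penalises new clusters through a λ² term added to
the k-means objective; here λ is instead defined directly as the maximum
distance allowed between a member and its cluster centre, and the algorithm
enforces that definition operationally — a point farther than λ from every
current centre spawns a new singleton cluster at its own position. This
threshold semantics is what makes λ physically interpretable (e.g. "two
waters more than 1.5 Å from a common centre are different water sites") and
is the contract all downstream tables rely on.

Algorithmic details, all chosen for determinism:

* Points are visited in a fixed order (sorted by model id, then feature kind,
  then source-atom indices) on every pass.
* The first pass starts with zero clusters, so the first point always spawns.
  Seeding with the global mean instead would violate the λ contract on the
  first pass for spread-out data.
* Ties (equidistant centres, tied medoids, tied occupancies in altloc
  resolution) break toward the lowest index / lexicographically smallest key.
* Convergence is the first full pass with no assignment change; at that point
  centres are reproduced by their own memberships, so every member is within
  λ of its centre. A cap of 100 passes guards against pathological
  oscillation (a warning is logged and the current assignment accepted; in
  practice the fixed point is reached within a handful of passes).
* Empty clusters are dropped after each pass; output clusters are ranked by
  size (ties by first-member input order), waters re-ranked by conservation.

The residue variant runs the same pass structure on a precomputed
dissimilarity matrix (heavy-atom RMSD between like-numbered residues, paired
by atom name, no re-superposition) with the medoid — the member minimising
the within-cluster dissimilarity sum — in place of the mean. A mean is not
available because only pairwise distances are defined.

Conservation counts distinct contributing models, not points: a model
contributing two waters to one cluster counts once. Within a binding-site
analysis the denominator is the number of site models, so analysing a site of
the full ensemble coincides exactly with analysing the sub-ensemble of that
site's models (this also fixes the semantics of per-site water conservation
when a target has allosteric binders).

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| λ water | 1.5 | Å | water-site clustering |
| λ pharmacophore | 2.0 | Å | per-kind feature clustering |
| λ fragment | 2.0 | Å | fragment-centroid clustering |
| λ residue | 2.5 | Å | RMSD/medoid clustering |
| λ ligand | 5.0 | Å | binding-site assignment |
| water contact | 1.5 | Å | water cluster must sit this close to a site ligand |
| residue contact | 5.0 | Å | residue must approach a site ligand this closely |
| min water conservation | 0.0 | fraction | reporting floor (strictly greater-than); typical interactive choices are 0.85 or 0.50 |
| Butina distance | 0.4 | Tanimoto distance | compound ordering |

The λ defaults are the values validated in the field for diverse targets;
all are exposed as CLI flags rather than requiring source edits. The
conservation floor defaults to 0 — everything is reported and the >85 % or
>50 % views are presentation-level filters.

## Ligand chemistry

Crystallographic ligands carry no bond orders, so connectivity is inferred
from interatomic distances (sum of covalent radii + 0.45 Å tolerance; PDB
files often lack CONECT records) and matched as a graph against the
single-bond skeleton of the manifest SMILES, which the user supplies with
tautomer and charge state already assigned. Bond orders, aromaticity and
formal charges are transferred from the template; coordinates are preserved
bit-exactly. Element-multiset comparison selects the ligand hetero group in
the chain and rejects ambiguous files (two copies of the ligand in one chain)
rather than guessing.

Pharmacophore kinds and their SMARTS: donor
`[$([N;!H0;v3,v4&+1]),$([O,S;H1;+0]),n&H1&+0]`; acceptor (standard composite
O/S/N/aromatic rule); halogen `[F,Cl,Br,I]`; ring-methyl `[CH3;!$(C=*)]-[R]`
(methyl on any ring, aromatic or not — configurable reading of "ring
methyl"); hydrophobe `[CX4H3,CX4H2;$([#6]~[#6])]` restricted to carbons with
exactly one heavy neighbour, i.e. singly substituted non-polar carbons;
aromatic features sit at the centroid of each aromatic SSSR ring. Matches
are de-duplicated within a kind by source-atom set, and an atom may carry
several kinds (a ring methyl is also a hydrophobe). Kinds never co-cluster.

Fragments follow matched-molecular-pair practice: every acyclic single bond
between heavy atoms is cut once (emitting both sides), and every unordered
pair of such bonds is cut simultaneously, emitting the core fragment that
carries both attachment points. Enumerating bond subsets this way gives, for
n-butane, six single-cut fragments and three double-cut cores (the two CH₂
positions and the central C₂H₄). Triple cuts are omitted: fragments feed
only spatial clustering, and double cuts already localise cores. A ligand
with no cuttable bond yields itself as a single fragment with zero
attachment points. Fragment clusters are computed and exported but no
ranking is built on them.

## The synthetic ensemble generator

Real multi-structure datasets cannot be bundled, so the generator emits
ensembles whose ground truth is known by construction: a rigid scaffold
(identical protein coordinates in every model, so superposition is exact), a
pocket with planted water sites occupied in an exactly-sized subset of
models, far-away decoy waters, one tyrosine flipping between two side-chain
conformations according to a per-model state list, and one ligand per model
placed by rigidly transforming a per-chemotype 3-D embedding
(translation-only per-model jitter; no conformer sampling).

The geometry is engineered so that recovery under the default λ values is
guaranteed, not merely likely: planted water sites sit > 3 Å apart and 0.8 Å
outside actual ligand atoms (so the 1.5 Å contact filter passes
deterministically — the first model of each chemotype is left unjittered);
water jitter is Gaussian with σ = 0.3 Å, clipped at 2σ, keeping every point
within λ/2 of its site; decoys stay ≥ 2·λ_water from planted sites and from
each other, so they form singleton clusters ranked below every planted site;
the rotamer flip moves seven side-chain atoms far enough for an
inter-rotamer RMSD of ≈ 7.47 Å, well beyond λ_residue. The default demo:
20 models, four water sites at conservations 1.00/0.90/0.60/0.30, a 6/14
rotamer split, and two chemotypes (phenol and 4-chlorotoluene) covering all
six pharmacophore kinds.

Because the stated conservations fix the absentee counts (0, 2, 8 and 14
models), no site can have exactly one absentee; the "ligand that uniquely
displaces a conserved water" motif is therefore realised as a designated
model (`m07`) that is absent from exactly one planted site — its displacement
row carries a single mark — while the second absentee of that site also
misses a less-conserved site.

What the generator does **not** emulate: crystallographic noise and
refinement artefacts, occupancy/B-factor variation, alternate
conformations, imperfect superposition, missing side-chain atoms, conformer
flexibility of ligands, correlated water networks. Passing the planted-truth
tests therefore demonstrates the correctness of the bookkeeping and the
clustering contracts on separable data, not robustness to borderline cases
where real features sit near the λ boundaries — there the output is a
deterministic but data-order-sensitive partition, which is inherent to
threshold clustering.

## Degenerate inputs and edge rules

* Alternate locations: per atom name, the highest-occupancy record wins;
  ties take the lexicographically smallest altloc character.
* Deuterium is treated as hydrogen and dropped; analyses are heavy-atom only.
* Waters are residues named HOH/WAT/DOD; only the oxygen position is used.
* Residue RMSD uses the intersection of atom names; conformations present in
  at most half of the models are excluded from the residue ranking with a
  logged note.
* A manifest row that fails to load skips that model with a warning; the run
  aborts only when no model loads.
* An empty manifest is a valid empty ensemble and produces empty tables.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
20-model demo ensemble, check the clustering fixed-point contract on seeded
random point sets (up to 500 points per instance, 100 instances per λ in the
suite), compare against a naive transcribed reference on instances up to 60
points, and validate the medoid variant against exhaustive partition search
on up to 8 items — sizes at which the exhaustive oracles are exact and the
whole run completes in well under the times a desk check allows.

## Known limitations

* Multi-residue (covalently linked or split) ligands and mmCIF input are not
  supported; one manifest row is one ligand-bound chain.
* No structure superposition is performed; inconsistent residue numbering
  across models silently fragments residue identities.
* λ selection is manual; no automatic scale selection is attempted.
* Threshold DP-means is order-dependent for data that is not well separated;
  the deterministic visit order makes results reproducible, not
  order-invariant, in that regime.
* Water displacement is defined purely as non-contribution of a model to a
  ligand-proximal cluster; no steric-overlap test is applied, so a model
  with a genuinely missing (unmodelled) water is indistinguishable from a
  true displacement.
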