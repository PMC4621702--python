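# plens — protein–ligand ensemble summarisation

Drug-discovery programmes routinely accumulate tens of crystal structures of
one protein target, each bound to a different ligand. Inspecting them a few
at a time in a generic viewer makes it easy to miss the trends that matter
for design: which water positions are conserved across the ensemble and which
ligands displace them, which binding-site residues flip between rotamers and
in response to which ligands, and which pharmacophoric features every ligand
shares (or conspicuously lacks). `plens` computes those answers as ranked,
per-ligand tables from a simple CSV manifest of pre-superposed
structures. It is aimed at structural biologists and computational chemists
doing structure-, fragment- and ensemble-based design.

## The core algorithm

Every analysis reduces to clustering with a single physically interpretable
distance parameter λ. `plens` uses a hard, threshold-driven DP-means
variant: points are visited in a deterministic order, and a point farther
than λ from every current cluster centre spawns a new cluster, otherwise it
joins its nearest centre; centres are recomputed as unweighted means after
each pass, and iteration stops at the first pass that changes no assignment.
At the fixed point every member lies within λ of its cluster centre, so λ is
exactly "the largest member-to-centre distance allowed" — no cluster count is
chosen in advance.

The defaults, in ångströms:

| feature              | λ   | metric                               |
|----------------------|-----|--------------------------------------|
| waters               | 1.5 | Euclidean, oxygen positions          |
| pharmacophores       | 2.0 | Euclidean, per kind                  |
| fragments            | 2.0 | Euclidean, fragment centroids        |
| residues             | 2.5 | all-against-all heavy-atom RMSD, medoid variant |
| ligands (sites)      | 5.0 | Euclidean, unweighted ligand centroids |

For residues only pairwise dissimilarities exist (heavy-atom RMSD between
like-numbered residues, no re-fitting — structures arrive pre-aligned), so
the cluster centre is replaced by the cluster medoid.

On top of the clusters, the summary products are:

* **sites** — ligand-centroid clusters; the most populated is the main site;
* **conserved waters** — clusters ranked by conservation (fraction of models
  contributing ≥ 1 water), filtered to those within 1.5 Å of a site ligand;
  the displacement matrix marks each (water, ligand) pair where the ligand's
  model contributes no water to the cluster;
* **pharmacophore presence** — per-kind grids (donor, acceptor, aromatic,
  hydrophobe, halogen, ring-methyl from SMARTS rules) with one column per
  ligand;
* **residue ranking** — residues within 5.0 Å of any site ligand, ordered by
  maximum pairwise RMSD, with per-ligand cluster assignments;
* **compound ordering** — Morgan (radius 2) fingerprints clustered with the
  Butina algorithm, for chemistry-aware column ordering.

## Worked example

The package ships a seeded synthetic-ensemble generator whose planted ground
truth exercises every analysis (see `docs/methods.md`). Running

```
plens demo --out demo --seed 17
```

writes the manifest, twenty PDB files and the analysis into `demo/`. The
ranked water table (`demo/results/waters.csv`) begins

```
rank,x,y,z,size,n_models,conservation
0,1.5972,6.6028,0.0668,20,20,1.0
1,1.2308,14.1894,0.0136,18,18,0.9
2,3.4793,11.4588,-0.0575,12,12,0.6
3,-0.2228,9.3507,-0.0862,6,6,0.3
```

— four pocket waters conserved in 100 %, 90 %, 60 % and 30 % of the twenty
models, followed by singleton bulk waters at 5 %. The displacement matrix
(`water_displacement.csv`) shows ligand `m07` as the one compound whose only
missing water is the second most conserved one — the planted analogue of a
ligand that uniquely displaces an otherwise-kept structural water:

```
rank,conservation,m00,...,m07,...
1,0.9,0,0,0,0,0,0,0,1,0,0,0,0,0,1,0,0,0,0,0,0
```

and the residue ranking (`residues.csv`) puts the bi-rotameric pocket
tyrosine first, split into its two planted conformational clusters:

```
chain,resseq,icode,resname,max_rmsd,n_clusters,cluster_sizes
A,6,,TYR,7.466146,2,14;6
A,12,,SER,0.0,1,20
```

To analyse your own target, provide a manifest with required columns
`pdb_path` and `smiles` (optional `compound_id`, `model_id`, `chain`; other
columns pass through) and run

```
plens run --manifest ensemble.csv --out results/ [--lam-water 1.5 ...]
```

All outputs are plain CSV plus one `summary.json` carrying the full bundle
and its provenance (λ values, cutoffs, version, input checksums).
Observations can be captured and shared as content-addressed records with
`plens annotate`, and `plens report` renders a bundle as one static HTML
page.

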