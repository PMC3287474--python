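# conspocket

Protein–ligand binding-site prediction that combines surface geometry
with residue conservation.

Most ligand-binding sites sit in concave clefts on the protein surface,
and the residues lining them tend to be evolutionarily conserved.
`conspocket` turns those two observations into a prediction pipeline for
structural biologists who have a structure (PDB) and a per-residue
conservation profile (ConSurf-style 1–9 grades) and want a ranked list
of candidate binding sites — plus a self-contained synthetic benchmark
for validating the whole pipeline without any external downloads.

## Method

For a structure with heavy atoms *A*:

1. **Cleft detection.** Per-atom solvent-accessible surface area (SASA)
   is computed with the Shrake–Rupley method (probe 1.4 Å,
   deterministic 960-point golden-spiral lattice). The surface set
   **S** = atoms with SASA > 1 Å². Qhull gives the convex hull of all
   atom centers; the hull-vertex set is expanded by adding every atom
   within 6.5 Å of a hull vertex, giving the convex "rind" **Q**. The
   cleft set is **S ∖ Q** — exposed atoms that sit in concavities.
2. **Conservation filtering.** Residues with conservation grade ≥ 7 on
   the 1–9 scale (9 = maximally conserved) contribute their atoms to
   the conserved set **C**. The potential set is **P = (S ∖ Q) ∩ C**.
3. **Clustering.** Atoms of **P** are grouped by single-linkage
   clustering cut at 4.5 Å (connected components of the ≤ 4.5 Å contact
   graph). Cluster centers within 8 Å are merged iteratively, each
   merged center recomputed as the mean over all member atoms, until
   every pair of pocket centers is more than 8 Å apart.
4. **Ranking.** Pockets are ranked by the sum of conservation grades
   over their distinct member residues (default), or by an estimated
   pocket volume (union of probe-inflated atom spheres on a 1 Å voxel
   grid).

Evaluation uses the standard geometric-center criterion: a predicted
pocket is a hit if its center lies within 4 Å (inclusive) of any atom of
a bound ligand; TOP-N success is the fraction of structures with a hit
among the N best-ranked pockets.

Everything is deterministic — there is no RNG anywhere in the prediction
path, and pocket centers are exactly equivariant under rotation and
translation of the input (no grid orientation artifacts).

## Worked example

`examples/predict_single_structure.py` builds a synthetic pseudo-protein
with one planted, conservation-enriched pocket and a ligand, then runs
the full pipeline through the public file readers:

```
atom sets: |S|=476 |Q|=964 |cleft|=7 |C|=353 |P|=6
rank 1: conservation score 40, volume 533 A^3, 5 atoms, center 1.95 A from the planted ligand centroid
```

Of 476 solvent-exposed atoms, only 7 lie outside the expanded convex
hull (the cleft); 6 of those belong to conserved residues and cluster
into a single pocket whose center lands 1.95 Å from the planted ligand —
well inside the 4 Å hit radius. The other examples benchmark a suite
(`benchmark_synthetic_suite.py`) and sweep the expansion distance ×
conservation cutoff grid (`sweep_parameters.py`).

The same functionality is available from the shell:

```bash
conspocket fixtures -n 50 --seed 1 --out-dir suite/
conspocket predict suite/fx000.pdb suite/fx000_grades.tsv --out-dir out/
conspocket eval suite/manifest.tsv --out-csv bench.csv
conspocket sweep suite/manifest.tsv --expand-dists 5.5,6.5,7.5 --cutoffs none,7,8
```

`predict` writes a ranked TSV/JSON report plus a PDB of PKT pseudo-atoms
(one HETATM per pocket center, score in the B-factor column) viewable in
any molecular viewer; every report embeds the full parameter set.

## Scope

`conspocket` consumes precomputed conservation grades (ConSurf-DB grades
tables or a plain chain/residue/grade TSV); it does not compute
conservation from alignments, fetch anything over the network, parse
mmCIF, or handle NMR ensembles (only the first MODEL of a file is used).
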