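# Methods

This note documents the model behind `conspocket`, the parameters that
matter, the numerical choices, what the synthetic benchmark does and
does not demonstrate, and the design decisions taken where the problem
left room.

## Model and assumptions

The pipeline rests on two assumptions: (i) ligands bind in concave
depressions of the protein surface, so binding-site atoms are solvent
exposed but far from the structure's convex hull; (ii) binding-site
residues are under purifying selection, so they carry high conservation
grades. Neither assumption is universal — shallow or cryptic sites
violate (i), and some binding sites (e.g. species-specific allosteric
pockets) violate (ii) — and the pipeline inherits those failure modes.

The prediction is a pure composition of set operations and clustering on
heavy-atom coordinates; hydrogens are dropped on input (crystal
structures rarely resolve them, and the radius set is a united-atom
set), waters are always removed, and alternate conformations are
resolved to the highest-occupancy conformer before anything else runs.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `sasa_probe` | 1.4 | Å | water-sized probe for SASA |
| `sasa_points` | 960 | – | golden-spiral test points per atom |
| `sasa_threshold` | 1.0 | Å² | strict `>` cutoff defining the surface set S |
| `expand_dist` | 6.5 | Å | hull expansion defining Q (inclusive `≤` to hull vertices) |
| `conservation_cutoff` | 7 | grade | residues with grade `≥` cutoff form C; `None` skips the filter |
| `atom_link_dist` | 4.5 | Å | single-linkage cut for clustering P |
| `center_merge_dist` | 8.0 | Å | iterated merging of cluster centers |
| `min_pocket_atoms` | 3 | – | discard smaller clusters as noise |
| `hit_cutoff` | 4.0 | Å | inclusive center-to-ligand-atom hit criterion |
| `volume_grid` | 1.0 | Å | voxel step for the volume estimate |

The cleft/conservation/merge/hit values (6.5 Å, cutoff 7, 8 Å, 4 Å) are
the established defaults of this family of geometry-plus-conservation
predictors. The remaining values are this implementation's choices:
1.4 Å is the conventional water probe; 960 points keep the worst-case
per-atom area quantum at ~0.14 Å², far below the 1 Å² threshold; 4.5 Å
is a heavy-atom contact distance with slack — the atom-level linkage
cutoff is genuinely underdetermined by the method description, so it is
exposed as a flag and covered by the sweep harness; `min_pocket_atoms=3`
suppresses single-atom noise pockets.

The conservation grade threshold reads `≥`, the SASA threshold `>`
("over"), the expansion and hit distances `≤` ("within"). Grades are
treated as ordinal; the only arithmetic on them is a within-structure
sum, since ConSurf color scales are not comparable across protein
families in absolute terms.

## Numerical choices

**SASA.** Shrake–Rupley with a golden-spiral (Fibonacci) lattice that
depends only on the point count — no RNG, so results are bit-stable
across runs and machines. Neighbor search uses a k-d tree restricted to
atoms within `r_i + r_j + 2·probe`; this is exactly equivalent to the
all-pairs computation. The space-fixed lattice makes per-atom areas
exactly translation invariant and rotation invariant to within ~1% at
960 points; total area errors against closed-form sphere and two-sphere
cap formulas measure below 0.1% and ~0.5% respectively. Radii are the
Chothia united heavy-atom set (C 1.87, N 1.65, O 1.40, S 1.85 Å),
default 1.80 Å for anything else.

**Convex hull and expansion.** Hull vertices come from Qhull via
`scipy.spatial.ConvexHull`; degenerate inputs (< 4 atoms, coplanar)
raise a geometry error rather than guessing. Expansion measures
center-to-center distance to hull *vertices* only — whether the original
formulation expanded from vertices or whole facets is not decidable; the
vertex reading matches "origin convex atoms" and is what is tested.

**Clustering.** "Simple hierarchical clustering at a spatial distance"
is realized as a single-linkage dendrogram cut, implemented as connected
components of the ≤ `link_dist` contact graph (provably the same
partition; an all-pairs union-find oracle verifies this in the tests).
Single linkage is the only standard linkage for which a plain distance
cutoff fully specifies the clustering. Center merging is iterated to a
fixpoint — each pass single-links centers within 8 Å, unions their
members and recomputes centers as member-atom means — so the output
guarantee "all pocket centers > 8 Å apart" is testable. Pre-ranking
order is (size descending, smallest member serial) for determinism.

**Volume.** The pocket "space volume" is defined here as the volume of
the union of probe-inflated member-atom spheres (r_vdw + 1.4 Å), counted
on a voxel grid anchored at global multiples of the step, which makes it
deterministic, monotone in pocket size, and translation-consistent to
one voxel shell. This is a reimplementation proxy: no operational volume
definition survives in the method description, so volume-ranked figures
are comparable within this package but not to other tools' volumes.

**Conservation score.** Sum of grades over *distinct* member residues
(atom multiplicity is deliberately ignored). Sum, not mean: re-ranking
precedents and the contrast with size-based ranking imply that large
*and* conserved should beat small and conserved; the sum captures both
signals, and a mean option remains behind a flag.

**Degenerate inputs.** An empty potential set is a result ("no pocket
found", distinct exit code in the CLI), not an error. Unmapped residues
count as grade 0 with a coverage warning above 10% unmapped — ConSurf
coverage gaps are common and should be visible, not fatal.

## The synthetic benchmark

`conspocket.fixtures` generates pseudo-proteins: carbon pseudo-atoms
tiling concentric golden-spiral shells at 2.6 Å spacing (a jittered
solid ball, roughly protein-like packing density), with binding pockets
carved as spherical bites (mouth radius ~0.45–0.52 of the shell radius,
depth 9–10.5 Å — druggable-pocket proportions) and a 3–8-atom ligand
nestled at each cavity bottom. Residues are singletons by default;
pocket-lining residues draw a grade ≥ 7 with probability 0.9, everything
else from a mildly bottom-heavy background distribution in which ~25% of
residues still reach the conserved range. Each suite member also carries
one *decoy* cleft — as large as a real pocket, but unconserved and
ligand-free — modeling the non-functional depressions real surfaces
have; without decoys the conservation filter could only remove signal,
and comparing filtered vs unfiltered runs would be meaningless.

Geometric soundness is enforced by construction: pocket directions come
from a randomly rotated tetrahedral template (109.5° pairwise
separation), which prevents two failure artifacts of deep pockets on a
ball — single-linkage bridging of two linings near the core, and fusion
of two pocket centers by the 8 Å merge step. Pocket count scales with
shell radius (one pocket below 15 Å, up to three at 18 Å) for the same
reason. All randomness flows from one seed; per-fixture seeds derive by
`(seed·1000 + index) mod 2³¹`, so any fixture regenerates in isolation,
and identical specs produce byte-identical PDB files.

On 50-structure suites the default pipeline recovers the planted site at
TOP-1 in ≥ 90% of structures (98% at seed 1; 92–100% across other seeds
checked), disabling the conservation filter never helps (62–90%), and a
pocket-free convex control yields zero predictions.

What passing these tests shows: the set algebra, clustering, ranking and
evaluation machinery do exactly what they claim, end to end, on inputs
whose ground truth is known by construction. What it does not show:
performance on real proteins — the fixtures have idealized concavity,
no chemistry, no grade noise structure (real ConSurf grades correlate
along sequence and bury conserved cores), and single-atom residues.
Real-structure success rates must be measured on real benchmark sets
with real conservation profiles.

## Problem sizes

The test suite and the acceptance script use 50-structure suites
(~700–1700 atoms per structure), 20-instance brute-force oracle checks
(200-point hulls, 100-point clusterings), and a 3 × 3 parameter sweep —
sizes chosen so the full validation runs in minutes on a single CPU
while every oracle remains an exact, independent computation.

## Known limitations

- The atom-level linkage distance (4.5 Å) is a free parameter; very
  large open grooves can fragment or chain depending on it.
- Pockets deeper than the hull-expansion distance are required for
  detection; shallow surface sites (depth ≲ 6.5 Å) are invisible by
  construction, as in any hull-difference method.
- Conservation ranking needs grade coverage of the chains in question;
  author-vs-PDB chain naming mismatches must be fixed via `--chain-map`.
- HETATM entities other than waters are all treated as ligands for
  evaluation; crystallization additives should be excluded explicitly
  (`exclude_ligands`) when that matters.
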