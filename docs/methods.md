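# Methods

This note records how `rnassess` computes each quantity, the assumptions
behind the synthetic test substrate, and the design decisions taken where
the choices were genuinely open.

## Structure model and correspondence

PDB text is parsed into ordered chains of nucleotide residues. Policy,
applied record by record: the first MODEL block is used unless another
index is requested (blind-prediction submissions are single-model);
alternate locations resolve to the highest occupancy, ties to the first
altloc encountered; HETATM nucleotides (pseudouridine and other modified
bases) are mapped to their parent base through a small extensible table and
unknown codes fail loudly rather than dropping residues silently; waters
and free ions are always discarded; other ligands are discarded by default
with an opt-in switch that keeps them outside all metrics (comparisons are
RNA-only even when the crystal carries a cofactor). Old-dialect primed
names (`O3*`) are normalised to `O3'`. Hydrogens are retained when present
and their presence is recorded, because the clash score depends on it.

Every metric operates on an explicit 1:1 nucleotide mapping. The default
mode aligns each chain pair globally (match +2, mismatch −1, gap open −5,
gap extend −1) and pairs aligned columns *including mismatches*, with a
warning; engineered constructs whose crystallised sequence differs from
the modelling target (e.g. a re-engineered tRNA acceptor stem) would break
pure residue-number matching, which remains available as `by-number` and
`by-index`. Unmatched residues are listed and counted in reports, never
silently dropped; metrics use paired residues only.

## Superposition and RMSD

Least-squares rigid superposition by the SVD form of the Kabsch algorithm;
the determinant of the rotation is forced to +1, so reflections are never
returned; degenerate (rank < 2) point sets are an error. RMSD is computed
over every heavy atom shared by both residues of each pair, in
deterministic order. The atom subset is exposed (`all-heavy`, `backbone`,
`c1-prime`, `phosphate`) because published comparisons do not always state
their convention; `all-heavy` is the default. No outlier rejection or
partial superposition is performed — local quality is the Deformation
Profile's job.

## Interaction annotation

Base pairs and stacks are detected geometrically from a per-base reference
frame: origin at the ring-atom centroid, z along the best-fit plane normal
(handedness fixed by ring traversal so the frame co-rotates with the
structure), x toward the glycosidic nitrogen.

A base pair requires, with default thresholds: at least two
hydrogen-bond-range donor/acceptor contacts ≤ 3.5 Å between edge atoms (or
one ≤ 3.2 Å), base planes within 65°, each origin within 2.5 Å of the
partner plane, and origins within 12 Å. The interacting edge per base
(Watson–Crick / Hoogsteen / Sugar) is the one whose atoms contribute the
most contacts, ties resolved W > H > S; orientation is cis when the
pseudo-dihedral C1'(i)–N(i)–N(j)–C1'(j) has magnitude ≤ 90°. A pair is
canonical when cis, both edges W, and the combination is AU, GC or GU —
the wobble pair counts on the Watson–Crick side by default, with a switch
for the stricter convention. Sequence neighbours (i, i+1) are eligible for
stacking only. Stacking requires origins within 5.5 Å, normals within 30°
(or beyond 150°), and the centre–centre vector within 40° of a normal.

These thresholds are conventional values for geometric annotation, kept in
one configuration block (`AnnotationConfig`) so the detector can be
calibrated against an external annotator when exact agreement with a
particular tool's conventions is needed. INF values are therefore
reproducible within this package's annotation convention, not guaranteed
to match any specific third-party annotator digit for digit.

## INF, DI, DP

`INF = sqrt(PPV × STY)` per category. Matching is by residue pair; the
category of a matched base pair (canonical vs non-WC) is taken from the
reference annotation, while unmatched model pairs fall into the model's own
category; a strict switch additionally requires identical edges and
orientation. Interactions touching residues outside the correspondence
count as FN (reference side) or FP (model side). An empty reference
category leaves INF undefined and is reported NA — never 0, which would
mean "everything predicted was wrong". DI divides RMSD by the pooled
(all-category) INF, the convention of the metric's defining publication;
per-category DI values are also reported.

The Deformation Profile anchors a superposition on each paired nucleotide
in turn (all its shared heavy atoms; a ±w window is available but the
default is single-residue anchoring, with multi-scale structure recovered
by domain aggregation) and records the mean distance of every other
nucleotide under that fit. Anchors with fewer than three usable atoms
produce NaN rows and columns. Domains are supplied as (name, chain, start,
end) ranges; min/mean/max are taken over the (anchor ∈ domain, measured ∈
domain) block.

## Torsions and MCQ

Eight angular slots per nucleotide: α (O3'(i−1)–P–O5'–C5'), β, γ, δ, ε, ζ
with the standard atom quadruples, χ (O4'–C1'–N9–C4 for purines,
O4'–C1'–N1–C2 for pyrimidines), and the pseudorotation phase P from the
five endocyclic torsions ν0–ν4 via
`tan P = ((ν4+ν1) − (ν3+ν0)) / (2 ν2 (sin 36° + sin 72°))`, the quadrant
fixed by the sign of ν2 and P reported in [0°, 360°). A slot is defined iff
all constituent atoms are present: chain 5'-termini lack α and β, 3'-termini
lack ε and ζ. Dihedrals use the atan2 formulation; degenerate geometry
(collinear triples) yields an undefined slot rather than a number.

MCQ-global is the circular mean — atan2 of averaged sines and cosines — of
the per-slot circular differences over slots defined on both sides; since
differences lie in [0°, 180°], so does the mean. Slots defined on one side
only are excluded and counted as a completeness penalty, with no value
imputation. An arithmetic-mean aggregation is provided as an option because
"mean dissimilarity" admits both readings; the circular mean is the default
to match the reference MCQ implementation. P is compared as one slot
alongside the seven dihedrals. Reports carry the interpretation bands for
large RNAs (< 15° similar, > 45° dissimilar). MCQ-local emits raw per-slot
differences.

## Clash score

A clash is a non-bonded pair with van der Waals overlap
`(r_a + r_b) − d ≥ 0.4 Å` (radii: C 1.70, N 1.55, O 1.52, P 1.80,
H 1.20 Å). Excluded: pairs within three covalent bonds, walking a
per-nucleotide bond table plus the O3'(i)–P(i+1) linkage (hydrogens bond to
their nearest heavy atom); and N/O pairs at d ≥ 2.6 Å, treated as hydrogen
bonds (configurable off). The score is 1000 × clashes / atoms over all
retained atoms. Neighbour search uses a KD-tree whose output is
structure-independent of any spatial partitioning parameter; a brute-force
all-pairs route is retained and must agree exactly. Full MolProbity-style
scoring places hydrogens and scores probe dots; this implementation scores
the atoms present, so agreement with published clash values on
hydrogen-free crystallographic files is approximate by design, and the
hydrogen status of every model is carried in its report. Exactly-boundary
overlaps are kept (comparison tolerance 1e-9) so the 0.4 Å definition is
inclusive.

## Synthetic decoys

The generator emulates the assessment setting — a known reference and
perturbed "predictions" with known ground truth — not RNA folding.

An ideal A-form duplex is built from a template nucleotide propagated by
helical symmetry (twist 32.7°, rise 2.81 Å — standard A-form fibre values).
The template is generated deterministically in code rather than shipped as
a coordinate file: base heavy atoms in their standard planar reference
frames (the Watson–Crick partner is the 180° rotation about the pair
x-axis), a C3'-endo ribose ring constructed as a puckered pentagon
(circumradius 1.24 Å, amplitude 0.38 Å, ring phase set so the
pseudorotation phase computes to ~16°), exocyclic substituents on ideal
tetrahedral slots, χ spun to −160° (anti), and the phosphate placed on the
intersection of the two bonding spheres so that both P–O5' (1.60 Å) and
O3'(i)–P(i+1) (1.59 Å) close exactly on *both* strands (the strand-2
nucleotide is the x-flip of the strand-1 template, which maps the helical
step to its inverse). The pair frame sits 5.0 Å off the helix axis with 24°
inclination; these two values and the ring phase were fixed once so the
construction satisfies its own validity contract — clash-free, one
canonical WC pair per position, adjacent residues stacked, all non-terminal
torsions defined — and are not tuning knobs for the metrics.

Perturbations: `noise` adds i.i.d. zero-mean Gaussian displacement per
coordinate (expected all-atom RMSD σ√3, the basis of the noise-recovery
checks); `rigid-domain` applies a rotation/translation to a residue range,
leaving all internal coordinates of both bodies intact; `bond-rotation`
rotates everything distal to one covalent bond, changing exactly the
torsion centred on it (in-ring bonds are rejected). Fixed seeds give
byte-identical PDB output.

What the fixtures do **not** emulate: loops, junctions, non-WC pairs,
tertiary contacts, experimental coordinate error structure, or hydrogens.
Passing tests therefore demonstrate the correctness of the metric
machinery on known ground truth, not the behaviour of the annotator on
irregular real-world motifs; for that, the threshold block is the
calibration surface.

## Numerical choices and limitations

* Output files print 4 decimals; PDB coordinates 3 decimals (≈ 0.0005 Å
  identity RMSD after a write/read round trip).
* Ranking: RMSD ascending, ties by DI then label; ranks are a permutation
  of 1..n over successfully scored models; failed models are reported as
  failed rows and the run continues (CLI exit code 3 on partial success).
* Problem sizes in the self-checks: identity and rigid-motion suites use a
  12-bp duplex (~510 atoms); noise recovery uses a 48-bp duplex
  (~2037 atoms) with 10 seeds per σ ∈ {0.1, 0.5, 1.0}; these sizes make the
  sampling error of the σ√3 comparison well under the 5% band.
* Validation against published per-model tables of real blind-prediction
  rounds requires the deposited coordinate sets, which are not bundled;
  with those inputs the pipeline runs unchanged via `rnassess assess`.
* mmCIF, assembly expansion, base–phosphate hydrogen-bond classes, A-minor
  typing, η/θ pseudo-torsions, suite rotamers, and hydrogen placement are
  out of scope.
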