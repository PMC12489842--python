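# Methods

## Scope and model of a "productive" complex

The package operationalizes a geometric definition of a productive
NTPDase–nucleotide complex. A complex passes the checklist when, in the
frame obtained by superposing its protein onto a reference complex:

1. the metal cofactor is **bidentately** coordinated — at least two
   substrate phosphate oxygens belonging to *distinct* phosphate groups
   (α/β/γ, decided by atom-name suffix) lie inside the coordination window;
2. the **DXG aspartates** of ACR1 and ACR4 flank the cofactor
   symmetrically, measured from each aspartate Cγ to the ion;
3. the **six conserved waters** are present: four in the cofactor's first
   hydration shell, one catalytic water near the terminal phosphorus, one
   more near the terminal phosphate oxygens;
4. the nucleoside geometry is canonical: **anti** glycosidic configuration
   and a furanose pucker in one of the two named classes (C2′-endo in the
   rat-enzyme reference complexes, C3′-endo predominating elsewhere).

The binding-mode classifier distinguishes the *canonical* linear-like pose
(all-common-atom substrate RMSD against the phosphate-count-matched
reference within threshold AND bidentate coordination), the *alternative*
pose (phosphate/ribose subset still aligned while the nucleobase plane is
rotated by more than 45°), and *nonproductive* (everything else).

## Superposition and RMSD conventions

Proteins are paired by global sequence alignment (BLOSUM62, gap open 10,
extend 0.5 — the defaults of the classic interactive alignment tools this
mirrors) over polymer residues carrying Cα atoms; the traceback of the
underlying aligner is deterministic. The rigid fit is the Kabsch SVD
solution with reflections excluded; iterative refinement drops residue
pairs deviating by more than the rejection cutoff (default 2.0 Å) and
refits, up to 5 cycles or until stable, mimicking the behavior of the
*align* tools used interactively in structural biology. RMSD is reported
over retained pairs and is non-increasing across cycles.

Substrate RMSD deliberately performs **no refitting**: after the proteins
are superposed, it is the plain coordinate RMSD over an explicit atom-name
correspondence. This measures how far the ligand sits from the reference
ligand *within the binding site*, which is the published convention the
package reproduces. Atom maps come in three subsets: `all_common`
(phosphate tail + ribose + shared base atoms), `phosphate_ribose`, and
`nucleobase`. The imido bridge of an analog is treated as equivalent to
the bridging oxygen it replaces (N3B ≈ O3B, N3A ≈ O3A), so analog and
true substrate compare transparently. Across base classes
(purine vs pyrimidine) the identically named base atoms are not chemically
equivalent positions, so `all_common` contributes no base atoms there and
reduces to the tail + ribose; this choice is configurable by picking the
subset explicitly.

## Ligand operations

**Analog conversion** changes exactly one atom record — the bridging
nitrogen's name and element — and nothing else; coordinates are
bit-identical and repeating the conversion is an error rather than a
silent no-op.

**Hybrid diphosphates** (GDP, UDP) are assembled because no crystal
complex provides them directly: the base donor (GTP/UTP analog) is
rigid-fitted onto the ADP analog through a nucleobase correspondence, and
the product takes the ADP analog's sugar + phosphate coordinates exactly
plus the fitted base. Purine→purine fitting uses the nine shared ring
atoms plus C1′; pyrimidine→purine uses the glycosidic-geometry-preserving
triple N1→N9, C2→C4, C6→C8 plus C1′→C1′, chosen because the glycosidic
bond geometry is the physically meaningful constraint. A base fit worse
than 1.0 Å RMSD over the mapped atoms, or a glycosidic C1′–N distance
outside 1.2–1.8 Å in the product, is an error.

**Conserved waters** are selected deterministically: shell = water oxygens
within the shell cutoff of the cofactor (3.2 Å default, the upper bound of
Ca²⁺–O coordination); catalytic = nearest non-shell water to the terminal
phosphorus — a stated approximation of the in-line attacking position, the
crystals' own annotations not being machine-readable; terminal = nearest
remaining water within 4.0 Å of the terminal phosphate oxygens. Ties break
by distance then lowest serial, making the selection invariant under water
record order. Fewer than four shell waters yields a warning-carrying
partial result, never silent success.

**Grafting** maps substrate, cofactor and waters by the protein
superposition transform and inserts them as a dedicated chain (default
`X`) with fresh serials; the bundle moves as one rigid body, so all
intra-bundle distances are preserved to numerical precision, and the
provenance (source, transform, superposition RMSD, component inventory)
is recorded alongside. Clashes in the grafted result are reported in the
validation output, never dropped.

## Nucleoside geometry

The pseudorotation phase is computed as the exact least-squares fit of the
cosine model νⱼ = τₘ·cos(P + 144°(j−2)) to the five endocyclic torsions:
with cⱼ = cos 144°(j−2), sⱼ = sin 144°(j−2), the normal equations give
a = (2/5)Σνⱼcⱼ, b = −(2/5)Σνⱼsⱼ, P = atan2(b, a), τₘ = √(a² + b²). On
torsions exactly following the model this coincides with the classic
two-term phase formula; on real (slightly anharmonic) rings it is the
best-fit phase and agrees with a brute-force grid search to the grid
resolution, which the property suite verifies at 0.01°. Class windows:
C3′-endo ⇔ P ∈ [0°, 36°), C2′-endo ⇔ P ∈ [144°, 180°), else "other" —
the standard nucleic-acid convention, the toolkit naming only the two
classes that occur in the reference material.

χ is the signed dihedral O4′–C1′–N9–C4 (purines) or O4′–C1′–N1–C2
(pyrimidines), anti ⇔ χ ∈ [90°, 180°] ∪ (−180°, −90°). The base-plane
angle is measured between least-squares ring planes (singular direction
of the centered ring coordinates, exocyclic substituents excluded) and
folded into [0°, 90°]; ring-plane angle was chosen over long-axis angle
as the less ambiguous reading of "approximately 90°" for the alternative
pose.

## Thresholds and defaults

| parameter | default | rationale |
|---|---|---|
| coordination window | 2.0–3.0 Å | canonical Ca²⁺–O coordination chemistry |
| shell cutoff | 3.2 Å | Ca²⁺–O first-shell upper bound |
| terminal-water cutoff | 4.0 Å | one water layer beyond the phosphate oxygens |
| DXG search radius | 6.0 Å | Cγ–ion distances cluster near 4.8 Å; 6 Å catches them without false positives; explicit residue override available for divergent isoforms |
| canonical RMSD threshold | 1.5 Å | separates the largest canonical exemplar (1.22 Å) from the alternative pose's tail fit (1.64 Å) |
| alternative tail threshold | 2.0 Å | the alternative pose's own tail RMSD (1.64 Å) exceeds the canonical threshold, so the alternative branch needs a more permissive bound; 2.0 Å is the conventional docking-quality bound |
| H-bond | d ≤ 3.5 Å, θ ≥ 120° | heavy-atom geometric criterion; the angle applies only when hydrogens exist (the crystal inputs carry none) |
| clash | d < 0.6 × Σ vdW | conservative hard-overlap factor |
| superposition | 5 cycles, 2.0 Å cutoff | the cited alignment tool's defaults, exposed as flags |

Altlocs resolve to the highest-occupancy conformer (ties: lexicographically
smallest indicator); only the first model of multi-model files is read;
asymmetric-unit coordinates are used as supplied (no assembly expansion);
hydrogens are kept if present but excluded from RMSD/distance work.
Superposition uses Cα atoms only and substrate RMSD heavy atoms only,
since sub-Å comparisons would otherwise hinge on invented hydrogen
positions.

## What the synthetic fixtures emulate — and what they do not

The fixture generator plants, exactly: the bidentate coordination
distances, the two DXG Cγ–ion distances (defaults 4.80/4.84 Å — the
productive-complex feature values), the four shell waters at 2.4 Å, the
catalytic and terminal waters, the requested pucker phase (±2°) and χ
(±2°), and arbitrary seeded rigid + Gaussian perturbations with the rigid
part as recoverable ground truth. The scaffold is a pair of short ideal
helices carrying Asp-x-Gly motifs with schematic backbones — a geometric
test vector, not a folded protein. Passing tests on fixtures therefore
demonstrates that the *measurements and transformations* are correct
(superposition, transplantation rigidity, checklist arithmetic,
classification logic), not that any particular real enzyme model is
accurate; conclusions about real complexes additionally require the
crystallographic inputs, which the acceptance checks consume when the
structure cache is populated.

## Numerical choices and degenerate inputs

Rigid fitting requires ≥ 3 non-collinear points (second singular value
< 1e-8 ⇒ geometry error); rejection that leaves < 3 pairs is a convergence
error reporting the last retained count. Proper rotations are enforced
(det = +1 within 1e-8). Plane fitting rejects collinear rings. Water/metal
recognition is format-level (component codes HOH/WAT/DOD; single-atom
residues with metallic elements), independent of any annotation tool.
Problem sizes in the automated runs (toy complexes of ~134 atoms, 25-seed
noise ensembles, 1,000-ring pucker checks) were chosen so every check
completes in seconds while the Monte-Carlo quantities are stable to well
inside their asserted bands.

## Known limitations

- No protonation, force-field typing, minimization or dynamics: the output
  is a starting structure for such refinement, and strained grafts are
  reported through the clash list rather than repaired.
- Cofactor chemistry is Ca²⁺-only; no ion substitution.
- The catalytic/terminal water distinction is a nearest-neighbor rule, an
  approximation where the crystals may reflect curated annotation.
- The ambiguous alternative-like pyrimidine pose seen in one solved
  complex is reported as geometry (tail RMSD, base angle) without
  asserting biological significance.
- π-stacking is not modeled; aromatic contacts surface only through the
  generic distance-based contact lists.
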