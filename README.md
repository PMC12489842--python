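# substrate-graft

Template-based construction and geometric validation of NTPDase–nucleotide
complexes.

## The problem

Ecto-nucleoside triphosphate diphosphohydrolases (NTPDases) hydrolyze NTPs
and NDPs to their monophosphates using a divalent metal cofactor, shaping
purinergic signaling. Their catalytic site — five apyrase conserved regions
(ACR1–5) — is strongly conserved, and the substrates of experimentally
solved productive complexes adopt a near-identical *canonical* pose: the
nucleoside in the **anti** configuration, phosphate tail and nucleobase in a
linear-like arrangement, the cofactor coordinated **bidentately** by
phosphate oxygens of two distinct phosphate groups, the DXG-motif
aspartates of ACR1/ACR4 placed symmetrically around the ion (Cγ–ion
distances near 4.80/4.84 Å), and six conserved waters (four in the ion's
first hydration shell, one catalytic, one near the terminal phosphate).

Docking routinely misses this pose. A more reliable route to modeled
complexes is to *transplant* the experimentally observed substrate —
together with the cofactor and conserved waters — from a solved complex
into a superposed target model, and then verify that the grafted complex
still satisfies the productive-site geometry. This package implements that
protocol end to end:

- **structures** — PDB/mmCIF I/O (via gemmi) with deterministic altloc
  resolution and category-aware atom selection, plus a cache-aware fetcher
  for PDB accessions;
- **superpose** — sequence-guided (BLOSUM62) pairing, Kabsch least-squares
  rigid fitting with iterative outlier rejection, and in-frame substrate
  RMSD over explicit atom maps (all-common / phosphate+ribose / nucleobase),
  with **no** ligand refitting: RMSD = √(Σᵢ‖xᵢ − yᵢ‖²/N) in the
  protein-aligned frame;
- **ligands** — component extraction, imido-analog → substrate conversion
  (N3β/N3α → O3β/O3α, coordinates untouched), GDP/UDP hybrid assembly
  (nucleobase of a triphosphate rigid-fitted onto the ADP analog's base,
  combined with the analog's sugar + phosphate tail), conserved-water
  selection, and rigid grafting with full provenance;
- **validate** — the productive checklist: bidentate coordination, DXG
  Cγ–cofactor distances, hydration-shell and catalytic/terminal water
  counts, hydrogen-bond and steric-clash contacts, ribose pseudorotation
  phase P and amplitude τₘ (least-squares fit of νⱼ = τₘ·cos(P + 144°(j−2))
  over the five endocyclic torsions), glycosidic torsion χ (anti/syn), and
  base-plane angle — then classifies the binding mode as *canonical*,
  *alternative* (tail aligned, base swung > 45°) or *nonproductive*;
- **fixtures** — fully offline synthetic complexes with planted ground
  truth: idealized nucleotides at any requested (P, χ), toy scaffolds with
  DXG motifs at exact planned distances, waters at planned positions, and
  seeded rigid/Gaussian perturbations.

## Worked example

Generate a synthetic productive complex, graft its substrate bundle onto
the bare protein, and validate:

```sh
$ substrate-graft fixtures --out fx
wrote complex.pdb, target.pdb, ground_truth.json -> fx

$ substrate-graft transfer --target fx/target.pdb --source fx/complex.pdb --out grafted.pdb
grafted {'substrate': 'ATP', 'cofactor': 'CA', 'n_waters': 6} -> grafted.pdb [mode: canonical]

$ substrate-graft validate grafted.pdb --reference fx/complex.pdb --report report.json
mode                canonical
substrate RMSD (A)  0.000
tail RMSD (A)       0.000
bidentate           True
DXG distances (A)   4.80 / 4.84
shell waters        4
pucker              C2'-endo (P=162.0)
chi                 anti (-120.0)
clashes             0
```

Reading the table: the transplanted nucleotide sits exactly on the
reference pose (RMSD 0 in the protein-aligned frame, no refit), the Ca²⁺
is coordinated by phosphate oxygens from two distinct groups, the two
DXG aspartate Cγ atoms sit at the planted 4.80/4.84 Å, the four
first-shell waters were carried over, the ribose is C2′-endo
(pseudorotation phase 162°) and the nucleoside is anti (χ = −120°) — the
complete productive-complex signature. The `transfer` step also converted
the non-hydrolyzable β,γ-imido analog into true ATP (bridging N3B → O3B)
before insertion. A complex failing the checklist exits nonzero with
`mode: nonproductive`.

Hybrid diphosphates, for which no crystal complex exists:

```sh
substrate-graft build-hybrid --base gtp.pdb:GNP --tail adp.pdb:APN --out gdp.pdb
```

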