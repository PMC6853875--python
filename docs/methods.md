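# Methods

## The model

A protein complex is partitioned into FMO fragments — one per amino-acid
residue, crystallographic water, or ligand — and the FMO2 pair interaction
energy between fragments *i* and *j* is decomposed (PIEDA) into
electrostatic, exchange-repulsion, charge-transfer(+mix), and dispersion
terms, optionally augmented by an implicit-solvent screening term:

PIE(ΔE_ij) = ΔE_es + ΔE_ex + ΔE_ct+mix + ΔE_di [+ ΔG_sol], in kcal/mol.

This package implements everything **around** the quantum chemistry: the
fragmentation and input deck, the output parsing, and the 3D-SPIEs screen
and its downstream aggregations. The SCF/MP2/PCM calculation itself is
deliberately external (GAMESS), both because it needs cluster resources and
because never shelling out keeps runs reproducible and testable.

## Fragmentation (HOP scheme)

Residue fragments do **not** coincide with chemical residues. The chain is
cut at the Cα sp³ bond rather than the peptide bond (hybrid orbital
projection, HOP): residue *i*'s backbone carbonyl C and O belong to fragment
*i + 1*, so a main-chain C=O hydrogen bond is attributed to the following
residue's fragment. Consequences implemented here:

* fragment *i* holds N_i, its amide H (absent for proline), Cα_i, Hα_i, the
  side chain, and — for *i* > 1 — C_{i−1}, O_{i−1}; the first residue of a
  chain additionally holds the N-terminal hydrogens, the last keeps its own
  C, O, OXT;
* one detached bond per internal Cα_i–C_i cut. The Cα is the bond-detached
  atom (BDA) and the carbonyl C the bond-attached atom (BAA); we assign the
  detached bond's owning fragment as the one containing the BAA (fragment
  *i + 1*), which owns the bond's electron pair;
* the carbonyl shift is applied only across genuine peptide bonds
  (C_i–N_{i+1} < 1.8 Å); a physical chain break suppresses both the shift
  and the detached bond, since fragmenting across a gap is meaningless;
* each water and each ligand is a single fragment; multi-residue peptide
  ligands are fragmented residue-wise like protein chains, since
  per-residue interactions of peptide inhibitors are the quantity of
  interest;
* the two cysteines of a disulfide bridge may be merged into one fragment.
  Disulfides are detected by SG–SG distance with a 2.5 Å cutoff (a typical
  S–S bond is ≈ 2.05 Å), pairing greedily by ascending distance so each
  cysteine joins at most one pair.

Formal charges are inferred from the hydrogens actually present, because
structures are protonated upstream at physiological pH and the proton
inventory — not the residue name — carries the protonation state:
Asp/Glu −1 without the acid proton, Lys +1 with three ζ-protons, Arg +1,
His +1 only with both ring nitrogens protonated, free N-terminus +1 with
three protons on N, C-terminus −1 with an unprotonated OXT. A residue with
no hydrogens at all falls back to name-based rules with a warning. Water
and ligand charges come from user configuration (default 0).

The emitted GAMESS deck contains $FMO (fragment count, charges, run-length
INDAT atom assignment), $FMOBND (BDA serial negated, per convention), a
$FMOHYB hybrid-orbital block, and $FMOXYZ coordinates. The $FMOHYB block is
a canned constant with the standard layout; its numeric coefficients are
placeholders a user should replace with the block distributed with their
GAMESS version — the deck's correctness-critical content (fragments,
charges, bonds, coordinates) is fully derived. Deck text is a pure function
of plan + structure + parameters, pinned by determinism tests.

## The 3D-SPIEs screen

* **Distance**: single linkage — the minimum over all atom pairs of the
  Euclidean distance between two fragments. Default cutoff 5.4 Å, the
  separation used for the electrostatic-potential approximation in FMO.
  All atoms including hydrogens participate (structures are protonated);
  a heavy-atom-only switch exists. The k-d-tree backend enumerates atom
  pairs within the cutoff and takes per-fragment-pair minima, which is
  exactly the naive double loop's answer (cross-checked in tests).
* **Energy**: keep pairs at least as attractive as −3.0 kcal/mol. When the
  PIEDA table carries a solvation column the screened total includes it.
* **Boundary semantics**: both thresholds are inclusive (≤), so the
  documented defaults are self-consistent: a pair at exactly 5.4 Å and
  exactly −3.0 kcal/mol is retained.
* **Classification** needs only a chain → group map: different groups →
  inter-group (PPI), same group → intra-group (non-PPI), one water →
  water-mediated, two waters → water–water. An antibody's heavy and light
  chains are conventionally mapped to one group so their mutual contacts
  stay intra-group and only antigen–antibody contacts count as PPI.
  Water–water pairs are reported but excluded from bridges and maps.
* **Water bridges**: exhaustive enumeration of (water, a, b) triples where
  both water legs are retained water-mediated records and a, b belong to
  different groups.
* **Hot-spot regions**: interface residues of one group, sorted by author
  numbering, split wherever consecutive members differ by more than
  `gap_tolerance` (default 2 — published hot-spot listings for this
  interface contain gaps of two within one region; the grouping is
  interpretive, so the tolerance is a parameter).
* **Interaction maps**: boolean residue × complex matrix over a common
  target group, with the most attractive PIE per cell and a per-residue
  commonality count. Rows are sorted by resseq; label collisions across
  complexes at the same residue number are an error, not a merge.

Pair labels follow the field's subscript/superscript convention
(`_L_Y56`, `HOH202^A`, `C23-C88` for a merged disulfide); with no notation
configured, labels fall back to `Y56:B`, which is always unique in a plan.

## Synthetic data

The toy generator emulates only what the analysis consumes: geometry and
bookkeeping, not physics. Chains are identical extended-conformation
peptides (idealized local geometry: amide H within 1.1 Å of N, Cα–C within
1.8 Å, peptide C–N ≈ 1.33 Å) stacked so the smallest inter-chain atom
distance approximately equals the configured gap (default 4.5 Å, which
places interface contacts just inside the 5.4 Å screen; 20 Å places none).
Interface waters sit midway between the nearest inter-chain Cα pairs, hence
within the cutoff of both chains — the geometry needed for water bridges.
Synthetic PIEDA tables plant attractive pairs (totals forced ≤ −3.0) on a
background drawn uniformly from (−2.9, +3.0), which by construction never
crosses the threshold; the screen must therefore recover the planted truth
with precision = recall = 1. What passing these tests does *not* show:
correctness of any quantum-chemical energy, PCM behavior, or realistic
conformational variety — the fixtures exercise set logic, geometry, and
I/O, not physics.

## Numerical choices

* Energies are stored in kcal/mol exactly as printed; no hartree
  conversion. Printed totals deviating from the component sum by more than
  0.01 kcal/mol are flagged, never silently corrected; parser round-trip
  tests hold to 1e−3.
* Coordinates are carried at PDB precision (3 decimals); the PDB writer
  round-trips field-for-field.
* Altloc groups collapse to the highest-occupancy atom, ties broken by
  altloc letter; a "first" policy is available.
* Duplicate PIEDA rows (restart logs) are last-wins with a warning;
  malformed rows are skipped with a line-numbered warning.
* Chain-break advisory threshold: Cα–Cα > 4.5 Å.

## Scope and limitations

* No structure preparation beyond subsetting and validation: loop building,
  protonation-state prediction, and minimization belong to upstream tools;
  `validate_for_fmo` only reports (missing hydrogens, unknown residues,
  altloc leftovers, chain breaks).
* No mmCIF input in this version; PDB only.
* N-glycans and other non-standard polymer attachments are treated as
  declared ligand fragments, not fragmented — flagged rather than guessed.
* Published headline counts for real complexes (e.g. 28 detected PPI in the
  wild-type PD-1/PD-L1 complex) require the original FMO-MP2/6-31G**/PCM
  results for full crystal structures; the package reproduces the analysis
  layer and verifies it on synthetic ground truth and on the published
  contact listings, not the quantum chemistry.
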