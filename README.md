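# spies3d

Quantum-chemistry-grade analysis of protein–protein and protein–ligand
interfaces via the fragment molecular orbital (FMO) method and **3D scattered
pair interaction energies (3D-SPIEs)**.

FMO divides a complex into fragments — here one fragment per amino-acid
residue, water, or ligand — and computes pair interaction energies (PIEs)
between them, decomposed (PIEDA) as

```
PIE (ΔE_ij^int) = ΔE_ij^es + ΔE_ij^ex + ΔE_ij^ct+mix + ΔE_ij^di [+ ΔG_sol]
```

(electrostatic, exchange-repulsion, charge-transfer + mix, dispersion, and
optional implicit-solvent screening, all in kcal/mol). Raw PIEs are badly
overestimated at long range, so 3D-SPIEs screens them twice: keep only
fragment pairs whose *single-linkage* distance (minimum over all atom pairs)
is within **5.4 Å**, and whose PIE is attractively more stable than
**−3.0 kcal/mol** (both inclusive, both configurable). Surviving pairs are
classified as inter-protein (PPI), intra-protein (non-PPI), or
water-mediated; waters bound on both sides of an interface become water
bridges; runs of sequence-adjacent interface residues form hot-spot regions;
and boolean residue × complex interaction maps aggregate many complexes
(e.g. a target protein against a panel of antibodies and small molecules)
against one common target.

The package is aimed at structural bioinformaticians and computational
chemists who run FMO2/PIEDA calculations in GAMESS on prepared PDB
structures and need the surrounding tooling:

* **structure_model** — read/subset/validate PDB structures (gemmi-backed),
  altloc resolution, disulfide detection, nearby-water retention;
* **fragmentation** — the one-fragment-per-residue hybrid-orbital-projection
  (HOP) scheme: each residue's backbone carbonyl shifts to the *next*
  residue's fragment, detached bonds sit at the Cα sp³ position, disulfide
  cysteine pairs merge into one fragment; formal charges are inferred from
  the hydrogens actually present; emits a GAMESS FMO2 input deck;
* **pieda_parse** — tolerant parsing of GAMESS PIEDA summary tables into
  typed records plus a CSV interchange format;
* **spies_core** — the 3D-SPIEs screen, classification, water bridges,
  hot-spot regions, interaction maps, 3D-scatter JSON export;
* **synthetic_fixtures** — seeded toy complexes and planted-truth synthetic
  PIEDA output so the entire pipeline is testable without GAMESS;
* **cli** — the `spies` command; it never invokes GAMESS itself (you run
  the emitted deck and hand back the log).

## Worked example

Everything below runs in seconds with no external quantum chemistry, using
the built-in fixture generator (two poly-Ala chains at a 4.5 Å interface gap
with two bridging waters, plus a synthetic PIEDA table with one planted
attractive contact between the chains):

```sh
$ spies fixtures --out-dir fix --seed 3
wrote fixture set to fix (12 residues, 12 fragments)

$ spies parse --gamess-out fix/gamess.out --plan fix/plan.json --out pie.csv
wrote pie.csv: 66 pairs, 12 fragments

$ spies analyze --pie pie.csv --plan fix/plan.json --pdb fix/toy.pdb \
        --groups "A=receptor;B=ligand" --out-dir out
retained 1 interactions (1 inter-group), 0 water bridges -> out

$ spies map --inputs toy=out/spies.csv --target-group receptor --out map.json
wrote map.json: 1 residues x 1 complexes
```

The 66 pairs are every fragment pair of the 12-fragment toy; exactly one
survives the 5.4 Å / −3.0 kcal/mol screen — the planted inter-chain contact:

```sh
$ head -2 out/spies.csv
frag_i,frag_j,label_i,label_j,chain_i,chain_j,kind_i,kind_j,resseq_i,resseq_j,distance,e_es,e_ex,e_ct_mix,e_di,g_sol,pie,iclass,group_i,group_j
1,6,A1:A,A1:B,A,B,residue,residue,1,1,4.987825,-4.000000,0.800000,-1.600000,-2.800000,-0.400000,-8.000000,inter_group,receptor,ligand
```

Reading the row: fragments 1 and 6 (residue Ala1 of chain A and Ala1 of
chain B) sit 4.99 Å apart (single linkage), interact at −8.0 kcal/mol
(components −4.0 es, +0.8 ex, −1.6 ct+mix, −2.8 di, −0.4 sol), and are
classified inter-group — a PPI dot in the 3D scatter (`out/scatter.json`).

For real work, replace the fixture with `spies prep` on a crystal structure
(e.g. trim an antibody to its Fv domains while keeping nearby waters),
`spies fmo-input` to emit the GAMESS deck, run GAMESS yourself, then
`spies parse` / `spies analyze` / `spies map` as above — or drive all stages
from a YAML config with `spies run --config config.yaml`, which writes a
manifest of artifact hashes for reproducibility.

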