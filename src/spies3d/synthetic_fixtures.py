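"""Seeded toy complexes and synthetic FMO output with known ground truth.

The toy structures are extended-conformation peptide chains with idealized
internal geometry, stacked so that the minimum inter-chain atom distance
approximately equals a configurable gap.  Only *distances* feed the
downstream analysis — energies come from the separately planted synthetic
PIE tables — so no attempt is made at realistic secondary structure or
quantum-chemical energy magnitudes.

Planted pairs in the synthetic PIEDA output carry attractive totals at or
below the significance threshold (−3.0 kcal/mol); background pairs draw
from a noise band that never crosses it, so the 3D-SPIEs screen must
recover exactly the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from spies3d.pieda_parse import PIETable, PairInteraction
from spies3d.fragmentation import FragmentationPlan
from spies3d.structure_model import Atom, Residue, Structure

__all__ = [
    "ToyComplexSpec",
    "SyntheticPIESpec",
    "make_toy_complex",
    "make_synthetic_fmo_output",
    "make_components",
]

ATTRACTIVE_CEILING = -3.0  # kcal/mol; planted pairs must be at or below this

# Residue-local template coordinates (Å): extended chain along +x,
# residue-to-residue spacing _SPACING.  Bond lengths are near-ideal where
# they matter (amide H on N < 1.1 Å; Cα–C < 1.8 Å; C(i)–N(i+1) ≈ 1.33 Å).
_SPACING = 3.7
_BACKBONE = {
    "N": (0.00, 0.30, 0.00),
    "H": (0.00, 1.31, 0.00),
    "CA": (1.20, -0.50, 0.00),
    "HA": (1.20, -1.10, 0.95),
    "C": (2.37, 0.30, 0.00),
    "O": (2.37, 1.53, 0.00),
}
_SIDECHAINS = {
    "ALA": {
        "CB": (1.40, -1.20, -1.20),
        "HB1": (2.30, -1.00, -1.50),
        "HB2": (0.80, -2.00, -1.40),
        "HB3": (1.60, -0.60, -2.10),
    },
    "GLY": {},
    # SG is positioned later, toward the disulfide partner
    "CYS": {
        "CB": (1.40, -1.20, -1.20),
        "HB2": (0.80, -2.00, -1.40),
        "HB3": (1.60, -0.60, -2.10),
    },
}
_THREE = {"A": "ALA", "G": "GLY", "C": "CYS"}


@dataclass(frozen=True)
class ToyComplexSpec:
    """Parameters of a desk-scale toy protein complex."""

    n_chains: int = 2
    residues_per_chain: int = 5
    sequence: str = "polyA"  # or a one-letter string drawn from A/G/C
    inter_chain_gap: float = 4.5  # Å, approximate minimum inter-chain distance
    n_waters: int = 2
    water_placement: str = "interface"  # or "random"
    disulfides: tuple[tuple[tuple[str, int], tuple[str, int]], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residues_per_chain < 1:
            raise ValueError("residues_per_chain must be >= 1")
        if self.water_placement not in ("interface", "random"):
            raise ValueError(f"unknown water_placement {self.water_placement!r}")

    def chain_sequence(self) -> list[str]:
        if self.sequence == "polyA":
            return ["ALA"] * self.residues_per_chain
        if len(self.sequence) != self.residues_per_chain:
            raise ValueError("sequence length != residues_per_chain")
        try:
            return [_THREE[c] for c in self.sequence]
        except KeyError as exc:
            raise ValueError(f"unsupported residue letter {exc}") from exc


def _chain_ids(n: int) -> list[str]:
    return [chr(ord("A") + i) for i in range(n)]


def make_toy_complex(spec: ToyComplexSpec) -> Structure:
    """Build a fully protonated toy multi-chain structure with waters.

    Chains are identical extended peptides offset in y so the smallest
    inter-chain atom distance is approximately ``inter_chain_gap``.
    Interface waters sit midway between the nearest inter-chain Cα pairs.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    seq = spec.chain_sequence()
    ds_members = {m for pair in spec.disulfides for m in pair}
    for pair in spec.disulfides:
        if pair[0] == pair[1]:
            raise ValueError(f"disulfide pair {pair} references one residue twice")

    # y-extent of the residue template, for stacking chains at the right gap
    all_y = [v[1] for v in _BACKBONE.values()] + [
        v[1] for sc in _SIDECHAINS.values() for v in sc.values()
    ]
    y_extent = max(all_y) - min(all_y)

    residues: list[Residue] = []
    serial = 0
    ca_by_chain: dict[str, list[tuple[int, np.ndarray]]] = {}

    def add_atom(name: str, element: str, pos: Sequence[float]) -> Atom:
        nonlocal serial
        serial += 1
        return Atom(
            serial=serial,
            name=name,
            element=element,
            coords=(round(float(pos[0]), 3), round(float(pos[1]), 3), round(float(pos[2]), 3)),
        )

    chains = _chain_ids(spec.n_chains)
    for ci, cid in enumerate(chains):
        y_off = ci * (y_extent + spec.inter_chain_gap)
        ca_by_chain[cid] = []
        for ri, resname in enumerate(seq, start=1):
            if (cid, ri) in ds_members:
                resname = "CYS"
            x_off = (ri - 1) * _SPACING
            atoms: list[Atom] = []
            for name, (x, y, z) in _BACKBONE.items():
                if name == "H" and ri == 1:
                    continue  # replaced by the N-terminal H1/H2/H3
                atoms.append(add_atom(name, name[0], (x + x_off, y + y_off, z)))
            if ri == 1:
                n_pos = np.add(_BACKBONE["N"], (x_off, y_off, 0.0))
                for k, dv in enumerate(
                    [(0.0, 1.01, 0.0), (-0.85, -0.40, 0.45), (0.85, -0.40, 0.45)], start=1
                ):
                    atoms.append(add_atom(f"H{k}", "H", n_pos + np.asarray(dv)))
            for name, (x, y, z) in _SIDECHAINS[resname].items():
                atoms.append(add_atom(name, name[0], (x + x_off, y + y_off, z)))
            if ri == len(seq):
                c_pos = np.add(_BACKBONE["C"], (x_off, y_off, 0.0))
                atoms.append(add_atom("OXT", "O", c_pos + np.asarray((1.10, -0.56, 0.0))))
            residues.append(
                Residue(
                    chain_id=cid,
                    resseq=ri,
                    icode="",
                    resname=resname,
                    atoms=tuple(atoms),
                    kind="amino_acid",
                )
            )
            ca = next(a for a in residues[-1].atoms if a.name == "CA")
            ca_by_chain[cid].append((ri, np.asarray(ca.coords)))

    # position disulfide SG atoms toward each other at ~2.05 Å separation
    if spec.disulfides:
        by_key = {(r.chain_id, r.resseq): i for i, r in enumerate(residues)}
        for (ka, kb) in spec.disulfides:
            if ka not in by_key or kb not in by_key:
                raise ValueError(f"disulfide references missing residue: {(ka, kb)}")
            ra, rb = residues[by_key[ka]], residues[by_key[kb]]
            ca_a = np.asarray(ra.atom("CA").coords)
            ca_b = np.asarray(rb.atom("CA").coords)
            mid = (ca_a + ca_b) / 2.0
            d = ca_b - ca_a
            norm = np.linalg.norm(d)
            if norm < 1e-6:
                raise ValueError(f"disulfide residues coincide: {(ka, kb)}")
            u = d / norm
            for res_i, sg_pos in ((by_key[ka], mid - 1.025 * u), (by_key[kb], mid + 1.025 * u)):
                res = residues[res_i]
                residues[res_i] = Residue(
                    chain_id=res.chain_id,
                    resseq=res.resseq,
                    icode=res.icode,
                    resname=res.resname,
                    atoms=res.atoms + (add_atom("SG", "S", sg_pos),),
                    kind=res.kind,
                )

    # waters
    water_pos: list[np.ndarray] = []
    if spec.n_waters > 0 and spec.n_chains >= 2 and spec.water_placement == "interface":
        pairs = []
        a_cas, b_cas = ca_by_chain[chains[0]], ca_by_chain[chains[1]]
        for _, pa in a_cas:
            for _, pb in b_cas:
                pairs.append((float(np.linalg.norm(pa - pb)), pa, pb))
        pairs.sort(key=lambda t: t[0])
        for k in range(spec.n_waters):
            _, pa, pb = pairs[k % len(pairs)]
            jitter = np.array([0.3 * (k // len(pairs)), 0.0, 0.0])
            water_pos.append((pa + pb) / 2.0 + jitter)
    elif spec.n_waters > 0:
        coords = np.array([a.coords for r in residues for a in r.atoms])
        lo, hi = coords.min(axis=0) - 3.0, coords.max(axis=0) + 3.0
        for _ in range(spec.n_waters):
            water_pos.append(rng.uniform(lo, hi))

    for wi, pos in enumerate(water_pos, start=201):
        atoms = (
            add_atom("O", "O", pos),
            add_atom("H1", "H", pos + np.asarray((0.76, 0.59, 0.0))),
            add_atom("H2", "H", pos + np.asarray((-0.76, 0.59, 0.0))),
        )
        residues.append(
            Residue(
                chain_id="W", resseq=wi, icode="", resname="HOH",
                atoms=atoms, kind="water", het=True,
            )
        )

    chain_order = tuple(chains) + (("W",) if water_pos else ())
    return Structure(
        residues=tuple(residues), chain_order=chain_order, title="toy complex"
    )


# ---------------------------------------------------------------------------
# synthetic PIEDA output

@dataclass(frozen=True)
class SyntheticPIESpec:
    """Ground truth for a synthetic PIEDA table.

    ``planted_pairs`` holds (i, j, components) with components a 5-tuple
    (es, ex, ct+mix, di, sol) whose sum must be at or below the −3.0
    kcal/mol significance ceiling; all other pairs draw background totals
    from ``background_range``, which by default never crosses it.
    """

    planted_pairs: tuple[tuple[int, int, tuple[float, ...]], ...] = ()
    background_range: tuple[float, float] = (-2.9, 3.0)
    with_solvation: bool = True
    seed: int = 0


def make_components(total: float, with_solvation: bool = True) -> tuple[float, ...]:
    """Split a target total into a plausible 5-term PIEDA decomposition."""
    es = round(0.5 * total, 3)
    ex = round(abs(total) * 0.1, 3)
    ct = round(0.2 * total, 3)
    sol = round(-abs(total) * 0.05, 3) if with_solvation else 0.0
    di = round(total - es - ex - ct - sol, 3)
    return (es, ex, ct, di, sol)


def make_synthetic_fmo_output(
    plan: FragmentationPlan, spec: SyntheticPIESpec
) -> tuple[str, PIETable]:
    """Emit GAMESS-dialect PIEDA text plus its ground-truth table.

    The text embeds a preamble, the PIEDA block marker, a column header,
    and one whitespace-formatted row per fragment pair; parsing it back
    recovers the returned table exactly.
    """
    n = len(plan.fragments)
    planted: dict[tuple[int, int], tuple[float, ...]] = {}
    for (i, j, comps) in spec.planted_pairs:
        if not (1 <= i < j <= n):
            raise ValueError(f"planted pair ({i},{j}) out of range for {n} fragments")
        comps = tuple(round(float(c), 3) for c in comps)
        if len(comps) != 5:
            raise ValueError("components must be a 5-tuple (es, ex, ct, di, sol)")
        if round(sum(comps), 3) > ATTRACTIVE_CEILING:
            raise ValueError(
                f"planted pair ({i},{j}) total {sum(comps):.3f} above the "
                f"{ATTRACTIVE_CEILING} kcal/mol ceiling"
            )
        planted[(i, j)] = comps

    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.background_range
    records: list[PairInteraction] = []
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            if (i, j) in planted:
                es, ex, ct, di, sol = planted[(i, j)]
            else:
                total = round(float(rng.uniform(lo, hi)), 3)
                es = round(float(rng.uniform(-1, 1)), 3)
                ex = round(float(rng.uniform(0, 1)), 3)
                ct = round(float(rng.uniform(-0.5, 0.5)), 3)
                sol = round(float(rng.uniform(-0.5, 0.5)), 3) if spec.with_solvation else 0.0
                di = round(total - es - ex - ct - sol, 3)
            sol_v = sol if spec.with_solvation else None
            total_v = round(es + ex + ct + di + (sol if spec.with_solvation else 0.0), 3)
            records.append(
                PairInteraction(
                    frag_i=i, frag_j=j,
                    e_es=es, e_ex=ex, e_ct_mix=ct, e_di=di,
                    g_sol=sol_v, total=total_v,
                )
            )
    table = PIETable(
        records=tuple(records),
        n_fragments=n,
        metadata={"source": "synthetic", "seed": str(spec.seed)},
    )

    lines = [
        " GAMESS (synthetic dialect) — FMO2 run emulation",
        " ..... preamble: SCC converged, monomer energies omitted .....",
        "",
        "          PAIR INTERACTION ENERGY DECOMPOSITION ANALYSIS (PIEDA)",
        "            all terms in kcal/mol",
        "",
    ]
    if spec.with_solvation:
        lines.append(
            "     I     J        ES        EX    CT+MIX        DI      SOLV     TOTAL"
        )
    else:
        lines.append("     I     J        ES        EX    CT+MIX        DI     TOTAL")
    lines.append("  " + "-" * 70)
    for r in records:
        cols = [f"{r.frag_i:>6d}", f"{r.frag_j:>6d}",
                f"{r.e_es:>10.3f}", f"{r.e_ex:>10.3f}",
                f"{r.e_ct_mix:>10.3f}", f"{r.e_di:>10.3f}"]
        if spec.with_solvation:
            cols.append(f"{r.g_sol:>10.3f}")
        cols.append(f"{r.total:>10.3f}")
        lines.append("".join(cols))
    lines += ["", " ..... end of PIEDA section .....", ""]
    return "\n".join(lines), table
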