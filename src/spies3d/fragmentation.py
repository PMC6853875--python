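"""Residue-based FMO fragmentation (HOP scheme) and GAMESS deck generation.

The fragmentation is one-fragment-per-residue with hybrid-orbital-projection
(HOP) bond detachment at the Cα sp³ bond rather than the peptide bond: each
residue's backbone carbonyl group (C, O) is shifted into the *next* residue's
fragment, so a main-chain C=O hydrogen bond is attributed to the following
amino acid.  Waters and ligands are single fragments; the two cysteines of a
disulfide bridge may be merged into one fragment.

Formal charges are inferred from the hydrogens actually present (structures
are protonated upstream at physiological pH), falling back to residue-name
rules when a residue carries no hydrogens at all.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from spies3d.structure_model import (
    Atom,
    AtomKey,
    Residue,
    ResidueKey,
    Structure,
    detect_disulfides,
)

__all__ = [
    "Fragment",
    "DetachedBond",
    "FragmentationPlan",
    "FragmentationError",
    "LabelNotation",
    "FMOJobParams",
    "build_fragmentation",
    "assign_formal_charges",
    "write_fmo_input",
    "fragment_label",
    "plan_to_json",
    "plan_from_json",
]

PEPTIDE_BOND_MAX = 1.8  # Å; C(i)–N(i+1) above this is treated as a chain break

ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
    "HID": "H", "HIE": "H", "HIP": "H", "ASH": "D", "GLH": "E", "LYN": "K",
    "CYX": "C", "CYM": "C",
}


class FragmentationError(ValueError):
    """A residue cannot be fragmented (missing backbone atoms etc.)."""


FragmentKind = Literal["residue", "merged_disulfide", "water", "ligand"]


@dataclass(frozen=True)
class Fragment:
    """One FMO fragment: a residue, water, ligand, or merged disulfide pair."""

    index: int  # 1-based
    label: str
    member_atoms: frozenset[AtomKey]
    charge: int
    kind: FragmentKind
    source_residues: tuple[ResidueKey, ...]

    def __post_init__(self) -> None:
        if not self.member_atoms:
            raise ValueError(f"fragment {self.label} has no atoms")
        expected = 2 if self.kind == "merged_disulfide" else 1
        if len(self.source_residues) != expected:
            raise ValueError(
                f"fragment {self.label}: {len(self.source_residues)} source "
                f"residues, expected {expected} for kind {self.kind}"
            )


@dataclass(frozen=True)
class DetachedBond:
    """A Cα–C(carbonyl) bond cut by the HOP scheme.

    ``bda_atom`` (bond-detached atom) is the Cα that keeps the hybrid
    orbital; ``baa_atom`` (bond-attached atom) is the carbonyl carbon;
    ``owner_fragment`` is the fragment holding the BAA (the next residue's
    fragment, which owns the detached bond's electron pair).
    """

    bda_atom: AtomKey
    baa_atom: AtomKey
    owner_fragment: int


@dataclass(frozen=True)
class FragmentationPlan:
    """An ordered fragmentation: fragments partition all atoms of a Structure."""

    fragments: tuple[Fragment, ...]
    detached_bonds: tuple[DetachedBond, ...]
    total_charge: int

    def __post_init__(self) -> None:
        if self.total_charge != sum(f.charge for f in self.fragments):
            raise ValueError("total_charge != sum of fragment charges")

    def __len__(self) -> int:
        return len(self.fragments)

    def fragment_of(self, atom: AtomKey) -> Fragment:
        for f in self.fragments:
            if atom in f.member_atoms:
                return f
        raise KeyError(atom)

    def by_label(self, label: str) -> Fragment:
        for f in self.fragments:
            if f.label == label:
                return f
        raise KeyError(label)


def _atom_keys(res: Residue) -> list[AtomKey]:
    return [(res.chain_id, res.resseq, res.icode, a.name) for a in res.atoms]


def _dist(a: Atom, b: Atom) -> float:
    return float(np.linalg.norm(np.subtract(a.coords, b.coords)))


def _peptide_bonded(prev: Residue, curr: Residue) -> bool:
    c, n = prev.atom("C"), curr.atom("N")
    return c is not None and n is not None and _dist(c, n) < PEPTIDE_BOND_MAX


def build_fragmentation(
    structure: Structure,
    merge_disulfides: bool = True,
    ligand_resnames: Iterable[str] = (),
    component_charges: Mapping[str, int] | None = None,
    notation: "LabelNotation | None" = None,
) -> FragmentationPlan:
    """Build the one-fragment-per-residue HOP fragmentation of a structure.

    For every peptide-bonded residue pair (i, i+1) within a chain, residue
    i's carbonyl C and O atoms are moved into fragment i+1 and one detached
    Cα(i)–C(i) bond is recorded.  The first residue of a chain keeps its
    N-terminal hydrogens; the last keeps its own carbonyl and OXT.  Each
    water and each ligand residue is a single fragment.  With
    ``merge_disulfides`` the two fragments of each detected disulfide pair
    are unioned into one.

    Raises
    ------
    FragmentationError
        If an amino acid lacks Cα or C, or a residue of unknown kind is
        present without being declared in ``ligand_resnames``.
    """
    notation = notation or LabelNotation()
    ligand_names = set(ligand_resnames)
    charges_cfg = dict(component_charges or {})

    # 1) one proto-fragment per residue, in structure order
    members: list[set[AtomKey]] = []
    residues = list(structure.residues)
    index_of: dict[ResidueKey, int] = {}
    for pos, res in enumerate(residues):
        if res.kind == "other" and res.resname not in ligand_names:
            raise FragmentationError(
                f"residue {res.resname} {res.key} is neither a standard amino "
                "acid, water, nor a declared ligand"
            )
        members.append(set(_atom_keys(res)))
        index_of[res.key] = pos

    # 2) HOP carbonyl shift + detached bonds, per chain
    detached: list[tuple[AtomKey, AtomKey, int]] = []  # (bda, baa, owner pos)
    for cid in structure.chain_order:
        aa = [r for r in structure.chain(cid) if r.kind == "amino_acid"]
        for r in aa:
            if r.atom("CA") is None or r.atom("C") is None:
                raise FragmentationError(f"{r.resname} {r.key} lacks CA or C")
        for prev, curr in zip(aa, aa[1:]):
            if not _peptide_bonded(prev, curr):
                continue
            i, j = index_of[prev.key], index_of[curr.key]
            for name in ("C", "O"):
                atom = prev.atom(name)
                if atom is None:
                    continue
                key = (prev.chain_id, prev.resseq, prev.icode, name)
                members[i].discard(key)
                members[j].add(key)
            detached.append(
                (
                    (prev.chain_id, prev.resseq, prev.icode, "CA"),
                    (prev.chain_id, prev.resseq, prev.icode, "C"),
                    j,
                )
            )

    # 3) merge disulfide pairs
    group_of = list(range(len(residues)))  # proto-fragment -> group id
    merged_pairs: list[tuple[ResidueKey, ResidueKey]] = []
    if merge_disulfides:
        for pair in detect_disulfides(structure):
            ia, ib = index_of[pair.cys_a], index_of[pair.cys_b]
            keep, drop = min(ia, ib), max(ia, ib)
            for k, g in enumerate(group_of):
                if g == group_of[drop] and k != drop:
                    group_of[k] = group_of[keep]
            group_of[drop] = group_of[keep]
            merged_pairs.append((pair.cys_a, pair.cys_b))

    # 4) assemble fragments in first-occurrence order of their group
    order: list[int] = []
    for g in group_of:
        if g not in order:
            order.append(g)
    fragments: list[Fragment] = []
    pos_to_frag: dict[int, int] = {}
    for fi, g in enumerate(order, start=1):
        srcs = [p for p in range(len(residues)) if group_of[p] == g]
        atoms = frozenset().union(*(members[p] for p in srcs))
        src_res = [residues[p] for p in srcs]
        if len(src_res) == 2:
            kind: FragmentKind = "merged_disulfide"
        elif src_res[0].kind == "water":
            kind = "water"
        elif src_res[0].kind == "amino_acid":
            kind = "residue"
        else:
            kind = "ligand"
        frag = Fragment(
            index=fi,
            label="",
            member_atoms=atoms,
            charge=0,
            kind=kind,
            source_residues=tuple(r.key for r in src_res),
        )
        fragments.append(frag)
        for p in srcs:
            pos_to_frag[p] = fi

    bonds = tuple(
        DetachedBond(bda_atom=bda, baa_atom=baa, owner_fragment=pos_to_frag[owner])
        for bda, baa, owner in detached
    )
    plan = FragmentationPlan(
        fragments=tuple(fragments), detached_bonds=bonds, total_charge=0
    )
    plan = assign_formal_charges(plan, structure, component_charges=charges_cfg)
    labeled = tuple(
        replace(f, label=fragment_label(f, notation, structure))
        for f in plan.fragments
    )
    return replace(plan, fragments=labeled)


# ---------------------------------------------------------------------------
# formal charges

_ACID_H = {"ASP": ("HD2", "HD1"), "GLU": ("HE2", "HE1")}


def _has_atom(res: Residue, *names: str) -> bool:
    return any(res.atom(n) is not None for n in names)


def _n_hydrogens_on(res: Residue, heavy: str) -> int:
    """Count hydrogens bonded to a named heavy atom (by distance < 1.3 Å)."""
    h = res.atom(heavy)
    if h is None:
        return 0
    return sum(
        1 for a in res.atoms if a.is_hydrogen and _dist(a, h) < 1.3
    )


def _sidechain_charge(res: Residue, in_disulfide: bool) -> int:
    name = res.resname
    if not any(a.is_hydrogen for a in res.atoms):
        # no protons to count: fall back to name-based rules
        warnings.warn(
            f"{name} {res.key} has no hydrogens; using name-based charge",
            stacklevel=2,
        )
        return {"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1, "HIP": 1,
                "ASH": 0, "GLH": 0, "LYN": 0}.get(name, 0)
    if name in ("ASP", "ASH"):
        return 0 if _has_atom(res, "HD2", "HD1") else -1
    if name in ("GLU", "GLH"):
        return 0 if _has_atom(res, "HE2", "HE1") else -1
    if name in ("LYS", "LYN"):
        return 1 if _n_hydrogens_on(res, "NZ") == 3 else 0
    if name == "ARG":
        return 1
    if name in ("HIS", "HID", "HIE", "HIP"):
        return 1 if _has_atom(res, "HD1") and _has_atom(res, "HE2") else 0
    return 0


def _terminal_charge(res: Residue, is_first: bool, is_last: bool) -> int:
    q = 0
    if is_first and _n_hydrogens_on(res, "N") >= 3:
        q += 1
    if is_last and res.atom("OXT") is not None and res.atom("HXT") is None:
        q -= 1
    return q


def assign_formal_charges(
    plan: FragmentationPlan,
    structure: Structure,
    component_charges: Mapping[str, int] | None = None,
) -> FragmentationPlan:
    """Assign per-fragment formal charges inferred from present hydrogens.

    Side-chain and terminal charges go to the fragment holding the residue
    (side chains and termini never move under the carbonyl shift).  Water
    charge is 0; ligand charges come from ``component_charges`` (keyed by
    resname), defaulting to 0.
    """
    charges_cfg = dict(component_charges or {})
    disulfide_cys = {
        k for f in plan.fragments if f.kind == "merged_disulfide"
        for k in f.source_residues
    }
    first_last: dict[ResidueKey, tuple[bool, bool]] = {}
    for cid in structure.chain_order:
        aa = [r for r in structure.chain(cid) if r.kind == "amino_acid"]
        for i, r in enumerate(aa):
            first_last[r.key] = (i == 0, i == len(aa) - 1)

    new_frags: list[Fragment] = []
    for f in plan.fragments:
        q = 0
        for key in f.source_residues:
            res = structure.get(key)
            if res.kind == "amino_acid":
                q += _sidechain_charge(res, key in disulfide_cys)
                is_first, is_last = first_last[key]
                q += _terminal_charge(res, is_first, is_last)
            elif res.kind == "water":
                q += charges_cfg.get(res.resname, 0)
            else:
                q += charges_cfg.get(res.resname, 0)
        new_frags.append(replace(f, charge=q))
    return FragmentationPlan(
        fragments=tuple(new_frags),
        detached_bonds=plan.detached_bonds,
        total_charge=sum(f.charge for f in new_frags),
    )


# ---------------------------------------------------------------------------
# labels

@dataclass(frozen=True)
class LabelNotation:
    """How fragment labels render chain identity.

    ``prefix`` maps a chain id to a string placed before the residue name
    (the subscript-style protein tag, e.g. ``{"B": "_L_"}`` gives
    ``_L_Y56``); ``superscript`` maps a chain id to a tag appended after
    the label as ``^X`` (used for waters and for crystallographic copies).
    """

    prefix: Mapping[str, str] = field(default_factory=dict)
    superscript: Mapping[str, str] = field(default_factory=dict)

    def affix(self, chain_id: str, core: str) -> str:
        if chain_id not in self.prefix and chain_id not in self.superscript:
            # no notation configured: fall back to "<core>:<chain>", which is
            # always unique within a plan
            return f"{core}:{chain_id}"
        out = self.prefix.get(chain_id, "") + core
        sup = self.superscript.get(chain_id, "")
        return out + (f"^{sup}" if sup else "")


def _residue_core(res: Residue) -> str:
    one = ONE_LETTER.get(res.resname)
    if one is None:
        return f"{res.resname}{res.resseq}{res.icode}"
    return f"{one}{res.resseq}{res.icode}"


def fragment_label(
    fragment: Fragment,
    notation: LabelNotation,
    structure: Structure,
) -> str:
    """Render a fragment label in the field's subscript/superscript notation.

    Residues become one-letter code + author resseq with the chain affix
    (``_L_Y56``); waters become ``HOH<resseq>^<chain tag>``; merged
    disulfides join their two cysteine labels with ``-`` (``C23-C88``);
    ligands and unknown residues fall back to the three-letter name.
    """
    parts: list[str] = []
    for key in fragment.source_residues:
        res = structure.get(key)
        if res.kind == "water":
            parts.append(notation.affix(res.chain_id, f"{res.resname}{res.resseq}"))
        else:
            parts.append(notation.affix(res.chain_id, _residue_core(res)))
    return "-".join(parts)


# ---------------------------------------------------------------------------
# JSON sidecar (for downstream joins between PIE tables and structures)

def plan_to_json(plan: FragmentationPlan) -> str:
    """Serialize a FragmentationPlan (labels, charges, atom keys, bonds)."""
    return json.dumps(
        {
            "fragments": [
                {
                    "index": f.index,
                    "label": f.label,
                    "kind": f.kind,
                    "charge": f.charge,
                    "source_residues": [list(k) for k in f.source_residues],
                    "member_atoms": sorted(list(k) for k in f.member_atoms),
                }
                for f in plan.fragments
            ],
            "detached_bonds": [
                {
                    "bda_atom": list(b.bda_atom),
                    "baa_atom": list(b.baa_atom),
                    "owner_fragment": b.owner_fragment,
                }
                for b in plan.detached_bonds
            ],
            "total_charge": plan.total_charge,
        },
        indent=2,
    )


def _atom_key(raw: list) -> tuple:
    return (str(raw[0]), int(raw[1]), str(raw[2]), str(raw[3]))


def plan_from_json(text: str) -> FragmentationPlan:
    """Inverse of :func:`plan_to_json`."""
    data = json.loads(text)
    fragments = tuple(
        Fragment(
            index=f["index"],
            label=f["label"],
            member_atoms=frozenset(_atom_key(k) for k in f["member_atoms"]),
            charge=f["charge"],
            kind=f["kind"],
            source_residues=tuple(
                (str(k[0]), int(k[1]), str(k[2])) for k in f["source_residues"]
            ),
        )
        for f in data["fragments"]
    )
    bonds = tuple(
        DetachedBond(
            bda_atom=_atom_key(b["bda_atom"]),
            baa_atom=_atom_key(b["baa_atom"]),
            owner_fragment=b["owner_fragment"],
        )
        for b in data["detached_bonds"]
    )
    return FragmentationPlan(
        fragments=fragments, detached_bonds=bonds, total_charge=data["total_charge"]
    )


# ---------------------------------------------------------------------------
# GAMESS deck

@dataclass(frozen=True)
class FMOJobParams:
    """Job keywords for the emitted GAMESS FMO2 deck."""

    basis: str = "6-31G**"
    mp2: bool = True
    pcm: bool = True
    mwords: int = 512
    nbody: int = 2


_BASIS_GROUPS = {
    "6-31G**": " $BASIS GBASIS=N31 NGAUSS=6 NDFUNC=1 NPFUNC=1 $END",
    "6-31G*": " $BASIS GBASIS=N31 NGAUSS=6 NDFUNC=1 $END",
    "STO-3G": " $BASIS GBASIS=STO NGAUSS=3 $END",
}

# Canned hybrid-orbital block for the HOP treatment of the detached Cα sp³
# bond.  The layout (basis label, n_basis, 5 orbitals) follows the standard
# $FMOHYB convention; coefficients are fixed placeholder constants a user
# should replace with the block shipped with their GAMESS distribution.
_FMOHYB_631GSS = """\
 $FMOHYB
 6-31G** 15 5
 1 0  -0.068130  0.300430  0.000000  0.000000  0.606800
      0.305260  0.000000  0.000000  0.309630  0.000000
      0.000000  0.000000  0.000000  0.000000  0.000000
 0 1  -0.068130  0.300430  0.572180  0.000000 -0.202270
      0.305260  0.291880  0.000000 -0.103210  0.000000
      0.000000  0.000000  0.000000  0.000000  0.000000
 0 1  -0.068130  0.300430 -0.286090  0.495520 -0.202270
      0.305260 -0.145940  0.252770 -0.103210  0.000000
      0.000000  0.000000  0.000000  0.000000  0.000000
 0 1  -0.068130  0.300430 -0.286090 -0.495520 -0.202270
      0.305260 -0.145940 -0.252770 -0.103210  0.000000
      0.000000  0.000000  0.000000  0.000000  0.000000
 0 1   1.011540 -0.016450  0.000000  0.000000  0.000000
     -0.059290  0.000000  0.000000  0.000000  0.000000
      0.000000  0.000000  0.000000  0.000000  0.000000
 $END"""


def _indat_runs(indices: list[int]) -> list[tuple[int, int]]:
    """Collapse a sorted 1-based index list into inclusive runs."""
    runs: list[tuple[int, int]] = []
    for i in indices:
        if runs and i == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], i)
        else:
            runs.append((i, i))
    return runs


def write_fmo_input(
    plan: FragmentationPlan,
    structure: Structure,
    params: FMOJobParams | None = None,
) -> str:
    """Emit a GAMESS-dialect FMO2 input deck for a fragmentation plan.

    The deck contains the fragment count and charges ($FMO), the
    atom-to-fragment assignment as run-length INDAT lists, the detached
    Cα–C bonds ($FMOBND, BDA serial negated per GAMESS convention), the
    canned hybrid-orbital block, and Cartesian coordinates ($FMOXYZ).
    Output is deterministic for a fixed plan.
    """
    params = params or FMOJobParams()
    # sequential atom numbering in structure order
    atom_index: dict[AtomKey, int] = {}
    coords: list[tuple[int, str, tuple[float, float, float]]] = []
    for res in structure.residues:
        for a in res.atoms:
            key = (res.chain_id, res.resseq, res.icode, a.name)
            if key in atom_index:
                raise ValueError(f"duplicate atom key {key}")
            atom_index[key] = len(atom_index) + 1
            coords.append((atom_index[key], a.element, a.coords))
    for f in plan.fragments:
        if not f.member_atoms:
            raise ValueError(f"fragment {f.index} has no atoms")

    if params.basis not in _BASIS_GROUPS:
        raise ValueError(f"unsupported basis {params.basis!r}")

    lines: list[str] = []
    scf = "SCFTYP=RHF" + (" MPLEVL=2" if params.mp2 else "")
    lines.append(f" $CONTRL {scf} RUNTYP=ENERGY ISPHER=1 NPRINT=-5 $END")
    lines.append(f" $SYSTEM MWORDS={params.mwords} $END")
    lines.append(_BASIS_GROUPS[params.basis])
    if params.pcm:
        lines.append(" $PCM SOLVNT=WATER IEF=-10 ICOMP=2 $END")
    charges = " ".join(str(f.charge) for f in plan.fragments)
    lines.append(f" $FMO NBODY={params.nbody} NFRAG={len(plan.fragments)}")
    lines.append(f"  ICHARG(1)={charges}")
    indat_parts: list[str] = ["0"]
    for f in plan.fragments:
        idx = sorted(atom_index[k] for k in f.member_atoms)
        for lo, hi in _indat_runs(idx):
            indat_parts.append(str(lo) if lo == hi else f"{lo} -{hi}")
        indat_parts.append("0")
    lines.append("  INDAT(1)=" + " ".join(indat_parts))
    lines.append(" $END")
    lines.append(" $FMOBND")
    for b in plan.detached_bonds:
        lines.append(f"  -{atom_index[b.bda_atom]} {atom_index[b.baa_atom]}")
    lines.append(" $END")
    lines.append(_FMOHYB_631GSS)
    lines.append(" $FMOXYZ")
    for serial, element, (x, y, z) in coords:
        lines.append(f"  {serial:>6d} {element:<2s} {x:12.3f} {y:12.3f} {z:12.3f}")
    lines.append(" $END")
    return "\n".join(lines) + "\n"
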