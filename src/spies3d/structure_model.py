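"""PDB structure model: reading, subsetting, disulfide detection, validation.

Carries the crystal coordinates that all downstream fragmentation and
inter-fragment distance work depends on.  Parsing and serialization are
delegated to :mod:`gemmi`; this module exposes a small typed view
(:class:`Atom` / :class:`Residue` / :class:`Structure`) in which altloc
groups have already been collapsed to a single atom and waters are
first-class residues.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "DisulfidePair",
    "ValidationIssue",
    "PDBFormatError",
    "EmptyStructureError",
    "SelectionError",
    "read_pdb",
    "read_pdb_string",
    "write_pdb",
    "select_region",
    "detect_disulfides",
    "validate_for_fmo",
]

WATER_NAMES = {"HOH", "WAT", "DOD"}

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common protonation-state variants produced by prep tools
    "HID", "HIE", "HIP", "ASH", "GLH", "LYN", "CYX", "CYM",
}

#: (chain_id, resseq, icode) — the stable identity of a residue.
ResidueKey = tuple[str, int, str]

#: (chain_id, resseq, icode, atom_name) — the stable identity of an atom.
AtomKey = tuple[str, int, str, str]


class PDBFormatError(ValueError):
    """The input could not be parsed as a PDB file."""


class EmptyStructureError(ValueError):
    """A structure or selection contains no atoms."""


class SelectionError(KeyError):
    """A region selection referenced a chain that does not exist."""


@dataclass(frozen=True)
class Atom:
    """One crystallographic atom (altlocs already resolved)."""

    serial: int
    name: str
    element: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(
                f"occupancy {self.occupancy} outside [0, 1] for atom {self.name}"
            )

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


ResidueKind = Literal["amino_acid", "water", "ligand", "other"]


@dataclass(frozen=True)
class Residue:
    """A residue, water, or ligand component of a chain."""

    chain_id: str
    resseq: int
    icode: str
    resname: str
    atoms: tuple[Atom, ...]
    kind: ResidueKind
    het: bool = False

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.resname} {self.resseq} has no atoms")

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.resseq, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_water(self) -> bool:
        return self.kind == "water"


@dataclass(frozen=True)
class Structure:
    """An ordered collection of residues with a stable chain order."""

    residues: tuple[Residue, ...]
    chain_order: tuple[str, ...]
    title: str = ""

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            seen: set[ResidueKey] = set()
            dup = next(k for k in keys if k in seen or seen.add(k))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate residue key {dup}")
        chains = {r.chain_id for r in self.residues}
        if not chains <= set(self.chain_order):
            raise ValueError("chain_order does not cover all chains")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def get(self, key: ResidueKey) -> Residue:
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(key)

    def chain(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def atom_coords(self) -> np.ndarray:
        """All atom coordinates, residue order, shape (n_atoms, 3)."""
        return np.array(
            [a.coords for r in self.residues for a in r.atoms], dtype=float
        )


@dataclass(frozen=True)
class DisulfidePair:
    """Two cysteines whose SG atoms are within bonding distance."""

    cys_a: ResidueKey
    cys_b: ResidueKey
    sg_distance: float


@dataclass(frozen=True)
class ValidationIssue:
    kind: str
    residue: ResidueKey | None
    message: str


def _classify(resname: str, het: bool) -> ResidueKind:
    if resname in WATER_NAMES:
        return "water"
    if resname in STANDARD_AMINO_ACIDS:
        return "amino_acid"
    if het:
        return "ligand"
    return "other"


def _resolve_altlocs(
    atoms: list[Atom], policy: str
) -> list[Atom]:
    """Collapse each altloc group (same atom name) to a single atom."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out: list[Atom] = []
    for name in order:
        group = by_name[name]
        if len(group) == 1:
            out.append(group[0])
        elif policy == "first":
            out.append(group[0])
        elif policy == "highest_occupancy":
            # ties broken by altloc letter order
            out.append(max(group, key=lambda a: (a.occupancy, _neg_ord(a.altloc))))
        else:
            raise ValueError(f"unknown altloc policy {policy!r}")
    return out


def _neg_ord(altloc: str) -> float:
    return -ord(altloc) if altloc else 0.0


def _from_gemmi(st: gemmi.Structure, altloc_policy: str) -> Structure:
    st.setup_entities()
    residues: list[Residue] = []
    chain_order: list[str] = []
    model = st[0]
    for chain in model:
        if chain.name not in chain_order:
            chain_order.append(chain.name)
        for res in chain:
            atoms = [
                Atom(
                    serial=a.serial,
                    name=a.name,
                    element=a.element.name,
                    coords=(round(a.pos.x, 3), round(a.pos.y, 3), round(a.pos.z, 3)),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    altloc=a.altloc if a.altloc != "\0" else "",
                )
                for a in res
            ]
            atoms = _resolve_altlocs(atoms, altloc_policy)
            het = res.het_flag == "H"
            residues.append(
                Residue(
                    chain_id=chain.name,
                    resseq=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    resname=res.name,
                    atoms=tuple(atoms),
                    kind=_classify(res.name, het),
                    het=het,
                )
            )
    if not residues:
        raise EmptyStructureError("structure contains no atoms")
    return Structure(
        residues=tuple(residues),
        chain_order=tuple(chain_order),
        title=st.name or "",
    )


def read_pdb(
    path: str | Path, altloc_policy: str = "highest_occupancy"
) -> Structure:
    """Read a PDB file, keeping waters and resolving altlocs per policy.

    Parameters
    ----------
    path:
        PDB-format file (ATOM/HETATM/TER records).
    altloc_policy:
        ``"highest_occupancy"`` (ties broken by altloc letter order) or
        ``"first"`` (file order).
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"cannot parse {path}: {exc}") from exc
    return _from_gemmi(st, altloc_policy)


def read_pdb_string(
    text: str, altloc_policy: str = "highest_occupancy", name: str = ""
) -> Structure:
    """Read a PDB-format string (used heavily by the synthetic fixtures)."""
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"cannot parse PDB text: {exc}") from exc
    st.name = name
    return _from_gemmi(st, altloc_policy)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure back to PDB; round-trips through :func:`read_pdb`."""
    Path(path).write_text(to_pdb_string(structure))


def to_pdb_string(structure: Structure) -> str:
    st = gemmi.Structure()
    st.name = structure.title
    model = gemmi.Model("1")
    for cid in structure.chain_order:
        residues = structure.chain(cid)
        if not residues:
            continue
        chain = gemmi.Chain(cid)
        for r in residues:
            gr = gemmi.Residue()
            gr.name = r.resname
            gr.seqid = gemmi.SeqId(r.resseq, r.icode or " ")
            gr.het_flag = "H" if r.het else "A"
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                ga.serial = a.serial
                if a.altloc:
                    ga.altloc = a.altloc
                gr.add_atom(ga)
            chain.add_residue(gr)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


RangeSpec = Sequence[tuple[int, int]] | None  # None means the whole chain


def select_region(
    structure: Structure,
    keep: Mapping[str, RangeSpec],
    waters_within: float | None = None,
) -> Structure:
    """Subset a structure to chains/residue ranges, optionally with nearby waters.

    Parameters
    ----------
    keep:
        Map chain id -> list of inclusive ``(start, end)`` resseq ranges, or
        ``None`` for the whole chain.
    waters_within:
        If given, additionally retain every water whose closest atom lies
        within this radius (Å) of any explicitly kept non-water atom.  This
        mirrors trimming an antibody to its Fv domains while keeping the
        crystallographic waters around the region.
    """
    missing = set(keep) - set(structure.chain_order)
    if missing:
        raise SelectionError(f"chain(s) not in structure: {sorted(missing)}")

    def _kept(r: Residue) -> bool:
        if r.chain_id not in keep:
            return False
        ranges = keep[r.chain_id]
        if ranges is None:
            return True
        return any(lo <= r.resseq <= hi for lo, hi in ranges)

    kept = [r for r in structure.residues if _kept(r)]
    if waters_within is not None:
        anchor = np.array(
            [a.coords for r in kept if not r.is_water for a in r.atoms], dtype=float
        )
        if anchor.size:
            kept_keys = {r.key for r in kept}
            for r in structure.residues:
                if not r.is_water or r.key in kept_keys:
                    continue
                pos = np.array([a.coords for a in r.atoms], dtype=float)
                d2 = ((pos[:, None, :] - anchor[None, :, :]) ** 2).sum(-1)
                if math.sqrt(d2.min()) <= waters_within:
                    kept.append(r)
    if not kept:
        raise EmptyStructureError("selection is empty")
    order = {k: i for i, k in enumerate(r.key for r in structure.residues)}
    kept.sort(key=lambda r: order[r.key])
    chains = tuple(c for c in structure.chain_order if any(r.chain_id == c for r in kept))
    return Structure(residues=tuple(kept), chain_order=chains, title=structure.title)


def detect_disulfides(
    structure: Structure, sg_cutoff: float = 2.5
) -> list[DisulfidePair]:
    """Pair cysteines by ascending SG–SG distance (greedy), up to ``sg_cutoff`` Å.

    Each CYS ends up in at most one pair.  CYS residues lacking an SG atom
    are skipped with a warning.
    """
    if sg_cutoff <= 0:
        raise ValueError("sg_cutoff must be positive")
    cys: list[tuple[ResidueKey, np.ndarray]] = []
    for r in structure.residues:
        if r.resname not in ("CYS", "CYX"):
            continue
        sg = r.atom("SG")
        if sg is None:
            warnings.warn(f"CYS {r.key} lacks an SG atom; skipped", stacklevel=2)
            continue
        cys.append((r.key, np.asarray(sg.coords)))
    candidates: list[tuple[float, ResidueKey, ResidueKey]] = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = float(np.linalg.norm(cys[i][1] - cys[j][1]))
            if d <= sg_cutoff:
                ka, kb = sorted((cys[i][0], cys[j][0]))
                candidates.append((d, ka, kb))
    candidates.sort()
    used: set[ResidueKey] = set()
    pairs: list[DisulfidePair] = []
    for d, ka, kb in candidates:
        if ka in used or kb in used:
            continue
        used.update((ka, kb))
        pairs.append(DisulfidePair(cys_a=ka, cys_b=kb, sg_distance=round(d, 3)))
    return pairs


CHAIN_BREAK_CA_CA = 4.5  # Å; advisory flag only


def validate_for_fmo(structure: Structure) -> list[ValidationIssue]:
    """Advisory pre-fragmentation checks; never mutates the structure.

    Flags residues with no hydrogens (charge assignment needs protons),
    unknown residue names, leftover altloc markers, and chain breaks
    (consecutive amino acids with Cα–Cα beyond 4.5 Å).
    """
    issues: list[ValidationIssue] = []
    for r in structure.residues:
        if r.kind == "amino_acid" and not any(a.is_hydrogen for a in r.atoms):
            issues.append(
                ValidationIssue("no_hydrogens", r.key, f"{r.resname} has no hydrogens")
            )
        if r.kind == "other":
            issues.append(
                ValidationIssue(
                    "unknown_residue", r.key, f"unrecognized residue name {r.resname}"
                )
            )
        names = [a.name for a in r.atoms]
        if len(names) != len(set(names)):
            issues.append(
                ValidationIssue(
                    "unresolved_altloc", r.key, "duplicate atom names within residue"
                )
            )
    for cid in structure.chain_order:
        aa = [r for r in structure.chain(cid) if r.kind == "amino_acid"]
        for prev, curr in zip(aa, aa[1:]):
            ca1, ca2 = prev.atom("CA"), curr.atom("CA")
            if ca1 is None or ca2 is None:
                continue
            d = float(np.linalg.norm(np.subtract(ca1.coords, ca2.coords)))
            if d > CHAIN_BREAK_CA_CA:
                issues.append(
                    ValidationIssue(
                        "chain_break",
                        curr.key,
                        f"Cα–Cα {d:.1f} Å between {prev.resseq} and {curr.resseq}",
                    )
                )
    return issues
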