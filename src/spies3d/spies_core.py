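"""3D scattered pair interaction energies (3D-SPIEs).

FMO pair interaction energies are notoriously overestimated at long range
(electrostatics), so raw PIE tables are screened twice before analysis:

* a geometric screen — keep fragment pairs whose *single-linkage* distance
  (minimum over all atom pairs) is within a cutoff, default 5.4 Å, the
  separation used for the electrostatic-potential approximation in FMO;
* an energetic screen — keep attractive pairs at least as stable as a
  significance threshold, default −3.0 kcal/mol.

Both boundaries are inclusive.  Each surviving pair becomes one dot of the
3D scatter (fragment i, fragment j, distance; energy as color) and is
classified as inter-group (PPI), intra-group (non-PPI), or water-mediated;
water-mediated legs on both sides of an interface form water bridges.
Runs of sequence-adjacent interface residues are grouped into hot-spot
regions, and boolean residue × complex interaction maps aggregate several
complexes against a common target protein.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from spies3d.fragmentation import Fragment, FragmentationPlan
from spies3d.pieda_parse import PairInteraction, PIETable
from spies3d.structure_model import Structure

__all__ = [
    "SPIESParams",
    "SPIERecord",
    "WaterBridge",
    "HotspotRegion",
    "InteractionMap",
    "min_fragment_distance",
    "all_pair_distances",
    "spies_filter",
    "classify_pairs",
    "detect_water_bridges",
    "hotspot_regions",
    "build_interaction_map",
    "export_scatter",
    "write_spie_records",
    "read_spie_records",
    "write_water_bridges",
]

InteractionClass = Literal["inter_group", "intra_group", "water_mediated", "water_water"]


@dataclass(frozen=True)
class SPIESParams:
    """Filter settings for the 3D-SPIEs screen (inclusive boundaries)."""

    distance_cutoff: float = 5.4  # Å
    attractive_threshold: float = -3.0  # kcal/mol
    include_repulsive: bool = False
    heavy_atoms_only: bool = False

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be positive")


@dataclass(frozen=True)
class SPIERecord:
    """One retained dot of the 3D scatter: a fragment pair that passed the screen."""

    frag_i: int
    frag_j: int
    label_i: str
    label_j: str
    chain_i: str
    chain_j: str
    kind_i: str
    kind_j: str
    resseq_i: int
    resseq_j: int
    distance: float  # Å, single linkage
    pie: float  # kcal/mol
    components: Mapping[str, float | None]
    iclass: InteractionClass | None = None
    group_i: str | None = None
    group_j: str | None = None


@dataclass(frozen=True)
class WaterBridge:
    """A water fragment attractively bound to residues on both interface sides."""

    water_label: str
    partner_a: str
    partner_b: str
    group_a: str
    group_b: str
    pie_a: float
    pie_b: float


@dataclass(frozen=True)
class HotspotRegion:
    """A run of sequence-adjacent residues carrying attractive PPI."""

    chain_group: str
    residues: tuple[int, ...]
    span: tuple[int, int]
    support: int  # retained inter-group records involving the region


# ---------------------------------------------------------------------------
# distances

def _fragment_coords(
    plan: FragmentationPlan, structure: Structure, heavy_only: bool = False
) -> dict[int, np.ndarray]:
    coords: dict[int, list[tuple[float, float, float]]] = {
        f.index: [] for f in plan.fragments
    }
    owner: dict[tuple, int] = {}
    for f in plan.fragments:
        for key in f.member_atoms:
            owner[key] = f.index
    for res in structure.residues:
        for a in res.atoms:
            key = (res.chain_id, res.resseq, res.icode, a.name)
            fi = owner.get(key)
            if fi is None:
                continue
            if heavy_only and a.is_hydrogen:
                continue
            coords[fi].append(a.coords)
    return {i: np.asarray(c, dtype=float) for i, c in coords.items()}


def min_fragment_distance(
    plan: FragmentationPlan,
    structure: Structure,
    i: int,
    j: int,
    heavy_atoms_only: bool = False,
) -> float:
    """Single-linkage distance between fragments i and j (Å).

    The minimum over all atom pairs of the Euclidean distance; symmetric.
    Two fragments joined by a detached Cα–C bond are this bond length apart.
    """
    if i == j:
        raise ValueError("i and j must differ")
    coords = _fragment_coords(plan, structure, heavy_atoms_only)
    a, b = coords[i], coords[j]
    if a.size == 0 or b.size == 0:
        raise ValueError(f"fragment {i if a.size == 0 else j} has no atoms")
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    return float(math.sqrt(d2.min()))


def all_pair_distances(
    plan: FragmentationPlan,
    structure: Structure,
    cutoff: float = 5.4,
    heavy_atoms_only: bool = False,
    backend: Literal["kdtree", "naive"] = "kdtree",
) -> dict[tuple[int, int], float]:
    """All fragment pairs with single-linkage distance ≤ cutoff (inclusive).

    The k-d-tree backend enumerates atom pairs within the cutoff and keeps
    the minimum per fragment pair — identical to the naive double loop,
    which remains available for cross-checking.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frag_coords = _fragment_coords(plan, structure, heavy_atoms_only)
    if backend == "naive":
        out: dict[tuple[int, int], float] = {}
        idx = sorted(frag_coords)
        for a_pos, i in enumerate(idx):
            for j in idx[a_pos + 1:]:
                a, b = frag_coords[i], frag_coords[j]
                if a.size == 0 or b.size == 0:
                    continue
                d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
                d = math.sqrt(d2.min())
                if d <= cutoff:
                    out[(i, j)] = d
        return out
    # kdtree backend
    pts: list[np.ndarray] = []
    frag_of: list[int] = []
    for i in sorted(frag_coords):
        c = frag_coords[i]
        if c.size == 0:
            continue
        pts.append(c)
        frag_of.extend([i] * len(c))
    all_pts = np.concatenate(pts, axis=0)
    frag_arr = np.asarray(frag_of)
    tree = cKDTree(all_pts)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    out = {}
    if len(pairs):
        fi = frag_arr[pairs[:, 0]]
        fj = frag_arr[pairs[:, 1]]
        mask = fi != fj
        d = np.linalg.norm(all_pts[pairs[mask, 0]] - all_pts[pairs[mask, 1]], axis=1)
        for (a, b), dist in zip(np.stack([fi[mask], fj[mask]], axis=1), d):
            key = (int(min(a, b)), int(max(a, b)))
            if key not in out or dist < out[key]:
                out[key] = float(dist)
    return out


# ---------------------------------------------------------------------------
# filtering and classification

def _frag_meta(f: Fragment) -> tuple[str, int]:
    chain, resseq, _icode = f.source_residues[0][0], f.source_residues[0][1], f.source_residues[0][2]
    return chain, resseq


def spies_filter(
    table: PIETable,
    distances: Mapping[tuple[int, int], float],
    plan: FragmentationPlan,
    params: SPIESParams | None = None,
) -> list[SPIERecord]:
    """Apply the 3D-SPIEs distance/energy screen to a PIE table.

    Keeps pairs with single-linkage distance ≤ ``distance_cutoff`` and
    (unless ``include_repulsive``) PIE ≤ ``attractive_threshold``; both
    boundaries inclusive.  ``distances`` must have been computed with a
    cutoff at least as large as the filter's.
    """
    params = params or SPIESParams()
    frag_by_index = {f.index: f for f in plan.fragments}
    out: list[SPIERecord] = []
    for rec in table.records:
        fi = frag_by_index.get(rec.frag_i)
        fj = frag_by_index.get(rec.frag_j)
        if fi is None or fj is None:
            warnings.warn(
                f"pair ({rec.frag_i},{rec.frag_j}) not in fragmentation plan; dropped",
                stacklevel=2,
            )
            continue
        d = distances.get((rec.frag_i, rec.frag_j))
        if d is None or d > params.distance_cutoff:
            continue
        pie = rec.pie
        if not params.include_repulsive and pie > params.attractive_threshold:
            continue
        chain_i, resseq_i = _frag_meta(fi)
        chain_j, resseq_j = _frag_meta(fj)
        out.append(
            SPIERecord(
                frag_i=rec.frag_i,
                frag_j=rec.frag_j,
                label_i=rec.label_i or fi.label,
                label_j=rec.label_j or fj.label,
                chain_i=chain_i,
                chain_j=chain_j,
                kind_i=fi.kind,
                kind_j=fj.kind,
                resseq_i=resseq_i,
                resseq_j=resseq_j,
                distance=d,
                pie=pie,
                components=rec.components,
            )
        )
    return out


def classify_pairs(
    records: Sequence[SPIERecord],
    chain_groups: Mapping[str, str],
) -> list[SPIERecord]:
    """Assign each record an interaction class from the chain-group map.

    Different groups → ``inter_group`` (PPI); same group → ``intra_group``
    (non-PPI); one water fragment → ``water_mediated``; both waters →
    ``water_water``.  Antibody heavy and light chains are conventionally
    mapped to a single group so their mutual contacts stay intra-group.
    """
    out: list[SPIERecord] = []
    for r in records:
        wi, wj = r.kind_i == "water", r.kind_j == "water"
        for chain, is_water in ((r.chain_i, wi), (r.chain_j, wj)):
            if chain not in chain_groups and not is_water:
                raise KeyError(f"chain {chain!r} not mapped to a group")
        gi = chain_groups.get(r.chain_i, "water" if wi else "")
        gj = chain_groups.get(r.chain_j, "water" if wj else "")
        if wi and wj:
            iclass: InteractionClass = "water_water"
        elif wi or wj:
            iclass = "water_mediated"
        elif gi != gj:
            iclass = "inter_group"
        else:
            iclass = "intra_group"
        out.append(replace(r, iclass=iclass, group_i=gi, group_j=gj))
    return out


def detect_water_bridges(records: Sequence[SPIERecord]) -> list[WaterBridge]:
    """Enumerate water bridges among classified, retained records.

    A bridge is a (water, a, b) triple where both water–a and water–b are
    retained ``water_mediated`` records and a and b belong to different
    chain groups.  Enumeration is exhaustive over the retained records;
    water–water contacts never participate.
    """
    legs: dict[str, list[tuple[str, str, float]]] = {}
    for r in records:
        if r.iclass != "water_mediated":
            continue
        if r.kind_i == "water":
            water, partner, pgroup = r.label_i, r.label_j, r.group_j
        else:
            water, partner, pgroup = r.label_j, r.label_i, r.group_i
        legs.setdefault(water, []).append((partner, pgroup or "", r.pie))
    bridges: list[WaterBridge] = []
    for water in sorted(legs):
        partners = sorted(legs[water])
        for x in range(len(partners)):
            for y in range(x + 1, len(partners)):
                pa, ga, ea = partners[x]
                pb, gb, eb = partners[y]
                if ga == gb:
                    continue
                bridges.append(
                    WaterBridge(
                        water_label=water,
                        partner_a=pa,
                        partner_b=pb,
                        group_a=ga,
                        group_b=gb,
                        pie_a=ea,
                        pie_b=eb,
                    )
                )
    return bridges


def hotspot_regions(
    records: Sequence[SPIERecord],
    group: str,
    gap_tolerance: int = 2,
) -> list[HotspotRegion]:
    """Group interface residues of one protein into hot-spot regions.

    Collects the residues of ``group`` appearing in retained inter-group
    records, sorts them by author resseq, and splits the list wherever two
    consecutive members differ by more than ``gap_tolerance``.  Support is
    the number of inter-group records touching the region.
    """
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    touches: dict[int, int] = {}
    for r in records:
        if r.iclass != "inter_group":
            continue
        if r.group_i == group:
            touches[r.resseq_i] = touches.get(r.resseq_i, 0) + 1
        if r.group_j == group:
            touches[r.resseq_j] = touches.get(r.resseq_j, 0) + 1
    if not touches:
        return []
    resseqs = sorted(touches)
    runs: list[list[int]] = [[resseqs[0]]]
    for s in resseqs[1:]:
        if s - runs[-1][-1] <= gap_tolerance:
            runs[-1].append(s)
        else:
            runs.append([s])
    return [
        HotspotRegion(
            chain_group=group,
            residues=tuple(run),
            span=(run[0], run[-1]),
            support=sum(touches[s] for s in run),
        )
        for run in runs
    ]


# ---------------------------------------------------------------------------
# interaction map

@dataclass(frozen=True)
class InteractionMap:
    """Boolean residue × complex matrix of significant attractive interactions."""

    residues: tuple[str, ...]  # row labels of the common target protein
    resseqs: tuple[int, ...]
    complexes: tuple[str, ...]  # column names
    present: tuple[tuple[bool, ...], ...]  # rows × columns
    strongest: tuple[tuple[float | None, ...], ...]  # most attractive PIE or None

    @property
    def commonality(self) -> tuple[int, ...]:
        """Per-residue count of complexes with a significant interaction."""
        return tuple(sum(row) for row in self.present)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [list(row) for row in self.present],
            index=list(self.residues),
            columns=list(self.complexes),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "residues": list(self.residues),
                "resseqs": list(self.resseqs),
                "complexes": list(self.complexes),
                "present": [list(r) for r in self.present],
                "strongest": [list(r) for r in self.strongest],
                "commonality": list(self.commonality),
            },
            indent=2,
        )


def build_interaction_map(
    record_sets: Mapping[str, Sequence[SPIERecord]],
    target_group: str,
) -> InteractionMap:
    """Aggregate several complexes' records against one common target protein.

    A cell (residue, complex) is true iff at least one retained inter-group
    record in that complex involves the residue (on the target side) and a
    partner-molecule fragment.  Rows are sorted by resseq.  Residues whose
    label differs between complexes at the same resseq raise an error
    listing the mismatches.
    """
    label_by_resseq: dict[int, str] = {}
    mismatches: list[str] = []
    hits: dict[str, dict[int, float]] = {name: {} for name in record_sets}
    for name, records in record_sets.items():
        for r in records:
            if r.iclass != "inter_group":
                continue
            for resseq, label, grp in (
                (r.resseq_i, r.label_i, r.group_i),
                (r.resseq_j, r.label_j, r.group_j),
            ):
                if grp != target_group:
                    continue
                prev = label_by_resseq.get(resseq)
                if prev is None:
                    label_by_resseq[resseq] = label
                elif prev != label:
                    mismatches.append(f"resseq {resseq}: {prev!r} vs {label!r} ({name})")
                best = hits[name].get(resseq)
                if best is None or r.pie < best:
                    hits[name][resseq] = r.pie
    if mismatches:
        raise ValueError("inconsistent target labels across complexes: " + "; ".join(mismatches))
    resseqs = tuple(sorted(label_by_resseq))
    complexes = tuple(record_sets)
    present = tuple(
        tuple(s in hits[name] for name in complexes) for s in resseqs
    )
    strongest = tuple(
        tuple(hits[name].get(s) for name in complexes) for s in resseqs
    )
    return InteractionMap(
        residues=tuple(label_by_resseq[s] for s in resseqs),
        resseqs=resseqs,
        complexes=complexes,
        present=present,
        strongest=strongest,
    )


# ---------------------------------------------------------------------------
# CSV I/O for retained records and bridges

_SPIE_COLUMNS = [
    "frag_i", "frag_j", "label_i", "label_j", "chain_i", "chain_j",
    "kind_i", "kind_j", "resseq_i", "resseq_j", "distance",
    "e_es", "e_ex", "e_ct_mix", "e_di", "g_sol", "pie",
    "iclass", "group_i", "group_j",
]


def write_spie_records(records: Sequence[SPIERecord], path) -> None:
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "frag_i": r.frag_i, "frag_j": r.frag_j,
            "label_i": r.label_i, "label_j": r.label_j,
            "chain_i": r.chain_i, "chain_j": r.chain_j,
            "kind_i": r.kind_i, "kind_j": r.kind_j,
            "resseq_i": r.resseq_i, "resseq_j": r.resseq_j,
            "distance": r.distance,
            "e_es": r.components.get("e_es"),
            "e_ex": r.components.get("e_ex"),
            "e_ct_mix": r.components.get("e_ct_mix"),
            "e_di": r.components.get("e_di"),
            "g_sol": r.components.get("g_sol"),
            "pie": r.pie,
            "iclass": r.iclass or "",
            "group_i": r.group_i or "", "group_j": r.group_j or "",
        }
        rows.append(row)
    pd.DataFrame(rows, columns=_SPIE_COLUMNS).to_csv(path, index=False, float_format="%.6f")


def read_spie_records(path) -> list[SPIERecord]:
    import pandas as pd

    df = pd.read_csv(path, keep_default_na=False, na_values=[""])

    def _opt(v):
        return None if (isinstance(v, float) and math.isnan(v)) or v == "" else v

    out: list[SPIERecord] = []
    for row in df.to_dict(orient="records"):
        g_sol = _opt(row.get("g_sol"))
        out.append(
            SPIERecord(
                frag_i=int(row["frag_i"]), frag_j=int(row["frag_j"]),
                label_i=str(row["label_i"]), label_j=str(row["label_j"]),
                chain_i=str(row["chain_i"]), chain_j=str(row["chain_j"]),
                kind_i=str(row["kind_i"]), kind_j=str(row["kind_j"]),
                resseq_i=int(row["resseq_i"]), resseq_j=int(row["resseq_j"]),
                distance=float(row["distance"]), pie=float(row["pie"]),
                components={
                    "e_es": float(row["e_es"]), "e_ex": float(row["e_ex"]),
                    "e_ct_mix": float(row["e_ct_mix"]), "e_di": float(row["e_di"]),
                    "g_sol": None if g_sol is None else float(g_sol),
                },
                iclass=_opt(str(row["iclass"]) or None),
                group_i=_opt(str(row["group_i"]) or None),
                group_j=_opt(str(row["group_j"]) or None),
            )
        )
    return out


def write_water_bridges(bridges: Sequence[WaterBridge], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "water": b.water_label,
                "partner_a": b.partner_a, "group_a": b.group_a, "pie_a": b.pie_a,
                "partner_b": b.partner_b, "group_b": b.group_b, "pie_b": b.pie_b,
            }
            for b in bridges
        ],
        columns=["water", "partner_a", "group_a", "pie_a", "partner_b", "group_b", "pie_b"],
    ).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# scatter export

def export_scatter(records: Sequence[SPIERecord]) -> list[dict]:
    """Serialize records as plot dots: x/y fragment labels, z distance, PIE value.

    Returns JSON-serializable dicts; an interactive rendering layer may
    consume them but never alters this representation.
    """
    return [
        {
            "x": r.label_i,
            "y": r.label_j,
            "z": r.distance,
            "value": r.pie,
            "iclass": r.iclass,
            "hover": {k: v for k, v in r.components.items()},
        }
        for r in records
    ]
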