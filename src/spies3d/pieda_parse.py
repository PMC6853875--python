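"""Parse FMO2/PIEDA pair-interaction tables from GAMESS output.

A pair interaction energy (PIE) between fragments i and j decomposes into
electrostatic, exchange-repulsion, charge-transfer(+mix), and dispersion
terms, with an optional solvent-screening term:

    PIE = ΔE_es + ΔE_ex + ΔE_ct+mix + ΔE_di [+ ΔG_sol]

Energies are kept in kcal/mol exactly as printed by the PIEDA summary
table; no unit conversion is attempted.  Parsing is whitespace-tolerant
(column names, not fixed offsets) and the supported dialect is
table-driven so other GAMESS vintages are a configuration entry.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PairInteraction",
    "PIETable",
    "PIEDAParseError",
    "parse_fmo_output",
    "total_pie",
    "write_pie_table",
    "read_pie_table",
]

EQ1_TOLERANCE = 1e-3  # kcal/mol; printed total vs component sum
FLAG_TOLERANCE = 1e-2  # kcal/mol; beyond this the record is flagged


class PIEDAParseError(ValueError):
    """No recognizable PIEDA summary block in the input text."""


@dataclass(frozen=True)
class PairInteraction:
    """PIEDA record for one fragment pair (energies in kcal/mol)."""

    frag_i: int
    frag_j: int
    e_es: float
    e_ex: float
    e_ct_mix: float
    e_di: float
    g_sol: float | None = None
    total: float | None = None
    label_i: str = ""
    label_j: str = ""

    def __post_init__(self) -> None:
        if not self.frag_i < self.frag_j:
            raise ValueError(f"require frag_i < frag_j, got ({self.frag_i}, {self.frag_j})")

    @property
    def pie(self) -> float:
        """The total PIE: printed total if present, else the component sum."""
        return self.total if self.total is not None else total_pie(self)

    @property
    def components(self) -> dict[str, float | None]:
        return {
            "e_es": self.e_es,
            "e_ex": self.e_ex,
            "e_ct_mix": self.e_ct_mix,
            "e_di": self.e_di,
            "g_sol": self.g_sol,
        }

    def sum_consistent(self, tol: float = FLAG_TOLERANCE) -> bool:
        """Whether the printed total matches the component sum within tol."""
        if self.total is None:
            return True
        return abs(self.total - total_pie(self)) <= tol


def total_pie(record: PairInteraction) -> float:
    """Sum the PIEDA components (ΔG_sol treated as 0 when absent)."""
    g = record.g_sol if record.g_sol is not None else 0.0
    return record.e_es + record.e_ex + record.e_ct_mix + record.e_di + g


@dataclass(frozen=True)
class PIETable:
    """All pair interactions from one FMO run."""

    records: tuple[PairInteraction, ...]
    n_fragments: int
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for r in self.records:
            ij = (r.frag_i, r.frag_j)
            if ij in seen:
                raise ValueError(f"duplicate pair {ij}")
            seen.add(ij)
            if r.frag_j > self.n_fragments:
                raise ValueError(
                    f"pair {ij} references fragment beyond n_fragments={self.n_fragments}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def get(self, i: int, j: int) -> PairInteraction:
        i, j = min(i, j), max(i, j)
        for r in self.records:
            if (r.frag_i, r.frag_j) == (i, j):
                return r
        raise KeyError((i, j))

    def inconsistent_records(self, tol: float = FLAG_TOLERANCE) -> list[PairInteraction]:
        """Records whose printed total deviates from the component sum.

        Flagged, never silently corrected.
        """
        return [r for r in self.records if not r.sum_consistent(tol)]


# ---------------------------------------------------------------------------
# GAMESS output parsing

#: Column-name map of the supported PIEDA summary dialect (2016-era FMO2
#: GAMESS).  Other vintages can be handled by passing a different map.
DEFAULT_DIALECT: Mapping[str, str] = {
    "I": "frag_i",
    "J": "frag_j",
    "ES": "e_es",
    "EX": "e_ex",
    "CT+MIX": "e_ct_mix",
    "DI": "e_di",
    "DISP": "e_di",
    "SOLV": "g_sol",
    "GSOL": "g_sol",
    "TOTAL": "total",
}

_BLOCK_MARKER = "PAIR INTERACTION ENERGY DECOMPOSITION"


def parse_fmo_output(
    text: str,
    dialect: Mapping[str, str] = DEFAULT_DIALECT,
    n_fragments: int | None = None,
) -> PIETable:
    """Extract the PIEDA summary table from GAMESS output text.

    The parser scans for the PIEDA block marker, reads the column-header
    line, maps columns through ``dialect``, and whitespace-splits the data
    rows — robust to column-width drift and to arbitrary preamble.
    Malformed rows are skipped with a line-numbered warning; duplicate
    (i, j) rows are last-wins (restart files repeat blocks).
    """
    lines = text.splitlines()
    start = None
    for k, line in enumerate(lines):
        if _BLOCK_MARKER in line.upper():
            start = k
            break
    if start is None:
        raise PIEDAParseError("no PIEDA summary block found")

    header_cols: list[str] | None = None
    header_line = 0
    for k in range(start + 1, len(lines)):
        toks = lines[k].split()
        if toks and toks[0].upper() == "I" and "J" in (t.upper() for t in toks):
            header_cols = [t.upper() for t in toks]
            header_line = k
            break
    if header_cols is None:
        raise PIEDAParseError("PIEDA block has no column header line")

    mapped = [dialect.get(c) for c in header_cols]
    by_pair: dict[tuple[int, int], PairInteraction] = {}
    nfrag_seen = 0
    for k in range(header_line + 1, len(lines)):
        raw = lines[k]
        toks = raw.split()
        if not toks:
            continue
        if raw.lstrip().startswith(("-", "=")) and set(raw.strip()) <= set("-="):
            continue  # rule line under the header
        if not toks[0].lstrip("-").isdigit():
            break  # end of table
        if len(toks) != len(header_cols):
            warnings.warn(f"malformed PIEDA row at line {k + 1}; skipped", stacklevel=2)
            continue
        row: dict[str, float] = {}
        try:
            for col, tok in zip(mapped, toks):
                if col is not None:
                    row[col] = float(tok)
        except ValueError:
            warnings.warn(f"malformed PIEDA row at line {k + 1}; skipped", stacklevel=2)
            continue
        i, j = int(row.pop("frag_i")), int(row.pop("frag_j"))
        i, j = min(i, j), max(i, j)
        if (i, j) in by_pair:
            warnings.warn(f"duplicate pair ({i},{j}); last occurrence wins", stacklevel=2)
        rec = PairInteraction(
            frag_i=i,
            frag_j=j,
            e_es=row.get("e_es", 0.0),
            e_ex=row.get("e_ex", 0.0),
            e_ct_mix=row.get("e_ct_mix", 0.0),
            e_di=row.get("e_di", 0.0),
            g_sol=row.get("g_sol"),
            total=row.get("total"),
        )
        by_pair[(i, j)] = rec
        nfrag_seen = max(nfrag_seen, j)
    if n_fragments is None:
        n_fragments = nfrag_seen
    records = tuple(by_pair[ij] for ij in sorted(by_pair))
    return PIETable(
        records=records,
        n_fragments=n_fragments,
        metadata={"source": "gamess-fmo2", "block": _BLOCK_MARKER},
    )


# ---------------------------------------------------------------------------
# CSV interchange

CSV_COLUMNS = [
    "frag_i", "frag_j", "label_i", "label_j",
    "e_es", "e_ex", "e_ct_mix", "e_di", "g_sol", "total",
]


def write_pie_table(table: PIETable, path: str | Path) -> None:
    """Write the interchange CSV (absent ΔG_sol emitted as an empty cell)."""
    rows = []
    for r in table.records:
        rows.append(
            {
                "frag_i": r.frag_i,
                "frag_j": r.frag_j,
                "label_i": r.label_i,
                "label_j": r.label_j,
                "e_es": r.e_es,
                "e_ex": r.e_ex,
                "e_ct_mix": r.e_ct_mix,
                "e_di": r.e_di,
                "g_sol": r.g_sol,
                "total": r.pie,
            }
        )
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")
    meta = dict(table.metadata) | {"n_fragments": str(table.n_fragments)}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


def _clean_str(v: object) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    return str(v)


def read_pie_table(path: str | Path) -> PIETable:
    """Read the interchange CSV written by :func:`write_pie_table`."""
    df = pd.read_csv(path)
    missing = {"frag_i", "frag_j", "e_es", "e_ex", "e_ct_mix", "e_di"} - set(df.columns)
    if missing:
        raise ValueError(f"PIE table missing mandatory columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        g_sol = getattr(row, "g_sol", None)
        if g_sol is not None and (isinstance(g_sol, float) and math.isnan(g_sol)):
            g_sol = None
        total = getattr(row, "total", None)
        if total is not None and (isinstance(total, float) and math.isnan(total)):
            total = None
        records.append(
            PairInteraction(
                frag_i=int(row.frag_i),
                frag_j=int(row.frag_j),
                e_es=float(row.e_es),
                e_ex=float(row.e_ex),
                e_ct_mix=float(row.e_ct_mix),
                e_di=float(row.e_di),
                g_sol=None if g_sol is None else float(g_sol),
                total=None if total is None else float(total),
                label_i=_clean_str(getattr(row, "label_i", "")),
                label_j=_clean_str(getattr(row, "label_j", "")),
            )
        )
    n_frag = max((r.frag_j for r in records), default=0)
    meta_path = Path(str(path) + ".meta.json")
    metadata: dict[str, str] = {}
    if meta_path.exists():
        metadata = json.loads(meta_path.read_text())
        n_frag = max(n_frag, int(metadata.get("n_fragments", n_frag)))
    return PIETable(records=tuple(records), n_fragments=n_frag, metadata=metadata)
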