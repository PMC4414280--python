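"""Continuous morphological character matrix construction and export.

The landmark (200), chromaticity (63) and Gabor (510) coefficient blocks
of each specimen concatenate into 773 candidate characters.  Characters
that are zero for every specimen are dropped; each remaining character is
z-standardized (mean 0, sd 1), min-max rescaled to [0, 1], and rounded to
three decimals (half-even).  The result exports as a TNT continuous-
character block or a NEXUS continuous-datatype file for parsimony
software; both formats round-trip exactly.

A constant non-zero character (sd = 0) has no z-score: it is retained at
the midpoint value 0.5 and logged rather than silently dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = ["CharacterMatrix", "build_matrix", "export_matrix", "read_matrix"]


@dataclass
class CharacterMatrix:
    values: pd.DataFrame  # taxa x characters, values in [0, 1] at 3 decimals
    provenance: pd.DataFrame  # per retained column: source set + original index
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)  # dropped-column log
    name_map: dict[str, str] = field(default_factory=dict)  # raw -> sanitized taxa

    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]

    @property
    def n_characters(self) -> int:
        return self.values.shape[1]


def build_matrix(
    landmark: pd.DataFrame, chrm: pd.DataFrame, gwt: pd.DataFrame, ddof: int = 1
) -> CharacterMatrix:
    """Concatenate, filter, standardize, rescale and round the three blocks.

    All blocks must be indexed by the same specimens in the same order.
    """
    blocks = {"LM": landmark, "CHRM": chrm, "GWT": gwt}
    idx = landmark.index
    for name, b in blocks.items():
        if not b.index.equals(idx):
            raise ValueError(f"{name} block does not cover the same specimens")
    prov_rows, cols, dropped = [], [], []
    for name, b in blocks.items():
        arr = b.to_numpy(dtype=float)
        for j in range(arr.shape[1]):
            col = arr[:, j]
            rec = {"source": name, "source_index": j, "source_column": str(b.columns[j])}
            if np.all(col == 0):
                dropped.append({**rec, "reason": "all-zero"})
                continue
            sd = col.std(ddof=ddof) if len(col) > ddof else 0.0
            if sd == 0 or col.max() == col.min():
                scaled = np.full_like(col, 0.5)
                rec["note"] = "constant; set to 0.5"
            else:
                z = (col - col.mean()) / sd
                scaled = (z - z.min()) / (z.max() - z.min())
            cols.append(np.round(scaled, 3))
            prov_rows.append(rec)
    values = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((len(idx), 0)),
        index=idx,
        columns=[f"{r['source']}_{r['source_index']}" for r in prov_rows],
    )
    return CharacterMatrix(
        values=values,
        provenance=pd.DataFrame(prov_rows),
        dropped=pd.DataFrame(dropped),
    )


def _sanitize(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.]", "_", str(name))


def export_matrix(matrix: CharacterMatrix, path: str | Path, dialect: str = "tnt") -> Path:
    """Write the matrix as a TNT continuous block or NEXUS continuous file."""
    if matrix.n_taxa == 0 or matrix.n_characters == 0:
        raise ValueError("cannot export an empty character matrix")
    path = Path(path)
    taxa = []
    matrix.name_map.clear()
    for t in matrix.values.index:
        s = _sanitize(t)
        if s != str(t):
            matrix.name_map[str(t)] = s
        taxa.append(s)
    if dialect == "tnt":
        lines = ["nstates cont;", "xread", f"{matrix.n_characters} {matrix.n_taxa}", "&[continuous]"]
        for taxon, (_, row) in zip(taxa, matrix.values.iterrows()):
            lines.append(taxon + " " + " ".join(f"{v:.3f}" for v in row))
        lines.append(";")
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "nexus":
        data = {t: [float(v) for v in row] for t, (_, row) in zip(taxa, matrix.values.iterrows())}
        cm = dendropy.ContinuousCharacterMatrix.from_dict(data)
        cm.write(path=str(path), schema="nexus")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def read_matrix(path: str | Path, dialect: str = "tnt") -> pd.DataFrame:
    """Parse an exported matrix back into a taxa x characters DataFrame."""
    path = Path(path)
    if dialect == "tnt":
        lines = [l.strip() for l in path.read_text().splitlines() if l.strip()]
        if lines[0] != "nstates cont;" or lines[1] != "xread":
            raise ValueError("not a TNT continuous-character file")
        nchar, ntax = (int(x) for x in lines[2].split())
        rows, names = [], []
        for line in lines[4 : 4 + ntax]:
            parts = line.split()
            names.append(parts[0])
            vals = [float(v) for v in parts[1:]]
            if len(vals) != nchar:
                raise ValueError(f"taxon {parts[0]} has {len(vals)} values, expected {nchar}")
            rows.append(vals)
        return pd.DataFrame(rows, index=names)
    if dialect == "nexus":
        cm = dendropy.ContinuousCharacterMatrix.get(path=str(path), schema="nexus")
        return pd.DataFrame(
            {t.label: [float(v) for v in cm[t]] for t in cm.taxon_namespace}
        ).T
    raise ValueError(f"unknown dialect {dialect!r}")
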