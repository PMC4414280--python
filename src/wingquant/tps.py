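"""TPS landmark-file reader and writer.

The TPS format (as produced by standard landmarking software) stores one
record per specimen: an ``LM=<count>`` line, ``count`` coordinate lines,
and trailing key=value lines such as ``ID=``, ``IMAGE=`` and ``SCALE=``.
Coordinates are multiplied by SCALE on read (when present and
``apply_scale`` is true); the writer emits files the reader round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["TPSRecord", "read_tps", "write_tps"]


@dataclass
class TPSRecord:
    coords: np.ndarray  # (n_landmarks, 2)
    id: str = ""
    image: str = ""
    scale: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("TPS coordinates must be an (n, 2) array")


class TPSParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def read_tps(path: str | Path, apply_scale: bool = True) -> list[TPSRecord]:
    """Parse a TPS file into records; honors SCALE when ``apply_scale``."""
    records: list[TPSRecord] = []
    pending: dict | None = None

    def close(rec: dict, line_no: int) -> None:
        if len(rec["coords"]) != rec["n"]:
            raise TPSParseError(
                f"record {rec['id'] or len(records)}: expected {rec['n']} landmarks, "
                f"got {len(rec['coords'])}",
                line_no,
            )
        coords = np.array(rec["coords"], dtype=float)
        scale = rec["scale"]
        if apply_scale and scale is not None:
            # scale is consumed: coordinates are now in scaled units, so the
            # record drops SCALE and writer round-trips are exact
            coords = coords * scale
            scale = None
        records.append(
            TPSRecord(coords=coords, id=rec["id"], image=rec["image"], scale=scale)
        )

    lines = Path(path).read_text().splitlines()
    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            if pending is not None:
                close(pending, i)
            pending = {"n": int(line[3:]), "coords": [], "id": "", "image": "", "scale": None}
        elif pending is None:
            raise TPSParseError("coordinate data before any LM= line", i)
        elif upper.startswith("ID="):
            pending["id"] = line[3:].strip()
        elif upper.startswith("IMAGE="):
            pending["image"] = line[6:].strip()
        elif upper.startswith("SCALE="):
            pending["scale"] = float(line[6:])
        else:
            parts = line.split()
            if len(parts) != 2:
                raise TPSParseError(f"expected 'x y', got {line!r}", i)
            if len(pending["coords"]) >= pending["n"]:
                raise TPSParseError("more coordinate lines than LM= declared", i)
            pending["coords"].append((float(parts[0]), float(parts[1])))
    if pending is not None:
        close(pending, len(lines))
    return records


def write_tps(records: list[TPSRecord], path: str | Path) -> Path:
    """Write records in TPS format (SCALE emitted but not un-applied)."""
    lines: list[str] = []
    for rec in records:
        lines.append(f"LM={rec.coords.shape[0]}")
        for x, y in rec.coords:
            lines.append(f"{x:.6f} {y:.6f}")
        if rec.image:
            lines.append(f"IMAGE={rec.image}")
        if rec.id:
            lines.append(f"ID={rec.id}")
        if rec.scale is not None:
            lines.append(f"SCALE={rec.scale}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
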