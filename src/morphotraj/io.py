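"""Reading and writing landmark files.

Two dialects are supported:

* **TPS** — Rohlf-style blocks: an ``LM=k`` (or ``LM3=k``) line, ``k``
  whitespace-separated coordinate rows (``x y z``), an ``ID=`` line, and
  ``KEY=VALUE`` comment lines carrying metadata (``SPECIES=``,
  ``AGE_CLASS=``, ``STRUCTURE=``, optional ``IDAS=``, ``SITE=``,
  ``SCALE=``).  Missing landmarks are written as the conventional
  ``9999 9999 9999`` sentinel triple.
* **CSV** — one row per specimen with columns ``specimen_id``, ``species``,
  ``age_class``, ``structure`` followed by ``x1,y1,z1,...,xk,yk,zk``
  (1-based landmark numbering in the header).  Missing landmarks are empty
  cells (the 9999 sentinel is also recognised on input).

Coordinates round-trip to 6 decimal places.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import LandmarkDataset, SpecimenRecord
from .templates import LandmarkTemplate

__all__ = ["read_landmarks", "write_landmarks", "MISSING_SENTINEL"]

MISSING_SENTINEL = 9999.0

_META_KEYS = ("SPECIES", "AGE_CLASS", "STRUCTURE", "IDAS", "SITE")


class LandmarkParseError(ValueError):
    """Raised when a landmark file cannot be parsed."""


def read_landmarks(path, format: str, template: LandmarkTemplate) -> LandmarkDataset:
    """Read a landmark file into a dataset validated against ``template``."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if format == "tps":
        dataset = _read_tps(text, template, source=str(path))
    elif format == "csv":
        dataset = _read_csv(text, template, source=str(path))
    else:
        raise ValueError(f"unknown format {format!r}; use 'tps' or 'csv'")
    dataset.log(f"read {len(dataset)} specimens from {path} ({format})")
    return dataset


def write_landmarks(dataset: LandmarkDataset, path, format: str) -> Path:
    """Write a dataset; re-reading reproduces coordinates to 6 decimals."""
    path = Path(path)
    if format == "tps":
        path.write_text(_format_tps(dataset), encoding="utf-8")
    elif format == "csv":
        path.write_text(_format_csv(dataset), encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}; use 'tps' or 'csv'")
    return path


# --- TPS dialect -----------------------------------------------------------


def _format_tps(dataset: LandmarkDataset) -> str:
    lines: list[str] = []
    for spec in dataset:
        lines.append(f"LM={spec.n_landmarks}")
        for i, (x, y, z) in enumerate(spec.coordinates):
            if spec.missing_mask[i]:
                lines.append("9999.000000 9999.000000 9999.000000")
            else:
                lines.append(f"{x:.6f} {y:.6f} {z:.6f}")
        lines.append(f"ID={spec.specimen_id}")
        lines.append(f"COMMENT=SPECIES={spec.species}")
        lines.append(f"COMMENT=AGE_CLASS={spec.age_class}")
        lines.append(f"COMMENT=STRUCTURE={spec.structure}")
        if spec.idas_stage is not None:
            lines.append(f"COMMENT=IDAS={spec.idas_stage}")
        if spec.site:
            lines.append(f"COMMENT=SITE={spec.site}")
    return "\n".join(lines) + ("\n" if lines else "")


def _read_tps(text: str, template: LandmarkTemplate, source: str) -> LandmarkDataset:
    specimens: list[SpecimenRecord] = []
    lines = text.splitlines()
    i, n_lines = 0, len(lines)
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        upper = line.upper()
        if not (upper.startswith("LM=") or upper.startswith("LM3=")):
            raise LandmarkParseError(
                f"{source}: line {i + 1}: expected LM=/LM3= header, got {line!r}"
            )
        try:
            k = int(line.split("=", 1)[1])
        except ValueError:
            raise LandmarkParseError(
                f"{source}: line {i + 1}: bad landmark count in {line!r}"
            ) from None
        if k != template.n_landmarks:
            raise LandmarkParseError(
                f"{source}: line {i + 1}: specimen has {k} landmarks but template "
                f"{template.structure_name} expects {template.n_landmarks}"
            )
        i += 1
        coords = np.zeros((k, 3))
        mask = np.zeros(k, dtype=bool)
        for j in range(k):
            if i >= n_lines:
                raise LandmarkParseError(
                    f"{source}: unexpected end of file inside coordinate block"
                )
            parts = lines[i].split()
            if len(parts) != 3:
                raise LandmarkParseError(
                    f"{source}: line {i + 1}: expected 3 coordinates, got "
                    f"{lines[i]!r}"
                )
            try:
                xyz = [float(p) for p in parts]
            except ValueError:
                raise LandmarkParseError(
                    f"{source}: line {i + 1}: non-numeric coordinate in {lines[i]!r}"
                ) from None
            if all(v == MISSING_SENTINEL for v in xyz):
                mask[j] = True
            else:
                coords[j] = xyz
            i += 1
        meta = {"ID": "", "SPECIES": "", "AGE_CLASS": "", "STRUCTURE": "",
                "IDAS": "", "SITE": "", "SCALE": ""}
        while i < n_lines:
            line = lines[i].strip()
            if not line:
                i += 1
                continue
            if line.upper().startswith(("LM=", "LM3=")):
                break
            key, _, value = line.partition("=")
            key = key.strip().upper()
            if key == "COMMENT":
                ckey, _, cvalue = value.partition("=")
                meta[ckey.strip().upper()] = cvalue.strip()
            elif key in meta:
                meta[key] = value.strip()
            i += 1
        scale = float(meta["SCALE"]) if meta["SCALE"] else 1.0
        if scale != 1.0:
            coords[~mask] *= scale
        specimens.append(
            SpecimenRecord(
                specimen_id=meta["ID"] or f"specimen_{len(specimens) + 1}",
                species=meta["SPECIES"] or "unknown",
                age_class=meta["AGE_CLASS"] or "adult",
                structure=meta["STRUCTURE"] or template.structure_name,
                coordinates=coords,
                missing_mask=mask,
                idas_stage=int(meta["IDAS"]) if meta["IDAS"] else None,
                site=meta["SITE"],
            )
        )
    return LandmarkDataset(template=template, specimens=specimens)


# --- CSV dialect -----------------------------------------------------------


def _coordinate_columns(k: int) -> list[str]:
    cols: list[str] = []
    for j in range(1, k + 1):
        cols.extend((f"x{j}", f"y{j}", f"z{j}"))
    return cols


def _format_csv(dataset: LandmarkDataset) -> str:
    k = dataset.template.n_landmarks
    header = ["specimen_id", "species", "age_class", "structure", "idas_stage",
              "site"] + _coordinate_columns(k)
    rows = [",".join(header)]
    for spec in dataset:
        cells = [
            spec.specimen_id, spec.species, spec.age_class, spec.structure,
            "" if spec.idas_stage is None else str(spec.idas_stage), spec.site,
        ]
        for j in range(k):
            if spec.missing_mask[j]:
                cells.extend(("", "", ""))
            else:
                cells.extend(f"{v:.6f}" for v in spec.coordinates[j])
        rows.append(",".join(cells))
    return "\n".join(rows) + "\n"


def _read_csv(text: str, template: LandmarkTemplate, source: str) -> LandmarkDataset:
    try:
        frame = pd.read_csv(_io.StringIO(text), dtype={"specimen_id": str, "site": str})
    except Exception as exc:  # pandas raises several parser error types
        raise LandmarkParseError(f"{source}: CSV parse failure: {exc}") from exc
    k = template.n_landmarks
    coord_cols = _coordinate_columns(k)
    missing_cols = [c for c in coord_cols if c not in frame.columns]
    if missing_cols:
        raise LandmarkParseError(
            f"{source}: landmark columns missing for template "
            f"{template.structure_name}: {missing_cols[:6]}..."
            if len(missing_cols) > 6
            else f"{source}: landmark columns missing: {missing_cols}"
        )
    extra = [c for c in frame.columns if c.startswith(("x", "y", "z"))
             and c not in coord_cols and c[1:].isdigit()]
    if extra:
        raise LandmarkParseError(
            f"{source}: file has more landmarks than template "
            f"{template.structure_name} ({extra[:3]}...)"
        )
    specimens: list[SpecimenRecord] = []
    for row_idx, row in frame.iterrows():
        values = row[coord_cols].to_numpy(dtype=float).reshape(k, 3)
        mask = ~np.isfinite(values).all(axis=1)
        mask |= np.all(values == MISSING_SENTINEL, axis=1)
        values[mask] = 0.0
        idas = row.get("idas_stage")
        idas = None if pd.isna(idas) else int(idas)
        site = row.get("site", "")
        specimens.append(
            SpecimenRecord(
                specimen_id=str(row["specimen_id"]),
                species=str(row["species"]),
                age_class=str(row["age_class"]),
                structure=str(row.get("structure", template.structure_name)),
                coordinates=values,
                missing_mask=mask,
                idas_stage=idas,
                site="" if pd.isna(site) else str(site),
            )
        )
    return LandmarkDataset(template=template, specimens=specimens)
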