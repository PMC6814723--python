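"""Reading and writing the pipeline's tabular interfaces.

Cell tables are CSV/TSV with columns: cell_id, animal_id, stage, x_um,
y_um, z (plus optional z_unit in {um, section}), cyto_display,
nuc_display (semicolon-joined subsets of C;Y;R, empty allowed), and
optional subtype, edu, ki67.  Section-indexed z is converted to µm via
the section thickness.  Boundary masks are JSON records with "pial" and
"ventricular" point lists in µm.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .color_model import CellRecord, ColorDisplay
from .spatial_stats import CorticalFrame

REQUIRED_COLUMNS = (
    "cell_id",
    "animal_id",
    "stage",
    "x_um",
    "y_um",
    "z",
    "cyto_display",
    "nuc_display",
)


def _parse_optional_bool(v) -> bool | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in {"1", "true", "yes", "t"}:
        return True
    if s in {"0", "false", "no", "f"}:
        return False
    raise ValueError(f"cannot parse boolean flag {v!r}")


def read_cell_table(
    path,
    section_thickness_um: float = 80.0,
) -> list[CellRecord]:
    """Read a cell table (CSV or TSV by extension) into CellRecords.

    All coordinates are returned in µm: rows with ``z_unit == 'section'``
    have z multiplied by the section thickness.  Unlabeled rows (both
    display columns empty) are rejected.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"cell_id": str, "animal_id": str, "stage": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")
    has_unit = "z_unit" in df.columns
    cells: list[CellRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        unit = str(d.get("z_unit", "um") or "um") if has_unit else "um"
        if unit not in {"um", "section"}:
            raise ValueError(f"cell {d['cell_id']}: unknown z_unit {unit!r}")
        z = float(d["z"]) * (section_thickness_um if unit == "section" else 1.0)
        cy = d.get("cyto_display")
        nu = d.get("nuc_display")
        display = ColorDisplay.from_strings(
            "" if pd.isna(cy) else str(cy), "" if pd.isna(nu) else str(nu)
        )
        cells.append(
            CellRecord(
                cell_id=str(d["cell_id"]),
                x=float(d["x_um"]),
                y=float(d["y_um"]),
                z=z,
                display=display,
                animal_id=str(d["animal_id"]),
                stage=str(d["stage"]),
                subtype=(
                    str(d["subtype"])
                    if "subtype" in d and not pd.isna(d["subtype"])
                    else "unknown"
                ),
                edu_positive=_parse_optional_bool(d.get("edu")),
                ki67_positive=_parse_optional_bool(d.get("ki67")),
            )
        )
    if not cells:
        raise ValueError(f"{path.name}: no labeled cells")
    return cells


def z_resolution_is_sectional(path) -> bool:
    """True when any row of the table carries section-indexed z."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    return "z_unit" in df.columns and (df["z_unit"].astype(str) == "section").any()


def read_frame(path) -> CorticalFrame:
    """Read a cortical boundary-mask JSON (first record if a list)."""
    return CorticalFrame.from_json(path)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
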