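"""Readers and writers for the exchanged table, alignment and PDB formats.

Tables are delimited text (CSV or TSV, sniffed from the extension/content)
with explicit unit-bearing headers; molarity columns accept SI-suffixed
strings ("1 nM", "2.5 uM").  Alignments are aligned FASTA or Clustal
(auto-detected, parsed with Bio.AlignIO).  Coordinates are PDB format
(Bio.PDB), heavy atoms only, altloc A, waters excluded.  Reports are JSON
or TSV with stable field ordering and 6-significant-digit floats.
"""

from __future__ import annotations

import dataclasses
import json
import re
from enum import Enum
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.PDB import PDBParser

from .ephys import DoseResponse, IVSeries
from .kinetics import AssayCondition, InhibitionCurve, TitrationSeries
from .motifs import KunitzAlignment, ToxinRecord
from .structure import Atom, StructureModel

__all__ = [
    "IOError_",
    "parse_molar",
    "read_alignment",
    "read_assay_table",
    "read_asa_table",
    "read_pdb",
    "write_report",
    "write_exposure_table",
]


class IOError_(ValueError):
    """Malformed input file or unwritable output."""


_SI = {
    "M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12,
    "fM": 1e-15,
}


def parse_molar(value: Any) -> float:
    """Parse a molar concentration, numeric or SI-suffixed ("1 nM" -> 1e-9)."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        out = float(value)
    else:
        text = str(value).strip()
        m = re.fullmatch(r"([-+0-9.eE]+)\s*([fpnuµm]?M)?", text)
        if not m:
            raise IOError_(f"cannot parse concentration {value!r}")
        out = float(m.group(1)) * _SI.get(m.group(2) or "M", 1.0)
    if not np.isfinite(out):
        raise IOError_(f"non-finite concentration {value!r}")
    if out < 0:
        raise IOError_(f"negative concentration {value!r}")
    return out


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


def read_alignment(path: str | Path) -> KunitzAlignment:
    """Read an aligned FASTA or Clustal file into a KunitzAlignment.

    The dialect is auto-detected from the first non-blank line ('>' for
    FASTA, a CLUSTAL header otherwise); Clustal conservation lines are
    ignored by the parser.  Ragged rows and duplicate ids are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line.strip()
                break
    if first.startswith(">"):
        fmt = "fasta"
    elif first.upper().startswith("CLUSTAL"):
        fmt = "clustal"
    else:
        raise IOError_(
            f"{path}: neither aligned FASTA nor Clustal (first line {first!r})"
        )
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise IOError_(f"{path}: alignment parse error: {exc}") from exc
    rows = [str(rec.seq) for rec in msa]
    ids = [rec.id for rec in msa]
    if len(set(ids)) != len(ids):
        raise IOError_(f"{path}: duplicate sequence ids")
    records = tuple(
        ToxinRecord(id=i, sequence=r.replace("-", "").replace(".", ""))
        for i, r in zip(ids, rows)
    )
    return KunitzAlignment(records=records, aligned_rows=tuple(rows))


# ---------------------------------------------------------------------------
# Assay tables
# ---------------------------------------------------------------------------


_SCHEMAS = {
    "inhibition": {"inhibitor_conc_M", "fractional_activity"},
    "titration": {"inhibitor_conc_M", "fractional_activity"},
    "dose_response": {"conc_M", "percent_block"},
    "iv": {"V_mV", "I_uA"},
    "iv_pair": {"V_mV", "I_control_uA", "I_toxin_uA"},
}


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        return pd.read_csv(path, sep=sep, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error variety
        raise IOError_(f"{path}: cannot parse table: {exc}") from exc


def read_assay_table(
    path: str | Path,
    schema: str,
    condition: AssayCondition | None = None,
    **kwargs: Any,
):
    """Read a delimited assay table into the matching domain object.

    ``schema`` selects the layout: ``inhibition`` (inhibitor_conc_M,
    fractional_activity), ``titration`` (same columns, plus E_total_M and
    E0_over_Ki keyword arguments), ``dose_response`` (conc_M,
    percent_block), ``iv`` (V_mV, I_uA).  Unknown columns beyond the schema
    are permitted; missing required columns raise with the expected header.
    """
    if schema not in _SCHEMAS:
        raise IOError_(
            f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}"
        )
    df = _read_table(path)
    required = _SCHEMAS[schema]
    missing = required - set(df.columns)
    if missing:
        raise IOError_(
            f"{path}: missing columns {sorted(missing)} for schema "
            f"{schema!r} (expected {sorted(required)})"
        )
    if schema == "inhibition":
        if condition is None:
            raise IOError_("inhibition schema requires an AssayCondition")
        conc = [parse_molar(v) for v in df["inhibitor_conc_M"]]
        return InhibitionCurve(
            condition=condition,
            I_grid=tuple(conc),
            fractional_activity=tuple(map(float, df["fractional_activity"])),
        )
    if schema == "titration":
        return TitrationSeries(
            E_total=parse_molar(kwargs.get("E_total_M", 0.0)),
            inhibitor_amounts=tuple(
                parse_molar(v) for v in df["inhibitor_conc_M"]
            ),
            fractional_activity=tuple(map(float, df["fractional_activity"])),
            E0_over_Ki=float(kwargs.get("E0_over_Ki", float("nan"))),
        )
    if schema == "dose_response":
        return DoseResponse(
            channel_id=str(kwargs.get("channel_id", "channel")),
            conc=tuple(parse_molar(v) for v in df["conc_M"]),
            percent_block=tuple(map(float, df["percent_block"])),
        )
    if schema == "iv":
        return IVSeries(
            V=tuple(map(float, df["V_mV"])),
            I=tuple(map(float, df["I_uA"])),
            condition=str(kwargs.get("condition", "control")),
            Erev=kwargs.get("Erev"),
        )
    # iv_pair
    return df


def read_asa_table(path: str | Path) -> dict[tuple[str, int], float]:
    """Read a TSV of (toxin_id, residue_number, relative_asa_percent)."""
    df = _read_table(path)
    required = {"toxin_id", "residue_number", "relative_asa_percent"}
    missing = required - set(df.columns)
    if missing:
        raise IOError_(f"{path}: missing columns {sorted(missing)}")
    return {
        (str(r.toxin_id), int(r.residue_number)): float(r.relative_asa_percent)
        for r in df.itertuples()
    }


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def read_pdb(
    path: str | Path,
    keep_hydrogens: bool = False,
    keep_waters: bool = False,
) -> StructureModel:
    """Read a PDB coordinate file into a StructureModel.

    Heavy atoms only by default; alternate locations resolve to altloc A
    (Bio.PDB's default policy); waters are excluded.  Raises when no atoms
    survive filtering.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    atoms: list[Atom] = []
    model = next(structure.get_models(), None)
    if model is None:
        raise IOError_(f"{path}: no models in PDB file")
    for chain in model:
        for residue in chain:
            if residue.get_resname().strip() in _WATER_NAMES and not keep_waters:
                continue
            for atom in residue:
                if atom.is_disordered():
                    atom = atom.disordered_get("A") \
                        if atom.disordered_has_id("A") else atom.selected_child
                element = (atom.element or "").strip().upper()
                if element == "H" and not keep_hydrogens:
                    continue
                x, y, z = atom.coord
                atoms.append(Atom(
                    chain=chain.id,
                    residue_number=residue.id[1],
                    residue_name=residue.get_resname().strip(),
                    atom_name=atom.get_name().strip(),
                    element=element,
                    x=float(x), y=float(y), z=float(z),
                ))
    if not atoms:
        raise IOError_(f"{path}: no ATOM records after filtering")
    return StructureModel(atoms=tuple(atoms), source=str(path))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return float(f"{v:.6g}") if np.isfinite(v) else None
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def write_report(
    results: Any,
    path: str | Path,
    format: str = "json",
    metadata: Mapping[str, Any] | None = None,
) -> Path:
    """Write an analysis result to JSON (any object) or TSV (tabular dict).

    Field ordering is stable (dataclass declaration order), floats are
    rendered at 6 significant digits, and ``metadata`` (configuration,
    seeds) is embedded under a ``provenance`` key so identical inputs yield
    byte-identical reports.
    """
    path = Path(path)
    payload = _jsonable(results)
    if metadata:
        payload = {"provenance": _jsonable(dict(metadata)), "results": payload}
    try:
        if format == "json":
            path.write_text(json.dumps(payload, indent=2, sort_keys=False)
                            + "\n")
        elif format == "tsv":
            df = pd.DataFrame(payload)
            df.to_csv(path, sep="\t", index=False)
        else:
            raise IOError_(f"unknown report format {format!r}")
    except OSError as exc:
        raise IOError_(f"cannot write report to {path}: {exc}") from exc
    return path


def write_exposure_table(table, path: str | Path) -> Path:
    """Write an ExposureTable as the TSV consumed by the motif ASA reader."""
    rows = [
        {
            "toxin_id": chain,
            "residue_number": num,
            "residue_name": table.residue_names[(chain, num)],
            "absolute_asa_A2": round(table.absolute[(chain, num)], 3),
            "relative_asa_percent": round(table.relative[(chain, num)], 3),
        }
        for (chain, num) in table.relative
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return Path(path)
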