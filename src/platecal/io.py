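"""Readers and writers for plate maps (JSON), transfer instructions (CSV)
and plate readings (wide/long CSV with an optional metadata sidecar)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .plate import PlateMap, TransferInstruction, WellAddress, WellSpec
from .simulate import PlateReading


# -- plate maps -------------------------------------------------------------

def plate_map_to_dict(plate_map: PlateMap) -> dict:
    return {
        "scheme": plate_map.scheme,
        "total_volume_uL": plate_map.total_volume,
        "meta": {k: v for k, v in plate_map.meta.items()},
        "wells": [
            {
                "well": str(w.address),
                "role": w.role,
                "target_ratio": w.target_ratio,
                "block": w.block,
                "replicate_group": w.replicate_group,
            }
            for w in plate_map.wells
        ],
    }


def write_plate_map(plate_map: PlateMap, path: str | Path) -> None:
    Path(path).write_text(json.dumps(plate_map_to_dict(plate_map), indent=2))


def read_plate_map(path: str | Path) -> PlateMap:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    try:
        wells = [
            WellSpec(
                address=WellAddress.from_string(w["well"]),
                role=w["role"],
                target_ratio=float(w["target_ratio"]),
                block=w.get("block"),
                replicate_group=int(w.get("replicate_group", 0)),
            )
            for w in data["wells"]
        ]
        return PlateMap(
            scheme=data["scheme"],
            wells=wells,
            total_volume=float(data["total_volume_uL"]),
            meta=data.get("meta", {}),
        )
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}: malformed plate map ({exc})") from exc


# -- transfer instructions --------------------------------------------------

INSTRUCTION_COLUMNS = ["step", "phase", "source", "destination", "volume_uL"]


def write_instructions(instructions: list[TransferInstruction], path: str | Path) -> None:
    pd.DataFrame(
        [(i.step, i.phase, i.source, i.destination, i.volume) for i in instructions],
        columns=INSTRUCTION_COLUMNS,
    ).to_csv(path, index=False)


def read_instructions(path: str | Path) -> list[TransferInstruction]:
    df = pd.read_csv(path)
    missing = set(INSTRUCTION_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing instruction columns {sorted(missing)}")
    try:
        return [
            TransferInstruction(
                step=int(r.step),
                phase=str(r.phase),
                source=str(r.source),
                destination=str(r.destination),
                volume=float(r.volume_uL),
            )
            for r in df.itertuples()
        ]
    except ValueError as exc:
        raise ParseError(f"{path}: malformed instruction ({exc})") from exc


# -- plate readings ---------------------------------------------------------

def _normalize_well(raw: str, context: str) -> str:
    try:
        return str(WellAddress.from_string(str(raw)))
    except ValueError as exc:
        raise ParseError(f"{context}: {exc}") from exc


def write_plate_reading(
    reading: PlateReading, path: str | Path, dialect: str = "wide",
    sidecar: bool = True,
) -> None:
    """Write a reading as CSV; metadata goes to a ``.meta.json`` sidecar."""
    path = Path(path)
    if dialect == "wide":
        df = pd.DataFrame(
            reading.absorbance,
            index=pd.Index(reading.wells, name="well"),
            columns=[int(v) if float(v).is_integer() else v for v in reading.wavelengths],
        )
        df.to_csv(path)
    elif dialect == "long":
        rows = [
            (w, lam, reading.absorbance[i, j])
            for i, w in enumerate(reading.wells)
            for j, lam in enumerate(reading.wavelengths)
        ]
        pd.DataFrame(rows, columns=["well", "wavelength_nm", "absorbance"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if sidecar:
        meta = {
            "run_id": reading.run_id,
            "plate_id": reading.plate_id,
            "instrument_id": reading.instrument_id,
            "repeat_index": reading.repeat_index,
            "timestamp": reading.timestamp,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_plate_reading(path: str | Path, dialect: str = "auto") -> PlateReading:
    """Read a wide or long plate-reading CSV into a validated PlateReading.

    Wide: first column ``well``, remaining headers integer wavelengths in nm.
    Long: columns ``well, wavelength_nm, absorbance``.  Well ids are
    normalized (``A01`` → ``A1``); duplicate wells, non-numeric cells and a
    non-monotone grid are parse errors.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if dialect == "auto":
        dialect = "long" if {"wavelength_nm", "absorbance"} <= set(df.columns) else "wide"
    if dialect == "long":
        required = {"well", "wavelength_nm", "absorbance"}
        if not required <= set(df.columns):
            raise ParseError(f"{path}: long dialect needs columns {sorted(required)}")
        df["well"] = [_normalize_well(w, f"{path}") for w in df["well"]]
        try:
            wide = df.pivot(index="well", columns="wavelength_nm", values="absorbance")
        except ValueError as exc:
            raise ParseError(f"{path}: duplicate (well, wavelength) entries") from exc
        wide = wide.reindex(pd.unique(df["well"]))  # keep file order, not lexicographic
        wells = list(wide.index)
        wavelengths = wide.columns.to_numpy(dtype=float)
        matrix = wide.to_numpy(dtype=float)
    else:
        if df.columns[0].lower() != "well":
            raise ParseError(f"{path}: wide dialect needs a leading 'well' column")
        wells = [_normalize_well(w, f"{path} row {i}") for i, w in enumerate(df.iloc[:, 0])]
        if len(set(wells)) != len(wells):
            dupes = sorted({w for w in wells if wells.count(w) > 1})
            raise ParseError(f"{path}: duplicate wells {dupes}")
        try:
            wavelengths = np.array([float(c) for c in df.columns[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric wavelength header ({exc})") from exc
        try:
            matrix = df.iloc[:, 1:].to_numpy(dtype=float)
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric absorbance cell ({exc})") from exc
    order = np.argsort(wavelengths)
    if not np.all(np.diff(wavelengths[order]) > 0):
        raise ParseError(f"{path}: wavelength grid has duplicates")
    wavelengths = wavelengths[order]
    matrix = matrix[:, order]
    if not np.all(np.isfinite(matrix)):
        raise ParseError(f"{path}: non-finite absorbance values")
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return PlateReading(
        wavelengths=wavelengths,
        absorbance=matrix,
        wells=wells,
        run_id=str(meta.get("run_id", "unknown")),
        plate_id=str(meta.get("plate_id", "01")),
        instrument_id=str(meta.get("instrument_id", "unknown")),
        repeat_index=int(meta.get("repeat_index", 0)),
        timestamp=str(meta.get("timestamp", "")),
    )
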