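"""CSV input/output for otolith and stranding tables.

Dialect: comma-separated UTF-8 with a mandatory header row, one row per
otolith (or stranding), missing values as empty fields. Lengths are written
with two decimals so that a write-then-read round trip reproduces every
stored field exactly.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    Grade,
    Nodules,
    PreyOtolith,
    ReferenceOtolith,
    Side,
    Species,
    StomachRecord,
)

REFERENCE_COLUMNS = ["fish_id", "species", "side", "ol_mm", "sl_mm", "cl_mm",
                     "ftl_mm", "fw_g", "nodules"]
PREY_COLUMNS = ["dolphin_id", "species_initial", "species_final", "side",
                "grade", "broken", "ol_mm", "sl_mm", "cl_mm", "nodules"]
STRANDING_COLUMNS = ["dolphin_id", "stranding_date", "predator_length_cm"]


def _fmt_mm(v: float | None) -> str:
    return "" if v is None else f"{v:.2f}"


def _fmt_num(v: float | None) -> str:
    if v is None:
        return ""
    return repr(float(v))


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return float(v)


def write_reference_csv(otoliths: Iterable[ReferenceOtolith], path: str | Path) -> None:
    rows = [{
        "fish_id": o.fish_id,
        "species": o.species.value,
        "side": o.side.value,
        "ol_mm": _fmt_mm(o.ol_mm),
        "sl_mm": _fmt_mm(o.sl_mm),
        "cl_mm": _fmt_mm(o.cl_mm),
        "ftl_mm": _fmt_num(o.ftl_mm),
        "fw_g": _fmt_num(o.fw_g),
        "nodules": o.nodules.value,
    } for o in otoliths]
    pd.DataFrame(rows, columns=REFERENCE_COLUMNS).to_csv(path, index=False)


def read_reference_csv(path: str | Path) -> list[ReferenceOtolith]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, REFERENCE_COLUMNS, path)
    return [
        ReferenceOtolith(
            fish_id=r.fish_id,
            species=Species(r.species),
            side=Side(r.side),
            ol_mm=_opt_float(r.ol_mm),
            sl_mm=_opt_float(r.sl_mm),
            cl_mm=_opt_float(r.cl_mm),
            ftl_mm=_opt_float(r.ftl_mm),
            fw_g=_opt_float(r.fw_g),
            nodules=Nodules(r.nodules) if r.nodules else Nodules.UNRECORDED,
        )
        for r in df.itertuples()
    ]


def write_prey_csv(otoliths: Iterable[PreyOtolith], path: str | Path) -> None:
    rows = [{
        "dolphin_id": o.dolphin_id,
        "species_initial": o.species_initial.value,
        "species_final": "" if o.species_final is None else o.species_final.value,
        "side": o.side.value,
        "grade": o.grade.value,
        "broken": str(o.broken).lower(),
        "ol_mm": _fmt_mm(o.ol_mm),
        "sl_mm": _fmt_mm(o.sl_mm),
        "cl_mm": _fmt_mm(o.cl_mm),
        "nodules": o.nodules.value,
    } for o in otoliths]
    pd.DataFrame(rows, columns=PREY_COLUMNS).to_csv(path, index=False)


def read_prey_csv(path: str | Path) -> list[PreyOtolith]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, PREY_COLUMNS, path)
    out = []
    for r in df.itertuples():
        grade = r.grade
        # accept a few aliases for the pooled moderate-severe grade
        if grade in {"3", "4", "5", "3-5", "G35"}:
            grade = Grade.G35
        out.append(PreyOtolith(
            dolphin_id=r.dolphin_id,
            species_initial=Species(r.species_initial),
            species_final=Species(r.species_final) if r.species_final else None,
            side=Side(r.side),
            grade=Grade(grade),
            broken=r.broken.strip().lower() in {"true", "1", "yes"},
            ol_mm=_opt_float(r.ol_mm),
            sl_mm=_opt_float(r.sl_mm),
            cl_mm=_opt_float(r.cl_mm),
            nodules=Nodules(r.nodules) if r.nodules else Nodules.UNRECORDED,
        ))
    return out


def write_strandings_csv(records: Iterable[StomachRecord], path: str | Path) -> None:
    rows = [{
        "dolphin_id": s.dolphin_id,
        "stranding_date": s.stranding_date.isoformat(),
        "predator_length_cm": _fmt_num(s.predator_length_cm),
    } for s in records]
    pd.DataFrame(rows, columns=STRANDING_COLUMNS).to_csv(path, index=False)


def read_strandings_csv(path: str | Path) -> list[StomachRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, STRANDING_COLUMNS, path)
    return [
        StomachRecord(
            dolphin_id=r.dolphin_id,
            stranding_date=_dt.date.fromisoformat(r.stranding_date),
            predator_length_cm=_opt_float(r.predator_length_cm),
        )
        for r in df.itertuples()
    ]


def attach_otoliths(strandings: Sequence[StomachRecord],
                    otoliths: Iterable[PreyOtolith]) -> list[StomachRecord]:
    """Attach prey otoliths to their stomach records by dolphin_id.

    Otoliths whose dolphin_id has no stranding record raise, since biomass
    fallback scaling needs a date for every stomach.
    """
    by_id = {s.dolphin_id: s for s in strandings}
    for s in strandings:
        s.otoliths = []
    for o in otoliths:
        try:
            by_id[o.dolphin_id].otoliths.append(o)
        except KeyError:
            raise KeyError(f"otolith references unknown dolphin {o.dolphin_id!r}")
    return list(strandings)


def validate_files(reference: str | Path | None = None,
                   prey: str | Path | None = None,
                   strandings: str | Path | None = None) -> list[str]:
    """Validate CSV files against the domain invariants.

    Returns a list of human-readable violation messages (empty = clean).
    Construction of the domain objects enforces the invariants, so this
    simply collects per-row failures instead of stopping at the first.
    """
    problems: list[str] = []
    for label, path, reader in (("reference", reference, read_reference_csv),
                                ("prey", prey, read_prey_csv),
                                ("strandings", strandings, read_strandings_csv)):
        if path is None:
            continue
        try:
            df = pd.read_csv(path, dtype=str, keep_default_na=False)
        except Exception as exc:  # unreadable file
            problems.append(f"{label} file {path}: {exc}")
            continue
        for i in range(len(df)):
            try:
                _read_single_row(df.iloc[[i]], reader)
            except Exception as exc:
                problems.append(f"{label} file {path} row {i + 2}: {exc}")
    return problems


def _read_single_row(df_row: pd.DataFrame, reader) -> None:
    import io as _io

    buf = _io.StringIO()
    df_row.to_csv(buf, index=False)
    buf.seek(0)
    reader(buf)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
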