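"""NONMEM-convention event-table I/O.

The de facto exchange format in pharmacometrics is a per-patient table of
dosing and observation rows: ``ID, TIME, EVID, AMT, DUR, DV`` plus covariate
columns (``AGE, SEX, HT, WT, SCR``). ``EVID=1`` rows are doses and carry
``AMT`` (mg) and ``DUR`` (infusion duration, h); ``EVID=0`` rows are
observations and carry ``DV`` (mg/L). Times are hours from the patient's
first record and must be non-decreasing within a patient.

Reading and writing round-trip losslessly; malformed rows are reported with
their 1-based file line numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .bayes import ObservedLevel
from .pk import DoseEvent
from .renal import PatientRecord, Sex

__all__ = ["PatientData", "EventTableError", "read_event_table", "write_event_table"]

REQUIRED_COLUMNS = ("ID", "TIME", "AMT", "DV", "EVID")
COLUMNS = ("ID", "TIME", "EVID", "AMT", "DUR", "DV", "AGE", "SEX", "HT", "WT", "SCR")

_SEX_CODE = {"F": Sex.female, "M": Sex.male}


class EventTableError(ValueError):
    """Schema or validation failure in an event table."""


@dataclass(frozen=True)
class PatientData:
    """One patient's slice of an event table."""

    record: PatientRecord
    doses: list[DoseEvent]
    levels: list[ObservedLevel]


def _line_no(df: pd.DataFrame, idx) -> int:
    # +2: 1-based counting plus the header line
    return int(df.index.get_loc(idx)) + 2


def read_event_table(path: str | Path) -> dict[str, PatientData]:
    """Parse an event-table CSV into per-patient records, doses and levels.

    An empty file (header only, or zero bytes) yields an empty collection.
    Missing required columns raise :class:`EventTableError`; malformed or
    time-disordered rows are reported with their line numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"ID": str, "SEX": str})
    except pd.errors.EmptyDataError:
        return {}
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise EventTableError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        return {}

    problems: list[str] = []
    out: dict[str, PatientData] = {}
    for pid, g in df.groupby("ID", sort=False):
        times = g["TIME"].to_numpy()
        bad = [ _line_no(df, i) for i, (a, b) in zip(g.index[1:], zip(times, times[1:])) if b < a ]
        if bad:
            problems.append(f"patient {pid}: times not non-decreasing at line(s) {bad}")
            continue
        first = g.iloc[0]
        try:
            record = PatientRecord(
                patient_id=str(pid),
                age=float(first["AGE"]),
                sex=_SEX_CODE.get(str(first.get("SEX", "")).strip().upper(), str(first.get("SEX", ""))),
                height=float(first["HT"]),
                weight=float(first["WT"]),
                serum_creatinine=float(first["SCR"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            problems.append(f"patient {pid} (line {_line_no(df, g.index[0])}): bad covariates: {exc}")
            continue
        doses: list[DoseEvent] = []
        levels: list[ObservedLevel] = []
        for i, row in g.iterrows():
            line = _line_no(df, i)
            try:
                evid = int(row["EVID"])
                t = float(row["TIME"])
                if t < 0:
                    raise ValueError(f"negative time {t}")
                if evid == 1:
                    doses.append(
                        DoseEvent(start_time=t, amount=float(row["AMT"]), infusion_duration=float(row["DUR"]))
                    )
                elif evid == 0:
                    levels.append(ObservedLevel(time=t, concentration=float(row["DV"])))
                else:
                    raise ValueError(f"unsupported EVID {evid}")
            except (TypeError, ValueError) as exc:
                problems.append(f"patient {pid} line {line}: {exc}")
        out[str(pid)] = PatientData(record=record, doses=doses, levels=levels)
    if problems:
        raise EventTableError(f"{path}: " + "; ".join(problems))
    return out


def write_event_table(data: dict[str, PatientData], path: str | Path) -> None:
    """Write per-patient data back to the event-table CSV layout (lossless
    round trip with :func:`read_event_table`)."""
    rows = []
    for pid, pdta in data.items():
        rec = pdta.record
        cov = {
            "AGE": rec.age,
            "SEX": "F" if rec.sex is Sex.female else "M",
            "HT": rec.height,
            "WT": rec.weight,
            "SCR": rec.serum_creatinine,
        }
        merged = [("dose", d.start_time, d) for d in pdta.doses] + [
            ("obs", lv.time, lv) for lv in pdta.levels
        ]
        for kind, t, item in sorted(merged, key=lambda x: x[1]):
            row = {"ID": pid, "TIME": t, **cov}
            if kind == "dose":
                row.update(EVID=1, AMT=item.amount, DUR=item.infusion_duration, DV="")
            else:
                row.update(EVID=0, AMT="", DUR="", DV=item.concentration)
            rows.append(row)
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)
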