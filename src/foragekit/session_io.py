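"""Session serialization: JSON-lines and paired-CSV formats.

JSONL layout: the first line is a header object

    {"schema": "foragekit-session", "version": 1, "units": "mm",
     "effector": ..., "constrained": ..., "movement_model": {...}}

followed by one object per trial with keys ``trial_id``, ``condition``,
``start_mm``, ``targets`` (15 entries of id/x_mm/y_mm/radius_mm/value) and
``harvests`` (harvest_index/chosen/origin/dt_s, origin -1 = start).

The paired-CSV format writes ``<base>.displays.csv``,
``<base>.harvests.csv`` and ``<base>.meta.json``.  Coordinates are stored
in millimeters in both formats and converted to meters on read; the
``units`` field in the header/meta is required and checked.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .choice import HarvestRecord, SessionData
from .environment import Display, N_TARGETS, START_INDEX, TargetSpec, condition
from .exceptions import SessionFormatError
from .movement import MovementTimeModel

_SCHEMA = "foragekit-session"
_MM = 1000.0


def _movement_model_to_json(model: MovementTimeModel) -> dict:
    return {
        "effector": model.effector,
        "slope_s_per_m": {f"{r * _MM:g}": s for r, s in model.slope_by_radius.items()},
        "intercept_s": {
            f"{r * _MM:g}": c for r, c in model.intercept_by_radius.items()
        },
        "resid_sd_s": {
            f"{r * _MM:g}": c for r, c in model.resid_sd_by_radius.items()
        },
    }


def _movement_model_from_json(obj: dict) -> MovementTimeModel:
    return MovementTimeModel(
        effector=obj["effector"],
        slope_by_radius={
            float(k) / _MM: v for k, v in obj["slope_s_per_m"].items()
        },
        intercept_by_radius={
            float(k) / _MM: v for k, v in obj["intercept_s"].items()
        },
        resid_sd_by_radius={
            float(k) / _MM: v for k, v in obj.get("resid_sd_s", {}).items()
        },
    )


def _trial_to_json(display: Display, records: list[HarvestRecord]) -> dict:
    return {
        "trial_id": display.trial_id,
        "condition": display.condition.name,
        "start_mm": [display.start_position[0] * _MM,
                     display.start_position[1] * _MM],
        "targets": [
            {
                "id": t.id,
                "x_mm": t.position[0] * _MM,
                "y_mm": t.position[1] * _MM,
                "radius_mm": t.radius * _MM,
                "value": t.value,
            }
            for t in display.targets
        ],
        "harvests": [
            {
                "harvest_index": r.harvest_index,
                "chosen": r.chosen_target_id,
                "origin": -1 if r.origin_target_id == START_INDEX
                else r.origin_target_id,
                "dt_s": r.inter_harvest_time,
            }
            for r in records
        ],
    }


def _trial_from_json(obj: dict, scale: float) -> tuple[Display, list[HarvestRecord]]:
    trial_id = int(obj["trial_id"])
    raw_targets = obj["targets"]
    if len(raw_targets) != N_TARGETS:
        raise SessionFormatError(
            f"trial {trial_id}: {len(raw_targets)} targets; expected {N_TARGETS}"
        )
    targets = [
        TargetSpec(
            id=int(t["id"]),
            position=(t["x_mm"] * scale, t["y_mm"] * scale),
            radius=t["radius_mm"] * scale,
            value=int(t["value"]),
        )
        for t in raw_targets
    ]
    start = obj.get("start_mm", [0.0, 0.0])
    display = Display(
        targets=targets,
        condition=condition(obj["condition"]),
        start_position=(start[0] * scale, start[1] * scale),
        trial_id=trial_id,
    )
    records = []
    for h in obj["harvests"]:
        chosen = int(h["chosen"])
        origin = int(h["origin"])
        records.append(
            HarvestRecord(
                trial_id=trial_id,
                harvest_index=int(h["harvest_index"]),
                chosen_target_id=chosen,
                origin_target_id=START_INDEX if origin == -1 else origin,
                inter_harvest_time=float(h["dt_s"]),
            )
        )
        display.targets[chosen].harvested = True
    display.reset_harvested()
    return display, records


def _check_units(units: str) -> float:
    if units == "mm":
        return 1.0 / _MM
    if units == "m":
        return 1.0
    raise SessionFormatError(f"unsupported units {units!r}; expected 'mm' or 'm'")


# ---------------------------------------------------------------------------
# JSONL
# ---------------------------------------------------------------------------


def write_session_jsonl(session: SessionData, path: str | Path) -> None:
    path = Path(path)
    header = {
        "schema": _SCHEMA,
        "version": 1,
        "units": "mm",
        "effector": session.effector,
        "constrained": session.constrained,
        "movement_model": _movement_model_to_json(session.movement_model),
    }
    with path.open("w") as fh:
        fh.write(json.dumps(header) + "\n")
        for display, records in session.trials:
            fh.write(json.dumps(_trial_to_json(display, records)) + "\n")


def read_session_jsonl(path: str | Path) -> SessionData:
    path = Path(path)
    with path.open() as fh:
        lines = [ln for ln in fh if ln.strip()]
    if not lines:
        raise SessionFormatError(f"{path}: empty session file")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise SessionFormatError(f"{path}: line 1: {exc}") from exc
    if header.get("schema") != _SCHEMA:
        raise SessionFormatError(f"{path}: missing schema header line")
    scale = _check_units(header.get("units", ""))
    trials = []
    for lineno, ln in enumerate(lines[1:], start=2):
        try:
            obj = json.loads(ln)
            trials.append(_trial_from_json(obj, scale))
        except SessionFormatError:
            raise
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
            raise SessionFormatError(f"{path}: line {lineno}: {exc}") from exc
    return SessionData(
        effector=header["effector"],
        movement_model=_movement_model_from_json(header["movement_model"]),
        trials=trials,
        constrained=bool(header.get("constrained", False)),
    )


# ---------------------------------------------------------------------------
# Paired CSV
# ---------------------------------------------------------------------------


def _csv_paths(base: str | Path) -> tuple[Path, Path, Path]:
    base = Path(base)
    stem = base.with_suffix("") if base.suffix == ".csv" else base
    return (
        stem.with_name(stem.name + ".displays.csv"),
        stem.with_name(stem.name + ".harvests.csv"),
        stem.with_name(stem.name + ".meta.json"),
    )


def write_session_csv(session: SessionData, base: str | Path) -> tuple[Path, Path, Path]:
    dpath, hpath, mpath = _csv_paths(base)
    drows, hrows = [], []
    for display, records in session.trials:
        for t in display.targets:
            drows.append(
                dict(
                    trial_id=display.trial_id,
                    condition=display.condition.name,
                    start_x_mm=display.start_position[0] * _MM,
                    start_y_mm=display.start_position[1] * _MM,
                    target_id=t.id,
                    x_mm=t.position[0] * _MM,
                    y_mm=t.position[1] * _MM,
                    radius_mm=t.radius * _MM,
                    value=t.value,
                )
            )
        for r in records:
            hrows.append(
                dict(
                    trial_id=r.trial_id,
                    harvest_index=r.harvest_index,
                    chosen_target_id=r.chosen_target_id,
                    origin_target_id=-1
                    if r.origin_target_id == START_INDEX
                    else r.origin_target_id,
                    inter_harvest_time_s=r.inter_harvest_time,
                )
            )
    pd.DataFrame(drows).to_csv(dpath, index=False)
    pd.DataFrame(
        hrows,
        columns=[
            "trial_id", "harvest_index", "chosen_target_id",
            "origin_target_id", "inter_harvest_time_s",
        ],
    ).to_csv(hpath, index=False)
    meta = {
        "schema": _SCHEMA,
        "version": 1,
        "units": "mm",
        "effector": session.effector,
        "constrained": session.constrained,
        "movement_model": _movement_model_to_json(session.movement_model),
    }
    mpath.write_text(json.dumps(meta, indent=2))
    return dpath, hpath, mpath


def read_session_csv(base: str | Path) -> SessionData:
    dpath, hpath, mpath = _csv_paths(base)
    for p in (dpath, hpath, mpath):
        if not p.exists():
            raise SessionFormatError(f"missing session component: {p}")
    meta = json.loads(mpath.read_text())
    if meta.get("schema") != _SCHEMA:
        raise SessionFormatError(f"{mpath}: not a {_SCHEMA} meta file")
    scale = _check_units(meta.get("units", ""))
    displays = pd.read_csv(dpath)
    harvests = pd.read_csv(hpath)
    trials = []
    for trial_id, grp in displays.groupby("trial_id", sort=True):
        if len(grp) != N_TARGETS:
            raise SessionFormatError(
                f"trial {trial_id}: {len(grp)} targets; expected {N_TARGETS}"
            )
        grp = grp.sort_values("target_id")
        targets = [
            TargetSpec(
                id=int(row.target_id),
                position=(row.x_mm * scale, row.y_mm * scale),
                radius=row.radius_mm * scale,
                value=int(row.value),
            )
            for row in grp.itertuples()
        ]
        first = grp.iloc[0]
        display = Display(
            targets=targets,
            condition=condition(str(first.condition)),
            start_position=(first.start_x_mm * scale, first.start_y_mm * scale),
            trial_id=int(trial_id),
        )
        recs = []
        sub = harvests[harvests.trial_id == trial_id].sort_values("harvest_index")
        for row in sub.itertuples():
            origin = int(row.origin_target_id)
            recs.append(
                HarvestRecord(
                    trial_id=int(trial_id),
                    harvest_index=int(row.harvest_index),
                    chosen_target_id=int(row.chosen_target_id),
                    origin_target_id=START_INDEX if origin == -1 else origin,
                    inter_harvest_time=float(row.inter_harvest_time_s),
                )
            )
        trials.append((display, recs))
    return SessionData(
        effector=meta["effector"],
        movement_model=_movement_model_from_json(meta["movement_model"]),
        trials=trials,
        constrained=bool(meta.get("constrained", False)),
    )


# ---------------------------------------------------------------------------
# Front door
# ---------------------------------------------------------------------------


def write_session(session: SessionData, path: str | Path, fmt: str | None = None) -> None:
    fmt = fmt or ("csv" if str(path).endswith(".csv") else "jsonl")
    if fmt == "jsonl":
        write_session_jsonl(session, path)
    elif fmt in ("csv", "csv-pair"):
        write_session_csv(session, path)
    else:
        raise ValueError(f"unknown session format {fmt!r}")


def read_session(path: str | Path, fmt: str | None = None) -> SessionData:
    fmt = fmt or ("csv" if str(path).endswith(".csv") else "jsonl")
    if fmt == "jsonl":
        return read_session_jsonl(path)
    if fmt in ("csv", "csv-pair"):
        return read_session_csv(path)
    raise ValueError(f"unknown session format {fmt!r}")
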