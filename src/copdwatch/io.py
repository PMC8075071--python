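"""CSV/JSON/YAML readers and writers for all pipeline artifacts.

CSV dialect: comma-separated, UTF-8, one header row, missing values as
empty fields, booleans serialized as 0/1, day indices 0-based from the
inclusion date.  Write-then-read of every schema reproduces the
in-memory objects exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .analysis import PeriodRow
from .cohort import DailyRecord, ExacerbationEvent, PatientProfile, SimConfig
from .summaries import UsageSummary
from .zones import Advice, AlertEvent, Zone

__all__ = [
    "load_config",
    "write_cohort", "read_cohort",
    "write_events", "read_events",
    "write_daily_records", "read_daily_records",
    "write_period_table", "read_period_table",
    "write_alerts", "read_alerts",
    "write_usage", "write_manifest",
]

COHORT_COLUMNS = [
    "patient_id", "age", "sex", "gold", "ics_use", "fev1pp",
    "latent_pre_rate", "latent_hosp_days_rate", "followup_post", "died",
]
EVENT_COLUMNS = ["patient_id", "period", "day", "severity", "hosp_days"]
DAILY_COLUMNS = [
    "patient_id", "day", "base_answered", "base_worse", "plus_answer", "steps", "ccq",
]
PERIOD_COLUMNS = [
    "patient_id", "intervention", "exposure_days", "n_exacerbations",
    "n_hosp_days", "age", "sex", "gold", "ics_use",
]
ALERT_COLUMNS = ["patient_id", "day", "from_zone", "to_zone", "recipient", "advice"]


def load_config(path: str | Path) -> SimConfig:
    """Read a SimConfig from a YAML or JSON file (keys = field names)."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not hold a mapping")
    return SimConfig.from_dict(data)


def _write_csv(df: pd.DataFrame, path: str | Path) -> None:
    # %.17g keeps float round-trips exact
    df.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")


def write_cohort(profiles: Sequence[PatientProfile], path: str | Path) -> None:
    rows = [dataclasses.asdict(p) for p in profiles]
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    df["ics_use"] = df["ics_use"].astype(int)
    df["died"] = df["died"].astype(int)
    _write_csv(df, path)


def read_cohort(path: str | Path) -> list[PatientProfile]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        PatientProfile(
            patient_id=int(r.patient_id),
            age=float(r.age),
            sex=str(r.sex),
            gold=str(r.gold),
            ics_use=bool(r.ics_use),
            fev1pp=float(r.fev1pp),
            latent_pre_rate=float(r.latent_pre_rate),
            latent_hosp_days_rate=float(r.latent_hosp_days_rate),
            followup_post=int(r.followup_post),
            died=bool(r.died),
        )
        for r in df.itertuples()
    ]


def write_events(
    events: Mapping[str, Mapping[int, Sequence[ExacerbationEvent]]],
    path: str | Path,
) -> None:
    """Write events keyed as ``{"pre": {pid: [...]}, "post": {...}}``."""
    rows = []
    for period in ("pre", "post"):
        for pid in sorted(events.get(period, {})):
            for ev in events[period][pid]:
                rows.append((pid, period, ev.day, ev.severity, ev.hosp_days))
    _write_csv(pd.DataFrame(rows, columns=EVENT_COLUMNS), path)


def read_events(path: str | Path) -> dict[str, dict[int, list[ExacerbationEvent]]]:
    df = pd.read_csv(path, float_precision="round_trip")
    out: dict[str, dict[int, list[ExacerbationEvent]]] = {"pre": {}, "post": {}}
    for r in df.itertuples():
        out[str(r.period)].setdefault(int(r.patient_id), []).append(
            ExacerbationEvent(
                day=int(r.day), severity=str(r.severity), hosp_days=int(r.hosp_days)
            )
        )
    return out


def write_daily_records(records: Sequence[DailyRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            (
                r.patient_id,
                r.day,
                int(r.base_answered),
                "" if r.base_worse is None else int(r.base_worse),
                "" if r.plus_answer is None else r.plus_answer,
                "" if r.steps is None else r.steps,
                "" if r.ccq is None else repr(r.ccq),
            )
        )
    _write_csv(pd.DataFrame(rows, columns=DAILY_COLUMNS), path)


def read_daily_records(path: str | Path) -> list[DailyRecord]:
    df = pd.read_csv(
        path, dtype={"plus_answer": "string"}, keep_default_na=True, float_precision="round_trip"
    )
    records = []
    for r in df.itertuples():
        records.append(
            DailyRecord(
                patient_id=int(r.patient_id),
                day=int(r.day),
                base_answered=bool(r.base_answered),
                base_worse=None if pd.isna(r.base_worse) else bool(int(r.base_worse)),
                plus_answer=None if pd.isna(r.plus_answer) else str(r.plus_answer),
                steps=None if pd.isna(r.steps) else int(r.steps),
                ccq=None if pd.isna(r.ccq) else float(r.ccq),
            )
        )
    return records


def write_period_table(rows: Sequence[PeriodRow], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in rows], columns=PERIOD_COLUMNS)
    df["ics_use"] = df["ics_use"].astype(int)
    df["gold"] = df["gold"].fillna("")
    _write_csv(df, path)


def read_period_table(path: str | Path) -> list[PeriodRow]:
    df = pd.read_csv(path, dtype={"gold": "string"}, float_precision="round_trip")
    rows = []
    for r in df.itertuples():
        rows.append(
            PeriodRow(
                patient_id=int(r.patient_id),
                intervention=int(r.intervention),
                exposure_days=float(r.exposure_days),
                n_exacerbations=int(r.n_exacerbations),
                n_hosp_days=int(r.n_hosp_days),
                age=float(r.age),
                sex=str(r.sex),
                gold=None if pd.isna(r.gold) else str(r.gold),
                ics_use=bool(r.ics_use),
            )
        )
    return rows


def write_alerts(alerts: Sequence[AlertEvent], path: str | Path) -> None:
    rows = [
        (a.patient_id, a.day, a.from_zone.name, a.to_zone.name, a.recipient, a.advice.value)
        for a in alerts
    ]
    _write_csv(pd.DataFrame(rows, columns=ALERT_COLUMNS), path)


def read_alerts(path: str | Path) -> list[AlertEvent]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        AlertEvent(
            patient_id=int(r.patient_id),
            day=int(r.day),
            from_zone=Zone[str(r.from_zone)],
            to_zone=Zone[str(r.to_zone)],
            recipient=str(r.recipient),
            advice=Advice(str(r.advice)),
        )
        for r in df.itertuples()
    ]


def write_usage(summaries: Sequence[UsageSummary], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
    _write_csv(df, path)


def write_manifest(
    out_dir: str | Path,
    command: str,
    seed: int,
    config: SimConfig | None,
    output_paths: Sequence[str | Path],
) -> Path:
    """Write the per-run provenance manifest next to the outputs."""
    out_dir = Path(out_dir)
    if config is not None:
        blob = json.dumps(config.to_dict(), sort_keys=True).encode()
        config_hash = hashlib.sha256(blob).hexdigest()
    else:
        config_hash = ""
    manifest = {
        "command": command,
        "config_hash": config_hash,
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "output_paths": [str(p) for p in output_paths],
    }
    path = out_dir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return path
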