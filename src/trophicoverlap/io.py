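"""Delimited-text readers/writers for every pipeline input and result.

One canonical dialect: comma-separated with a fixed header (tab available
via ``sep="\\t"``).  Readers group and canonically sort rows so that parsed
objects are invariant to input row order, and every validation failure
names the offending row or key.  Results are serialized as JSON, which
round-trips all numeric fields exactly (floats via repr).

Stomach table columns
    fish_id, species, fork_length_mm, site_id, date (ISO-8601), reef_type,
    depth_m, prey_taxon, count, weight_g, is_bait, is_unidentifiable
    [, cohabitation].  A row with an empty prey_taxon declares an empty
    stomach.

Survey table columns
    site_id, cruise, gear, reef_type, depth_m, species, maxn, catch_count
    (maxn filled iff gear == ROV).

Trial log columns
    trial_id, treatment, time_s, species, outcome.

Category map columns
    taxon, category.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .schemas import (
    GEARS,
    TRIAL_PREY_POOL,
    CategoryMap,
    PreyItem,
    StomachSample,
    SurveyObservation,
    TrialEvent,
    ValidationError,
    season_from_date,
)

_STOMACH_COLS = [
    "fish_id", "species", "fork_length_mm", "site_id", "date", "reef_type",
    "depth_m", "prey_taxon", "count", "weight_g", "is_bait", "is_unidentifiable",
]
_SURVEY_COLS = ["site_id", "cruise", "gear", "reef_type", "depth_m", "species",
                "maxn", "catch_count"]
_TRIAL_COLS = ["trial_id", "treatment", "time_s", "species", "outcome"]

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _read_table(path: str | Path, required: Sequence[str], sep: str = ",") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing required column(s) {missing}")
    return df


def _as_bool(raw: str, row: int, col: str) -> bool:
    v = raw.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValidationError(f"row {row}: cannot parse boolean {col}={raw!r}")


def _as_float(raw: str, row: int, col: str, allow_missing: bool = False) -> float | None:
    v = raw.strip()
    if v == "":
        if allow_missing:
            return None
        raise ValidationError(f"row {row}: missing value for {col}")
    try:
        return float(v)
    except ValueError:
        raise ValidationError(f"row {row}: cannot parse number {col}={raw!r}") from None


def _as_int(raw: str, row: int, col: str, allow_missing: bool = False) -> int | None:
    f = _as_float(raw, row, col, allow_missing)
    if f is None:
        return None
    if f != int(f):
        raise ValidationError(f"row {row}: {col}={raw!r} is not an integer")
    return int(f)


def _as_date(raw: str, row: int) -> _dt.date:
    try:
        return _dt.date.fromisoformat(raw.strip())
    except ValueError:
        raise ValidationError(f"row {row}: date {raw!r} is not ISO-8601") from None


def read_stomach_table(path: str | Path, sep: str = ",",
                       season_months=None) -> list[StomachSample]:
    """Parse a stomach-contents table into one :class:`StomachSample` per fish.

    Rows sharing a ``fish_id`` are grouped; duplicate (fish, taxon, flags)
    rows are aggregated by summing counts and weights.  Season is derived
    from the ISO date through the configured month map.
    """
    df = _read_table(path, _STOMACH_COLS, sep)
    has_cohab = "cohabitation" in df.columns
    fish: dict[str, dict[str, Any]] = {}
    items: dict[str, dict[tuple, list[float]]] = {}
    for idx, rec in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        row = dict(zip(df.columns, rec))
        fid = row["fish_id"].strip()
        if not fid:
            raise ValidationError(f"row {idx}: empty fish_id")
        date = _as_date(row["date"], idx)
        meta = dict(
            fish_id=fid,
            species=row["species"].strip(),
            fork_length=_as_float(row["fork_length_mm"], idx, "fork_length_mm"),
            site_id=row["site_id"].strip(),
            date=date,
            season=season_from_date(date, season_months),
            reef_type=row["reef_type"].strip(),
            depth=_as_float(row["depth_m"], idx, "depth_m"),
            cohabitation=(row["cohabitation"].strip() or None) if has_cohab else None,
        )
        prev = fish.setdefault(fid, meta)
        if prev is not meta and prev != meta:
            raise ValidationError(f"row {idx}: fish {fid!r} has inconsistent covariates across rows")
        taxon = row["prey_taxon"].strip()
        if taxon == "":
            items.setdefault(fid, {})
            continue  # empty-stomach declaration
        count = _as_int(row["count"], idx, "count")
        weight = _as_float(row["weight_g"], idx, "weight_g")
        if count < 0:
            raise ValidationError(f"row {idx}: negative count {count}")
        if weight < 0:
            raise ValidationError(f"row {idx}: negative weight {weight}")
        key = (taxon, _as_bool(row["is_bait"], idx, "is_bait"),
               _as_bool(row["is_unidentifiable"], idx, "is_unidentifiable"))
        acc = items.setdefault(fid, {}).setdefault(key, [0, 0.0])
        acc[0] += count
        acc[1] += weight
    samples = []
    for fid in sorted(fish):
        prey = tuple(
            PreyItem(taxon=k[0], count=int(v[0]), weight=v[1], is_bait=k[1], is_unidentifiable=k[2])
            for k, v in sorted(items.get(fid, {}).items())
        )
        try:
            samples.append(StomachSample(items=prey, **fish[fid]))
        except ValidationError as e:
            raise ValidationError(f"fish {fid!r}: {e}") from None
    return samples


def read_survey_table(path: str | Path, sep: str = ",") -> list[SurveyObservation]:
    """Parse a survey table; exactly one record per (site, cruise, gear, species)."""
    df = _read_table(path, _SURVEY_COLS, sep)
    seen: set[tuple] = set()
    out = []
    for idx, rec in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, rec))
        gear = row["gear"].strip()
        key = (row["site_id"].strip(), row["cruise"].strip(), gear, row["species"].strip())
        if key in seen:
            raise ValidationError(f"row {idx}: duplicate observation key {key}")
        seen.add(key)
        maxn = _as_int(row["maxn"], idx, "maxn", allow_missing=True)
        catch = _as_int(row["catch_count"], idx, "catch_count", allow_missing=True)
        if gear in GEARS and gear != "ROV" and maxn is not None:
            raise ValidationError(f"row {idx}: maxn given for non-ROV gear {gear!r}")
        try:
            out.append(SurveyObservation(
                site_id=key[0], cruise=_as_int(row["cruise"], idx, "cruise"),
                gear=gear, reef_type=row["reef_type"].strip(),
                depth=_as_float(row["depth_m"], idx, "depth_m"),
                species=key[3], maxn=maxn, catch_count=catch,
            ))
        except ValidationError as e:
            raise ValidationError(f"row {idx}: {e}") from None
    out.sort(key=lambda o: (o.site_id, o.cruise, o.gear, o.species))
    return out


def read_trial_log(path: str | Path, sep: str = ",") -> list[TrialEvent]:
    """Parse a mesocosm event log, sorted by (trial, time); enforce the
    15-shrimp prey pool per trial."""
    df = _read_table(path, _TRIAL_COLS, sep)
    events = []
    for idx, rec in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, rec))
        try:
            events.append(TrialEvent(
                trial_id=row["trial_id"].strip(),
                treatment=row["treatment"].strip(),
                time=_as_float(row["time_s"], idx, "time_s"),
                species=row["species"].strip(),
                outcome=row["outcome"].strip(),
            ))
        except ValidationError as e:
            raise ValidationError(f"row {idx}: {e}") from None
    events.sort(key=lambda e: (e.trial_id, e.time, e.species, e.outcome))
    per_trial: dict[str, int] = {}
    for e in events:
        if e.outcome == "success":
            per_trial[e.trial_id] = per_trial.get(e.trial_id, 0) + 1
            if per_trial[e.trial_id] > TRIAL_PREY_POOL:
                raise ValidationError(
                    f"trial {e.trial_id!r}: more than {TRIAL_PREY_POOL} successes "
                    f"(prey pool exhausted at {TRIAL_PREY_POOL})"
                )
    return events


def read_category_map(path: str | Path, sep: str = ",") -> CategoryMap:
    df = _read_table(path, ["taxon", "category"], sep)
    mapping: dict[str, str] = {}
    for idx, rec in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, rec))
        taxon = row["taxon"].strip()
        if taxon in mapping and mapping[taxon] != row["category"].strip():
            raise ValidationError(f"row {idx}: taxon {taxon!r} mapped to two categories")
        mapping[taxon] = row["category"].strip()
    return CategoryMap(mapping=mapping)


# ---------------------------------------------------------------------------
# result serialization


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {"__type__": type(obj).__name__,
                **{k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.Series):
        return {"index": [str(i) for i in obj.index], "values": _jsonable(obj.to_numpy())}
    if isinstance(obj, pd.DataFrame):
        return {"columns": list(map(str, obj.columns)),
                "index": list(map(str, obj.index)),
                "data": _jsonable(obj.to_numpy())}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, _dt.date):
        return obj.isoformat()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_result(result: Any, path: str | Path) -> None:
    """Serialize an analysis result (dataclass / dict / DataFrame tree) as
    JSON.  Numeric fields round-trip exactly; key order is deterministic."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(result), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_result(path: str | Path) -> Any:
    with open(path) as fh:
        return json.load(fh)
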