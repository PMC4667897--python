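"""Domain record types shared by every analysis stage.

The pipeline revolves around four tabular inputs: stomach-contents records
(one row per prey item per fish), multi-gear reef surveys (one row per
site/cruise/gear/species), mesocosm predation-event logs, and a mapping
from fine prey taxa to the broad categories used for diet indices.  The
classes here are plain frozen dataclasses with validation in
``__post_init__``; the CSV plumbing lives in :mod:`trophicoverlap.io`.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

SPECIES = ("RS", "VS")  # red snapper, vermilion snapper
SEASONS = ("spring", "summer")
REEF_TYPES = ("artificial", "natural")
GEARS = ("ROV", "vertical_longline", "hook_and_line")
CRUISES = (1, 2, 3)
TREATMENTS = ("control", "RS6", "VS6", "MIX33")
OUTCOMES = ("success", "fail")

#: fish per species per treatment (substitutive design: total density fixed)
TREATMENT_DESIGN: Mapping[str, Mapping[str, int]] = {
    "control": {"RS": 0, "VS": 0},
    "RS6": {"RS": 6, "VS": 0},
    "VS6": {"RS": 0, "VS": 6},
    "MIX33": {"RS": 3, "VS": 3},
}

#: shrimp introduced per trial; successes cannot exceed this
TRIAL_PREY_POOL = 15
#: recorded trial duration, seconds
TRIAL_DURATION_S = 1800

#: depth-bin presets (metres).  The community analysis uses four 20 m bins,
#: the diet analysis a shallow/deep split.
DEPTH_BIN_PRESETS: Mapping[str, Sequence[float]] = {
    "community_20m_bins": (20.0, 40.0, 60.0, 80.0, 100.0),
    "diet_2_bins": (20.0, 60.0, 100.0),
}

#: month -> season; configurable because cruise labels ("Spring 2011") never
#: pin down month boundaries.  Months outside the map are rejected.
DEFAULT_SEASON_MONTHS: Mapping[int, str] = {
    2: "spring", 3: "spring", 4: "spring", 5: "spring", 6: "spring",
    7: "summer", 8: "summer", 9: "summer", 10: "summer", 11: "summer",
}


class ValidationError(ValueError):
    """Raised when an input record violates its schema contract."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def depth_bin_label(depth: float, preset: str | Sequence[float]) -> str:
    """Assign a depth (m) to its bin label, e.g. ``"20-40m"``.

    ``preset`` is a preset name or an explicit increasing edge sequence.
    The shallowest bin is closed on both sides; deeper bins are
    left-open/right-closed so a 40 m site falls in "20-40m".
    """
    edges = DEPTH_BIN_PRESETS[preset] if isinstance(preset, str) else tuple(preset)
    _check(len(edges) >= 2, "depth bin preset needs at least two edges")
    if not (edges[0] <= depth <= edges[-1]):
        raise ValidationError(
            f"depth {depth} m outside binning range [{edges[0]}, {edges[-1]}]"
        )
    for lo, hi in zip(edges[:-1], edges[1:]):
        if depth <= hi:
            return f"{lo:g}-{hi:g}m"
    raise AssertionError("unreachable")


def season_from_date(date: _dt.date, months: Mapping[int, str] | None = None) -> str:
    months = DEFAULT_SEASON_MONTHS if months is None else months
    try:
        return months[date.month]
    except KeyError:
        raise ValidationError(
            f"month {date.month} of {date.isoformat()} has no configured season"
        ) from None


@dataclass(frozen=True)
class PreyItem:
    """A single prey entry from one stomach.

    ``weight`` is wet weight in grams at 0.01 g resolution; zero-weight
    items with positive counts are legal (mass below scale resolution) and
    contribute to %N/%O only.  Items flagged ``is_unidentifiable`` (chyme)
    or ``is_bait`` carry weight but are excluded from index math.
    """

    taxon: str
    count: int
    weight: float
    is_bait: bool = False
    is_unidentifiable: bool = False

    def __post_init__(self) -> None:
        _check(bool(self.taxon), "prey item needs a non-empty taxon")
        _check(self.count >= 0, f"negative count {self.count} for taxon {self.taxon!r}")
        _check(self.weight >= 0, f"negative weight {self.weight} for taxon {self.taxon!r}")


@dataclass(frozen=True)
class StomachSample:
    """One fish's stomach: covariates plus its (possibly empty) prey items."""

    fish_id: str
    species: str
    fork_length: float  # mm
    site_id: str
    date: _dt.date
    season: str
    reef_type: str
    depth: float  # m
    items: tuple[PreyItem, ...] = ()
    cohabitation: str | None = None  # "sympatric" / "allopatric" when known

    def __post_init__(self) -> None:
        _check(self.species in SPECIES, f"unknown species code {self.species!r} for fish {self.fish_id}")
        _check(self.fork_length > 0, f"fork_length must be > 0 for fish {self.fish_id}")
        _check(self.season in SEASONS, f"unknown season {self.season!r} for fish {self.fish_id}")
        _check(self.reef_type in REEF_TYPES, f"unknown reef_type {self.reef_type!r} for fish {self.fish_id}")
        _check(self.depth > 0, f"depth must be > 0 for fish {self.fish_id}")
        if self.cohabitation is not None:
            _check(self.cohabitation in ("sympatric", "allopatric"),
                   f"unknown cohabitation label {self.cohabitation!r} for fish {self.fish_id}")
        object.__setattr__(self, "items", tuple(self.items))

    @property
    def identifiable_items(self) -> tuple[PreyItem, ...]:
        return tuple(i for i in self.items if not i.is_bait and not i.is_unidentifiable)

    @property
    def has_identifiable_prey(self) -> bool:
        return len(self.identifiable_items) > 0

    def replace_items(self, items: Sequence[PreyItem]) -> "StomachSample":
        return dataclasses.replace(self, items=tuple(items))


@dataclass(frozen=True)
class SurveyObservation:
    """One species' detection record for one site/cruise/gear.

    ``maxn`` (maximum count in any single video frame) is defined for ROV
    records only; capture gears carry ``catch_count`` instead.
    """

    site_id: str
    cruise: int
    gear: str
    reef_type: str
    depth: float
    species: str
    maxn: int | None = None
    catch_count: int | None = None

    def __post_init__(self) -> None:
        key = f"({self.site_id}, cruise {self.cruise}, {self.gear}, {self.species})"
        _check(self.cruise in CRUISES, f"unknown cruise {self.cruise} at {key}")
        _check(self.gear in GEARS, f"unknown gear {self.gear!r} at {key}")
        _check(self.reef_type in REEF_TYPES, f"unknown reef_type {self.reef_type!r} at {key}")
        _check(self.species in SPECIES, f"unknown species {self.species!r} at {key}")
        _check(self.depth > 0, f"depth must be > 0 at {key}")
        if self.gear == "ROV":
            _check(self.maxn is not None, f"ROV record missing maxn at {key}")
            _check(self.catch_count is None, f"ROV record may not carry catch_count at {key}")
            _check(self.maxn >= 0, f"negative maxn at {key}")
        else:
            _check(self.catch_count is not None, f"capture-gear record missing catch_count at {key}")
            _check(self.maxn is None, f"maxn only defined for ROV gear at {key}")
            _check(self.catch_count >= 0, f"negative catch_count at {key}")

    @property
    def detected(self) -> bool:
        return (self.maxn or 0) > 0 or (self.catch_count or 0) > 0


@dataclass(frozen=True)
class TrialEvent:
    """One time-stamped predation attempt in a mesocosm trial."""

    trial_id: str
    treatment: str
    time: float  # seconds since prey introduction
    species: str
    outcome: str

    def __post_init__(self) -> None:
        _check(self.treatment in TREATMENTS, f"unknown treatment {self.treatment!r} in trial {self.trial_id}")
        _check(self.species in SPECIES, f"unknown species {self.species!r} in trial {self.trial_id}")
        _check(self.outcome in OUTCOMES, f"unknown outcome {self.outcome!r} in trial {self.trial_id}")
        _check(0 <= self.time <= TRIAL_DURATION_S,
               f"event time {self.time}s outside [0, {TRIAL_DURATION_S}] in trial {self.trial_id}")
        _check(self.treatment != "control", f"control trial {self.trial_id} may not contain events")
        n_fish = TREATMENT_DESIGN[self.treatment][self.species]
        _check(n_fish > 0, f"species {self.species} absent from treatment {self.treatment} (trial {self.trial_id})")


@dataclass(frozen=True)
class CategoryMap:
    """Total mapping from prey taxon to broad analysis category."""

    mapping: Mapping[str, str]
    categories: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        mapping = dict(self.mapping)
        object.__setattr__(self, "mapping", mapping)
        cats = tuple(self.categories) or tuple(sorted(set(mapping.values())))
        object.__setattr__(self, "categories", cats)
        missing = set(mapping.values()) - set(cats)
        _check(not missing, f"mapped categories absent from category list: {sorted(missing)}")

    def __getitem__(self, taxon: str) -> str:
        try:
            return self.mapping[taxon]
        except KeyError:
            raise ValidationError(f"prey taxon {taxon!r} has no category mapping") from None

    def __len__(self) -> int:
        return len(self.mapping)
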