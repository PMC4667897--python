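"""Spatial co-occurrence summaries and MaxN-by-stratum descriptives.

Presence of a species at a site/cruise is declared when *any* gear
detected it (ROV MaxN > 0 or any capture count > 0); absence requires
every gear fished there to report zero.  Site/cruise visits with no
observation rows at all are excluded from denominators (missing effort is
not absence) and counted in ``n_excluded``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schemas import SPECIES, SurveyObservation, ValidationError, depth_bin_label

STATES = ("both", "RS_only", "VS_only", "neither")


@dataclass(frozen=True)
class CooccurrenceSummary:
    """Four-state site classification, per cruise and pooled."""

    counts: pd.DataFrame       # rows: cruise labels + "combined"; cols: STATES
    percentages: pd.DataFrame  # same shape, rows sum to 100
    n_excluded: int


@dataclass(frozen=True)
class StratumSummary:
    stratum: str
    species: str
    n: int
    mean: float
    median: float
    q1: float
    q3: float


def combine_detections(observations: Iterable[SurveyObservation]) -> pd.DataFrame:
    """Per-(site, cruise) presence flags per species, OR-ed across gears.

    Returns a DataFrame indexed by (site_id, cruise) with one boolean
    column per species.  A species with no record at a visited site/cruise
    is treated as undetected there (all listed gears reported nothing).
    """
    rows = list(observations)
    if not rows:
        empty = pd.MultiIndex.from_arrays([[], []], names=["site_id", "cruise"])
        return pd.DataFrame(columns=list(SPECIES), index=empty)
    df = pd.DataFrame(
        [(o.site_id, o.cruise, o.species, o.detected) for o in rows],
        columns=["site_id", "cruise", "species", "detected"],
    )
    wide = (df.groupby(["site_id", "cruise", "species"])["detected"].any()
              .unstack("species", fill_value=False)
              .reindex(columns=list(SPECIES), fill_value=False))
    return wide.sort_index()


def cooccurrence_summary(presence: pd.DataFrame) -> CooccurrenceSummary:
    """Classify each site/cruise visit into {both, RS only, VS only,
    neither}; report counts and percentages per cruise and combined
    (site-cruise visits as the pooled unit)."""
    if presence.empty:
        raise ValidationError("no site/cruise visits to summarize")
    rs = presence["RS"].astype(bool)
    vs = presence["VS"].astype(bool)
    state = np.select(
        [rs & vs, rs & ~vs, ~rs & vs], ["both", "RS_only", "VS_only"], default="neither"
    )
    df = pd.DataFrame({"cruise": presence.index.get_level_values("cruise"), "state": state})
    counts = (df.groupby("cruise")["state"].value_counts().unstack(fill_value=0)
                .reindex(columns=list(STATES), fill_value=0))
    counts.index = [f"cruise_{c}" for c in counts.index]
    counts.loc["combined"] = counts.sum(axis=0)
    pct = 100.0 * counts.div(counts.sum(axis=1), axis=0)
    return CooccurrenceSummary(counts=counts, percentages=pct, n_excluded=0)


def maxn_by_stratum(observations: Iterable[SurveyObservation],
                    strata: Sequence[str] = ("reef_type",),
                    depth_preset: str = "community_20m_bins") -> list[StratumSummary]:
    """Mean/median/quartiles of ROV MaxN per species within each stratum.

    ``strata`` is any subset of {"reef_type", "depth_bin"}; non-detections
    enter as MaxN = 0.  Only ROV records are used (MaxN is undefined for
    capture gears).
    """
    valid = {"reef_type", "depth_bin"}
    unknown = set(strata) - valid
    if unknown:
        raise ValidationError(f"unknown stratum key(s) {sorted(unknown)}")
    rows = []
    for o in observations:
        if o.gear != "ROV":
            continue
        labels = []
        if "reef_type" in strata:
            labels.append(o.reef_type)
        if "depth_bin" in strata:
            labels.append(depth_bin_label(o.depth, depth_preset))
        rows.append((" × ".join(labels) if labels else "all", o.species, o.maxn))
    if not rows:
        raise ValidationError("no ROV observations to stratify")
    df = pd.DataFrame(rows, columns=["stratum", "species", "maxn"])
    out = []
    for (stratum, sp), grp in df.groupby(["stratum", "species"], sort=True):
        v = grp["maxn"].to_numpy(float)
        out.append(StratumSummary(
            stratum=stratum, species=sp, n=int(v.size),
            mean=float(v.mean()), median=float(np.median(v)),
            q1=float(np.percentile(v, 25)), q3=float(np.percentile(v, 75)),
        ))
    return out


def maxn_sample_matrix(observations: Iterable[SurveyObservation],
                       depth_preset: str = "community_20m_bins"):
    """Site/cruise × species MaxN matrix with habitat factors, ready for the
    community PERMANOVA.  Returns (values, sample_ids, species, factors)."""
    rows = [(o.site_id, o.cruise, o.species, o.maxn, o.reef_type, o.depth)
            for o in observations if o.gear == "ROV"]
    if not rows:
        raise ValidationError("no ROV observations for community matrix")
    df = pd.DataFrame(rows, columns=["site_id", "cruise", "species", "maxn",
                                     "reef_type", "depth"])
    wide = (df.pivot_table(index=["site_id", "cruise"], columns="species",
                           values="maxn", fill_value=0)
              .reindex(columns=sorted(df["species"].unique()), fill_value=0))
    meta = df.drop_duplicates(["site_id", "cruise"]).set_index(["site_id", "cruise"])
    sample_ids = [f"{s}/c{c}" for s, c in wide.index]
    factors = pd.DataFrame({
        "reef_type": meta.loc[wide.index, "reef_type"].to_numpy(),
        "depth_bin": [depth_bin_label(d, depth_preset)
                      for d in meta.loc[wide.index, "depth"]],
    }, index=sample_ids)
    return wide.to_numpy(float), sample_ids, tuple(wide.columns), factors
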