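"""Diet-composition indices from stomach contents.

For prey category *i* across a set of stomachs:

    %N_i = 100 * (number of prey items of i) / (all identifiable prey items)
    %O_i = 100 * (stomachs containing i) / (stomachs with identifiable prey)
    %W_i = 100 * (weight of i) / (weight of all identifiable contents)
    IRI_i = (%N_i + %W_i) * %O_i          (additive, classical form; default)
          or %N_i * %W_i * %O_i           (multiplicative variant)
    %IRI_i = 100 * IRI_i / sum_j IRI_j

Two estimators are supported.  ``pooled`` computes %N/%W from grand totals
over all stomachs (the form the equations above read as, and the input to
the overlap analysis).  ``mean_of_stomachs`` computes per-stomach percent
compositions first and averages them across stomachs with identifiable
prey, reporting standard errors — the form diet tables are commonly
printed in.  %O is identical under both.

The additive/multiplicative IRI ambiguity is real in the literature: the
source equations are sometimes typeset multiplicatively while the printed
%IRI values follow the classical additive Pinkas form.  Both ship;
additive is the default (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schemas import CategoryMap, PreyItem, StomachSample, ValidationError

ESTIMATORS = ("pooled", "mean_of_stomachs")
IRI_VARIANTS = ("additive", "multiplicative")


@dataclass(frozen=True)
class DietSummary:
    """Per-category diet composition for one species/stratum."""

    species: str
    stratum: str
    pctN: pd.Series
    pctW: pd.Series
    pctO: pd.Series
    iri: pd.Series
    pctIRI: pd.Series
    n_stomachs_with_prey: int
    estimator: str
    iri_variant: str
    pctN_se: pd.Series | None = None
    pctW_se: pd.Series | None = None

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.pctN.index)

    def table(self) -> pd.DataFrame:
        cols = {"pctN": self.pctN, "pctW": self.pctW, "pctO": self.pctO,
                "iri": self.iri, "pctIRI": self.pctIRI}
        if self.pctN_se is not None:
            cols["pctN_se"] = self.pctN_se
            cols["pctW_se"] = self.pctW_se
        return pd.DataFrame(cols)


def condense_categories(samples: Iterable[StomachSample], cmap: CategoryMap) -> list[StomachSample]:
    """Re-label prey items to broad categories, aggregating within each fish.

    Counts and weights are summed within (fish, category, flags); bait and
    unidentifiable flags partition the aggregation so exclusions stay
    intact.  Raises on any taxon the map does not cover.
    """
    out = []
    for s in samples:
        agg: dict[tuple, list[float]] = {}
        for item in s.items:
            key = (cmap[item.taxon], item.is_bait, item.is_unidentifiable)
            acc = agg.setdefault(key, [0, 0.0])
            acc[0] += item.count
            acc[1] += item.weight
        out.append(s.replace_items(
            PreyItem(taxon=k[0], count=int(v[0]), weight=v[1], is_bait=k[1], is_unidentifiable=k[2])
            for k, v in sorted(agg.items())
        ))
    return out


def filter_contents(samples: Iterable[StomachSample], exclude_bait: bool = True,
                    exclude_unidentifiable: bool = True) -> list[StomachSample]:
    """Drop flagged items.  Fish left with no items are retained (they fall
    out of the %O denominator downstream but stay countable)."""
    out = []
    for s in samples:
        kept = [i for i in s.items
                if not (exclude_bait and i.is_bait)
                and not (exclude_unidentifiable and i.is_unidentifiable)]
        out.append(s.replace_items(kept))
    return out


def _item_frame(samples: Sequence[StomachSample]) -> pd.DataFrame:
    rows = [(s.fish_id, i.taxon, i.count, i.weight)
            for s in samples for i in s.identifiable_items]
    return pd.DataFrame(rows, columns=["fish_id", "category", "count", "weight"])


def diet_summary(samples: Sequence[StomachSample], estimator: str = "pooled",
                 iri_variant: str = "additive", species: str = "",
                 stratum: str = "all",
                 categories: Sequence[str] | None = None) -> DietSummary:
    """Compute %N/%O/%W and (%)IRI over ``samples`` (already condensed and
    filtered).  ``categories`` fixes/ orders the category axis (needed to
    align two species for an overlap matrix); defaults to the categories
    observed, sorted."""
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    if iri_variant not in IRI_VARIANTS:
        raise ValueError(f"unknown IRI variant {iri_variant!r}")
    df = _item_frame(samples)
    if df.empty:
        raise ValidationError("no stomach with identifiable prey: diet indices undefined")
    cats = list(categories) if categories is not None else sorted(df["category"].unique())
    unknown = set(df["category"]) - set(cats)
    if unknown:
        raise ValidationError(f"categories outside the configured list: {sorted(unknown)}")
    n_stomachs = df["fish_id"].nunique()

    occ = df.groupby("category")["fish_id"].nunique().reindex(cats, fill_value=0)
    pctO = 100.0 * occ / n_stomachs

    pctN_se = pctW_se = None
    if estimator == "pooled":
        counts = df.groupby("category")["count"].sum().reindex(cats, fill_value=0)
        weights = df.groupby("category")["weight"].sum().reindex(cats, fill_value=0.0)
        if counts.sum() == 0:
            raise ValidationError("zero total prey count: %N undefined")
        if weights.sum() == 0:
            raise ValidationError("zero total prey weight: %W undefined")
        pctN = 100.0 * counts / counts.sum()
        pctW = 100.0 * weights / weights.sum()
    else:
        per_n = (df.pivot_table(index="fish_id", columns="category", values="count",
                                aggfunc="sum", fill_value=0)
                 .reindex(columns=cats, fill_value=0))
        per_w = (df.pivot_table(index="fish_id", columns="category", values="weight",
                                aggfunc="sum", fill_value=0.0)
                 .reindex(columns=cats, fill_value=0.0))
        # per-stomach percent composition; stomachs with zero identifiable
        # weight (all items below scale resolution) drop out of the %W mean
        prop_n = per_n.div(per_n.sum(axis=1), axis=0) * 100.0
        w_tot = per_w.sum(axis=1)
        prop_w = per_w.loc[w_tot > 0].div(w_tot[w_tot > 0], axis=0) * 100.0
        pctN = prop_n.mean(axis=0)
        pctW = prop_w.mean(axis=0)
        pctN_se = prop_n.std(axis=0, ddof=1) / np.sqrt(len(prop_n)) if len(prop_n) > 1 else prop_n.iloc[0] * 0.0
        pctW_se = prop_w.std(axis=0, ddof=1) / np.sqrt(len(prop_w)) if len(prop_w) > 1 else prop_w.iloc[0] * 0.0

    iri, pctIRI = compute_iri(pctN, pctW, pctO, iri_variant)
    return DietSummary(species=species, stratum=stratum,
                       pctN=pctN, pctW=pctW, pctO=pctO, iri=iri, pctIRI=pctIRI,
                       n_stomachs_with_prey=int(n_stomachs), estimator=estimator,
                       iri_variant=iri_variant, pctN_se=pctN_se, pctW_se=pctW_se)


def compute_iri(pctN: pd.Series, pctW: pd.Series, pctO: pd.Series,
                variant: str = "additive") -> tuple[pd.Series, pd.Series]:
    """Index of relative importance per category, plus its %IRI normalization."""
    if variant not in IRI_VARIANTS:
        raise ValueError(f"unknown IRI variant {variant!r}")
    if not (len(pctN) == len(pctW) == len(pctO)):
        raise ValidationError("IRI inputs must have equal length")
    index = pctN.index if isinstance(pctN, pd.Series) else pd.RangeIndex(len(pctN))
    pctN, pctW, pctO = (pd.Series(np.asarray(v, dtype=float), index=index)
                        for v in (pctN, pctW, pctO))
    if variant == "additive":
        iri = (pctN + pctW) * pctO
    else:
        iri = pctN * pctW * pctO
    total = iri.sum()
    if total <= 0:
        raise ValidationError("all IRI values are zero: %IRI normalization impossible")
    return iri, 100.0 * iri / total
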