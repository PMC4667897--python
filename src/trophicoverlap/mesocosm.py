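"""Mesocosm feeding-trial summaries, contrasts, and regressions.

Trials follow a substitutive design (total predator density fixed at 6):
control (no fish), 6 red snapper (RS6), 6 vermilion snapper (VS6), or
3 + 3 (MIX33), each offered 15 brown shrimp and recorded for 30 minutes.
The trial is the independent unit; per-species tallies within a trial are
scaled by the designed fish count to shrimp-per-fish.

Contrasts between (treatment, species) groups use Welch's two-sample t by
default, with an exact/Monte-Carlo permutation test on the mean
difference always available (exhaustive enumeration whenever the group
sizes allow).  The two regressions are ordinary least squares: shrimp per
fish on predation success rate (species-within-trial units), and squared
cumulative consumption on time × species (the square transform
linearizes the saturating consumption curves).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

from .schemas import (
    TREATMENT_DESIGN,
    TRIAL_DURATION_S,
    TRIAL_PREY_POOL,
    TrialEvent,
    ValidationError,
)


@dataclass(frozen=True)
class SpeciesTally:
    species: str
    n_fish: int
    consumed: int
    failed: int

    @property
    def shrimp_per_fish(self) -> float:
        return self.consumed / self.n_fish if self.n_fish else float("nan")

    @property
    def attempts(self) -> int:
        return self.consumed + self.failed

    @property
    def success_rate(self) -> float | None:
        """consumed / attempts; None when the species never struck."""
        return self.consumed / self.attempts if self.attempts else None


@dataclass(frozen=True)
class TrialSummary:
    trial_id: str
    treatment: str
    tallies: tuple[SpeciesTally, ...]
    duration: float = TRIAL_DURATION_S

    def tally(self, species: str) -> SpeciesTally:
        for t in self.tallies:
            if t.species == species:
                return t
        raise KeyError(species)

    @property
    def total_consumed(self) -> int:
        return sum(t.consumed for t in self.tallies)


@dataclass(frozen=True)
class ContrastResult:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    difference: float
    statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int


@dataclass(frozen=True)
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int
    p_value: float
    response_transform: str
    interaction_f: float | None = None
    interaction_p: float | None = None
    n_obs: int = 0


def trial_summary(events: Sequence[TrialEvent], trial_id: str, treatment: str,
                  design: Mapping[str, Mapping[str, int]] | None = None) -> TrialSummary:
    """Tally successes/failures per species for one trial; shrimp-per-fish
    uses the designed fish count for that species in that treatment."""
    design = TREATMENT_DESIGN if design is None else design
    if treatment not in design:
        raise ValidationError(f"unknown treatment {treatment!r} for trial {trial_id}")
    counts = design[treatment]
    tallies = []
    total = 0
    for sp, n_fish in counts.items():
        ev = [e for e in events if e.trial_id == trial_id and e.species == sp]
        if ev and n_fish == 0:
            raise ValidationError(
                f"trial {trial_id}: events recorded for {sp}, absent from treatment {treatment}")
        consumed = sum(e.outcome == "success" for e in ev)
        failed = sum(e.outcome == "fail" for e in ev)
        total += consumed
        tallies.append(SpeciesTally(species=sp, n_fish=n_fish, consumed=consumed, failed=failed))
    if total > TRIAL_PREY_POOL:
        raise ValidationError(f"trial {trial_id}: {total} successes exceed the "
                              f"{TRIAL_PREY_POOL}-shrimp pool")
    return TrialSummary(trial_id=trial_id, treatment=treatment, tallies=tuple(tallies))


def summarize_trials(events: Iterable[TrialEvent],
                     trial_treatments: Mapping[str, str],
                     design: Mapping[str, Mapping[str, int]] | None = None) -> list[TrialSummary]:
    """One :class:`TrialSummary` per trial in ``trial_treatments`` (which
    must list every trial, including event-less controls)."""
    events = list(events)
    known = set(trial_treatments)
    stray = {e.trial_id for e in events} - known
    if stray:
        raise ValidationError(f"events for unknown trial id(s) {sorted(stray)}")
    return [trial_summary(events, tid, trt, design)
            for tid, trt in sorted(trial_treatments.items())]


def _per_fish_values(summaries: Iterable[TrialSummary],
                     group: tuple[str, str]) -> np.ndarray:
    treatment, species = group
    vals = [s.tally(species).shrimp_per_fish for s in summaries if s.treatment == treatment]
    return np.asarray(vals, dtype=float)


def _perm_pvalue_mean_diff(a: np.ndarray, b: np.ndarray, seed: int | None,
                           max_exact: int = 200_000, reps: int = 20_000) -> tuple[float, float]:
    """Two-tailed permutation p for |mean(a) - mean(b)|.

    Complete enumeration of group assignments when C(n, na) <= max_exact,
    else Monte-Carlo with add-one correction.
    """
    pooled = np.concatenate([a, b])
    na, n = a.size, a.size + b.size
    obs = abs(a.mean() - b.mean())
    n_comb = math.comb(n, na)
    tol = 1e-12
    if n_comb <= max_exact:
        count = 0
        idx = np.arange(n)
        for comb in itertools.combinations(idx, na):
            sel = np.zeros(n, dtype=bool)
            sel[list(comb)] = True
            d = abs(pooled[sel].mean() - pooled[~sel].mean())
            count += d >= obs - tol
        return obs, count / n_comb
    if seed is None:
        raise ValidationError("a seed is required for Monte-Carlo permutation")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(reps):
        perm = rng.permutation(pooled)
        count += abs(perm[:na].mean() - perm[na:].mean()) >= obs - tol
    return obs, (count + 1) / (reps + 1)


def compare_consumption(summaries: Sequence[TrialSummary],
                        group_a: tuple[str, str], group_b: tuple[str, str],
                        method: str = "welch", seed: int | None = None) -> ContrastResult:
    """Two-sample comparison of per-trial shrimp-per-fish between two
    (treatment, species) groups.

    ``method``: ``"welch"`` (unequal-variance t, trials as units) or
    ``"permutation"`` (two-tailed test on the mean difference, exact when
    enumerable)."""
    a = _per_fish_values(summaries, group_a)
    b = _per_fish_values(summaries, group_b)
    label_a = f"{group_a[0]}:{group_a[1]}"
    label_b = f"{group_b[0]}:{group_b[1]}"
    if method == "welch":
        if a.size < 2 or b.size < 2:
            raise ValidationError("Welch's t needs at least 2 trials per group")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        stat, pval = float(t), float(p)
    elif method == "permutation":
        if a.size < 1 or b.size < 1:
            raise ValidationError("permutation test needs at least 1 trial per group")
        stat, pval = _perm_pvalue_mean_diff(a, b, seed)
    else:
        raise ValidationError(f"unknown contrast method {method!r}")
    return ContrastResult(group_a=label_a, group_b=label_b,
                          mean_a=float(a.mean()), mean_b=float(b.mean()),
                          difference=float(a.mean() - b.mean()),
                          statistic=stat, p_value=pval, method=method,
                          n_a=int(a.size), n_b=int(b.size))


def success_rate_regression(summaries: Sequence[TrialSummary]) -> RegressionResult:
    """OLS of shrimp-per-fish on predation success rate.

    Observations are species-within-trial units (each species present in a
    trial contributes one point); units whose species made no attempt have
    an undefined success rate and are excluded.
    """
    rows = []
    for s in summaries:
        for t in s.tallies:
            if t.n_fish == 0:
                continue
            sr = t.success_rate
            if sr is None:
                continue
            rows.append((sr, t.shrimp_per_fish))
    if len(rows) < 3:
        raise ValidationError("need at least 3 species-trial points with defined success rate")
    df = pd.DataFrame(rows, columns=["success_rate", "per_fish"])
    if df["success_rate"].nunique() == 1:
        raise ValidationError("zero variance in success rate: regression undefined")
    x = sm.add_constant(df["success_rate"])
    fit = sm.OLS(df["per_fish"], x).fit()
    constant_y = df["per_fish"].nunique() == 1  # R^2 and F degenerate to 0
    return RegressionResult(
        params=fit.params, bse=fit.bse,
        r_squared=0.0 if constant_y else float(fit.rsquared),
        f_statistic=0.0 if constant_y else float(fit.fvalue),
        df_model=int(fit.df_model), df_resid=int(fit.df_resid),
        p_value=1.0 if constant_y else float(fit.f_pvalue),
        response_transform="identity", n_obs=int(fit.nobs),
    )


def cumulative_curve(events: Sequence[TrialEvent], trial_id: str, species: str,
                     grid: np.ndarray, per_fish: bool = True,
                     design: Mapping[str, Mapping[str, int]] | None = None) -> np.ndarray:
    """Cumulative successful strikes for one trial/species evaluated on a
    time grid (seconds); nondecreasing step function, optionally per fish."""
    design = TREATMENT_DESIGN if design is None else design
    times = np.sort([e.time for e in events
                     if e.trial_id == trial_id and e.species == species
                     and e.outcome == "success"])
    cum = np.searchsorted(times, np.asarray(grid, dtype=float), side="right").astype(float)
    if per_fish:
        ev = [e for e in events if e.trial_id == trial_id]
        if not ev:
            return cum * np.nan
        n_fish = design[ev[0].treatment][species]
        cum = cum / n_fish if n_fish else cum * np.nan
    return cum


def feeding_rate_model(events: Sequence[TrialEvent],
                       grid_minutes: Sequence[float] | None = None,
                       pool_trials: bool = False,
                       design: Mapping[str, Mapping[str, int]] | None = None) -> RegressionResult:
    """OLS of squared cumulative per-fish consumption on time, species and
    their interaction.

    Each (trial, species) pair with fish present contributes its cumulative
    curve evaluated on the grid (default every minute over 0-30 min);
    ``pool_trials`` instead averages curves within species first.  The
    square transform linearizes root-like saturating curves; the
    interaction term tests whether the two species' feeding rates differ.
    """
    events = list(events)
    if grid_minutes is None:
        grid_minutes = np.arange(1.0, TRIAL_DURATION_S / 60.0 + 1e-9, 1.0)
    grid_minutes = np.asarray(list(grid_minutes), dtype=float)
    if grid_minutes.size < 2:
        raise ValidationError("time grid needs at least 2 points")
    design = TREATMENT_DESIGN if design is None else design
    grid_s = grid_minutes * 60.0

    trials: dict[str, str] = {}
    for e in events:
        trials.setdefault(e.trial_id, e.treatment)
    rows = []
    for tid, trt in sorted(trials.items()):
        for sp, n_fish in design[trt].items():
            if n_fish == 0:
                continue
            curve = cumulative_curve(events, tid, sp, grid_s, per_fish=True, design=design)
            rows.append(pd.DataFrame({"time": grid_minutes, "species": sp,
                                      "trial": tid, "cum": curve}))
    if not rows:
        raise ValidationError("no trial/species observations for the feeding-rate model")
    df = pd.concat(rows, ignore_index=True)
    if df["species"].nunique() < 2:
        raise ValidationError("feeding-rate model needs both species present")
    if pool_trials:
        df = (df.groupby(["species", "time"], as_index=False)["cum"].mean())
    df["y"] = df["cum"] ** 2
    df["is_rs"] = (df["species"] == "RS").astype(float)
    df["tx"] = df["time"] * df["is_rs"]
    x = sm.add_constant(df[["time", "is_rs", "tx"]])
    fit = sm.OLS(df["y"], x).fit()
    # interaction F on 1 df = square of its t statistic
    t_int = float(fit.tvalues["tx"])
    return RegressionResult(
        params=fit.params, bse=fit.bse, r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue), df_model=int(fit.df_model),
        df_resid=int(fit.df_resid), p_value=float(fit.f_pvalue),
        response_transform="square", interaction_f=t_int ** 2,
        interaction_p=float(fit.pvalues["tx"]), n_obs=int(fit.nobs),
    )
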