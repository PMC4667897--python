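"""Multivariate community statistics on Bray-Curtis dissimilarities.

The chain is the PRIMER-style one: square-root transform the sample ×
variable abundance matrix, compute zero-adjusted Bray-Curtis
dissimilarities on the 0-100 scale,

    BC(x, y) = 100 * sum_k |x_k - y_k| / sum_k (x_k + y_k)

after appending a constant dummy variable to every sample (so two empty
samples are perfectly similar instead of undefined), then test factor
effects by PERMANOVA and decompose significant contrasts with SIMPER.

PERMANOVA partitions the total sum of squares of the distance matrix via
the Gower-centered inner-product matrix G = -(1/2) J D^2 J (J the
centering projector):  for a sequence of model terms with cumulative hat
matrices H_0 (intercept) .. H_m,

    SS(term k) = tr((H_k - H_{k-1}) G)      (sequential, Type I)
    pseudo-F_k = (SS_k / df_k) / (SS_res / df_res)

with significance from unrestricted permutation of sample labels
(equivalently, conjugating G by a permutation).  Sequential SS means term
order matters in unbalanced designs; the order is caller-controlled and
recorded.  Interaction tests under unrestricted permutation are
approximate — see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .schemas import ValidationError

DUMMY_VARIABLE = "__dummy__"


@dataclass(frozen=True)
class SampleMatrix:
    """Nonnegative sample × variable abundances plus per-sample factors."""

    sample_ids: tuple[str, ...]
    variables: tuple[str, ...]
    values: np.ndarray
    factors: pd.DataFrame

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "variables", tuple(self.variables))
        if v.shape != (len(self.sample_ids), len(self.variables)):
            raise ValidationError("sample matrix shape does not match labels")
        if np.any(v < 0):
            raise ValidationError("sample matrix values must be nonnegative")
        if list(self.factors.index) != list(self.sample_ids):
            raise ValidationError("factor table must be indexed by the sample ids, in order")
        if self.factors.isna().any().any():
            raise ValidationError("every sample needs a level for every factor")


@dataclass(frozen=True)
class PermanovaTerm:
    term: str
    df: int
    ss: float
    pseudo_f: float | None
    p_perm: float | None


@dataclass(frozen=True)
class PermanovaResult:
    terms: tuple[PermanovaTerm, ...]
    residual_df: int
    residual_ss: float
    total_df: int
    total_ss: float
    permutations: int
    seed: int

    def table(self) -> pd.DataFrame:
        rows = [(t.term, t.df, t.ss, t.pseudo_f, t.p_perm) for t in self.terms]
        rows.append(("Residual", self.residual_df, self.residual_ss, None, None))
        rows.append(("Total", self.total_df, self.total_ss, None, None))
        return pd.DataFrame(rows, columns=["term", "df", "SS", "pseudo_F", "p_perm"])


@dataclass(frozen=True)
class SimperResult:
    level_a: str
    level_b: str
    contributions: pd.Series          # per-variable, dissimilarity scale
    mean_values: pd.DataFrame         # variables x {level_a, level_b}
    average_dissimilarity: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "average_dissimilarity", float(self.contributions.sum()))

    def table(self) -> pd.DataFrame:
        order = self.contributions.sort_values(ascending=False)
        cum = 100.0 * order.cumsum() / order.sum() if order.sum() > 0 else order * 0.0
        return pd.DataFrame({
            "contribution": order,
            "cumulative_pct": cum,
            f"mean_{self.level_a}": self.mean_values[self.level_a].reindex(order.index),
            f"mean_{self.level_b}": self.mean_values[self.level_b].reindex(order.index),
        })


def sqrt_transform(values: np.ndarray) -> np.ndarray:
    """Elementwise square root; tempers dominance of abundant variables."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValidationError("square-root transform requires nonnegative values")
    return np.sqrt(values)


def zero_adjusted_bray_curtis(values: np.ndarray, dummy_value: float = 1.0) -> np.ndarray:
    """Pairwise zero-adjusted Bray-Curtis dissimilarities (percent scale).

    A constant ``dummy_value`` column is appended to every sample before
    the standard BC formula, making two all-zero samples identical
    (dissimilarity 0) rather than undefined.  ``dummy_value`` is on the
    (possibly transformed) scale of ``values``.
    """
    if dummy_value <= 0:
        raise ValidationError("dummy_value must be positive")
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValidationError("Bray-Curtis requires nonnegative values")
    x = np.column_stack([values, np.full(values.shape[0], float(dummy_value))])
    diff = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    tot = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    d = 100.0 * diff / tot
    np.fill_diagonal(d, 0.0)
    return d


def _gower_center(dist: np.ndarray) -> np.ndarray:
    n = dist.shape[0]
    a = -0.5 * dist ** 2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def _dummy_columns(levels: pd.Series) -> np.ndarray:
    """Treatment-coded indicator columns (first level dropped)."""
    cats = sorted(levels.unique())
    return np.column_stack([(levels == c).to_numpy(float) for c in cats[1:]]) \
        if len(cats) > 1 else np.empty((len(levels), 0))


def _term_design(factors: pd.DataFrame, term: str) -> np.ndarray:
    if ":" in term:
        f1, f2 = (t.strip() for t in term.split(":", 1))
        a, b = _dummy_columns(factors[f1]), _dummy_columns(factors[f2])
        return np.column_stack([a[:, i] * b[:, j]
                                for i in range(a.shape[1]) for j in range(b.shape[1])]) \
            if a.shape[1] and b.shape[1] else np.empty((len(factors), 0))
    if term not in factors.columns:
        raise ValidationError(f"unknown factor {term!r}")
    return _dummy_columns(factors[term])


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection onto col(x) plus its rank, via SVD (robust to aliasing)."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    keep = s > 1e-10 * s.max()
    u = u[:, keep]
    return u @ u.T, int(keep.sum())


def permanova(dist: np.ndarray, factors: pd.DataFrame, terms: Sequence[str],
              perms: int = 999, seed: int | None = None) -> PermanovaResult:
    """Distance-based multivariate ANOVA with sequential SS and permutation p.

    ``terms`` lists main effects (factor names) and interactions
    (``"a:b"``) in the order they should claim variance.  p-values come
    from ``perms`` unrestricted permutations of sample labels, add-one
    corrected.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or not np.allclose(dist, dist.T, atol=1e-8):
        raise ValidationError("distance matrix must be square and symmetric")
    if len(factors) != n:
        raise ValidationError("factor table length does not match distance matrix")
    if perms < 1:
        raise ValidationError("perms must be >= 1")
    if seed is None:
        raise ValidationError("a seed is required for permutation p-values")
    for t in terms:
        for f in (x.strip() for x in t.split(":")):
            if f not in factors.columns:
                raise ValidationError(f"unknown factor {f!r}")
            if factors[f].nunique() < 2:
                raise ValidationError(f"factor {f!r} has a single level")

    g = _gower_center(dist)
    total_ss = float(np.trace(g))

    # cumulative hat matrices: intercept, then each term in order
    hats = [np.full((n, n), 1.0 / n)]
    ranks = [1]
    design = np.ones((n, 1))
    for t in terms:
        cols = _term_design(factors, t)
        design = np.column_stack([design, cols])
        h, r = _hat(design)
        hats.append(h)
        ranks.append(r)
    dfs = np.diff(ranks)
    df_res = n - ranks[-1]
    if df_res < 1:
        raise ValidationError("more model terms than residual degrees of freedom")
    if np.any(dfs == 0):
        bad = [t for t, d in zip(terms, dfs) if d == 0]
        raise ValidationError(f"term(s) {bad} are aliased with earlier terms (zero df)")

    # difference projectors; residual projector last
    deltas = [hats[i + 1] - hats[i] for i in range(len(terms))]
    resid = np.eye(n) - hats[-1]

    def _partition(gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float(np.sum(d * gm)) for d in deltas])
        return ss, float(np.sum(resid * gm))

    ss_terms, ss_res = _partition(g)

    def _f(ss_t: np.ndarray, ss_r: float) -> np.ndarray:
        ms_res = ss_r / df_res
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_t / dfs) / ms_res
        # all-identical samples: 0/0 -> 0 by convention
        f = np.where(np.abs(ss_t) < 1e-12, 0.0, f)
        f = np.where((ms_res <= 1e-12) & (ss_t > 1e-12), np.inf, f)
        return f

    f_obs = _f(ss_terms, ss_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(perms):
        p = rng.permutation(n)
        gp = g[np.ix_(p, p)]
        ss_p, ss_rp = _partition(gp)
        exceed += _f(ss_p, ss_rp) >= f_obs - 1e-12
    p_perm = (exceed + 1.0) / (perms + 1.0)

    rows = tuple(
        PermanovaTerm(term=t, df=int(d), ss=float(s), pseudo_f=float(f), p_perm=float(p))
        for t, d, s, f, p in zip(terms, dfs, ss_terms, f_obs, p_perm)
    )
    return PermanovaResult(terms=rows, residual_df=int(df_res), residual_ss=float(ss_res),
                           total_df=n - 1, total_ss=total_ss,
                           permutations=int(perms), seed=int(seed))


def pairwise_permanova(dist: np.ndarray, factors: pd.DataFrame, factor: str,
                       level_pair: tuple[str, str], perms: int = 999,
                       seed: int | None = None) -> PermanovaResult:
    """One-factor PERMANOVA restricted to two levels of ``factor``;
    samples at other levels are ignored entirely."""
    a, b = level_pair
    mask = factors[factor].isin([a, b]).to_numpy()
    for lev in (a, b):
        if int((factors[factor] == lev).sum()) < 2:
            raise ValidationError(f"level {lev!r} of {factor!r} has fewer than 2 samples")
    sub = factors.loc[mask, [factor]].copy()
    d = np.asarray(dist, dtype=float)[np.ix_(mask, mask)]
    return permanova(d, sub, [factor], perms=perms, seed=seed)


def simper(values: np.ndarray, variables: Sequence[str], groups: Sequence[str],
           level_pair: tuple[str, str], dummy_value: float | None = 1.0) -> SimperResult:
    """Per-variable decomposition of average between-group BC dissimilarity.

    For every between-group sample pair the BC numerator share of each
    variable, 100*|x_k - y_k| / sum_l (x_l + y_l), is averaged; the
    contributions sum exactly to the mean between-group zero-adjusted BC
    dissimilarity.  ``values`` should already be on the transformed scale;
    ``dummy_value=None`` skips the zero adjustment.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    a, b = level_pair
    ia, ib = np.flatnonzero(groups == a), np.flatnonzero(groups == b)
    if ia.size == 0 or ib.size == 0:
        raise ValidationError(f"empty group among {level_pair}")
    variables = list(variables)
    if dummy_value is not None:
        if dummy_value <= 0:
            raise ValidationError("dummy_value must be positive")
        values = np.column_stack([values, np.full(values.shape[0], float(dummy_value))])
        variables = variables + [DUMMY_VARIABLE]
    xa, xb = values[ia], values[ib]                      # (na, k), (nb, k)
    diff = np.abs(xa[:, None, :] - xb[None, :, :])       # (na, nb, k)
    tot = (xa[:, None, :] + xb[None, :, :]).sum(axis=2)  # (na, nb)
    safe = np.where(tot == 0, np.inf, tot)               # all-zero pair, no dummy
    contrib = (100.0 * diff / safe[:, :, None]).mean(axis=(0, 1))
    means = pd.DataFrame({a: xa.mean(axis=0), b: xb.mean(axis=0)}, index=variables)
    return SimperResult(level_a=str(a), level_b=str(b),
                        contributions=pd.Series(contrib, index=variables),
                        mean_values=means)
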