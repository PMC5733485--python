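"""CIB composites, reliability statistics, and feature-rating correlations.

The Coding Interactive Behavior (CIB) system rates adult-infant
interactions on 1-5 Likert scales, averaged into composites (e.g. maternal
sensitivity, infant negativity); some constituent scales are reversed
(r -> 6 - r) before averaging, and composite membership differs by infant
age. Reliability is summarised with Cronbach's alpha (internal consistency
of a composite's scales) and ICC(2,1) (two-way random effects, absolute
agreement, single measures — inter-rater reliability). Features are related
to composites with two-tailed Spearman rank correlations, pairwise-complete
per cell, with no multiplicity adjustment by default (a Benjamini-Hochberg
option exists for responsible reuse).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class RatingStatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Composites
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CompositeDef:
    """One composite: its constituent scales and their orientation."""

    name: str
    scales: list[str]
    reversed_scales: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.reversed_scales = frozenset(self.reversed_scales)
        unknown = self.reversed_scales - set(self.scales)
        if unknown:
            raise RatingStatsError(
                f"composite {self.name!r}: reversed scales {sorted(unknown)} not in scale list"
            )


def parse_composite_map(raw: Mapping[str, Mapping[str, list]]) -> dict[str, list[CompositeDef]]:
    """Parse a composite map (e.g. loaded from YAML) into definitions per age group.

    Expected layout::

        age_group:
          Composite name:
            - Scale A
            - {scale: Scale B, reversed: true}
    """
    out: dict[str, list[CompositeDef]] = {}
    for age, comps in raw.items():
        defs = []
        for name, entries in comps.items():
            scales, rev = [], set()
            for e in entries:
                if isinstance(e, str):
                    scales.append(e)
                else:
                    scales.append(e["scale"])
                    if e.get("reversed"):
                        rev.add(e["scale"])
            defs.append(CompositeDef(name=name, scales=scales, reversed_scales=frozenset(rev)))
        out[age] = defs
    return out


def composite_scores(
    ratings: pd.DataFrame,
    composites: Sequence[CompositeDef],
    likert_max: int = 5,
) -> pd.DataFrame:
    """Average (orientation-adjusted) scales into composite scores per dyad.

    ``ratings`` has one row per dyad (index = dyad id) and one column per
    CIB scale, values on the 1-``likert_max`` scale. Reversed scales map
    ``r -> (likert_max + 1) - r`` before averaging. Single-scale composites
    pass through.
    """
    vals = ratings.to_numpy(dtype=float)
    if np.nanmin(vals) < 1 or np.nanmax(vals) > likert_max:
        raise RatingStatsError(f"ratings must lie on the 1-{likert_max} scale")
    out = {}
    for comp in composites:
        missing = [s for s in comp.scales if s not in ratings.columns]
        if missing:
            raise RatingStatsError(
                f"composite {comp.name!r}: missing scale(s) {missing}"
            )
        block = ratings[comp.scales].astype(float).copy()
        for s in comp.reversed_scales:
            block[s] = (likert_max + 1) - block[s]
        out[comp.name] = block.mean(axis=1)
    return pd.DataFrame(out, index=ratings.index)


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------

def cronbach_alpha(items: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha for an (observations x items) matrix.

    ``alpha = k/(k-1) * (1 - sum(item variances) / variance of item sums)``
    with sample (n-1) variances.
    """
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise RatingStatsError("cronbach_alpha needs >= 2 observations and >= 2 items")
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise RatingStatsError("cronbach_alpha undefined: zero total variance")
    item_vars = x.var(axis=0, ddof=1)
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def icc_2_1(
    ratings: np.ndarray | pd.DataFrame, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``ratings`` is a complete (targets x raters) table. From the two-way
    ANOVA mean squares (rows MSR, columns MSC, error MSE)::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    The confidence interval is the standard F-based interval for this model
    (McGraw & Wong). A degenerate table (no between-target variance) yields
    a coefficient <= 0, reported as is rather than clamped.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise RatingStatsError("icc_2_1 needs >= 2 targets and >= 2 raters")
    if not np.isfinite(x).all():
        raise RatingStatsError("icc_2_1 needs a complete two-way table")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise RatingStatsError("icc_2_1 undefined: degenerate all-constant table")
    icc = float((msr - mse) / denom)

    # McGraw & Wong F-based interval (as used for ICC(A,1)).
    alpha = 1.0 - confidence
    if mse == 0 and msc == 0:
        return icc, (icc, icc)
    a = k * icc / (n * (1.0 - icc)) if icc < 1 else math.inf
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1 else math.inf
    if math.isinf(a) or math.isinf(b):
        return icc, (icc, icc)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return icc, (float(lower), float(upper))


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def _rank_average(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "t",
) -> tuple[float, float]:
    """Spearman rank correlation with a two-tailed p-value.

    Ties receive average ranks; rho is the Pearson correlation of the
    ranks. ``method="t"`` uses the t-approximation with n-2 df (the default,
    appropriate at the study's sample sizes); ``method="exact"`` enumerates
    all permutations (only for n <= 9). Pairs with a missing value are
    dropped (pairwise-complete). A constant vector leaves rho undefined
    (NaN, NaN), as does n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise RatingStatsError("spearman expects two equal-length 1-D vectors")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    if method == "t":
        res = stats.spearmanr(x, y)
        rho = float(res.statistic)
        # perfectly concordant/discordant ranks are +-1 exactly; don't let
        # floating-point rounding in the rank-Pearson computation blur that
        rx, ry = _rank_average(x), _rank_average(y)
        if np.array_equal(rx, ry):
            rho = 1.0
        elif np.array_equal(rx, n + 1 - ry):
            rho = -1.0
        return rho, float(res.pvalue)
    if method != "exact":
        raise RatingStatsError(f"unknown method {method!r}; expected 't' or 'exact'")
    if n > 9:
        raise RatingStatsError("exact permutation p-value limited to n <= 9")
    rx, ry = _rank_average(x), _rank_average(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    rho = float(np.mean(rx * ry))
    perms = np.array(list(itertools.permutations(range(n))))
    rho_perm = (rx[perms] * ry).mean(axis=1)
    p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    return rho, p


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (NaNs propagate)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    q = p[ok]
    m = q.size
    order = np.argsort(q)
    ranked = q[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def correlation_table(
    features: pd.DataFrame,
    composites: pd.DataFrame,
    feature_names: Iterable[str] | None = None,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Spearman correlations of each (feature x body part) with each composite.

    ``features`` is the long-form feature table (``dyad_id``, ``body_part``,
    one column per feature); ``composites`` is indexed by dyad id with one
    column per composite. Each cell is computed pairwise-complete, reporting
    rho, the two-tailed p and the n actually used; cells with n < 3 are
    missing. Returns a long-form frame with columns
    ``feature, body_part, composite, rho, p, n`` (plus ``p_adj`` with
    ``bh_correction``).
    """
    from .features import FEATURE_NAMES

    feature_names = list(feature_names) if feature_names is not None else [
        f for f in FEATURE_NAMES if f in features.columns
    ]
    common = features["dyad_id"].isin(composites.index)
    if not common.any():
        logger.warning("correlation_table: no overlapping dyads between features and composites")
        return pd.DataFrame(columns=["feature", "body_part", "composite", "rho", "p", "n"])
    feats = features[common]
    rows = []
    for bp, chunk in feats.groupby("body_part", sort=False):
        comp_block = composites.reindex(chunk["dyad_id"])
        for fname in feature_names:
            fvals = chunk[fname].to_numpy(dtype=float)
            for cname in composites.columns:
                cvals = comp_block[cname].to_numpy(dtype=float)
                ok = np.isfinite(fvals) & np.isfinite(cvals)
                n = int(ok.sum())
                rho, p = spearman(fvals, cvals) if n >= 3 else (math.nan, math.nan)
                rows.append(
                    {"feature": fname, "body_part": bp, "composite": cname,
                     "rho": rho, "p": p, "n": n}
                )
                logger.debug("cell %s/%s/%s: n=%d", fname, bp, cname, n)
    table = pd.DataFrame(rows)
    if bh_correction and len(table):
        table["p_adj"] = benjamini_hochberg(table["p"].to_numpy())
    return table


def pivot_correlations(table: pd.DataFrame, value: str = "rho") -> pd.DataFrame:
    """Pivot the long-form correlation table into (feature x body part) rows."""
    return table.pivot_table(
        index=["feature", "body_part"], columns="composite", values=value, sort=False
    )
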