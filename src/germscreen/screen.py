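"""The three candidate filters (COR, CV, DAM) and their intersection.

A metabolite is a germination candidate when it passes all three of:

* **COR** — its replicate-mean content across the six informative time
  points (6–48 HAI) correlates with the germination rate (two-sided
  Pearson test; pass when p < α and \\|r\\| > r_min, defaults 0.05 / 0.8),
  in at least one variety;
* **CV** — its content fluctuates over germination: the coefficient of
  variation σ/μ of its per-time-point means exceeds 30% in at least one
  variety;
* **DAM** — it is differentially accumulated between the varieties at at
  least one tested time point: fold change of replicate means > 2 and a
  Benjamini–Hochberg-adjusted two-sample Student's t-test p < 0.05
  (adjustment applied within each time point across metabolites).

The COR p-value is the classical t transform: t = r·√(n−2)/√(1−r²) with
n−2 degrees of freedom, two-sided — the same test ``cor.test`` performs.

Missing policy: correlations are pairwise-complete; a metabolite is
dropped from a t-test at a time point when any replicate is missing in
either group.  Every exclusion is logged with a reason code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import DegenerateDataError, InputError, MetabolomeMatrix

__all__ = [
    "ScreeningResult",
    "pearson_r",
    "correlation_pvalue",
    "cor_screen",
    "cv",
    "cv_screen",
    "dam_screen",
    "intersect_screens",
    "DEFAULT_COR_TIMEPOINTS",
]

log = logging.getLogger(__name__)

#: time points used by the COR and DAM screens: germination is quiescent
#: before 6 HAI, so 0 and 3 HAI carry no trait signal.
DEFAULT_COR_TIMEPOINTS = (6, 9, 12, 24, 36, 48)


# ---------------------------------------------------------------------------
# correlation primitives
# ---------------------------------------------------------------------------


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length series.

    Pairwise-complete: entries missing in either series are dropped.
    Requires ≥ 3 complete pairs and non-constant series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("series lengths differ")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise DegenerateDataError("need ≥ 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant series: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via t = r·√(n−2)/√(1−r²), df = n−2.

    |r| = 1 is degenerate and returns exactly 0.
    """
    if n < 3:
        raise InputError("need n ≥ 3")
    if not -1.0 <= r <= 1.0:
        raise InputError(f"r = {r} outside [−1, 1]")
    if abs(r) == 1.0:
        log.info("degenerate |r| = 1: p reported as 0")
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def cor_screen(
    matrix: MetabolomeMatrix,
    phenotype: pd.DataFrame,
    variety=None,
    timepoints: Sequence[int] = DEFAULT_COR_TIMEPOINTS,
    alpha: float = 0.05,
    r_min: float = 0.8,
) -> pd.DataFrame:
    """Metabolite–germination-rate correlation edges for one or all varieties.

    For each metabolite and variety, Pearson r between the replicate-mean
    content and the replicate-mean germination fraction across
    ``timepoints`` (default 6–48 HAI, n = 6).  Returns one edge row per
    metabolite × variety with columns ``metabolite_id, variety, r, n,
    t_statistic, p, passes``; metabolites with a constant series are
    excluded with a logged reason.
    """
    varieties = [variety] if variety is not None else matrix.varieties
    timepoints = list(timepoints)
    rows = []
    for var in varieties:
        germ = (
            phenotype[phenotype["variety"] == var]
            .groupby("timepoint_hai")["germination_fraction"]
            .mean()
        )
        missing = [t for t in timepoints if t not in germ.index]
        if missing:
            raise InputError(
                f"phenotype lacks germination rate at {missing} HAI for {var!r}"
            )
        g = germ.loc[timepoints].to_numpy(dtype=float)
        means = matrix.timepoint_means(var)
        absent = [t for t in timepoints if t not in means.index]
        if absent:
            raise InputError(f"matrix lacks time points {absent} for {var!r}")
        sub = means.loc[timepoints]
        for met in sub.columns:
            x = sub[met].to_numpy(dtype=float)
            try:
                r = pearson_r(x, g)
            except DegenerateDataError as exc:
                log.info("COR excluded %s (%s): %s", met, var, exc)
                continue
            n = int((~np.isnan(x)).sum())
            p = correlation_pvalue(r, n)
            t_stat = (
                float(r * np.sqrt(n - 2) / np.sqrt(1 - r * r)) if abs(r) < 1 else np.inf
            )
            rows.append(
                {
                    "metabolite_id": met,
                    "variety": var,
                    "r": r,
                    "n": n,
                    "t_statistic": t_stat,
                    "p": p,
                    "passes": bool(p < alpha and abs(r) > r_min),
                }
            )
    return pd.DataFrame(
        rows, columns=["metabolite_id", "variety", "r", "n", "t_statistic", "p", "passes"]
    )


# ---------------------------------------------------------------------------
# coefficient of variation
# ---------------------------------------------------------------------------


def cv(values) -> float:
    """Coefficient of variation σ/μ (sample SD, n−1 denominator).

    Undefined for non-positive mean or fewer than two values.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        raise DegenerateDataError("need ≥ 2 values")
    mu = v.mean()
    if mu <= 0:
        raise DegenerateDataError(f"non-positive mean {mu}")
    return float(v.std(ddof=1) / mu)


def cv_screen(
    matrix: MetabolomeMatrix,
    variety,
    threshold: float = 0.30,
    basis: str = "means",
) -> tuple[set, pd.Series]:
    """Metabolites whose CV across the time course exceeds ``threshold``.

    ``basis="means"`` (default) computes the CV over the variety's
    per-time-point replicate means (8 values for the full design);
    ``basis="replicates"`` uses every replicate-level value instead.
    Returns ``(passing set, per-metabolite CV series)``; metabolites whose
    CV is undefined are excluded with a logged reason.
    """
    if basis == "means":
        data = matrix.timepoint_means(variety)
    elif basis == "replicates":
        mask = matrix.samples["variety"] == variety
        data = matrix.values.loc[mask.index[mask]]
    else:
        raise InputError(f"unknown CV basis {basis!r}")
    out = {}
    for met in data.columns:
        try:
            out[met] = cv(data[met].to_numpy(dtype=float))
        except DegenerateDataError as exc:
            log.info("CV excluded %s (%s): %s", met, variety, exc)
    series = pd.Series(out, name=f"cv[{variety}]")
    return set(series.index[series > threshold]), series


# ---------------------------------------------------------------------------
# differential accumulation
# ---------------------------------------------------------------------------


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def dam_screen(
    matrix: MetabolomeMatrix,
    timepoints: Sequence[int] = DEFAULT_COR_TIMEPOINTS,
    fc_min: float = 2.0,
    alpha: float = 0.05,
    varieties: Sequence | None = None,
    gate: str = "adjusted",
    equal_var: bool = True,
    pseudocount: float | None = None,
) -> tuple[pd.DataFrame, set]:
    """Differential accumulation between the two varieties per time point.

    At each tested time point and for each metabolite: a two-sided
    two-sample Student's t-test (equal variance by default; Welch via
    ``equal_var=False``) on the replicate values, and a fold change
    computed from the replicate means as larger/smaller (≥ 1 by
    construction) with a ``direction`` flag naming the higher variety.  A
    pseudo-count (default: half the smallest positive value in the matrix)
    guards zero means.  p-values are Benjamini–Hochberg adjusted within
    each time point across metabolites; a metabolite is significant there
    when fold change > ``fc_min`` and the gating p (adjusted by default,
    raw via ``gate="raw"``) is < ``alpha``.

    Degenerate cells: zero variance in both groups with equal means →
    p = 1; with unequal means → flagged ``degenerate`` and gated on fold
    change alone.  Returns ``(records DataFrame, union set over time
    points)``.
    """
    if varieties is None:
        varieties = matrix.varieties
    if len(varieties) != 2:
        raise InputError("DAM needs exactly two varieties")
    if gate not in ("adjusted", "raw"):
        raise InputError("gate must be 'adjusted' or 'raw'")
    va, vb = varieties
    positive = matrix.values.to_numpy(dtype=float)
    positive = positive[~np.isnan(positive) & (positive > 0)]
    eps = pseudocount if pseudocount is not None else (
        0.5 * positive.min() if positive.size else 0.0
    )

    groups = {
        (v, t): sids
        for (v, t), sids in matrix.replicate_groups()
    }
    records = []
    for t in timepoints:
        for v in (va, vb):
            if (v, t) not in groups or len(groups[(v, t)]) < 2:
                raise InputError(f"need ≥ 2 replicates for {v!r} at {t} HAI")
        a = matrix.values.loc[groups[(va, t)]].to_numpy(dtype=float)
        b = matrix.values.loc[groups[(vb, t)]].to_numpy(dtype=float)
        batch = []
        for j, met in enumerate(matrix.values.columns):
            x, y = a[:, j], b[:, j]
            if np.isnan(x).any() or np.isnan(y).any():
                log.info("DAM dropped %s at %s HAI: missing replicate", met, t)
                continue
            ma, mb = x.mean(), y.mean()
            hi, lo = (ma, mb) if ma >= mb else (mb, ma)
            fc = (hi + eps) / (lo + eps)
            direction = va if ma >= mb else vb
            degenerate = False
            if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
                if ma == mb:
                    p = 1.0
                else:
                    p = 0.0
                    degenerate = True
            else:
                p = float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)
            batch.append(
                {
                    "metabolite_id": met,
                    "timepoint_hai": t,
                    f"mean_{va}": ma,
                    f"mean_{vb}": mb,
                    "fold_change": fc,
                    "direction": direction,
                    "raw_p": p,
                    "degenerate": degenerate,
                }
            )
        if not batch:
            continue
        bdf = pd.DataFrame(batch)
        bdf["adjusted_p"] = _bh_adjust(bdf["raw_p"].to_numpy())
        gate_p = bdf["adjusted_p"] if gate == "adjusted" else bdf["raw_p"]
        bdf["significant"] = (bdf["fold_change"] > fc_min) & (
            (gate_p < alpha) | bdf["degenerate"]
        )
        records.append(bdf)
    out = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(
            columns=[
                "metabolite_id",
                "timepoint_hai",
                f"mean_{va}",
                f"mean_{vb}",
                "fold_change",
                "direction",
                "raw_p",
                "degenerate",
                "adjusted_p",
                "significant",
            ]
        )
    )
    dam_set = set(out.loc[out["significant"], "metabolite_id"])
    return out, dam_set


# ---------------------------------------------------------------------------
# intersection
# ---------------------------------------------------------------------------


@dataclass
class ScreeningResult:
    """The three per-method candidate sets and their intersection.

    Per-variety subsets are retained for COR and CV; the method-level set
    is their union across varieties by default (``mode="intersection"``
    combines varieties by intersection instead).  ``class_counts`` breaks
    the final candidate set down by compound class.
    """

    cor_by_variety: Mapping
    cv_by_variety: Mapping
    dam_set: set
    mode: str
    thresholds: dict = field(default_factory=dict)
    class_counts: pd.Series | None = None

    def _combine(self, sets) -> set:
        sets = list(sets)
        if not sets:
            return set()
        if self.mode == "union":
            return set().union(*sets)
        return set.intersection(*map(set, sets))

    @property
    def cor_set(self) -> set:
        return self._combine(self.cor_by_variety.values())

    @property
    def cv_set(self) -> set:
        return self._combine(self.cv_by_variety.values())

    @property
    def intersection_set(self) -> set:
        return self.cor_set & self.cv_set & self.dam_set


def intersect_screens(
    cor_edges: pd.DataFrame,
    cv_sets: Mapping,
    dam_set: set,
    annotations: pd.DataFrame | None = None,
    mode: str = "union",
    thresholds: dict | None = None,
) -> ScreeningResult:
    """Intersect the COR, CV and DAM screens into the candidate set.

    ``cor_edges`` is the edge table from :func:`cor_screen`; ``cv_sets``
    maps variety → passing set from :func:`cv_screen`.  All three screens
    must have been computed on the same metabolite universe.  Per-class
    counts come from ``annotations`` (metabolite-indexed, with a
    ``compound_class`` column) when given.
    """
    if mode not in ("union", "intersection"):
        raise InputError("mode must be 'union' or 'intersection'")
    cor_by_variety = {
        var: set(grp.loc[grp["passes"], "metabolite_id"])
        for var, grp in cor_edges.groupby("variety")
    } if len(cor_edges) else {}
    universe = None
    if annotations is not None:
        universe = set(annotations.index)
        for name, s in (("COR", set(cor_edges["metabolite_id"]) if len(cor_edges) else set()),
                        ("CV", set().union(*cv_sets.values()) if cv_sets else set()),
                        ("DAM", set(dam_set))):
            stray = s - universe
            if stray:
                raise InputError(
                    f"{name} set contains metabolites outside the annotated universe: "
                    f"{sorted(stray)[:3]}"
                )
    result = ScreeningResult(
        cor_by_variety=cor_by_variety,
        cv_by_variety=dict(cv_sets),
        dam_set=set(dam_set),
        mode=mode,
        thresholds=dict(thresholds or {}),
    )
    if annotations is not None:
        cand = sorted(result.intersection_set)
        result.class_counts = (
            annotations.loc[cand, "compound_class"].value_counts().sort_index()
        )
    return result
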