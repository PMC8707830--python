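"""Stage segmentation and genotype-lag estimation from metabolome profiles.

The metabolome of each variety × time point is summarised as the
replicate-mean profile over metabolites; Pearson correlation between
profiles yields the (2·T × 2·T) matrix behind the clustered heatmap view
of germination.  Germination is then segmented per variety into k
contiguous stages by an order-constrained agglomerative merge, and the
slow variety's developmental lag is read off by best-matching each of its
time-point profiles against the fast variety's.

Order-constrained segmentation (rather than free hierarchical clustering)
makes "Stage I/II/III" well-defined: stages are contiguous intervals of
time points by construction.  A free complete-linkage dendrogram can still
be produced for display via :func:`plot_correlation_heatmap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import InputError, MetabolomeMatrix

__all__ = [
    "StageSegmentation",
    "LagEstimate",
    "timepoint_profiles",
    "profile_correlation",
    "segment_stages",
    "estimate_lag",
    "plot_correlation_heatmap",
]


def timepoint_profiles(matrix: MetabolomeMatrix) -> pd.DataFrame:
    """One replicate-mean profile per variety × time point.

    Returns a DataFrame with one column per profile, labelled
    ``"{variety}@{timepoint}"``, indexed by metabolite.  Means are
    missing-aware; a cell where every replicate is missing is an error
    (QC should not leave empty cells).
    """
    cols = {}
    for (variety, tp), sids in matrix.replicate_groups():
        prof = matrix.values.loc[sids].mean(axis=0, skipna=True)
        if prof.isna().any():
            met = prof.index[prof.isna()][0]
            raise InputError(
                f"no replicate value at {variety} {tp} HAI for metabolite {met!r}"
            )
        cols[f"{variety}@{tp}"] = prof
    out = pd.DataFrame(cols)
    out.columns.name = "profile"
    return out


def profile_correlation(profiles: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix between profiles (unit diagonal).

    Pairwise-complete over metabolites; a constant profile has undefined
    correlations, reported as missing.
    """
    if profiles.shape[1] < 2:
        raise InputError("need at least two profiles")
    corr = profiles.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def _profile_key(variety, timepoint) -> str:
    return f"{variety}@{timepoint}"


@dataclass
class StageSegmentation:
    """k contiguous stages for one variety.

    ``stages`` is an ordered list of lists of time points covering the
    grid; ``boundaries`` holds the last time point of each stage except
    the final one (so k stages ⇒ k−1 boundaries).  ``linkage`` records
    the merge order (pairs of segment start-indices with their mean PCC).
    """

    variety: object
    stages: list
    correlation: pd.DataFrame
    linkage: list = field(default_factory=list)

    @property
    def boundaries(self) -> list:
        return [stage[-1] for stage in self.stages[:-1]]


def segment_stages(
    corr: pd.DataFrame, variety, k: int = 3, timepoints=None
) -> StageSegmentation:
    """Order-constrained agglomerative segmentation of one variety's time course.

    Starting from one segment per time point, repeatedly merge the
    adjacent pair of segments with the highest between-segment mean PCC
    until ``k`` segments remain.  Ties break toward the earlier boundary.
    """
    if k < 1:
        raise InputError("k must be ≥ 1")
    if timepoints is None:
        timepoints = sorted(
            int(c.split("@")[1]) for c in corr.columns if str(c).startswith(f"{variety}@")
        )
    if not timepoints:
        raise InputError(f"no profiles for variety {variety!r}")
    if k > len(timepoints):
        raise InputError("k must be ≤ number of time points")
    keys = [_profile_key(variety, t) for t in timepoints]
    sub = corr.loc[keys, keys].to_numpy(dtype=float)

    segments = [[i] for i in range(len(timepoints))]
    linkage = []
    while len(segments) > k:
        best_j, best_score = None, -np.inf
        for j in range(len(segments) - 1):
            block = sub[np.ix_(segments[j], segments[j + 1])]
            score = float(np.nanmean(block))
            if score > best_score + 1e-12:  # strict: ties keep the earlier pair
                best_j, best_score = j, score
        linkage.append((segments[best_j][0], segments[best_j + 1][0], best_score))
        segments[best_j : best_j + 2] = [segments[best_j] + segments[best_j + 1]]
    stages = [[timepoints[i] for i in seg] for seg in segments]
    return StageSegmentation(
        variety=variety,
        stages=stages,
        correlation=corr.loc[keys, keys],
        linkage=linkage,
    )


@dataclass
class LagEstimate:
    """Per-time-point lag of the slow variety behind the fast one.

    ``table`` columns: slow time point, best-matching fast time point, its
    PCC, lag in hours, and whether the match is censored (the best match
    sits on an end of the fast grid, so the true lag may exceed the
    observable range).  ``median_lag`` is the median over uncensored time
    points, falling back to all time points when every match is censored.
    """

    table: pd.DataFrame
    fast_variety: object
    slow_variety: object

    @property
    def median_lag(self) -> float:
        usable = self.table.loc[~self.table["censored"], "lag_hours"]
        if usable.empty:
            usable = self.table["lag_hours"]
        return float(np.median(usable))

    def stage_median(self, stages) -> dict:
        """Median lag per stage, given a stage list for the slow variety."""
        out = {}
        for i, stage in enumerate(stages, start=1):
            sel = self.table["timepoint_hai"].isin(stage)
            out[i] = float(np.median(self.table.loc[sel, "lag_hours"]))
        return out


def estimate_lag(
    corr: pd.DataFrame, fast_variety="fast", slow_variety="slow"
) -> LagEstimate:
    """Lag of the slow variety read from best-matching time-point profiles.

    For each slow time point t, lag(t) = t − argmaxₛ PCC(fast_s, slow_t);
    ties pick the smaller fast time point.
    """
    fast_tps = sorted(
        int(c.split("@")[1]) for c in corr.columns if str(c).startswith(f"{fast_variety}@")
    )
    slow_tps = sorted(
        int(c.split("@")[1]) for c in corr.columns if str(c).startswith(f"{slow_variety}@")
    )
    if not fast_tps or not slow_tps:
        raise InputError("both varieties must be present in the correlation matrix")
    rows = []
    for t in slow_tps:
        col = corr.loc[[_profile_key(fast_variety, s) for s in fast_tps],
                       _profile_key(slow_variety, t)]
        vals = col.to_numpy(dtype=float)
        best = int(np.nanargmax(vals))  # argmax; earlier ties win via argmax order
        s_best = fast_tps[best]
        rows.append(
            {
                "timepoint_hai": t,
                "matched_fast_timepoint": s_best,
                "pcc": float(vals[best]),
                "lag_hours": float(t - s_best),
                "censored": s_best in (fast_tps[0], fast_tps[-1]),
            }
        )
    return LagEstimate(
        table=pd.DataFrame(rows), fast_variety=fast_variety, slow_variety=slow_variety
    )


def plot_correlation_heatmap(corr: pd.DataFrame, path) -> None:
    """Clustered heatmap of the profile-correlation matrix (display only)."""
    import matplotlib

    matplotlib.use("Agg")
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform
    import matplotlib.pyplot as plt

    dist = squareform(np.clip(1.0 - corr.to_numpy(dtype=float), 0.0, None), checks=False)
    order = hierarchy.leaves_list(hierarchy.complete(dist))
    ordered = corr.iloc[order, order]
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(ordered.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(ordered)), ordered.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(ordered)), ordered.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
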