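"""Z-score trajectory standardization and accumulation/consumption labels.

Each candidate metabolite's per-time-point means (one 8-point row per
variety) are standardized to a z profile and classified by a reproducible
rule: Spearman rank correlation ρ of the profile against time calls the
monotone patterns (ρ ≥ +0.6 accumulation, ρ ≤ −0.6 consumption); a
non-monotone profile with a sufficiently prominent interior extremum is
called accumulation-then-consumption (interior maximum) or
consumption-then-accumulation (interior minimum); anything else is flat.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import InputError, MetabolomeMatrix

__all__ = [
    "zscore_profile",
    "classify_trajectory",
    "trajectory_patterns",
    "patterns_long_format",
    "LABELS",
]

LABELS = (
    "accumulation",
    "consumption",
    "accumulation-then-consumption",
    "consumption-then-accumulation",
    "flat",
)

#: raw relative variation below which a profile is called flat outright.
#: Rank statistics are scale-free, so arbitrarily small replicate noise on
#: a constant trajectory would otherwise be read as a trend.
DEFAULT_FLAT_CV = 0.05


def zscore_profile(means) -> np.ndarray:
    """Standardize per-time-point means: (x − mean)/SD with sample SD.

    A constant input returns all zeros (the flat profile).
    """
    x = np.asarray(means, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def classify_trajectory(
    z_profile,
    timepoints,
    rho_threshold: float = 0.6,
    prominence: float = 1.0,
) -> str:
    """Label a z profile as one of :data:`LABELS`.

    Monotone trend via Spearman ρ against time; otherwise an interior
    maximum whose height clears both endpoints by ``prominence`` z-units
    is accumulation-then-consumption (symmetrically for an interior
    minimum); otherwise flat.
    """
    z = np.asarray(z_profile, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if z.shape != t.shape:
        raise InputError("profile and timepoints lengths differ")
    if np.allclose(z, 0.0):
        return "flat"
    rho = stats.spearmanr(t, z).statistic
    if rho >= rho_threshold:
        return "accumulation"
    if rho <= -rho_threshold:
        return "consumption"
    imax = int(np.argmax(z))
    imin = int(np.argmin(z))
    peak_prom = z[imax] - max(z[0], z[-1]) if 0 < imax < len(z) - 1 else -np.inf
    dip_prom = min(z[0], z[-1]) - z[imin] if 0 < imin < len(z) - 1 else -np.inf
    if peak_prom >= prominence and peak_prom >= dip_prom:
        return "accumulation-then-consumption"
    if dip_prom >= prominence:
        return "consumption-then-accumulation"
    return "flat"


def trajectory_patterns(
    matrix: MetabolomeMatrix,
    metabolites=None,
    basis: str = "per_variety",
    rho_threshold: float = 0.6,
    prominence: float = 1.0,
    flat_cv: float = DEFAULT_FLAT_CV,
) -> pd.DataFrame:
    """Z profiles and pattern labels per metabolite × variety.

    ``basis="per_variety"`` standardizes each variety's time-point means
    separately (the default: one 8-point row per variety);
    ``basis="pooled"`` standardizes over both varieties' concatenated
    means.  Profiles whose raw means vary by less than ``flat_cv``
    (CV of the means) are labelled flat without consulting the rank rule.

    Returns a tidy DataFrame with columns ``metabolite_id, variety,
    label, trend_rho`` plus one ``z@{t}`` column per time point.
    """
    if basis not in ("per_variety", "pooled"):
        raise InputError(f"unknown z-score basis {basis!r}")
    mets = list(metabolites) if metabolites is not None else list(matrix.metabolites.index)
    unknown = [m for m in mets if m not in matrix.values.columns]
    if unknown:
        raise InputError(f"unknown metabolites: {unknown[:3]}")
    means = {v: matrix.timepoint_means(v) for v in matrix.varieties}
    rows = []
    for met in mets:
        pooled_vals = np.concatenate(
            [means[v][met].to_numpy(dtype=float) for v in matrix.varieties]
        )
        pooled_mu, pooled_sd = pooled_vals.mean(), pooled_vals.std(ddof=1)
        for v in matrix.varieties:
            series = means[v][met]
            tps = series.index.to_numpy(dtype=float)
            raw = series.to_numpy(dtype=float)
            if basis == "per_variety":
                z = zscore_profile(raw)
            else:
                z = (raw - pooled_mu) / pooled_sd if pooled_sd > 0 else np.zeros_like(raw)
            mu = raw.mean()
            raw_cv = raw.std(ddof=1) / mu if mu > 0 else np.inf
            if raw_cv < flat_cv:
                label, rho = "flat", 0.0
            else:
                label = classify_trajectory(z, tps, rho_threshold, prominence)
                rho = float(stats.spearmanr(tps, z).statistic) if np.ptp(z) > 0 else 0.0
            row = {"metabolite_id": met, "variety": v, "label": label, "trend_rho": rho}
            row.update({f"z@{int(t)}": float(zz) for t, zz in zip(tps, z)})
            rows.append(row)
    if not rows:
        zcols = [f"z@{int(t)}" for t in matrix.timepoints]
        return pd.DataFrame(
            columns=["metabolite_id", "variety", "label", "trend_rho"] + zcols
        )
    return pd.DataFrame(rows)


def patterns_long_format(patterns: pd.DataFrame) -> pd.DataFrame:
    """Heatmap-ready long format: metabolite × variety × time point × z."""
    zcols = [c for c in patterns.columns if c.startswith("z@")]
    long = patterns.melt(
        id_vars=["metabolite_id", "variety", "label"],
        value_vars=zcols,
        var_name="timepoint_hai",
        value_name="z",
    )
    long["timepoint_hai"] = long["timepoint_hai"].str.removeprefix("z@").astype(int)
    return long.sort_values(["metabolite_id", "variety", "timepoint_hai"]).reset_index(
        drop=True
    )
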