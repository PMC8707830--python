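"""Germination physiology: water uptake, variety and treatment comparisons.

Water absorption rate follows the gravimetric definition
A_r = (W_a − W_b)/W_b × 100 with W_a the fresh (imbibed) and W_b the dry
seed weight, so A_r is invariant to the weight unit.  Germination rates
are stored as fractions in [0, 1] and rendered as percentages in reports.
Between-variety and treatment-vs-control comparisons use two-sided
Student's t-tests on per-dish replicate fractions, with the conventional
star coding (* p<0.05, ** p<0.01, *** p<0.001, NS otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import InputError

__all__ = [
    "water_absorption_rate",
    "significance_stars",
    "compare_varieties",
    "treatment_response",
    "VarietyComparison",
]

import warnings


def water_absorption_rate(w_a, w_b):
    """A_r = (W_a − W_b)/W_b × 100 (% of dry weight).

    Vectorized; requires W_b > 0.  A fresh weight below the dry weight
    yields a negative rate with a warning (physically suspect but kept,
    since it can arise from weighing noise).
    """
    w_a = np.asarray(w_a, dtype=float)
    w_b = np.asarray(w_b, dtype=float)
    if (w_b <= 0).any():
        raise InputError("dry weight W_b must be > 0")
    if (w_a < w_b).any():
        warnings.warn("fresh weight below dry weight: negative A_r", stacklevel=2)
    out = (w_a - w_b) / w_b * 100.0
    return float(out) if out.ndim == 0 else out


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass
class VarietyComparison:
    variety_a: object
    variety_b: object
    timepoint_hai: int
    mean_a: float
    mean_b: float
    t_statistic: float
    p: float
    stars: str


def _replicate_values(phenotype, variety, timepoint, column, treatment=None):
    sel = (phenotype["variety"] == variety) & (phenotype["timepoint_hai"] == timepoint)
    if treatment is not None and "treatment" in phenotype.columns:
        sel &= phenotype["treatment"] == treatment
    vals = phenotype.loc[sel, column].dropna().to_numpy(dtype=float)
    return vals


def compare_varieties(
    phenotype: pd.DataFrame,
    variety_a,
    variety_b,
    timepoint: int,
    column: str = "germination_fraction",
) -> VarietyComparison:
    """Two-sided Student's t-test between varieties at one time point."""
    a = _replicate_values(phenotype, variety_a, timepoint, column)
    b = _replicate_values(phenotype, variety_b, timepoint, column)
    if len(a) < 2 or len(b) < 2:
        raise InputError(
            f"need ≥ 2 replicates per variety at {timepoint} HAI "
            f"(got {len(a)} and {len(b)})"
        )
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
        t, p = float(res.statistic), float(res.pvalue)
    return VarietyComparison(
        variety_a=variety_a,
        variety_b=variety_b,
        timepoint_hai=int(timepoint),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_statistic=t,
        p=p,
        stars=significance_stars(p),
    )


def treatment_response(
    phenotype: pd.DataFrame,
    control: str = "CK",
    timepoints=None,
    varieties=None,
) -> pd.DataFrame:
    """Treatment-vs-control germination comparison per concentration × time point.

    ``phenotype`` must carry a ``treatment`` column whose levels are the
    control label plus dose labels (any concentration grid is accepted
    and echoed as given).  Returns one row per variety × treatment × time
    point with the mean treated/control rates, Student's t, p, and stars.
    """
    if "treatment" not in phenotype.columns:
        raise InputError("phenotype table has no treatment column")
    levels = phenotype["treatment"].unique().tolist()
    if control not in levels:
        raise InputError(f"control series {control!r} missing from treatment column")
    doses = [lvl for lvl in levels if lvl != control]
    if varieties is None:
        varieties = sorted(phenotype["variety"].unique().tolist())
    if timepoints is None:
        timepoints = sorted(phenotype["timepoint_hai"].unique().tolist())
    rows = []
    for var in varieties:
        for dose in doses:
            for t in timepoints:
                treated = _replicate_values(
                    phenotype, var, t, "germination_fraction", treatment=dose
                )
                ctrl = _replicate_values(
                    phenotype, var, t, "germination_fraction", treatment=control
                )
                if len(treated) < 2 or len(ctrl) < 2:
                    raise InputError(
                        f"need ≥ 2 replicates for {var!r} {dose!r} and control at {t} HAI"
                    )
                if treated.std(ddof=1) == 0 and ctrl.std(ddof=1) == 0:
                    tt, p = (0.0, 1.0) if treated.mean() == ctrl.mean() else (np.inf, 0.0)
                else:
                    res = stats.ttest_ind(treated, ctrl, equal_var=True)
                    tt, p = float(res.statistic), float(res.pvalue)
                rows.append(
                    {
                        "variety": var,
                        "treatment": dose,
                        "timepoint_hai": int(t),
                        "mean_treated": float(treated.mean()),
                        "mean_control": float(ctrl.mean()),
                        "difference": float(treated.mean() - ctrl.mean()),
                        "t_statistic": tt,
                        "p": p,
                        "stars": significance_stars(p),
                    }
                )
    return pd.DataFrame(rows)
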