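"""Replicate-concordance quality control.

A replicate whose metabolite vector correlates poorly with its sibling
replicates at the same variety × time point is flagged (default: mean
Pearson r to siblings < 0.9) and can optionally be dropped before any
downstream statistics.  Removal is opt-in; the default behaviour is to
report only, because silent data removal is hazardous.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import InputError, MetabolomeMatrix

__all__ = ["ReplicateQCReport", "replicate_concordance", "drop_flagged"]

log = logging.getLogger(__name__)

DEFAULT_QC_THRESHOLD = 0.9


@dataclass
class ReplicateQCReport:
    """Per-sample sibling concordance with flags.

    ``table`` columns: variety, timepoint_hai, replicate, mean_sibling_pcc,
    n_siblings, flagged, exempt.  ``removed`` lists samples actually
    dropped (⊆ flagged), filled in by :func:`drop_flagged`.
    """

    table: pd.DataFrame
    threshold: float
    removed: list = field(default_factory=list)

    @property
    def flagged(self) -> list:
        return self.table.index[self.table["flagged"]].tolist()


def _pairwise_pcc(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        return np.nan
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def replicate_concordance(
    matrix: MetabolomeMatrix, threshold: float = DEFAULT_QC_THRESHOLD
) -> ReplicateQCReport:
    """Mean Pearson correlation of each replicate against its siblings.

    A sample is flagged when its mean sibling PCC falls below
    ``threshold``.  One discordant replicate also depresses its siblings'
    mean PCC, so flagging is worst-first: the lowest-concordance replicate
    in a cell is flagged, concordance is recomputed among the remainder,
    and the step repeats while any replicate stays below threshold (a pair
    that survives is never split further — two mutually discordant
    replicates leave no way to tell which one is wrong, so the worse one
    is flagged and the last is kept).  The reported ``mean_sibling_pcc``
    is the initial all-sibling mean.  A variety × time point with a
    single replicate is exempt (warned, never flagged).
    """
    rows = {}
    for (variety, tp), sids in matrix.replicate_groups():
        if len(sids) < 2:
            warnings.warn(
                f"single replicate at {variety} {tp} HAI: exempt from QC", stacklevel=2
            )
        vals = matrix.values.loc[sids].to_numpy(dtype=float)
        pcc = np.full((len(sids), len(sids)), np.nan)
        for i in range(len(sids)):
            for j in range(i + 1, len(sids)):
                pcc[i, j] = pcc[j, i] = _pairwise_pcc(vals[i], vals[j])

        def mean_sib(i, active):
            sib = [pcc[i, j] for j in active if j != i and not np.isnan(pcc[i, j])]
            return float(np.mean(sib)) if sib else np.nan

        active = list(range(len(sids)))
        flagged_idx = set()
        while len(active) > 1:
            scores = {i: mean_sib(i, active) for i in active}
            low = [i for i in active if scores[i] < threshold]
            if not low:
                break
            worst = min(low, key=lambda i: (scores[i], i))
            flagged_idx.add(worst)
            active.remove(worst)

        for i, sid in enumerate(sids):
            exempt = len(sids) < 2
            rows[sid] = {
                "variety": variety,
                "timepoint_hai": tp,
                "replicate": matrix.samples.loc[sid, "replicate"],
                "mean_sibling_pcc": mean_sib(i, range(len(sids))),
                "n_siblings": len(sids) - 1,
                "exempt": exempt,
                "flagged": (not exempt) and (i in flagged_idx),
            }
    table = pd.DataFrame.from_dict(rows, orient="index").loc[matrix.samples.index]
    table.index.name = "sample_id"
    return ReplicateQCReport(table=table, threshold=threshold)


def drop_flagged(matrix: MetabolomeMatrix, report: ReplicateQCReport) -> MetabolomeMatrix:
    """Return the matrix without flagged samples, logging each removal.

    Errors if the report does not match the matrix or if removal would
    leave a variety × time point with no replicate at all.
    """
    if set(report.table.index) != set(matrix.samples.index):
        raise InputError("QC report does not match the matrix it is applied to")
    flagged = set(report.flagged)
    if not flagged:
        return matrix
    keep = [s for s in matrix.samples.index if s not in flagged]
    remaining = matrix.samples.loc[keep].groupby(["variety", "timepoint_hai"]).size()
    emptied = set(matrix.samples.groupby(["variety", "timepoint_hai"]).size().index) - set(
        remaining.index
    )
    if emptied:
        raise InputError(
            f"dropping flagged replicates would leave no replicate at {sorted(emptied)}"
        )
    for sid in sorted(flagged):
        row = report.table.loc[sid]
        log.info(
            "QC removed %s (mean sibling PCC %.3f < %.3f)",
            sid,
            row["mean_sibling_pcc"],
            report.threshold,
        )
    report.removed = sorted(flagged)
    return matrix.subset_samples(keep)
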