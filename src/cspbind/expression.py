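"""Relative gene expression by the comparative-Ct (2^-ddCt) method.

A target gene's threshold cycles are normalized to a reference
(housekeeping) gene within each sample, then to a calibrator sample:

    dCt  = mean Ct(target) - mean Ct(reference)        per sample
    ddCt = dCt(sample) - dCt(calibrator)
    fold = 2 ** -ddCt

Replicate Ct values are averaged before differencing; the calibrator's
fold change is 1 by construction.  Uncertainty is propagated from the
replicate Ct variance: sd(dCt) = sqrt(sd_target^2 + sd_reference^2),
and the fold range is [2^-(ddCt+sd), 2^-(ddCt-sd)].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "CtRecord",
    "RelativeExpression",
    "ddct_fold_change",
    "summarize_replicates",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class CtRecord:
    """One replicate threshold-cycle measurement."""

    sample_id: str
    gene_id: str
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.ct):
            raise ValueError(f"Ct must be finite, got {self.ct}")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")


@dataclass(frozen=True)
class RelativeExpression:
    """Fold change of a target gene in one sample, relative to the calibrator."""

    sample_id: str
    gene_id: str
    fold_change: float
    sd: float           # delta-method sd of the fold change
    ddct: float
    fold_lo: float      # 2^-(ddCt + sd_dCt)
    fold_hi: float      # 2^-(ddCt - sd_dCt)


def _collect(table: Sequence[CtRecord]) -> Dict[str, Dict[str, List[float]]]:
    by_sample: Dict[str, Dict[str, List[float]]] = {}
    for rec in table:
        by_sample.setdefault(rec.sample_id, {}).setdefault(rec.gene_id, []).append(rec.ct)
    return by_sample


def ddct_fold_change(table: Sequence[CtRecord], target_gene: str,
                     reference_gene: str,
                     calibrator_sample: str) -> List[RelativeExpression]:
    """Compute 2^-ddCt fold changes for every sample in a Ct table.

    Every sample must carry replicates of both the target and the
    reference gene; the calibrator sample must be present.  Samples are
    returned in first-appearance order, the calibrator with fold change
    exactly 1.
    """
    by_sample = _collect(table)
    if calibrator_sample not in by_sample:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in table")
    for sample, genes in by_sample.items():
        for gene in (target_gene, reference_gene):
            if gene not in genes:
                raise ValueError(f"sample {sample!r} is missing gene {gene!r}")

    def dct_and_sd(sample: str) -> tuple[float, float]:
        t = np.asarray(by_sample[sample][target_gene], dtype=float)
        r = np.asarray(by_sample[sample][reference_gene], dtype=float)
        sd_t = float(t.std(ddof=1)) if len(t) > 1 else 0.0
        sd_r = float(r.std(ddof=1)) if len(r) > 1 else 0.0
        return float(t.mean() - r.mean()), math.hypot(sd_t, sd_r)

    dct_cal, _ = dct_and_sd(calibrator_sample)
    results: List[RelativeExpression] = []
    for sample in by_sample:
        dct, sd_dct = dct_and_sd(sample)
        ddct = dct - dct_cal
        fold = 2.0 ** (-ddct)
        results.append(RelativeExpression(
            sample_id=sample, gene_id=target_gene, fold_change=fold,
            sd=fold * _LN2 * sd_dct, ddct=ddct,
            fold_lo=2.0 ** (-(ddct + sd_dct)),
            fold_hi=2.0 ** (-(ddct - sd_dct))))
    return results


Grouping = Union[None, Mapping[str, str], Callable[[RelativeExpression], str]]


def summarize_replicates(results: Sequence[RelativeExpression],
                         grouping: Grouping = None) -> pd.DataFrame:
    """Per-group mean, sample sd and n of fold changes.

    ``grouping`` maps each result to a group label: a dict keyed by
    sample_id, a callable, or None (each sample its own group).  Groups
    named by a mapping but matching no result are omitted with a warning.
    """
    def label(r: RelativeExpression) -> str:
        if grouping is None:
            return r.sample_id
        if callable(grouping):
            return grouping(r)
        return grouping[r.sample_id]

    folds: Dict[str, List[float]] = {}
    for r in results:
        folds.setdefault(label(r), []).append(r.fold_change)

    if isinstance(grouping, Mapping):
        for group in dict.fromkeys(grouping.values()):
            if group not in folds:
                warnings.warn(f"group {group!r} has no results; omitted")

    rows = []
    for group, values in folds.items():
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        rows.append({"group": group, "mean": float(arr.mean()),
                     "sd": sd, "n": len(arr)})
    return pd.DataFrame(rows, columns=["group", "mean", "sd", "n"])
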