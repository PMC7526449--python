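"""Ranking regulators by correlation of activity with skin severity.

Within one intrinsic subset, each regulator's activity is correlated
(Pearson) with the modified Rodnan skin score (MRSS) over the subset's
samples; per-cohort correlations are aggregated (mean by default, median
optionally) and ranked in decreasing order. The top and bottom k (default
50 each) are flagged as the clinically relevant regulators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ActivityMatrix, ClinicalTable


class CorrelationError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationRanking:
    table: pd.DataFrame  # index regulator; per-dataset PCC, aggregate, rank, flag

    def flagged(self, flag: str) -> list[str]:
        return list(self.table.index[self.table["flag"] == flag])


def correlate_mrss(
    am: ActivityMatrix,
    ct: ClinicalTable,
    subset: str,
    collapse_patients: bool = False,
) -> dict[str, float]:
    """Pearson correlation of each regulator's activity with MRSS.

    Restricted to samples of the given intrinsic subset with a known MRSS.
    With ``collapse_patients`` each patient contributes one observation
    (mean activity, first recorded MRSS); by default every biopsy sample is
    an independent observation.
    """
    samples = [
        s
        for s in ct.subset_samples(subset)
        if s in am.samples and pd.notna(ct.data.loc[s, "mrss"])
    ]
    if len(samples) < 3:
        raise CorrelationError(
            f"subset {subset!r}: need >=3 samples with MRSS, got {len(samples)}"
        )
    activity = am.scores[samples]
    mrss = ct.data.loc[samples, "mrss"].astype(float)
    if collapse_patients:
        patients = ct.data.loc[samples, "patient_id"]
        activity = activity.T.groupby(patients.to_numpy()).mean().T
        mrss = mrss.groupby(patients.to_numpy()).first()
        activity = activity[mrss.index]
        if activity.shape[1] < 3:
            raise CorrelationError("fewer than 3 patients after collapsing")
    y = mrss.to_numpy(dtype=float)
    if np.std(y) == 0.0:
        raise CorrelationError(f"subset {subset!r}: MRSS has zero variance")
    x = activity.to_numpy(dtype=float)
    xs = x.std(axis=1)
    flat = xs == 0.0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} regulator(s) with zero activity variance "
            f"excluded from correlation in subset {subset!r}",
            stacklevel=2,
        )
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = (xc @ yc) / (np.sqrt((xc**2).sum(axis=1)) * np.sqrt((yc**2).sum()))
    return {
        str(reg): float(pcc[i])
        for i, reg in enumerate(activity.index)
        if not flat[i]
    }


def aggregate_rank(
    tables: dict[str, dict[str, float]] | list[dict[str, float]],
    method: str = "mean",
    k: int = 50,
) -> CorrelationRanking:
    """Aggregate per-cohort correlations and flag the top/bottom k.

    The aggregate (mean or median) is taken over the cohorts in which a
    regulator was scored; regulators are ranked in decreasing aggregate with
    name tie-breaks, and the k highest / k lowest are flagged ``top50`` /
    ``bottom50``.
    """
    if method not in ("mean", "median"):
        raise CorrelationError(f"unknown aggregation method {method!r}")
    if isinstance(tables, list):
        tables = {f"dataset_{i}": t for i, t in enumerate(tables)}
    if not tables:
        raise CorrelationError("no correlation tables supplied")
    df = pd.DataFrame(tables)
    df = df.dropna(how="all")
    if 2 * k > df.shape[0]:
        raise CorrelationError(
            f"k={k} too large for {df.shape[0]} regulators (need k <= n/2)"
        )
    agg = df.mean(axis=1) if method == "mean" else df.median(axis=1)
    out = df.copy()
    out["aggregate"] = agg
    # deterministic: decreasing aggregate, ties broken by regulator name
    out = out.iloc[
        np.lexsort((out.index.to_numpy(), -out["aggregate"].to_numpy()))
    ]
    out["rank"] = np.arange(1, len(out) + 1)
    flags = np.array(["none"] * len(out), dtype=object)
    flags[:k] = "top50"
    flags[-k:] = "bottom50"
    out["flag"] = flags
    out.index.name = "regulator"
    return CorrelationRanking(table=out)
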