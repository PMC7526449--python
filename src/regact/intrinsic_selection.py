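"""Selection of "intrinsic" regulators and activity clustering.

A regulator is intrinsic when its activity is consistent within each
gene-expression-defined patient subset but variable across subsets. The
within-between (WB) score quantifies this as the ratio of within-group to
between-group sum of squares of the activity vector: low WB marks a
regulator whose activity tracks the subset structure.

Significance comes from a permutation null: subset labels are shuffled
jointly for all regulators and the WB scores recomputed; the plug-in FDR at
a regulator's WB value is the average null count at or below that value
divided by the observed count, capped at 1 and made monotone in WB.
Regulators passing a strict FDR cutoff in enough independent cohorts are
the selected intrinsic regulators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .io_formats import ActivityMatrix


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class WBResult:
    regulator: str
    wb_score: float  # SSW/SSB, +inf when between-group variance is 0
    fdr: float
    dataset: str = ""


def _group_matrix(labels: np.ndarray) -> list[np.ndarray]:
    groups = [np.flatnonzero(labels == g) for g in np.unique(labels)]
    if len(groups) < 2:
        raise SelectionError("within-between score needs >=2 groups")
    for g in groups:
        if g.size < 2:
            raise SelectionError("every group needs >=2 samples")
    return groups


def _wb_scores(matrix: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized SSW/SSB over the rows of a (regulators x samples) matrix."""
    groups = _group_matrix(labels)
    grand = matrix.mean(axis=1)
    ssw = np.zeros(matrix.shape[0])
    ssb = np.zeros(matrix.shape[0])
    for idx in groups:
        sub = matrix[:, idx]
        mean_g = sub.mean(axis=1)
        ssw += ((sub - mean_g[:, None]) ** 2).sum(axis=1)
        ssb += idx.size * (mean_g - grand) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        wb = ssw / ssb
    wb[ssb == 0.0] = np.inf
    # 0/0 (constant vector): no between-group signal either -> sentinel
    wb[np.isnan(wb)] = np.inf
    return wb


def within_between_score(scores, labels) -> float:
    """SSW/SSB of one activity vector; lower = more intrinsic.

    Returns +inf when the between-group variance is zero (no subset signal
    to speak of).
    """
    x = np.asarray(scores, dtype=float)[None, :]
    return float(_wb_scores(x, np.asarray(labels))[0])


def intrinsic_fdr(
    am: ActivityMatrix,
    labels,
    n_perm: int = 1000,
    seed: int = 0,
    dataset: str = "",
) -> list[WBResult]:
    """Permutation FDR for the within-between score of every regulator.

    Labels are permuted jointly across regulators each iteration, preserving
    inter-regulator correlation. FDR(r) = E_perm[#null WB <= WB_r] /
    #observed WB <= WB_r, capped at 1, then made monotone nondecreasing in
    WB by a cumulative minimum from the loosest threshold down.
    """
    labels = np.asarray(labels)
    if labels.size != am.scores.shape[1]:
        raise SelectionError("labels must cover all samples")
    matrix = am.scores.to_numpy(dtype=float)
    observed = _wb_scores(matrix, labels)

    obs_sorted = np.sort(observed)
    n_reg = observed.size
    null_counts = np.zeros(n_reg)
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        null = np.sort(_wb_scores(matrix, rng.permutation(labels)))
        null_counts += np.searchsorted(null, observed, side="right")
    mean_null = null_counts / n_perm
    obs_count = np.searchsorted(obs_sorted, observed, side="right")
    fdr = np.minimum(mean_null / obs_count, 1.0)

    # monotone in WB: from loose (large WB) to strict, cumulative minimum
    order = np.argsort(observed, kind="stable")
    fdr_sorted = fdr[order]
    fdr_sorted = np.minimum.accumulate(fdr_sorted[::-1])[::-1]
    fdr[order] = fdr_sorted

    return [
        WBResult(
            regulator=str(reg),
            wb_score=float(observed[i]),
            fdr=float(fdr[i]),
            dataset=dataset,
        )
        for i, reg in enumerate(am.regulators)
    ]


def select_intrinsic(
    per_dataset: dict[str, list[WBResult]],
    fdr_threshold: float = 0.02,
    min_datasets: int = 3,
) -> list[str]:
    """Regulators under the FDR cutoff (strict) in at least ``min_datasets``.

    A regulator absent from a dataset simply does not pass there.
    """
    if len(per_dataset) < min_datasets:
        raise SelectionError(
            f"need >= {min_datasets} datasets, got {len(per_dataset)}"
        )
    passing: dict[str, int] = {}
    for results in per_dataset.values():
        for r in results:
            if r.fdr < fdr_threshold:
                passing[r.regulator] = passing.get(r.regulator, 0) + 1
    return sorted(r for r, n in passing.items() if n >= min_datasets)


def wb_table(per_dataset: dict[str, list[WBResult]]) -> pd.DataFrame:
    """Long-format WB/FDR table across datasets, for export."""
    rows = [
        (ds, r.regulator, r.wb_score, r.fdr)
        for ds, results in per_dataset.items()
        for r in results
    ]
    return pd.DataFrame(rows, columns=["dataset", "regulator", "wb_score", "fdr"])


@dataclass
class ClusterResult:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    zscores: pd.DataFrame


def cluster_activity(am: ActivityMatrix, regulators=None) -> ClusterResult:
    """Hierarchically cluster z-scored activity rows and sample columns.

    Rows are standardized to mean 0, sd 1 per regulator (zero-variance rows
    are excluded with a warning), then complete-linkage agglomeration on
    Euclidean distances orders both regulators and samples for heatmap
    display or export.
    """
    df = am.scores
    if regulators is not None:
        missing = [r for r in regulators if r not in df.index]
        if missing:
            raise SelectionError(f"regulators not scored: {missing[:5]}")
        df = df.loc[list(regulators)]
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise SelectionError("clustering needs >=2 regulators and >=2 samples")
    sd = df.std(axis=1, ddof=1)
    flat = sd == 0.0
    if flat.any():
        warnings.warn(
            f"excluding {int(flat.sum())} zero-variance regulator row(s) "
            "from clustering",
            stacklevel=2,
        )
        df = df.loc[~flat]
        sd = sd[~flat]
    if df.shape[0] < 2:
        raise SelectionError("fewer than 2 variable rows to cluster")
    z = df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)
    row_link = linkage(z.to_numpy(), method="complete", metric="euclidean")
    col_link = linkage(z.to_numpy().T, method="complete", metric="euclidean")
    return ClusterResult(
        row_order=[z.index[i] for i in leaves_list(row_link)],
        col_order=[z.columns[i] for i in leaves_list(col_link)],
        row_linkage=row_link,
        col_linkage=col_link,
        zscores=z,
    )
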