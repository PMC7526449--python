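"""Quadrant stratification of patients by regulator pairs.

For every unordered pair of regulators, samples fall into four groups by
the signs of the two activity scores (cutoff 0; a score of exactly 0 counts
as non-positive): group 1 double positive, group 2 first positive only,
group 3 double negative, group 4 second positive only. Group 1 ("double
positive") is contrasted against each other group on MRSS with two-sided
rank-sum tests; p-values from the whole scan are pooled and
Benjamini-Hochberg adjusted, and a pair is significant when all three
contrasts pass the q cutoff and group 1 has the strictly greatest median
MRSS.

Downstream contrasts on the same grouping: contingency enrichment (dcSSc,
early-stage, treatment fractions; two-tailed Fisher), an ILD fold-change
scan over significant pairs, and a paired t test of forced vital capacity
decline from baseline to a late follow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ActivityMatrix, ClinicalTable


class SubgroupError(ValueError):
    pass


GROUP_IDS = (1, 2, 3, 4)


def quadrant_assign(a: float, b: float) -> int:
    """Quadrant group for one sample from a pair of activity scores."""
    if not (math.isfinite(a) and math.isfinite(b)):
        raise SubgroupError("non-finite activity score")
    if a > 0:
        return 1 if b > 0 else 2
    return 4 if b > 0 else 3


def assign_groups(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized quadrant assignment over samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise SubgroupError("non-finite activity score")
    return np.where(a > 0, np.where(b > 0, 1, 2), np.where(b > 0, 4, 3))


def rank_sum_test(x, y) -> float:
    """Two-sided Mann-Whitney-Wilcoxon p-value.

    Exact enumeration when m+n <= 12 with no ties; otherwise the normal
    approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    exact = pooled.size <= 12 and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.pvalue)


@dataclass
class PairResult:
    pair: tuple[str, str]
    group_sizes: dict[int, int]
    median_mrss: dict[int, float]
    p_values: dict[int, float] = field(default_factory=dict)  # contrast group -> p
    q_values: dict[int, float] = field(default_factory=dict)
    tested: bool = False
    significant: bool = False
    dcssc_stats: dict | None = None
    ild_fold_change: float | None = None
    ild_fractions: dict[int, float] | None = None


def pairwise_severity_scan(
    am: ActivityMatrix,
    ct: ClinicalTable,
    regulators: list[str],
    q_threshold: float = 0.01,
    min_group: int = 3,
) -> list[PairResult]:
    """Scan all unordered regulator pairs for a severe double-positive group.

    Per pair, group 1 MRSS is compared with groups 2, 3 and 4 by two-sided
    rank-sum tests; all p-values from the scan are pooled and BH-adjusted.
    A pair is significant when all three q-values are below ``q_threshold``
    and group 1's median MRSS is strictly the greatest. Pairs where any
    contrasted group has fewer than ``min_group`` samples are reported
    untested.
    """
    if len(regulators) < 2:
        raise SubgroupError("need >=2 regulators for a pairwise scan")
    missing = [r for r in regulators if r not in am.regulators]
    if missing:
        raise SubgroupError(f"regulators not scored: {missing[:5]}")
    samples = [
        s for s in am.samples if s in ct.samples and pd.notna(ct.data.loc[s, "mrss"])
    ]
    if not samples:
        raise SubgroupError("no samples with MRSS available")
    scores = am.scores.loc[regulators, samples].to_numpy(dtype=float)
    mrss = ct.data.loc[samples, "mrss"].to_numpy(dtype=float)

    results: list[PairResult] = []
    pooled_p: list[float] = []
    pooled_at: list[tuple[int, int]] = []  # (result index, contrast group)
    for ia, ib in combinations(range(len(regulators)), 2):
        groups = assign_groups(scores[ia], scores[ib])
        by_group = {g: mrss[groups == g] for g in GROUP_IDS}
        sizes = {g: int(v.size) for g, v in by_group.items()}
        medians = {
            g: float(np.median(v)) if v.size else float("nan")
            for g, v in by_group.items()
        }
        res = PairResult(
            pair=(regulators[ia], regulators[ib]),
            group_sizes=sizes,
            median_mrss=medians,
        )
        if sizes[1] >= min_group and all(
            sizes[g] >= min_group for g in (2, 3, 4)
        ):
            res.tested = True
            for g in (2, 3, 4):
                p = rank_sum_test(by_group[1], by_group[g])
                res.p_values[g] = p
                pooled_p.append(p)
                pooled_at.append((len(results), g))
        results.append(res)

    if pooled_p:
        q = stats.false_discovery_control(np.asarray(pooled_p), method="bh")
        for (ri, g), qv in zip(pooled_at, q):
            results[ri].q_values[g] = float(qv)
    for res in results:
        if res.tested:
            res.significant = all(
                res.q_values[g] < q_threshold for g in (2, 3, 4)
            ) and all(
                res.median_mrss[1] > res.median_mrss[g] for g in (2, 3, 4)
            )
    return results


@dataclass
class GroupEnrichment:
    fractions: dict[int, float]  # per-group fraction of flag among known
    counts: dict[int, tuple[int, int]]  # (flagged, unflagged)
    fold_changes: dict[int, float]  # group 1 vs comparator; inf sentinel
    fisher_p: dict[int, float]


def contingency_enrichment(groups, flag) -> GroupEnrichment:
    """Fraction of a boolean covariate per quadrant group, vs group 1.

    Samples with unknown flag are ignored. Fold change is
    fraction(group 1) / fraction(comparator) with an infinite sentinel when
    the comparator fraction is 0; Fisher's exact test (two-tailed) is run on
    each group-1-vs-comparator 2x2 table. Empty comparators are skipped.
    """
    groups = np.asarray(groups)
    flag = np.asarray(
        [None if f is None or (isinstance(f, float) and np.isnan(f)) else bool(f) for f in flag],
        dtype=object,
    )
    known = flag != None  # noqa: E711  (object-array comparison)
    groups, flag = groups[known], flag[known].astype(bool)
    fractions: dict[int, float] = {}
    counts: dict[int, tuple[int, int]] = {}
    for g in GROUP_IDS:
        sel = groups == g
        n = int(sel.sum())
        pos = int(flag[sel].sum())
        counts[g] = (pos, n - pos)
        fractions[g] = pos / n if n else float("nan")
    if counts[1][0] + counts[1][1] == 0:
        raise SubgroupError("group 1 is empty")
    fold: dict[int, float] = {}
    fisher: dict[int, float] = {}
    for g in (2, 3, 4):
        n_g = counts[g][0] + counts[g][1]
        if n_g == 0:
            continue
        fc = (
            float("inf")
            if fractions[g] == 0.0 and fractions[1] > 0.0
            else (1.0 if fractions[g] == fractions[1] else fractions[1] / fractions[g])
        )
        fold[g] = fc
        table = [list(counts[1]), list(counts[g])]
        fisher[g] = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return GroupEnrichment(
        fractions=fractions, counts=counts, fold_changes=fold, fisher_p=fisher
    )


def ild_fold_change_scan(
    am: ActivityMatrix,
    ct: ClinicalTable,
    regulators: list[str],
    q_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    min_group: int = 3,
) -> list[PairResult]:
    """Severity scan plus an ILD-fraction fold-change filter.

    Among pairs significant at ``q_threshold``, the fraction of ILD in
    group 1 is compared with the pooled groups 2-4; pairs with fold change
    strictly greater than ``fc_threshold`` are retained. Per-group ILD
    fractions are recorded on each retained pair.
    """
    ild = ct.data["ild"]
    annotated = [s for s in ild.index if ild[s] is not None]
    if not annotated:
        raise SubgroupError("no ILD-annotated samples")
    results = pairwise_severity_scan(
        am, ct, regulators, q_threshold=q_threshold, min_group=min_group
    )
    samples = [
        s
        for s in am.samples
        if s in ct.samples
        and pd.notna(ct.data.loc[s, "mrss"])
        and ct.data.loc[s, "ild"] is not None
    ]
    scores = am.scores.loc[regulators, samples].to_numpy(dtype=float)
    ild_flag = ct.data.loc[samples, "ild"].astype(bool).to_numpy()
    index = {r: i for i, r in enumerate(regulators)}
    retained: list[PairResult] = []
    for res in results:
        if not res.significant:
            continue
        ia, ib = index[res.pair[0]], index[res.pair[1]]
        groups = assign_groups(scores[ia], scores[ib])
        in1 = groups == 1
        if not in1.any() or in1.all():
            continue
        frac1 = float(ild_flag[in1].mean())
        frac_rest = float(ild_flag[~in1].mean())
        fc = float("inf") if frac_rest == 0.0 and frac1 > 0.0 else (
            1.0 if frac1 == frac_rest else frac1 / frac_rest
        )
        res.ild_fold_change = fc
        res.ild_fractions = {
            g: float(ild_flag[groups == g].mean()) if (groups == g).any() else float("nan")
            for g in GROUP_IDS
        }
        if fc > fc_threshold:
            retained.append(res)
    retained.sort(key=lambda r: (-r.ild_fold_change, r.pair))
    return retained


@dataclass
class FVCGroupResult:
    group: int
    n: int
    t_statistic: float | None
    p_value: float | None
    mean_decline: float | None
    untestable: bool = False
    degenerate: bool = False


def fvc_decline_test(
    ct: ClinicalTable, groups: dict[str, int], min_months: float = 36.0
) -> dict[int, FVCGroupResult]:
    """Paired t test of FVC %predicted decline per quadrant group.

    ``groups`` maps sample ids to quadrant groups; each patient is assigned
    the group of their earliest sample. Baseline FVC is the first point of
    the series and follow-up the latest point at >= ``min_months``; patients
    without a qualifying follow-up are excluded. The statistic is computed
    on decline = baseline - follow-up, so a positive t indicates decline.
    """
    df = ct.data
    per_patient: dict[str, tuple[float, int, float, float]] = {}
    for sample, group in groups.items():
        if sample not in df.index:
            continue
        row = df.loc[sample]
        series = row["fvc_percent_predicted"]
        if not series:
            continue
        patient = row["patient_id"]
        t0 = series[0][0]
        prev = per_patient.get(patient)
        if prev is not None and prev[0] <= t0:
            continue  # keep the earliest sample per patient
        baseline = series[0][1]
        late = [v for m, v in series if m - series[0][0] >= min_months]
        if not late:
            continue
        per_patient[patient] = (t0, int(group), baseline, late[-1])

    out: dict[int, FVCGroupResult] = {}
    for g in GROUP_IDS:
        pairs = [
            (base, last)
            for (_, grp, base, last) in per_patient.values()
            if grp == g
        ]
        if len(pairs) < 2:
            out[g] = FVCGroupResult(
                group=g,
                n=len(pairs),
                t_statistic=None,
                p_value=None,
                mean_decline=None,
                untestable=True,
            )
            continue
        base = np.array([p[0] for p in pairs])
        last = np.array([p[1] for p in pairs])
        decline = base - last
        if np.std(decline, ddof=1) == 0.0:
            out[g] = FVCGroupResult(
                group=g,
                n=len(pairs),
                t_statistic=None,
                p_value=None,
                mean_decline=float(decline.mean()),
                degenerate=True,
            )
            continue
        res = stats.ttest_rel(base, last)
        out[g] = FVCGroupResult(
            group=g,
            n=len(pairs),
            t_statistic=float(res.statistic),
            p_value=float(res.pvalue),
            mean_decline=float(decline.mean()),
        )
    return out


def pair_results_frame(results: list[PairResult]) -> pd.DataFrame:
    """Flat table of a pairwise scan, for export."""
    rows = []
    for r in results:
        row = {
            "regulator_a": r.pair[0],
            "regulator_b": r.pair[1],
            "tested": r.tested,
            "significant": r.significant,
        }
        for g in GROUP_IDS:
            row[f"n_group{g}"] = r.group_sizes.get(g, 0)
            row[f"median_mrss_group{g}"] = r.median_mrss.get(g, float("nan"))
        for g in (2, 3, 4):
            row[f"p_vs_group{g}"] = r.p_values.get(g, float("nan"))
            row[f"q_vs_group{g}"] = r.q_values.get(g, float("nan"))
        if r.ild_fold_change is not None:
            row["ild_fold_change"] = r.ild_fold_change
        rows.append(row)
    return pd.DataFrame(rows)
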