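"""Quadrant assignment, rank-sum/Fisher/paired-t kernels, pair scans."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from regact.io_formats import ActivityMatrix, ClinicalTable
from regact.subgroup_analysis import (
    SubgroupError,
    assign_groups,
    contingency_enrichment,
    fvc_decline_test,
    ild_fold_change_scan,
    pair_results_frame,
    pairwise_severity_scan,
    quadrant_assign,
    rank_sum_test,
)


def exact_rank_sum_p(x, y):
    """Two-sided rank-sum p by enumerating all C(m+n, m) assignments."""
    pooled = np.concatenate([x, y])
    m = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[:m].sum()
    mean = m * (len(pooled) + 1) / 2
    count = total = 0
    for pos in combinations(range(len(pooled)), m):
        s = ranks[list(pos)].sum()
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total


class TestQuadrantAssign:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (0.5, 0.3, 1),
            (0.5, -0.3, 2),
            (-0.5, -0.3, 3),
            (-0.5, 0.3, 4),
            (0.0, 0.3, 4),  # zero counts as non-positive
            (0.0, 0.0, 3),
        ],
    )
    def test_mapping(self, a, b, expected):
        assert quadrant_assign(a, b) == expected

    def test_nonfinite_errors(self):
        with pytest.raises(SubgroupError):
            quadrant_assign(float("nan"), 1.0)

    def test_vectorized_matches_scalar(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        groups = assign_groups(a, b)
        assert groups.sum() > 0
        for i in range(50):
            assert groups[i] == quadrant_assign(a[i], b[i])

    def test_group_sizes_partition_samples(self, rng):
        a, b = rng.normal(size=200), rng.normal(size=200)
        groups = assign_groups(a, b)
        assert sum((groups == g).sum() for g in (1, 2, 3, 4)) == 200


class TestRankSum:
    def test_exact_small_sample_example(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_agrees_with_enumeration_small_partitions(self, rng):
        for _ in range(30):
            m = int(rng.integers(2, 6))
            n = int(rng.integers(2, 11 - m))
            vals = rng.permutation(np.arange(1, m + n + 1)).astype(float)
            x, y = vals[:m], vals[m:]
            assert rank_sum_test(x, y) == pytest.approx(
                exact_rank_sum_p(x, y), abs=1e-9
            )

    def test_large_or_tied_samples_use_asymptotic(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(loc=2.0, size=30)
        p = rank_sum_test(x, y)
        assert 0 < p < 1e-4


def _scan_inputs(scores_by_reg, mrss, extra_clinical=None):
    samples = [f"s{i}" for i in range(len(mrss))]
    am = ActivityMatrix(
        scores=pd.DataFrame.from_dict(scores_by_reg, orient="index", columns=samples)
    )
    data = {
        "sample_id": samples,
        "patient_id": samples,
        "mrss": mrss,
        "subset": ["fibroproliferative"] * len(samples),
    }
    if extra_clinical:
        data.update(extra_clinical)
    df = pd.DataFrame(data).set_index("sample_id")
    if "ild" in df.columns:
        df["ild"] = df["ild"].astype(object)
    if "fvc_percent_predicted" not in df.columns:
        df["fvc_percent_predicted"] = [[] for _ in samples]
    return am, ClinicalTable(data=df)


class TestPairwiseScan:
    def test_pair_count_two_regulators(self, rng):
        am, ct = _scan_inputs(
            {"A": rng.normal(size=12), "B": rng.normal(size=12)},
            list(rng.integers(0, 40, size=12)),
        )
        assert len(pairwise_severity_scan(am, ct, ["A", "B"])) == 1

    def test_pair_count_fifty_regulators(self, rng):
        n = 24
        scores = {f"R{i:02d}": rng.normal(size=n) for i in range(50)}
        am, ct = _scan_inputs(scores, list(rng.integers(0, 40, size=n)))
        results = pairwise_severity_scan(am, ct, sorted(scores))
        assert len(results) == 1225

    def test_single_regulator_errors(self, rng):
        am, ct = _scan_inputs({"A": rng.normal(size=6)}, [1, 2, 3, 4, 5, 6])
        with pytest.raises(SubgroupError):
            pairwise_severity_scan(am, ct, ["A"])

    def test_small_groups_reported_untested(self):
        am, ct = _scan_inputs(
            {"A": [1, 1, 1, 1, -1, -1], "B": [1, 1, 1, 1, 1, -1]},
            [10, 12, 14, 16, 5, 6],
        )
        (res,) = pairwise_severity_scan(am, ct, ["A", "B"], min_group=3)
        assert not res.tested and not res.significant

    def test_planted_severe_pair_flagged(self, rng):
        """Group 1 with much higher MRSS is detected; q >= p for BH."""
        n = 80
        a, b = rng.normal(size=n), rng.normal(size=n)
        group1 = (a > 0) & (b > 0)
        mrss = np.clip(
            np.round(rng.normal(14, 4, size=n) + 14 * group1), 0, 51
        ).astype(int)
        noise = {f"N{i}": rng.normal(size=n) for i in range(4)}
        am, ct = _scan_inputs({"A": a, "B": b, **noise}, list(mrss))
        results = pairwise_severity_scan(am, ct, ["A", "B", *sorted(noise)])
        by_pair = {r.pair: r for r in results}
        assert by_pair[("A", "B")].significant
        for g in (2, 3, 4):
            r = by_pair[("A", "B")]
            assert r.q_values[g] >= r.p_values[g]

    def test_results_frame_shape(self, rng):
        am, ct = _scan_inputs(
            {"A": rng.normal(size=20), "B": rng.normal(size=20), "C": rng.normal(size=20)},
            list(rng.integers(0, 40, size=20)),
        )
        frame = pair_results_frame(pairwise_severity_scan(am, ct, ["A", "B", "C"]))
        assert len(frame) == 3
        assert {"regulator_a", "significant", "q_vs_group2"} <= set(frame.columns)


class TestContingency:
    def test_fisher_worked_example(self):
        groups = [1, 1, 1, 2, 2, 2]
        flag = [True, True, True, False, False, False]
        enr = contingency_enrichment(groups, flag)
        assert enr.fisher_p[2] == pytest.approx(0.1)

    def test_fraction_and_fold_arithmetic(self):
        groups = [1] * 10 + [2] * 21
        flag = [True] * 5 + [False] * 5 + [True] * 6 + [False] * 15
        enr = contingency_enrichment(groups, flag)
        assert enr.fractions[1] == pytest.approx(0.5)
        assert enr.fractions[2] == pytest.approx(6 / 21)
        assert enr.fold_changes[2] == pytest.approx(1.75)

    def test_identical_fractions_fold_one(self):
        enr = contingency_enrichment([1, 1, 2, 2], [True, False, True, False])
        assert enr.fold_changes[2] == 1.0

    def test_zero_comparator_fraction_infinite(self):
        enr = contingency_enrichment([1, 1, 1, 2, 2, 2], [True, True, True, False, False, False])
        assert enr.fold_changes[2] == np.inf

    def test_unknown_flags_ignored(self):
        enr = contingency_enrichment([1, 1, 2, 2, 2], [True, None, True, False, None])
        assert enr.counts[1] == (1, 0)
        assert enr.counts[2] == (1, 1)


class TestIldScan:
    def _fixture(self, rng, n=120, p_dp=0.5, p_bg=0.2, shift=14):
        a, b = rng.normal(size=n), rng.normal(size=n)
        dp = (a > 0) & (b > 0)
        mrss = np.clip(np.round(rng.normal(14, 4, n) + shift * dp), 0, 51).astype(int)
        ild = rng.random(n) < np.where(dp, p_dp, p_bg)
        noise = {f"N{i}": rng.normal(size=n) for i in range(3)}
        am, ct = _scan_inputs(
            {"A": a, "B": b, **noise},
            list(mrss),
            extra_clinical={"ild": [bool(v) for v in ild]},
        )
        return am, ct, sorted({"A", "B", *noise})

    def test_planted_pair_retained(self, rng):
        am, ct, regs = self._fixture(rng)
        retained = ild_fold_change_scan(am, ct, regs, q_threshold=0.05, fc_threshold=1.5)
        assert ("A", "B") in [r.pair for r in retained]
        (res,) = [r for r in retained if r.pair == ("A", "B")]
        assert res.ild_fold_change > 1.5
        assert set(res.ild_fractions) == {1, 2, 3, 4}

    def test_fold_change_boundary_strict(self, rng):
        am, ct, regs = self._fixture(rng)
        # raising the threshold to the measured fold excludes the pair
        retained = ild_fold_change_scan(am, ct, regs, fc_threshold=1.5)
        fc = [r.ild_fold_change for r in retained if r.pair == ("A", "B")][0]
        again = ild_fold_change_scan(am, ct, regs, fc_threshold=fc)
        assert ("A", "B") not in [r.pair for r in again]

    def test_equal_ild_everywhere_nothing_retained(self, rng):
        am, ct, regs = self._fixture(rng, p_dp=0.3, p_bg=0.3)
        retained = ild_fold_change_scan(am, ct, regs, fc_threshold=1.5)
        for r in retained:
            assert r.ild_fold_change > 1.5  # only genuinely enriched pairs

    def test_no_annotation_errors(self, rng):
        am, ct = _scan_inputs(
            {"A": rng.normal(size=6), "B": rng.normal(size=6)},
            [1, 2, 3, 4, 5, 6],
            extra_clinical={"ild": [None] * 6},
        )
        with pytest.raises(SubgroupError):
            ild_fold_change_scan(am, ct, ["A", "B"])


def _fvc_ct(series_by_patient):
    samples = list(series_by_patient)
    df = pd.DataFrame(
        {
            "sample_id": samples,
            "patient_id": samples,
            "mrss": [10] * len(samples),
            "subset": ["fibroproliferative"] * len(samples),
            "fvc_percent_predicted": [series_by_patient[s] for s in samples],
        }
    ).set_index("sample_id")
    return ClinicalTable(data=df)


class TestFvcDecline:
    def test_worked_paired_t_example(self):
        ct = _fvc_ct(
            {
                "p1": [(0, 90), (40, 80)],
                "p2": [(0, 85), (40, 78)],
                "p3": [(0, 95), (40, 88)],
            }
        )
        res = fvc_decline_test(ct, {"p1": 1, "p2": 1, "p3": 1}, min_months=36)
        assert res[1].t_statistic == pytest.approx(8.0)
        assert res[1].p_value == pytest.approx(0.0153, abs=1e-3)

    def test_symmetric_differences_null(self):
        ct = _fvc_ct({"p1": [(0, 90), (40, 92)], "p2": [(0, 90), (40, 88)]})
        res = fvc_decline_test(ct, {"p1": 1, "p2": 1}, min_months=36)
        assert res[1].t_statistic == pytest.approx(0.0)
        assert res[1].p_value == pytest.approx(1.0)

    def test_single_patient_untestable(self):
        ct = _fvc_ct({"p1": [(0, 90), (40, 80)]})
        res = fvc_decline_test(ct, {"p1": 1}, min_months=36)
        assert res[1].untestable

    def test_short_followup_excluded(self):
        ct = _fvc_ct(
            {
                "p1": [(0, 90), (12, 80)],
                "p2": [(0, 85), (40, 78)],
                "p3": [(0, 95), (40, 88)],
            }
        )
        res = fvc_decline_test(ct, {"p1": 1, "p2": 1, "p3": 1}, min_months=36)
        assert res[1].n == 2

    def test_zero_variance_degenerate(self):
        ct = _fvc_ct({"p1": [(0, 90), (40, 85)], "p2": [(0, 80), (40, 75)]})
        res = fvc_decline_test(ct, {"p1": 1, "p2": 1}, min_months=36)
        assert res[1].degenerate
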