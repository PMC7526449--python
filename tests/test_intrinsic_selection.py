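"""Within-between scoring, permutation FDR and clustering."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regact.intrinsic_selection import (
    SelectionError,
    WBResult,
    cluster_activity,
    intrinsic_fdr,
    select_intrinsic,
    within_between_score,
)
from regact.io_formats import ActivityMatrix


class TestWithinBetween:
    def test_zero_within_variance(self):
        assert within_between_score([1, 1, 3, 3], ["A", "A", "B", "B"]) == 0.0

    def test_worked_ratio(self):
        # SSW = 0.5 + 0.5, SSB = 2*(1.5-2.5)^2 + 2*(3.5-2.5)^2 = 4
        assert within_between_score([1, 2, 3, 4], ["A", "A", "B", "B"]) == 0.25

    def test_constant_vector_sentinel(self):
        assert within_between_score([2, 2, 2, 2], ["A", "A", "B", "B"]) == np.inf

    def test_single_group_errors(self):
        with pytest.raises(SelectionError):
            within_between_score([1, 2, 3], ["A", "A", "A"])

    def test_small_group_errors(self):
        with pytest.raises(SelectionError):
            within_between_score([1, 2, 3], ["A", "A", "B"])

    @given(
        st.floats(min_value=0.1, max_value=50),
        st.floats(min_value=-20, max_value=20),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b):
        x = np.array([0.3, 1.2, -0.5, 2.2, 2.5, 1.9])
        labels = ["A", "A", "A", "B", "B", "B"]
        base = within_between_score(x, labels)
        assert within_between_score(a * x + b, labels) == pytest.approx(
            base, rel=1e-9
        )


def _am(matrix, names=None):
    matrix = np.asarray(matrix, dtype=float)
    names = names or [f"R{i}" for i in range(matrix.shape[0])]
    return ActivityMatrix(
        scores=pd.DataFrame(
            matrix, index=names, columns=[f"s{j}" for j in range(matrix.shape[1])]
        )
    )


def exhaustive_fdr(matrix, labels):
    """FDR over ALL distinct label arrangements, with monotone enforcement."""
    matrix = np.asarray(matrix, dtype=float)
    observed = np.array(
        [within_between_score(row, labels) for row in matrix]
    )
    arrangements = sorted(set(permutations(labels)))
    null_counts = np.zeros(len(observed))
    for arr in arrangements:
        null = np.array([within_between_score(row, list(arr)) for row in matrix])
        null_counts += np.array([(null <= o).sum() for o in observed])
    mean_null = null_counts / len(arrangements)
    obs_count = np.array([(observed <= o).sum() for o in observed])
    fdr = np.minimum(mean_null / obs_count, 1.0)
    order = np.argsort(observed, kind="stable")
    f = fdr[order]
    f = np.minimum.accumulate(f[::-1])[::-1]
    fdr[order] = f
    return observed, fdr


class TestIntrinsicFdr:
    def test_strong_regulator_gets_zero_fdr(self, rng):
        # one perfectly grouped regulator among noise: WB=0 beats every null
        strong = [0, 0, 0, 5, 5, 5, 9, 9, 9]
        noise = rng.normal(size=(3, 9))
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        am = _am(np.vstack([strong, noise]))
        results = intrinsic_fdr(am, labels, n_perm=200, seed=0)
        assert results[0].wb_score == 0.0
        assert results[0].fdr == 0.0

    def test_fdr_capped_at_one(self, rng):
        am = _am(rng.normal(size=(5, 8)))
        labels = ["A"] * 4 + ["B"] * 4
        results = intrinsic_fdr(am, labels, n_perm=100, seed=1)
        assert max(r.fdr for r in results) <= 1.0
        # the loosest threshold admits everything observed and null alike
        loosest = max(results, key=lambda r: r.wb_score)
        assert loosest.fdr == pytest.approx(1.0, abs=0.05)

    def test_fdr_monotone_in_wb(self, rng):
        am = _am(rng.normal(size=(6, 8)))
        labels = ["A"] * 4 + ["B"] * 4
        results = intrinsic_fdr(am, labels, n_perm=100, seed=2)
        ordered = sorted(results, key=lambda r: r.wb_score)
        fdrs = [r.fdr for r in ordered]
        assert fdrs == sorted(fdrs)

    def test_matches_exhaustive_permutation_oracle(self, rng):
        """Sampled FDR tracks the all-arrangements oracle within 3 MC SE."""
        matrix = rng.normal(size=(4, 6))
        matrix[0, :3] += 3.0  # one genuinely grouped regulator
        labels = ["A", "A", "A", "B", "B", "B"]
        observed, exact = exhaustive_fdr(matrix, labels)

        n_perm = 3000
        results = intrinsic_fdr(_am(matrix), labels, n_perm=n_perm, seed=3)
        # per-regulator MC standard error of the mean null count
        arrangements = sorted(set(permutations(labels)))
        counts = np.array(
            [
                [
                    (
                        np.array(
                            [
                                within_between_score(row, list(arr))
                                for row in matrix
                            ]
                        )
                        <= o
                    ).sum()
                    for arr in arrangements
                ]
                for o, row_o in zip(observed, matrix)
            ]
        )
        obs_count = np.array([(observed <= o).sum() for o in observed])
        se = counts.std(axis=1) / np.sqrt(n_perm) / obs_count
        for r, e, s in zip(results, exact, se):
            assert abs(r.fdr - e) <= 3 * max(s, 1e-12) + 1e-12

    def test_mismatched_labels_error(self, rng):
        am = _am(rng.normal(size=(2, 6)))
        with pytest.raises(SelectionError):
            intrinsic_fdr(am, ["A", "B"], n_perm=10)


class TestSelectIntrinsic:
    def _results(self, fdrs_by_dataset):
        return {
            ds: [WBResult("R1", 0.1, f, ds)]
            for ds, f in fdrs_by_dataset.items()
        }

    def test_selected_with_three_passing(self):
        per = self._results({"d1": 0.01, "d2": 0.015, "d3": 0.019, "d4": 0.5})
        assert select_intrinsic(per, 0.02, 3) == ["R1"]

    def test_not_selected_with_one_passing(self):
        per = self._results({"d1": 0.5, "d2": 0.5, "d3": 0.5, "d4": 0.01})
        assert select_intrinsic(per, 0.02, 3) == []

    def test_boundary_is_strict(self):
        per = self._results({"d1": 0.02, "d2": 0.02, "d3": 0.02, "d4": 0.02})
        assert select_intrinsic(per, 0.02, 3) == []

    def test_absent_regulator_does_not_pass(self):
        per = {
            "d1": [WBResult("R1", 0.1, 0.001, "d1")],
            "d2": [WBResult("R1", 0.1, 0.001, "d2")],
            "d3": [WBResult("R2", 0.1, 0.001, "d3")],
        }
        assert select_intrinsic(per, 0.02, 3) == []

    def test_too_few_datasets_error(self):
        with pytest.raises(SelectionError):
            select_intrinsic({"d1": []}, 0.02, 3)


class TestClusterActivity:
    def test_identical_rows_merge_first_at_zero(self, rng):
        base = rng.normal(size=6)
        m = np.vstack([base, base, rng.normal(size=6) * 3])
        res = cluster_activity(_am(m))
        first = res.row_linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == 0.0

    def test_nearest_samples_merge_first(self):
        m = np.vstack([[0.0, 0.1, 10.0], [0.0, 0.1, 10.0]])
        res = cluster_activity(_am(m))
        first = res.col_linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}

    def test_zscore_contract(self, rng):
        m = rng.normal(size=(5, 8))
        res = cluster_activity(_am(m))
        np.testing.assert_allclose(res.zscores.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(res.zscores.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_zero_variance_row_excluded_with_warning(self, rng):
        m = np.vstack([np.ones(6), rng.normal(size=(2, 6))])
        with pytest.warns(UserWarning, match="zero-variance"):
            res = cluster_activity(_am(m))
        assert "R0" not in res.row_order

    def test_requires_two_regulators(self, rng):
        with pytest.raises(SelectionError):
            cluster_activity(_am(rng.normal(size=(1, 6))))


class TestRecoveryOnSyntheticCohorts:
    def test_planted_regulators_recovered_and_null_calibrated(self):
        """Planted subset-specific regulators are selected at FDR<2% in >=3
        of 4 cohorts with high sensitivity/precision; label shuffling and a
        zero-effect generator both break selection."""
        import dataclasses

        from regact.base_scoring import base_activity, normalize_expression
        from regact.synthetic_data import default_config, simulate_multicohort

        n_selected_perm = []
        for seed in (101, 202, 303):
            base_cfg = default_config(
                seed=seed,
                n_genes=600,
                n_regulators=60,
                targets_per_regulator=30,
                samples_per_subset=15,
            )
            cfgs = [
                dataclasses.replace(base_cfg, seed=seed + i) for i in range(4)
            ]
            cohorts = simulate_multicohort(cfgs, shared_truth=True)
            per_dataset = {}
            rng_np = np.random.default_rng(seed)
            truth = cohorts[0][3]
            for i, (em, sets, ct, _) in enumerate(cohorts):
                am = base_activity(
                    normalize_expression(em), sets, n_perm=50, seed=seed + i
                )
                labels = ct.data.loc[am.samples, "subset"].to_numpy()
                per_dataset[f"c{i}"] = intrinsic_fdr(
                    am, labels, n_perm=200, seed=seed + i, dataset=f"c{i}"
                )
                # permuted labels destroy selection (collect for final check)
                perm_labels = rng_np.permutation(labels)
                n_selected_perm.append(
                    sum(
                        1
                        for r in intrinsic_fdr(
                            am, perm_labels, n_perm=200, seed=seed + i
                        )
                        if r.fdr < 0.02
                    )
                )
            selected = set(select_intrinsic(per_dataset, 0.02, 3))
            planted = truth.planted_regulators()
            sensitivity = len(selected & planted) / len(planted)
            assert sensitivity >= 0.9, (seed, sorted(selected), sorted(planted))
            if selected:
                fdp = len(selected - planted) / len(selected)
                assert fdp <= 0.1, (seed, sorted(selected - planted))
        # shuffled labels: on average few regulators pass per cohort
        assert np.mean(n_selected_perm) <= 0.05 * 60
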