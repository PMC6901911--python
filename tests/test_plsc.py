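"""PLSC construction, inference and selection contracts.

SVD identities are checked against dense linear-algebra oracles computed
in the tests; permutation and bootstrap inference are calibrated on
independent random blocks where the null behaviour is known.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dilradiomics import plsc


def _random_table(rng, n_subjects=6, n_features=5, effect=0.0):
    rows = []
    for i in range(n_subjects):
        for roi, sign in (("DIL", 1.0), ("NT", -1.0)):
            base = rng.standard_normal(n_features)
            for mod in ("T2W", "ADC"):
                vals = base + 0.5 * rng.standard_normal(n_features) \
                    + sign * effect
                rows.append({"subject_id": f"s{i}", "roi_kind": roi,
                             "modality": mod,
                             **{f"f{j}": vals[j] for j in range(n_features)}})
    return pd.DataFrame(rows)


class TestBuildBlocks:
    def test_columns_standardized(self, rng):
        bx, by = plsc.build_blocks(_random_table(rng))
        for blk in (bx, by):
            np.testing.assert_allclose(blk.data.mean(axis=0), 0, atol=1e-12)
            np.testing.assert_allclose(blk.data.std(axis=0, ddof=1), 1,
                                       atol=1e-12)

    def test_zero_variance_column_zeroed(self, rng):
        table = _random_table(rng)
        table["f0"] = 3.14
        bx, _ = plsc.build_blocks(table)
        np.testing.assert_array_equal(bx.data[:, 0], 0.0)
        assert bx.col_scales[0] == 1.0

    def test_row_alignment_survives_shuffling(self, rng):
        table = _random_table(rng)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        bx1, by1 = plsc.build_blocks(table)
        bx2, by2 = plsc.build_blocks(shuffled)
        # labels travel with rows: re-order block 2 to block 1's keys
        key1 = list(zip(bx1.subject_ids, bx1.roi_kinds))
        key2 = list(zip(bx2.subject_ids, bx2.roi_kinds))
        perm = [key2.index(k) for k in key1]
        np.testing.assert_allclose(bx2.data[perm], bx1.data, atol=1e-12)
        np.testing.assert_allclose(by2.data[perm], by1.data, atol=1e-12)

    def test_missing_modality_rejected(self, rng):
        table = _random_table(rng)
        broken = table.drop(table[(table.subject_id == "s0")
                                  & (table.modality == "ADC")
                                  & (table.roi_kind == "DIL")].index)
        with pytest.raises(ValueError, match="missing"):
            plsc.build_blocks(broken)


class TestFitPLSC:
    def test_symmetric_case_y_equals_x(self, rng):
        table = _random_table(rng)
        bx, _ = plsc.build_blocks(table)
        by = plsc.ObservationBlock(
            data=bx.data.copy(), modality="ADC", subject_ids=bx.subject_ids,
            roi_kinds=bx.roi_kinds, col_means=bx.col_means,
            col_scales=bx.col_scales, feature_names=bx.feature_names)
        m = plsc.fit_plsc(bx, by)
        n = bx.data.shape[0]
        eigvals = np.sort(np.linalg.eigvalsh(bx.data.T @ bx.data / (n - 1)))[::-1]
        np.testing.assert_allclose(m.singular_values, eigvals, atol=1e-10)
        np.testing.assert_allclose(np.abs(m.U), np.abs(m.V), atol=1e-8)

    def test_hand_example_matches_svd_oracle(self):
        """4x2 integer blocks: singular values from an independent SVD."""
        X = np.array([[1, 2], [3, -1], [-2, 0], [-2, -1]], dtype=float)
        Y = np.array([[2, 1], [1, -2], [-1, 1], [-2, 0]], dtype=float)
        bx = plsc.ObservationBlock(
            data=(X - X.mean(0)) / X.std(0, ddof=1), modality="T2W",
            subject_ids=np.array(["a", "b", "c", "d"]),
            roi_kinds=np.array(["DIL", "NT", "DIL", "NT"]),
            col_means=X.mean(0), col_scales=X.std(0, ddof=1))
        by = plsc.ObservationBlock(
            data=(Y - Y.mean(0)) / Y.std(0, ddof=1), modality="ADC",
            subject_ids=bx.subject_ids, roi_kinds=bx.roi_kinds,
            col_means=Y.mean(0), col_scales=Y.std(0, ddof=1))
        m = plsc.fit_plsc(bx, by)
        R = bx.data.T @ by.data / 3.0
        expected = np.linalg.svd(R, compute_uv=False)
        np.testing.assert_allclose(m.singular_values, expected, atol=1e-12)

    def test_inertia_equals_frobenius_norm(self, rng):
        bx, by = plsc.build_blocks(_random_table(rng))
        m = plsc.fit_plsc(bx, by)
        R = bx.data.T @ by.data / (bx.n_rows - 1)
        assert m.inertia == pytest.approx(np.sum(R ** 2))

    def test_salience_orthonormality_and_ordering(self, rng):
        bx, by = plsc.build_blocks(_random_table(rng, n_features=8))
        m = plsc.fit_plsc(bx, by)
        np.testing.assert_allclose(m.U.T @ m.U, np.eye(m.U.shape[1]), atol=1e-8)
        np.testing.assert_allclose(m.V.T @ m.V, np.eye(m.V.shape[1]), atol=1e-8)
        assert np.all(np.diff(m.singular_values) <= 1e-12)

    def test_latent_score_covariance_proportional_to_delta(self, rng):
        bx, by = plsc.build_blocks(_random_table(rng, n_features=4))
        m = plsc.fit_plsc(bx, by)
        n = bx.n_rows
        for k in range(len(m.singular_values)):
            cov = (m.Lx[:, k] @ m.Ly[:, k]) / (n - 1)
            assert cov == pytest.approx(m.singular_values[k], abs=1e-10)

    def test_needs_three_rows(self, rng):
        tab = _random_table(rng, n_subjects=1)
        bx, by = plsc.build_blocks(tab)
        with pytest.raises(ValueError, match="3 rows"):
            plsc.fit_plsc(plsc.ObservationBlock(bx.data[:2], "T2W",
                                                bx.subject_ids[:2],
                                                bx.roi_kinds[:2],
                                                bx.col_means, bx.col_scales),
                          plsc.ObservationBlock(by.data[:2], "ADC",
                                                by.subject_ids[:2],
                                                by.roi_kinds[:2],
                                                by.col_means, by.col_scales))


class TestPermutationTest:
    def test_p_in_unit_interval_and_bounds(self, rng):
        bx, by = plsc.build_blocks(_random_table(rng))
        res = plsc.permutation_test_inertia(bx, by, n_permutations=99, seed=0)
        assert 1 / 100 <= res.p_value <= 1.0
        assert res.null_inertia.shape == (99,)

    def test_strong_association_beats_all_permutations(self, rng):
        tab = _random_table(rng, n_subjects=20, effect=3.0)
        bx, by = plsc.build_blocks(tab)
        res = plsc.permutation_test_inertia(bx, by, n_permutations=200, seed=1)
        assert res.p_value == pytest.approx(1 / 201)

    def test_type_i_error_calibrated_under_null(self):
        """Independent random blocks: rejection rate at alpha=0.05 over
        200 replicates stays near nominal, and null p-values are uniform."""
        n_rep, B, alpha = 200, 200, 0.05
        pvals = np.empty(n_rep)
        for rep in range(n_rep):
            rng = np.random.default_rng(10_000 + rep)
            X = rng.standard_normal((20, 6))
            Y = rng.standard_normal((20, 6))
            bx = plsc.ObservationBlock(
                (X - X.mean(0)) / X.std(0, ddof=1), "T2W",
                np.arange(20).astype(str), np.array(["DIL", "NT"] * 10),
                X.mean(0), X.std(0, ddof=1))
            by = plsc.ObservationBlock(
                (Y - Y.mean(0)) / Y.std(0, ddof=1), "ADC",
                bx.subject_ids, bx.roi_kinds, Y.mean(0), Y.std(0, ddof=1))
            pvals[rep] = plsc.permutation_test_inertia(
                bx, by, n_permutations=B, seed=rep).p_value
        rate = np.mean(pvals <= alpha)
        assert 0.01 <= rate <= 0.11
        assert stats.kstest(pvals, "uniform").pvalue > 1e-4

    def test_b_must_be_positive(self, rng):
        bx, by = plsc.build_blocks(_random_table(rng))
        with pytest.raises(ValueError):
            plsc.permutation_test_inertia(bx, by, n_permutations=0)


class TestBootstrapRatios:
    def _blocks_from(self, X, Y):
        n = X.shape[0]
        mk = lambda M, mod: plsc.ObservationBlock(
            (M - M.mean(0)) / M.std(0, ddof=1), mod,
            np.arange(n).astype(str), np.array(["DIL", "NT"] * (n // 2)),
            M.mean(0), M.std(0, ddof=1),
            feature_names=[f"f{j}" for j in range(M.shape[1])])
        return mk(X, "T2W"), mk(Y, "ADC")

    def test_zero_variance_salience_gets_infinite_ratio(self, rng):
        """Rank-1 identical blocks: every resample reproduces the same
        salience, so the ratio is the +inf sentinel, ranked first."""
        a = rng.standard_normal(12)
        u = np.array([3.0, 1.0, 0.5])
        X = np.outer(a, u)
        bx, by = self._blocks_from(X, X.copy())
        rx, ry = plsc.bootstrap_ratios(bx, by, n_boot=100, seed=0)
        assert np.isinf(rx.ratios).any()
        assert np.isinf(rx.ratios[rx.ranks[0]])

    def test_pure_noise_false_positive_rate_near_nominal(self):
        """|ratio| > 2 under independent noise blocks ~ 5% of features."""
        flags = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((40, 40))
            Y = rng.standard_normal((40, 40))
            bx, by = self._blocks_from(X, Y)
            rx, ry = plsc.bootstrap_ratios(bx, by, n_boot=500, seed=seed)
            flags += [rx.significant.mean(), ry.significant.mean()]
        assert 0.0 <= np.mean(flags) <= 0.15

    def test_planted_feature_ranked_first(self, rng):
        """A single column carrying the group contrast dominates the
        first-latent saliences in both blocks."""
        n = 40
        g = np.tile([1.0, -1.0], n // 2)
        X = 0.3 * rng.standard_normal((n, 6))
        Y = 0.3 * rng.standard_normal((n, 6))
        X[:, 2] += 3.0 * g
        Y[:, 4] += 3.0 * g
        bx, by = self._blocks_from(X, Y)
        rx, ry = plsc.bootstrap_ratios(bx, by, n_boot=200, seed=5)
        assert rx.ranks[0] == 2
        assert ry.ranks[0] == 4
        assert rx.significant[2] and ry.significant[4]

    def test_ranks_are_a_permutation(self, rng):
        X = rng.standard_normal((20, 7))
        Y = rng.standard_normal((20, 7))
        bx, by = self._blocks_from(X, Y)
        rx, _ = plsc.bootstrap_ratios(bx, by, n_boot=100, seed=2)
        assert sorted(rx.ranks) == list(range(7))


class TestAnovaAndSelection:
    def test_identical_groups_give_zero_f(self):
        scores = np.tile(np.arange(4.0), 2)[:, None]
        labels = np.array(["DIL"] * 4 + ["NT"] * 4)
        res = plsc.anova_latent(scores, labels)
        assert res.F[0] == pytest.approx(0.0)

    def test_f_equals_squared_t(self, rng):
        a, b = rng.standard_normal(10), 1.0 + rng.standard_normal(12)
        scores = np.concatenate([a, b])[:, None]
        labels = np.array(["DIL"] * 10 + ["NT"] * 12)
        res = plsc.anova_latent(scores, labels)
        t = stats.ttest_ind(a, b).statistic
        assert res.F[0] == pytest.approx(t ** 2, rel=1e-10)

    def test_holm_step_down_hand_example(self):
        """p = {0.001, 0.02, 0.04} with m = 3 at alpha 0.05: the ordered
        thresholds 0.05/3, 0.05/2, 0.05 reject all three."""
        reject = plsc.multipletests([0.001, 0.02, 0.04], alpha=0.05,
                                    method="holm")[0]
        assert reject.all()
        # and 0.03 in the middle position fails its 0.025 threshold,
        # stopping the step-down before the last hypothesis
        reject2 = plsc.multipletests([0.001, 0.03, 0.04], alpha=0.05,
                                     method="holm")[0]
        assert list(reject2) == [True, False, False]

    def test_silhouette_separated_and_interleaved(self):
        labels = np.array(["DIL", "NT"] * 3)
        apart = np.array([10.0, -10.0, 10.1, -10.1, 9.9, -9.9])[:, None]
        sil, ok = plsc.silhouette_filter(apart, labels)
        assert sil[0] > 0.95 and ok[0]
        inter = np.arange(6.0)[:, None]   # alternating labels along a line
        sil2, ok2 = plsc.silhouette_filter(inter, labels)
        # direct formula oracle
        expected = []
        for i in range(6):
            own = [j for j in range(6) if j != i and (j - i) % 2 == 0]
            other = [j for j in range(6) if (j - i) % 2 == 1]
            a = np.mean([abs(i - j) for j in own])
            b = np.mean([abs(i - j) for j in other])
            expected.append((b - a) / max(a, b))
        assert sil2[0] == pytest.approx(np.mean(expected), abs=1e-12)
        assert not ok2[0]

    def test_strong_cohort_selects_at_least_one_per_modality(self, study_selection):
        assert len(study_selection.selected_x) >= 1
        assert len(study_selection.selected_y) >= 1
        assert not study_selection.is_empty

    def test_null_cohort_selection_empty(self):
        from dilradiomics.pipeline import extract_features
        from dilradiomics.synthcohort import CohortConfig, generate_cohort

        cfg = CohortConfig(n_subjects=10, volume_shape=(8, 32, 32),
                           dil_radius=3, effect_size=0.0, n_group_b=0, seed=21)
        table = extract_features(generate_cohort(cfg))
        bx, by = plsc.build_blocks(table)
        sel = plsc.select_discriminant(plsc.fit_plsc(bx, by))
        assert sel.is_empty


class TestProjection:
    def test_training_rows_reproduce_scores(self, rng):
        table = _random_table(rng, n_subjects=8)
        bx, by = plsc.build_blocks(table)
        m = plsc.fit_plsc(bx, by)
        raw_x = bx.data * bx.col_scales + bx.col_means
        lx, _ = plsc.project(m, raw_x=raw_x)
        np.testing.assert_allclose(lx, m.Lx, atol=1e-10)

    def test_zero_standardized_vector_scores_zero(self, rng):
        table = _random_table(rng)
        bx, by = plsc.build_blocks(table)
        m = plsc.fit_plsc(bx, by)
        lx, ly = plsc.project(m, raw_x=bx.col_means[None, :],
                              raw_y=by.col_means[None, :])
        np.testing.assert_allclose(lx, 0.0, atol=1e-12)
        np.testing.assert_allclose(ly, 0.0, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        bx, by = plsc.build_blocks(_random_table(rng))
        m = plsc.fit_plsc(bx, by)
        with pytest.raises(ValueError, match="mismatch"):
            plsc.project(m, raw_x=np.zeros((1, 3)))

    def test_rows_score_near_their_group_centroid(self, study_model,
                                                  study_features):
        """Projected rows overwhelmingly land on their own group's side
        of the first latent (individual overlap outliers are expected in
        a stochastic cohort)."""
        m = study_model
        labels = m.block_x.roi_kinds
        sub = study_features[study_features.modality == "ADC"]
        raw = sub[m.block_y.feature_names].to_numpy(float)
        _, ly = plsc.project(m, raw_y=raw)
        lv1_all = m.Ly[:, 0]
        dil_c = lv1_all[labels == "DIL"].mean()
        nt_c = lv1_all[labels == "NT"].mean()
        kinds = sub["roi_kind"].to_numpy()
        own = np.where(kinds == "DIL", dil_c, nt_c)
        other = np.where(kinds == "DIL", nt_c, dil_c)
        frac = np.mean(np.abs(ly[:, 0] - own) < np.abs(ly[:, 0] - other))
        assert frac >= 0.85
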