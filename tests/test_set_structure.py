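import numpy as np
import pandas as pd
import pytest
from scipy import stats

from slidefx.set_structure import (
    SET_LABELS,
    build_partition,
    classify_median_methylation,
    cpg_correlation_summary,
    define_shigh,
    enrichment_anova,
    enrichment_chisq,
    neighbor_slide_enrichment,
    partition_cpg_sets,
    pca_slide_effects,
)


def _fractions(rows, cohorts=None):
    frame = pd.DataFrame(rows, index=[f"cg{i}" for i in range(len(rows))])
    if cohorts:
        frame.columns = cohorts
    return frame


class TestPartition:
    def test_max_over_cohorts_drives_label(self):
        part = partition_cpg_sets(_fractions([[0.10, 0.85, 0.30]]))
        assert part.loc["cg0", "set_label"] == "S80-100"
        assert part.loc["cg0", "max_fraction"] == 0.85

    @pytest.mark.parametrize(
        "fraction,label",
        [
            (0.0, "S0-20"),
            (0.2 - 1e-9, "S0-20"),
            (0.2, "S20-40"),
            (0.6, "S60-80"),
            (0.8, "S80-100"),  # lower edge inclusive
            (1.0, "S80-100"),
        ],
    )
    def test_bin_edges_lower_inclusive(self, fraction, label):
        part = partition_cpg_sets(_fractions([[fraction]]))
        assert part.loc["cg0", "set_label"] == label

    def test_partition_is_disjoint_cover(self, rng):
        frame = _fractions(rng.uniform(0, 1, (500, 3)))
        part = partition_cpg_sets(frame)
        assert len(part) == 500
        assert part["set_label"].isin(SET_LABELS).all()
        # label reproducible from max_fraction alone
        relabel = partition_cpg_sets(part[["max_fraction"]])
        assert (relabel["set_label"] == part["set_label"]).all()

    def test_all_missing_cpgs_excluded_with_warning(self):
        frame = _fractions([[0.5, 0.1], [np.nan, np.nan]])
        with pytest.warns(UserWarning, match="no valid fit"):
            part = partition_cpg_sets(frame)
        assert list(part.index) == ["cg0"]

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            partition_cpg_sets(_fractions([[1.2]]))


class TestShigh:
    def test_seven_of_nine_above_threshold_flags(self):
        row = [0.65] * 7 + [0.10] * 2
        flags = define_shigh(_fractions([row]), 0.60, 7)
        assert bool(flags.iloc[0])

    def test_six_of_nine_is_not_enough(self):
        row = [0.95] * 6 + [0.10] * 3
        flags = define_shigh(_fractions([row]), 0.60, 7)
        assert not bool(flags.iloc[0])

    def test_threshold_boundary_inclusive(self):
        flags = define_shigh(_fractions([[0.60] * 9]), 0.60, 9)
        assert bool(flags.iloc[0])

    def test_missing_cohorts_not_counted(self):
        row = [0.9] * 6 + [np.nan, np.nan, np.nan]
        assert not bool(define_shigh(_fractions([row]), 0.60, 7).iloc[0])

    def test_min_cohorts_above_available_rejected(self):
        with pytest.raises(ValueError, match="min_cohorts"):
            define_shigh(_fractions([[0.9, 0.9]]), 0.60, 3)

    def test_shigh_subset_of_top_sets(self, rng):
        frame = _fractions(rng.uniform(0, 1, (300, 9)))
        part = build_partition(frame, threshold=0.60, min_cohorts=1)
        flagged = part[part["in_shigh"]]
        assert flagged["set_label"].isin(["S60-80", "S80-100"]).all()


class TestSlideEffectPCA:
    def test_rank_one_matrix_single_component(self, rng):
        u = rng.normal(size=8)
        v = rng.normal(size=20)
        blups = pd.DataFrame(np.outer(u, v),
                             index=[f"sl{i}" for i in range(8)],
                             columns=[f"cg{i}" for i in range(20)])
        pca = pca_slide_effects(blups)
        assert pca.var_explained[0] == pytest.approx(1.0, abs=1e-10)
        assert np.all(pca.var_explained[1:] < 1e-10)

    def test_known_singular_values_give_exact_shares(self, rng):
        # construct a matrix with singular values (2, 1): shares (0.8, 0.2)
        q1, _ = np.linalg.qr(rng.normal(size=(10, 2)))
        q2, _ = np.linalg.qr(rng.normal(size=(15, 2)))
        mat = 2.0 * np.outer(q1[:, 0], q2[:, 0]) + 1.0 * np.outer(q1[:, 1], q2[:, 1])
        mat = mat - mat.mean(axis=0, keepdims=True)  # keep centring a no-op
        # re-orthogonalize exactly via SVD of the centred matrix
        uu, ss, vv = np.linalg.svd(mat, full_matrices=False)
        mat = (uu[:, :2] * np.array([2.0, 1.0])) @ vv[:2]
        mat = mat - mat.mean(axis=0, keepdims=True)
        blups = pd.DataFrame(mat)
        pca = pca_slide_effects(blups)
        assert pca.var_explained[0] == pytest.approx(0.8, abs=1e-6)
        assert pca.var_explained[1] == pytest.approx(0.2, abs=1e-6)

    def test_scores_orthogonal_and_variances_sum_to_one(self, rng):
        blups = pd.DataFrame(rng.normal(size=(12, 30)))
        pca = pca_slide_effects(blups)
        gram = pca.scores.to_numpy().T @ pca.scores.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8
        assert pca.var_explained.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(pca.var_explained) <= 1e-12)

    def test_reconstruction_from_all_components(self, rng):
        blups = pd.DataFrame(rng.normal(size=(10, 9)))
        pca = pca_slide_effects(blups)
        centred = blups.to_numpy() - blups.to_numpy().mean(axis=0, keepdims=True)
        recon = pca.scores.to_numpy() @ pca.loadings.to_numpy().T
        np.testing.assert_allclose(recon, centred, atol=1e-8)

    def test_sign_convention_loading_sum_nonnegative(self, rng):
        pca = pca_slide_effects(pd.DataFrame(rng.normal(size=(8, 12))))
        sums = pca.loadings.sum(axis=0).to_numpy()
        assert np.all(sums >= -1e-10)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError, match="components"):
            pca_slide_effects(pd.DataFrame(rng.normal(size=(4, 5))), n_components=4)

    def test_missing_entries_rejected(self):
        bad = pd.DataFrame([[1.0, np.nan], [0.0, 1.0], [2.0, 0.5]])
        with pytest.raises(ValueError, match="missing"):
            pca_slide_effects(bad)


class TestMedianClassification:
    def test_cutoff_at_half_with_high_ties(self):
        beta = pd.DataFrame(
            [[0.6] * 5, [0.4] * 5, [0.5] * 5], index=["a", "b", "c"]
        )
        out = classify_median_methylation(beta)
        assert list(out) == ["high", "low", "high"]

    def test_agrees_with_independent_median(self, rng):
        beta = pd.DataFrame(rng.uniform(0, 1, (200, 31)))
        out = classify_median_methylation(beta)
        for i in range(200):
            med = float(np.sort(beta.to_numpy()[i])[15])  # exact middle order stat
            assert (out.iloc[i] == "high") == (med >= 0.5)

    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            classify_median_methylation(pd.DataFrame([[1.2, 0.5]]))


class TestCorrelationSummary:
    def test_duplicated_row_has_unit_correlation(self, rng):
        x = rng.normal(size=50)
        frame = pd.DataFrame([x, x, rng.normal(size=50)])
        corr, summary = cpg_correlation_summary(frame)
        assert corr.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_independent_rows_have_low_median_abs_r(self, rng):
        frame = pd.DataFrame(rng.normal(size=(40, 500)))
        _, summary = cpg_correlation_summary(frame)
        assert summary["median"] < 0.1

    def test_shared_factor_rows_have_high_median_abs_r(self, rng):
        u = rng.normal(size=200)
        frame = pd.DataFrame(
            np.outer(rng.choice([-1.0, 1.0], 30), u) + 0.4 * rng.normal(size=(30, 200))
        )
        _, summary = cpg_correlation_summary(frame)
        assert summary["median"] > 0.5

    def test_zero_variance_row_excluded_with_warning(self, rng):
        frame = pd.DataFrame(rng.normal(size=(3, 20)))
        frame.iloc[1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            corr, _ = cpg_correlation_summary(frame)
        assert corr.shape == (2, 2)


def _neighbor_setup(n_anchor=20, n_near=40, n_far=400, near_frac=0.9, far_frac=0.1,
                    jitter=None):
    rows = []
    fracs = []
    pos = 10_000
    rng = np.random.default_rng(0)
    for i in range(n_anchor):
        rows.append((f"anchor{i}", "1", pos))
        fracs.append((f"anchor{i}", 0.95, True))
        for j in range(n_near // n_anchor):
            rows.append((f"near{i}_{j}", "1", pos + 50 + 10 * j))
            f = near_frac if jitter is None else float(rng.uniform(0, 1))
            fracs.append((f"near{i}_{j}", f, False))
        pos += 10_000
    for i in range(n_far):
        rows.append((f"far{i}", "2", 1000 + 1000 * i))
        f = far_frac if jitter is None else float(rng.uniform(0, 1))
        fracs.append((f"far{i}", f, False))
    ann = pd.DataFrame(
        [(c, p) for _, c, p in rows], index=[r[0] for r in rows],
        columns=["chromosome", "position"],
    )
    part = pd.DataFrame(
        {
            "max_fraction": [f for _, f, _ in fracs],
            "in_shigh": [s for _, _, s in fracs],
        },
        index=[c for c, _, _ in fracs],
    )
    return part, ann


class TestNeighborEnrichment:
    def test_extreme_separation_is_highly_significant(self):
        part, ann = _neighbor_setup()
        res = neighbor_slide_enrichment(part, ann, radius_bp=100)
        assert res["pvalue"] < 1e-6
        assert res["median_neighbors"] > res["median_baseline"]

    def test_window_endpoints_inclusive(self):
        ann = pd.DataFrame(
            {
                "chromosome": ["1", "1", "1", "1", "2", "2", "2"],
                "position": [1000, 900, 1100, 1101, 500, 600, 700],
            },
            index=["anchor", "edge_lo", "edge_hi", "outside", "b1", "b2", "b3"],
        )
        part = pd.DataFrame(
            {
                "max_fraction": [0.9, 0.5, 0.5, 0.5, 0.1, 0.1, 0.1],
                "in_shigh": [True, False, False, False, False, False, False],
            },
            index=ann.index,
        )
        res = neighbor_slide_enrichment(part, ann, radius_bp=100)
        # positions 900 and 1100 are neighbours; 1101 is not
        assert res["n_neighbors"] == 2
        assert res["n_baseline"] == 4

    def test_null_pvalues_uniform_over_replicates(self):
        # neighbours drawn from the same distribution as the baseline
        pvals = []
        for rep in range(200):
            part, ann = _neighbor_setup(jitter=rep)
            rng = np.random.default_rng(rep)
            part = part.copy()
            nonanchor = ~part["in_shigh"]
            part.loc[nonanchor, "max_fraction"] = rng.uniform(0, 1, int(nonanchor.sum()))
            pvals.append(neighbor_slide_enrichment(part, ann, 100)["pvalue"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_no_neighbours_is_an_error(self):
        ann = pd.DataFrame(
            {"chromosome": ["1", "2"], "position": [1000, 1000]},
            index=["anchor", "far"],
        )
        part = pd.DataFrame(
            {"max_fraction": [0.9, 0.1], "in_shigh": [True, False]}, index=ann.index
        )
        with pytest.raises(ValueError, match="no neighbours"):
            neighbor_slide_enrichment(part, ann, 100)


class TestEnrichmentTests:
    def test_chisq_equal_proportions_is_null(self):
        stat, p = enrichment_chisq([[50, 50], [50, 50]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_chisq_hand_computed_value(self):
        # Pearson formula by hand: sum (O-E)^2/E = 128 for this table
        stat, p = enrichment_chisq([[10, 90], [90, 10]])
        assert stat == pytest.approx(128.0, abs=1e-10)

    def test_chisq_matches_pearson_formula_on_random_tables(self, rng):
        for _ in range(100):
            table = rng.integers(5, 100, (2, 4)).astype(float)
            stat, _ = enrichment_chisq(table)
            # independent hand computation of the Pearson statistic
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            hand = float(((table - expected) ** 2 / expected).sum())
            assert stat == pytest.approx(hand, abs=1e-8)

    def test_chisq_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError):
            enrichment_chisq([[0, 10], [0, 20]])

    def test_anova_null_behaviour(self, rng):
        values = rng.normal(size=3000)
        groups = np.repeat(["a", "b", "c"], 1000)
        f, p = enrichment_anova(values, groups)
        assert p > 1e-4 and f < 5

    def test_anova_extreme_separation(self, rng):
        values = np.concatenate([rng.normal(0, 1, 50), rng.normal(10, 1, 50)])
        groups = np.repeat(["a", "b"], 50)
        _, p = enrichment_anova(values, groups)
        assert p < 1e-10

    def test_anova_matches_hand_f_statistic(self, rng):
        values = rng.normal(size=90)
        groups = np.repeat(["a", "b", "c"], 30)
        f, _ = enrichment_anova(values, groups)
        # independent computation from sums of squares
        grand = values.mean()
        ssb = sum(30 * (values[groups == g].mean() - grand) ** 2 for g in "abc")
        ssw = sum(((values[groups == g] - values[groups == g].mean()) ** 2).sum()
                  for g in "abc")
        hand = (ssb / 2) / (ssw / 87)
        assert f == pytest.approx(hand, abs=1e-8)

    def test_anova_small_group_rejected(self):
        with pytest.raises(ValueError, match="2 members"):
            enrichment_anova([1.0, 2.0, 3.0], ["a", "a", "b"])
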