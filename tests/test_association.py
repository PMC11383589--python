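"""Clinical statistics against brute-force oracles and planted signals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gepnet.containers import ClinicalTable, GROUP_ORDER
from gepnet.association import (
    composition_test,
    derive_gene_modules,
    dunn_posthoc,
    log_normalize,
    module_score,
    program_activity_anova,
    program_case_control,
    score_activity_correlation,
)


def make_clinical(groups, vas=None):
    n = len(groups)
    if vas is None:
        vas = np.linspace(0, 10, n)
    return ClinicalTable(pd.DataFrame({
        "sample_id": [f"S{i:02d}" for i in range(n)],
        "donor_id": [f"D{i:02d}" for i in range(n)],
        "group": groups,
        "vas_global": vas,
        "on_medication": [g == "Active" for g in groups],
    }))


def kruskal_oracle(groups):
    """Direct rank-based H statistic with tie correction."""
    all_vals = np.concatenate(groups)
    n = len(all_vals)
    ranks = stats.rankdata(all_vals)
    start, H = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        H += r.sum() ** 2 / len(g)
        start += len(g)
    H = 12.0 / (n * (n + 1)) * H - 3 * (n + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return H / tie


def welch_oracle(a, b):
    """Textbook Welch t and Satterthwaite df -> two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def anova_oracle(groups):
    """Sum-of-squares decomposition -> F."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum()
                    for g in groups)
    df_b, df_w = len(groups) - 1, len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestDunnAndKruskal:
    def test_kruskal_matches_rank_oracle_on_toy_table(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        H, _ = stats.kruskal(*groups)
        assert abs(H - kruskal_oracle(groups)) < 1e-10

    def test_dunn_z_matches_direct_computation(self):
        groups = {"A": np.array([1.0, 2, 3, 4]),
                  "B": np.array([5.0, 6, 7]),
                  "C": np.array([2.5, 3.5, 8, 9])}
        out = dunn_posthoc(groups, [("A", "B"), ("A", "C")]).set_index(
            ["group_a", "group_b"]
        )
        vals = np.concatenate(list(groups.values()))
        ranks = stats.rankdata(vals)
        rA, rB = ranks[:4].mean(), ranks[4:7].mean()
        n = len(vals)
        _, counts = np.unique(vals, return_counts=True)
        var = n * (n + 1) / 12 - np.sum(counts**3 - counts) / (12 * (n - 1))
        z_expected = (rA - rB) / np.sqrt(var * (1 / 4 + 1 / 3))
        assert abs(out.loc[("A", "B"), "z"] - z_expected) < 1e-10

    def test_null_false_positive_rate(self, rng):
        hits = 0
        for _ in range(500):
            groups = [rng.standard_normal(6) for _ in range(3)]
            _, p = stats.kruskal(*groups)
            hits += p < 0.05
        assert hits / 500 <= 0.06  # ~94%+ of null sims non-significant


class TestCompositionTest:
    @staticmethod
    def _cohort(rng, shift_ct=None):
        groups = (["HC"] * 5 + ["Inactive"] * 6 + ["Active"] * 7
                  + ["TreatmentNaive"] * 9)
        clinical = make_clinical(groups)
        counts = pd.DataFrame(
            rng.integers(50, 150, size=(27, 4)),
            index=clinical.sample_ids,
            columns=["B", "CD4T", "NK", "Myeloid"],
        )
        if shift_ct:
            tn = [s for s, g in zip(clinical.sample_ids, groups)
                  if g == "TreatmentNaive"]
            counts.loc[tn, shift_ct] += 400
        return counts, clinical

    def test_shifted_cell_type_detected_in_tn_pairs(self, rng):
        counts, clinical = self._cohort(rng, shift_ct="B")
        out = composition_test(counts, clinical)
        dunn = out[(out["unit"] == "B") & (out["test"] == "dunn")]
        tn_rows = dunn[dunn["comparison"].str.startswith("TreatmentNaive")]
        assert (tn_rows["p_adj"] < 0.05).all()
        assert (tn_rows["direction"] == "up").all()

    def test_adjusted_p_at_least_raw(self, rng):
        counts, clinical = self._cohort(rng)
        out = composition_test(counts, clinical)
        with_adj = out.dropna(subset=["p_adj"])
        assert (with_adj["p_adj"] >= with_adj["p"] - 1e-12).all()

    def test_compositional_closure_gives_opposed_spearman_signs(self):
        # one cell type strictly increases with VAS; the other compensates
        n = 20
        groups = (["HC"] * 5 + ["Inactive"] * 5 + ["Active"] * 5
                  + ["TreatmentNaive"] * 5)
        clinical = make_clinical(groups, vas=np.linspace(0, 10, n))
        up = np.arange(50, 50 + n)
        down = 200 - up
        counts = pd.DataFrame({"up_ct": up, "down_ct": down},
                              index=clinical.sample_ids)
        out = composition_test(counts, clinical)
        sp = out[out["test"] == "spearman_vas"].set_index("unit")
        assert sp.loc["up_ct", "statistic"] == pytest.approx(1.0)
        assert sp.loc["down_ct", "statistic"] == pytest.approx(-1.0)

    def test_small_group_skipped_not_fatal(self, rng, caplog):
        groups = (["HC"] * 1 + ["Inactive"] * 9 + ["Active"] * 8
                  + ["TreatmentNaive"] * 9)
        clinical = make_clinical(groups)
        counts = pd.DataFrame(
            rng.integers(50, 150, size=(27, 2)),
            index=clinical.sample_ids, columns=["B", "NK"],
        )
        with caplog.at_level("WARNING"):
            out = composition_test(counts, clinical)
        assert not out[out["comparison"] == "Inactive_vs_HC"].shape[0]


class TestCaseControl:
    def test_welch_matches_textbook_oracle(self):
        groups = ["TreatmentNaive"] * 3 + ["HC"] * 3
        clinical = make_clinical(groups)
        scores = pd.DataFrame(
            {"p1": [2.0, 4, 6, 1, 3, 5]}, index=clinical.sample_ids
        )
        out = program_case_control(scores, clinical).iloc[0]
        t_exp, p_exp = welch_oracle([2, 4, 6], [1, 3, 5])
        assert abs(out["statistic"] - t_exp) < 1e-10
        assert abs(out["p"] - p_exp) < 1e-10

    def test_null_p_centered(self, rng):
        groups = ["Active"] * 22 + ["HC"] * 5
        clinical = make_clinical(groups)
        ps = []
        for _ in range(200):
            scores = pd.DataFrame({"p1": rng.standard_normal(27)},
                                  index=clinical.sample_ids)
            ps.append(program_case_control(scores, clinical)["p"].iloc[0])
        assert 0.4 < np.mean(ps) < 0.6

    def test_degenerate_zero_variance_flagged(self):
        groups = ["Active"] * 3 + ["HC"] * 3
        clinical = make_clinical(groups)
        scores = pd.DataFrame({"p1": [1.0] * 6}, index=clinical.sample_ids)
        out = program_case_control(scores, clinical).iloc[0]
        assert out["p"] == 1.0 and out["degenerate"]


class TestActivityAnova:
    def test_f_matches_sum_of_squares_oracle(self):
        groups = (["HC"] * 3 + ["Inactive"] * 3 + ["Active"] * 3
                  + ["TreatmentNaive"] * 3)
        clinical = make_clinical(groups)
        vals = [1.0, 2, 3, 2, 3, 4, 6, 7, 8, 6.5, 7.5, 8.5]
        scores = pd.DataFrame({"p1": vals}, index=clinical.sample_ids)
        out = program_activity_anova(scores, clinical)
        F = out[out["test"] == "anova"]["statistic"].iloc[0]
        oracle = anova_oracle([vals[0:3], vals[3:6], vals[6:9], vals[9:12]])
        assert abs(F - oracle) < 1e-10

    def test_three_group_layout_oracle(self):
        # printed toy layout: 3 groups x 3 values
        toy = [[1.0, 2, 3], [4.0, 5, 6], [7.0, 8, 9]]
        F, _ = stats.f_oneway(*toy)
        assert abs(F - anova_oracle(toy)) < 1e-10

    def test_pure_tn_shift_flags_only_tn_pairs(self, rng):
        groups = (["HC"] * 5 + ["Inactive"] * 6 + ["Active"] * 7
                  + ["TreatmentNaive"] * 9)
        clinical = make_clinical(groups)
        x = rng.standard_normal(27) * 0.3
        x[18:] += 5.0  # large TreatmentNaive shift
        scores = pd.DataFrame({"p1": x}, index=clinical.sample_ids)
        out = program_activity_anova(scores, clinical)
        tukey = out[out["test"] == "tukey"]
        tn = tukey["comparison"].str.contains("TreatmentNaive")
        assert (tukey[tn]["p"] < 0.01).all()
        assert (tukey[~tn]["p"] > 0.05).all()

    def test_null_f_calibrated(self, rng):
        from scipy.stats import kstest

        groups = (["HC"] * 5 + ["Inactive"] * 6 + ["Active"] * 7
                  + ["TreatmentNaive"] * 9)
        clinical = make_clinical(groups)
        ps = []
        for _ in range(300):
            scores = pd.DataFrame({"p1": rng.standard_normal(27)},
                                  index=clinical.sample_ids)
            out = program_activity_anova(scores, clinical)
            ps.append(out[out["test"] == "anova"]["p"].iloc[0])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_missing_group_named_in_error(self):
        clinical = make_clinical(["HC"] * 3 + ["Active"] * 3
                                 + ["TreatmentNaive"] * 3
                                 + ["Inactive"] * 1)
        scores = pd.DataFrame({"p1": np.arange(10.0)},
                              index=clinical.sample_ids)
        with pytest.raises(ValueError, match="Inactive"):
            program_activity_anova(scores, clinical)


class TestGeneModules:
    @staticmethod
    def _block_expression(rng):
        # two orthogonal blocks over (sample, cell type) profiles
        cols = pd.MultiIndex.from_product(
            [[f"S{i}" for i in range(6)], ["B", "NK"]]
        )
        up = np.array([1.0, 1, 1, -1, -1, -1] * 2).reshape(2, 6).T.ravel()
        rows = {}
        for g in range(5):
            rows[f"IFN{g}"] = np.tile([3.0, 3, 3, 0, 0, 0], 2) \
                + rng.normal(0, 0.05, 12)
        for g in range(4):
            rows[f"RIBO{g}"] = np.tile([0.0, 0, 0, 3, 3, 3], 2) \
                + rng.normal(0, 0.05, 12)
        return pd.DataFrame(rows).T.set_axis(cols, axis=1)

    def test_two_planted_blocks_recovered_exactly(self, rng):
        expr = self._block_expression(rng)
        de = {"B": list(expr.index), "NK": list(expr.index)}
        modules = derive_gene_modules(de, expr, n_modules=2)
        sets = [set(m["genes"]) for m in modules]
        assert {g for g in expr.index if g.startswith("IFN")} in sets
        assert {g for g in expr.index if g.startswith("RIBO")} in sets

    def test_matches_reference_agglomerative_implementation(self, rng):
        from sklearn.cluster import AgglomerativeClustering

        expr = pd.DataFrame(
            rng.random((20, 6)),
            index=[f"G{i:02d}" for i in range(20)],
            columns=pd.MultiIndex.from_product(
                [["S1", "S2", "S3"], ["B", "NK"]]
            ),
        )
        de = {"B": list(expr.index), "NK": list(expr.index)}
        modules = derive_gene_modules(de, expr, n_modules=4)
        M = expr.to_numpy()
        M = (M - M.mean(1, keepdims=True)) / M.std(1, ddof=0, keepdims=True)
        ref = AgglomerativeClustering(n_clusters=4, linkage="complete",
                                      metric="euclidean").fit_predict(M)
        ours = np.empty(20, dtype=int)
        for mid, m in enumerate(modules):
            for g in m["genes"]:
                ours[list(expr.index).index(g)] = mid
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(ref, ours) == 1.0

    def test_gene_in_single_cell_type_excluded(self, rng):
        expr = self._block_expression(rng)
        de = {"B": list(expr.index), "NK": [g for g in expr.index
                                            if g != "IFN0"]}
        modules = derive_gene_modules(de, expr, n_modules=2)
        all_genes = {g for m in modules for g in m["genes"]}
        assert "IFN0" not in all_genes

    def test_too_few_shared_genes_rejected(self, rng):
        expr = self._block_expression(rng)
        de = {"B": ["IFN0"], "NK": ["RIBO0"]}
        with pytest.raises(ValueError):
            derive_gene_modules(de, expr, n_modules=2)


class TestModuleScore:
    def test_all_zero_matrix_scores_zero(self):
        expr = pd.DataFrame(
            np.zeros((30, 10)),
            index=[f"G{i:02d}" for i in range(30)],
        )
        s = module_score(expr, ["G00", "G05"], seed=0)
        assert np.allclose(s, 0.0)

    def test_degenerate_single_bin_matches_direct_mean_difference(self, rng):
        expr = pd.DataFrame(
            rng.random((40, 8)), index=[f"G{i:02d}" for i in range(40)]
        )
        gset = ["G00", "G10", "G20"]
        # n_ctrl large: control mean over a single bin converges to the
        # all-gene mean only in expectation; instead compare the exact
        # construction with every gene as its own control draw
        s = module_score(expr, gset, n_bins=1, n_ctrl=5000, seed=1)
        direct = expr.loc[gset].mean(axis=0) - expr.mean(axis=0)
        assert np.allclose(s, direct, atol=0.02)

    def test_matched_distribution_scores_near_zero(self, rng):
        # every gene iid: the set matches its control pool by construction
        expr = pd.DataFrame(
            rng.normal(1.0, 0.2, size=(200, 1000)),
            index=[f"G{i:03d}" for i in range(200)],
        )
        gset = [f"G{i:03d}" for i in range(0, 200, 4)]
        s = module_score(expr, gset, seed=3)
        assert abs(s.mean()) < 0.01

    def test_absent_set_lists_missing_genes(self, rng):
        expr = pd.DataFrame(rng.random((5, 3)),
                            index=["A", "B", "C", "D", "E"])
        with pytest.raises(ValueError, match="missing"):
            module_score(expr, ["ZZZ"], seed=0)

    def test_log_normalize_scales_cells(self):
        counts = pd.DataFrame({"c1": [10, 0, 10], "c2": [1, 1, 2]},
                              index=["G1", "G2", "G3"])
        ln = log_normalize(counts, target_sum=100)
        assert ln["c1"].iloc[0] == pytest.approx(np.log1p(50))
        assert ln["c2"].iloc[1] == pytest.approx(np.log1p(25))


class TestCollapseDonors:
    def test_longitudinal_samples_averaged_within_donor(self):
        from gepnet.association import collapse_donors

        table = pd.DataFrame({
            "sample_id": ["S1", "S2", "S3"],
            "donor_id": ["D1", "D1", "D2"],
            "group": ["Active", "Inactive", "HC"],
            "vas_global": [5.0, 1.0, 0.0],
            "on_medication": [True, False, False],
        })
        clinical = ClinicalTable(table)
        scores = pd.DataFrame({"p1": [2.0, 4.0, 10.0]},
                              index=["S1", "S2", "S3"])
        collapsed, donor_clinical = collapse_donors(scores, clinical)
        assert collapsed.loc["D1", "p1"] == pytest.approx(3.0)
        assert collapsed.loc["D2", "p1"] == pytest.approx(10.0)
        assert len(donor_clinical) == 2
        assert donor_clinical.groups()["D1"] == "Active"


class TestActivityCorrelation:
    def test_identity_scores_give_rho_one(self):
        groups = ["Active"] * 10
        clinical = make_clinical(groups, vas=np.linspace(1, 9, 10))
        scores = pd.DataFrame({"p1": clinical.vas().to_numpy()},
                              index=clinical.sample_ids)
        out = score_activity_correlation(scores, clinical)
        assert out["statistic"].iloc[0] == pytest.approx(1.0)

    def test_null_rho_within_bounds(self, rng):
        groups = ["Active"] * 27
        clinical = make_clinical(groups, vas=rng.random(27) * 10)
        hits = 0
        for _ in range(100):
            scores = pd.DataFrame({"p1": rng.standard_normal(27)},
                                  index=clinical.sample_ids)
            rho = score_activity_correlation(scores, clinical)[
                "statistic"].iloc[0]
            hits += abs(rho) < 0.4
        assert hits >= 93

    def test_constant_scores_flagged(self):
        clinical = make_clinical(["HC"] * 6)
        scores = pd.DataFrame({"p1": [2.0] * 6}, index=clinical.sample_ids)
        out = score_activity_correlation(scores, clinical)
        assert out["degenerate"].iloc[0]
        assert np.isnan(out["statistic"].iloc[0])

    def test_planted_biomarker_tracks_vas(self, multi_type_cohort):
        ds = multi_type_cohort
        adt_sample = ds.adt.join(
            ds.cell_metadata.set_index("barcode")["sample_id"]
        ).groupby("sample_id").mean()
        out = score_activity_correlation(adt_sample, ds.clinical,
                                         family="biomarker")
        assert out["statistic"].iloc[0] >= 0.6
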