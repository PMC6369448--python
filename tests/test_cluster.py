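"""Cluster assembly, quality scoring, MAF binning and ROC calibration."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from popvar import cluster as cl
from popvar import datasets
from popvar.cluster import _auc_rank, _brute_silhouette
from popvar.containers import GenotypeMatrix, IntensityTable
from popvar.exceptions import DataError


def make_intensity_and_calls(points, labels, batches=None):
    """One-variant containers from explicit points and call labels."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if batches is None:
        batches = np.zeros(n, dtype=int)
    samples = [f"s{i}" for i in range(n)]
    intens = IntensityTable(
        a=pts[:, 0][:, None], b=pts[:, 1][:, None],
        sample_ids=samples, variant_ids=["v"], batch_ids=np.asarray(batches),
    )
    geno = GenotypeMatrix(
        np.asarray(labels, dtype=np.int8)[:, None], samples, ["v"],
        np.asarray(batches),
    )
    return intens, geno


class TestAssembleAndFit:
    def test_merges_all_batches(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(30, 2)) + 5
        batches = np.repeat([0, 1, 2], 10)
        intens, geno = make_intensity_and_calls(pts, [0] * 30, batches)
        data = cl.assemble_cluster_data(intens, geno, "v")
        assert len(data.points) == 30
        assert data.n_batches_present == 3

    def test_class_point_counts_match_genotype_column(self, small_cohort):
        vid = small_cohort.panel.loc[
            small_cohort.panel.quality_class == "true_poly_good", "variant_id"
        ].iloc[0]
        data = cl.assemble_cluster_data(
            small_cohort.intensities, small_cohort.observed_genotypes, vid
        )
        col = small_cohort.observed_genotypes.column(vid)
        for g in (0, 1, 2):
            assert (data.points.called_genotype == g).sum() == (col == g).sum()

    def test_unknown_variant_errors(self, small_cohort):
        with pytest.raises(DataError):
            cl.assemble_cluster_data(
                small_cohort.intensities, small_cohort.observed_genotypes, "nope"
            )

    def test_fitted_centers_recover_truth(self):
        rng = np.random.default_rng(1)
        n = 400
        pts = np.vstack(
            [rng.normal([10, 0], 1.0, size=(n, 2)), rng.normal([0, 10], 1.0, size=(n, 2))]
        )
        labels = [0] * n + [1] * n
        intens, geno = make_intensity_and_calls(pts, labels)
        model = cl.fit_cluster_model(cl.assemble_cluster_data(intens, geno, "v"))
        se = 1.0 / np.sqrt(n)
        assert np.allclose(model.components[0]["center"], [10, 0], atol=3 * se)
        assert np.allclose(model.components[1]["center"], [0, 10], atol=3 * se)
        assert model.components[0]["weight"] == pytest.approx(0.5)

    def test_single_class_model(self):
        pts = np.random.default_rng(2).normal([3, 3], 0.1, size=(20, 2))
        intens, geno = make_intensity_and_calls(pts, [0] * 20)
        model = cl.fit_cluster_model(cl.assemble_cluster_data(intens, geno, "v"))
        assert model.classes_present == (0,)
        assert model.components[0]["weight"] == 1.0

    def test_singleton_class_uses_pooled_spherical(self):
        pts = np.vstack([np.random.default_rng(3).normal([3, 3], 0.2, size=(20, 2)),
                         [[8.0, 8.0]]])
        intens, geno = make_intensity_and_calls(pts, [0] * 20 + [1])
        model = cl.fit_cluster_model(cl.assemble_cluster_data(intens, geno, "v"))
        cov = model.components[1]["cov"]
        assert np.all(np.isfinite(cov)) and cov[0, 0] > 0

    def test_fewer_than_two_points_errors(self):
        intens, geno = make_intensity_and_calls([[1.0, 1.0]], [0])
        with pytest.raises(DataError):
            cl.fit_cluster_model(cl.assemble_cluster_data(intens, geno, "v"))


class TestSeparationStatistics:
    def two_cluster_fixture(self, d, sigma):
        # four points per class arranged so the sample covariance has
        # largest-axis SD exactly sigma (after small-class shrinkage)
        a = sigma * np.sqrt(1.5)
        offsets = np.array([[a, 0], [-a, 0], [0, a], [0, -a]])
        pts = np.vstack([offsets, offsets + [d, 0]])
        labels = [0] * 4 + [1] * 4
        return make_intensity_and_calls(pts, labels)

    def test_point_mass_clusters_exact_ratio(self):
        intens, geno = self.two_cluster_fixture(d=6.0, sigma=1.0)
        model = cl.fit_cluster_model(cl.assemble_cluster_data(intens, geno, "v"))
        sep, _, _ = cl.separation_statistics(model)
        # intensities are stored float32, hence the modest tolerance
        assert sep == pytest.approx(6.0, rel=1e-5)

    def test_duplicated_clusters_zero_separation(self):
        intens, geno = self.two_cluster_fixture(d=0.0, sigma=1.0)
        model = cl.fit_cluster_model(cl.assemble_cluster_data(intens, geno, "v"))
        sep, _, _ = cl.separation_statistics(model)
        assert sep == 0.0

    def test_single_class_zero_separation(self):
        pts = np.random.default_rng(4).normal([2, 2], 0.1, size=(30, 2))
        intens, geno = make_intensity_and_calls(pts, [0] * 30)
        model = cl.fit_cluster_model(cl.assemble_cluster_data(intens, geno, "v"))
        sep, noise, _ = cl.separation_statistics(model)
        assert sep == 0.0 and noise > 0

    def test_silhouette_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        xy = np.vstack([rng.normal(0, 1, (6, 2)), rng.normal(4, 1, (6, 2))])
        labels = np.array([0] * 6 + [1] * 6)
        ours = _brute_silhouette(xy, labels)
        assert ours == pytest.approx(float(silhouette_score(xy, labels)), rel=1e-9)


class TestAssignQualityScore:
    def test_no_discernible_clusters_scores_low(self):
        qa = cl.assign_quality_score(0.0, 0.2, n_rare_calls=40)
        assert qa.score <= 2 and qa.group == "low"

    def test_clear_separation_scores_five(self):
        qa = cl.assign_quality_score(6.0, 0.1, n_rare_calls=40)
        assert qa.score == 5 and qa.group == "high"

    def test_intermediate_is_unclear(self):
        qa = cl.assign_quality_score(2.0, 0.1, n_rare_calls=40)
        assert qa.score == 3 and qa.group == "unclear"

    def test_noisy_variants_of_each_level(self):
        assert cl.assign_quality_score(6.0, 0.9, 40).score == 4
        assert cl.assign_quality_score(0.5, 0.9, 40).score == 2
        assert cl.assign_quality_score(0.5, 0.1, 40).score == 1

    def test_too_few_rare_calls_caps_score(self):
        assert cl.assign_quality_score(8.0, 0.1, n_rare_calls=3).score == 2
        assert cl.assign_quality_score(8.0, 0.1, n_rare_calls=0).score == 1

    def test_monotone_in_separation(self):
        for noise in (0.1, 0.9):
            scores = [
                cl.assign_quality_score(s, noise, 40).score
                for s in np.linspace(0, 8, 60)
            ]
            assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_group_score_consistency(self):
        for sep in np.linspace(0, 8, 30):
            qa = cl.assign_quality_score(sep, 0.3, 40)
            expected = {1: "low", 2: "low", 3: "unclear", 4: "high", 5: "high"}
            assert qa.group == expected[qa.score]


class TestScorePanelOnSyntheticData:
    def test_good_variants_outscore_smears_across_seeds(self):
        """Mean automated score of real well-assayed variants exceeds the
        mean score of monomorphic smears in every seeded replicate."""
        from popvar import simulate as sim

        for seed in range(5):
            probs = tuple(
                {"true_poly_good": 0.5, "true_poly_noisy": 0.0, "monomorphic_smear": 0.5}
                for _ in range(8)
            )
            cfg = sim.SimConfig(
                master_seed=seed, n_samples=4000, n_variants=24, n_batches=6,
                maf_range=(2e-3, 1e-2), quality_class_probs=probs,
            )
            coh = sim.simulate_cohort(cfg)
            qa = cl.score_panel(coh.intensities, coh.observed_genotypes)
            merged = qa.merge(coh.panel, on="variant_id")
            means = merged.groupby("quality_class")["score"].mean()
            assert means["true_poly_good"] > means["monomorphic_smear"]

    def test_silhouette_good_exceeds_noisy_same_seed(self, small_cohort):
        qa = cl.score_panel(
            small_cohort.intensities,
            small_cohort.observed_genotypes,
            compute_silhouette=True,
        )
        merged = qa.merge(small_cohort.panel, on="variant_id")
        sil = merged.dropna(subset=["silhouette"]).groupby("quality_class")[
            "silhouette"
        ].mean()
        assert sil["true_poly_good"] > sil["true_poly_noisy"]


class TestManualScores:
    def table(self, scores):
        return pd.DataFrame(
            {"variant_id": [f"v{i}" for i in range(len(scores))], "score": scores}
        )

    def test_average_and_retention_boundary(self):
        out = cl.ingest_manual_scores(self.table([5, 4]), self.table([4, 4]))
        assert out.loc[out.variant_id == "v0", "avg_score"].iloc[0] == 4.5
        assert bool(out.loc[out.variant_id == "v0", "retained"].iloc[0])
        # average exactly 4 is NOT retained (strict >)
        assert out.loc[out.variant_id == "v1", "avg_score"].iloc[0] == 4.0
        assert not bool(out.loc[out.variant_id == "v1", "retained"].iloc[0])

    def test_single_scorer_unclear(self):
        out = cl.ingest_manual_scores(self.table([3]))
        assert out.loc[0, "group"] == "unclear" and not out.loc[0, "retained"]

    def test_average_group_boundaries(self):
        out = cl.ingest_manual_scores(self.table([2, 3]), self.table([2, 2]))
        assert out.loc[out.variant_id == "v0", "group"].iloc[0] == "low"  # 2.0
        assert out.loc[out.variant_id == "v1", "group"].iloc[0] == "unclear"  # 2.5

    def test_out_of_range_errors(self):
        with pytest.raises(DataError):
            cl.ingest_manual_scores(self.table([6]))

    def test_scorer_agreement_identical(self):
        r2, agree = cl.scorer_agreement([1, 2, 4, 5], [1, 2, 4, 5])
        assert r2 == pytest.approx(1.0) and agree == 100.0

    def test_scorer_agreement_hand_computed(self):
        # Pearson r of (1,2,4,5) vs (2,1,5,4) is 0.8 -> r^2 = 0.64;
        # both reviewers agree on low-vs-high for all four variants
        r2, agree = cl.scorer_agreement([1, 2, 4, 5], [2, 1, 5, 4])
        assert r2 == pytest.approx(0.64)
        assert agree == 100.0

    def test_unclear_excluded_from_agreement(self):
        _, agree = cl.scorer_agreement([1, 3, 5, 1], [5, 1, 5, 1])
        # decisive pairs: (1,5) disagree, (5,5) agree, (1,1) agree
        assert agree == pytest.approx(100 * 2 / 3)

    def test_constant_scores_error(self):
        with pytest.raises(DataError, match="constant"):
            cl.scorer_agreement([1, 1, 1, 1], [1, 2, 3, 4])


class TestMafBinning:
    def test_reference_counts_reproduce_published_totals(self):
        expanded = cl.expand_bin_table(datasets.ukb_quality_by_maf_bin())
        table = cl.bin_by_maf(expanded)
        totals = table[table.bin_lo.isna()].iloc[0]
        assert totals["fp"] == 2928
        assert totals["tp"] == 1244
        assert totals["unclear"] == 413
        assert totals["total"] == 4585
        # and per-bin counts survive the round trip through binning
        body = table.dropna(subset=["bin_lo"]).reset_index(drop=True)
        ref = datasets.ukb_quality_by_maf_bin()
        assert (body[["fp", "tp", "unclear"]].to_numpy()
                == ref[["fp", "tp", "unclear"]].to_numpy()).all()

    def test_empty_panel_all_zero(self):
        table = cl.bin_by_maf(pd.DataFrame(columns=["maf_pct", "group"]))
        assert table.dropna(subset=["bin_lo"])[["fp", "tp", "unclear"]].sum().sum() == 0

    def test_boundary_goes_to_upper_bin(self):
        panel = pd.DataFrame({"maf_pct": [0.001], "group": ["high"]})
        table = cl.bin_by_maf(panel, include_total=False)
        row = table[np.isclose(table.bin_lo, 0.001)].iloc[0]
        assert row["tp"] == 1

    def test_common_variant_errors(self):
        panel = pd.DataFrame({"maf_pct": [1.5], "group": ["high"]})
        with pytest.raises(DataError):
            cl.bin_by_maf(panel)

    def test_counts_conserved(self, small_cohort):
        rng = np.random.default_rng(0)
        panel = pd.DataFrame(
            {
                "maf_pct": rng.uniform(0, 1, 500),
                "group": rng.choice(["low", "high", "unclear"], 500),
            }
        )
        table = cl.bin_by_maf(panel, include_total=False)
        assert table["total"].sum() == 500


class TestFprAtThreshold:
    def test_published_counts_at_low_threshold(self):
        table = datasets.ukb_quality_by_maf_bin()
        fpr = cl.fpr_at_maf_threshold(table, 0.001)
        assert fpr == pytest.approx(1810 / 3046)
        assert round(100 * fpr) in (59, 60)

    def test_published_counts_at_higher_threshold(self):
        fpr = cl.fpr_at_maf_threshold(datasets.ukb_quality_by_maf_bin(), 0.005)
        assert fpr == pytest.approx(212 / 1230)

    def test_all_high_quality_gives_zero(self):
        panel = pd.DataFrame({"maf_pct": [0.2, 0.4, 0.6], "group": ["high"] * 3})
        assert cl.fpr_at_maf_threshold(panel, 0.1) == 0.0

    def test_misaligned_threshold_errors(self):
        with pytest.raises(DataError):
            cl.fpr_at_maf_threshold(datasets.ukb_quality_by_maf_bin(), 0.002)

    def test_threshold_above_all_mafs_errors(self):
        panel = pd.DataFrame({"maf_pct": [0.2], "group": ["high"]})
        with pytest.raises(DataError):
            cl.fpr_at_maf_threshold(panel, 0.9)


def auc_oracle(maf, is_high):
    """O(n^2) pairwise concordance with ties counted one half."""
    maf = np.asarray(maf, dtype=float)
    hi = maf[np.asarray(is_high)]
    lo = maf[~np.asarray(is_high)]
    wins = (hi[:, None] > lo[None, :]).sum() + 0.5 * (hi[:, None] == lo[None, :]).sum()
    return wins / (len(hi) * len(lo))


class TestRoc:
    def test_perfect_separation(self):
        maf = [0.001, 0.002, 0.1, 0.2]
        group = ["low", "low", "high", "high"]
        res = cl.roc_maf_vs_quality(maf, group, n_boot=50, seed=0)
        assert res.auc == 1.0

    def test_auc_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(6)
        n = 2000
        maf = np.round(10 ** rng.uniform(-3, 0, n), 4)  # plenty of ties
        is_high = rng.random(n) < 0.3
        group = np.where(is_high, "high", "low")
        res = cl.roc_maf_vs_quality(maf, group, n_boot=10, seed=0)
        assert res.auc == pytest.approx(auc_oracle(maf, is_high), rel=1e-12)
        assert res.auc == pytest.approx(_auc_rank(maf, is_high), rel=1e-12)

    def test_reference_binned_auc(self):
        expanded = cl.expand_bin_table(datasets.ukb_quality_by_maf_bin())
        res = cl.roc_maf_vs_quality(
            expanded["maf_pct"], expanded["group"], n_boot=100, seed=1
        )
        # concordance sum enumerated by hand over the binned counts:
        # sum_i tp_i * (cumulative fp below bin i + fp_i / 2) = 3,355,788
        assert res.auc == pytest.approx(3_355_788 / (1244 * 2928), abs=1e-12)
        assert res.auc == pytest.approx(0.921, abs=0.001)
        assert res.ci[0] < res.auc < res.ci[1]
        assert res.fpr_at_thresholds[0.001] == pytest.approx(1810 / 3046)

    def test_null_auc_near_half(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            maf = rng.uniform(0, 1, 1000)
            group = np.where(rng.random(1000) < 0.5, "high", "low")
            aucs.append(cl.roc_maf_vs_quality(maf, group, n_boot=10, seed=0).auc)
        assert all(0.45 <= a <= 0.55 for a in aucs)

    def test_single_class_errors(self):
        with pytest.raises(DataError):
            cl.roc_maf_vs_quality([0.1, 0.2], ["high", "high"], n_boot=10)

    def test_curve_monotone(self):
        rng = np.random.default_rng(8)
        maf = rng.uniform(0, 1, 300)
        group = np.where(rng.random(300) < maf, "high", "low")
        res = cl.roc_maf_vs_quality(maf, group, n_boot=10, seed=0)
        tpr = res.curve_points.sort_values("fpr")["tpr"].to_numpy()
        assert np.all(np.diff(tpr) >= -1e-12)
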