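import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pmdkit import regions


def bh_oracle(pvals):
    """Hand enumeration of the Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def cpg_frame(positions, betas, coverage=10, chrom="c", score=None):
    df = pd.DataFrame({
        "chrom": chrom,
        "start": positions,
        "end": np.asarray(positions) + 2,
        "beta": betas,
        "coverage": coverage,
    })
    if score is not None:
        df["score"] = score
    return df


def region_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestRegionMeans:
    def test_simple_mean(self):
        sample = cpg_frame([10, 20], [0.2, 0.4])
        out = regions.region_means(region_frame([("c", 0, 100)]), {"s": sample})
        assert out["mean_s"].tolist() == [pytest.approx(0.3)]
        assert out["n_s"].tolist() == [2]

    def test_low_coverage_gives_absent_mean(self):
        sample = cpg_frame([10], [0.2], coverage=4)
        out = regions.region_means(region_frame([("c", 0, 100)]), {"s": sample}, min_coverage=5)
        assert np.isnan(out["mean_s"].iloc[0])

    def test_solo_wcgw_restriction_without_flagged_cpgs(self):
        sample = cpg_frame([10, 20], [0.2, 0.4], score=[0.1, 0.5])
        out = regions.region_means(
            region_frame([("c", 0, 100)]), {"s": sample},
            restriction="solo_wcgw", wcgw_min_score=0.9,
        )
        assert np.isnan(out["mean_s"].iloc[0])

    def test_invariant_to_cpg_and_sample_order(self, rng):
        pos = np.sort(rng.choice(5000, size=60, replace=False))
        betas = rng.uniform(size=60)
        s1 = cpg_frame(pos, betas)
        shuffled = s1.sample(frac=1, random_state=3).reset_index(drop=True)
        shuffled = shuffled.sort_values("start").reset_index(drop=True)
        regs = region_frame([("c", 0, 2500), ("c", 2500, 5000)])
        a = regions.region_means(regs, {"x": s1, "y": s1})
        b = regions.region_means(regs, {"y": shuffled, "x": s1})
        np.testing.assert_allclose(a["mean_x"], b["mean_y"])


class TestTileMeans:
    def test_tile_average_and_empty_tile(self):
        sample = cpg_frame([100, 200], [1.0, 0.0])
        out = regions.tile_means({"s": sample}, {"c": 20_000}, tile_bp=10_000)["s"]
        assert out["mean_beta"].iloc[0] == pytest.approx(0.5)
        assert np.isnan(out["mean_beta"].iloc[1])

    def test_masked_cgi_removed_before_averaging(self):
        sample = cpg_frame([100, 5000], [1.0, 0.0])
        mask = region_frame([("c", 4000, 6000)])
        out = regions.tile_means({"s": sample}, {"c": 10_000}, tile_bp=10_000, mask=mask)["s"]
        assert out["mean_beta"].iloc[0] == pytest.approx(1.0)


class TestClassifyRegions:
    def means(self, rows_a, rows_b, n_regions=None):
        n = n_regions or len(rows_a)
        base = region_frame([("c", i * 100, i * 100 + 100) for i in range(n)])
        ma, mb = base.copy(), base.copy()
        for j in range(len(rows_a[0])):
            ma[f"mean_a{j}"] = [r[j] for r in rows_a]
        for j in range(len(rows_b[0])):
            mb[f"mean_b{j}"] = [r[j] for r in rows_b]
        ma.columns = [c.replace("mean_a", "mean_s") for c in ma.columns]
        mb.columns = [c.replace("mean_b", "mean_s") for c in mb.columns]
        return ma, mb

    def test_separated_groups_called_tumor_specific(self):
        ma, mb = self.means([[0.1, 0.12, 0.09, 0.11]], [[0.9, 0.88, 0.91, 0.9]])
        out = regions.classify_regions(ma, mb, fdr_threshold=0.1, alternative="less")
        assert out["label"].tolist() == ["tumor_specific"]
        assert out["pvalue"].iloc[0] < 1e-4
        # Welch statistic cross-check
        expect = stats.ttest_ind(
            [0.1, 0.12, 0.09, 0.11], [0.9, 0.88, 0.91, 0.9],
            equal_var=False, alternative="less",
        ).pvalue
        assert out["pvalue"].iloc[0] == pytest.approx(expect)

    def test_identical_groups_not_tumor_specific(self):
        ma, mb = self.means([[0.5, 0.52, 0.48]], [[0.5, 0.52, 0.48]])
        out = regions.classify_regions(ma, mb, fdr_threshold=0.1)
        assert out["pvalue"].iloc[0] >= 0.5
        assert out["label"].tolist() == ["cell_type_specific"]

    def test_zero_variance_identical_means_p_one(self):
        ma, mb = self.means([[0.4, 0.4]], [[0.4, 0.4]])
        out = regions.classify_regions(ma, mb, fdr_threshold=0.1)
        assert out["pvalue"].iloc[0] == 1.0

    def test_untested_regions_reported_and_conserved(self):
        ma, mb = self.means([[0.1, 0.2], [np.nan, 0.2]], [[0.9, 0.8], [0.9, 0.8]])
        out = regions.classify_regions(ma, mb, fdr_threshold=0.1)
        assert sorted(out["label"]) == ["tumor_specific", "untested"]
        assert len(out) == 2

    def test_fdr_threshold_required(self):
        ma, mb = self.means([[0.1, 0.2]], [[0.9, 0.8]])
        with pytest.raises(ValueError, match="required"):
            regions.classify_regions(ma, mb, fdr_threshold=None)

    def test_null_simulation_type_i_control(self):
        r = np.random.default_rng(7)
        n, k = 1000, 4
        base = region_frame([("c", i * 100, i * 100 + 100) for i in range(n)])
        ma, mb = base.copy(), base.copy()
        for j in range(k):
            ma[f"mean_s{j}"] = r.uniform(0.3, 0.7, n)
            mb[f"mean_s{j}"] = r.uniform(0.3, 0.7, n)
        out = regions.classify_regions(ma, mb, fdr_threshold=0.1)
        rate = (out["label"] == "tumor_specific").mean()
        assert rate <= 0.12


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        ma, mb = TestClassifyRegions().means(
            [[0.1, 0.2]] * 4, [[0.9, 0.8]] * 4
        )
        out = regions.classify_regions(ma, mb, fdr_threshold=0.1)
        # direct check of the adjustment machinery against the known example
        from statsmodels.stats.multitest import multipletests
        q = multipletests([0.01, 0.02, 0.04, 0.8], method="fdr_bh")[1]
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.8])
        np.testing.assert_allclose(q, bh_oracle([0.01, 0.02, 0.04, 0.8]))

    def test_matches_step_up_oracle_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(25):
            p = rng.uniform(size=rng.integers(2, 21))
            np.testing.assert_allclose(
                multipletests(p, method="fdr_bh")[1], bh_oracle(p), atol=1e-12
            )

    def test_q_at_least_p(self):
        r = np.random.default_rng(5)
        base = region_frame([("c", i * 10, i * 10 + 10) for i in range(50)])
        ma, mb = base.copy(), base.copy()
        for j in range(3):
            ma[f"mean_s{j}"] = r.uniform(size=50)
            mb[f"mean_s{j}"] = r.uniform(size=50)
        out = regions.classify_regions(ma, mb, fdr_threshold=0.05)
        tested = out[out["label"] != "untested"]
        assert (tested["qvalue"] >= tested["pvalue"] - 1e-12).all()


class TestDeltaFilter:
    def stats_frame(self, q, d):
        return pd.DataFrame({"qvalue": q, "delta": d})

    def test_strict_boundaries(self):
        df = self.stats_frame([0.01, 0.01, 0.05], [0.3, 0.2, 0.5])
        out = regions.delta_filter(df, q_threshold=0.05, min_abs_delta=0.2)
        assert out["delta"].tolist() == [0.3]

    def test_negative_delta_kept_by_magnitude(self):
        df = self.stats_frame([0.001], [-0.45])
        assert len(regions.delta_filter(df)) == 1


class TestMaskRegions:
    def test_pmd_mask_subtracts(self):
        regs = region_frame([("c", 0, 100)])
        out = regions.mask_regions(regs, region_frame([("c", 40, 60)]))
        assert out[["start", "end"]].values.tolist() == [[0, 40], [60, 100]]
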