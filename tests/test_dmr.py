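"""DMR detection: smoothing, dispersion shrinkage, Wald calibration, regions."""

import numpy as np
import pandas as pd
import pytest

import methdyn as md
from methdyn.dmr import DmrCallerConfig  # noqa: F401
from methdyn.dmr import (
    _max_sum_segment,
    align_counts,
    call_dmrs,
    estimate_dispersion,
    smooth_methylation,
    wald_site_test,
)
from methdyn.dmr import test_contrast as run_contrast


def beta_binomial(rng, n, mu, phi):
    a = mu * (1 - phi) / phi
    b = (1 - mu) * (1 - phi) / phi
    return rng.binomial(n, rng.beta(a, b, size=np.shape(n)))


def aligned_frame(m, n, samples_a=("a1", "a2", "a3"), samples_b=("b1", "b2", "b3"),
                  pos=None):
    """Assemble the aligned count frame wald_site_test consumes."""
    n_sites = m.shape[0]
    pos = np.arange(n_sites) * 50 + 1 if pos is None else pos
    idx = pd.MultiIndex.from_arrays(
        [np.repeat("chr1", n_sites), pos, np.repeat("+", n_sites)],
        names=["chrom", "pos", "strand"])
    df = pd.DataFrame(index=idx)
    for j, s in enumerate(list(samples_a) + list(samples_b)):
        df[f"m:{s}"] = m[:, j]
        df[f"n:{s}"] = n[:, j]
    df.attrs["samples_a"] = list(samples_a)
    df.attrs["samples_b"] = list(samples_b)
    return df


class TestSmoothing:
    def test_constant_fractions_are_a_fixed_point(self):
        pos = np.array([100, 150, 200, 600])
        m = np.array([5.0, 10, 2, 8])
        n = m / 0.5
        out = smooth_methylation(pos, m, n, window=500)
        assert out == pytest.approx([0.5] * 4)

    def test_isolated_site_unchanged(self):
        out = smooth_methylation(np.array([100]), np.array([3.0]), np.array([10.0]))
        assert out == pytest.approx([0.3])

    def test_three_site_coverage_weighted_mean(self):
        """Coverages {10,10,20}, fractions {0,1,0.5}: centre smooths to 0.5."""
        pos = np.array([100, 200, 300])
        n = np.array([10.0, 20, 10])
        m = np.array([0.0, 10, 10])  # fractions 0, 0.5, 1
        out = smooth_methylation(pos, m, n, window=500)
        assert out[1] == pytest.approx((0 * 10 + 0.5 * 20 + 1 * 10) / 40)

    def test_unsorted_input_preserves_order(self):
        pos = np.array([300, 100, 200])
        m = np.array([1.0, 2, 3])
        n = np.array([10.0, 10, 10])
        out = smooth_methylation(pos, m, n, window=10)  # windows isolate sites
        assert out == pytest.approx(m / n)


class TestDispersion:
    def test_binomial_data_shrinks_to_lower_clip(self):
        rng = np.random.default_rng(1)
        n = np.full((400, 6), 200)
        m = rng.binomial(n, 0.4)
        phi = estimate_dispersion(m, n, np.array([0, 0, 0, 1, 1, 1]))
        assert phi.mean() < 1e-3

    def test_single_site_takes_genome_prior(self):
        rng = np.random.default_rng(2)
        n = np.full((500, 6), 30)
        m = beta_binomial(rng, n, 0.3, 0.08)
        phi_many = estimate_dispersion(m, n, np.array([0, 0, 0, 1, 1, 1]))
        # a site with depth in a single sample has no residual dof: prior only
        n1 = n.copy()
        n1[0, 1:] = 0
        m1 = m.copy()
        m1[0, 1:] = 0
        phi_one = estimate_dispersion(m1, n1, np.array([0, 0, 0, 1, 1, 1]))
        informative = phi_one[1:]
        # the degenerate site sits exactly at the pooled prior of the rest
        assert phi_one[0] == pytest.approx(np.exp(np.mean(np.log(informative))), rel=1)
        assert 1e-6 <= phi_one[0] <= 0.999

    def test_parameter_recovery_within_band(self):
        rng = np.random.default_rng(3)
        n = np.full((1000, 6), 30)
        m = beta_binomial(rng, n, 0.3, 0.1)
        phi = estimate_dispersion(m, n, np.array([0, 0, 0, 1, 1, 1]))
        assert 0.05 <= phi.mean() <= 0.2

    def test_clipped_to_valid_range(self):
        rng = np.random.default_rng(4)
        n = rng.integers(1, 10, (200, 6))
        m = rng.binomial(n, 0.5)
        phi = estimate_dispersion(m, n, np.array([0, 0, 0, 1, 1, 1]))
        assert ((phi >= 1e-6) & (phi <= 0.999)).all()


class TestWaldTest:
    def test_equal_groups_give_zero_statistic(self):
        n = np.full((5, 6), 40)
        m = np.full((5, 6), 10)
        res = wald_site_test(aligned_frame(m, n), window=0)
        assert res["w"].to_numpy() == pytest.approx([0.0] * 5)
        assert res["p_value"].to_numpy() == pytest.approx([1.0] * 5)

    def test_group_swap_negates_w_keeps_p(self):
        rng = np.random.default_rng(5)
        n = rng.poisson(30, (200, 6)) + 1
        m = beta_binomial(rng, n, 0.4, 0.05)
        m[:100, :3] += (0.2 * n[:100, :3]).astype(int)  # shift group A
        m = np.minimum(m, n)
        fwd = wald_site_test(aligned_frame(m, n), window=0)
        swapped = aligned_frame(
            np.concatenate([m[:, 3:], m[:, :3]], axis=1),
            np.concatenate([n[:, 3:], n[:, :3]], axis=1))
        rev = wald_site_test(swapped, window=0)
        assert rev["w"].to_numpy() == pytest.approx(-fwd["w"].to_numpy())
        assert rev["p_value"].to_numpy() == pytest.approx(fwd["p_value"].to_numpy())

    def test_w_sign_matches_mean_difference(self):
        rng = np.random.default_rng(6)
        n = rng.poisson(30, (300, 6)) + 1
        m = beta_binomial(rng, n, 0.4, 0.05)
        res = wald_site_test(aligned_frame(m, n), window=0)
        diff = res["mu1"] - res["mu2"]
        nz = diff != 0
        assert (np.sign(res["w"][nz]) == np.sign(diff[nz])).all()

    def test_null_type_one_error_in_band(self):
        """mu=0.3 both groups, phi=0.05: raw p<0.05 fraction stays calibrated."""
        rng = np.random.default_rng(7)
        n = rng.poisson(30, (2000, 6)) + 1
        m = beta_binomial(rng, n, 0.3, 0.05)
        res = wald_site_test(aligned_frame(m, n), window=0)
        frac = (res["p_value"] < 0.05).mean()
        assert 0.02 <= frac <= 0.10

    def test_zero_depth_sites_are_skipped_by_alignment(self, methylome):
        reports, _ = methylome
        names = list(reports)
        aligned = align_counts({names[0]: reports[names[0]]},
                               {names[3]: reports[names[3]]}, min_depth=1)
        for col in aligned.columns:
            if col.startswith("n:"):
                assert (aligned[col] >= 1).all()


class TestRegionCalling:
    def empty_results(self):
        return pd.DataFrame(columns=["chrom", "pos", "strand", "mu1", "mu2",
                                     "raw1", "raw2", "phi", "w", "p_value",
                                     "context"])

    def site_results(self, pos, p, w, raw_diff=0.3):
        n = len(pos)
        return pd.DataFrame({
            "chrom": "chr1", "pos": pos, "strand": "+",
            "mu1": 0.5 + np.asarray(w, float) * 0.0 + raw_diff / 2,
            "mu2": 0.5 - raw_diff / 2,
            "raw1": 0.5 + np.sign(w) * raw_diff / 2,
            "raw2": 0.5 - np.sign(w) * raw_diff / 2,
            "phi": 0.05, "w": w, "p_value": p, "context": "CG"})

    def test_no_significant_sites_empty(self):
        res = self.site_results(np.arange(5) * 10 + 1, [0.5] * 5, [1.0] * 5)
        assert len(call_dmrs(res)) == 0
        assert len(call_dmrs(self.empty_results())) == 0

    def test_merge_gap_semantics(self):
        """Two significant clusters 150 bp apart: split at gap 100, one at 200."""
        pos = np.concatenate([np.arange(1, 61, 10), np.arange(201, 261, 10)])
        p = np.full(12, 1e-8)
        w = np.full(12, 6.0)
        res = self.site_results(pos, p, w)
        split = call_dmrs(res, min_len=10, min_sites=3, merge_gap=100)
        joined = call_dmrs(res, min_len=10, min_sites=3, merge_gap=200)
        assert len(split) == 2
        assert len(joined) == 1
        assert joined.loc[0, "length"] == 251 - 1 + 1

    def test_sign_change_breaks_runs(self):
        pos = np.arange(1, 121, 10)
        w = np.where(pos < 60, 6.0, -6.0)
        res = self.site_results(pos, np.full(12, 1e-8), w)
        out = call_dmrs(res, min_len=10, min_sites=3)
        assert len(out) == 2
        assert set(out["direction"]) == {"higher at A", "higher at B"}

    def test_filters_enforce_min_sites_and_length(self):
        res = self.site_results(np.array([1, 11]), [1e-8] * 2, [6.0] * 2)
        assert len(call_dmrs(res, min_sites=3)) == 0
        res2 = self.site_results(np.array([1, 11, 21]), [1e-8] * 3, [6.0] * 3)
        assert len(call_dmrs(res2, min_sites=3, min_len=50)) == 0  # span 21 bp
        assert len(call_dmrs(res2, min_sites=3, min_len=20)) == 1

    def test_threshold_relaxation_only_extends_coverage(self, methylome,
                                                        sim_config):
        reports, _ = methylome
        rep_a = {s: reports[s] for s, g in sim_config.samples if g == "4M"}
        rep_b = {s: reports[s] for s, g in sim_config.samples if g == "6M"}
        sites, _ = run_contrast(rep_a, rep_b, contexts=("CG",))
        strict = call_dmrs(sites, p_threshold=1e-8)
        loose = call_dmrs(sites, p_threshold=1e-4)
        for _, d in strict.iterrows():
            covering = loose[(loose["chrom"] == d["chrom"])
                             & (loose["start"] <= d["end"])
                             & (loose["end"] >= d["start"])]
            assert len(covering) >= 1, dict(d)

    def test_contexts_never_mix_within_a_region(self, methylome, sim_config):
        reports, _ = methylome
        rep_a = {s: reports[s] for s, g in sim_config.samples if g == "4M"}
        rep_b = {s: reports[s] for s, g in sim_config.samples if g == "10M"}
        sites, dmrs = run_contrast(rep_a, rep_b)
        assert sites.groupby(["chrom", "pos", "strand"])["context"].nunique().max() == 1
        if len(dmrs):
            assert dmrs["context"].isin(["CG", "CHG", "CHH"]).all()

    def test_max_sum_segment_matches_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            x = rng.normal(0, 1, rng.integers(1, 15))
            lo, hi = _max_sum_segment(x)
            best = max(
                (x[i:j + 1].sum(), i, j)
                for i in range(len(x)) for j in range(i, len(x)))
            assert x[lo:hi + 1].sum() == pytest.approx(best[0])


class TestPlantedRecovery:
    def jaccard(self, a, b):
        s, e = max(a[0], b[0]), min(a[1], b[1])
        inter = max(0, e - s)
        return inter / ((a[1] - a[0]) + (b[1] - b[0]) - inter)

    def test_single_200bp_region_recovered_across_seeds(self):
        """Planted 200 bp, delta 0.30, depth 30, 3v3: Jaccard >= 0.8 in >=18/20."""
        good = 0
        for seed in range(20):
            cfg = md.SimConfig(seed=2000 + seed, n_chroms=1, chrom_length=40_000,
                               n_genes=5, n_dmrs=1, dmr_len_range=(200, 200),
                               n_degs=0, control_sites=200)
            cat = md.build_toy_annotation(cfg)
            reports, truth = md.simulate_methylome(cfg, cat)
            t = truth.dmr_intervals[0]
            pair = next(p for p in cfg.group_pairs if t[3] in p)
            rep_a = {s: reports[s] for s, g in cfg.samples if g == pair[0]}
            rep_b = {s: reports[s] for s, g in cfg.samples if g == pair[1]}
            _, dmrs = run_contrast(rep_a, rep_b, contexts=("CG",),
                                    group_labels=pair)
            js = [self.jaccard((t[1], t[2]), (d["start"] - 1, d["end"]))
                  for _, d in dmrs.iterrows()]
            good += bool(js) and max(js) >= 0.8
        assert good >= 18

    def test_direction_labels_match_planted_shifts(self, methylome, sim_config):
        reports, truth = methylome
        pair = ("4M", "6M")
        rep_a = {s: reports[s] for s, g in sim_config.samples if g == pair[0]}
        rep_b = {s: reports[s] for s, g in sim_config.samples if g == pair[1]}
        _, dmrs = run_contrast(rep_a, rep_b, contexts=("CG",), group_labels=pair)
        for chrom, s, e, grp, delta, _ctx in truth.dmrs_for_pair(*pair):
            hits = dmrs[(dmrs["chrom"] == chrom) & (dmrs["start"] - 1 < e)
                        & (dmrs["end"] > s)]
            if not len(hits):
                continue
            # shifted group higher iff delta > 0
            expect = f"higher at {grp}" if delta > 0 else (
                f"higher at {pair[0] if grp != pair[0] else pair[1]}")
            assert (hits["direction"] == expect).all()


class TestDerived:
    @pytest.mark.parametrize(
        "m1,m2,expected",
        [(0.5, 0.5, 0.0),
         (0.8, 0.19, np.log2(0.81 / 0.20))],  # ~2.018
    )
    def test_methylation_log2fc(self, m1, m2, expected):
        assert md.dmr_methylation_log2fc(m1, m2) == pytest.approx(expected, abs=1e-9)

    def test_methylation_log2fc_antisymmetric(self):
        a = md.dmr_methylation_log2fc(0.7, 0.2)
        b = md.dmr_methylation_log2fc(0.2, 0.7)
        assert a == pytest.approx(-b)

    def test_summary_of_single_dmr(self):
        dmrs = pd.DataFrame([{
            "chrom": "chr1", "start": 100, "end": 206, "length": 107,
            "n_sites": 23, "n_significant": 20, "mean_meth1": 0.6,
            "mean_meth2": 0.3, "meth_diff": 0.3, "area_stat": 100.0,
            "context": "CG", "direction": "higher at A"}])
        s = md.summarize_dmrs(dmrs)
        assert s["length_median"] == 107
        assert s["frac_length_le_200"] == 1.0
        assert s["mean_sites_per_dmr"] == 23
        assert s["per_context"] == {"CG": 1}

    def test_summary_with_catalog_counts_multilabel_features(self, catalog,
                                                             methylome,
                                                             sim_config):
        reports, _ = methylome
        rep_a = {s: reports[s] for s, g in sim_config.samples if g == "4M"}
        rep_b = {s: reports[s] for s, g in sim_config.samples if g == "6M"}
        _, dmrs = run_contrast(rep_a, rep_b, contexts=("CG",))
        s = md.summarize_dmrs(dmrs, catalog)
        if s["n_dmrs"]:
            # multi-label: feature hits can exceed the region count
            assert sum(s["feature_counts"].values()) >= 0
            assert s["n_dmrs"] == len(dmrs)

    def test_empty_table_summary(self):
        assert md.summarize_dmrs(pd.DataFrame(columns=["length"]))["n_dmrs"] == 0
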