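"""Feature catalogs: derivation rules, oracle agreement, profiles, statistics."""

import numpy as np
import pandas as pd
import pytest

import methdyn as md
from methdyn.annotation import (
    FEATURE_LABELS,
    FeatureCatalog,
    GeneModel,
    dunn_test,
    region_labels_for_gene,
    write_catalog,
)


def two_gene_catalog() -> FeatureCatalog:
    """Hand-built: a + gene and a - gene on one 50 kb chromosome."""
    fwd = GeneModel("g1", "fwd", "chr1", "+", 10_000, 14_000,
                    exons=[(10_000, 11_000), (13_000, 14_000)],
                    utr5=[(10_000, 10_200)], utr3=[(13_800, 14_000)])
    rev = GeneModel("g2", "rev", "chr1", "-", 30_000, 33_000,
                    exons=[(30_000, 33_000)],
                    utr5=[(32_800, 33_000)], utr3=[(30_000, 30_200)])
    return FeatureCatalog({"chr1": 50_000}, genes=[fwd, rev],
                          cgi=[("chr1", 9_500, 10_200)],
                          repeats=[("chr1", 20_000, 20_400)])


class TestCatalogDerivation:
    def test_promoter_is_1kb_upstream_through_tss_strand_aware(self):
        cat = two_gene_catalog()
        # + gene: TSS base 10000 (0-based) -> promoter 9000..10001 half-open,
        # i.e. 1-based 9001..10001 = TSS-1000 .. TSS
        assert cat.genes["g1"].promoter() == (9_000, 10_001)
        # - gene: TSS base 32999 -> promoter covers 32999..34000
        assert cat.genes["g2"].promoter() == (32_999, 34_000)

    def test_reversing_strand_reflects_promoter_about_tss(self):
        plus = GeneModel("g", "g", "chr1", "+", 5_000, 8_000, exons=[(5_000, 8_000)])
        minus = GeneModel("g", "g", "chr1", "-", 5_000, 8_000, exons=[(5_000, 8_000)])
        assert plus.promoter() == (4_000, 5_001)      # left of the + TSS
        assert minus.promoter() == (7_999, 9_000)     # right of the - TSS
        ps, pe = plus.promoter()
        ms, me = minus.promoter()
        assert (pe - ps) == (me - ms)                  # same size either side

    def test_single_exon_gene_has_no_introns(self):
        cat = two_gene_catalog()
        assert cat.genes["g2"].introns == []
        assert cat.genes["g1"].introns == [(11_000, 13_000)]

    def test_shores_clip_at_neighbouring_cgis(self):
        cat = FeatureCatalog({"chr1": 20_000}, cgi=[("chr1", 5_000, 6_000),
                                                    ("chr1", 7_000, 8_000)])
        shores = sorted((s, e) for _c, s, e, _g in cat.feature_intervals("shore"))
        assert (6_000, 7_000) in shores            # clipped between the CGIs
        assert (3_000, 5_000) in shores
        assert (8_000, 10_000) in shores

    def test_out_of_bounds_interval_rejected_with_coordinates(self):
        with pytest.raises(ValueError, match="outside"):
            FeatureCatalog({"chr1": 1_000}, cgi=[("chr1", 500, 2_000)])


class TestGtfRoundTrip:
    def test_written_catalog_reloads_identically(self, tmp_path, catalog):
        paths = write_catalog(catalog, tmp_path)
        back = md.load_annotation(paths["gtf"], paths["cgi"], paths["repeats"],
                                  paths["chrom_sizes"])
        assert set(back.genes) == set(catalog.genes)
        for gid, g in catalog.genes.items():
            b = back.genes[gid]
            assert (b.chrom, b.strand, b.start, b.end) == (
                g.chrom, g.strand, g.start, g.end)
            assert sorted(b.exons) == sorted(g.exons)
            assert sorted(b.utr5) == sorted(g.utr5)
        assert back.cgi == catalog.cgi
        assert back.chrom_sizes == catalog.chrom_sizes


class TestGeneAssociation:
    def test_1kb_boundary_inclusive_at_999_exclusive_past_1001(self):
        cat = two_gene_catalog()
        tss0 = 10_000  # + gene start
        assert md.associate_gene(("chr1", tss0 - 999, tss0 - 998), cat) == {"g1"}
        assert md.associate_gene(("chr1", tss0 - 1_000, tss0 - 999), cat) == {"g1"}
        assert md.associate_gene(("chr1", tss0 - 1_001, tss0 - 1_000), cat) == set()

    def test_downstream_of_tts_symmetric(self):
        cat = two_gene_catalog()
        tts_end = 14_000  # + gene end (half-open)
        assert md.associate_gene(("chr1", tts_end + 999, tts_end + 1_000), cat) == {"g1"}
        assert md.associate_gene(("chr1", tts_end + 1_000, tts_end + 1_001), cat) == set()


class TestFeatureAssignment:
    def test_exon_intron_junction_is_multilabel(self):
        cat = two_gene_catalog()
        hit = md.assign_features(("chr1", 10_900, 11_100), cat)
        assert {"exon", "intron"} <= hit.labels
        single = md.assign_features(("chr1", 10_900, 11_100), cat, single_label=True)
        assert single.labels == {"exon"}  # priority mode keeps one label

    def test_intergenic_interval_has_no_labels(self):
        cat = two_gene_catalog()
        hit = md.assign_features(("chr1", 45_000, 45_100), cat)
        assert hit.labels == set() and hit.gene_ids == set()

    def test_agreement_with_quadratic_oracle(self):
        """Random queries vs a brute-force all-intervals scan."""
        rng = np.random.default_rng(11)
        genes, cgi, repeats = [], [], []
        cursor = 2_000
        for i in range(12):
            span = int(rng.integers(1_000, 3_000))
            start = cursor + int(rng.integers(1_500, 3_000))
            strand = "+" if rng.random() < 0.5 else "-"
            mid = start + span // 2
            genes.append(GeneModel(f"g{i}", f"g{i}", "chr1", strand, start,
                                   start + span,
                                   exons=[(start, mid - 100), (mid, start + span)]))
            cursor = start + span
        for _ in range(10):
            s = int(rng.integers(0, 90_000))
            cgi.append(("chr1", s, s + int(rng.integers(200, 600))))
        for _ in range(10):
            s = int(rng.integers(0, 90_000))
            repeats.append(("chr1", s, s + int(rng.integers(100, 400))))
        cat = FeatureCatalog({"chr1": 100_000}, genes=genes,
                             cgi=md.synthetic._merge_intervals(cgi),
                             repeats=md.synthetic._merge_intervals(repeats))

        all_feats = {
            label: [(c, s, e) for c, s, e, _g in cat.feature_intervals(label)]
            for label in FEATURE_LABELS
        }
        for _ in range(300):
            qs = int(rng.integers(0, 99_900))
            qe = qs + int(rng.integers(1, 500))
            hit = md.assign_features(("chr1", qs, qe), cat)
            brute_labels = {
                label
                for label, ivs in all_feats.items()
                if any(qs < e and s < qe for _c, s, e in ivs)
            }
            assert hit.labels == brute_labels, (qs, qe)
            brute_genes = {
                g.gene_id for g in genes
                if qs < g.end + 1_000 and g.start - 1_000 < qe
            }
            assert md.associate_gene(("chr1", qs, qe), cat) == brute_genes

    def test_region_labels_include_tss_tes_windows(self):
        cat = two_gene_catalog()
        g = cat.genes["g1"]
        labels = region_labels_for_gene(("chr1", 9_900, 10_100), g, cat)
        assert "TSS" in labels and "Promoter" in labels and "Exon" in labels
        labels_end = region_labels_for_gene(("chr1", 14_500, 14_600), g, cat)
        assert labels_end == ["TES"]


class TestMethylationProfile:
    def test_feature_mean_of_zero_and_one_is_fifty_percent(self):
        cat = two_gene_catalog()
        calls = md.call_true_methylated(pd.DataFrame(
            [("chr1", 10_101, "+", 10, 0, "CG", "CGG"),   # exon site, fully meth
             ("chr1", 10_151, "+", 0, 10, "CG", "CGG")],  # exon site, unmeth
            columns=["chrom", "pos", "strand", "m", "u", "context", "tri"]))
        prof = md.feature_methylation_profile({"s": calls}, cat)
        exon = prof[(prof["feature"] == "exon")]["meth_pct"].iloc[0]
        assert exon == pytest.approx(50.0)

    def test_empty_feature_is_missing_not_zero(self):
        cat = two_gene_catalog()
        calls = md.call_true_methylated(pd.DataFrame(
            [("chr1", 45_001, "+", 5, 5, "CG", "CGG")],
            columns=["chrom", "pos", "strand", "m", "u", "context", "tri"]))
        prof = md.feature_methylation_profile({"s": calls}, cat)
        assert prof[prof["feature"] == "repeat"]["meth_pct"].isna().all()

    def test_planted_feature_ordering_recovered(self, sim_config, catalog,
                                                calls_by_sample):
        prof = md.feature_methylation_profile(calls_by_sample, catalog)
        means = prof.groupby("feature")["meth_pct"].mean()
        base = sim_config.baseline_meth_by_feature
        assert means["promoter"] < means["intron"]
        assert means["utr5"] < means["repeat"]
        # recovered ordering matches the configured baseline ordering
        for a, b in [("promoter", "intron"), ("cgi", "repeat")]:
            assert (means[a] < means[b]) == (base[a] < base[b])


class TestGroupStats:
    def test_identical_groups_give_null_anova(self):
        prof = pd.DataFrame(
            {"sample": [f"s{i}" for i in range(6)] * 2,
             "feature": ["exon"] * 6 + ["intron"] * 6,
             "n_sites": 10,
             "meth_pct": [50.0, 51.0, 49.0, 50.0, 51.0, 49.0] * 2})
        stats = md.group_stats(prof, {f"s{i}": "A" if i < 3 else "B"
                                      for i in range(6)})
        f = stats["anova_features"]["F"]
        assert f == pytest.approx(0.0, abs=1e-10)

    def test_dunn_statistic_matches_hand_computation(self):
        """{1,2,3} vs {4,5,6}: mean ranks 2 and 5, sigma from Dunn's formula."""
        out = dunn_test({"lo": np.array([1.0, 2, 3]), "hi": np.array([4.0, 5, 6])})
        z = out.loc[0, "z"]
        sigma = np.sqrt((6 * 7 / 12) * (1 / 3 + 1 / 3))
        assert abs(z) == pytest.approx(3 / sigma, abs=1e-3)
        assert abs(z) == pytest.approx(1.964, abs=1e-3)

    def test_small_group_skips_normality_with_warning(self):
        prof = pd.DataFrame(
            {"sample": ["s1", "s2"], "feature": ["exon"] * 2, "n_sites": 5,
             "meth_pct": [10.0, 20.0]})
        with pytest.warns(UserWarning, match="normality"):
            md.group_stats(prof, {"s1": "A", "s2": "A"})

    def test_planted_stage_shift_detected_in_most_runs(self):
        """A late-stage promoter/intron methylation rise should be flagged."""
        detected = 0
        runs = 20
        for seed in range(runs):
            cfg = md.SimConfig(
                seed=3000 + seed, n_chroms=1, chrom_length=100_000, n_genes=14,
                n_dmrs=0, n_degs=0, control_sites=300,
                stage_shift={"10M": {"promoter": 0.10, "intron": 0.08}})
            cat = md.build_toy_annotation(cfg)
            reports, _ = md.simulate_methylome(cfg, cat)
            calls = {s: md.call_true_methylated(r) for s, r in reports.items()}
            prof = md.feature_methylation_profile(calls, cat)
            stats = md.group_stats(prof, dict(cfg.samples))
            tt = pd.DataFrame(stats["t_tests"])
            hit = tt[(tt["feature"].isin(["promoter", "intron"]))
                     & ((tt["stage_a"] == "10M") | (tt["stage_b"] == "10M"))]
            detected += bool(len(hit)) and (hit["p_value"] < 0.05).all()
        assert detected >= 0.9 * runs
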