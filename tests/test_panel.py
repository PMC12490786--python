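"""Off-target panel caller: SNP rule, background model, thresholds, t-test."""

import math

import numpy as np
import pandas as pd
import pytest

from ampedit.panel import (BackgroundModel, NoPretreatmentError, PanelDataset,
                           PanelSample, analyze_panel,
                           annotate_nearest_gene, call_candidate_positions,
                           classify_snps, estimate_background, filter_by_depth,
                           read_features_bed, read_features_gff,
                           summarize_panel)
from ampedit.panel import test_candidates as run_candidate_tests
from ampedit.simulate import (EditSpec, PanelSimConfig,
                              random_panel_sites, simulate_panel)


def counts_from_freq(site_seq, freq_map, depth):
    """Deterministic count table: freq_map maps (pos, base) -> frequency."""
    counts = np.zeros((20, 4), dtype=np.int64)
    for p in range(20):
        alt_total = 0
        for b_i, b in enumerate("ACGT"):
            f = freq_map.get((p + 1, b), 0.0)
            c = round(f * depth)
            counts[p, b_i] = c
            alt_total += c if b != site_seq[p] else 0
        ref_i = "ACGT".index(site_seq[p])
        counts[p, ref_i] = depth - (counts[p].sum() - counts[p, ref_i])
    return counts


def make_sample(sites, timepoint, is_pre, freq_maps=None, depth=5000):
    freq_maps = freq_maps or {}
    site_counts = {s.name: counts_from_freq(s.sequence,
                                            freq_maps.get(s.name, {}), depth)
                   for s in sites}
    return PanelSample("subj", timepoint, is_pre, site_counts,
                       {s.name: depth for s in sites})


@pytest.fixture()
def sites():
    return random_panel_sites(5, seed=42)


class TestDepthFilter:
    def test_strictly_more_than_min_reads(self, sites):
        s = make_sample(sites, "pre", True)
        s.site_reads[sites[0].name] = 1001
        s.site_reads[sites[1].name] = 1000
        s.site_reads[sites[2].name] = 0
        kept = filter_by_depth(s, 1000)
        assert sites[0].name in kept
        assert sites[1].name not in kept
        assert sites[2].name not in kept

    def test_raising_min_reads_never_adds_sites(self, sites):
        s = make_sample(sites, "pre", True)
        for i, site in enumerate(sites):
            s.site_reads[site.name] = 500 * i
        prev = filter_by_depth(s, 0)
        for cut in (100, 500, 1000, 2000):
            cur = filter_by_depth(s, cut)
            assert cur <= prev
            prev = cur


class TestSnpRule:
    def alt_base(self, site, pos):
        return next(b for b in "ACGT" if b != site.sequence[pos - 1])

    def dataset(self, sites, pre_freq, post_freqs):
        site = sites[0]
        alt = self.alt_base(site, 11)
        samples = [make_sample(sites, "pre", True,
                               {site.name: {(11, alt): pre_freq}})]
        for i, f in enumerate(post_freqs):
            samples.append(make_sample(sites, f"p{i}", False,
                                       {site.name: {(11, alt): f}}))
        return PanelDataset(sites=list(sites), samples=samples), site, alt

    def test_germline_variant_is_snp(self, sites):
        ds, site, alt = self.dataset(sites, 0.5, [0.5, 0.5, 0.5])
        snps = classify_snps(ds.samples, ds)
        assert (site.name, 11, alt) in snps

    def test_low_pre_frequency_is_not_snp(self, sites):
        ds, site, alt = self.dataset(sites, 0.05, [0.5, 0.5, 0.5])
        assert classify_snps(ds.samples, ds) == []

    def test_absent_at_one_timepoint_is_not_snp(self, sites):
        ds, site, alt = self.dataset(sites, 0.15, [0.15, 0.0, 0.15])
        assert classify_snps(ds.samples, ds) == []

    def test_missing_depth_timepoint_does_not_break_presence(self, sites):
        ds, site, alt = self.dataset(sites, 0.15, [0.15, 0.15, 0.15])
        # site fails depth at one post timepoint: treated as missing, not absent
        ds.samples[2].site_reads[site.name] = 10
        assert (site.name, 11, alt) in classify_snps(ds.samples, ds)

    def test_no_pretreatment_sample_rejected(self, sites):
        samples = [make_sample(sites, "p0", False)]
        ds = PanelDataset(sites=list(sites), samples=samples)
        with pytest.raises(NoPretreatmentError):
            classify_snps(samples, ds)

    def test_idempotent_on_snp_free_data(self, sites):
        ds, site, alt = self.dataset(sites, 0.5, [0.5, 0.5, 0.5])
        snps = classify_snps(ds.samples, ds)
        # a second pass classifies the same set (rule is deterministic)
        assert classify_snps(ds.samples, ds) == snps


class TestBackgroundModel:
    def test_three_value_pool_arithmetic(self, sites):
        # hand-build a pre sample whose pooled error rates are {.001,.002,.003}
        site = sites[0]
        sample = make_sample([site], "pre", True, depth=100000)
        counts = sample.site_counts[site.name]
        for p, err in ((0, 0.001), (1, 0.002), (2, 0.003)):
            ref_i = "ACGT".index(site.sequence[p])
            alt_i = (ref_i + 1) % 4
            c = round(err * 100000)
            counts[p, ref_i] -= c
            counts[p, alt_i] += c
        ds = PanelDataset(sites=[site], samples=[sample])
        errs = sample.error_rates(site.name, site.sequence)[:3]
        np.testing.assert_allclose(errs, [0.001, 0.002, 0.003], atol=1e-12)
        arr = np.array([0.001, 0.002, 0.003])
        bg = estimate_background(sample, ds, [])
        # pool includes the 17 clean positions too; check the constructed ones
        assert bg.n_positions_used == 20
        assert bg.mean_error == pytest.approx(arr.sum() / 20)
        pool = np.concatenate([arr, np.zeros(17)])
        assert bg.sd_error == pytest.approx(pool.std(ddof=1))
        assert bg.threshold == bg.mean_error + 2 * bg.sd_error

    def test_snp_position_excluded_from_pool(self, sites):
        site = sites[0]
        alt = next(b for b in "ACGT" if b != site.sequence[10])
        noisy = make_sample([site], "pre", True,
                            {site.name: {(11, alt): 0.5}})
        clean = make_sample([site], "pre", True)
        ds = PanelDataset(sites=[site], samples=[noisy])
        bg_excl = estimate_background(noisy, ds, [(site.name, 11, alt)])
        bg_clean = estimate_background(clean, ds, [])
        assert bg_excl.n_positions_used == 19
        assert bg_excl.mean_error == pytest.approx(bg_clean.mean_error)

    def test_all_zero_errors(self, sites):
        sample = make_sample(sites, "pre", True)
        ds = PanelDataset(sites=list(sites), samples=[sample])
        bg = estimate_background(sample, ds, [])
        assert bg.mean_error == 0.0 and bg.sd_error == 0.0

    def test_insufficient_pool_rejected(self, sites):
        sample = make_sample(sites, "pre", True, depth=10)
        ds = PanelDataset(sites=list(sites), samples=[sample])
        with pytest.raises(ValueError):
            estimate_background(sample, ds, [], min_reads=1000)


class TestCandidateRule:
    def bg(self):
        return BackgroundModel("subj", 0.001, 0.0005, 100, ())

    def test_frequency_above_both_thresholds_is_candidate(self, sites):
        site = sites[0]
        alt = next(b for b in "ACGT" if b != site.sequence[5])
        post = make_sample(sites, "p0", False, {site.name: {(6, alt): 0.006}})
        ds = PanelDataset(sites=list(sites), samples=[post])
        cands = call_candidate_positions([post], ds, self.bg(), [])
        assert cands == [(site.name, 6, site.sequence[5], alt)]

    def test_above_sd_threshold_but_below_floor_rejected(self, sites):
        site = sites[0]
        alt = next(b for b in "ACGT" if b != site.sequence[5])
        post = make_sample(sites, "p0", False, {site.name: {(6, alt): 0.004}})
        ds = PanelDataset(sites=list(sites), samples=[post])
        assert call_candidate_positions([post], ds, self.bg(), []) == []

    def test_snp_position_never_candidate(self, sites):
        site = sites[0]
        alt = next(b for b in "ACGT" if b != site.sequence[5])
        post = make_sample(sites, "p0", False, {site.name: {(6, alt): 0.5}})
        ds = PanelDataset(sites=list(sites), samples=[post])
        assert call_candidate_positions([post], ds, self.bg(),
                                        [(site.name, 6, alt)]) == []


class TestCandidateTesting:
    def build(self, sites, pre_f, post_fs):
        site = sites[0]
        alt = next(b for b in "ACGT" if b != site.sequence[3])
        samples = [make_sample(sites, "pre", True,
                               {site.name: {(4, alt): pre_f}}, depth=100000)]
        for i, f in enumerate(post_fs):
            samples.append(make_sample(sites, f"p{i}", False,
                                       {site.name: {(4, alt): f}},
                                       depth=100000))
        ds = PanelDataset(sites=list(sites), samples=samples)
        cand = [(site.name, 4, site.sequence[3], alt)]
        bg = BackgroundModel("subj", 0.0001, 0.0001, 100, ())
        return ds, cand, bg

    def test_clear_elevation_is_significant(self, sites):
        ds, cand, bg = self.build(sites, 0.001, [0.010, 0.011, 0.009, 0.010])
        calls = run_candidate_tests(cand, ds.samples, ds, bg)
        c = calls[0]
        # closed form: t = (mean - pre) / (sd/sqrt(n))
        obs = np.array([0.010, 0.011, 0.009, 0.010])
        t_expect = (obs.mean() - 0.001) / (obs.std(ddof=1) / 2)
        assert c.t_statistic == pytest.approx(t_expect)
        assert c.p_value < 0.001
        assert c.significant

    def test_posts_equal_to_pre_give_half_p(self, sites):
        ds, cand, bg = self.build(sites, 0.01, [0.01, 0.01, 0.01])
        c = run_candidate_tests(cand, ds.samples, ds, bg)[0]
        assert c.t_statistic == 0.0
        assert c.p_value == 0.5
        assert not c.significant

    def test_single_post_observation_is_indeterminate(self, sites):
        ds, cand, bg = self.build(sites, 0.001, [0.01])
        c = run_candidate_tests(cand, ds.samples, ds, bg)[0]
        assert c.p_value is None
        assert not c.significant
        assert "fewer than 2" in c.reason


class TestEndToEnd:
    def test_spike_in_called_and_null_sites_quiet(self):
        sites = random_panel_sites(30, seed=77)
        target = sites[4]
        pos = 1 + target.sequence.index("A")
        tps = ["pre"] + [f"p{i}" for i in range(6)]
        config = PanelSimConfig(
            sites=sites, timepoints=tps, pretreatment="pre", depth=5000,
            true_edit_specs=(EditSpec(target.name, pos, 0.01, "p0"),),
            error_rate=1e-3, seed=78)
        result = analyze_panel(simulate_panel(config))[0]
        sig = {(c.site, c.position) for c in result.significant_calls}
        assert sig == {(target.name, pos)}

    def test_longitudinal_summary_recovers_trajectory(self):
        sites = random_panel_sites(10, seed=79)
        target = sites[2]
        pos = 1 + target.sequence.index("A")
        tps = ["pre", "p0", "p1", "p2", "p3"]
        config = PanelSimConfig(
            sites=sites, timepoints=tps, pretreatment="pre", depth=50000,
            true_edit_specs=(EditSpec(target.name, pos, 0.02, "p0",
                                      trajectory=(0.02, 0.015, 0.012, 0.01)),),
            error_rate=1e-3, seed=80)
        result = analyze_panel(simulate_panel(config))[0]
        longi = summarize_panel(result, simulate_panel(config))
        traj = longi[~longi["is_pretreatment"]]["frequency"].to_numpy()
        assert len(traj) == 4
        assert all(np.diff(traj) < 0)      # monotone decline
        assert abs(traj[0] - 0.02) < 0.005

    def test_no_pretreatment_sample_is_an_error(self, sites):
        samples = [make_sample(sites, f"p{i}", False) for i in range(3)]
        ds = PanelDataset(sites=list(sites), samples=samples)
        with pytest.raises(NoPretreatmentError):
            analyze_panel(ds)


class TestAnnotation:
    def make_call(self, dataset, site_name):
        from ampedit.panel import CandidateCall
        return CandidateCall("subj", site_name, 5, "A", "G", {}, 0.0, 0.0,
                             5.0, 0.001, True)

    def features(self):
        return pd.DataFrame([
            {"contig": "chrS", "start": 900, "end": 1100, "name": "geneA",
             "feature_type": "gene"},
            {"contig": "chrS", "start": 950, "end": 1010, "name": "geneA_ex1",
             "feature_type": "exon"},
            {"contig": "chrS", "start": 8000, "end": 9000, "name": "geneB",
             "feature_type": "gene"},
        ])

    def test_overlapping_exon_is_exonic_distance_zero(self, sites):
        ds = PanelDataset(sites=list(sites), samples=[])
        call = self.make_call(ds, sites[0].name)   # site start 1000
        ann = annotate_nearest_gene([call], ds, self.features())
        row = ann.iloc[0]
        assert row["distance"] == 0.0
        assert row["region"] == "exonic"

    def test_nearest_feature_by_midpoint(self, sites):
        ds = PanelDataset(sites=list(sites), samples=[])
        call = self.make_call(ds, sites[4].name)   # site start 5000
        ann = annotate_nearest_gene([call], ds, self.features())
        row = ann.iloc[0]
        assert row["nearest_feature"] == "geneB"
        assert row["region"] == "intergenic"
        assert row["distance"] == pytest.approx(abs(8500 - 5010))

    def test_empty_annotation_set_reports_missing(self, sites):
        ds = PanelDataset(sites=list(sites), samples=[])
        call = self.make_call(ds, sites[0].name)
        empty = pd.DataFrame(columns=["contig", "start", "end", "name"])
        ann = annotate_nearest_gene([call], ds, empty)
        assert ann.iloc[0]["region"] == "intergenic"
        assert ann.iloc[0]["distance"] is None or math.isnan(ann.iloc[0]["distance"])

    def test_bed_and_gff_readers(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t100\t200\tgeneX\t0\t+\n")
        df = read_features_bed(bed)
        assert df.iloc[0]["name"] == "geneX"
        gff = tmp_path / "genes.gff3"
        gff.write_text("##gff-version 3\n"
                       "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1;Name=geneY\n"
                       "chr1\tsrc\texon\t101\t150\t.\t+\t.\tID=g1.e1\n")
        df = read_features_gff(gff)
        assert list(df["name"]) == ["geneY", "g1.e1"]
        assert df.iloc[0]["start"] == 100   # converted to 0-based
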