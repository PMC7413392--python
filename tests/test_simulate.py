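import json

import numpy as np
import pytest

from embryomark.binning import downsample_counts, filter_bins
from embryomark.calling import call_marks
from embryomark.dnm import dnm_enrichment_test, marked_intervals
from embryomark.patterns import pattern_table
from embryomark.promoters import (BROAD_EXPRESSED, INACTIVE, NARROW_EXPRESSED,
                                  skew_statistic, summarize_cluster)
from embryomark.simulate import (PlantedPattern, SimConfig, archetype_profiles,
                                 simulate_dataset, simulate_dnm_study,
                                 simulate_tss_profiles)


class TestConfig:
    def test_state_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(state_mix={NARROW_EXPRESSED: 0.5, INACTIVE: 0.4})

    def test_too_many_planted_bins(self, tiny_config):
        cfg = SimConfig(
            n_chroms=1, chrom_length=10_000, tissues=("heart",),
            planted_patterns=(PlantedPattern("H3K27ac", ("heart",), 100),))
        with pytest.raises(ValueError, match="too many planted bins"):
            simulate_dataset(cfg)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(dnm_rate_marked=-1.0)


class TestDataset:
    def test_same_seed_byte_identical(self, tiny_config):
        c1, g1, e1, t1 = simulate_dataset(tiny_config)
        c2, g2, e2, t2 = simulate_dataset(tiny_config)
        assert np.array_equal(c1.counts, c2.counts)
        assert g1.equals(g2)
        assert e1.equals(e2)
        assert t1.true_pattern_of_bin == t2.true_pattern_of_bin

    def test_no_signal_case_planted_bins_exchangeable(self, tiny_config):
        cfg = SimConfig(**{**tiny_config.__dict__, "signal_mean": 0.0})
        counts, _, _, truth = simulate_dataset(cfg)
        calls = call_marks(downsample_counts(counts, seed=1))
        devs = []
        for s in calls.samples:
            if s.is_input or s.mark != "H3K27ac":
                continue
            planted = np.array(truth.true_marked_bins[s.sample_id])
            col = calls.column(s.sample_id)
            # with zero added signal the planted bins behave like background:
            # their call rate matches the genome-wide call rate (up to the
            # binomial noise of 100 planted bins per sample)
            devs.append(abs(col[planted].mean() - col.mean()))
        assert np.mean(devs) <= 0.05
        assert max(devs) <= 0.15

    def test_planted_tissue_pattern_ranks_first(self):
        tissues = ("A", "B")
        cfg = SimConfig(
            n_chroms=1, chrom_length=2_000_000, tissues=tissues,
            planted_patterns=(PlantedPattern("H3K27ac", ("A",), 500),),
            enhancer_target_pairs=0, n_genes=50, seed=21)
        counts, _, _, truth = simulate_dataset(cfg)
        calls = call_marks(downsample_counts(counts, seed=1),
                           filter_bins(counts))
        k27 = calls.subset_samples(lambda s: s.mark == "H3K27ac" and not s.is_input)
        pt = pattern_table(k27, min_samples=2)
        assert pt.loc[0, "pattern"] == ("A_H3K27ac_r1", "A_H3K27ac_r2")

    def test_mark_recovery_at_10x_background(self):
        # default 10,000-bin genome; signal 30x the background mean
        cfg = SimConfig(n_genes=100, seed=13)
        counts, _, _, truth = simulate_dataset(cfg)
        calls = call_marks(downsample_counts(counts, seed=2),
                           filter_bins(counts))
        sens, fmr = [], []
        for s in calls.samples:
            if s.is_input or s.mark != "H3K27ac":
                continue
            planted = set(truth.true_marked_bins[s.sample_id])
            called = set(np.flatnonzero(calls.column(s.sample_id)).tolist())
            sens.append(len(planted & called) / len(planted))
            fmr.append(len(called - planted) / (len(calls.bin_index) - len(planted)))
        assert np.mean(sens) >= 0.95
        assert np.mean(fmr) <= 0.02

    def test_enhancer_targets_within_1mb(self, tiny_config):
        counts, genes, _, truth = simulate_dataset(tiny_config)
        tss = dict(zip(genes["gene_id"], zip(genes["chrom"], genes["tss"])))
        for b, g in truth.true_target_of_enhancer.items():
            chrom, start, end = counts.bin_index.coords(b)
            gchrom, gtss = tss[g]
            assert gchrom == chrom
            assert abs(gtss - (start + end) // 2) <= 1_000_000 + 500

    def test_ground_truth_json_roundtrip(self, tiny_config, tmp_path):
        _, _, _, truth = simulate_dataset(tiny_config)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        payload = json.loads(path.read_text())
        assert set(payload["true_marked_bins"]) == set(truth.true_marked_bins)


class TestProfiles:
    def test_all_inactive_mix_classifies_inactive(self):
        mix = {INACTIVE: 1.0}
        cfg = SimConfig(n_genes=100, tissues=("heart",), state_mix=mix, seed=1)
        profiles, truth, _ = simulate_tss_profiles(cfg)
        assert (truth == INACTIVE).all().all()
        for t in ("H3K4me3", "H3K27me3"):
            assert profiles["heart"][0].tracks[t].mean() < 5

    def test_narrow_archetype_skew_above_cut(self):
        prof = archetype_profiles(NARROW_EXPRESSED)
        summ = summarize_cluster(prof)
        assert summ.skew > 0.65
        assert summ.downstream_fraction > 0.9

    def test_broad_archetype_downstream_but_low_skew(self):
        prof = archetype_profiles(BROAD_EXPRESSED)
        summ = summarize_cluster(prof)
        assert summ.downstream_fraction > 0.9
        assert summ.skew < 0.65

    def test_broad_roughly_double_narrow(self):
        narrow = archetype_profiles(NARROW_EXPRESSED)
        broad = archetype_profiles(BROAD_EXPRESSED)
        ratio = broad["RNA"].sum() / narrow["RNA"].sum()
        assert 1.5 <= ratio <= 2.5

    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_genes=50, tissues=("heart",), seed=9)
        p1, t1, _ = simulate_tss_profiles(cfg)
        p2, t2, _ = simulate_tss_profiles(cfg)
        assert t1.equals(t2)
        assert np.array_equal(p1["heart"][0].tracks["RNA"],
                              p2["heart"][0].tracks["RNA"])


class TestDnmStudy:
    def _calls(self, cfg):
        counts, _, _, _ = simulate_dataset(cfg)
        return counts, call_marks(downsample_counts(counts, seed=1),
                                  filter_bins(counts))

    def test_zero_unmarked_rate_puts_all_dnms_in_elements(self, tiny_config):
        cfg = SimConfig(**{**tiny_config.__dict__,
                           "dnm_rate_marked": 1e-3, "dnm_rate_unmarked": 0.0})
        counts, calls = self._calls(cfg)
        regions, dnms, _ = simulate_dnm_study(cfg, calls)
        elements = marked_intervals(calls, marks=["H3K27ac"], replicated=True)
        res = dnm_enrichment_test(dnms, elements, regions,
                                  counts.bin_index.chrom_sizes)
        assert len(dnms) > 0
        assert res.observed == len(dnms)

    def test_empty_region_set_rejected(self, tiny_config):
        cfg = SimConfig(**{**tiny_config.__dict__, "n_dnm_regions": 0})
        counts, calls = self._calls(tiny_config)
        with pytest.raises(ValueError, match="region"):
            simulate_dnm_study(cfg, calls)

    def test_equal_rates_ratio_near_one(self, tiny_config):
        cfg = SimConfig(**{**tiny_config.__dict__,
                           "dnm_rate_marked": 6e-4, "dnm_rate_unmarked": 6e-4})
        counts, calls = self._calls(cfg)
        elements = marked_intervals(calls, marks=["H3K27ac"], replicated=True)
        cover = 0
        for s in range(30):
            regions, dnms, _ = simulate_dnm_study(cfg, calls, seed=500 + s)
            res = dnm_enrichment_test(dnms, elements, regions,
                                      counts.bin_index.chrom_sizes)
            cover += res.ci_low <= 1.0 <= res.ci_high
        assert cover / 30 >= 0.85
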