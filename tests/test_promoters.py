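import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from embryomark.promoters import (
    ACTIVELY_REPRESSED, BIDIR2, BIDIRECTIONAL_EXPRESSED, BROAD_EXPRESSED,
    EXPRESSED2, INACTIVE, NARROW_EXPRESSED, PROMOTER_STATES, TRACKS,
    ClassifierThresholds, ClusterSummary, PromoterStateTable, TssProfileSet,
    assign_states, build_tss_profiles, classify_cluster, cluster_promoters,
    cross_tissue_states, fisher_2x2, skew_statistic, summarize_cluster,
    tf_repression_enrichment,
)
from embryomark.simulate import SimConfig, archetype_profiles, simulate_tss_profiles


class TestBuildProfiles:
    def _signal(self, chrom_len=20_000):
        return {t: {"chrA": np.zeros(chrom_len)} for t in TRACKS}

    def test_minus_strand_gene_is_flipped(self):
        sig = self._signal()
        # signal 5' of the TSS in genome coordinates = downstream for "-"
        sig["H3K4me3"]["chrA"][9000:10000] = 1.0
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chrA"],
                              "strand": ["-"], "tss": [10_000]})
        p = build_tss_profiles(sig, genes, {"chrA": 20_000})
        k4 = p.tracks["H3K4me3"][0]
        assert k4[50:].sum() > 0 and k4[:50].sum() == 0

    def test_uniform_signal_flat_profile(self):
        sig = self._signal()
        sig["RNA"]["chrA"][:] = 1.0
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chrA"],
                              "strand": ["+"], "tss": [10_000]})
        p = build_tss_profiles(sig, genes, {"chrA": 20_000})
        rna = p.tracks["RNA"][0]
        assert np.allclose(rna, 60.0)  # 60 bp windows of unit signal
        assert rna[50:].sum() / rna.sum() == pytest.approx(0.5)

    def test_delta_signal_lands_in_correct_window(self):
        sig = self._signal()
        sig["H3K27ac"]["chrA"][10_100] = 5.0  # TSS + 100 bp
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chrA"],
                              "strand": ["+"], "tss": [10_000]})
        p = build_tss_profiles(sig, genes, {"chrA": 20_000})
        prof = p.tracks["H3K27ac"][0]
        # offset 3000+100 bp -> window index 3100 // 60 = 51
        assert prof[51] == 5.0 and prof.sum() == 5.0

    def test_edge_gene_dropped(self):
        genes = pd.DataFrame({"gene_id": ["g1", "g2"], "chrom": ["chrA"] * 2,
                              "strand": ["+", "+"], "tss": [1000, 10_000]})
        p = build_tss_profiles(self._signal(), genes, {"chrA": 20_000})
        assert p.genes == ["g2"]


class TestSkew:
    def test_symmetric_profile_zero(self):
        tri = np.concatenate([np.arange(1, 51), np.arange(1, 51)[::-1]])
        assert skew_statistic(tri) == pytest.approx(0.0, abs=1e-12)

    def test_right_tailed_profile_matches_direct_moments(self):
        prof = np.array([100, 80, 60, 40, 20] + [1] * 95, dtype=float)
        # independent weighted-moment computation
        i = np.arange(1, 101)
        w = prof / prof.sum()
        mu = (i * w).sum()
        m2 = (w * (i - mu) ** 2).sum()
        m3 = (w * (i - mu) ** 3).sum()
        assert skew_statistic(prof) == pytest.approx(m3 / m2 ** 1.5, rel=1e-12)
        assert skew_statistic(prof) > 0

    def test_mirror_image_negates(self, rng):
        prof = rng.random(100)
        assert skew_statistic(prof[::-1]) == pytest.approx(
            -skew_statistic(prof), abs=1e-10)

    def test_all_zero_undefined(self):
        assert math.isnan(skew_statistic(np.zeros(100)))


def _summary(k4=0.0, k27ac=0.0, k27me3=0.0, rna=0.0, ds=0.5, skew=0.0):
    return ClusterSummary(
        mean_signal={"H3K4me3": k4, "H3K27ac": k27ac,
                     "H3K27me3": k27me3, "RNA": rna},
        downstream_fraction=ds, skew=skew)


MAXIMA = {"H3K4me3": 1.0, "H3K27ac": 1.0, "H3K27me3": 1.0, "RNA": 1.0}


class TestClassifyRules:
    @pytest.mark.parametrize("summary,expected", [
        (_summary(k27me3=0.6, rna=0.05), ACTIVELY_REPRESSED),
        (_summary(k4=0.4, ds=0.95, skew=0.8, rna=0.5), NARROW_EXPRESSED),
        (_summary(k4=0.4, ds=0.95, skew=0.3, rna=0.5), BROAD_EXPRESSED),
        (_summary(k4=0.4, ds=0.5, rna=0.5), BIDIRECTIONAL_EXPRESSED),
        (_summary(k4=0.1, ds=0.5, rna=0.5), BIDIR2),
        (_summary(k4=0.4, ds=0.95, skew=0.8, rna=0.05), EXPRESSED2),
        (_summary(k4=0.1, k27me3=0.1, rna=0.05), INACTIVE),
    ])
    def test_rule_table(self, summary, expected):
        state, low_conf = classify_cluster(summary, MAXIMA)
        assert state == expected
        assert not low_conf

    def test_repression_takes_precedence(self):
        # repressed rule fires before the expressed rules
        s = _summary(k4=0.9, k27me3=0.9, rna=0.05, ds=0.95, skew=0.9)
        assert classify_cluster(s, MAXIMA)[0] == ACTIVELY_REPRESSED

    def test_scale_invariance(self):
        s1 = _summary(k4=0.4, ds=0.95, skew=0.8, rna=0.5)
        s2 = _summary(k4=4.0, ds=0.95, skew=0.8, rna=5.0)
        maxima10 = {t: 10.0 for t in MAXIMA}
        assert classify_cluster(s1, MAXIMA)[0] == classify_cluster(s2, maxima10)[0]

    def test_noiseless_archetypes_all_recovered(self):
        arches = {s: archetype_profiles(s) for s in PROMOTER_STATES}
        summaries = {s: summarize_cluster(a) for s, a in arches.items()}
        maxima = {t: max(s.mean_signal[t] for s in summaries.values())
                  for t in TRACKS}
        for state, summ in summaries.items():
            got, low_conf = classify_cluster(summ, maxima)
            assert got == state
            assert not low_conf


class TestClustering:
    def test_two_planted_archetypes_fully_separated(self, rng):
        a = archetype_profiles(NARROW_EXPRESSED)
        b = archetype_profiles(ACTIVELY_REPRESSED)
        n = 60
        tracks = {t: np.vstack([rng.poisson(a[t], (n, 100)),
                                rng.poisson(b[t], (n, 100))]).astype(float)
                  for t in TRACKS}
        p = TssProfileSet([f"g{i}" for i in range(2 * n)], tracks, 60)
        labels, _ = cluster_promoters(p, k=2, seed=0)
        truth = [0] * n + [1] * n
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k1_single_cluster_and_k_too_large(self, rng):
        tracks = {t: rng.poisson(1.0, (5, 100)).astype(float) for t in TRACKS}
        p = TssProfileSet([f"g{i}" for i in range(5)], tracks, 60)
        labels, _ = cluster_promoters(p, k=1, seed=0)
        assert set(labels) == {0}
        with pytest.raises(ValueError):
            cluster_promoters(p, k=6, seed=0)

    def test_same_seed_same_assignment(self, rng):
        tracks = {t: rng.poisson(2.0, (40, 100)).astype(float) for t in TRACKS}
        p = TssProfileSet([f"g{i}" for i in range(40)], tracks, 60)
        l1, _ = cluster_promoters(p, k=3, seed=5)
        l2, _ = cluster_promoters(p, k=3, seed=5)
        assert np.array_equal(l1, l2)


class TestAssignStates:
    def test_planted_state_recovery(self):
        cfg = SimConfig(n_genes=600, tissues=("heart", "brain"), seed=11)
        profiles, truth, _ = simulate_tss_profiles(cfg)
        table = assign_states(profiles, k=5, seed=11)
        assert (table.states == truth).to_numpy().mean() >= 0.95

    def test_identical_replicates_concordant(self):
        cfg = SimConfig(n_genes=200, tissues=("heart",), seed=3)
        profiles, _, _ = simulate_tss_profiles(cfg)
        rep = profiles["heart"][0]
        table = assign_states({"heart": [rep, rep]}, k=5, seed=0)
        assert table.concordant["heart"].all()

    def test_extended_k_isolates_weak_k4_repressed_subcluster(self):
        mix = {NARROW_EXPRESSED: 0.2, BROAD_EXPRESSED: 0.2,
               BIDIRECTIONAL_EXPRESSED: 0.1, ACTIVELY_REPRESSED: 0.2,
               INACTIVE: 0.3, BIDIR2: 0.0, EXPRESSED2: 0.0}
        cfg = SimConfig(n_genes=800, tissues=("kidney",), state_mix=mix, seed=5)
        profiles, truth, biv = simulate_tss_profiles(cfg, bivalent_like_frac=0.08)
        table = assign_states(profiles, k=10, seed=5)
        biv_genes = biv["kidney"]
        assert len(biv_genes) > 20
        clusters = table.cluster_ids.loc[biv_genes, "kidney"]
        # the weak-K4 + K27me3 archetype concentrates in one dedicated cluster
        top = clusters.value_counts()
        assert top.iloc[0] / len(biv_genes) >= 0.9
        members = table.cluster_ids["kidney"] == top.index[0]
        assert members.sum() <= len(biv_genes) * 1.2


def _table(states, tissues):
    genes = [f"g{i}" for i in range(len(states))]
    df = pd.DataFrame(states, index=genes, columns=tissues)
    ones = pd.DataFrame(0, index=genes, columns=tissues)
    flags = pd.DataFrame(True, index=genes, columns=tissues)
    return PromoterStateTable(df, ones, flags)


class TestCrossTissue:
    def test_disallowed_and_residual_sets(self):
        tissues = ["A", "B", "C"]
        table = _table([
            [NARROW_EXPRESSED, BROAD_EXPRESSED, BROAD_EXPRESSED],   # invariant
            [NARROW_EXPRESSED, ACTIVELY_REPRESSED, ACTIVELY_REPRESSED],  # disallowed A
            [BROAD_EXPRESSED, INACTIVE, INACTIVE],                   # inactive elsewhere
            [NARROW_EXPRESSED, ACTIVELY_REPRESSED, INACTIVE],        # mixed
        ], tissues)
        out = cross_tissue_states(table)
        assert out["disallowed"]["A"] == ["g1"]
        assert out["inactive_elsewhere"]["A"] == ["g2"]
        assert out["mixed_elsewhere"]["A"] == ["g3"]
        assert out["disallowed"]["B"] == []
        # g0 expressed everywhere: amalgamated state invariant
        assert out["amalgamated"].loc["g0"].nunique() == 1
        assert out["variable_fraction"] == pytest.approx(3 / 4)

    def test_requires_two_tissues(self):
        table = _table([[NARROW_EXPRESSED]], ["A"])
        with pytest.raises(ValueError):
            cross_tissue_states(table)


class TestFisher:
    def test_balanced_table_or_one(self):
        odds, p = fisher_2x2(10, 20, 5, 10)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_tiny_table_matches_enumeration_oracle(self):
        a, b, c, d = 3, 1, 1, 3
        odds, p = fisher_2x2(a, b, c, d)
        # enumerate all tables with the same margins
        r1, c1, n = a + b, a + c, a + b + c + d
        probs = []
        for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
            probs.append(math.comb(c1, x) * math.comb(n - c1, r1 - x)
                         / math.comb(n, r1))
        obs = probs[a - max(0, r1 + c1 - n)]
        expected_p = sum(pr for pr in probs if pr <= obs + 1e-12)
        assert p == pytest.approx(expected_p, rel=1e-9)
        assert odds == pytest.approx(9.0)

    def test_zero_margin_undefined(self):
        odds, _ = fisher_2x2(0, 0, 3, 4)
        assert math.isnan(odds)

    def test_tf_enrichment_counts(self):
        tissues = ["A", "B"]
        states = [[ACTIVELY_REPRESSED, INACTIVE]] * 3 + [[INACTIVE, INACTIVE]] * 7
        table = _table(states, tissues)
        is_tf = pd.Series([True, True, False, True, False, False, False,
                           False, False, False], index=table.genes)
        res = tf_repression_enrichment(table, is_tf)
        assert res["table"] == ((2, 1), (1, 6))
        assert res["odds_ratio"] == pytest.approx(12.0)
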