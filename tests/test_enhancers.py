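"""Enhancer enrichment filter and random-order specificity overlay.

The overlay is verified against a brute-force base-level simulator that
replays the sequential algorithm on per-base boolean arrays.
"""

import numpy as np
import pandas as pd
import pytest

from embryomark.enhancers import (PeakSet, enrichment_filter,
                                  overlay_concordance, specificity_overlay)
from embryomark.simulate import SimConfig, simulate_peak_sets
from embryomark import intervals as iv


def _peaks(tissue, triples):
    df = pd.DataFrame(triples, columns=["chrom", "start", "end"])
    df["rpkm"] = 50.0
    return PeakSet(tissue, df)


class TestEnrichmentFilter:
    def _one_peak(self, rpkm):
        return PeakSet("heart", pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1000], "rpkm": [rpkm]}))

    @pytest.mark.parametrize("rpkm,refs,kept", [
        (30.0, [12.0] * 7, True),    # >= 25 and >= 2.5x all references
        (30.0, [12.0] * 6 + [13.0], False),  # 30 < 2.5 * 13 = 32.5
        (24.0, [0.0] * 7, False),    # below the absolute floor
    ])
    def test_rule_arithmetic(self, rpkm, refs, kept):
        ref = pd.DataFrame([refs])
        out = enrichment_filter(self._one_peak(rpkm), ref)
        assert len(out) == (1 if kept else 0)

    def test_empty_reference_degrades_with_warning(self):
        with pytest.warns(UserWarning, match="reference"):
            out = enrichment_filter(self._one_peak(30.0),
                                    pd.DataFrame(index=[0]))
        assert len(out) == 1


def overlay_oracle(peak_sets, order, genome=20_000, min_length=200,
                   overlap_frac=0.5):
    """Base-level replay of the sequential overlay on boolean arrays."""
    def cover(peaks):
        m = np.zeros(genome, dtype=bool)
        for _, s, e in peaks:
            m[s:e] = True
        return m

    existing = [(peak_sets[order[0]].tissue, s, e)
                for _, s, e in peak_sets[order[0]].peaks[
                    ["chrom", "start", "end"]].itertuples(index=False)]
    existing = [(t, s, e) for t, s, e in existing]
    footprint = cover([(None, s, e) for _, s, e in existing])
    for idx in order[1:]:
        ps = peak_sets[idx]
        new = [(ps.tissue, int(r.start), int(r.end))
               for r in ps.peaks.itertuples(index=False)]
        new_mask = cover([(None, s, e) for _, s, e in new])
        kept_ex = [p for p in existing
                   if new_mask[p[1]:p[2]].sum() < overlap_frac * (p[2] - p[1])]
        kept_new = [p for p in new
                    if footprint[p[1]:p[2]].sum() < overlap_frac * (p[2] - p[1])]
        nxt = []
        for t, s, e in kept_ex:
            m = np.zeros(genome, dtype=bool)
            m[s:e] = True
            m &= ~new_mask
            nxt.extend(_runs(m, t))
        for t, s, e in kept_new:
            m = np.zeros(genome, dtype=bool)
            m[s:e] = True
            m &= ~footprint
            nxt.extend(_runs(m, t))
        existing = nxt
        footprint |= new_mask
    return sorted((t, s, e) for t, s, e in existing if e - s > min_length)


def _runs(mask, tissue):
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        ends = ends + [mask.size]
    return [(tissue, int(s), int(e)) for s, e in zip(starts, ends)]


class TestOverlay:
    def test_disjoint_inputs_pass_through(self):
        a = _peaks("A", [("chr1", 0, 1000), ("chr1", 5000, 6000)])
        b = _peaks("B", [("chr1", 2000, 3000)])
        res = specificity_overlay([a, b], seed=0)
        got = set(map(tuple, res.regions[["chrom", "start", "end", "tissue"]]
                      .itertuples(index=False)))
        assert got == {("chr1", 0, 1000, "A"), ("chr1", 5000, 6000, "A"),
                       ("chr1", 2000, 3000, "B")}

    def test_worked_majority_overlap_example(self):
        # A (1000 bp) overlapped 600 bp by B (800 bp): A removed (60%),
        # B removed too (600 >= 50% of 800); nothing survives
        a = _peaks("A", [("chr1", 0, 1000)])
        b = _peaks("B", [("chr1", 400, 1200)])
        res = specificity_overlay([a, b], seed=0)
        assert len(res.regions) == 0

    def test_asymmetric_overlap_subtracts_bases(self):
        # A 1000 bp; B 3000 bp overlapping A by 600: A removed (60%),
        # B kept (20%) minus the 600 overlapping bases
        a = _peaks("A", [("chr1", 0, 1000)])
        b = _peaks("B", [("chr1", 400, 3400)])
        for seed in (0, 1):  # both orders
            res = specificity_overlay([a, b], seed=seed)
            got = list(res.regions.itertuples(index=False))
            assert len(got) == 1
            r = got[0]
            assert (r.chrom, r.start, r.end, r.tissue) == ("chr1", 1000, 3400, "B")

    def test_shared_by_all_absent_everywhere(self):
        shared = ("chr1", 10_000, 11_000)
        sets = [_peaks(t, [shared, ("chr1", 2000 * i, 2000 * i + 500)])
                for i, t in enumerate(["A", "B", "C"])]
        res = specificity_overlay(sets, seed=3)
        for r in res.regions.itertuples(index=False):
            assert not (r.start < 11_000 and r.end > 10_000)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_base_level_oracle(self, seed, rng):
        rg = np.random.default_rng(seed)
        sets = []
        for t in "ABC":
            starts = np.sort(rg.choice(np.arange(0, 19_000, 250), 12,
                                       replace=False))
            rows = []
            last_end = -1
            for s in starts:
                e = int(s + rg.integers(210, 700))
                if s <= last_end:
                    continue
                rows.append(("chr1", int(s), min(e, 20_000)))
                last_end = min(e, 20_000)
            sets.append(_peaks(t, rows))
        res = specificity_overlay(sets, seed=seed)
        order = np.random.default_rng(seed).permutation(3)
        want = overlay_oracle(sets, list(order))
        got = sorted((r.tissue, r.start, r.end)
                     for r in res.regions.itertuples(index=False))
        assert got == want

    def test_outputs_disjoint_and_subset_of_inputs(self):
        cfg = SimConfig(seed=1)
        sets, _, _ = simulate_peak_sets(cfg, n_peaks=150,
                                        overlap_fraction=0.05, seed=2)
        res = specificity_overlay(sets, seed=5)
        for chrom, grp in res.regions.groupby("chrom"):
            g = grp.sort_values("start")
            assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()
        inputs = {p.tissue: {c: iv.merge(g["start"].to_numpy(), g["end"].to_numpy())
                             for c, g in p.peaks.groupby("chrom")} for p in sets}
        for r in res.regions.itertuples(index=False):
            ms, me = inputs[r.tissue].get(r.chrom, ((), ()))
            assert iv.overlap_length(r.start, r.end, ms, me) == r.end - r.start


class TestConcordance:
    def test_identical_seeds_match_one(self):
        cfg = SimConfig(seed=1)
        sets, _, _ = simulate_peak_sets(cfg, n_peaks=100, seed=4)
        assert overlay_concordance(sets, 9, 9) == pytest.approx(1.0)

    def test_disjoint_sets_order_invariant(self):
        a = _peaks("A", [("chr1", 0, 1000)])
        b = _peaks("B", [("chr1", 5000, 6000)])
        c = _peaks("C", [("chr2", 0, 500)])
        assert overlay_concordance([a, b, c], 1, 2) == pytest.approx(1.0)

    def test_low_overlap_high_concordance(self):
        cfg = SimConfig(seed=0)
        sets, _, _ = simulate_peak_sets(cfg, n_peaks=200,
                                        overlap_fraction=0.01, seed=1)
        vals = [overlay_concordance(sets, 2 * i, 2 * i + 1) for i in range(5)]
        assert min(vals) >= 0.95

    def test_full_pipeline_recovers_planted_specific_bases(self):
        cfg = SimConfig(seed=3)
        sets, ref, truth = simulate_peak_sets(cfg, n_peaks=200,
                                              overlap_fraction=0.01, seed=6)
        filtered = [enrichment_filter(s, ref[s.tissue]) for s in sets]
        res = specificity_overlay(filtered, seed=11)
        recovered, total = 0, 0
        for t, want in truth.items():
            got = res.regions[res.regions["tissue"] == t]
            merged = {c: iv.merge(g["start"].to_numpy(), g["end"].to_numpy())
                      for c, g in got.groupby("chrom")}
            for c, s, e in want:
                total += e - s
                recovered += iv.overlap_length(s, e, *merged.get(c, ((), ())))
        assert recovered / total >= 0.90
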