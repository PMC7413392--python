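"""Synthetic multi-tissue epigenomes with planted ground truth.

Emulates the statistical shape of replicated multi-tissue histone-mark
ChIP-seq binned to 1 kb, paired RNA expression, TSS profile archetypes for
the seven promoter states, and a DNM study over surveyed non-coding regions:

* background bin counts are negative-binomial (overdispersed, as ChIP bin
  counts are), with per-tissue input-control tracks at the same level;
* marked bins are planted in chosen sample subsets (tissue-specific or
  shared patterns) by adding Poisson signal on top of the background;
* enhancer-target pairs share a latent per-tissue activity so that bin
  signal and target-gene expression correlate at a controllable level;
* DNMs are placed with a higher per-base rate inside (slop-expanded) marked
  elements than elsewhere in the surveyed regions.

Everything is deterministic given the config seed.  What the generator does
not emulate: raw reads, fragment-length effects, GC bias, mappability,
copy-number artefacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as iv
from .binning import BinCountMatrix, SampleMeta, make_bins
from .calling import MarkCallMatrix
from .promoters import (
    ACTIVELY_REPRESSED, BIDIR2, BIDIRECTIONAL_EXPRESSED, BROAD_EXPRESSED,
    EXPRESSED2, INACTIVE, NARROW_EXPRESSED, TRACKS, TssProfileSet,
)

__all__ = ["PlantedPattern", "SimConfig", "GroundTruth", "simulate_dataset",
           "simulate_tss_profiles", "simulate_dnm_study", "archetype_profiles"]

DEFAULT_TISSUES = ("heart", "brain", "liver", "kidney", "limb", "palate")

# five major promoter states carry the default mass; the two minor states
# (bidir2, expressed2) are tissue-restricted findings and default to zero
DEFAULT_STATE_MIX = {
    NARROW_EXPRESSED: 0.15,
    BROAD_EXPRESSED: 0.25,
    BIDIRECTIONAL_EXPRESSED: 0.10,
    BIDIR2: 0.0,
    EXPRESSED2: 0.0,
    ACTIVELY_REPRESSED: 0.15,
    INACTIVE: 0.35,
}


@dataclass(frozen=True)
class PlantedPattern:
    """Bins marked in every replicate of ``tissues`` for ``mark``."""

    mark: str
    tissues: tuple[str, ...]
    n_bins: int


def _default_patterns(tissues):
    """One tissue-specific H3K27ac pattern per tissue plus one shared-all."""
    pats = [PlantedPattern("H3K27ac", (t,), 300) for t in tissues]
    pats.append(PlantedPattern("H3K27ac", tuple(tissues), 200))
    return tuple(pats)


@dataclass
class SimConfig:
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    bin_width: int = 1000
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    replicates_per_tissue: int = 2
    marks: tuple[str, ...] = ("H3K4me3", "H3K27ac", "H3K27me3")
    background_mean: float = 1.0
    background_dispersion: float = 0.3
    signal_mean: float = 30.0
    planted_patterns: tuple[PlantedPattern, ...] | None = None
    n_genes: int = 5000
    state_mix: dict = field(default_factory=lambda: dict(DEFAULT_STATE_MIX))
    enhancer_target_pairs: int = 40
    coupling_r: float = 0.9
    dnm_rate_marked: float = 1.45e-4
    dnm_rate_unmarked: float = 1.0e-4
    n_dnm_regions: int = 1500
    dnm_region_length: int = 700
    profile_noise: float = 0.25   # sd of per-gene lognormal amplitude factor
    include_input: bool = True
    input_depth_factor: float = 0.1  # input sequencing depth relative to ChIP
    seed: int = 0

    def __post_init__(self):
        if self.planted_patterns is None:
            self.planted_patterns = _default_patterns(self.tissues)
        if abs(sum(self.state_mix.values()) - 1.0) > 1e-9:
            raise ValueError("state_mix proportions must sum to 1")
        for name in ("background_mean", "signal_mean", "dnm_rate_marked",
                     "dnm_rate_unmarked", "background_dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if not 0 < self.coupling_r <= 1:
            raise ValueError("coupling_r must be in (0, 1]")
        for p in self.planted_patterns:
            if p.mark not in self.marks:
                raise ValueError(f"pattern mark {p.mark!r} not in marks")
            unknown = set(p.tissues) - set(self.tissues)
            if unknown:
                raise ValueError(f"pattern tissues {sorted(unknown)} not in tissues")

    @property
    def chrom_sizes(self):
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    def sample_metas(self):
        metas = []
        for t in self.tissues:
            for m in self.marks:
                for r in range(1, self.replicates_per_tissue + 1):
                    metas.append(SampleMeta(f"{t}_{m}_r{r}", t, r, m))
            if self.include_input:
                metas.append(SampleMeta(f"{t}_input", t, 1, "input", is_input=True))
        return metas


@dataclass
class GroundTruth:
    true_marked_bins: dict            # sample_id -> sorted list of bin ids
    true_pattern_of_bin: dict         # bin id -> tuple of sample ids
    true_state_of_gene: object = None  # gene x tissue DataFrame of states
    true_target_of_enhancer: dict = field(default_factory=dict)  # bin -> gene
    true_enriched_elements: object = None  # {chrom: (starts, ends)}
    true_dnm_rate_ratio: float | None = None

    def to_json(self, path):
        payload = {
            "true_marked_bins": {k: list(map(int, v))
                                 for k, v in self.true_marked_bins.items()},
            "true_pattern_of_bin": {str(k): list(v)
                                    for k, v in self.true_pattern_of_bin.items()},
            "true_target_of_enhancer": {str(k): v for k, v in
                                        self.true_target_of_enhancer.items()},
            "true_dnm_rate_ratio": self.true_dnm_rate_ratio,
        }
        if self.true_state_of_gene is not None:
            payload["true_state_of_gene"] = self.true_state_of_gene.to_dict()
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _nb_counts(rng, mean, dispersion, size):
    """Negative binomial with var = mean + dispersion * mean^2."""
    if mean == 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion == 0:
        return rng.poisson(mean, size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size)


def simulate_dataset(config: SimConfig):
    """Bin counts, gene annotation, expression and ground truth.

    Returns (BinCountMatrix, genes DataFrame, expression DataFrame,
    GroundTruth).  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    bins = make_bins(config.chrom_sizes, config.bin_width)
    metas = config.sample_metas()
    counts = np.empty((len(bins), len(metas)), dtype=np.int64)
    for j, m in enumerate(metas):
        depth = config.input_depth_factor if m.is_input else 1.0
        counts[:, j] = _nb_counts(rng, depth * config.background_mean,
                                  config.background_dispersion, len(bins))

    n_planted = sum(p.n_bins for p in config.planted_patterns)
    n_enh = config.enhancer_target_pairs
    if n_planted + n_enh > len(bins):
        raise ValueError("too many planted bins")
    chosen = rng.choice(len(bins), size=n_planted + n_enh, replace=False)
    pattern_bins, enhancer_bins = chosen[:n_planted], chosen[n_planted:]

    sid = {m.sample_id: j for j, m in enumerate(metas)}
    true_marked = {m.sample_id: [] for m in metas}
    true_pattern = {}
    pos = 0
    for pat in config.planted_patterns:
        sub = [m.sample_id for m in metas
               if not m.is_input and m.mark == pat.mark and m.tissue in pat.tissues]
        bin_ids = pattern_bins[pos:pos + pat.n_bins]
        pos += pat.n_bins
        for b in bin_ids:
            true_pattern[int(b)] = tuple(sub)
        for s in sub:
            j = sid[s]
            if config.signal_mean > 0:
                counts[bin_ids, j] += rng.poisson(config.signal_mean, pat.n_bins)
            true_marked[s].extend(int(b) for b in bin_ids)

    # gene annotation: TSS kept >= 3 kb from chromosome edges
    flank = 3000
    gene_chrom_idx = rng.integers(0, config.n_chroms, config.n_genes)
    gene_tss = rng.integers(flank, config.chrom_length - flank, config.n_genes)
    genes = pd.DataFrame({
        "gene_id": [f"g{i:05d}" for i in range(config.n_genes)],
        "chrom": [f"chr{c + 1}" for c in gene_chrom_idx],
        "strand": rng.choice(["+", "-"], config.n_genes),
        "tss": gene_tss,
        "is_TF": rng.random(config.n_genes) < 0.084,
        "has_CpG": rng.random(config.n_genes) < 0.677,
    })

    # expression: per-gene baseline with independent per-tissue variation
    n_t = len(config.tissues)
    base = rng.lognormal(mean=3.0, sigma=1.0, size=config.n_genes)
    tissue_var = rng.lognormal(mean=0.0, sigma=0.5, size=(config.n_genes, n_t))
    expr = base[:, None] * tissue_var

    # enhancer-target coupling via a shared latent per-tissue activity
    rho = config.coupling_r
    targets = {}
    if n_enh:
        target_rows = rng.choice(config.n_genes, size=n_enh, replace=False)
        sigma = 0.6
        for b, gi in zip(enhancer_bins, target_rows):
            # relocate the enhancer bin within 1 Mb of the target gene's TSS
            chrom = genes.loc[gi, "chrom"]
            tss = int(genes.loc[gi, "tss"])
            lo = max(0, tss - 1_000_000)
            hi = min(config.chrom_length - 1, tss + 1_000_000)
            pos_bp = int(rng.integers(lo, hi))
            b = bins.bin_id(chrom, pos_bp)
            while int(b) in true_pattern or int(b) in targets:
                pos_bp = int(rng.integers(lo, hi))
                b = bins.bin_id(chrom, pos_bp)
            z = rng.standard_normal(n_t)
            eps = rng.standard_normal(n_t)
            expr[gi] = 50.0 * np.exp(sigma * z)
            activity = np.exp(sigma * (rho * z + np.sqrt(1 - rho ** 2) * eps))
            for ti, t in enumerate(config.tissues):
                for m in metas:
                    if m.tissue == t and m.mark == "H3K27ac" and not m.is_input:
                        counts[b, sid[m.sample_id]] += rng.poisson(
                            config.signal_mean * activity[ti])
            targets[int(b)] = genes.loc[gi, "gene_id"]

    expression = pd.DataFrame(expr, index=genes["gene_id"],
                              columns=list(config.tissues))
    truth = GroundTruth(
        true_marked_bins={k: sorted(v) for k, v in true_marked.items()},
        true_pattern_of_bin=true_pattern,
        true_target_of_enhancer=targets,
    )
    matrix = BinCountMatrix(bins, metas, counts)
    return matrix, genes, expression, truth


# --- TSS profile archetypes -------------------------------------------------

_W = 100  # windows over TSS +/- 3 kb (60 bp each)

# background floors (expected reads per window)
_BG = {"H3K4me3": 1.0, "H3K27ac": 1.0, "H3K27me3": 1.0, "RNA": 0.3}


def _downstream(shape50):
    v = np.zeros(_W)
    v[_W // 2:] = shape50
    return v


def archetype_profiles(state):
    """Noise-free mean profiles ({track: 100-window vector}) for one state.

    Shapes realise the state definitions: narrow-expressed H3K4me3 decays
    sharply downstream of the TSS (> 90% of reads downstream, skew > 0.65);
    broad-expressed is a downstream plateau of roughly double the width and
    mean (skew < 0.65) with double the transcription; bidirectional splits
    H3K4me3 symmetrically across the TSS; actively-repressed has a broad
    H3K27me3 dome and near-zero RNA; inactive is background everywhere.
    """
    j = np.arange(_W // 2, dtype=float)       # downstream window index
    i = np.arange(_W, dtype=float)            # full-grid index
    prof = {t: np.full(_W, _BG[t]) for t in TRACKS}

    narrow_k4 = _downstream(300.0 * np.exp(-j / 6.0))
    plateau = np.where(j < 24, 150.0, 150.0 * np.exp(-(j - 24) / 4.0))
    rna_short = _downstream(80.0 * np.exp(-j / 15.0))
    rna_long = _downstream(160.0 * np.exp(-j / 15.0))

    if state == NARROW_EXPRESSED:
        prof["H3K4me3"] += narrow_k4
        prof["H3K27ac"] += _downstream(120.0 * np.exp(-j / 8.0))
        prof["RNA"] += rna_short
    elif state == BROAD_EXPRESSED:
        prof["H3K4me3"] += _downstream(plateau)
        prof["H3K27ac"] += _downstream(np.where(j < 24, 100.0,
                                                100.0 * np.exp(-(j - 24) / 4.0)))
        prof["RNA"] += rna_long
    elif state == BIDIRECTIONAL_EXPRESSED:
        sym = 150.0 * np.exp(-np.abs(i - (_W - 1) / 2) / 6.0)
        prof["H3K4me3"] += sym
        prof["H3K27ac"] += 0.8 * sym
        prof["RNA"] += rna_short
    elif state == BIDIR2:
        prof["H3K27ac"] += _downstream(80.0 * np.exp(-j / 8.0))
        prof["RNA"] += rna_short
    elif state == EXPRESSED2:
        prof["H3K4me3"] += narrow_k4
        prof["H3K27ac"] += _downstream(120.0 * np.exp(-j / 8.0))
        # transcript detection at the TSS limited (long-gene artefact)
    elif state == ACTIVELY_REPRESSED:
        prof["H3K27me3"] += 120.0 * np.exp(-np.abs(i - (_W - 1) / 2) / 30.0)
    elif state == INACTIVE:
        pass
    elif state == "bivalent_like":
        prof["H3K27me3"] += 120.0 * np.exp(-np.abs(i - (_W - 1) / 2) / 30.0)
        prof["H3K4me3"] += _downstream(40.0 * np.exp(-j / 6.0))
        prof["RNA"] += _downstream(3.0 * np.exp(-j / 15.0))
    else:
        raise ValueError(f"unknown state {state!r}")
    return prof


def simulate_tss_profiles(config: SimConfig, seed=None, bivalent_like_frac=0.0):
    """Per-tissue replicated TSS profiles realising planted promoter states.

    States are drawn per gene per tissue from ``config.state_mix`` (optionally
    with an extra weak-H3K4me3 + H3K27me3 archetype at ``bivalent_like_frac``,
    recorded as actively_repressed in the truth table but listed separately).
    Each replicate is an independent Poisson realisation of the archetype
    mean scaled by a per-gene-per-tissue lognormal amplitude factor.

    Returns (profiles: {tissue: [TssProfileSet per replicate]},
    truth_states: gene x tissue DataFrame, bivalent_like: {tissue: gene ids}).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    states = [s for s, w in config.state_mix.items() if w > 0]
    weights = np.array([config.state_mix[s] for s in states], dtype=float)
    if bivalent_like_frac > 0:
        weights = weights * (1 - bivalent_like_frac)
        states = states + ["bivalent_like"]
        weights = np.append(weights, bivalent_like_frac)
    weights = weights / weights.sum()
    if config.n_genes < len(states):
        raise ValueError("n_genes must be >= number of states with nonzero mix")
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]

    arch = {s: archetype_profiles(s) for s in states}
    arch_mat = {t: np.array([arch[s][t] for s in states]) for t in TRACKS}
    truth = {}
    biv = {}
    profiles = {}
    for tissue in config.tissues:
        drawn = rng.choice(len(states), size=config.n_genes, p=weights)
        tissue_states = [states[d] for d in drawn]
        truth[tissue] = [ACTIVELY_REPRESSED if s == "bivalent_like" else s
                         for s in tissue_states]
        biv[tissue] = [g for g, s in zip(gene_ids, tissue_states)
                       if s == "bivalent_like"]
        amp = rng.lognormal(0.0, config.profile_noise, config.n_genes)
        reps = []
        for _ in range(config.replicates_per_tissue):
            tracks = {}
            for t in TRACKS:
                mean = _BG[t] + amp[:, None] * (arch_mat[t][drawn] - _BG[t])
                tracks[t] = rng.poisson(mean).astype(float)
            reps.append(TssProfileSet(list(gene_ids), tracks, window_width=60))
        profiles[tissue] = reps
    truth_df = pd.DataFrame(truth, index=gene_ids)
    return profiles, truth_df, biv


def simulate_peak_sets(config: SimConfig, n_peaks=300, overlap_fraction=0.01,
                       seed=None, rpkm_low=8.0, rpkm_high=60.0,
                       frac_unenriched=0.2):
    """Per-tissue H3K27ac peak sets with controlled inter-tissue overlap.

    Peaks are placed in disjoint 3 kb slots so that, apart from the
    deliberately overlapped fraction, peaks of different tissues never touch.
    For ``overlap_fraction`` of peaks a second peak covering >= 60% of the
    original is added to another tissue's set (such shared peaks are expected
    to be consumed by the specificity overlay).  A fraction of peaks is
    "unenriched": low RPKM and high reference signal, to be removed by the
    enrichment filter.  Returns (peak_sets, reference_rpkm {tissue:
    DataFrame}, truth {tissue: set of planted specific (chrom, start, end)}).
    """
    from .enhancers import PeakSet  # local import to avoid a cycle

    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    slot = 3000
    slots_per_chrom = config.chrom_length // slot
    total_slots = config.n_chroms * slots_per_chrom
    n_tissues = len(config.tissues)
    need = n_tissues * n_peaks
    if need > total_slots:
        raise ValueError("too many peaks for the genome")
    chosen = rng.choice(total_slots, size=need, replace=False)

    peaks = {t: [] for t in config.tissues}
    truth = {t: set() for t in config.tissues}
    n_ref = 7
    ref_rows = {t: [] for t in config.tissues}
    for i, slot_id in enumerate(chosen):
        tissue = config.tissues[i % n_tissues]
        chrom = f"chr{slot_id // slots_per_chrom + 1}"
        base = (slot_id % slots_per_chrom) * slot
        length = int(rng.integers(300, 1500))
        # leave room for a 30%-shifted shared copy within the slot
        start = base + int(rng.integers(0, slot - length - 500))
        end = start + length
        unenriched = rng.random() < frac_unenriched
        if unenriched:
            rpkm = float(rng.uniform(2, 20))
            ref = rng.uniform(10, 40, n_ref)
        else:
            rpkm = float(rng.uniform(30, rpkm_high + 30))
            ref = rng.uniform(0, rpkm / 4.0, n_ref)
        peaks[tissue].append((chrom, start, end, rpkm))
        ref_rows[tissue].append(ref)
        shared = rng.random() < overlap_fraction
        if shared and not unenriched:
            other = config.tissues[int(rng.integers(0, n_tissues))]
            if other != tissue:
                shift = int(0.3 * length)
                peaks[other].append((chrom, start + shift, end + shift, rpkm))
                ref_rows[other].append(rng.uniform(0, rpkm / 4.0, n_ref))
        elif not unenriched:
            truth[tissue].add((chrom, start, end))

    peak_sets, reference = [], {}
    for t in config.tissues:
        df = pd.DataFrame(peaks[t], columns=["chrom", "start", "end", "rpkm"])
        order = df.sort_values(["chrom", "start"]).index
        peak_sets.append(PeakSet(t, df.loc[order].reset_index(drop=True)))
        reference[t] = pd.DataFrame(np.array(ref_rows[t])[order],
                                    columns=[f"ref{i}" for i in range(n_ref)])
        reference[t].reset_index(drop=True, inplace=True)
    return peak_sets, reference, truth


def simulate_dnm_study(config: SimConfig, calls: MarkCallMatrix, seed=None,
                       slop=1000, mark="H3K27ac"):
    """Surveyed non-coding regions and DNMs with planted rate enrichment.

    Regions (categories UCE/EVE/PHE in the study's proportions) are placed
    uniformly; DNMs arise per base at ``dnm_rate_marked`` inside the
    slop-expanded marked elements and ``dnm_rate_unmarked`` elsewhere within
    the surveyed regions.  Returns (regions DataFrame, dnms DataFrame,
    GroundTruth with the true rate ratio and element set).
    """
    if config.n_dnm_regions < 1:
        raise ValueError("region set must be non-empty")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    from .dnm import marked_intervals, _expand_clip  # local to avoid cycle

    elements = marked_intervals(calls, marks=[mark], replicated=True)
    chrom_sizes = calls.bin_index.chrom_sizes
    expanded = _expand_clip(elements, slop, chrom_sizes)

    chroms = list(chrom_sizes)
    cat_p = {"UCE": 0.702, "EVE": 0.097, "PHE": 0.201}
    cats = rng.choice(list(cat_p), size=config.n_dnm_regions,
                      p=list(cat_p.values()))
    lengths = np.maximum(200, rng.poisson(config.dnm_region_length,
                                          config.n_dnm_regions))
    rows = []
    for L, cat in zip(lengths, cats):
        c = chroms[rng.integers(0, len(chroms))]
        s = int(rng.integers(0, chrom_sizes[c] - L))
        rows.append({"chrom": c, "start": s, "end": s + int(L), "category": cat})
    regions = pd.DataFrame(rows)

    dnm_rows = []
    for row in regions.itertuples(index=False):
        # piecewise segments: covered (marked) and uncovered within the region
        segs = _split_by_coverage(row.start, row.end,
                                  expanded.get(row.chrom, ((), ())))
        for s, e, covered in segs:
            rate = config.dnm_rate_marked if covered else config.dnm_rate_unmarked
            n = rng.poisson(rate * (e - s))
            for p in rng.integers(s, e, n):
                dnm_rows.append({"chrom": row.chrom, "pos": int(p),
                                 "category": row.category})
    dnms = pd.DataFrame(dnm_rows, columns=["chrom", "pos", "category"])
    ratio = (config.dnm_rate_marked / config.dnm_rate_unmarked
             if config.dnm_rate_unmarked > 0 else float("inf"))
    truth = GroundTruth(true_marked_bins={}, true_pattern_of_bin={},
                        true_enriched_elements=elements,
                        true_dnm_rate_ratio=ratio)
    return regions, dnms, truth


def _split_by_coverage(start, end, merged):
    """Split [start, end) into (s, e, covered) segments vs a merged set."""
    ms, me = merged
    segs = []
    uncovered = iv.subtract_from(start, end, ms, me)
    for s, e in uncovered:
        segs.append((s, e, False))
    for s, e in zip(ms, me):
        lo, hi = max(start, s), min(end, e)
        if hi > lo:
            segs.append((lo, hi, True))
    segs.sort()
    return segs
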