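"""TSS-profile clustering and rule-based promoter-state classification.

For each gene, signal for three histone marks (H3K4me3, H3K27ac, H3K27me3)
and RNA is profiled over TSS +/- 3 kb in 100 strand-oriented windows.  Genes
are k-means-clustered on within-gene rank-transformed profiles, and each
cluster is classified into one of seven promoter states by threshold rules on
cluster-mean signal relative to the per-tissue maximum across clusters:

* actively_repressed    H3K27me3 > 50% of max, RNA < 10% of max
* narrow_expressed      H3K4me3 > 25% of max, > 90% of its reads downstream
                        of the TSS, downstream skew > 0.65, RNA > 10% of max
* broad_expressed       as narrow but skew < 0.65
* bidirectional_expressed  H3K4me3 > 25% of max, < 90% downstream, RNA > 10%
* bidir2                as bidirectional but without the H3K4me3 signal
* expressed2            H3K4me3 > 25% of max but RNA < 10% of max (transcript
                        detection at the TSS limited for long genes)
* inactive              H3K4me3 and H3K27me3 < 25% of max, RNA < 10% of max

Rules are evaluated in that order; the first match wins.  Skew is the moment
coefficient of skewness of the window-index distribution weighted by counts,
measured across 100 equidistant points from the TSS to +3 kb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

TRACKS = ("H3K4me3", "H3K27ac", "H3K27me3", "RNA")

# promoter states, in rule-evaluation order
ACTIVELY_REPRESSED = "actively_repressed"
NARROW_EXPRESSED = "narrow_expressed"
BROAD_EXPRESSED = "broad_expressed"
BIDIRECTIONAL_EXPRESSED = "bidirectional_expressed"
BIDIR2 = "bidir2"
EXPRESSED2 = "expressed2"
INACTIVE = "inactive"

PROMOTER_STATES = (
    ACTIVELY_REPRESSED,
    NARROW_EXPRESSED,
    BROAD_EXPRESSED,
    BIDIRECTIONAL_EXPRESSED,
    BIDIR2,
    EXPRESSED2,
    INACTIVE,
)

EXPRESSED_STATES = frozenset(
    {NARROW_EXPRESSED, BROAD_EXPRESSED, BIDIRECTIONAL_EXPRESSED, BIDIR2}
)

__all__ = [
    "TRACKS",
    "PROMOTER_STATES",
    "EXPRESSED_STATES",
    "ClassifierThresholds",
    "TssProfileSet",
    "ClusterSummary",
    "PromoterStateTable",
    "build_tss_profiles",
    "cluster_promoters",
    "skew_statistic",
    "summarize_cluster",
    "classify_cluster",
    "assign_states",
    "cross_tissue_states",
    "tf_repression_enrichment",
    "fisher_2x2",
]


@dataclass(frozen=True)
class ClassifierThresholds:
    repressed_k27me3_frac: float = 0.50
    expr_rna_frac: float = 0.10
    k4_frac: float = 0.25
    downstream_frac: float = 0.90
    skew_cut: float = 0.65
    n_percentiles: int = 100
    flank: int = 3000
    k_default: int = 5
    k_extended: tuple[int, ...] = (7, 10, 11)

    def __post_init__(self):
        for f in (self.repressed_k27me3_frac, self.expr_rna_frac, self.k4_frac,
                  self.downstream_frac, self.skew_cut):
            if not 0 < f < 1:
                raise ValueError("classifier fractions must be in (0, 1)")


@dataclass
class TssProfileSet:
    """genes x windows signal per track, strand-oriented (downstream right)."""

    genes: list[str]
    tracks: dict[str, np.ndarray]
    window_width: int

    def __post_init__(self):
        n = len(self.genes)
        w = None
        for t, m in self.tracks.items():
            m = np.asarray(m, dtype=float)
            self.tracks[t] = m
            if m.shape[0] != n:
                raise ValueError(f"track {t} row count != genes")
            if (m < 0).any():
                raise ValueError(f"track {t} has negative signal")
            if w is None:
                w = m.shape[1]
            elif m.shape[1] != w:
                raise ValueError("tracks have different window counts")
        self.n_windows = w

    @staticmethod
    def average(profile_sets):
        """Element-wise mean over replicate profile sets (same genes)."""
        first = profile_sets[0]
        for p in profile_sets[1:]:
            if p.genes != first.genes:
                raise ValueError("profile sets have different gene lists")
        tracks = {
            t: np.mean([p.tracks[t] for p in profile_sets], axis=0)
            for t in first.tracks
        }
        return TssProfileSet(list(first.genes), tracks, first.window_width)


def build_tss_profiles(signal, genes, chrom_sizes, flank=3000, n_windows=100):
    """Windowed strand-oriented TSS profiles from per-bp signal arrays.

    ``signal`` maps track -> {chrom -> per-bp float array}; ``genes`` is a
    DataFrame with gene_id, chrom, strand, tss.  Genes whose +/- flank spans
    leave the chromosome, or on unknown chromosomes, are dropped with a log
    message.  Column ``n_windows - 1`` is always +flank downstream in the
    transcribed direction.
    """
    if (2 * flank) % n_windows:
        raise ValueError("2*flank must be divisible by n_windows")
    ww = 2 * flank // n_windows
    kept, profiles = [], {t: [] for t in signal}
    for row in genes.itertuples(index=False):
        if row.chrom not in chrom_sizes:
            logger.info("gene %s on unknown chromosome %s dropped", row.gene_id, row.chrom)
            continue
        lo, hi = row.tss - flank, row.tss + flank
        if lo < 0 or hi > chrom_sizes[row.chrom]:
            logger.info("gene %s too close to chromosome edge, dropped", row.gene_id)
            continue
        kept.append(row.gene_id)
        for t, per_chrom in signal.items():
            v = np.asarray(per_chrom[row.chrom][lo:hi], dtype=float)
            prof = v.reshape(n_windows, ww).sum(axis=1)
            if row.strand == "-":
                prof = prof[::-1]
            profiles[t].append(prof)
    tracks = {t: np.array(v) if v else np.empty((0, n_windows)) for t, v in profiles.items()}
    return TssProfileSet(kept, tracks, ww)


def rank_transform(profiles: TssProfileSet):
    """Within-gene rank transform per track, concatenated across tracks."""
    mats = []
    for t in TRACKS:
        if t not in profiles.tracks:
            continue
        m = profiles.tracks[t]
        mats.append(stats.rankdata(m, axis=1) if m.size else m)
    return np.hstack(mats)


def _kmeans_labels(X, k, seed, n_init):
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError("k exceeds number of genes")
    if k == 1:
        return np.zeros(n, dtype=int)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(X)


def cluster_promoters(profiles: TssProfileSet, k, seed=0, n_init=25,
                      rank_matrix=None):
    """K-means on rank-transformed concatenated profiles.

    ``rank_matrix`` overrides the feature matrix (used when clustering on
    rank profiles averaged over replicates).  Returns (labels, cluster mean
    *untransformed* profiles per track: {track: k x W array}).
    """
    X = rank_transform(profiles) if rank_matrix is None else rank_matrix
    labels = _kmeans_labels(X, k, seed, n_init)
    means = {
        t: np.array([profiles.tracks[t][labels == c].mean(axis=0) if (labels == c).any()
                     else np.zeros(profiles.n_windows) for c in range(k)])
        for t in profiles.tracks
    }
    return labels, means


def skew_statistic(profile):
    """Moment skewness g1 of the window-index distribution weighted by counts.

    Indices 1..n are treated as a discrete variable with weights given by the
    (non-negative) profile values; returns m3 / m2**1.5.  NaN when the profile
    sums to zero or has zero variance.
    """
    w = np.asarray(profile, dtype=float)
    if (w < 0).any():
        raise ValueError("profile values must be non-negative")
    tot = w.sum()
    if tot == 0:
        return float("nan")
    i = np.arange(1, w.size + 1, dtype=float)
    mean = np.sum(i * w) / tot
    d = i - mean
    m2 = np.sum(w * d ** 2) / tot
    m3 = np.sum(w * d ** 3) / tot
    if m2 == 0:
        return float("nan")
    return float(m3 / m2 ** 1.5)


@dataclass
class ClusterSummary:
    """Scalar features of one cluster used by the state rules."""

    mean_signal: dict[str, float]      # per track, mean over all windows
    downstream_fraction: float          # H3K4me3 mass downstream of the TSS
    skew: float                         # skew of downstream H3K4me3 profile
    n_genes: int = 0


def summarize_cluster(mean_profiles, n_percentiles=100, n_genes=0):
    """ClusterSummary from per-track cluster-mean profiles ({track: W vector}).

    The downstream H3K4me3 profile (second half of the windows) is resampled
    by linear interpolation to ``n_percentiles`` equidistant points before
    the skew computation.
    """
    k4 = np.asarray(mean_profiles["H3K4me3"], dtype=float)
    w = k4.size
    down = k4[w // 2:]
    tot = k4.sum()
    ds_frac = float(down.sum() / tot) if tot > 0 else float("nan")
    grid = np.linspace(0, down.size - 1, n_percentiles)
    down100 = np.interp(grid, np.arange(down.size), down)
    return ClusterSummary(
        mean_signal={t: float(np.mean(v)) for t, v in mean_profiles.items()},
        downstream_fraction=ds_frac,
        skew=skew_statistic(down100),
        n_genes=n_genes,
    )


def _frac(value, maximum):
    return value / maximum if maximum > 0 else 0.0


def classify_cluster(summary: ClusterSummary, track_maxima,
                     thresholds: ClassifierThresholds = ClassifierThresholds()):
    """Promoter state of one cluster given per-tissue track maxima.

    ``track_maxima`` maps track -> max cluster-mean signal over all clusters
    in the tissue.  Returns (state, low_confidence flag); the flag is set
    only when no rule matched and the inactive fallback applies.
    """
    t = thresholds
    k4 = _frac(summary.mean_signal["H3K4me3"], track_maxima["H3K4me3"])
    k27me3 = _frac(summary.mean_signal["H3K27me3"], track_maxima["H3K27me3"])
    rna = _frac(summary.mean_signal["RNA"], track_maxima["RNA"])
    ds = summary.downstream_fraction
    skew = summary.skew

    if k27me3 > t.repressed_k27me3_frac and rna < t.expr_rna_frac:
        return ACTIVELY_REPRESSED, False
    if k4 > t.k4_frac and ds > t.downstream_frac and skew > t.skew_cut and rna > t.expr_rna_frac:
        return NARROW_EXPRESSED, False
    if k4 > t.k4_frac and ds > t.downstream_frac and skew < t.skew_cut and rna > t.expr_rna_frac:
        return BROAD_EXPRESSED, False
    if k4 > t.k4_frac and ds < t.downstream_frac and rna > t.expr_rna_frac:
        return BIDIRECTIONAL_EXPRESSED, False
    if k4 <= t.k4_frac and rna > t.expr_rna_frac:
        return BIDIR2, False
    if k4 > t.k4_frac and rna < t.expr_rna_frac:
        return EXPRESSED2, False
    if k4 < t.k4_frac and k27me3 < t.k4_frac and rna < t.expr_rna_frac:
        return INACTIVE, False
    return INACTIVE, True


@dataclass
class PromoterStateTable:
    """Gene x tissue promoter states with cluster ids and concordance flags."""

    states: pd.DataFrame           # gene x tissue, state strings
    cluster_ids: pd.DataFrame      # gene x tissue, int cluster id
    concordant: pd.DataFrame       # gene x tissue, bool replicate agreement
    low_confidence: dict = field(default_factory=dict)  # tissue -> cluster ids

    @property
    def genes(self):
        return list(self.states.index)

    @property
    def tissues(self):
        return list(self.states.columns)


def _classify_profiles(profiles, k, seed, thresholds, rank_matrix=None):
    """Cluster one tissue's profiles and classify each cluster.

    Returns (per-gene states array, labels, low-confidence cluster ids).
    """
    labels, means = cluster_promoters(profiles, k, seed=seed,
                                      rank_matrix=rank_matrix)
    summaries = []
    for c in range(k):
        mp = {t: means[t][c] for t in means}
        summaries.append(summarize_cluster(mp, thresholds.n_percentiles,
                                           n_genes=int((labels == c).sum())))
    maxima = {t: max(s.mean_signal[t] for s in summaries) for t in means}
    cluster_states, lowconf = [], []
    for c, s in enumerate(summaries):
        state, flag = classify_cluster(s, maxima, thresholds)
        cluster_states.append(state)
        if flag:
            lowconf.append(c)
    gene_states = np.array([cluster_states[l] for l in labels], dtype=object)
    return gene_states, labels, lowconf


def assign_states(profiles_by_tissue, k=5, seed=0,
                  thresholds: ClassifierThresholds = ClassifierThresholds()):
    """Cluster and classify every tissue; replicate-averaged profiles decide.

    ``profiles_by_tissue`` maps tissue -> list of replicate TssProfileSet.
    Replicates are averaged before the deciding clustering: the k-means
    feature matrix is the mean of the per-replicate within-gene rank
    transforms (averaging in rank space preserves the tie structure of
    low-signal profiles that raw-count averaging destroys), while cluster
    mean signal for classification comes from the count-averaged profiles.
    Each replicate is additionally classified alone, and a gene is flagged
    concordant when all single-replicate states agree with each other.
    """
    states, clusters, concord, lowconf = {}, {}, {}, {}
    genes = None
    for tissue, reps in profiles_by_tissue.items():
        if not reps:
            raise ValueError(f"tissue {tissue} has no replicates")
        avg = TssProfileSet.average(reps) if len(reps) > 1 else reps[0]
        if genes is None:
            genes = avg.genes
        elif avg.genes != genes:
            raise ValueError("tissues have different gene lists")
        rank_avg = (np.mean([rank_transform(r) for r in reps], axis=0)
                    if len(reps) > 1 else None)
        gene_states, labels, lc = _classify_profiles(avg, k, seed, thresholds,
                                                     rank_matrix=rank_avg)
        states[tissue] = gene_states
        clusters[tissue] = labels
        lowconf[tissue] = lc
        if len(reps) > 1:
            per_rep = [_classify_profiles(r, k, seed, thresholds)[0] for r in reps]
            agree = np.ones(len(genes), dtype=bool)
            for other in per_rep[1:]:
                agree &= per_rep[0] == other
            concord[tissue] = agree
        else:
            concord[tissue] = np.ones(len(genes), dtype=bool)
    return PromoterStateTable(
        states=pd.DataFrame(states, index=genes),
        cluster_ids=pd.DataFrame(clusters, index=genes),
        concordant=pd.DataFrame(concord, index=genes),
        low_confidence=lowconf,
    )


def cross_tissue_states(table: PromoterStateTable,
                        expressed_states=EXPRESSED_STATES):
    """Cross-tissue summary: amalgamated transitions and disallowed sets.

    All transcribed states are amalgamated into a single ``expressed``
    category.  For each tissue three gene sets are reported: genes expressed
    uniquely there and actively repressed in *all* other tissues
    (``disallowed``), expressed uniquely there and inactive in all others
    (``inactive_elsewhere``), and expressed uniquely there with a mixture
    elsewhere (``mixed_elsewhere``).
    """
    tissues = table.tissues
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    amalg = table.states.map(lambda s: "expressed" if s in expressed_states else s)
    variable = amalg.nunique(axis=1) > 1
    out = {
        "amalgamated": amalg,
        "variable_fraction": float(variable.mean()),
        "disallowed": {},
        "inactive_elsewhere": {},
        "mixed_elsewhere": {},
    }
    expressed = table.states.isin(expressed_states)
    for t in tissues:
        others = [o for o in tissues if o != t]
        unique = expressed[t] & ~expressed[others].any(axis=1)
        other_states = table.states[others]
        all_rep = (other_states == ACTIVELY_REPRESSED).all(axis=1)
        all_inact = (other_states == INACTIVE).all(axis=1)
        out["disallowed"][t] = list(table.states.index[unique & all_rep])
        out["inactive_elsewhere"][t] = list(table.states.index[unique & all_inact])
        out["mixed_elsewhere"][t] = list(table.states.index[unique & ~all_rep & ~all_inact])
    return out


def fisher_2x2(a, b, c, d):
    """Odds ratio and two-sided Fisher exact p for table [[a, b], [c, d]].

    OR = (a*d)/(b*c); NaN when a margin (row or column total) is zero.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if 0 in (a + b, c + d, a + c, b + d):
        return float("nan"), 1.0
    odds = float("inf") if b * c == 0 else (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


def tf_repression_enrichment(table: PromoterStateTable, is_tf):
    """Are TF genes over-represented among genes repressed in >= 1 tissue?

    ``is_tf`` is a boolean Series indexed by gene (or array aligned to the
    table's genes).  Returns a dict with the 2x2 table (rows TF / non-TF,
    columns repressed-in->=1-tissue / not), the odds ratio and the two-sided
    Fisher exact p-value.
    """
    repressed_any = (table.states == ACTIVELY_REPRESSED).any(axis=1)
    if isinstance(is_tf, pd.Series):
        is_tf = is_tf.reindex(table.states.index).to_numpy()
    is_tf = np.asarray(is_tf, dtype=bool)
    if is_tf.size != len(table.genes):
        raise ValueError("is_tf not aligned to the state table")
    if is_tf.all() or not is_tf.any():
        raise ValueError("need at least one TF and one non-TF gene")
    rep = repressed_any.to_numpy()
    a = int(np.sum(is_tf & rep))
    b = int(np.sum(is_tf & ~rep))
    c = int(np.sum(~is_tf & rep))
    d = int(np.sum(~is_tf & ~rep))
    odds, p = fisher_2x2(a, b, c, d)
    return {"table": ((a, b), (c, d)), "odds_ratio": odds, "p_value": p}
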