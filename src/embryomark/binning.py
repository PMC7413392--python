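"""Fixed-width genome binning, read-start counting, bin filters and
binomial-thinning downsampling.

The genome is partitioned into non-overlapping contiguous bins (default 1 kb).
ChIP-seq reads are counted into bins by their mapped start position.  Bins are
filtered when saturated in every sample, dominated by input-control signal, or
pericentromeric.  For cross-sample comparability, counts are downsampled by
binomial thinning so that every sample's 99th-percentile nonzero count matches
the smallest such value across samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SampleMeta",
    "BinIndex",
    "BinCountMatrix",
    "BinFilterMask",
    "make_bins",
    "count_starts",
    "filter_bins",
    "downsample_counts",
]


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one sequencing dataset: tissue, replicate, histone mark."""

    sample_id: str
    tissue: str
    replicate: int
    mark: str
    is_input: bool = False


class BinIndex:
    """Partition of a genome into fixed-width bins with global integer ids.

    Bins are 0-based half-open intervals; ids are ordered by (chromosome
    order as given, coordinate).  The final bin of a chromosome may be
    shorter than ``bin_width``.
    """

    def __init__(self, chrom_sizes, bin_width):
        if bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        items = list(chrom_sizes.items()) if isinstance(chrom_sizes, dict) else list(chrom_sizes)
        names = [c for c, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome name in chrom_sizes")
        for c, L in items:
            if L < 1:
                raise ValueError(f"chromosome {c} has non-positive length")
        self.chrom_sizes = dict(items)
        self.bin_width = int(bin_width)
        self.chroms = names
        self._n_bins = {c: int(-(-L // bin_width)) for c, L in items}  # ceil
        offs = np.cumsum([0] + [self._n_bins[c] for c in names])
        self._offsets = {c: int(o) for c, o in zip(names, offs)}
        self.n_bins = int(offs[-1])

    def __len__(self):
        return self.n_bins

    def bin_id(self, chrom, pos):
        """Global bin id containing position ``pos`` on ``chrom``."""
        if chrom not in self._offsets:
            raise KeyError(chrom)
        if pos < 0 or pos >= self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self._offsets[chrom] + pos // self.bin_width

    def coords(self, bin_id):
        """(chrom, start, end) of a global bin id."""
        if bin_id < 0 or bin_id >= self.n_bins:
            raise IndexError(bin_id)
        for c in self.chroms:
            off = self._offsets[c]
            if bin_id < off + self._n_bins[c]:
                i = bin_id - off
                start = i * self.bin_width
                end = min(start + self.bin_width, self.chrom_sizes[c])
                return c, start, end
        raise IndexError(bin_id)  # pragma: no cover

    def chrom_range(self, chrom):
        """(first_id, last_id + 1) of the bins on a chromosome."""
        off = self._offsets[chrom]
        return off, off + self._n_bins[chrom]

    def bin_ids_overlapping(self, chrom, start, end):
        """Global ids of bins intersecting ``[start, end)`` by >= 1 bp."""
        if chrom not in self._offsets:
            return np.empty(0, dtype=np.int64)
        L = self.chrom_sizes[chrom]
        start = max(0, start)
        end = min(L, end)
        if end <= start:
            return np.empty(0, dtype=np.int64)
        lo = start // self.bin_width
        hi = -(-end // self.bin_width)  # ceil
        off = self._offsets[chrom]
        return np.arange(off + lo, off + hi, dtype=np.int64)

    def to_dataframe(self):
        rows = []
        for c in self.chroms:
            L = self.chrom_sizes[c]
            n = self._n_bins[c]
            starts = np.arange(n, dtype=np.int64) * self.bin_width
            ends = np.minimum(starts + self.bin_width, L)
            rows.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends}))
        df = pd.concat(rows, ignore_index=True)
        df.index.name = "bin_id"
        return df


@dataclass
class BinCountMatrix:
    """bins x samples non-negative integer counts plus sample metadata."""

    bin_index: BinIndex
    samples: list[SampleMeta]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.bin_index), len(self.samples)):
            raise ValueError("counts shape does not match bins x samples")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id")

    @property
    def sample_ids(self):
        return [s.sample_id for s in self.samples]

    def column(self, sample_id):
        return self.counts[:, self.sample_ids.index(sample_id)]

    def subset_samples(self, keep):
        """New matrix restricted to samples for which ``keep(meta)`` is true."""
        idx = [i for i, s in enumerate(self.samples) if keep(s)]
        return BinCountMatrix(self.bin_index, [self.samples[i] for i in idx],
                              self.counts[:, idx])

    def to_dataframe(self):
        df = pd.DataFrame(self.counts, columns=self.sample_ids)
        df.index.name = "bin_id"
        return df


@dataclass
class BinFilterMask:
    """Per-bin keep flag with a removal reason for each dropped bin."""

    keep: np.ndarray
    reasons: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.keep = np.asarray(self.keep, dtype=bool)
        removed = set(np.flatnonzero(~self.keep).tolist())
        if set(self.reasons) != removed:
            raise ValueError("reasons must cover exactly the removed bins")

    @property
    def n_removed(self):
        return int((~self.keep).sum())


def make_bins(chrom_sizes, bin_width=1000):
    """Partition a genome into non-overlapping contiguous fixed-width bins."""
    return BinIndex(chrom_sizes, bin_width)


def count_starts(reads, bins: BinIndex):
    """Count read start positions into bins; strand is ignored.

    ``reads`` is an iterable of (chrom, start[, strand]) tuples or a DataFrame
    with ``chrom`` and ``start`` columns.  Reads on chromosomes absent from
    the index are dropped (count logged).  Negative coordinates are an error.
    """
    counts = np.zeros(len(bins), dtype=np.int64)
    if isinstance(reads, pd.DataFrame):
        chroms = reads["chrom"].to_numpy()
        starts = reads["start"].to_numpy()
    else:
        reads = list(reads)
        chroms = np.array([r[0] for r in reads], dtype=object)
        starts = np.array([r[1] for r in reads], dtype=np.int64) if reads else np.empty(0, dtype=np.int64)
    if starts.size and (starts < 0).any():
        raise ValueError("negative read coordinate")
    dropped = 0
    for chrom in pd.unique(chroms) if len(chroms) else []:
        sel = starts[chroms == chrom]
        if chrom not in bins.chrom_sizes:
            dropped += sel.size
            continue
        L = bins.chrom_sizes[chrom]
        in_range = sel < L
        dropped += int((~in_range).sum())
        sel = sel[in_range]
        off, _ = bins.chrom_range(chrom)
        np.add.at(counts, off + sel // bins.bin_width, 1)
    if dropped:
        logger.info("count_starts: dropped %d reads outside the bin index", dropped)
    return counts


def filter_bins(counts: BinCountMatrix, pericentromeric=None,
                saturation=10_000, input_frac=0.5):
    """Flag bins to exclude from mark calling.

    A bin is removed iff (a) its count exceeds ``saturation`` in *every*
    non-input sample, (b) the mean count over input controls is >=
    ``input_frac`` of the mean over non-input samples, or (c) it overlaps a
    pericentromeric interval by >= 1 bp.  Reasons follow that fixed order.
    ``pericentromeric`` is a DataFrame with chrom/start/end columns or None.
    """
    is_input = np.array([s.is_input for s in counts.samples])
    if not (~is_input).any():
        raise ValueError("need at least one non-input sample")
    chip = counts.counts[:, ~is_input]

    saturated = (chip > saturation).all(axis=1)

    if is_input.any():
        inp_mean = counts.counts[:, is_input].mean(axis=1)
        chip_mean = chip.mean(axis=1)
        input_dom = inp_mean >= input_frac * chip_mean
    else:
        warnings.warn("no input samples: input-domination filter skipped")
        input_dom = np.zeros(len(counts.bin_index), dtype=bool)

    peri = np.zeros(len(counts.bin_index), dtype=bool)
    if pericentromeric is not None:
        for row in pericentromeric.itertuples(index=False):
            ids = counts.bin_index.bin_ids_overlapping(row.chrom, row.start, row.end)
            peri[ids] = True

    keep = ~(saturated | input_dom | peri)
    reasons = {}
    for i in np.flatnonzero(~keep):
        if saturated[i]:
            reasons[int(i)] = "saturated"
        elif input_dom[i]:
            reasons[int(i)] = "input_dominated"
        else:
            reasons[int(i)] = "pericentromeric"
    return BinFilterMask(keep, reasons)


def downsample_counts(counts: BinCountMatrix, quantile=0.99, seed=0,
                      per_mark=True):
    """Binomially thin each sample to the smallest per-sample signal quantile.

    For each sample the ``quantile`` quantile of its *nonzero* bin counts is
    computed; every count is thinned with retention probability
    ``min(1, t / q_s)`` where ``t`` is the minimum quantile across the
    samples being equalised.  With ``per_mark=True`` (default) the minimum is
    taken within each histone mark separately (cross-sample comparisons are
    always within a mark, and signal scale differs between marks); with
    ``per_mark=False`` a single global minimum is used.  Expectation of each
    thinned count is the original times its retention probability.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    rng = np.random.default_rng(seed)
    q = np.empty(len(counts.samples))
    for j in range(len(counts.samples)):
        col = counts.counts[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            warnings.warn(f"sample {counts.samples[j].sample_id} is all zero; not thinned")
            q[j] = np.nan
        else:
            q[j] = np.quantile(nz, quantile)
    if per_mark:
        groups = {}
        for j, s in enumerate(counts.samples):
            groups.setdefault(s.mark, []).append(j)
    else:
        groups = {"all": list(range(len(counts.samples)))}
    thinned = np.empty_like(counts.counts)
    for idx in groups.values():
        qs = q[idx]
        t = np.nanmin(qs) if not np.isnan(qs).all() else np.nan
        for j in idx:
            p = 1.0 if np.isnan(q[j]) or np.isnan(t) else min(1.0, t / q[j])
            col = counts.counts[:, j]
            thinned[:, j] = col if p >= 1.0 else rng.binomial(col, p)
    return BinCountMatrix(counts.bin_index, list(counts.samples), thinned)
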