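"""Binary mark calling from ranked bin counts via the elbow threshold.

Ordering a sample's bin counts by rank produces a hockey-stick curve: a long
near-zero tail and a short steep signal tail.  The elbow is the point on the
min-max-normalised curve closest (Euclidean) to the corner (max rank, zero
count); its count value is the per-sample threshold, and a bin is *marked*
when its count is strictly greater than the threshold.  Replicate agreement
between binary call vectors is quantified by the phi coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .binning import BinCountMatrix, BinFilterMask, SampleMeta

__all__ = ["ElbowResult", "MarkCallMatrix", "elbow_threshold", "call_marks", "phi_correlation"]


@dataclass
class ElbowResult:
    threshold: float
    elbow_rank: int  # 0-based index into the ascending-sorted counts
    n_marked: int
    curve: np.ndarray | None = None  # optional (rank, count) pairs for audit


@dataclass
class MarkCallMatrix:
    """bins x samples boolean marked calls with per-sample thresholds."""

    bin_index: object
    samples: list[SampleMeta]
    calls: np.ndarray
    thresholds: dict[str, ElbowResult]

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=bool)
        if self.calls.shape != (len(self.bin_index), len(self.samples)):
            raise ValueError("calls shape does not match bins x samples")

    @property
    def sample_ids(self):
        return [s.sample_id for s in self.samples]

    def column(self, sample_id):
        return self.calls[:, self.sample_ids.index(sample_id)]

    def subset_samples(self, keep):
        idx = [i for i, s in enumerate(self.samples) if keep(s)]
        metas = [self.samples[i] for i in idx]
        thr = {m.sample_id: self.thresholds[m.sample_id] for m in metas
               if m.sample_id in self.thresholds}
        return MarkCallMatrix(self.bin_index, metas, self.calls[:, idx], thr)


def elbow_threshold(counts, keep_curve=False):
    """Elbow of the ascending rank curve of a count vector.

    Counts are sorted ascending (ties broken by position for stability),
    ranks and counts min-max normalised to [0, 1], and the elbow taken as the
    rank minimising the distance to the corner (1, 0); ties go to the
    smallest rank.  Threshold = the count at the elbow; marked = strictly
    greater.  A constant vector yields that value as threshold, zero marked
    bins, and a warning.
    """
    counts = np.asarray(counts)
    n = counts.size
    if n < 2:
        raise ValueError("need at least 2 counts")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    order = np.argsort(counts, kind="stable")
    sorted_c = counts[order].astype(float)
    cmax = sorted_c[-1]
    if cmax == sorted_c[0]:
        warnings.warn("all counts equal: degenerate elbow, zero bins marked")
        return ElbowResult(threshold=float(cmax), elbow_rank=n - 1, n_marked=0,
                           curve=_curve(sorted_c) if keep_curve else None)
    x = np.arange(1, n + 1) / n
    y = sorted_c / cmax
    d2 = (1.0 - x) ** 2 + y ** 2
    elbow = int(np.argmin(d2))  # first minimum = smallest rank on ties
    thr = float(sorted_c[elbow])
    return ElbowResult(threshold=thr, elbow_rank=elbow,
                       n_marked=int((counts > thr).sum()),
                       curve=_curve(sorted_c) if keep_curve else None)


def _curve(sorted_c):
    return np.column_stack([np.arange(1, sorted_c.size + 1), sorted_c])


def call_marks(counts: BinCountMatrix, mask: BinFilterMask | None = None):
    """Per-sample elbow thresholds on kept bins; removed bins never marked."""
    keep = mask.keep if mask is not None else np.ones(len(counts.bin_index), dtype=bool)
    if keep.size != len(counts.bin_index):
        raise ValueError("mask not aligned to counts")
    calls = np.zeros_like(counts.counts, dtype=bool)
    thresholds = {}
    for j, meta in enumerate(counts.samples):
        res = elbow_threshold(counts.counts[keep, j])
        thresholds[meta.sample_id] = res
        calls[:, j] = keep & (counts.counts[:, j] > res.threshold)
    return MarkCallMatrix(counts.bin_index, list(counts.samples), calls, thresholds)


def phi_correlation(calls_a, calls_b):
    """Phi coefficient of two boolean vectors (= Pearson r of the 0/1 codes).

    Returns NaN when any 2x2 margin is zero (phi undefined).
    """
    a = np.asarray(calls_a, dtype=bool)
    b = np.asarray(calls_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 2:
        raise ValueError("need length >= 2")
    n11 = float(np.sum(a & b))
    n10 = float(np.sum(a & ~b))
    n01 = float(np.sum(~a & b))
    n00 = float(np.sum(~a & ~b))
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0:
        return float("nan")
    return (n11 * n00 - n10 * n01) / np.sqrt(denom)
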