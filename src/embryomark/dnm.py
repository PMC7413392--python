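"""De novo mutation enrichment in marked non-coding elements.

Surveyed non-coding regions (ultra-conserved elements, experimentally
validated enhancers, putative heart enhancers) and the DNMs found within them
are overlaid on binary mark calls.  A region "overlaps" a mark when the
region expanded by +/- 1 kb intersects a marked bin by >= 1 bp.  Enrichment
of DNMs in marked elements is an observed/expected ratio under a
uniform-per-base null within the surveyed bases, with an exact (Garwood)
Poisson confidence interval on the observed count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals as iv
from .calling import MarkCallMatrix

__all__ = ["EnrichmentResult", "marked_intervals", "annotate_regions",
           "poisson_ci", "dnm_enrichment_test"]

REGION_CATEGORIES = ("UCE", "EVE", "PHE", "other")


@dataclass
class EnrichmentResult:
    observed: int
    expected: float
    ratio: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05


def marked_intervals(calls: MarkCallMatrix, marks=None, replicated=False):
    """Merged genomic intervals of marked bins.

    ``marks``: restrict to these histone marks (None = all non-input
    samples).  ``replicated``: require the bin to be marked in every
    replicate of at least one tissue (for that mark) instead of any sample.
    Returns {chrom: (starts, ends)} merged interval arrays.
    """
    chip = calls.subset_samples(
        lambda s: not s.is_input and (marks is None or s.mark in marks))
    if not chip.samples:
        raise ValueError("no matching samples")
    if replicated:
        flags = np.zeros(len(chip.bin_index), dtype=bool)
        groups = {}
        for j, s in enumerate(chip.samples):
            groups.setdefault((s.tissue, s.mark), []).append(j)
        for idx in groups.values():
            if len(idx) >= 2:
                flags |= chip.calls[:, idx].all(axis=1)
    else:
        flags = chip.calls.any(axis=1)
    out = {}
    bi = chip.bin_index
    ids = np.flatnonzero(flags)
    if ids.size == 0:
        return out
    coords = pd.DataFrame([bi.coords(int(i)) for i in ids],
                          columns=["chrom", "start", "end"])
    for chrom, grp in coords.groupby("chrom", sort=False):
        out[chrom] = iv.merge(grp["start"].to_numpy(), grp["end"].to_numpy())
    return out


def _expand_clip(merged_by_chrom, slop, chrom_sizes):
    out = {}
    for chrom, (s, e) in merged_by_chrom.items():
        L = chrom_sizes[chrom]
        out[chrom] = iv.merge(np.clip(s - slop, 0, L), np.clip(e + slop, 0, L))
    return out


def annotate_regions(regions, calls: MarkCallMatrix, slop=1000, marks=None):
    """Per-region mark-overlap annotation with +/- slop expansion.

    ``regions``: DataFrame with chrom, start, end, category.  For each region
    and each mark, reports whether its slop-expanded interval intersects any
    marked bin (``any``), a bin marked in both replicates of some tissue
    (``replicated``), and the tissues with replicated overlap.  Also returns
    per-category summary fractions.
    """
    if marks is None:
        marks = sorted({s.mark for s in calls.samples if not s.is_input})
    chrom_sizes = calls.bin_index.chrom_sizes
    per_mark = {}
    for m in marks:
        per_mark[m] = {
            "any": _expand_clip(marked_intervals(calls, marks=[m]), slop, chrom_sizes),
            "replicated": _expand_clip(
                marked_intervals(calls, marks=[m], replicated=True), slop, chrom_sizes),
        }
        tissues = sorted({s.tissue for s in calls.samples
                          if not s.is_input and s.mark == m})
        per_mark[m]["by_tissue"] = {}
        for t in tissues:
            sub = calls.subset_samples(
                lambda s, t=t, m=m: not s.is_input and s.tissue == t and s.mark == m)
            if len(sub.samples) >= 2:
                flags = sub.calls.all(axis=1)
                ids = np.flatnonzero(flags)
                if ids.size:
                    coords = pd.DataFrame(
                        [calls.bin_index.coords(int(i)) for i in ids],
                        columns=["chrom", "start", "end"])
                    merged = {c: iv.merge(g["start"].to_numpy(), g["end"].to_numpy())
                              for c, g in coords.groupby("chrom", sort=False)}
                    per_mark[m]["by_tissue"][t] = _expand_clip(merged, slop, chrom_sizes)

    def hits(chrom, start, end, merged):
        if chrom not in merged:
            return False
        ms, me = merged[chrom]
        return iv.overlap_length(start, end, ms, me) > 0

    rows = []
    for row in regions.itertuples(index=False):
        rec = {"chrom": row.chrom, "start": row.start, "end": row.end,
               "category": getattr(row, "category", "other")}
        for m in marks:
            rec[f"{m}_any"] = hits(row.chrom, row.start, row.end, per_mark[m]["any"])
            rec[f"{m}_replicated"] = hits(row.chrom, row.start, row.end,
                                          per_mark[m]["replicated"])
            rec[f"{m}_tissues"] = ",".join(
                t for t, mg in per_mark[m]["by_tissue"].items()
                if hits(row.chrom, row.start, row.end, mg))
        rows.append(rec)
    ann = pd.DataFrame(rows)
    flag_cols = [c for c in ann.columns if c.endswith("_any") or c.endswith("_replicated")]
    summary = (ann.groupby("category")[flag_cols].mean()
               if len(ann) else pd.DataFrame(columns=flag_cols))
    return ann, summary


def poisson_ci(observed, alpha=0.05):
    """Exact (Garwood) confidence interval for a Poisson mean.

    lo = chi2.ppf(alpha/2, 2k)/2 (0 when k = 0);
    hi = chi2.ppf(1 - alpha/2, 2k + 2)/2.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    k = int(observed)
    if k < 0:
        raise ValueError("observed must be >= 0")
    lo = 0.0 if k == 0 else 0.5 * stats.chi2.ppf(alpha / 2, 2 * k)
    hi = 0.5 * stats.chi2.ppf(1 - alpha / 2, 2 * (k + 1))
    return float(lo), float(hi)


def dnm_enrichment_test(dnms, elements_by_chrom, surveyed, chrom_sizes,
                        slop=1000, alpha=0.05, null="per_base"):
    """Observed/expected DNM enrichment in slop-expanded marked elements.

    ``dnms``: DataFrame with chrom, pos; DNMs outside the surveyed regions
    are dropped (logged via a returned count is unnecessary - they simply do
    not count).  ``elements_by_chrom``: {chrom: (starts, ends)} merged marked
    elements (e.g. from :func:`marked_intervals`); expanded by ``slop`` and
    clipped at chromosome ends.  ``surveyed``: DataFrame chrom/start/end of
    the sequenced regions.  Under the default per-base null, expected =
    total DNMs x (surveyed bases covered by expanded elements / total
    surveyed bases); under ``null="per_element"`` the covered fraction is the
    fraction of surveyed *regions* overlapping an expanded element.
    """
    expanded = _expand_clip(elements_by_chrom, slop, chrom_sizes)

    total_bp = 0
    covered_bp = 0
    n_regions = 0
    n_regions_cov = 0
    for row in surveyed.itertuples(index=False):
        L = row.end - row.start
        total_bp += L
        n_regions += 1
        if row.chrom in expanded:
            ms, me = expanded[row.chrom]
            ov = iv.overlap_length(row.start, row.end, ms, me)
        else:
            ov = 0
        covered_bp += ov
        n_regions_cov += int(ov > 0)
    if total_bp == 0:
        raise ValueError("surveyed region set is empty")

    surv_by_chrom = {c: iv.merge(g["start"].to_numpy(), g["end"].to_numpy())
                     for c, g in surveyed.groupby("chrom", sort=False)}

    def inside(merged, chrom, pos):
        if chrom not in merged:
            return False
        ms, me = merged[chrom]
        j = np.searchsorted(ms, pos, side="right") - 1
        return j >= 0 and pos < me[j]

    total_dnms = 0
    observed = 0
    for row in dnms.itertuples(index=False):
        if not inside(surv_by_chrom, row.chrom, row.pos):
            continue
        total_dnms += 1
        if inside(expanded, row.chrom, row.pos):
            observed += 1

    if null == "per_base":
        frac = covered_bp / total_bp
    elif null == "per_element":
        frac = n_regions_cov / n_regions
    else:
        raise ValueError(f"unknown null {null!r}")
    expected = total_dnms * frac
    if expected == 0:
        return EnrichmentResult(observed, 0.0, float("nan"),
                                float("nan"), float("nan"), alpha)
    lo, hi = poisson_ci(observed, alpha)
    return EnrichmentResult(observed=observed, expected=float(expected),
                            ratio=observed / expected,
                            ci_low=lo / expected, ci_high=hi / expected,
                            alpha=alpha)
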