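"""Enhancer-to-gene correlation over megabase windows.

Downsampled bin counts are averaged within tissues and, for each query bin,
Pearson-correlated across tissues against the expression of every gene whose
TSS lies within 1 Mb of the bin midpoint (a 2 Mb window).  Negative r is
reported as well - anticorrelation to a neighbouring gene is meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binning import BinCountMatrix

__all__ = ["CorrelationReport", "tissue_signal_matrix", "correlate_bins_to_genes"]


@dataclass
class CorrelationReport:
    """Per-bin gene correlations, sorted by |r| descending (NaN last)."""

    bin_id: int
    genes: pd.DataFrame  # gene_id, distance, r
    top_gene: str | None  # gene with the maximum r (not |r|)
    n_genes_in_window: int = field(default=0)


def tissue_signal_matrix(counts: BinCountMatrix, mark):
    """Mean count per bin per tissue over the replicates of one mark.

    Input-control samples are excluded; tissues lacking the mark are dropped
    with a warning.  Returns a DataFrame (bins x tissues).
    """
    chip = counts.subset_samples(lambda s: not s.is_input and s.mark == mark)
    if not chip.samples:
        raise ValueError(f"no samples with mark {mark!r}")
    tissues = list(dict.fromkeys(s.tissue for s in counts.samples if not s.is_input))
    cols = {}
    for t in tissues:
        idx = [j for j, s in enumerate(chip.samples) if s.tissue == t]
        if not idx:
            warnings.warn(f"tissue {t} has no {mark} sample; dropped")
            continue
        cols[t] = chip.counts[:, idx].mean(axis=1)
    df = pd.DataFrame(cols)
    df.index.name = "bin_id"
    return df


def _pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))


def correlate_bins_to_genes(signal, expression, genes, bin_index,
                            window=1_000_000, bins=None, log1p=False):
    """Correlate bin signal with expression of genes within ``window`` bp.

    ``signal``: bins x tissues DataFrame (from :func:`tissue_signal_matrix`);
    ``expression``: gene x tissue DataFrame; ``genes``: annotation DataFrame
    with gene_id, chrom, tss.  Tissue axes are aligned by name and at least
    3 shared tissues are required.  Distance is bin midpoint to TSS, with a
    closed bound (a gene at exactly ``window`` bp is included).  Returns a
    dict bin_id -> CorrelationReport.
    """
    shared = [t for t in signal.columns if t in expression.columns]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared tissues for correlation")
    sig = signal[shared].to_numpy(dtype=float)
    expr = expression[shared].to_numpy(dtype=float)
    if log1p:
        sig, expr = np.log1p(sig), np.log1p(expr)
    gene_ids = np.asarray(genes["gene_id"])
    gene_chrom = np.asarray(genes["chrom"])
    gene_tss = np.asarray(genes["tss"], dtype=np.int64)
    expr_row = {g: i for i, g in enumerate(expression.index)}

    query = np.arange(len(bin_index)) if bins is None else np.asarray(bins)
    reports = {}
    for b in query:
        chrom, start, end = bin_index.coords(int(b))
        mid = (start + end) // 2
        near = np.flatnonzero((gene_chrom == chrom)
                              & (np.abs(gene_tss - mid) <= window))
        rows = []
        for gi in near:
            g = gene_ids[gi]
            if g not in expr_row:
                continue
            r = _pearson(sig[b], expr[expr_row[g]])
            rows.append((g, int(abs(gene_tss[gi] - mid)), r))
        df = pd.DataFrame(rows, columns=["gene_id", "distance", "r"])
        df = df.sort_values("r", key=lambda s: s.abs(), ascending=False,
                            na_position="last").reset_index(drop=True)
        valid = df.dropna(subset=["r"])
        top = None if valid.empty else valid.loc[valid["r"].idxmax(), "gene_id"]
        reports[int(b)] = CorrelationReport(bin_id=int(b), genes=df,
                                            top_gene=top,
                                            n_genes_in_window=len(df))
    return reports
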