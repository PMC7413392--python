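"""Plain-text readers and writers: chrom.sizes, BED, count/state matrices.

All tables are TSV; BED files follow the 0-based half-open convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import BinCountMatrix, BinIndex, SampleMeta

__all__ = [
    "read_chrom_sizes", "write_chrom_sizes",
    "read_bed", "write_bed",
    "write_count_matrix", "read_count_matrix",
    "write_gene_annotation", "read_gene_annotation",
    "write_expression", "read_expression",
    "write_calls_bed",
]


def read_chrom_sizes(path):
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_chrom_sizes(chrom_sizes, path):
    with open(path, "w") as fh:
        for c, L in chrom_sizes.items():
            fh.write(f"{c}\t{L}\n")


def read_bed(path):
    """BED3+ as a DataFrame (chrom, start, end[, name, score, strand])."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_bed(df, path, cols=None):
    cols = cols or [c for c in ["chrom", "start", "end", "name", "score", "strand"]
                    if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_count_matrix(matrix: BinCountMatrix, counts_path, samples_path):
    matrix.to_dataframe().to_csv(counts_path, sep="\t")
    pd.DataFrame([vars(s) for s in matrix.samples]).to_csv(
        samples_path, sep="\t", index=False)


def read_count_matrix(counts_path, samples_path, bin_index: BinIndex):
    df = pd.read_csv(counts_path, sep="\t", index_col="bin_id")
    meta = pd.read_csv(samples_path, sep="\t")
    samples = [SampleMeta(r.sample_id, r.tissue, int(r.replicate), r.mark,
                          bool(r.is_input)) for r in meta.itertuples(index=False)]
    counts = df[[s.sample_id for s in samples]].to_numpy()
    return BinCountMatrix(bin_index, samples, counts)


def write_gene_annotation(genes, path):
    genes.to_csv(path, sep="\t", index=False)


def read_gene_annotation(path):
    return pd.read_csv(path, sep="\t")


def write_expression(expression, path):
    expression.to_csv(path, sep="\t")


def read_expression(path):
    return pd.read_csv(path, sep="\t", index_col=0)


def write_calls_bed(calls, sample_id, counts, path):
    """Marked bins of one sample as BED (name=sample, score=count)."""
    col = calls.column(sample_id)
    ids = np.flatnonzero(col)
    rows = []
    for b in ids:
        chrom, start, end = calls.bin_index.coords(int(b))
        rows.append((chrom, start, end, sample_id, int(counts[b])))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_json(obj, path):
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))
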