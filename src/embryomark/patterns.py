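"""Cross-sample presence patterns of marked bins and tissue-specific sets.

A bin's *pattern* is the exact subset of samples in which it is marked.
Patterns are frequency-ranked genome-wide (the EulerGrid view).  From the
same call matrix, tissue-specific (marked in every replicate of exactly one
tissue and nowhere else), tissue-selective (marked in a tissue's replicates
and in at most half of all samples) and shared (marked in more than half of
all samples) bin sets are derived.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calling import MarkCallMatrix

__all__ = ["pattern_table", "select_bins"]


def pattern_table(calls, min_samples=2):
    """Frequency-ranked table of exact sample-subset patterns.

    Bins marked in fewer than ``min_samples`` samples are excluded.  Returns
    a DataFrame with columns ``pattern`` (tuple of sample ids, in sample
    order), ``n_bins`` and dense 1-based ``rank`` (descending ``n_bins``,
    ties broken by the pattern bit-vector order).
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if isinstance(calls, MarkCallMatrix):
        mat, sample_ids = calls.calls, calls.sample_ids
    else:
        mat, sample_ids = calls
        mat = np.asarray(mat, dtype=bool)
    sel = mat[mat.sum(axis=1) >= min_samples]
    if sel.shape[0] == 0:
        return pd.DataFrame(columns=["pattern", "n_bins", "rank"])
    uniq, counts = np.unique(sel, axis=0, return_counts=True)
    # sort by descending count, then by bit-vector (lexicographic) for ties
    keys = [tuple(row) for row in uniq]
    order = sorted(range(len(keys)), key=lambda i: (-counts[i], keys[i]))
    rows = []
    for rank, i in enumerate(order, start=1):
        subset = tuple(sid for sid, on in zip(sample_ids, uniq[i]) if on)
        rows.append({"pattern": subset, "n_bins": int(counts[i]), "rank": rank})
    return pd.DataFrame(rows)


def select_bins(calls: MarkCallMatrix, mode, tissue=None, max_fraction=0.5):
    """Bin ids that are tissue-specific, tissue-selective, or shared.

    Input-control samples are excluded.  ``tissue_specific``: marked in every
    replicate of ``tissue`` and in no other sample.  ``tissue_selective``:
    marked in every replicate of ``tissue`` and in at most
    ``max_fraction`` of all samples (the tissue's own replicates included).
    ``shared``: marked in more than half of all samples.  Only replicated
    tissues (>= 2 samples) are valid query tissues; unreplicated tissues
    still count toward "other samples".
    """
    chip = calls.subset_samples(lambda s: not s.is_input)
    tissues_of = np.array([s.tissue for s in chip.samples])
    n_samples = len(chip.samples)
    n_marked = chip.calls.sum(axis=1)

    if mode == "shared":
        return np.flatnonzero(n_marked > n_samples / 2)

    if mode not in ("tissue_specific", "tissue_selective"):
        raise ValueError(f"unknown mode {mode!r}")
    if tissue is None:
        raise ValueError("tissue required for this mode")
    own = tissues_of == tissue
    if not own.any():
        raise ValueError(f"unknown tissue {tissue!r}")
    if own.sum() < 2:
        raise ValueError(f"tissue {tissue!r} is unreplicated; specificity undefined")
    in_all_reps = chip.calls[:, own].all(axis=1)
    if mode == "tissue_specific":
        no_other = ~chip.calls[:, ~own].any(axis=1)
        return np.flatnonzero(in_all_reps & no_other)
    return np.flatnonzero(in_all_reps & (n_marked <= max_fraction * n_samples))
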