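#!/usr/bin/env python
"""Generate the default synthetic multi-tissue epigenome and write it out.

Produces the replicated bin-count matrix (3 marks + input x 6 tissues x 2
replicates over a 2 x 5 Mb toy genome), gene annotation, expression matrix
and the planted ground truth used by every later stage.
"""

import json
from pathlib import Path

from embryomark.configs import default_config
from embryomark.genomeio import (write_chrom_sizes, write_count_matrix,
                                 write_expression, write_gene_annotation)
from embryomark.simulate import simulate_dataset

OUT = Path("scratch/data")
SUMMARY = Path("results")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = default_config(seed=1)
    counts, genes, expression, truth = simulate_dataset(cfg)
    write_chrom_sizes(cfg.chrom_sizes, OUT / "chrom.sizes")
    write_count_matrix(counts, OUT / "bin_counts.tsv", OUT / "samples.tsv")
    write_gene_annotation(genes, OUT / "genes.tsv")
    write_expression(expression, OUT / "expression.tsv")
    truth.to_json(OUT / "ground_truth.json")
    SUMMARY.mkdir(parents=True, exist_ok=True)
    n_planted = len(truth.true_pattern_of_bin)
    (SUMMARY / "data_summary.json").write_text(json.dumps({
        "n_bins": len(counts.bin_index), "n_samples": len(counts.samples),
        "n_genes": len(genes), "n_planted_bins": n_planted,
        "n_enhancer_pairs": len(truth.true_target_of_enhancer)}, indent=2))
    print(f"{len(counts.bin_index)} bins x {len(counts.samples)} samples; "
          f"{len(genes)} genes; {n_planted} planted marked bins; "
          f"{len(truth.true_target_of_enhancer)} enhancer-target pairs")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
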