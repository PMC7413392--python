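#!/usr/bin/env python
"""Cluster TSS profiles, classify the seven promoter states, and summarise
cross-tissue behaviour: disallowed genes and TF-repression enrichment.

Runs the default 5,000-gene, 6-tissue dataset; reports planted-state
recovery, the fraction of genes with a variable promoter state, per-tissue
disallowed sets, and the TF odds ratio both on the synthetic data and from
the published marginal counts (19,791 genes / 1,659 TFs / 31.2% vs 20.0%).
"""

from pathlib import Path

import pandas as pd

from embryomark.configs import default_config
from embryomark.genomeio import write_json
from embryomark.promoters import (assign_states, cross_tissue_states,
                                  fisher_2x2, tf_repression_enrichment)
from embryomark.simulate import simulate_dataset, simulate_tss_profiles

OUT = Path("results/promoter_states")
SCRATCH = Path("scratch/promoter_states")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    cfg = default_config(seed=1)
    profiles, truth, _ = simulate_tss_profiles(cfg)
    table = assign_states(profiles, k=5, seed=1)
    table.states.to_csv(SCRATCH / "states.tsv", sep="\t")
    state_counts = table.states.apply(lambda c: c.value_counts()).fillna(0).astype(int)
    state_counts.to_csv(OUT / "state_counts.tsv", sep="\t")
    recovery = (table.states == truth).to_numpy().mean()
    concord = table.concordant.to_numpy().mean()

    ct = cross_tissue_states(table)
    ct["amalgamated"].to_csv(SCRATCH / "states_amalgamated.tsv", sep="\t")
    write_json({"variable_fraction": ct["variable_fraction"],
                "disallowed": ct["disallowed"],
                "inactive_elsewhere": ct["inactive_elsewhere"],
                "mixed_elsewhere": ct["mixed_elsewhere"]},
               OUT / "cross_tissue.json")

    _, genes, _, _ = simulate_dataset(cfg)
    is_tf = pd.Series(genes["is_TF"].to_numpy(), index=genes["gene_id"])
    tf_syn = tf_repression_enrichment(table, is_tf)

    # the published marginals reconstruct the study's own 2x2 table
    a = round(0.312 * 1659)
    c = round(0.200 * 18_132)
    odds, p = fisher_2x2(a, 1659 - a, c, 18_132 - c)
    write_json({"synthetic": tf_syn,
                "published_marginals": {"odds_ratio": odds, "p_value": p}},
               OUT / "tf_enrichment.json")

    print(f"planted-state recovery {recovery:.4f}; "
          f"replicate concordance {concord:.4f}")
    print(f"variable promoter state across tissues: "
          f"{ct['variable_fraction']:.3f} of genes")
    n_dis = {t: len(v) for t, v in ct["disallowed"].items()}
    print(f"disallowed genes per tissue: {n_dis}")
    print(f"TF repression OR (synthetic) {tf_syn['odds_ratio']:.2f}; "
          f"from published marginals {odds:.2f} (p={p:.2e})")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
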