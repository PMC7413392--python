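"""End-to-end orchestration of the synthetic analysis with a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .binning import downsample_counts, filter_bins
from .calling import call_marks, phi_correlation
from .correlation import correlate_bins_to_genes, tissue_signal_matrix
from .dnm import dnm_enrichment_test, marked_intervals
from .genomeio import (write_chrom_sizes, write_count_matrix,
                       write_expression, write_gene_annotation, write_json)
from .patterns import pattern_table, select_bins
from .promoters import assign_states, cross_tissue_states, tf_repression_enrichment
from .simulate import SimConfig, simulate_dataset, simulate_dnm_study, simulate_tss_profiles

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Stage parameters; defaults are the study's published values."""

    bin_width: int = 1000
    saturation: int = 10_000
    input_frac: float = 0.5
    quantile: float = 0.99
    k_clusters: int = 5
    min_samples: int = 2
    min_peak_length: int = 200
    overlap_frac: float = 0.5
    min_rpkm: float = 25.0
    min_fold: float = 2.5
    window: int = 1_000_000
    slop: int = 1000
    alpha: float = 0.05
    seed: int = 0
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    @classmethod
    def from_json(cls, path):
        data = json.loads(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path):
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir):
    """Simulate, call, classify, pattern, correlate and test, with manifest.

    Writes stage outputs as TSV/JSON under ``outdir`` and a manifest JSON
    recording the seed, parameters, file hashes and per-stage row counts.
    Returns the manifest dict.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "params": asdict(config), "stages": {}, "warnings": []}

    sim_kwargs = dict(config.sim)
    sim_kwargs.setdefault("seed", config.seed)
    sim_kwargs.setdefault("bin_width", config.bin_width)
    sim = SimConfig(**sim_kwargs)

    logger.info("stage simulate")
    counts, genes, expression, truth = simulate_dataset(sim)
    write_chrom_sizes(sim.chrom_sizes, out / "chrom.sizes")
    write_count_matrix(counts, out / "bin_counts.tsv", out / "samples.tsv")
    write_gene_annotation(genes, out / "genes.tsv")
    write_expression(expression, out / "expression.tsv")
    truth.to_json(out / "ground_truth.json")
    manifest["stages"]["simulate"] = {"n_bins": len(counts.bin_index),
                                      "n_samples": len(counts.samples),
                                      "n_genes": len(genes)}

    logger.info("stage filter + downsample + call")
    mask = filter_bins(counts, saturation=config.saturation,
                       input_frac=config.input_frac)
    down = downsample_counts(counts, quantile=config.quantile, seed=config.seed)
    calls = call_marks(down, mask)
    thr = {sid: {"threshold": r.threshold, "n_marked": r.n_marked}
           for sid, r in calls.thresholds.items()}
    write_json(thr, out / "thresholds.json")
    manifest["stages"]["call_marks"] = {"n_removed_bins": mask.n_removed,
                                        "thresholds": thr}

    logger.info("stage replicate agreement")
    phis = {}
    for t in sim.tissues:
        for m in sim.marks:
            reps = [s.sample_id for s in calls.samples
                    if s.tissue == t and s.mark == m and not s.is_input]
            if len(reps) >= 2:
                phis[f"{t}_{m}"] = phi_correlation(calls.column(reps[0]),
                                                   calls.column(reps[1]))
    write_json(phis, out / "replicate_phi.json")

    logger.info("stage patterns")
    k27ac = calls.subset_samples(lambda s: s.mark == "H3K27ac" and not s.is_input)
    pt = pattern_table(k27ac, min_samples=config.min_samples)
    pt_out = pt.copy()
    pt_out["pattern"] = pt_out["pattern"].map(lambda p: ",".join(p))
    pt_out.to_csv(out / "pattern_table.tsv", sep="\t", index=False)
    spec_counts = {t: int(select_bins(k27ac, "tissue_specific", t).size)
                   for t in sim.tissues}
    write_json(spec_counts, out / "tissue_specific_counts.json")
    manifest["stages"]["patterns"] = {"n_patterns": len(pt),
                                      "tissue_specific": spec_counts}

    logger.info("stage promoter states")
    profiles, truth_states, _ = simulate_tss_profiles(sim)
    table = assign_states(profiles, k=config.k_clusters, seed=config.seed)
    table.states.to_csv(out / "promoter_states.tsv", sep="\t")
    ct = cross_tissue_states(table)
    ct["amalgamated"].to_csv(out / "states_amalgamated.tsv", sep="\t")
    write_json({"variable_fraction": ct["variable_fraction"],
                "disallowed": ct["disallowed"],
                "inactive_elsewhere": ct["inactive_elsewhere"]},
               out / "cross_tissue.json")
    is_tf = pd.Series(genes["is_TF"].to_numpy(), index=genes["gene_id"])
    tf = tf_repression_enrichment(table, is_tf)
    write_json(tf, out / "tf_enrichment.json")
    recovery = float((table.states == truth_states).to_numpy().mean())
    manifest["stages"]["promoter_states"] = {
        "state_recovery": recovery,
        "variable_fraction": ct["variable_fraction"],
        "tf_odds_ratio": tf["odds_ratio"]}

    logger.info("stage target correlation")
    if len(sim.tissues) < 3 or not truth.true_target_of_enhancer:
        manifest["stages"]["correlation"] = {
            "skipped": "needs >= 3 tissues and planted enhancer-target pairs"}
    else:
        signal = tissue_signal_matrix(down, "H3K27ac")
        enh_bins = sorted(truth.true_target_of_enhancer)
        reports = correlate_bins_to_genes(signal, expression, genes,
                                          counts.bin_index, window=config.window,
                                          bins=enh_bins)
        rows = []
        for b, rep in reports.items():
            for g in rep.genes.itertuples(index=False):
                rows.append((b, g.gene_id, g.distance, g.r,
                             g.gene_id == rep.top_gene))
        pd.DataFrame(rows, columns=["bin_id", "gene_id", "distance", "r",
                                    "is_top"]
                     ).to_csv(out / "bin_gene_correlation.tsv", sep="\t",
                              index=False)
        n_top = sum(rep.top_gene == truth.true_target_of_enhancer[b]
                    for b, rep in reports.items())
        manifest["stages"]["correlation"] = {
            "n_enhancer_bins": len(reports),
            "target_top_fraction": n_top / len(reports)}

    logger.info("stage dnm enrichment")
    regions, dnms, dnm_truth = simulate_dnm_study(sim, calls)
    regions.to_csv(out / "surveyed_regions.tsv", sep="\t", index=False)
    dnms.to_csv(out / "dnms.tsv", sep="\t", index=False)
    elements = marked_intervals(calls, marks=["H3K27ac"], replicated=True)
    res = dnm_enrichment_test(dnms, elements, regions,
                              counts.bin_index.chrom_sizes,
                              slop=config.slop, alpha=config.alpha)
    write_json(vars(res), out / "dnm_enrichment.json")
    manifest["stages"]["dnm"] = {"observed": res.observed, "ratio": res.ratio,
                                 "ci": [res.ci_low, res.ci_high],
                                 "true_ratio": dnm_truth.true_dnm_rate_ratio}

    manifest["files"] = {p.name: _sha256(p) for p in sorted(out.iterdir())
                         if p.is_file() and p.name != "manifest.json"}
    write_json(manifest, out / "manifest.json")
    return manifest
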