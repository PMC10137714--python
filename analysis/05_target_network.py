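#!/usr/bin/env python
"""Duplex-energy target prediction, network assembly, and enrichment.

Scans regulator seeds against the 3'UTR set, filters candidate sites at
the -20 kcal/mol duplex-energy threshold, retains edges where a
differentially expressed regulator is anti-correlated with an oppositely
regulated target, and runs ORA/GSEA over the bundled gene sets.
"""

from pathlib import Path

import pandas as pd

from tsrnakit.pipeline import (PipelineConfig, stage_enrich, stage_network,
                               stage_targets)

RUN_DIR = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    config = PipelineConfig.from_yaml(RUN_DIR / "config.yaml")
    stage_targets(RUN_DIR, config)
    stage_network(RUN_DIR, config)
    stage_enrich(RUN_DIR, config)

    hits = pd.read_csv(RUN_DIR / "duplex_hits.tsv", sep="\t")
    print(f"duplex hits at <= {config.energy_threshold} kcal/mol: {len(hits)}"
          f" (MFE range {hits['mfe'].min():.1f} to {hits['mfe'].max():.1f})")
    edges = pd.read_csv(RUN_DIR / "edges.tsv", sep="\t")
    retained = edges[edges["retained"]]
    print(f"network edges retained: {len(retained)}/{len(edges)}")
    truth = pd.read_csv(RUN_DIR / "truth_edges.tsv", sep="\t")
    true_set = set(map(tuple, truth.to_numpy()))
    got = set(map(tuple, retained[["regulator_id", "target_gene_id"]]
                  .to_numpy()))
    tp = len(got & true_set)
    print(f"planted edges recovered: {tp}/{len(true_set)} "
          f"(precision {tp / max(1, len(got)):.2f})")
    ora = pd.read_csv(RUN_DIR / "ora.tsv", sep="\t", index_col=0)
    print("\nover-representation of network targets:")
    print(ora.sort_values("p_value").round(6).to_string())
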