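"""End-to-end pipeline stages over a run directory.

Each stage reads its inputs from (and writes its artifacts into) a run
directory, appending an entry to ``manifest.json`` recording the stage,
parameters hash, seed, and artifact list, so that identical configs produce
identical manifests and result files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__, align, classify, codonaa, de, duplex, network
from . import reference as ref
from . import simulate as sim
from .classify import TsRNAType

STAGES = ("simulate", "classify", "quantify", "de", "features", "targets",
          "network", "enrich", "aacorr")


@dataclass
class PipelineConfig:
    """Declarative configuration; thresholds default to the published rule set."""

    seed: int = 0
    # decision thresholds
    log2fc_threshold: float = 1.0
    p_threshold: float = 0.05
    energy_threshold: float = -20.0  # kcal/mol
    seed_start: int = 2
    seed_end: int = 7
    # aligner / read filter
    max_mismatch: int = 0
    min_len: int = 15
    max_len: int = 45
    # simulation scale
    n_genes: int = 44
    n_fragments: int = 300
    error_rate: float = 0.0
    n_samples_per_group: int = 3
    dispersion: float = 0.1
    n_planted: int = 30
    planted_log2fc: float = 2.0
    n_utr_targets: int = 10
    n_decoys: int = 20
    target_site_kind: str = "perfect"
    aa_target_r: float = 0.7

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"invalid config keys: {sorted(unknown)}")
        return cls(**data)

    def param_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def sim_config(self) -> sim.SimulationConfig:
        return sim.SimulationConfig(
            n_genes=self.n_genes, n_fragments=self.n_fragments,
            error_rate=self.error_rate,
            n_samples_per_group=self.n_samples_per_group,
            dispersion=self.dispersion,
            planted_log2fc=(self.planted_log2fc,), n_planted=self.n_planted,
            n_utr_targets=self.n_utr_targets, n_decoys=self.n_decoys,
            target_site_kind=self.target_site_kind,
            aa_target_r=self.aa_target_r, seed=self.seed)


def _record_manifest(run_dir: Path, stage: str, config: PipelineConfig,
                     artifacts: Sequence[str]) -> None:
    path = run_dir / "manifest.json"
    manifest = []
    if path.exists():
        manifest = json.loads(path.read_text())
    manifest = [m for m in manifest if m["stage"] != stage]
    manifest.append({
        "stage": stage, "version": __version__, "seed": config.seed,
        "param_hash": config.param_hash(), "artifacts": sorted(artifacts),
    })
    manifest.sort(key=lambda m: STAGES.index(m["stage"]))
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> str:
    df.to_csv(path, sep="\t", **kwargs)
    return path.name


def _samples(config: PipelineConfig) -> Tuple[List[str], Dict[str, str]]:
    n = config.n_samples_per_group
    samples = [f"A{i+1}" for i in range(n)] + [f"B{i+1}" for i in range(n)]
    return samples, {s: s[0] for s in samples}


def stage_simulate(run_dir: Path, config: PipelineConfig) -> List[str]:
    run_dir.mkdir(parents=True, exist_ok=True)
    artifacts: List[str] = []
    models = sim.simulate_reference(config.n_genes, seed=config.seed)
    ref.write_trna_references(models, run_dir / "reference.fasta",
                              run_dir / "landmarks.tsv")
    artifacts += ["reference.fasta", "landmarks.tsv"]

    reads, truth = sim.simulate_fragmentome(models, config.sim_config())
    for sample, seqs in reads.items():
        fname = f"reads_{sample}.fastq"
        sim.write_fastq(run_dir / fname, seqs, prefix=f"{sample}_")
        artifacts.append(fname)
    artifacts.append(_write_tsv(truth, run_dir / "truth_fragments.tsv"))
    samples, groups = _samples(config)
    artifacts.append(_write_tsv(
        pd.DataFrame({"sample": samples,
                      "group": [groups[s] for s in samples]}),
        run_dir / "groups.tsv", index=False))

    system = sim.simulate_regulatory_system(config.sim_config())
    with open(run_dir / "regulators.fasta", "w") as handle:
        for rid, seq in sorted(system["regulators"].items()):
            handle.write(f">{rid}\n{seq}\n")
    with open(run_dir / "utrs.fasta", "w") as handle:
        for gid, seq in sorted(system["utrs"].items()):
            handle.write(f">{gid}\n{seq}\n")
    artifacts += ["regulators.fasta", "utrs.fasta"]
    artifacts.append(_write_tsv(system["expr_regulators"],
                                run_dir / "expr_regulators.tsv"))
    artifacts.append(_write_tsv(system["expr_mrna"],
                                run_dir / "expr_mrna.tsv"))
    artifacts.append(_write_tsv(
        pd.DataFrame(system["truth_edges"],
                     columns=["regulator_id", "target_gene_id"]),
        run_dir / "truth_edges.tsv", index=False))

    cds, parental, aa_truth = sim.simulate_cds_with_aa_corr(
        config.aa_target_r, seed=config.seed)
    with open(run_dir / "cds.fasta", "w") as handle:
        for gid, seq in sorted(cds.items()):
            handle.write(f">{gid}\n{seq}\n")
    artifacts.append("cds.fasta")
    artifacts.append(_write_tsv(aa_truth, run_dir / "truth_aa.tsv"))

    genes = list(system["expr_mrna"].index)
    targets = [g for _, g in system["truth_edges"]]
    decoys = [g for g in genes if g not in targets]
    rng = np.random.default_rng(config.seed + 1)
    with open(run_dir / "gene_sets.gmt", "w") as handle:
        handle.write("planted_targets\tsimulated\t" + "\t".join(targets) + "\n")
        handle.write("decoy_genes\tsimulated\t" + "\t".join(decoys) + "\n")
        for i in range(3):
            pick = sorted(rng.choice(genes, size=min(8, len(genes)),
                                     replace=False))
            handle.write(f"random_set_{i}\tsimulated\t" + "\t".join(pick) + "\n")
    artifacts.append("gene_sets.gmt")
    _record_manifest(run_dir, "simulate", config, artifacts)
    return artifacts


def _load_records(run_dir: Path) -> pd.DataFrame:
    return pd.read_csv(run_dir / "records.tsv", sep="\t")


def stage_classify(run_dir: Path, config: PipelineConfig) -> List[str]:
    models, problems = ref.load_trna_references(
        run_dir / "reference.fasta", run_dir / "landmarks.tsv")
    if problems:
        raise ValueError(f"invalid reference models: {problems}")
    samples, _ = _samples(config)
    files = {s: run_dir / f"reads_{s}.fastq" for s in samples}
    missing = [str(p) for p in files.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing read files: {missing}")
    reads = align.collapse_reads(files)
    reads, report = align.filter_reads(reads, min_len=config.min_len,
                                       max_len=config.max_len)
    alignments, unaligned = align.align_to_trna(
        reads, models, max_mismatch=config.max_mismatch)
    records = classify.merge_and_name(reads, alignments, models)
    artifacts = [
        _write_tsv(classify.records_to_table(records),
                   run_dir / "records.tsv", index=False),
        _write_tsv(align.alignments_to_table(alignments),
                   run_dir / "alignments.tsv", index=False),
    ]
    (run_dir / "filter_report.json").write_text(
        json.dumps({"filter": report, "n_unaligned": len(unaligned)},
                   indent=1, sort_keys=True) + "\n")
    artifacts.append("filter_report.json")
    for name, table in classify.summarize_landscape(records).items():
        artifacts.append(_write_tsv(table, run_dir / f"summary_{name}.tsv"))
    _record_manifest(run_dir, "classify", config, artifacts)
    return artifacts


def stage_quantify(run_dir: Path, config: PipelineConfig) -> List[str]:
    records = _load_records(run_dir)
    samples, _ = _samples(config)
    counts = records.set_index("name")[samples]
    artifacts = [_write_tsv(counts, run_dir / "counts.tsv"),
                 _write_tsv(de.normalize_rpm(counts), run_dir / "rpm.tsv")]
    _record_manifest(run_dir, "quantify", config, artifacts)
    return artifacts


def stage_de(run_dir: Path, config: PipelineConfig) -> List[str]:
    counts = pd.read_csv(run_dir / "counts.tsv", sep="\t", index_col=0)
    _, groups = _samples(config)
    matrix = de.CountMatrix(counts, groups)
    phi = de.estimate_common_dispersion(matrix)
    results = de.nb_exact_test(matrix, phi=phi)
    summary = de.de_summary(results, matrix)
    artifacts = [_write_tsv(results, run_dir / "de_tsrna.tsv")]
    (run_dir / "de_summary.json").write_text(json.dumps(
        {"phi": phi, "tally": summary["tally"],
         "n_significant": summary["n_significant"]},
        indent=1, sort_keys=True) + "\n")
    artifacts.append("de_summary.json")
    mrna = pd.read_csv(run_dir / "expr_mrna.tsv", sep="\t", index_col=0)
    results_m = de.nb_exact_test(de.CountMatrix(mrna, groups))
    artifacts.append(_write_tsv(results_m, run_dir / "de_mrna.tsv"))
    reg = pd.read_csv(run_dir / "expr_regulators.tsv", sep="\t", index_col=0)
    results_r = de.nb_exact_test(de.CountMatrix(reg, groups))
    artifacts.append(_write_tsv(results_r, run_dir / "de_regulators.tsv"))
    _record_manifest(run_dir, "de", config, artifacts)
    return artifacts


def stage_features(run_dir: Path, config: PipelineConfig) -> List[str]:
    from .seqfeatures import length_distribution, seed_profile

    records = _load_records(run_dir)
    samples, _ = _samples(config)
    totals = records[samples].sum(axis=1)
    seqs = records["sequence"].tolist()
    artifacts = []
    prof_u = seed_profile(seqs, positions=(config.seed_start, config.seed_end))
    prof_w = seed_profile(seqs, weights=totals.tolist(),
                          positions=(config.seed_start, config.seed_end))
    artifacts.append(_write_tsv(prof_u.freq, run_dir / "seed_profile.tsv"))
    artifacts.append(_write_tsv(prof_w.freq,
                                run_dir / "seed_profile_weighted.tsv"))
    hist = length_distribution(records["length"], totals,
                               bins=(config.min_len, config.max_len))
    artifacts.append(_write_tsv(hist, run_dir / "length_distribution.tsv"))
    _record_manifest(run_dir, "features", config, artifacts)
    return artifacts


def stage_targets(run_dir: Path, config: PipelineConfig) -> List[str]:
    regulators = codonaa.read_fasta_dict(run_dir / "regulators.fasta")
    utrs = codonaa.read_fasta_dict(run_dir / "utrs.fasta")
    hits = duplex.predict_targets(regulators, utrs,
                                  energy_threshold=config.energy_threshold)
    artifacts = [_write_tsv(duplex.hits_to_table(hits),
                            run_dir / "duplex_hits.tsv", index=False)]
    _record_manifest(run_dir, "targets", config, artifacts)
    return artifacts


def _load_hits(run_dir: Path) -> List[duplex.DuplexHit]:
    table = pd.read_csv(run_dir / "duplex_hits.tsv", sep="\t")
    return [duplex.DuplexHit(r.regulator_id, r.gene_id, r.site_start,
                             r.site_end, r.mfe, r.seed_class, ())
            for r in table.itertuples()]


def stage_network(run_dir: Path, config: PipelineConfig) -> List[str]:
    de_reg = pd.read_csv(run_dir / "de_regulators.tsv", sep="\t", index_col=0)
    de_mrna = pd.read_csv(run_dir / "de_mrna.tsv", sep="\t", index_col=0)
    expr_reg = pd.read_csv(run_dir / "expr_regulators.tsv", sep="\t",
                           index_col=0)
    expr_mrna = pd.read_csv(run_dir / "expr_mrna.tsv", sep="\t", index_col=0)
    edges, degree = network.build_network(
        de_reg, de_mrna, _load_hits(run_dir), expr_reg, expr_mrna)
    artifacts = [
        _write_tsv(network.edges_to_table(edges), run_dir / "edges.tsv",
                   index=False),
        _write_tsv(degree, run_dir / "degree.tsv", index=False),
    ]
    _record_manifest(run_dir, "network", config, artifacts)
    return artifacts


def stage_enrich(run_dir: Path, config: PipelineConfig) -> List[str]:
    gmt = network.read_gmt(run_dir / "gene_sets.gmt")
    de_mrna = pd.read_csv(run_dir / "de_mrna.tsv", sep="\t", index_col=0)
    edges = pd.read_csv(run_dir / "edges.tsv", sep="\t")
    universe = list(de_mrna.index)
    query = sorted(set(edges.loc[edges["retained"], "target_gene_id"])
                   & set(universe))
    artifacts = []
    if query:
        ora = network.ora_hypergeometric(query, universe, gmt)
        artifacts.append(_write_tsv(ora, run_dir / "ora.tsv"))
    ranked = de_mrna["log2fc"].sort_values(ascending=False)
    gsea = network.gsea_preranked(ranked, gmt, n_perm=200, seed=config.seed)
    artifacts.append(_write_tsv(gsea, run_dir / "gsea.tsv"))
    _record_manifest(run_dir, "enrich", config, artifacts)
    return artifacts


def stage_aacorr(run_dir: Path, config: PipelineConfig) -> List[str]:
    cds = codonaa.read_fasta_dict(run_dir / "cds.fasta")
    truth = pd.read_csv(run_dir / "truth_aa.tsv", sep="\t", index_col=0)
    parental = codonaa.AAUsageVector(
        codonaa.AA_20, truth["parental_proportion"].to_numpy(), 1.0)
    usage = codonaa.aa_usage_from_cds(cds)
    r, p = codonaa.aa_correlation(parental, usage)
    table = pd.DataFrame({
        "parental_proportion": parental.as_series(),
        "cds_usage": usage.as_series()})
    artifacts = [_write_tsv(table, run_dir / "aa_vectors.tsv")]
    (run_dir / "aa_correlation.json").write_text(
        json.dumps({"R": r, "p": p}, indent=1, sort_keys=True) + "\n")
    artifacts.append("aa_correlation.json")
    _record_manifest(run_dir, "aacorr", config, artifacts)
    return artifacts


STAGE_FUNCS = {
    "simulate": stage_simulate, "classify": stage_classify,
    "quantify": stage_quantify, "de": stage_de, "features": stage_features,
    "targets": stage_targets, "network": stage_network,
    "enrich": stage_enrich, "aacorr": stage_aacorr,
}


def run_stage(name: str, run_dir, config: PipelineConfig) -> List[str]:
    run_dir = Path(run_dir)
    if name == "all":
        artifacts: List[str] = []
        for stage in STAGES:
            artifacts += STAGE_FUNCS[stage](run_dir, config)
        return artifacts
    if name not in STAGE_FUNCS:
        raise KeyError(f"unknown stage {name!r}")
    return STAGE_FUNCS[name](run_dir, config)
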