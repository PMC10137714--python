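"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study design the pipeline is built for: a
reference set of tRNA genes on canonical cloverleaf coordinates, cleavage
fragmentomes drawn from the nine type definitions, two-condition
(n = 3 vs 3) negative-binomial count matrices with planted fold changes,
3'UTR sets with planted target sites anti-coupled to regulator expression,
and CDS sets realizing a planted amino-acid-usage correlation. Every
emitted read or record traces back to one truth row.

Abundances follow a lognormal mean (sigma = 1.5) with NB sampling noise,
which qualitatively reproduces the extreme read concentration of real
tsRNA libraries (a handful of fragments dominating the library).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from . import classify as _cls
from .classify import TsRNAType
from .codonaa import AA_20, AAUsageVector
from .duplex import reverse_complement
from .reference import (AMINO_ACIDS_22, LandmarkSet, TRNAGeneModel,
                        build_mature)

DEFAULT_TYPE_MIXTURE: Dict[TsRNAType, float] = {
    TsRNAType.TRF_5C: 0.30,  # dominant class in adipose tsRNA libraries
    TsRNAType.TRF_5A: 0.07,
    TsRNAType.TRF_5B: 0.12,
    TsRNAType.TRF_3A: 0.08,
    TsRNAType.TRF_3B: 0.08,
    TsRNAType.TRF_1: 0.05,
    TsRNAType.I_TRF: 0.12,
    TsRNAType.TIRNA_5: 0.14,
    TsRNAType.TIRNA_3: 0.04,  # rarest class
}


@dataclass
class SimulationConfig:
    n_genes: int = 44  # parental tRNA diversity of the real landscape
    n_fragments: int = 300
    type_mixture: Dict[TsRNAType, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MIXTURE))
    error_rate: float = 0.0  # per-base substitution probability
    n_samples_per_group: int = 3
    dispersion: float = 0.1
    planted_log2fc: Tuple[float, ...] = ()
    n_planted: int = 0
    n_utr_targets: int = 10
    n_decoys: int = 60
    n_background_regulators: int = 90
    target_site_kind: str = "perfect"  # or "seed_only"
    aa_target_r: float = 0.7
    mean_log_mu: float = np.log(60.0)  # lognormal abundance, median 60 reads
    mean_log_sigma: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.type_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type mixture sums to {total}, not 1")
        if not (0.0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.target_site_kind not in ("perfect", "seed_only"):
            raise ValueError("target_site_kind must be perfect|seed_only")


# ---------------------------------------------------------------------------
# reference simulation


def simulate_reference(n_genes: int, seed: int = 0) -> List[TRNAGeneModel]:
    """Random tRNA gene models on the canonical 76-nt landmark frame.

    Amino-acid/anticodon labels cycle through the 22 parental labels;
    roughly every tenth gene is flagged mitochondrial.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    landmarks = LandmarkSet(d_loop=(14, 21), anticodon_loop=(32, 38),
                            anticodon=(34, 36), t_loop=(54, 60), mature_end=76)
    models: List[TRNAGeneModel] = []
    copies: Dict[Tuple[str, str], int] = {}
    seen_mature: set = set()
    for i in range(n_genes):
        aa = AMINO_ACIDS_22[i % len(AMINO_ACIDS_22)]
        while True:
            body = rng.choice(list("ACGT"), size=73)
            anticodon = "".join(rng.choice(list("ACGT"), size=3))
            body[33:36] = list(anticodon)
            gene_seq = "".join(body)
            if gene_seq.endswith("CCA"):
                continue  # keep the 73+CCA frame: mature must be 76 nt
            mature, appended = build_mature(gene_seq)
            if mature not in seen_mature:
                seen_mature.add(mature)
                break
        trailer = "".join(rng.choice(list("ACGT"), size=12)) + "TTTT"
        copies[(aa, anticodon)] = copies.get((aa, anticodon), 0) + 1
        origin = "mitochondrial" if (i % 10) == 9 else "cytosolic"
        model = TRNAGeneModel(
            gene_id=f"tRNA-{aa}-{anticodon}-{copies[(aa, anticodon)]}-1",
            amino_acid=aa, anticodon=anticodon, origin=origin,
            gene_seq=gene_seq, mature_seq=mature, trailer_seq=trailer,
            landmarks=landmarks, cca_appended=appended)
        model.validate()
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# fragmentome simulation


def _type_window(model: TRNAGeneModel, ts_type: TsRNAType,
                 min_len: int = 15, max_len: int = 45
                 ) -> List[Tuple[str, int, int]]:
    """All (space, start, end) placements admissible for a type on a model.

    The windows invert the classifier's decision table, so an error-free
    fragment drawn here is classified back to its planted type.
    """
    lm = model.landmarks
    me = lm.mature_end
    ac_lo, ac_hi = lm.anticodon_loop
    out: List[Tuple[str, int, int]] = []

    def add(space: str, start: int, end: int) -> None:
        if min_len <= end - start + 1 <= max_len:
            out.append((space, start, end))

    if ts_type is TsRNAType.TRF_1:
        plen = me + len(model.trailer_seq)
        for start in range(me + 1, me + _cls.TRF1_START_SLACK + 1):
            for end in range(start + min_len - 1, plen + 1):
                add("precursor", start, end)
        return out
    for start in range(1, _cls.ANCHOR5_MAX_START + 1):
        if ts_type is TsRNAType.TRF_5A:
            for end in range(start + min_len - 1, lm.d_loop[1] + 1):
                add("mature", start, end)
        elif ts_type is TsRNAType.TRF_5B:
            for end in range(lm.d_loop[1] + 1, ac_lo - _cls.AC_STEM_LEN):
                add("mature", start, end)
        elif ts_type is TsRNAType.TRF_5C:
            for end in range(ac_lo - _cls.AC_STEM_LEN, ac_lo):
                add("mature", start, end)
        elif ts_type is TsRNAType.TIRNA_5:
            lo = max(ac_lo, start + _cls.HALF_LEN[0] - 1)
            hi = min(me, start + _cls.HALF_LEN[1] - 1)
            for end in range(lo, hi + 1):
                add("mature", start, end)
    if ts_type in (TsRNAType.TIRNA_3, TsRNAType.TRF_3A, TsRNAType.TRF_3B):
        for end in range(me - _cls.ANCHOR3_SLACK, me + 1):
            if ts_type is TsRNAType.TIRNA_3:
                for start in range(ac_lo, ac_hi + 1):
                    add("mature", start, end)
            elif ts_type is TsRNAType.TRF_3A:
                for start in range(max(ac_hi + 1, end - _cls.TRF3_LEN_SPLIT + 1),
                                   end - min_len + 2):
                    add("mature", start, end)
            else:
                for start in range(ac_hi + 1, end - _cls.TRF3_LEN_SPLIT + 1):
                    add("mature", start, end)
    elif ts_type is TsRNAType.I_TRF:
        for start in range(_cls.ANCHOR5_MAX_START + 1, me):
            for end in range(start + min_len - 1,
                             min(me - _cls.ANCHOR3_SLACK - 1, start + max_len - 1) + 1):
                add("mature", start, end)
    return out


def simulate_fragmentome(models: Sequence[TRNAGeneModel],
                         config: SimulationConfig, emit_reads: bool = True
                         ) -> Tuple[Dict[str, List[str]], pd.DataFrame]:
    """Draw a fragmentome; returns (per-sample read lists, truth table).

    The truth table has one row per distinct fragment: coordinates, planted
    type, error-free sequence, true log2 fold change (group B over A is
    ``-true_log2fc`` for the DE convention A over B), and per-sample counts.
    Reads in the per-sample lists carry sequencing errors at
    ``config.error_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    types = list(config.type_mixture)
    probs = np.array([config.type_mixture[t] for t in types])
    windows: Dict[Tuple[str, TsRNAType], List[Tuple[str, int, int]]] = {}
    resampled = 0

    fragments = []
    seen = set()
    attempts = 0
    while len(fragments) < config.n_fragments:
        attempts += 1
        if attempts > 50 * config.n_fragments:
            raise RuntimeError("cannot draw enough distinct fragments")
        model = models[rng.integers(len(models))]
        ts_type = types[rng.choice(len(types), p=probs)]
        key = (model.gene_id, ts_type)
        if key not in windows:
            windows[key] = _type_window(model, ts_type)
        window = windows[key]
        if not window:
            resampled += 1  # empty admissible window on this model
            continue
        space, start, end = window[rng.integers(len(window))]
        source = model.mature_seq if space == "mature" else model.precursor_seq
        seq = source[start - 1:end]
        if seq in seen:
            continue
        seen.add(seq)
        fragments.append((model, ts_type, space, start, end, seq))

    n = len(fragments)
    groups = (["A"] * config.n_samples_per_group
              + ["B"] * config.n_samples_per_group)
    samples = [f"{g}{i % config.n_samples_per_group + 1}"
               for i, g in enumerate(groups)]
    means = np.exp(rng.normal(config.mean_log_mu, config.mean_log_sigma, n))
    lfc = np.zeros(n)
    n_planted = min(config.n_planted, n)
    if n_planted and config.planted_log2fc:
        planted_idx = rng.choice(n, size=n_planted, replace=False)
        vals = np.resize(np.asarray(config.planted_log2fc), n_planted)
        signs = rng.choice([-1.0, 1.0], size=n_planted)
        lfc[planted_idx] = vals * signs

    rows = []
    reads: Dict[str, List[str]] = {s: [] for s in samples}
    for i, (model, ts_type, space, start, end, seq) in enumerate(fragments):
        row = {
            "fragment_id": f"f{i:05d}", "gene_id": model.gene_id,
            "space": space, "start": start, "end": end,
            "type": ts_type.value, "sequence": seq,
            "true_log2fc": lfc[i], "mean_A": means[i],
            "mean_B": means[i] * 2 ** lfc[i],
        }
        for s, g in zip(samples, groups):
            mu = row["mean_A"] if g == "A" else row["mean_B"]
            count = _nb_draw(rng, mu, config.dispersion)
            row[s] = count
            if emit_reads:
                for _ in range(count):
                    reads[s].append(_with_errors(rng, seq, config.error_rate))
        rows.append(row)
    truth = pd.DataFrame(rows).set_index("fragment_id")
    truth.attrs["resampled"] = resampled
    truth.attrs["samples"] = samples
    truth.attrs["groups"] = dict(zip(samples, groups))
    return reads, truth


def _nb_draw(rng: np.random.Generator, mu: float, phi: float) -> int:
    if mu <= 0:
        return 0
    if phi <= 1e-12:
        return int(rng.poisson(mu))
    r = 1.0 / phi
    p = r / (r + mu)
    return int(rng.negative_binomial(r, p))


def _with_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


def write_fastq(path, sequences: Sequence[str], prefix: str = "read") -> None:
    with open(path, "w") as handle:
        for i, seq in enumerate(sequences, start=1):
            handle.write(f"@{prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# regulatory-system simulation


def simulate_regulatory_system(config: SimulationConfig) -> Dict[str, object]:
    """Regulators anti-coupled to planted-site targets, plus decoy genes.

    Each true target's 3'UTR carries one planted site (perfect reverse
    complement of the regulator, or a seed-only match); regulator
    expression is differentially expressed between the groups and the
    target tracks it inversely in log space before NB noise. Decoy genes
    carry no planted site. Both expression matrices include a majority of
    flat background features, as in real libraries where differential
    features are a small fraction — this keeps library-size normalization
    composition-stable. Returns a dict with regulator/UTR sequences, count
    matrices, the group map, and the truth edge list.
    """
    config.validate()
    if config.n_utr_targets < 1:
        raise ValueError("n_utr_targets must be >= 1")
    rng = np.random.default_rng(config.seed)
    n_per = config.n_samples_per_group
    samples = [f"A{i+1}" for i in range(n_per)] + [f"B{i+1}" for i in range(n_per)]
    groups = {s: s[0] for s in samples}

    regulators: Dict[str, str] = {}
    utrs: Dict[str, str] = {}
    truth_edges: List[Tuple[str, str]] = []
    expr_reg: Dict[str, np.ndarray] = {}
    expr_gene: Dict[str, np.ndarray] = {}

    beta = 1.0  # log-space coupling strength regulator -> target
    for t in range(config.n_utr_targets):
        reg_id = f"tsR{t:03d}"
        gene_id = f"G{t:03d}"
        reg_seq = "".join(rng.choice(list("ACGT"), size=22))
        utr = list(rng.choice(list("ACGT"), size=200))
        if config.target_site_kind == "perfect":
            site = reverse_complement(reg_seq).replace("U", "T")
        else:
            site = reverse_complement(reg_seq[1:7]).replace("U", "T")
        pos = int(rng.integers(40, 200 - len(site)))
        utr[pos:pos + len(site)] = list(site)
        regulators[reg_id] = reg_seq
        utrs[gene_id] = "".join(utr)
        truth_edges.append((reg_id, gene_id))

        lfc = 3.0 * (1 if t % 2 == 0 else -1)
        base_r = float(np.exp(rng.normal(np.log(400), 0.3)))
        mu_r = np.array([base_r * (2 ** (lfc if g == "B" else 0.0))
                         for g in (groups[s] for s in samples)])
        counts_r = np.array([_nb_draw(rng, m, 0.05) for m in mu_r], dtype=float)
        base_t = float(np.exp(rng.normal(np.log(600), 0.3)))
        rel = np.clip(counts_r, 1.0, None) / base_r
        mu_t = base_t * rel ** (-beta)
        counts_t = np.array([_nb_draw(rng, m, 0.05) for m in mu_t], dtype=float)
        expr_reg[reg_id] = counts_r
        expr_gene[gene_id] = counts_t

    for b in range(config.n_background_regulators):
        base = float(np.exp(rng.normal(np.log(400), 0.5)))
        expr_reg[f"bg{b:03d}"] = np.array(
            [_nb_draw(rng, base, 0.05) for _ in samples], dtype=float)

    for d in range(config.n_decoys):
        gene_id = f"D{d:03d}"
        utrs[gene_id] = "".join(rng.choice(list("ACGT"), size=200))
        base = float(np.exp(rng.normal(np.log(500), 0.5)))
        lfc = rng.choice([0.0, 0.0, 0.0, 0.0, 2.0, -2.0])
        mu = np.array([base * (2 ** (lfc if groups[s] == "B" else 0.0))
                       for s in samples])
        expr_gene[gene_id] = np.array(
            [_nb_draw(rng, m, 0.05) for m in mu], dtype=float)

    return {
        "regulators": regulators,
        "utrs": utrs,
        "expr_regulators": pd.DataFrame.from_dict(
            expr_reg, orient="index", columns=samples),
        "expr_mrna": pd.DataFrame.from_dict(
            expr_gene, orient="index", columns=samples),
        "groups": groups,
        "truth_edges": truth_edges,
    }


# ---------------------------------------------------------------------------
# CDS simulation with planted amino-acid correlation


def _gaussian_copula_rho(target_r: float, sigma: float) -> float:
    """Latent-normal correlation giving Pearson ``target_r`` after exp()."""
    v = sigma ** 2
    return float(np.log(1.0 + target_r * (np.exp(v) - 1.0)) / v)


def simulate_cds_with_aa_corr(aa_target_r: float, n_genes: int = 20,
                              seed: int = 0, n_codons_total: int = 4000,
                              sigma: float = 0.6
                              ) -> Tuple[Dict[str, str], AAUsageVector,
                                         pd.DataFrame]:
    """CDS set whose amino-acid usage correlates with a parental-AA vector.

    Two 20-dimensional lognormal weight vectors share a latent Gaussian
    correlation calibrated so the *expected* Pearson correlation of the
    weights equals ``aa_target_r``; one becomes the parental-tRNA
    proportion vector, the other is realized as integer codon counts and
    emitted as CDS sequences (so translating the CDS reproduces the emitted
    usage exactly). Returns (cds dict, parental AAUsageVector, truth table).
    """
    if not -1.0 <= aa_target_r <= 1.0:
        raise ValueError("aa_target_r must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    rho = _gaussian_copula_rho(aa_target_r, sigma)
    rho = float(np.clip(rho, -1.0, 1.0))
    g1 = rng.normal(size=20)
    g2 = rho * g1 + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.normal(size=20)
    w1 = np.exp(sigma * g1)
    w2 = np.exp(sigma * g2)
    parental = w1 / w1.sum()
    codon_props = w2 / w2.sum()

    counts = np.floor(codon_props * n_codons_total).astype(int)
    counts[np.argmax(counts)] += n_codons_total - counts.sum()
    table = CodonTable.unambiguous_dna_by_id[1]
    by_aa: Dict[str, List[str]] = {}
    one_to_three = {"A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp",
                    "C": "Cys", "Q": "Gln", "E": "Glu", "G": "Gly",
                    "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
                    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser",
                    "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val"}
    for codon, aa1 in table.forward_table.items():
        aa3 = one_to_three.get(aa1)
        if aa3:
            by_aa.setdefault(aa3, []).append(codon)
    codon_pool: List[str] = []
    for aa, c in zip(AA_20, counts):
        choices = sorted(by_aa[aa])
        codon_pool.extend(
            choices[int(k)] for k in rng.integers(len(choices), size=c))
    rng.shuffle(codon_pool)

    per_gene = max(1, len(codon_pool) // n_genes)
    cds: Dict[str, str] = {}
    for g in range(n_genes):
        chunk = codon_pool[g * per_gene:(g + 1) * per_gene] \
            if g < n_genes - 1 else codon_pool[(n_genes - 1) * per_gene:]
        if not chunk:
            chunk = ["ATG"]
        cds[f"deg{g:03d}"] = "".join(chunk)

    truth = pd.DataFrame({
        "amino_acid": AA_20,
        "parental_proportion": parental,
        "codon_usage_proportion": counts / counts.sum(),
        "codon_count": counts,
    }).set_index("amino_acid")
    truth.attrs["aa_target_r"] = aa_target_r
    truth.attrs["latent_rho"] = rho
    vec = AAUsageVector(AA_20, parental, float(parental.sum()))
    return cds, vec, truth
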