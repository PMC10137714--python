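# tsrnakit

Analysis pipeline for the landscape of tRNA-derived small RNAs (tsRNAs) in
two-condition small-RNA sequencing designs, built around the comparison of
subcutaneous vs visceral white adipose tissue. tsRNAs are cleavage products
of mature and precursor tRNAs; where the cut falls on the cloverleaf decides
the class, and the classes differ in biogenesis and function. The package is
aimed at small-RNA bioinformaticians who want every step of such an analysis
— classification, quantification, target prediction, network inference —
as tested, reusable library code with a fully ground-truthed simulator in
place of the (unavailable) sequencing libraries.

## What it computes

* **Nine-type classification.** Each aligned fragment is assigned one of
  tRF-5a/5b/5c, tRF-3a/3b, tRF-1, i-tRF, tiRNA-5, tiRNA-3 from its cut
  positions relative to the cloverleaf landmarks (D-loop, anticodon loop,
  T-loop, mature 3′ end, RNase Z trailer). tRNA halves (tiRNA) are the
  30–36-nt products of anticodon-loop cleavage; tRF-3s end in the
  post-transcriptional CCA; tRF-1s begin immediately after the mature 3′ end
  on the precursor.
* **Differential expression.** A conditional exact negative-binomial test in
  the edgeR tradition with a single pooled dispersion φ (Var = μ + φμ²);
  a feature is called at |log₂FC| ≥ 1 and p ≤ 0.05, with BH FDR reported.
* **Seed features.** Base-preference profiles over positions 2–7 (the seed)
  and length distributions, by distinct sequence and by reads.
* **Target prediction.** Exact seed (2–7) reverse-complement matches on
  3′UTRs, scored by a nearest-neighbor duplex minimum-free-energy dynamic
  program (Turner-style stacks, linear bulge/internal-loop penalties) and
  retained at ΔG ≤ −20 kcal/mol.
* **Regulatory network.** An edge regulator→mRNA is kept iff a duplex hit
  exists, both features are differentially expressed in opposite directions,
  and their expression is negatively correlated. Hypergeometric ORA and
  preranked GSEA run over user-supplied GMT gene sets.
* **Amino-acid correlation.** Pearson correlation between the parental-tRNA
  amino-acid spectrum of the tsRNA landscape and the amino-acid usage of a
  CDS set (e.g. differentially expressed mRNAs), on the 20-residue alphabet.
* **Synthetic data.** `tsrnakit.simulate` generates every input with known
  truth: tRNA references on canonical landmarks, fragmentomes drawn from the
  nine type definitions, n = 3 vs 3 NB count matrices with planted fold
  changes, UTR/expression systems with planted target sites, and CDS sets
  with a planted amino-acid-usage correlation.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data, writing their tables to `results/run/` (regenerated on each run; the
directory is not shipped):

```bash
python analysis/01_simulate_data.py
python analysis/02_classify_landscape.py
python analysis/03_differential_expression.py
python analysis/04_seed_features.py
python analysis/05_target_network.py
python analysis/06_aa_correlation.py
```

Selected output (seed 1):

```
identified 300 distinct tsRNAs
type composition (% of distinct tsRNAs / % of reads):
tRF-5c  28.67  40.31      # the dominant class, as in real adipose libraries
...
common dispersion estimate: phi = 0.0351
significant tsRNAs: 41 (tally: {'up_in_A': 24, 'up_in_B': 17})
planted fold changes recovered: 29/30 (97%)
duplex hits at <= -20.0 kcal/mol: 10 (MFE range -44.6 to -28.8)
network edges retained: 10/10
planted edges recovered: 10/10 (precision 1.00)
parental-AA vs CDS-usage correlation (this run): R = 0.14, p = 0.57 (planted r = 0.7)
recovery over 10 seeds: mean R = 0.67 (range 0.14 to 0.96)
```

The fold-change tally counts features passing |log₂FC| ≥ 1 and p ≤ 0.05 in
each direction; 29 of 30 planted fourfold changes are re-detected. All ten
planted regulator→target edges survive the duplex-energy, opposite-DE and
anti-correlation filters with no false edges. The amino-acid correlation
illustrates honest sampling noise: a Pearson over 20 amino acids has a
standard error near 0.12, so single draws scatter widely around the planted
0.7 while the 10-seed mean recovers it.

The same stages are exposed as a CLI (`tsrnakit simulate|classify|quantify|
de|features|targets|network|enrich|aacorr|all`), driven by a YAML config
whose defaults are the decision thresholds above.

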