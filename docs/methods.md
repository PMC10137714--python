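# Methods

## Coordinate frame and gene models

All classification runs on 1-based closed intervals over the *mature* tRNA
sequence; precursor coordinates extend the same axis so that trailer
position 1 is `mature_end + 1`. Landmarks (D-loop, anticodon loop,
anticodon, T-loop) are inputs, supplied per gene in a TSV sidecar —
the package never infers secondary structure from sequence. The canonical
template used by the simulator and the enumeration checks follows standard
tRNA numbering: a 76-nt mature sequence with D-loop 14–21, anticodon loop
32–38 (anticodon 34–36), T-loop 54–60, CCA at 74–76, and a 16-nt precursor
trailer ending in a TTTT terminator.

**CCA policy.** Mature references are always CCA-terminated: when the
genomic copy lacks CCA it is appended (mirroring post-transcriptional CCA
addition) and the append is flagged. Reads ending in CCA therefore align to
every reference regardless of its genomic 3′ state. The precursor string is
the mature string plus the trailer; this is a modeling convenience (a real
primary transcript lacks CCA), and its only consequence is that
mature-internal placements also exist in precursor space, where they are
suppressed in favor of the mature placement.

## Alignment

Reads are collapsed to distinct sequences with per-sample counts, adapter-
trimmed (3′ exact-prefix match, ≥ 8-nt overlap), and filtered to 15–45 nt
with no ambiguous base by default. Placement is gap-free and sense-strand
only; all placements achieving the minimal substitution count for a read
(default maximum 0, configurable to 1) are kept across genes and spaces,
and each receives weight 1/k for k retained placements, so weighted counts
are conserved exactly. No quality-aware trimming is attempted — the adapter
and quality settings of the original libraries are not recorded anywhere,
so the defaults here are documented choices, not reconstructions.

## Nine-type classifier

With L the fragment length, `mature_end` = m, anticodon loop [a₁, a₂]:

| rule | label |
|---|---|
| precursor space, start > m (within 2 nt) | tRF-1 |
| 5′-anchored (start ≤ 3), end ≥ a₁, L ∈ [30, 36] | tiRNA-5 |
| 5′-anchored, end in D-loop | tRF-5a |
| 5′-anchored, end between D-loop and anticodon stem | tRF-5b |
| 5′-anchored, end in the 5′ anticodon stem (5 nt before the loop) | tRF-5c |
| 3′-anchored (end ≥ m − 1), start in the loop | tiRNA-3 |
| 3′-anchored, start after the loop, L ≤ 20 / L > 20 | tRF-3a / tRF-3b |
| everything else | i-tRF |

The 5′ rule precedes the 3′ rule, so near-full-length fragments are judged
by their 5′ cut. Design notes:

* **Anchor tolerances** (start ≤ 3; end ≥ m − 1) absorb non-templated end
  raggedness. The 5′ tolerance of 2 nt is forced by geometry: with the loop
  starting at position 32, the 30-nt lower bound of the half-length window
  is reachable only from start 3. On the canonical template the set of
  5′-anchored, in-loop-ending fragments labeled tiRNA-5 then spans exactly
  30–36 nt, the textbook half definition.
* **tRF-5b/5c boundary.** The 5-series is position-defined (cleavage between
  the D-loop and the anticodon loop); the b/c split sits at the 5′ anticodon
  stem (5 nt before the loop), which makes the conventional length bands
  emerge on the canonical template (5a ≤ 21 nt, 5b 22–26 nt, 5c 27–31 nt).
* **Length-gating asymmetry.** tiRNA-5 is gated to 30–36 nt; 5′-anchored
  fragments reaching the loop but longer than 36 nt drop into the i-tRF
  bucket (used here as "no defined end class", a deliberate catch-all).
  tiRNA-3 is position-only: on the canonical geometry a loop-to-3′-end half
  spans 38–45 nt, so a 30–36 gate would empty the class entirely. The
  30–36 definition is treated as a statement about 5′ halves.
* Precursor placements spanning the RNase Z site have no canonical class
  and also fall to i-tRF.

Merging: identical sequences collapse to one record whose parents are all
optimally matching genes; the majority-weight type wins (ties to the
lexicographically first label, flagged); mitochondrial origin requires all
parents mitochondrial, mixed parentage counts as cytosolic and is flagged.
Names follow `tRF-<AA>-<anticodon>-<serial>` with serials assigned per
family in descending total-count order. Because published landscape
percentages sometimes count distinct tsRNAs and sometimes reads, every
summary table carries both bases.

## Differential expression

Counts are equalized to the geometric-mean library size (kept as reals;
library sizes default to column sums but can be supplied when the matrix is
a subset of a larger library). A single common dispersion φ is estimated by
pooled method of moments, φ̂ = Σ(S² − x̄) / Σ(x̄² − S²/n) over features and
groups, floored at 0 — no trended or tagwise shrinkage. The test is a
conditional exact test: group sums (rounded to integers — the discrete
enumeration needs integer support) are compared under the conditional law
of a sum of NB(μ, φ) samples given the total, which depends only on the
per-group sample numbers through the NB sizes nᵢ/φ; all outcomes no more
probable than the one observed are summed (binomial when φ = 0). log₂FC
uses mean equalized counts with a +0.5 pseudo-count — fold change only,
never the test. Significance is |log₂FC| ≥ 1 and raw p ≤ 0.05; BH FDR is
reported alongside but does not gate the call (the decision rule is stated
on raw p). At n = 3 vs 3 with φ = 0.1 the test holds its size (empirical
type-I ≈ 0.05 on 10,000 null features) and detects fourfold changes at
moderate abundance with > 90% power — both asserted in the test suite.

## Duplex energetics and target prediction

The seed is positions 2–7; candidate sites are exact Watson–Crick reverse
complements of the seed on the UTR (no G:U in the seed; G:U is allowed
elsewhere in the duplex). Each site window (site plus 30 nt upstream on the
UTR) is scored by a dynamic program over intermolecular duplex alignments:
states are "last paired position" pairs, moves add one pair at ≤ 4 unpaired
nt per side, costing a nearest-neighbor stack when contiguous or a linear
penalty otherwise (bulge 3.0, internal loop 1.5 kcal/mol per nt), plus a
duplex initiation cost of +4.09 kcal/mol. Watson–Crick stack energies are
the standard Turner-2004 ΔG°37 set; G:U-containing stacks use a simplified
uniform −0.5 kcal/mol so that adding any canonical stack never raises the
energy (a monotonicity property the tests assert). No intramolecular
structure is modeled. DNA input is treated as RNA (T ≡ U). Hits are
retained at ΔG ≤ −20 kcal/mol — "binding energies lower than 20 kcal/mol"
is read as a stability magnitude, the only physically sensible reading —
with one best hit per regulator–gene pair (ties to the leftmost site).
Under these parameters an isolated 6-bp seed helix scores around
−10 kcal/mol and never passes the filter; passing requires ~12 or more
well-stacked pairs, which is what makes the planted-site recovery clean.
The DP equals exhaustive enumeration of all admissible pairings on short
sequences (1,000 seeded trials in the suite).

## Network, ORA, GSEA

An edge is retained iff (duplex hit) ∧ (both features significant, opposite
directions) ∧ (Pearson r < 0 across shared samples). Only the *sign* of the
correlation is required by default: with three replicates per condition a
correlation p-value carries almost no information, and pretending otherwise
would be false precision; a p cutoff is available for larger designs. ORA
is the hypergeometric upper tail over user-supplied GMT sets with BH FDR.
GSEA is the classic running sum (hits weighted by |score|^p normalized to
unit mass, p = 1 default; misses decrement 1/(N − N_hit)), with ES the
signed extremum; p and NES come from gene-label permutation under a fixed
seed, because the interface is a ranked list, not a sample-level matrix.

## Amino-acid usage correlation

CDS usage is pooled per gene (each gene counted once; expression weighting
optional by supplying weights upstream), stop codons excluded, frame
violations trimmed with a note. The parental spectrum counts each distinct
tsRNA once by default (read weighting available); multi-parent records
split fractionally. Comparison runs on the 20-residue alphabet: translation
cannot produce selenocysteine or a distinct initiator Met, so parental iMet
folds into Met and Sec-parented mass is excluded and renormalized (logged).
Pearson R with a two-sided t-based p is reported. A Pearson over 20 points
has standard error ≈ (1 − r²)/√19 ≈ 0.12 at r = 0.7: single simulated data
sets scatter widely around a planted correlation and only multi-seed
averages pin it down — the recovery checks therefore average 10 seeds.

## Simulator

* **References:** random 73-nt bodies + CCA on canonical landmarks;
  amino-acid labels cycle through all 22 (20 standard + Sec + iMet);
  every tenth gene is flagged mitochondrial.
* **Fragmentome:** type drawn from a configurable mixture (default
  dominated by tRF-5c, tiRNA-3 rarest, matching the observed landscape
  ordering); cut coordinates uniform within the type's admissible window —
  the exact inverse of the classifier's decision table, so error-free
  fragments classify back to truth by construction; types with an empty
  window on a given gene are resampled and logged.
* **Counts:** per-fragment lognormal mean (median 60 reads, σ = 1.5 —
  σ ≥ 1.5 qualitatively reproduces the extreme concentration of real tsRNA
  libraries, where a handful of fragments dominate) with NB noise at common
  φ (default 0.1) over n = 3 vs 3 samples, mirroring the three-animal,
  two-depot design; planted log₂ fold changes applied in group B with
  random sign. Substitution errors only (rate ε ≤ 0.05, default 0), no
  indels — matching the gap-free aligner.
* **Regulatory system:** each true regulator carries a planted UTR site
  (perfect complement, or seed-only to exercise the energy filter's
  rejection); regulator DE is planted at |log₂FC| = 3 and each target's
  per-sample mean tracks its regulator inversely in log space before NB
  noise. Both matrices contain a majority of flat background features —
  as in real libraries, where differential features are a small fraction —
  which keeps library-size normalization composition-stable; without the
  background, normalizing a 10-feature matrix with eightfold planted
  changes visibly distorts every fold change.
* **CDS set:** two 20-dim lognormal weight vectors with a latent Gaussian
  correlation calibrated in closed form (ρ_latent = ln(1 + r(e^{σ²}−1))/σ²,
  σ = 0.6) so the expected Pearson of the weights equals the planted r;
  one becomes the parental spectrum, the other is realized as integer codon
  counts (≥ 300 codons total) and emitted as CDS sequences, so translation
  reproduces the emitted usage exactly.

Everything is driven by integer-seeded `numpy.random.default_rng` streams;
fixed seed ⇒ byte-identical outputs, asserted in the suite.

## What the simulations do and do not show

The simulator plants clean, strong effects (fourfold fragment changes,
eightfold regulator changes, perfect complement sites, generous read
depth). Passing recovery tests therefore demonstrates that the *machinery*
is correct — classification inverts the generative windows, the exact test
is calibrated and powered at the design's n, the energy filter separates
planted sites from seed-only decoys, the network rule recovers planted
architecture — not that effects of this size or cleanliness exist in real
adipose tissue. Real libraries add tRNA-modification-induced
misincorporations and RT stops (not modeled), adapter/quality artifacts
beyond the simple 3′-adapter rule, multi-mapping across near-identical
isodecoders at much higher reference density, and compositional effects
that a single common dispersion only approximates.

## Problem sizes

Default scales — 44 genes, 300 fragments (2,000 in the classifier-recovery
check), 10,000 features in the calibration check, 10 planted edges over a
90-regulator/70-gene background, 1,000 duplex oracle trials at ≤ 12 nt,
10 seeds for correlation recovery — were chosen so the full suite and the
analysis scripts complete in well under a minute each on a laptop-class
machine while leaving the statistical assertions comfortable margins.

## Known limitations

* Exact-test behavior differs in detail from edgeR (no quantile adjustment,
  no tagwise shrinkage); conclusions rest only on the printed thresholds.
* Duplex energies are not RNAhybrid-exact: the wobble set and linear loop
  penalties are simplifications, versioned in `energy_params.py`.
* The aligner is exact/1-mismatch and gap-free by design; it is not a
  general short-read mapper.
* Classification boundaries (anchor tolerances, the 5b/5c stem boundary,
  the tRF-3a/3b 20-nt split) are documented defaults; published pipelines
  vary and none publishes exact offsets.
* GMT content is user-supplied; no live pathway-database access.
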