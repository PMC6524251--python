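# Methods

This note documents the statistical model behind `dmrperm`, the synthetic
study the generator emulates, and the numerical and design choices made
where several defensible options existed. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The analysis model

### Scales and transforms

Methylation enters as β values (fraction methylated, in [0, 1]) and is
tested on the M scale, M = log₂(β/(1 − β)), the variance-stabilising logit
that makes Gaussian-error regression defensible across the β range. The
transform requires β strictly inside (0, 1); matrices are clipped to
[ε, 1 − ε] with ε = 10⁻⁶ (configurable) before the logit. The two
transforms are exact inverses, implemented via `scipy.special.logit/expit`
for numerical stability at extreme M.

### Probe and sample QC

Two exclusion dialects are implemented, differing exactly in their
thresholds and inequalities:

| rule | 450K | EPIC |
|---|---|---|
| bead count | < 3 in ≥ 5% of samples | < 3 in > 10% of samples |
| detection p | > 0.001 in ≥ 5% of samples | > 0.01 in > 10% of samples |
| blacklist | user-supplied probe-id file | — |

The bead-count rule's sample fraction is not standardised for the 450K
dialect; we use the same ≥ 5% fraction as its detection rule (the common
`pfilter` convention). Boundary behaviour is part of the contract and is
tested: 5% exactly trips the 450K rule (≥), 10% exactly does not trip the
EPIC rule (strict >). A sample fails when *more than* 1% of its probes
exceed the detection threshold. Detection p values are intensity-based
quantities from the scanner; they are inputs here and never recomputed
from β values. Probe blacklists (cross-hybridising, SNP-proximal,
non-autosomal) are user files; the package ships no annotation.

### Adjustment covariates

The cohort regression adjusts for cellular composition, genetic ancestry
and smoking — the three classic whole-blood EWAS confounders — all
inferred from the methylation matrix itself:

* **Cell proportions**: constrained least squares of each sample's β
  vector onto reference profiles R (probes × cell types):
  min‖b − Rw‖² subject to w ≥ 0 and Σw = 1, solved by SLSQP with an
  analytic gradient (`ftol` 10⁻¹⁴); tiny negative components are clipped
  and the vector renormalised, so outputs satisfy the simplex constraints
  to 10⁻⁸. A rank-deficient reference (indistinguishable profiles) is
  rejected. In the noiseless full-rank case the solution is exact.
* **Ancestry PCs**: genotype leaks into apparent methylation at probes
  whose hybridisation is affected by nearby common SNPs, so principal
  components restricted to a user-supplied SNP-proximal probe list act as
  ancestry indicators. β values at the listed probes are centred per
  probe and decomposed by SVD; the first k = 2 sample scores are used.
  Signs are fixed by making each component's largest-magnitude loading
  positive, so results are invariant to sample order.
* **Smoking score**: Σᵢ wᵢ Mᵢ over a user-supplied list of
  smoking-responsive CpGs with weights, one scalar per sample. The score
  is linear in the weights; listed probes missing from the data are
  dropped with a warning.

### Per-CpG association

**Cohort arm.** For each probe, ordinary least squares of M on
{intercept, exposure, age, sex, five of six cell proportions, PC1, PC2,
smoking score}; one proportion (by default the last column, conventionally
the dominant granulocyte fraction) is dropped because the proportions sum
to one. The exposure coefficient is tested two-sided against t(n − p).
The implementation is vectorised across probes (one shared projection
matrix); constant probes get effect 0, p = 1 and a `constant` flag. Every
probe also carries Δβ (exposed-minus-control group mean difference of β),
the signed z = sign(effect)·Φ⁻¹(1 − p/2), and a direction label
(`hypo` iff Δβ < 0).

**Paired arm.** Within-donor differences (deprived − normal, M scale) are
tested with the exact Wilcoxon signed-rank distribution: zero differences
dropped, tied |d| given average ranks, and the null distribution of W⁺
built by dynamic-programming convolution over the (doubled, hence integer)
ranks — exact for up to 25 informative pairs, with a tie- and
continuity-corrected normal approximation beyond. The two-sided rule is
p = min(1, 2·min(P(W ≤ w), P(W ≥ w))). The effect is the median paired
ΔM; Δβ is the mean within-donor β difference. With n pairs the smallest
attainable two-sided p is 2/2ⁿ (0.0625 at n = 5); this discreteness
matters downstream (below).

**Diagnostics.** Genomic inflation λ = median(χ²₁-quantile of p) / 0.4549
and QQ coordinates; a well-calibrated null has λ ≈ 1.

### DMR calling

Candidate regions are maximal runs of consecutive map probes that all
pass the per-CpG seed threshold, with inter-probe gaps ≤ 1 kb, at least 2
probes long. Each run is scored with the equal-weight Stouffer statistic
S = Σzᵢ/√k referred to a two-sided normal tail; runs with region p < 0.01
are reported with their span (stored 0-based half-open, reported 1-based
inclusive), probe list, mean Δβ and direction. Defaults: seed threshold
α = 0.05 (cohort), max gap 1 kb, both widely used conventions for
kernel-based region callers.

Seed threshold in the paired arm: because the exact signed-rank p cannot
go below 2/2ⁿ, an α = 0.05 gate would exclude *every* probe at n = 5. The
pipeline therefore uses α just above the attainable floor (0.07 at n = 5,
via `paired_seed_alpha`), which admits exactly the probes whose every
pair moved in the same direction — the natural notion of nominal
significance this design can express (null rate 2/2⁵ = 6.25%).

The Gaussian region p ignores inter-CpG correlation; it serves only as a
nominal gate. Region-level significance is recalibrated empirically by
the permutation framework, which is agnostic to the region statistic.

### Replication inference

* **Concordant overlap**: two DMRs overlap if their half-open intervals
  intersect by ≥ 1 bp; only pairs with equal direction labels count
  (an interval replicated with the opposite sign is evidence against,
  not for).
* **Per-DMR empirical p**: the observed |S| is ranked within the |S| of
  *all* contiguous k-CpG windows genome-wide (k = the DMR's CpG count),
  computed by chromosome-wise cumulative sums. With ≤ 10⁶ windows the
  universe is enumerated exhaustively and p = (#windows with |S| ≥
  |S_obs|)/#windows, the observed window counting itself (p ≥ 1/N);
  larger universes are sampled uniformly with the add-one estimator
  p = (1 + #extreme)/(draws + 1), which can never return zero. The mode
  is recorded in the result. A relative tolerance of 10⁻⁹ on the
  comparison makes the observed window's self-count robust to float
  summation order.
* **Overlap-count null**: each permutation independently relocates every
  DMR in both lists to a uniformly chosen window of matching CpG count,
  keeping its direction label, and recounts concordant overlaps;
  p = (1 + #{count ≥ observed})/(draws + 1), 10,000 draws by default.
  Direction labels travel with the regions (rather than being
  re-randomised) so the null respects the observed direction composition;
  within-list collisions after relocation are permitted.
* **Replicated DMRs**: the final call of the analysis — concordant
  overlapping pairs whose empirical p is ≤ 0.01 in *both* arms
  (`CrossDesignResult.replicated_pairs`). The two-stage structure is
  deliberate: chance co-location of two weak 2-CpG regions across arms
  does occur, and the window-permutation stage is precisely what rejects
  it.
* **Combination and enrichment**: Fisher's method
  X² = −2Σln pᵢ ~ χ²(2k) combines the two arms' empirical p values per
  replicated region. Pearson χ² (df = 1, no continuity correction) on
  explicit 2×2 tables serves the overlap-enrichment comparisons; the
  pipeline builds two tables from its own run (cross-classification of
  shared probes by nominal significance in each arm, and arm × nominal
  rate).

## The synthetic study

No public dataset accompanies this design, so the generator is a
first-class module that emulates the statistical structure the analysis
assumes; every downstream stage is tested against it.

* **Genome**: n chromosomes with exponential inter-CpG gaps (mean 300 bp,
  rounded, min 2 bp), giving both tight clusters and gaps beyond the 1 kb
  run threshold, so split/merge logic is exercised by construction.
* **Cell reference**: bimodal Beta(0.4, 0.4) baseline per probe, shared
  across cell types, with ~15% of probes cell-type discriminating
  (independent Beta(0.5, 0.5) per type), clipped to [0.02, 0.98]. The
  sparse discrimination mirrors sorted-leukocyte panels and matters for
  calibration: if every probe discriminated, the curvature of M in the
  mixture proportions would act as a shared latent confounder that the
  linear proportion adjustment cannot remove, inflating the null
  beyond its binomial behaviour.
* **Cohort arm** (default 25 exposed / 54 controls): per-sample Dirichlet
  proportions (blood-like mean composition, concentration 50) mix the
  reference; on the M scale the generator adds age and sex slopes (all
  probes), a smoking slope (0.5 per unit level on 10 designated probes,
  matched by the emitted weight list), a population shift (0.5 on 40
  designated ancestry probes), exposure effects at spiked regions
  (exposed samples only), and N(0, 0.05²) noise; then transforms back to
  β and clips. True proportions and all covariates are recorded in the
  sample sheet. Ages are drawn at the exposed/control group means 50.3
  and 46.8 with within-group SD 2.0 — wide enough that age and the
  birth-window exposure remain separately identifiable in the adjusted
  regression; with near-zero within-group age variance the two become
  collinear and no effect size is detectable.
* **Paired arm** (default 5 donors × 2 conditions): a Beta(2, 2) baseline
  methylome, a per-donor per-probe normal intercept (SD 0.3) shared by
  the paired columns, effects added to the deprived column only, and
  N(0, 0.1²) column noise. The donor intercept cancels in within-donor
  differences, which the test suite asserts as a signed-rank invariance.
* **Effect sizes**: effects are additive on the M scale (Δβ is an output);
  `delta_m_for_delta_beta` maps a target β difference at a β₀ = 0.5
  baseline to the M shift (Δβ −0.03 ↔ ΔM −0.173; Δβ −0.25 ↔ ΔM −1.585).
  `choose_effect_regions` places spike regions so that each maps to
  exactly one candidate run: internal gaps ≤ 1 kb and (by default)
  flanking gaps > 1 kb. The isolation matters in the paired arm, where a
  flanking CpG sitting at the discrete p floor with the opposite sign
  would otherwise join a 4-CpG run and drag its Stouffer statistic below
  the region gate.
* **QC artifacts**: passing cells get detection p ~ U(0, 10⁻⁴) and bead
  counts in [5, 30]; designated failing cells get detection p ~ U(0.02,
  0.5) and/or bead counts in {0, 1, 2}, with exact per-probe failure
  counts controllable for boundary tests.

What the generator does **not** emulate — and hence what green tests do
not certify about real data: spatial correlation of methylation between
neighbouring CpGs (probes are independent given the design), probe-type
chemistry and colour-channel artefacts, batch/plate structure,
array-specific detection-p physics, and any real annotation (gene models,
true smoking CpGs, true cell references). In particular, the empirical
window p on real data would face correlated neighbouring statistics; the
permutation framework itself is agnostic to this, but its calibration
here is demonstrated only under independence.

## Numerical choices and degenerate inputs

* p values are floored at 10⁻³⁰⁰ before probit/χ² transforms; perfect
  fits (zero residual with nonzero effect) receive the floor rather than
  p = 0, keeping p in (0, 1].
* Constant methylation rows: effect 0, p 1, z 0, flagged — never an error.
* All-zero paired differences: p 1, flagged `all_zero`.
* The exact signed-rank DP uses doubled ranks so average ranks stay
  integral; untied rows share one cached distribution per n (the common
  fast path), tied rows get per-row convolutions.
* Exposure without contrast, rank-deficient designs, empty window
  universes, zero-margin contingency tables and mismatched matrices are
  rejected with explicit errors.
* Every stochastic routine takes a seed and is a pure function of its
  arguments; the pipeline derives child seeds from one root generator.

## Problem sizes

The test suite and acceptance script run the full design at 5,000 probes
(4 chromosomes), n = 79 cohort samples and 5 donor pairs, with 1,000–
10,000 permutation draws — sizes chosen so the complete two-arm analysis,
including 20 replicate end-to-end recovery runs, executes in minutes on a
single core while every window universe stays large enough (≈ 5,000
same-size windows) for empirical p values well below the 0.01 gate.

## Known limitations

* The OLS arm assumes homoskedastic Gaussian M-value errors; no robust or
  mixed-model variants.
* The Stouffer region p treats CpGs as independent; it is a gate, not a
  calibrated region p — the empirical window p is the calibrated object.
* The overlap-count null relocates regions independently; it does not
  preserve any clustering of DMRs along the genome.
* Reference-based deconvolution only; no reference-free alternatives.
* Normalisation (which requires raw intensity data) is out of scope;
  inputs are assumed normalised β values.
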