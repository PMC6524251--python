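# dmrperm

Cross-design differential DNA-methylation analysis with window-permutation
inference.

`dmrperm` is for epigenetics researchers who want to ask whether regional
methylation changes seen in an observational exposure cohort are *replicated*
by a controlled in vitro exposure — two designs with different tissues,
platforms and confounding structure, sharing only the genome. The package
implements the complete chain for Illumina-array data:

* **QC** — the standard probe/sample exclusion rules in both the 450K
  dialect (bead count < 3 or detection p > 0.001 in ≥ 5% of samples, plus
  user-supplied blacklists) and the EPIC dialect (strict > 10% fractions,
  detection threshold 0.01), and the β ↔ M transform
  M = log₂(β / (1 − β)).
* **Covariates** — reference-based cell-type deconvolution by constrained
  least squares (min‖b − Rw‖² s.t. w ≥ 0, Σw = 1), methylation-derived
  ancestry principal components from SNP-proximal probes, and a weighted
  smoking proxy score Σᵢ wᵢ Mᵢ.
* **EWAS** — mass-univariate covariate-adjusted OLS on M values (cohort
  arm) and the exact paired Wilcoxon signed-rank test (in vitro arm), with
  QQ/λ inflation diagnostics.
* **DMR calling** — maximal runs of consecutive nominally significant CpGs
  (inter-probe gap ≤ 1 kb) scored with the Stouffer statistic
  S = Σzᵢ/√k, kept at region-level nominal p < 0.01.
* **Replication inference** — direction-concordant overlap of the two DMR
  lists; a per-DMR **empirical p** ranking |S| against *all contiguous
  same-size CpG windows genome-wide*; a permutation null for the
  **overlap count** (every DMR relocated to a random same-size window,
  10,000 permutations); Fisher's method to combine the two arms' empirical
  p values; and Pearson χ² for 2×2 overlap-enrichment comparisons.
* **Synthetic data** — a generator for the full two-arm design (cohort:
  25 exposed vs 54 controls as whole-blood cell mixtures; paired: 5 donors
  × 2 conditions) with spiked hypomethylated regions, so the entire
  pipeline runs closed-loop without any external data or annotation.

The estimator classes (`CellTypeDeconvolver`, `AncestryPCA`,
`MassUnivariateOLS`, `PairedWilcoxon`, `DMRCaller`) follow scikit-learn
conventions (`fit`, fitted attributes with trailing underscores); the
module-level functions are thin wrappers in the field's probes × samples
orientation.

## Worked example

Simulate a small two-arm study with one region hypomethylated in *both*
arms (Δβ ≈ −0.03 in the cohort, ≈ −0.25 in vitro) and one discordant decoy
(hypo in the cohort, hyper in vitro), then run the full analysis:

```python
import dmrperm as dp

cpg_map = dp.generate_map(n_chrom=2, cpgs_per_chrom=600, mean_gap_bp=300, seed=99)
regions = dp.choose_effect_regions(cpg_map, sizes=[4, 5],
                                   delta_ms=[dp.delta_m_for_delta_beta(-0.03)] * 2,
                                   seed=5)
true_region, decoy = regions
dm_paired = dp.delta_m_for_delta_beta(-0.25)
study = dp.simulate_cross_design_study(
    cpg_map=cpg_map,
    cohort_effects=regions,
    paired_effects=[dp.EffectSpec(true_region.chrom, true_region.start,
                                  true_region.n_cpgs, dm_paired),
                    dp.EffectSpec(decoy.chrom, decoy.start, decoy.n_cpgs,
                                  -dm_paired)],
    seed=17)
res = dp.run_cross_design_analysis(study.cohort, study.paired, study.reference,
                                   study.smoking_weights, study.ancestry_probes,
                                   n_draws=1000, seed=17)
```

Output of the summary loop (see `tests/test_pipeline.py` for the full
assertions):

```
cohort DMRs: 3   paired DMRs: 4
concordant overlaps: 1
  chr2:164360-165051  4 CpGs  direction=hypo  empirical p (cohort)=0.002513  empirical p (paired)=0.002513  combined=8.19e-05
replicated DMRs (both empirical p <= 0.01): 1
overlap-count null p: 0.02098
inflation lambda (cohort arm): 1.038
```

Reading the numbers: each arm calls a handful of regions at nominal 0.01
(the decoy appears in both lists but with opposite directions, so it is
not counted as an overlap). The one concordant region ranks in the top
0.26% of all 4-CpG windows in both arms (empirical p = 0.0025 each;
the exhaustive universe here holds ~1,200 windows), Fisher-combining the
two arms gives p ≈ 8×10⁻⁵, and relocating every DMR to random same-size
windows produces ≥ 1 concordant overlap in only ~2% of permutations. The
cohort regression is well calibrated (λ ≈ 1.04).

The same stages are available from the shell:

```bash
dmrperm simulate --n-probes 2000 --n-chrom 2 --seed 5 --out-dir sim/
dmrperm qc --betas sim/cohort_betas.tsv --det-p sim/cohort_detp.tsv \
           --beads sim/cohort_beads.tsv --platform 450k \
           --out-betas cohort_filtered.tsv --report qc.json
dmrperm ewas --design cohort --betas cohort_filtered.tsv \
             --samples sim/cohort_samples.csv --map sim/map.bed \
             --reference sim/cell_reference.tsv \
             --smoking-weights sim/smoking_weights.tsv \
             --ancestry-probes sim/ancestry_probes.txt --out assoc_cohort.tsv
dmrperm ewas --design paired --betas sim/paired_betas.tsv \
             --samples sim/paired_samples.csv --map sim/map.bed \
             --out assoc_paired.tsv
dmrperm dmr --assoc assoc_cohort.tsv --map sim/map.bed \
            --out-bed dmrs.bed --out-tsv dmrs.tsv
dmrperm replicate --assoc-a assoc_cohort.tsv --assoc-b assoc_paired.tsv \
                  --map sim/map.bed --seed 4 --out-dir rep/
```

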