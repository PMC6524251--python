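"""End-to-end cross-design analysis.

Runs the full inference chain on a two-arm study sharing one CpG map:
covariate estimation and per-CpG regression in the cohort arm, exact paired
signed-rank testing in the in vitro arm, DMR calling in both, direction-
concordant overlap, per-DMR empirical p values against same-size windows,
the overlap-count permutation null, Fisher combination of the two arms'
empirical p values per replicated region, and the two 2x2 chi-squared
enrichment comparisons.

The paired arm's per-CpG seed threshold defaults to 0.07 rather than 0.05:
with five donors the smallest attainable exact two-sided signed-rank p is
2/2^5 = 0.0625, so a 0.05 gate would exclude every probe. The 0.07 default
admits exactly the probes whose five pairs all move in the same direction
(null rate 6.25%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import build_covariate_table
from .datatypes import CellReference, MethylationDataset, OverlapPair, PermutationResult
from .dmr import call_dmrs
from .ewas import (fit_cpg_regression, inflation_lambda, make_design,
                   paired_wilcoxon)
from .permutation import (arm_rate_table, empirical_dmr_p, fisher_combine,
                          nominal_cross_table, overlap_count_null,
                          overlap_dmrs, overlap_enrichment_chisq)
from .qc import beta_to_m

__all__ = ["CrossDesignResult", "run_cross_design_analysis", "paired_seed_alpha"]


def paired_seed_alpha(n_donors: int, margin: float = 1.1) -> float:
    """Seed threshold just above the exact signed-rank p floor 2/2^n."""
    return min(0.5, margin * 2.0 / 2 ** n_donors)


@dataclass
class CrossDesignResult:
    """Everything the two-arm analysis computes."""

    assoc_cohort: pd.DataFrame
    assoc_paired: pd.DataFrame
    dmrs_cohort: list
    dmrs_paired: list
    overlaps: list
    dmr_perm_cohort: list  # PermutationResult per overlapping cohort DMR
    dmr_perm_paired: list
    combined_p: list  # Fisher combination of the two arms' empirical p per pair
    overlap_null: PermutationResult | None
    cross_chisq: tuple | None
    rate_chisq: tuple | None
    lambda_cohort: float
    lambda_paired: float

    @property
    def n_concordant_overlaps(self) -> int:
        return len(self.overlaps)

    def replicated_pairs(self, alpha: float = 0.01) -> list:
        """Concordant overlapping pairs confirmed by permutation: both arms'
        per-DMR empirical p values are <= ``alpha``. This is the final
        'replicated DMR' call of the analysis — a region must overlap with
        concordant direction *and* rank in the top ``alpha`` of same-size
        windows in each arm."""
        return [pair for pair, rc, rp in zip(self.overlaps, self.dmr_perm_cohort,
                                             self.dmr_perm_paired)
                if rc.empirical_p <= alpha and rp.empirical_p <= alpha]


def run_cross_design_analysis(cohort: MethylationDataset, paired: MethylationDataset,
                              reference: CellReference, smoking_weights: pd.Series,
                              ancestry_probe_ids, *,
                              alpha_cpg_cohort: float = 0.05,
                              alpha_cpg_paired: float | None = None,
                              alpha_dmr: float = 0.01, max_gap: int = 1000,
                              min_cpgs: int = 2, n_draws: int = 10_000,
                              perm_mode: str = "auto",
                              seed: int = 0) -> CrossDesignResult:
    """Run the full cross-design analysis on two QC'd arms sharing a map.

    ``cohort`` needs a sample sheet with ``exposure``, ``age``, ``sex``;
    ``paired`` needs ``donor`` and ``condition`` ('normal'/'deprived')
    columns. ``seed`` drives every stochastic permutation step.
    """
    if not cohort.cpg_map.equals(paired.cpg_map):
        raise ValueError("the two arms must share one CpG map (same build and probes)")
    cpg_map = cohort.cpg_map
    rng = np.random.default_rng(seed)

    # cohort arm: covariates + mass-univariate regression
    cov = build_covariate_table(cohort.betas, cohort.sample_sheet, reference,
                                smoking_weights, ancestry_probe_ids)
    design = make_design(cov)
    M_cohort = beta_to_m(cohort.betas)
    assoc_cohort = fit_cpg_regression(M_cohort, design, betas=cohort.betas,
                                      cpg_map=cpg_map)

    # paired arm: exact signed-rank on within-donor differences
    sheet = paired.sample_sheet
    norm_cols, dep_cols = [], []
    for donor, grp in sheet.groupby("donor", sort=True):
        cond = grp["condition"]
        n = grp.index[cond == "normal"]
        d = grp.index[cond == "deprived"]
        if len(n) != 1 or len(d) != 1:
            raise ValueError(f"donor {donor!r} is not a clean normal/deprived pair")
        norm_cols.append(n[0])
        dep_cols.append(d[0])
    M_paired = beta_to_m(paired.betas)
    if alpha_cpg_paired is None:
        alpha_cpg_paired = paired_seed_alpha(len(norm_cols))
    assoc_paired = paired_wilcoxon(M_paired[norm_cols], M_paired[dep_cols],
                                   pairing=dict(zip(norm_cols, dep_cols)),
                                   cpg_map=cpg_map)

    dmrs_cohort = call_dmrs(assoc_cohort, cpg_map, alpha_cpg=alpha_cpg_cohort,
                            max_gap=max_gap, min_cpgs=min_cpgs, alpha_dmr=alpha_dmr)
    dmrs_paired = call_dmrs(assoc_paired, cpg_map, alpha_cpg=alpha_cpg_paired,
                            max_gap=max_gap, min_cpgs=min_cpgs, alpha_dmr=alpha_dmr)
    overlaps = overlap_dmrs(dmrs_cohort, dmrs_paired, require_concordance=True)

    perm_c, perm_p, combined = [], [], []
    for pair in overlaps:
        rc = empirical_dmr_p(pair.dmr_a, assoc_cohort, cpg_map, mode=perm_mode,
                             n_draws=n_draws, seed=int(rng.integers(2**31)))
        rp = empirical_dmr_p(pair.dmr_b, assoc_paired, cpg_map, mode=perm_mode,
                             n_draws=n_draws, seed=int(rng.integers(2**31)))
        perm_c.append(rc)
        perm_p.append(rp)
        combined.append(fisher_combine([rc.empirical_p, rp.empirical_p]))

    overlap_null = None
    if dmrs_cohort and dmrs_paired:
        overlap_null = overlap_count_null(dmrs_cohort, dmrs_paired, cpg_map,
                                          n_draws=n_draws,
                                          seed=int(rng.integers(2**31)))

    cross = nominal_cross_table(assoc_cohort, assoc_paired,
                                alpha_a=alpha_cpg_cohort, alpha_b=alpha_cpg_paired)
    rate = arm_rate_table(assoc_cohort, assoc_paired,
                          alpha_a=alpha_cpg_cohort, alpha_b=alpha_cpg_paired)
    cross_chisq = overlap_enrichment_chisq(cross) if np.all(cross.sum(axis=0) > 0) \
        and np.all(cross.sum(axis=1) > 0) else None
    rate_chisq = overlap_enrichment_chisq(rate) if np.all(rate.sum(axis=0) > 0) \
        and np.all(rate.sum(axis=1) > 0) else None

    return CrossDesignResult(
        assoc_cohort=assoc_cohort, assoc_paired=assoc_paired,
        dmrs_cohort=dmrs_cohort, dmrs_paired=dmrs_paired, overlaps=overlaps,
        dmr_perm_cohort=perm_c, dmr_perm_paired=perm_p, combined_p=combined,
        overlap_null=overlap_null, cross_chisq=cross_chisq, rate_chisq=rate_chisq,
        lambda_cohort=inflation_lambda(assoc_cohort),
        lambda_paired=inflation_lambda(assoc_paired),
    )
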