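"""Generator behaviour: determinism, invariants, and exact constructions."""

import numpy as np
import pandas as pd
import pytest

import dmrperm as dp
from dmrperm.qc import beta_to_m, m_to_beta


class TestGenerateMap:
    def test_basic_invariants(self):
        m = dp.generate_map(1, 5, 200.0, seed=3)
        assert len(m) == 5
        pos = m.table["pos"].to_numpy()
        assert np.all(np.diff(pos) > 0)
        assert m.probe_ids.is_unique

    def test_determinism(self):
        a = dp.generate_map(2, 50, 300.0, seed=9)
        b = dp.generate_map(2, 50, 300.0, seed=9)
        assert a.equals(b)
        c = dp.generate_map(2, 50, 300.0, seed=10)
        assert not a.equals(c)

    def test_gap_tail_matches_exponential(self):
        """Fraction of gaps beyond 1 kb follows the exponential tail."""
        m = dp.generate_map(2, 100, 300.0, seed=7)
        gaps = np.concatenate([np.diff(m.table["pos"].to_numpy()[m.chrom_slice(c)])
                               for c in m.chromosomes])
        frac = float((gaps > 1000).mean())
        expect = np.exp(-1000.0 / 300.0)
        se = np.sqrt(expect * (1 - expect) / gaps.size)
        assert abs(frac - expect) < 3 * se

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            dp.generate_map(0, 5, 100.0)
        with pytest.raises(ValueError):
            dp.generate_map(1, 5, -1.0)


class TestGenerateCohort:
    def test_default_design_size(self, small_map, reference):
        ds = dp.generate_cohort(small_map, dp.CohortModel(cell_reference=reference))
        assert ds.betas.shape == (len(small_map), 79)
        assert ds.sample_sheet["exposure"].sum() == 25
        assert (ds.sample_sheet["exposure"] == 0).sum() == 54

    def test_noiseless_identity_equals_reference_mixture(self, small_map, reference):
        """Zero noise, zero effects, fixed proportions: betas are exactly the
        mixed reference profiles, and both groups have identical means."""
        w = np.full(6, 1 / 6)
        model = dp.CohortModel(cell_reference=reference, n_exposed=3, n_control=4,
                               noise_sd=0.0, fixed_proportions=w,
                               covariate_effects={}, seed=1)
        ds = dp.generate_cohort(small_map, model)
        mix = reference.profiles.loc[small_map.probe_ids].to_numpy() @ w
        np.testing.assert_allclose(ds.betas.to_numpy(),
                                   np.tile(mix[:, None], (1, 7)), atol=1e-9)
        expo = ds.sample_sheet["exposure"].to_numpy() == 1
        np.testing.assert_allclose(ds.betas.to_numpy()[:, expo].mean(1),
                                   ds.betas.to_numpy()[:, ~expo].mean(1), atol=1e-12)

    def test_spiked_delta_m_is_exact_without_noise(self, small_map, reference):
        spec = dp.EffectSpec(chrom="chr1", start=5, n_cpgs=4, delta_m=-0.8)
        model = dp.CohortModel(cell_reference=reference, n_exposed=5, n_control=6,
                               noise_sd=0.0, fixed_proportions=np.full(6, 1 / 6),
                               covariate_effects={}, seed=2)
        ds = dp.generate_cohort(small_map, model, [spec])
        M = beta_to_m(ds.betas).to_numpy()
        expo = ds.sample_sheet["exposure"].to_numpy() == 1
        dM = M[:, expo].mean(1) - M[:, ~expo].mean(1)
        gi = spec.global_indices(small_map)
        np.testing.assert_allclose(dM[gi], -0.8, atol=1e-9)
        untouched = np.setdiff1d(np.arange(len(small_map)), gi)
        np.testing.assert_allclose(dM[untouched], 0.0, atol=1e-9)

    def test_effect_region_outside_map_rejected(self, small_map, reference):
        model = dp.CohortModel(cell_reference=reference)
        bad = dp.EffectSpec(chrom="chr1", start=28, n_cpgs=5, delta_m=-1.0)
        with pytest.raises(ValueError, match="outside map"):
            dp.generate_cohort(small_map, model, [bad])

    def test_reference_missing_probes_rejected(self, small_map, reference):
        model = dp.CohortModel(
            cell_reference=dp.CellReference(reference.profiles.iloc[:-3]))
        with pytest.raises(ValueError, match="missing"):
            dp.generate_cohort(small_map, model)

    def test_betas_in_open_unit_interval(self, cohort_small):
        vals = cohort_small.betas.to_numpy()
        assert np.all(vals > 0) and np.all(vals < 1)

    def test_m_beta_round_trip_on_generated_data(self, cohort_small):
        B = cohort_small.betas
        np.testing.assert_allclose(m_to_beta(beta_to_m(B)).to_numpy(),
                                   B.to_numpy(), atol=1e-12)

    def test_determinism(self, small_map, reference):
        model = dp.CohortModel(cell_reference=reference, seed=33)
        a = dp.generate_cohort(small_map, model)
        b = dp.generate_cohort(small_map, model)
        pd.testing.assert_frame_equal(a.betas, b.betas)
        pd.testing.assert_frame_equal(a.sample_sheet, b.sample_sheet)

    def test_dirichlet_proportions_converge_to_prior_mean(self, small_map, reference):
        model = dp.CohortModel(cell_reference=reference, n_exposed=600,
                               n_control=600, seed=8)
        ds = dp.generate_cohort(small_map, model)
        W = ds.sample_sheet[[f"true_{c}" for c in reference.cell_names]].to_numpy()
        alpha = model.dirichlet_alpha
        expect = alpha / alpha.sum()
        var = expect * (1 - expect) / (alpha.sum() + 1)
        se = np.sqrt(var / W.shape[0])
        assert np.all(np.abs(W.mean(axis=0) - expect) < 3 * se)


class TestGeneratePaired:
    def test_default_design_size(self, small_map):
        ds = dp.generate_paired(small_map, seed=1)
        assert ds.betas.shape[1] == 10
        assert set(ds.sample_sheet["condition"]) == {"normal", "deprived"}
        assert ds.sample_sheet["donor"].nunique() == 5

    def test_degenerate_all_columns_identical(self, small_map):
        ds = dp.generate_paired(small_map, donor_sd=0.0, noise_sd=0.0, seed=2)
        vals = ds.betas.to_numpy()
        assert np.allclose(vals, vals[:, [0]])

    def test_within_donor_delta_is_exact_without_noise(self, small_map):
        spec = dp.EffectSpec(chrom="chr2", start=3, n_cpgs=5, delta_m=-1.5)
        ds = dp.generate_paired(small_map, effects=[spec], donor_sd=0.4,
                                noise_sd=0.0, seed=3)
        M = beta_to_m(ds.betas)
        gi = spec.global_indices(small_map)
        for donor in ds.sample_sheet["donor"].unique():
            dM = (M[f"{donor}_deprived"] - M[f"{donor}_normal"]).to_numpy()
            np.testing.assert_allclose(dM[gi], -1.5, atol=1e-9)
            np.testing.assert_allclose(np.delete(dM, gi), 0.0, atol=1e-9)

    def test_too_few_donors_rejected(self, small_map):
        with pytest.raises(ValueError):
            dp.generate_paired(small_map, n_donors=1)


class TestQCArtifacts:
    def test_all_pass_when_nothing_fails(self, cohort_small):
        det, beads = dp.generate_qc_artifacts(cohort_small, seed=4)
        assert (det.to_numpy() < 0.001).all()
        assert (beads.to_numpy() >= 3).all()
        rep = dp.filter_probes_450k(det, beads)
        assert not rep.exclusions

    def test_flagged_probe_excluded_by_450k_filter(self, cohort_small):
        import math
        n = cohort_small.n_samples
        probe = cohort_small.betas.index[7]
        det, beads = dp.generate_qc_artifacts(
            cohort_small, seed=5, fail_cells={probe: math.ceil(0.05 * n)})
        rep = dp.filter_probes_450k(det, beads)
        assert probe in rep.exclusions
        assert set(rep.exclusions) == {probe}

    def test_sample_failures_flagged(self, cohort_small):
        sid = cohort_small.betas.columns[0]
        det, _ = dp.generate_qc_artifacts(cohort_small, sample_fail_ids=[sid],
                                          sample_fail_probe_fraction=0.05, seed=6)
        assert dp.filter_samples(det, 0.001, 0.01) == [sid]

    def test_unknown_sample_rejected(self, cohort_small):
        with pytest.raises(ValueError, match="unknown sample"):
            dp.generate_qc_artifacts(cohort_small, sample_fail_ids=["nope"])

    def test_seeded_regeneration_identical(self, cohort_small):
        a = dp.generate_qc_artifacts(cohort_small, probe_fail_rate=0.1, seed=7)
        b = dp.generate_qc_artifacts(cohort_small, probe_fail_rate=0.1, seed=7)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])


class TestEffectHelpers:
    def test_delta_m_moves_beta_by_requested_amount(self):
        dm = dp.delta_m_for_delta_beta(-0.03, beta0=0.5)
        assert abs(m_to_beta(beta_to_m(0.5) + dm) - 0.47) < 1e-12

    def test_effect_spec_validation(self):
        with pytest.raises(ValueError):
            dp.EffectSpec(chrom="chr1", start=0, n_cpgs=0, delta_m=-1.0)
        with pytest.raises(ValueError):
            dp.EffectSpec(chrom="chr1", start=0, n_cpgs=2, delta_m=0.0)
        assert dp.EffectSpec("chr1", 0, 2, -1.0).direction == "hypo"
        assert dp.EffectSpec("chr1", 0, 2, 1.0).direction == "hyper"

    def test_chosen_regions_are_single_runs(self):
        m = dp.generate_map(4, 1250, 300.0, seed=123)
        specs = dp.choose_effect_regions(m, [4, 5, 13], [-0.5, -0.5, -0.5], seed=3)
        pos = m.table["pos"].to_numpy()
        taken = []
        for s in specs:
            gi = s.global_indices(m)
            assert np.all(np.diff(pos[gi]) <= 1000)  # internal gaps
            sl = m.chrom_slice(s.chrom)
            if gi[0] > sl.start:  # isolation on the left
                assert pos[gi[0]] - pos[gi[0] - 1] > 1000
            if gi[-1] < sl.stop - 1:  # isolation on the right
                assert pos[gi[-1] + 1] - pos[gi[-1]] > 1000
            taken.append(set(gi.tolist()))
        assert not (taken[0] & taken[1] or taken[0] & taken[2] or taken[1] & taken[2])
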