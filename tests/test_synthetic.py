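"""Synthetic-data generators: determinism, conservation, planted effects."""

import numpy as np
import pytest

import somnotype as st


class TestMouseActivity:
    def test_identical_seed_gives_bit_identical_traces(self):
        spec = st.MouseCohortSpec(n_per_genotype=2, days=2, seed=77)
        sched = st.ld_schedule(2)
        t1 = st.simulate_mouse_activity(spec, sched)
        t2 = st.simulate_mouse_activity(spec, sched)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_trace_length_and_value_range(self):
        spec = st.MouseCohortSpec(n_per_genotype=1, days=3, seed=1)
        (trace, *rest) = st.simulate_mouse_activity(spec, st.ld_schedule(3))
        assert trace.n_bins == 3 * 86400 // 10
        assert trace.values.min() >= 0 and trace.values.max() <= 100

    def test_every_bin_is_active_or_immobile(self):
        spec = st.MouseCohortSpec(n_per_genotype=1, days=1, seed=2)
        (trace, *_) = st.simulate_mouse_activity(spec, st.ld_schedule(1))
        active = trace.values > 0
        assert int(active.sum()) + int((~active).sum()) == trace.n_bins

    def test_nocturnal_cohort_more_active_in_dark(self, ld_cohort):
        traces, _ = ld_cohort
        wins = 0
        for trace in [t for t in traces if t.genotype == "WT"]:
            dark = trace.schedule.is_dark(trace.bin_times())
            if trace.values[dark].mean() > trace.values[~dark].mean():
                wins += 1
        assert wins >= 5

    def test_brief_bout_deficit_monotone_over_seeds(self):
        """Halving the sub-minute weight lowers expected sub-minute bout
        counts, checked across many seeds (planted-effect monotonicity)."""
        def mean_subminute(deficit, seeds):
            counts = []
            for seed in seeds:
                spec = st.MouseCohortSpec(
                    n_per_genotype=1, days=1,
                    genotypes={"G": st.GenotypeParams(brief_bout_deficit=deficit)},
                    seed=seed,
                )
                (tr,) = st.simulate_mouse_activity(spec, st.ld_schedule(1))
                counts.append(
                    st.categorize_bouts(st.segment_activity_bouts(tr))["<1 min"]
                )
            return np.mean(counts)

        seeds = range(50)
        assert mean_subminute(0.5, seeds) < mean_subminute(1.0, seeds)

    def test_schedule_shorter_than_requested_days_rejected(self):
        spec = st.MouseCohortSpec(days=7, seed=0)
        with pytest.raises(st.ParameterError):
            st.simulate_mouse_activity(spec, st.ld_schedule(3))

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(st.ParameterError):
            st.MouseCohortSpec(days=0)
        with pytest.raises(st.ParameterError):
            st.MouseCohortSpec(bin_seconds=7)  # must divide 60
        with pytest.raises(st.ParameterError):
            st.GenotypeParams(brief_bout_deficit=0.0)
        with pytest.raises(st.ParameterError):
            st.BoutMixture(weights=(0.0, 0.0, 0.0, 0.0))

    def test_tau_lengthens_with_light_when_slope_positive(self):
        blocks, t = [], 0
        for days, cond, lux in ((12, "DD", 0), (12, "LL", 100)):
            blocks.append(st.LightBlock(t, t + days * 86400, cond, lux))
            t += days * 86400
        spec = st.MouseCohortSpec(
            n_per_genotype=2, days=12,
            genotypes={"G": st.GenotypeParams(intrinsic_tau_h=23.7,
                                              aschoff_slope=0.4)},
            seed=31,
        )
        traces = st.simulate_mouse_activity(spec, st.LightingSchedule(tuple(blocks)))
        table = st.light_response_table(traces)
        piv = table.pivot_table(index="subject", columns="lux", values="tau_h")
        assert (piv[100.0] > piv[0.0]).all()


class TestDiary:
    def test_duty_cycle_within_ten_percent(self):
        spec = st.DiarySpec(cycle_length_h=72, sleep_fraction=0.35, seed=8)
        diary = st.simulate_sleep_diary(spec)
        assert abs(diary.flags.mean() - 0.35) <= 0.1 * 0.35 + 0.02

    def test_deterministic(self):
        spec = st.DiarySpec(seed=4)
        a = st.simulate_sleep_diary(spec)
        b = st.simulate_sleep_diary(spec)
        np.testing.assert_array_equal(a.flags, b.flags)

    def test_degenerate_specs_rejected(self):
        with pytest.raises(st.ParameterError):
            st.DiarySpec(sleep_fraction=0.0)
        with pytest.raises(st.ParameterError):
            st.DiarySpec(cycle_length_h=24.0)
        with pytest.raises(st.ParameterError):
            st.DiarySpec(days=30)
        with pytest.raises(st.ParameterError):
            st.DiarySpec(resolution_h=2)

    def test_ultralong_cycle_recovered_by_periodogram(self):
        diary = st.simulate_sleep_diary(st.DiarySpec(cycle_length_h=72, seed=3))
        pg = st.chi_square_periodogram(
            diary.flags.astype(float), (16, 120), analysis_bin_s=3600
        )
        tau = st.estimate_tau(pg)
        assert tau is not None and 56 <= tau <= 90


class TestPedigreeVcf:
    def test_background_variants_never_pass_the_funnel(self):
        spec = st.PedigreeVcfSpec(n_background_variants=400, planted=(), seed=6)
        records, ped = st.make_toy_pedigree_vcf(spec)
        cs, _ = st.run_full_filter(records, ped)
        assert cs.n_total == 0

    def test_planted_compound_het_is_gene_level_pair(self):
        spec = st.PedigreeVcfSpec(
            n_background_variants=20,
            planted=(st.PlantedVariant(model="compound_het"),),
            seed=1,
        )
        records, ped = st.make_toy_pedigree_vcf(spec)
        cs, _ = st.run_full_filter(records, ped)
        (gene,) = cs.compound_het
        assert len(cs.compound_het[gene]) == 2

    def test_unknown_model_rejected(self):
        with pytest.raises(st.ParameterError):
            st.PlantedVariant(model="dominant")

    def test_gll_margins_match_planted_confidence(self):
        spec = st.PedigreeVcfSpec(
            n_background_variants=0,
            planted=(st.PlantedVariant(model="shared_denovo", gll_margin=6.0),),
            seed=0,
        )
        (rec,), _ = st.make_toy_pedigree_vcf(spec)
        for sample in rec.genotypes:
            assert rec.gll_margin(sample) == pytest.approx(-6.0)


class TestDoseResponseTable:
    def test_reference_response_is_one(self):
        tab = st.simulate_dose_response(ec50_mM=0.53)
        ref = tab.loc[tab.concentration_mM == 10.0, "response"].item()
        assert ref == pytest.approx(1.0)

    def test_response_at_ec50_is_midpoint(self):
        tab = st.simulate_dose_response(
            ec50_mM=0.53, top=1.2, bottom=0.1,
            concentrations=(0.01, 0.1, 0.53, 5.0, 50.0),
        )
        mid = tab.loc[tab.concentration_mM == 0.53, "response"].item()
        assert mid == pytest.approx((1.2 + 0.1) / 2)

    def test_noisy_table_reproducible(self):
        a = st.simulate_dose_response(noise_sd=0.05, seed=3)
        b = st.simulate_dose_response(noise_sd=0.05, seed=3)
        np.testing.assert_array_equal(a.response, b.response)

    def test_concentrations_must_span_ec50(self):
        with pytest.raises(st.ParameterError):
            st.simulate_dose_response(ec50_mM=0.5, concentrations=(1.0, 3.0, 10.0))
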