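"""Synthetic cohort generator: concentrations, spectra, survival."""
import numpy as np
import pytest

import pancmetab as pm
from pancmetab.quantification import integrate_peak


def two_group_design(stats_a, stats_b, n_a=5, n_b=6):
    return pm.CohortDesign(groups=(
        pm.GroupSpec("A", n_a, stats_a, tissue="PP"),
        pm.GroupSpec("B", n_b, stats_b, tissue="PA"),
    ))


class TestConcentrations:
    def test_zero_sd_reproduces_means_exactly(self, assignments):
        stats = {"lactate": (12.0, 0.0), "choline": (1.5, 0.0)}
        design = two_group_design(stats, stats)
        quant, meta = pm.simulate_concentrations(design, seed=0, assignments=assignments)
        assert (quant["lactate"] == 12.0).all()
        assert (quant["choline"] == 1.5).all()

    def test_same_seed_identical(self, table2_design, assignments):
        q1, m1 = pm.simulate_concentrations(table2_design, 7, assignments)
        q2, m2 = pm.simulate_concentrations(table2_design, 7, assignments)
        assert q1.equals(q2)
        assert m1 == m2

    def test_lactate_mean_matches_design_at_large_n(self, assignments):
        # law of large numbers against the stated zero-truncated Gaussian
        design = pm.CohortDesign(groups=(
            pm.GroupSpec("PA", 10000, {"lactate": (16.1370, 4.7272)}, tissue="PA"),
        ))
        quant, _ = pm.simulate_concentrations(design, seed=5, assignments=assignments)
        se = 4.7272 / np.sqrt(10000)
        assert abs(quant["lactate"].mean() - 16.1370) < 3 * se + 0.01

    def test_all_non_negative(self, assignments):
        design = pm.CohortDesign(groups=(
            pm.GroupSpec("A", 500, {"tyrosine": (0.05, 0.3)}, tissue="PA"),
        ))
        quant, _ = pm.simulate_concentrations(design, seed=1, assignments=assignments)
        assert (quant["tyrosine"] >= 0).all()

    def test_column_order_follows_assignment_table(self, table2_design, assignments):
        quant, _ = pm.simulate_concentrations(table2_design, 0, assignments)
        expected = [
            m for m in assignments.quantified_metabolites
            if m in table2_design.metabolites
        ]
        assert list(quant.columns) == expected

    def test_weights_in_analytic_range(self, table2_cohort):
        _, meta = table2_cohort
        assert all(15.0 <= m.weight_mg <= 20.0 for m in meta)

    def test_pathway_correlation_induces_dependence(self, assignments):
        stats = {"glucose": (2.0, 0.5), "lactate": (10.0, 2.0)}
        base = pm.CohortDesign(groups=(pm.GroupSpec("A", 4000, stats),))
        corr = pm.CohortDesign(
            groups=(pm.GroupSpec("A", 4000, stats),),
            correlation=0.8,
            pathway_blocks=(("glucose", "lactate"),),
        )
        q0, _ = pm.simulate_concentrations(base, 3, assignments)
        q1, _ = pm.simulate_concentrations(corr, 3, assignments)
        assert abs(np.corrcoef(q0["glucose"], q0["lactate"])[0, 1]) < 0.1
        assert np.corrcoef(q1["glucose"], q1["lactate"])[0, 1] > 0.5


class TestSpectra:
    def test_zero_concentrations_give_zero_intensity(self, assignments, synth_params):
        quants = {m: 0.0 for m in assignments.quantified_metabolites}
        s = pm.synthesize_spectrum(quants, 17.0, assignments, synth_params)
        assert np.all(s.intensity == 0)

    def test_synthesis_is_linear(self, assignments):
        params = pm.SpectrumSynthParams(points=16384)
        qa = {"lactate": 10.0, "choline": 1.0}
        qb = {"lactate": 2.0, "choline": 4.0}
        qsum = {k: qa[k] + qb[k] for k in qa}
        sa = pm.synthesize_spectrum(qa, 17.0, assignments, params)
        sb = pm.synthesize_spectrum(qb, 17.0, assignments, params)
        ssum = pm.synthesize_spectrum(qsum, 17.0, assignments, params)
        np.testing.assert_allclose(sa.intensity + sb.intensity, ssum.intensity, rtol=1e-12)

    def test_doubling_one_metabolite_localizes_to_its_window(
        self, assignments, synth_params
    ):
        base = {"glycine": 2.0, "taurine": 4.0, "creatine": 1.5}
        s1 = pm.synthesize_spectrum(base, 17.0, assignments, synth_params)
        s2 = pm.synthesize_spectrum(
            {**base, "glycine": 4.0}, 17.0, assignments, synth_params
        )
        a1 = integrate_peak(s1, 3.56, baseline="none")
        a2 = integrate_peak(s2, 3.56, baseline="none")
        assert a2 == pytest.approx(2 * a1, rel=0.02)
        for other in (3.43, 3.93):  # taurine, creatine windows
            b1 = integrate_peak(s1, other, baseline="none")
            b2 = integrate_peak(s2, other, baseline="none")
            assert abs(b2 - b1) < 0.01 * b1

    def test_ppm_range_must_cover_quantification_peaks(self, assignments):
        params = pm.SpectrumSynthParams(points=4096, ppm_range=(2.0, 5.0))
        with pytest.raises(ValueError, match="does not cover"):
            pm.synthesize_spectrum({"tyrosine": 1.0}, 17.0, assignments, params)


class TestReferenceScan:
    def test_lactate_ch_window_area(self, assignments):
        # wide window captures essentially the whole line
        params = pm.SpectrumSynthParams()
        ref = pm.synthesize_reference_scan(params, assignments=assignments)
        area = integrate_peak(ref, 4.13, halfwidth=0.15, baseline="none")
        assert area == pytest.approx(params.response_factor * 3000.0, rel=0.005)

    def test_methyl_to_methine_proton_ratio(self, assignments, reference_scan):
        ch = integrate_peak(reference_scan.spectrum, 4.13, baseline="none")
        ch3 = integrate_peak(reference_scan.spectrum, 1.33, baseline="none")
        assert ch3 == pytest.approx(3 * ch, rel=0.01)

    def test_noise_perturbs_window_integrals_boundedly(self, assignments):
        quiet = pm.SpectrumSynthParams(points=65536)
        noisy = pm.SpectrumSynthParams(points=65536, noise_sd=2.0)
        r0 = pm.synthesize_reference_scan(quiet, assignments=assignments)
        r1 = pm.synthesize_reference_scan(noisy, assignments=assignments, seed=9)
        for center in (4.13, 1.33):
            a0 = integrate_peak(r0, center, baseline="none")
            a1 = integrate_peak(r1, center, baseline="none")
            assert abs(a1 - a0) < 5 * 2.0 * 0.008  # 5 noise_sd x window width


class TestSurvival:
    def _meta(self, n, group):
        return [
            pm.SampleMetadata(f"{group}{i}", "PA", False, group) for i in range(n)
        ]

    def test_zero_censoring_gives_all_events(self):
        params = pm.SurvivalSimParams(groups={"unknown": (24.0, 0.0)})
        out = pm.simulate_survival(self._meta(50, "unknown"), params, seed=0)
        assert all(m.event for m in out)

    def test_exponential_median_closed_form(self):
        params = pm.SurvivalSimParams(groups={"unknown": (24.0, 0.1)})
        out = pm.simulate_survival(self._meta(20000, "unknown"), params, seed=1)
        times = np.array([m.survival_time_months for m in out])
        median = np.median(times)
        # asymptotic SE of the sample median of an exponential
        se = 24.0 / np.sqrt(20000)
        assert abs(median - 24.0 * np.log(2)) < 3 * se

    def test_same_seed_identical(self):
        meta = self._meta(20, "unknown")
        a = pm.simulate_survival(meta, seed=4)
        b = pm.simulate_survival(meta, seed=4)
        assert a == b

    def test_labelled_groups_respect_their_windows(self):
        out = pm.simulate_survival(
            self._meta(200, "long") + self._meta(200, "short"), seed=2
        )
        for m in out:
            if m.survival_group == "long":
                assert m.survival_time_months > 36
            else:
                assert m.survival_time_months < 12
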