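import math
from dataclasses import replace

import numpy as np
import pytest

from amykin.binding import classify_pre
from amykin.synthetic import (
    AggregationModel,
    AssayDesign,
    ExchangeModel,
    PREGroundTruth,
    default_aggregation_model,
    default_exchange_model,
    generate_tht_assay,
    simulate_aggregation,
    simulate_bli,
    simulate_pre_profile,
    simulate_titration,
    titration_csp_table,
)

T = np.arange(0.0, 48.0, 0.1)


class TestSimulateAggregation:
    def test_no_nucleation_source_stays_flat(self):
        m = AggregationModel(kn=0.0, k2=0.0, P0=0.0, M0=0.0)
        assert np.allclose(simulate_aggregation(m, T), 0.0, atol=1e-9)

    def test_seeded_pure_elongation_initial_slope(self):
        # dM/dt|0 = 2*kplus*m_tot*P0 when M0 << m_tot and no nucleation
        m = AggregationModel(kn=0.0, k2=0.0, P0=1e-4, M0=1e-3, kplus=25.0)
        t = np.arange(0.0, 0.201, 0.001)
        M = simulate_aggregation(m, t, raw=True)
        slope = (M[1] - M[0]) / (t[1] - t[0])
        assert slope == pytest.approx(2 * m.kplus * m.m_tot * m.P0, rel=1e-3)

    def test_half_end_occupancy_equals_half_elongation_rate(self):
        """c_inh = Kend with surface/plateau action off is exactly kplus/2."""
        big = 1e12
        inhibited = AggregationModel(c_inh=0.12, Kend=0.12, Ksurf=big, K_plat=big)
        halved = AggregationModel(c_inh=0.0, kplus=inhibited.kplus / 2.0)
        Ma = simulate_aggregation(inhibited, T, raw=True)
        Mb = simulate_aggregation(halved, T, raw=True)
        assert np.allclose(Ma, Mb, rtol=1e-5, atol=1e-7)

    def test_monomer_conservation_over_parameter_grid(self):
        """|m + M_raw - m_tot| < 1e-6 m_tot across a 5x5 (kplus, k2) grid."""
        t = np.arange(0.0, 48.0, 0.5)
        for kplus in np.geomspace(5, 100, 5):
            for k2 in np.geomspace(1e-4, 1e-2, 5):
                m = AggregationModel(kplus=float(kplus), k2=float(k2))
                M = simulate_aggregation(m, t, raw=True)
                mono = m.m_tot - M
                assert np.all(np.abs(mono + M - m.m_tot) < 1e-6 * m.m_tot)
                # non-decreasing up to solver tolerance at the plateau
                assert np.all(np.diff(M) >= -1e-7 * m.m_tot)
                assert np.all(M <= m.m_tot + 1e-9)

    def test_final_mass_monotone_in_inhibitor(self):
        finals, halves = [], []
        for c in [0.0, 0.01, 0.1, 0.5, 1.0, 5.0]:
            M = simulate_aggregation(AggregationModel(c_inh=c), T)
            finals.append(M[-1])
            halves.append(T[np.searchsorted(M, M[-1] / 2)])
        assert np.all(np.diff(finals) <= 1e-9)          # non-increasing
        assert np.all(np.diff(halves) >= -1e-9)         # non-decreasing

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            AggregationModel(M0=10.0, m_tot=5.0)
        with pytest.raises(ValueError):
            AggregationModel(nc=0)
        with pytest.raises(ValueError):
            AggregationModel(kplus=-1.0)


class TestGenerateThTAssay:
    def test_noise_free_replicates_identical(self):
        design = AssayDesign(n_ratios=2, n_replicates=3, noise_sd=0.0,
                             lag_jitter_sd=0.0, t_grid=np.arange(0, 24, 0.2))
        data = generate_tht_assay(default_aggregation_model(), design)
        for ratio in data.ratios():
            group = data.by_ratio(ratio)
            for c in group[1:]:
                assert np.array_equal(c.y, group[0].y)

    def test_control_plus_ten_ratios_gives_eleven_conditions(self):
        design = AssayDesign(n_ratios=10, include_control=True,
                             t_grid=np.arange(0, 24, 0.2))
        data = generate_tht_assay(default_aggregation_model(), design)
        assert len(data.ratios()) == 11
        assert len(data) == 33

    def test_same_seed_bit_identical(self):
        design = AssayDesign(n_ratios=3, rng_seed=42,
                             t_grid=np.arange(0, 24, 0.2))
        a = generate_tht_assay(default_aggregation_model(), design)
        b = generate_tht_assay(default_aggregation_model(), design)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.y, cb.y)

    def test_short_time_grid_refused(self):
        design = AssayDesign(t_grid=np.arange(0, 5.9, 0.1))
        with pytest.raises(ValueError, match="60"):
            generate_tht_assay(default_aggregation_model(), design)

    def test_seeded_modes_add_seed_mass(self):
        design = AssayDesign(n_ratios=2, n_replicates=1, noise_sd=0.0,
                             lag_jitter_sd=0.0, seed_mode="sonicated",
                             t_grid=np.arange(0, 24, 0.2))
        data = generate_tht_assay(default_aggregation_model(), design)
        y0 = data.curves[0].y[0]
        # initial fluorescence reflects the 8.5% seed mass
        expected = design.gain * design.seed_fraction * 5.0 + design.baseline
        assert y0 == pytest.approx(expected, rel=0.05)


class TestSimulateTitration:
    def test_zero_ratio_peaks_at_free_shifts(self, exchange_model):
        series = simulate_titration(exchange_model, [0.0])
        for peak in series.points[0].peaks:
            hf, xf = exchange_model.delta_free[peak.residue_id]
            assert peak.shift_H == pytest.approx(hf)
            assert peak.shift_X == pytest.approx(xf)

    def test_saturation_limit_reaches_bound_shifts(self, exchange_model):
        series = simulate_titration(exchange_model, [1e6])
        pt = series.points[0]
        assert pt.p_bound == pytest.approx(1.0, abs=1e-4)
        for peak in pt.peaks:
            hb, xb = exchange_model.delta_bound[peak.residue_id]
            assert peak.shift_H == pytest.approx(hb, abs=1e-4)

    def test_equal_concentrations_closed_form_bound_fraction(self):
        # P0 = L0 = KD: p_b = (3 - sqrt(5)) / 2
        model = default_exchange_model(KD=61.0, L0=61.0)
        series = simulate_titration(model, [1.0])
        assert series.points[0].p_bound == pytest.approx(
            (3.0 - math.sqrt(5.0)) / 2.0, rel=1e-12
        )
        # shifts verified against the hand-evaluated affine interpolation
        pb = (3.0 - math.sqrt(5.0)) / 2.0
        peak = series.points[0].peaks[0]
        hf, _ = model.delta_free[peak.residue_id]
        hb, _ = model.delta_bound[peak.residue_id]
        assert peak.shift_H == pytest.approx(hf + pb * (hb - hf), rel=1e-12)

    def test_intensity_decreases_with_binding(self, exchange_model):
        series = simulate_titration(exchange_model, [0.0, 0.5, 1.0, 2.0])
        intensities = [pt.peaks[0].intensity for pt in series.points]
        assert np.all(np.diff(intensities) < 0)

    def test_negative_ratio_rejected(self, exchange_model):
        with pytest.raises(ValueError):
            simulate_titration(exchange_model, [-0.1])

    def test_csp_table_requires_apo_first(self, exchange_model):
        series = simulate_titration(exchange_model, [0.5, 1.0])
        with pytest.raises(ValueError, match="apo"):
            titration_csp_table(series)


class TestSimulatePRE:
    def test_noiseless_active_ratio_is_one_minus_loss(self):
        truth = PREGroundTruth(active_residues={"alpha": frozenset({5})},
                               loss_active=0.8)
        out = simulate_pre_profile(truth, {"alpha": [5, 6]})
        dia, para = out["alpha"]
        ratios = {p.residue_id: q.intensity / p.intensity
                  for p, q in zip(dia, para)}
        assert ratios[5] == pytest.approx(0.2)
        assert ratios[6] == pytest.approx(0.9)

    def test_empty_active_set_all_ratios_above_half(self):
        truth = PREGroundTruth(active_residues={}, loss_inactive=0.1)
        out = simulate_pre_profile(truth, {"beta": list(range(1, 20))})
        dia, para = out["beta"]
        assert all(q.intensity / p.intensity > 0.5 for p, q in zip(dia, para))

    def test_fifty_percent_rule_round_trip(self):
        """classify_pre on noiseless output recovers the truth exactly."""
        active = frozenset({3, 7, 11})
        truth = PREGroundTruth(active_residues={"alpha": active})
        dia, para = simulate_pre_profile(truth, {"alpha": list(range(1, 15))})["alpha"]
        profiles = classify_pre(dia, para)
        assert {p.residue_id for p in profiles if p.pre_active} == set(active)

    def test_invariant_violation_rejected(self):
        with pytest.raises(ValueError, match="50"):
            PREGroundTruth(active_residues={}, loss_active=0.4)

    def test_duplicate_residues_rejected(self):
        truth = PREGroundTruth(active_residues={})
        with pytest.raises(ValueError, match="duplicate"):
            simulate_pre_profile(truth, {"alpha": [1, 1, 2]})


class TestSimulateBLI:
    def test_midpoint_of_langmuir(self):
        df = simulate_bli(KD=11.0, Rmax=2.0, concs=[11.0])
        assert df["response"].iloc[0] == pytest.approx(1.0)

    def test_low_concentration_limit(self):
        df = simulate_bli(KD=11.0, Rmax=2.0, concs=[1e-6])
        assert df["response"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_non_positive_concentration_rejected(self):
        with pytest.raises(ValueError):
            simulate_bli(KD=11.0, Rmax=1.0, concs=[0.0, 1.0])
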