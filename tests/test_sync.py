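import numpy as np
import pytest

import ita
from ita.sync import delta_series


class TestTemporalCorrelation:
    def test_affine_relation_gives_unit_correlation(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        assert ita.temporal_correlation(x, 2 * x + 1) == pytest.approx(1.0)

    def test_negated_series_gives_minus_one(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        assert ita.temporal_correlation(x, -x) == pytest.approx(-1.0)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ita.temporal_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_independent_series_average_near_zero(self):
        rng = np.random.default_rng(0)
        rs = [
            ita.temporal_correlation(rng.normal(size=18), rng.normal(size=18))
            for _ in range(1000)
        ]
        assert abs(np.mean(rs)) < 0.02


class TestSelfFlux:
    def test_affine_series_has_zero_flux(self):
        cm = ita.CMSeries(cm=2.0 + 0.5 * np.arange(6), gene_set_label="GA")
        assert np.allclose(ita.self_flux(cm).values, 0.0)

    def test_1_2_4_gives_minus_one_at_interior(self):
        fx = ita.self_flux(ita.CMSeries(cm=np.array([1.0, 2.0, 4.0])))
        assert fx.values.tolist() == [-1.0]

    def test_constant_series_zero(self):
        fx = ita.self_flux(ita.CMSeries(cm=np.full(5, 3.3)))
        assert np.allclose(fx.values, 0.0)

    def test_lengths(self):
        t = np.array([0.0, 10, 15, 20, 30])
        fx = ita.self_flux(ita.CMSeries(cm=np.arange(5.0) ** 2), t)
        assert fx.values.size == 3 and np.array_equal(fx.time_points_min, t[1:-1])
        ds = delta_series(np.arange(5.0), t)
        assert ds.values.size == 4 and np.array_equal(ds.time_points_min, t[1:])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ita.self_flux(ita.CMSeries(cm=np.array([1.0, 2.0])))


def _tables(t, s_cp, s_pes, s_wes, s_joint, mi):
    et = ita.EntropyTable(
        time_points_min=t,
        s={"CP": s_cp, "PES": s_pes, "WES": s_wes},
        s_low={}, run_s_high={}, run_s_low={}, converged={}, conv_diff={},
        n_bins=30,
    )
    mt = ita.MITable(
        time_points_min=t, s_joint=s_joint, mi=mi,
        s_joint_low=s_joint, mi_low=mi,
        run_s_joint=s_joint[None, :], run_mi=mi[None, :],
    )
    return et, ita.derived_mi(et, mt)


class TestSyncReport:
    def test_constructed_offset_recovered_exactly(self):
        t = np.arange(5.0)
        s_cp = np.array([3.0, 3.1, 3.05, 3.2, 3.15])
        s_pes = np.array([3.3, 3.35, 3.3, 3.4, 3.38])
        mi = np.full(5, 0.2)
        # choose S(WES) so that I_net = S(CP) + 0.01 exactly
        s_wes = s_pes - 0.01
        s_joint = np.array([6.1, 6.2, 6.15, 6.3, 6.25])
        et, mt = _tables(t, s_cp, s_pes, s_wes, s_joint, mi)
        rep = ita.sync_report(et, mt)
        assert rep.offset_mean == pytest.approx(0.01, abs=1e-12)
        assert rep.r_scp_inet == pytest.approx(1.0)

    def test_offset_identity(self, hrg_metrics):
        et, mt = hrg_metrics
        rep = ita.sync_report(et, mt)
        assert rep.offset_mean == pytest.approx(
            mt.i_net.mean() - et.s["CP"].mean(), abs=1e-12
        )
        assert -1 <= rep.r_scp_inet <= 1
        assert -1 <= rep.r_spes_mi <= 1

    def test_strong_cp_synchronization_on_synthetic(self, hrg_metrics):
        # I_net = S(CP) + (S(PES) - S(WES)) tracks S(CP) tightly
        rep = ita.sync_report(*hrg_metrics)
        assert rep.r_scp_inet > 0.95
        assert rep.offset_mean > 0  # positive higher-order contribution

    def test_constant_ihigh_reported_missing(self):
        t = np.arange(4.0)
        s_cp = np.array([3.0, 3.1, 3.2, 3.3])
        s_pes = np.array([3.2, 3.2, 3.2, 3.2])
        mi = s_cp + s_pes - (s_cp + 3.2)  # makes I_high exactly 0
        et, mt = _tables(t, s_cp, s_pes, s_cp + 3.2 - 0.0, np.full(4, 6.0), mi)
        assert np.allclose(mt.i_high, 0.0)
        with pytest.warns(UserWarning, match="constant"):
            rep = ita.sync_report(et, mt)
        assert np.isnan(rep.r_sjoint_ihigh)


class TestConcurrence:
    def test_identical_fluxes_fully_correlated(self):
        t = np.arange(8.0)
        rng = np.random.default_rng(0)
        cm = ita.CMSeries(cm=rng.normal(size=8), gene_set_label="CP")
        fx = ita.self_flux(cm, t)
        ds = delta_series(rng.normal(size=8), t)
        tab = ita.concurrence(fx, fx, ds, n_shuffles=49)
        row = tab[tab["pair"] == "flux_cp~flux_ga"].iloc[0]
        assert row["r"] == pytest.approx(1.0)

    def test_constant_series_missing_with_warning(self):
        t = np.arange(8.0)
        rng = np.random.default_rng(1)
        fx = ita.self_flux(ita.CMSeries(cm=rng.normal(size=8)), t)
        flat = ita.FluxSeries(values=np.zeros(6), time_points_min=t[1:-1])
        ds = delta_series(rng.normal(size=8), t)
        with pytest.warns(UserWarning, match="constant"):
            tab = ita.concurrence(fx, flat, ds, n_shuffles=19)
        assert np.isnan(tab[tab["pair"] == "flux_cp~flux_ga"]["r"].iloc[0])

    def test_empty_overlap_rejected(self):
        a = ita.FluxSeries(values=np.arange(3.0), time_points_min=np.arange(3.0))
        b = ita.FluxSeries(values=np.arange(3.0), time_points_min=np.arange(3.0) + 10)
        with pytest.raises(ValueError, match="common"):
            ita.concurrence(a, b, a)

    def test_synthetic_flux_entropy_synchrony_beats_null(self, hrg_data, hrg_metrics):
        _, m, _ = hrg_data
        et, _ = hrg_metrics
        # CP flux from the CP CM of the shared dataset
        v = ita.compute_rmsf(m)
        part_genes = [g for g, ln in zip(m.gene_ids, v.ln_nrmsf) if -2.6 < ln < -2.4]
        cm_cp = ita.center_of_mass(m, part_genes, label="CP")
        cm_ga = ita.center_of_mass(m, label="GA")
        fx_cp = ita.self_flux(cm_cp, m.time_points_min)
        fx_ga = ita.self_flux(cm_ga, m.time_points_min)
        ds = delta_series(et.s["CP"], m.time_points_min)
        tab = ita.concurrence(fx_cp, fx_ga, ds, n_shuffles=199, seed=0)
        row = tab[tab["pair"] == "flux_cp~ds_cp"].iloc[0]
        assert row["p_perm"] < 0.05

    def test_permutation_p_uniformish_under_null(self):
        rng = np.random.default_rng(2)
        t = np.arange(12.0)
        ps = []
        for i in range(60):
            a = ita.FluxSeries(values=rng.normal(size=10), time_points_min=t[1:-1])
            b = ita.FluxSeries(values=rng.normal(size=10), time_points_min=t[1:-1])
            ds = delta_series(rng.normal(size=11), t[1:])
            tab = ita.concurrence(a, b, ds, n_shuffles=39, seed=i)
            ps.append(tab["p_perm"].iloc[0])
        assert 0.3 < np.mean(ps) < 0.7


class TestEntropyProduction:
    def test_isolated_change_is_pure_production(self):
        led = ita.entropy_production(0.5)
        assert led.sigma == 0.5 and not led.second_law_violated

    def test_balanced_exchange_gives_zero(self):
        led = ita.entropy_production(0.0, q=0.2 * 310.15, matter=-0.2)
        assert led.sigma == pytest.approx(0.0)
        assert not led.second_law_violated

    def test_negative_sigma_flagged(self):
        led = ita.entropy_production(0.0, q=0.3 * 310.15, matter=0.0)
        assert led.sigma == pytest.approx(-0.3)
        assert led.second_law_violated

    def test_default_temperature_is_cell_culture(self):
        assert ita.entropy_production(0.1).t_kelvin == pytest.approx(310.15)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            ita.entropy_production(0.1, t_kelvin=0.0)
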