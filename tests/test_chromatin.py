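import numpy as np
import pytest

import ita
from ita.variability import VariabilityTable

FAST = ita.BootstrapConfig(
    sample_size=300, n_bins=20, iters_entropy=(20, 60), iters_mi=(5, 10),
    n_runs=2, seed=4,
)


def _vt_with_labels(gene_ids, ln_nrmsf):
    ln = np.asarray(ln_nrmsf, dtype=float)
    return VariabilityTable(
        gene_ids=tuple(gene_ids),
        rmsf=np.exp(ln),
        nrmsf=np.exp(ln),
        ln_nrmsf=ln,
        sort_order=np.argsort(-ln),
    )


class TestDecomposition:
    def test_single_bin_carries_all_entropy(self):
        rng = np.random.default_rng(0)
        logx = rng.normal(0, 1, size=(200, 3))
        m = ita.ExpressionMatrix(
            gene_ids=tuple(f"g{i}" for i in range(200)),
            time_points_min=np.arange(3.0),
            values=np.exp(logx),
        )
        v = _vt_with_labels(m.gene_ids, np.full(200, -2.0))  # one shared bin
        em = ita.entropy_decomposition(m, v, FAST, n_nrmsf_bins=10,
                                       full_population=True)
        nonzero = np.abs(em.contributions).sum(axis=1) > 0
        assert nonzero.sum() == 1
        assert np.allclose(em.contributions.sum(axis=0), em.s_wes)

    def test_conservation_at_every_time_point(self, hrg_data):
        _, m, _ = hrg_data
        v = ita.compute_rmsf(m)
        em = ita.entropy_decomposition(m, v, FAST, n_nrmsf_bins=40)
        assert np.abs(em.contributions.sum(axis=0) - em.s_wes).max() < 1e-9

    def test_identical_strata_share_contributions(self):
        """Two equal strata with the same expression distribution but
        different ln(nrmsf) labels receive equal contributions."""
        rng = np.random.default_rng(1)
        logx = rng.normal(0, 1, size=(400, 3))
        m = ita.ExpressionMatrix(
            gene_ids=tuple(f"g{i}" for i in range(400)),
            time_points_min=np.arange(3.0),
            values=np.exp(logx),
        )
        ln = np.where(np.arange(400) < 200, -1.0, -3.0)
        v = _vt_with_labels(m.gene_ids, ln)
        em = ita.entropy_decomposition(m, v, FAST, n_nrmsf_bins=8)
        per_bin = em.contributions.sum(axis=1)
        hi, lo = per_bin[per_bin > 0]
        assert hi == pytest.approx(lo, rel=0.10)

    def test_seed_determinism(self, hrg_data):
        _, m, _ = hrg_data
        v = ita.compute_rmsf(m)
        a = ita.entropy_decomposition(m, v, FAST, n_nrmsf_bins=20)
        b = ita.entropy_decomposition(m, v, FAST, n_nrmsf_bins=20)
        assert np.array_equal(a.contributions, b.contributions)

    def test_literal_contributions_overcount(self):
        rng = np.random.default_rng(2)
        logx = rng.normal(0, 1, size=(300, 3))
        m = ita.ExpressionMatrix(
            gene_ids=tuple(f"g{i}" for i in range(300)),
            time_points_min=np.arange(3.0),
            values=np.exp(logx),
        )
        v = _vt_with_labels(m.gene_ids, rng.uniform(-4, -1, 300))
        exact = ita.entropy_decomposition(m, v, FAST, n_nrmsf_bins=10,
                                          full_population=True)
        literal = ita.entropy_decomposition(m, v, FAST, n_nrmsf_bins=10,
                                            full_population=True,
                                            literal_contributions=True)
        # the literal per-gene term double-counts shared bins
        assert literal.contributions.sum(axis=0)[0] > exact.s_wes[0]


class TestDeltaMap:
    def test_identical_time_points_give_zero_delta(self):
        em = ita.EntropyMap(
            nrmsf_edges=np.linspace(-3, 0, 5),
            time_points_min=np.arange(3.0),
            contributions=np.tile(np.array([[0.5], [0.3], [0.2], [0.0]]), (1, 3)),
            s_wes=np.ones(3),
        )
        assert np.allclose(ita.delta_map(em).values, 0.0)

    def test_columns_telescope_to_wes_delta(self, hrg_data):
        _, m, _ = hrg_data
        v = ita.compute_rmsf(m)
        em = ita.entropy_decomposition(m, v, FAST, n_nrmsf_bins=30)
        dm = ita.delta_map(em)
        assert np.allclose(dm.values.sum(axis=0), np.diff(em.s_wes), atol=1e-12)

    def test_largest_change_at_planted_pulse(self, hrg_data):
        _, m, truth = hrg_data
        v = ita.compute_rmsf(m)
        em = ita.entropy_decomposition(m, v, FAST, n_nrmsf_bins=40)
        dm = ita.delta_map(em)
        j = int(np.argmax(np.abs(dm.values).sum(axis=0)))
        pulse_intervals = {
            j for j in range(dm.values.shape[1])
            if dm.interval_starts_min[j] in truth.pulse_times_min
            or dm.interval_ends_min[j] in truth.pulse_times_min
        }
        assert j in pulse_intervals

    def test_sign_labels(self):
        em = ita.EntropyMap(
            nrmsf_edges=np.linspace(-2, 0, 3),
            time_points_min=np.arange(3.0),
            contributions=np.array([[0.1, 0.3, 0.3], [0.5, 0.2, 0.2]]),
            s_wes=np.array([0.6, 0.5, 0.5]),
        )
        labels = ita.delta_map(em).sign_labels()
        assert labels[0, 0] == "unfolding" and labels[1, 0] == "folding"
        assert labels[0, 1] == ""


class TestBimodalFlags:
    def _dm(self, values):
        values = np.asarray(values, dtype=float)
        return ita.DeltaEntropyMap(
            nrmsf_edges=np.linspace(-4, 0, values.shape[0] + 1),
            interval_starts_min=np.arange(values.shape[1], dtype=float),
            interval_ends_min=np.arange(values.shape[1], dtype=float) + 1,
            values=values,
        )

    def test_zero_map_has_no_flags(self):
        dm = self._dm(np.zeros((20, 4)))
        assert not ita.flag_cp_bimodal(dm, (-2.5, -2.0)).any()

    def test_two_sided_excursion_is_flagged(self):
        vals = np.random.default_rng(0).normal(0, 0.01, size=(40, 2))
        dm = self._dm(vals)
        centers = dm.bin_centers
        win = np.flatnonzero((centers > -2.5) & (centers < -2.0))
        vals[win[0], 1] = 0.5
        vals[win[1], 1] = -0.5
        flags = ita.flag_cp_bimodal(self._dm(vals), (-2.5, -2.0), threshold_sd=2)
        assert not flags[0] and flags[1]

    def test_one_sided_excursion_not_flagged(self):
        vals = np.random.default_rng(1).normal(0, 0.01, size=(40, 1))
        dm = self._dm(vals)
        win = np.flatnonzero((dm.bin_centers > -2.5) & (dm.bin_centers < -2.0))
        vals[win[0], 0] = 0.5  # positive only
        assert not ita.flag_cp_bimodal(self._dm(vals), (-2.5, -2.0)).any()

    def test_window_narrower_than_bin_rejected(self):
        dm = self._dm(np.zeros((4, 2)))  # bin width 1.0
        with pytest.raises(ValueError, match="narrower"):
            ita.flag_cp_bimodal(dm, (-2.1, -2.05))


class TestTransitionPoint:
    def test_linear_interpolation_between_bins(self):
        tp, crossings = ita.transition_point([1.0, -1.0], [-3.2, -3.0])
        assert tp == pytest.approx(-3.1)
        assert crossings == [pytest.approx(-3.1)]

    def test_all_positive_profile_has_no_crossing(self):
        tp, crossings = ita.transition_point([0.2, 0.5, 0.1], [-3.0, -2.5, -2.0])
        assert tp is None and crossings == []

    def test_planted_crossing_recovered_within_bin_width(self):
        centers = np.linspace(-4.0, -2.0, 41)  # bin width 0.05
        profile = -(centers + 3.05) + np.random.default_rng(0).normal(0, 0.01, 41)
        tp, _ = ita.transition_point(profile, centers)
        assert tp == pytest.approx(-3.05, abs=0.05)

    def test_principal_crossing_is_largest_magnitude_pair(self):
        profile = [0.05, -0.05, 0.8, -0.8]
        centers = [-4.0, -3.5, -3.0, -2.5]
        tp, crossings = ita.transition_point(profile, centers)
        assert len(crossings) == 3
        assert tp == pytest.approx(-2.75)
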