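import numpy as np
import pandas as pd
import pytest

from lncfunnel.mea import (
    SpikeRaster,
    compute_well_metrics,
    detect_bursts,
    detect_network_bursts,
    detect_spikes,
    mean_firing_rate,
    neural_activity_score,
    synchrony_index,
)
from lncfunnel.synthetic import gen_spike_raster


def _raster(spikes, duration=60.0):
    return SpikeRaster(list(spikes), {e: np.asarray(t, float) for e, t in spikes.items()}, duration)


class TestDetectSpikes:
    def test_flat_trace_yields_no_spikes(self):
        raster = detect_spikes({"e": np.zeros(5000)}, fs=10_000)
        assert raster.spikes["e"].size == 0

    def test_three_injected_deflections_detected(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 20_000)
        for idx in (3000, 9000, 15_000):
            v[idx] += 20
        raster = detect_spikes({"e": v}, fs=10_000)
        np.testing.assert_allclose(raster.spikes["e"], [0.3, 0.9, 1.5])

    def test_exact_six_sigma_is_not_a_spike(self):
        # alternating +/-1 trace: median 0, MAD 1, sigma = 1/0.6745
        v = np.tile([1.0, -1.0], 500)
        sigma = 1.0 / 0.6745
        v_boundary = v.copy()
        v_boundary[0] = 6 * sigma
        assert detect_spikes({"e": v_boundary}, fs=1000).spikes["e"].size == 0
        v_above = v.copy()
        v_above[0] = 6 * sigma + 1e-6
        assert detect_spikes({"e": v_above}, fs=1000).spikes["e"].size == 1

    def test_refractory_window_collapses_to_peak(self):
        v = np.tile([1.0, -1.0], 500)
        v[100], v[101], v[102] = 50.0, 80.0, 60.0
        (t,) = detect_spikes({"e": v}, fs=1000).spikes["e"]
        assert t == pytest.approx(0.101)

    def test_invalid_fs_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes({"e": np.zeros(10)}, fs=0)


class TestFiringRate:
    def test_one_hz(self):
        r = _raster({"e": np.arange(0.5, 900, 1.0)}, duration=900)
        rates, well = mean_firing_rate(r)
        assert rates["e"] == pytest.approx(1.0)
        assert well == pytest.approx(1.0)

    def test_empty_raster_zero(self):
        r = _raster({"e": []}, duration=10)
        assert mean_firing_rate(r)[1] == 0.0

    def test_silent_electrodes_count_in_well_mean(self):
        spikes = {f"e{i}": [] for i in range(16)}
        spikes["e0"] = np.linspace(1, 899, 150)
        r = _raster(spikes, duration=900)
        _, well = mean_firing_rate(r)
        assert well == pytest.approx(150 / 900 / 16)


class TestBursts:
    def test_five_spikes_at_definition(self):
        (b,) = detect_bursts([0, 0.05, 0.10, 0.15, 0.20])
        assert (b.start, b.end, b.n_spikes) == (0, 0.20, 5)

    def test_four_spikes_is_not_a_burst(self):
        assert detect_bursts([0, 0.05, 0.10, 0.15]) == []

    def test_broken_run_keeps_only_qualifying_tail(self):
        bursts = detect_bursts([0, 0.05, 0.10, 0.25, 0.30, 0.35, 0.40, 0.45])
        assert [(b.start, b.n_spikes) for b in bursts] == [(0.25, 5)]

    def test_isi_boundary_inclusive(self):
        # ISIs exactly at the cutoff (0.125 is exactly representable)
        train = np.arange(5) * 0.125
        (b,) = detect_bursts(train, isi_max=0.125)
        assert b.n_spikes == 5
        assert detect_bursts(train, isi_max=0.124) == []

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            detect_bursts([0.5, 0.1])

    def test_equals_brute_force_run_enumeration(self):
        def oracle(train, min_spikes=5, isi_max=0.1):
            """All maximal qualifying runs by direct enumeration."""
            out = []
            for i in range(len(train)):
                for j in range(i + min_spikes - 1, len(train)):
                    window = train[i : j + 1]
                    if all(
                        b - a <= isi_max for a, b in zip(window, window[1:])
                    ):
                        maximal = (i == 0 or train[i] - train[i - 1] > isi_max) and (
                            j == len(train) - 1 or train[j + 1] - train[j] > isi_max
                        )
                        if maximal:
                            out.append((train[i], train[j], j - i + 1))
            return sorted(set(out))

        rng = np.random.default_rng(77)
        for _ in range(30):
            n = int(rng.integers(0, 50))
            train = np.sort(rng.uniform(0, 3, size=n))
            train = np.unique(train)
            got = [(b.start, b.end, b.n_spikes) for b in detect_bursts(train)]
            assert sorted(got) == oracle(list(train))


class TestNetworkBursts:
    def _with_cluster(self, n_electrodes=16, cluster_electrodes=6, n_spikes=60):
        # background: 5 well-separated spikes per electrode keeps everyone
        # active without pooled ISIs under 100 ms
        spikes = {
            f"e{i:02d}": list(10 + (i * 5 + np.arange(5)) * 0.55)
            for i in range(n_electrodes)
        }
        cluster = 1.0 + np.arange(n_spikes) * 0.01
        for k, t in enumerate(cluster):
            spikes[f"e{k % cluster_electrodes:02d}"].append(t)
        return _raster({e: np.sort(v) for e, v in spikes.items()}, duration=60)

    def test_cluster_over_six_of_sixteen_detected(self):
        (nb,) = detect_network_bursts(self._with_cluster())
        assert nb.n_spikes == 60
        assert len(nb.participating) == 6  # 37.5% > 35%

    def test_participation_boundary_five_of_sixteen_rejected(self):
        assert detect_network_bursts(self._with_cluster(cluster_electrodes=5)) == []

    def test_forty_nine_spikes_rejected(self):
        assert detect_network_bursts(self._with_cluster(n_spikes=49)) == []

    def test_planted_network_bursts_counted_exactly(self):
        raster = gen_spike_raster(
            n_electrodes=16, duration=900, base_rate=0.2,
            network_spec=(4, 7, 80), seed=5,
        )
        assert len(detect_network_bursts(raster)) == 4

    def test_no_active_electrodes_returns_empty(self):
        r = _raster({f"e{i}": [] for i in range(4)}, duration=60)
        assert detect_network_bursts(r) == []


class TestSynchrony:
    def test_identical_periodic_trains_give_one(self):
        t = np.arange(0.5, 900, 1.0)
        r = _raster({"a": t, "b": t.copy()}, duration=900)
        assert synchrony_index(r) == pytest.approx(1.0)

    def test_independent_poisson_near_uniform_floor(self):
        r = gen_spike_raster(n_electrodes=2, duration=900, base_rate=2.0, seed=19)
        assert synchrony_index(r) == pytest.approx(0.02, abs=0.01)

    def test_single_spiking_electrode_rejected(self):
        r = _raster({"a": [1.0, 2.0], "b": []}, duration=10)
        with pytest.raises(ValueError):
            synchrony_index(r)

    def test_relabeling_and_time_shift_invariance(self):
        rng = np.random.default_rng(2)
        a = np.sort(rng.uniform(0, 50, 80))
        b = np.sort(rng.uniform(0, 50, 70))
        r1 = _raster({"x": a, "y": b}, duration=100)
        r2 = _raster({"y": a + 10, "x": b + 10}, duration=100)
        assert synchrony_index(r1) == pytest.approx(synchrony_index(r2), abs=1e-12)


class TestNas:
    def _wells(self, varying):
        df = pd.DataFrame(
            {
                "mean_firing_rate": varying,
                "burst_frequency": [1.0] * len(varying),
                "network_burst_frequency": [0.1] * len(varying),
                "synchrony_index": [0.5] * len(varying),
                "active_fraction": [1.0] * len(varying),
            },
            index=[f"w{i}" for i in range(len(varying))],
        )
        return df

    def test_identical_wells_equal_nas(self):
        nas = neural_activity_score(self._wells([2.0, 2.0]))
        assert nas["w0"] == nas["w1"]

    def test_single_varying_metric_worked_example(self):
        nas = neural_activity_score(self._wells([0.0, 5.0, 10.0]))
        np.testing.assert_allclose(nas.values, [0.0, 0.1, 0.2])

    def test_maximal_well_scores_one(self):
        df = self._wells([0.0, 1.0])
        for c in df.columns:
            df.loc["w1", c] = df[c].max() + 1.0
        assert neural_activity_score(df)["w1"] == pytest.approx(1.0)

    def test_monotone_in_any_single_metric(self):
        rng = np.random.default_rng(12)
        base = pd.DataFrame(
            rng.uniform(0, 2, size=(4, 5)),
            columns=[
                "mean_firing_rate",
                "burst_frequency",
                "network_burst_frequency",
                "synchrony_index",
                "active_fraction",
            ],
        )
        nas0 = neural_activity_score(base)
        for col in base.columns:
            bumped = base.copy()
            bumped.loc[2, col] += 0.5
            assert neural_activity_score(bumped)[2] >= nas0[2] - 1e-12


class TestRasterIo:
    def test_csv_roundtrip(self, tmp_path):
        r = gen_spike_raster(n_electrodes=3, duration=20, base_rate=1.0, seed=1)
        p = tmp_path / "raster.csv"
        r.to_csv(p)
        back = SpikeRaster.from_csv(p)
        assert back.duration == r.duration
        for e in r.electrode_ids:
            if r.spikes[e].size:
                np.testing.assert_allclose(back.spikes[e], r.spikes[e], atol=1e-6)

    def test_well_metrics_fields_nonnegative(self):
        r = gen_spike_raster(
            n_electrodes=8, duration=120, base_rate=1.0,
            burst_spec=(3, 6, 0.02), seed=3,
        )
        m = compute_well_metrics(r)
        assert m.mean_firing_rate > 0
        assert m.burst_frequency >= 3 * 8 / 120 * 0.99
        assert 0 <= m.synchrony_index <= 1
        assert 0 <= m.active_fraction <= 1
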