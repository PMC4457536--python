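import numpy as np

import pytest

from cbcstim import cable, experiments as E, membrane as mb, protocols as P


def synthetic_ca_trace(t_end=30.0, dt=0.05, baseline=0.15, peak=1.0,
                       offset=5.0, tau=1.5):
    """Trace whose terminal calcium decays exponentially after `offset`."""
    t = np.arange(0.0, t_end + dt / 2, dt)
    ca = np.full_like(t, baseline)
    after = t >= offset
    ca[after] = baseline + (peak - baseline) * np.exp(-(t[after] - offset) / tau)
    return cable.Trace(t=t, vm=np.zeros((t.size, 1)), ca=ca[:, None],
                       i_ca=np.zeros((t.size, 1)),
                       terminal_ids=np.array([0]))


class TestCaDecayTime:
    def test_flat_trace_recovers_immediately(self):
        tr = synthetic_ca_trace(peak=0.15)
        decay, censored = E.ca_decay_time(tr, 5.0)
        assert decay == 0.0 and not censored

    def test_exponential_decay_crossing_matches_closed_form(self):
        tr = synthetic_ca_trace(peak=1.0, tau=1.5)
        decay, censored = E.ca_decay_time(tr, 5.0, rel_threshold=0.02)
        # (peak - b) exp(-t/tau) = rel * b  =>  t = tau ln((peak-b)/(rel b))
        expected = 1.5 * np.log(0.85 / (0.02 * 0.15))
        assert not censored
        assert decay == pytest.approx(expected, abs=0.1)

    def test_unrecovered_trace_is_censored(self):
        tr = synthetic_ca_trace(t_end=6.0, peak=3.0, offset=5.0, tau=50.0)
        decay, censored = E.ca_decay_time(tr, 5.0)
        assert censored and decay == pytest.approx(1.0, abs=0.1)

    def test_trace_without_terminals_rejected(self):
        tr = cable.Trace(t=np.arange(3.0), vm=np.zeros((3, 1)),
                         ca=np.zeros((3, 0)), i_ca=np.zeros((3, 0)),
                         terminal_ids=np.array([], dtype=int))
        with pytest.raises(ValueError):
            E.ca_decay_time(tr, 1.0)


class TestFrequencyResponse:
    def test_single_frequency_normalizes_to_one(self):
        df = E.frequency_response(mb.TTypeChannel(), freqs=[200.0],
                                  min_settle_ms=40.0)
        assert df["normalized"].iloc[0] == pytest.approx(1.0)

    def test_sweep_reports_all_frequencies_sorted(self):
        df = E.frequency_response(mb.LTypeChannel(), freqs=[100.0, 50.0],
                                  min_settle_ms=40.0)
        assert list(df["freq_hz"]) == [50.0, 100.0]
        assert (df["peak_inward_ua_cm2"] >= 0).all()


class TestStandardRun:
    def test_zero_drive_leaves_cell_at_rest(self, on_cell, field20):
        wf = P.monophasic(0.0, 1.0)
        res = E.run_standard(on_cell, field20, wf, t_end=3.0)
        assert np.allclose(res.summary["max_depolarization_mv"], 0.0,
                           atol=1e-9)
        assert res.summary["peak_terminal_ca_um"].iloc[0] == pytest.approx(
            0.15, abs=1e-9)

    def test_passive_flag_disables_channels(self, on_cell, field20,
                                            standard_pulse):
        res = E.run_standard(on_cell, field20, standard_pulse, active=False,
                             t_end=3.0)
        assert res.summary["peak_terminal_ca_um"].iloc[0] == pytest.approx(
            0.15, abs=1e-12)


class TestAxonSweep:
    def test_rows_and_consistency_with_standard_run(self, on_cell, field20,
                                                    standard_pulse):
        res = E.axon_length_sweep(on_cell, field20,
                                  factors=[1.0, 0.6, 0.2],
                                  waveform=standard_pulse)
        assert len(res.summary) == 3
        full = E.run_standard(on_cell, field20, standard_pulse, active=False)
        ref = full.summary.set_index("region").loc[
            "terminal", "max_depolarization_mv"]
        row = res.summary.set_index("factor").loc[1.0]
        assert row["terminal_depolarization_mv"] == pytest.approx(ref,
                                                                  rel=1e-9)

    def test_depolarization_weakens_with_shorter_axon(self, on_cell, field20,
                                                      standard_pulse):
        res = E.axon_length_sweep(on_cell, field20,
                                  factors=[1.0, 0.7, 0.4, 0.2],
                                  waveform=standard_pulse)
        depol = res.summary["terminal_depolarization_mv"].to_numpy()
        assert np.all(np.diff(depol) < 0)       # factors listed descending


class TestPositionMap:
    def test_degenerate_map_equals_standard_run(self, off_cell, field20):
        wf = P.monophasic(1.0, 0.5)
        pm = E.position_map(off_cell, field20, wf, x_range=(0.0, 0.0),
                            z_range=(0.0, 0.0), t_end=10.0)
        assert pm.peak_ca.shape == (1, 1)
        ref = E.run_standard(off_cell, field20, wf, t_end=10.0)
        assert pm.peak_ca[0, 0] == pytest.approx(
            ref.summary["peak_terminal_ca_um"].iloc[0], rel=1e-9)

    def test_grid_bookkeeping(self, off_cell, field20):
        wf = P.monophasic(1.0, 0.5)
        pm = E.position_map(off_cell, field20, wf, x_range=(-2.0, 2.0),
                            z_range=(0.0, 2.0), step=2.0, t_end=5.0)
        assert pm.peak_ca.shape == (2, 3)
        assert pm.n_positions == 6

    def test_default_grid_covers_816_positions(self):
        xs = np.arange(-47.0, 47.0 + 1.0, 2.0)
        zs = np.arange(0.0, 32.0 + 1.0, 2.0)
        assert len(xs) * len(zs) == 816


class TestChannelSwap:
    def test_same_channel_on_both_cells(self, field20):
        res = E.channel_swap(field20, mb.LTypeChannel(),
                             P.monophasic(1.0, 0.5))
        assert list(res.summary["cell_type"]) == ["ON_type9", "OFF_type3"]
        assert (res.summary["channel"] == "CaL").all()
        assert (res.summary["peak_terminal_ca_um"] > 0.15).all()


class TestBiphasicPhaseOrder:
    def test_phase_order_preference_differs_between_cell_types(
            self, on_cell, off_cell, field20):
        """The ON cell accumulates most calcium when the terminal-depolarizing
        phase trails (its fast-deactivating L-channel is loaded by the second
        phase and discharges on the return to rest); the OFF cell prefers the
        depolarizing phase first (its slowly deactivating T-channel stays open
        through the trailing phase)."""
        def peak_ca(cell, order):
            wf = P.biphasic(1.0, 1.0, 50.0, order)
            res = E.run_standard(cell, field20, wf, t_end=30.0)
            return float(res.summary["peak_terminal_ca_um"].iloc[0])

        # "anodic" order = depolarizing phase second (package convention)
        on_trail = peak_ca(on_cell, "anodic")
        on_lead = peak_ca(on_cell, "cathodic")
        off_lead = peak_ca(off_cell, "cathodic")
        off_trail = peak_ca(off_cell, "anodic")
        assert on_trail > on_lead
        assert off_lead > off_trail
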