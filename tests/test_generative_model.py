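import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dualroute.generative_model import (
    LeadField,
    SensorGeometry,
    SimulationError,
    StimulusInput,
    SourceTimeSeries,
    build_lead_field,
    default_geometry,
    default_params,
    project_to_sensors,
    read_timeseries_tsv,
    relative_sensitivity,
    simulate_sources,
    write_timeseries_tsv,
)

TIMES = np.arange(0.0, 251.0, 1.0)


def amy_onset_ms(series, frac=0.05):
    idx = [i for i, l in enumerate(series.node_labels) if l.startswith("AMY")]
    act = np.sqrt((series.values[idx] ** 2).mean(axis=0))
    above = np.where(act >= frac * act.max())[0]
    return series.times_ms[above[0]]


class TestDynamics:
    def test_rest_is_exact_fixed_point_over_one_second(self, cs_model):
        silent = StimulusInput(amplitude=0.0)
        out = simulate_sources(
            cs_model, default_params(cs_model), silent, np.arange(0.0, 1001.0, 1.0)
        )
        assert np.abs(out.values).max() == 0.0

    def test_step_halving_convergence_below_one_percent(self, cs_model):
        p, stim = default_params(cs_model), StimulusInput()
        coarse = simulate_sources(cs_model, p, stim, TIMES, dt_ms=1.0)
        fine = simulate_sources(cs_model, p, stim, TIMES, dt_ms=0.5)
        rel = np.sqrt(np.mean((coarse.values - fine.values) ** 2)) / np.sqrt(
            np.mean(fine.values**2)
        )
        assert rel < 0.01

    def test_subcortical_route_gives_earlier_amygdala_onset(
        self, cs_model, c_model
    ):
        """Across jittered parameter draws near the priors, amygdala activity
        onsets strictly earlier with the direct thalamic route than without."""
        rng = np.random.default_rng(42)
        stim = StimulusInput()
        for _ in range(20):
            p_cs, p_c = default_params(cs_model), default_params(c_model)
            jitter = {
                k: 0.125 * rng.standard_normal() for k in p_cs.log_gain
            }
            for k in p_cs.log_gain:
                p_cs.log_gain[k] += jitter[k]
            for k in p_c.log_gain:
                p_c.log_gain[k] += jitter[k]
            s_cs = simulate_sources(cs_model, p_cs, stim, TIMES)
            s_c = simulate_sources(c_model, p_c, stim, TIMES)
            assert amy_onset_ms(s_cs) < amy_onset_ms(s_c)

    def test_unstable_integration_names_node_and_time(self, cs_model):
        p = default_params(cs_model)
        for k in p.log_gain:
            p.log_gain[k] = 800.0  # exp overflows -> non-finite inflow
        with pytest.raises(SimulationError, match=r"node \w+.*t="):
            with np.errstate(over="ignore", invalid="ignore"):
                simulate_sources(cs_model, p, StimulusInput(), TIMES)

    def test_missing_connection_gain_rejected(self, cs_model):
        p = default_params(cs_model)
        p.log_gain.pop(next(iter(p.log_gain)))
        with pytest.raises(SimulationError, match="missing log_gain"):
            simulate_sources(cs_model, p, StimulusInput(), TIMES)


class TestStimulus:
    @given(
        peak=st.floats(5.0, 60.0),
        dispersion=st.floats(2.0, 30.0),
        amplitude=st.one_of(st.just(0.0), st.floats(1e-3, 10.0)),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_waveform_peaks_at_peak_ms(self, peak, dispersion, amplitude):
        stim = StimulusInput(
            peak_ms=peak, dispersion_ms=dispersion, amplitude=amplitude
        )
        t = np.linspace(0, 200, 4001)
        u = stim.waveform(t)
        assert np.all(u >= 0)
        assert u.max() == pytest.approx(amplitude, rel=1e-3, abs=1e-12)
        if amplitude > 0:
            assert t[np.argmax(u)] == pytest.approx(peak, abs=0.1)

    def test_invalid_stimulus_rejected(self):
        with pytest.raises(ValueError):
            StimulusInput(peak_ms=0.0)
        with pytest.raises(ValueError):
            StimulusInput(amplitude=-1.0)


def two_node_geometry(ecc_a, ecc_b):
    d = np.array([0.8, 0.3, 0.4])
    d = d / np.linalg.norm(d)
    o = np.cross([0, 0, 1.0], d)
    o /= np.linalg.norm(o)
    chans = default_geometry(["A1_L", "A1_R"]).channel_pos
    return SensorGeometry(
        channel_labels=tuple(f"c{i}" for i in range(len(chans))),
        channel_pos=chans,
        node_labels=("AMY_L", "AMY_R"),
        node_pos=np.array([ecc_a * d, ecc_b * d]),
        node_ecc=np.array([ecc_a, ecc_b]),
        node_ori=np.array([o, o]),
    )


class TestLeadField:
    def test_depth_attenuation_monotone_for_matched_orientation(self):
        lf = build_lead_field(
            two_node_geometry(0.9, 0.5), rng_seed=0, orientation_jitter_deg=0.0
        )
        norms = lf.column_norms()
        assert norms[0] > norms[1]

    def test_deterministic_under_seed(self, cs_model):
        geom = default_geometry(cs_model.labels)
        a = build_lead_field(geom, rng_seed=3)
        b = build_lead_field(geom, rng_seed=3)
        assert np.array_equal(a.gain, b.gain)
        c = build_lead_field(geom, rng_seed=4)
        assert not np.array_equal(a.gain, c.gain)

    def test_node_at_sphere_centre_rejected(self):
        geom = two_node_geometry(0.9, 0.5)
        geom.node_ecc[1] = 0.0
        with pytest.raises(ValueError, match="silent"):
            build_lead_field(geom)

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            LeadField(("c0", "c1"), ("AMY_L",), np.zeros((2, 1)))

    def test_packaged_sensitivity_ordering(self):
        labels = [
            f"{r}_{h}"
            for r in ("A1", "AMY", "HIPP", "STG")
            for h in ("L", "R")
        ]
        lf = build_lead_field(default_geometry(labels), rng_seed=0)
        hipp = relative_sensitivity(lf, "HIPP")
        amy = relative_sensitivity(lf, "AMY")
        stg = relative_sensitivity(lf, "STG")
        assert hipp < amy < 100.0 < stg
        assert relative_sensitivity(lf, "A1") == pytest.approx(100.0)

    def test_sensitivity_scale_invariant_and_checks_region(self):
        labels = ["A1_L", "A1_R", "AMY_L", "AMY_R"]
        lf = build_lead_field(default_geometry(labels), rng_seed=1)
        scaled = LeadField(
            lf.channel_labels, lf.node_labels, 7.3 * lf.gain, lf.node_regions
        )
        assert relative_sensitivity(lf, "AMY") == pytest.approx(
            relative_sensitivity(scaled, "AMY")
        )
        with pytest.raises(ValueError, match="not present"):
            relative_sensitivity(lf, "HIPP")


class TestProjection:
    def test_identity_lead_field_returns_sources(self):
        src = SourceTimeSeries(
            ("AMY_L", "AMY_R"), np.arange(3.0), np.arange(6.0).reshape(2, 3)
        )
        lf = LeadField(("c0", "c1"), ("AMY_L", "AMY_R"), np.eye(2))
        assert np.array_equal(project_to_sensors(src, lf), src.values)

    def test_linearity_and_zero(self, cs_model, small_cs_leadfield):
        rng = np.random.default_rng(0)
        t = np.arange(5.0)
        a = rng.standard_normal((6, 5))
        b = rng.standard_normal((6, 5))
        labels = small_cs_leadfield.node_labels
        pa = project_to_sensors(SourceTimeSeries(labels, t, a), small_cs_leadfield)
        pb = project_to_sensors(SourceTimeSeries(labels, t, b), small_cs_leadfield)
        pab = project_to_sensors(
            SourceTimeSeries(labels, t, a + b), small_cs_leadfield
        )
        assert np.allclose(pab, pa + pb)
        z = project_to_sensors(
            SourceTimeSeries(labels, t, np.zeros((6, 5))), small_cs_leadfield
        )
        assert np.all(z == 0)

    def test_label_mismatch_rejected(self, small_cs_leadfield):
        src = SourceTimeSeries(
            ("X_L", "X_R"), np.arange(3.0), np.zeros((2, 3))
        )
        with pytest.raises(ValueError, match="labels"):
            project_to_sensors(src, small_cs_leadfield)


def test_leadfield_tsv_json_round_trip(tmp_path, small_cs_leadfield):
    from dualroute.generative_model import read_leadfield, write_leadfield

    write_leadfield(small_cs_leadfield, tmp_path / "lf")
    back = read_leadfield(tmp_path / "lf")
    assert back.node_labels == small_cs_leadfield.node_labels
    assert back.node_regions == small_cs_leadfield.node_regions
    assert np.allclose(back.gain, small_cs_leadfield.gain, atol=1e-9)


def test_timeseries_tsv_round_trip(tmp_path):
    t = np.arange(0.0, 20.0, 4.0)
    vals = np.random.default_rng(1).standard_normal((3, t.size))
    path = tmp_path / "ts.tsv"
    write_timeseries_tsv(path, t, vals, ["a", "b", "c"])
    t2, v2, labels = read_timeseries_tsv(path)
    assert labels == ("a", "b", "c")
    assert np.allclose(t, t2) and np.allclose(vals, v2)
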