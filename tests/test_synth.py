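"""Synthetic session generator: schedule structure, Poisson spike
statistics, and rate-to-point-process heart generation."""

import numpy as np
import pytest
from scipy import stats

from conftest import small_config
from groomctx.errors import SchedulingError
from groomctx.session import Block
from groomctx.synth import (HeartSpec, SessionConfig, UnitSpec, demo_config,
                            generate_session, make_schedule, simulate_heart,
                            simulate_spike_train)


class TestSchedule:
    def test_airflow_block_has_110_events(self):
        blocks, events = make_schedule(demo_config(seed=1))
        for b in blocks:
            n = sum(e.block_id == b.block_id for e in events)
            if b.kind == "airflow":
                assert n == 110  # 11 locations x 10 repeats
            else:
                assert n == 100  # 2 locations x 10 sweeps x 5 sets

    def test_each_airflow_set_is_a_permutation_of_locations(self):
        _, events = make_schedule(demo_config(seed=2))
        first_block = [e for e in events if e.block_id == 0]
        for k in range(10):
            locs = sorted(e.location for e in first_block[k * 11:(k + 1) * 11])
            assert locs == list(range(1, 12))

    def test_grooming_durations_and_isis_within_bounds(self):
        _, events = make_schedule(demo_config(seed=3))
        sweeps = [e for e in events if e.modality == "grooming"]
        durs = [e.duration_ms for e in sweeps]
        assert min(durs) >= 1000 and max(durs) <= 2000
        gaps = [b.onset_ms - a.offset_ms for a, b in zip(sweeps, sweeps[1:])
                if a.block_id == b.block_id]
        assert min(gaps) >= 2000 and max(gaps) <= 4000

    def test_reward_after_each_airflow_set_and_each_grooming_block(self):
        blocks, _ = make_schedule(demo_config(seed=1))
        for b in blocks:
            assert len(b.reward_windows) == (10 if b.kind == "airflow" else 1)

    def test_same_seed_reproduces_schedule(self):
        a = make_schedule(demo_config(seed=9))
        b = make_schedule(demo_config(seed=9))
        assert a == b
        c = make_schedule(demo_config(seed=10))
        assert a[1] != c[1]

    def test_configured_duration_too_short_raises(self):
        cfg = demo_config(seed=1)
        cfg.block_durations_ms = [1000] * len(cfg.block_kinds)
        with pytest.raises(SchedulingError):
            make_schedule(cfg)

    def test_seed_is_mandatory(self):
        from groomctx.errors import SessionValidationError
        with pytest.raises(SessionValidationError):
            SessionConfig(seed=None).validate()


class TestSpikes:
    def test_zero_rates_give_empty_train(self):
        blocks = [Block(0, "airflow", 0, 10_000)]
        spec = UnitSpec("u", baseline_hz_by_context=0.0)
        train = simulate_spike_train(spec, blocks, [], seed=0)
        assert len(train) == 0

    def test_homogeneous_count_in_poisson_interval(self):
        """10 Hz for 100 s: count within the 99% Poisson interval of 1000."""
        blocks = [Block(0, "airflow", 0, 100_000)]
        spec = UnitSpec("u", baseline_hz_by_context=10.0)
        train = simulate_spike_train(spec, blocks, [], seed=42)
        lo, hi = stats.poisson.ppf([0.005, 0.995], 1000)
        assert lo <= len(train) <= hi

    def test_baseline_recovery_per_block_kind(self):
        cfg = small_config(seed=4)
        session = generate_session(cfg)
        u = session.unit("up0")
        spec = next(s for s in cfg.units if s.unit_id == "up0")
        for b in session.blocks:
            seg = u.spike_times_ms
            n = np.searchsorted(seg, b.end_ms) - np.searchsorted(seg, b.start_ms)
            dur_s = b.duration_ms / 1000.0
            lam = spec.baseline_hz_by_context[b.kind]
            se = np.sqrt(lam / dur_s)
            assert abs(n / dur_s - lam) < 3 * se + 0.1  # +0.1 for evoked-free slack

    def test_evoked_kernel_recovery_at_50_trials(self):
        """Transient (3x gain) then sustained (1x gain) windows recover the
        configured +10 Hz within 3 SE of the empirical mean."""
        blocks = [Block(0, "airflow", 0, 300_000)]
        from groomctx.session import StimulusEvent
        events = [StimulusEvent(i, 0, "airflow", 1, 5000 + 5000 * i,
                                6000 + 5000 * i) for i in range(50)]
        spec = UnitSpec("u", baseline_hz_by_context=5.0, evoked_gain_airflow=10.0)
        train = simulate_spike_train(spec, blocks, events, seed=7)
        t = train.spike_times_ms

        def win_rate(off0, off1):
            counts = [np.searchsorted(t, e.onset_ms + off1)
                      - np.searchsorted(t, e.onset_ms + off0) for e in events]
            rates = np.array(counts) * 1000.0 / (off1 - off0)
            return rates.mean(), rates.std(ddof=1) / np.sqrt(len(rates))

        m, se = win_rate(0, 100)       # transient: 5 + 30
        assert abs(m - 35.0) < 3 * se
        m, se = win_rate(100, 1000)    # sustained: 5 + 10
        assert abs(m - 15.0) < 3 * se

    def test_adding_a_unit_does_not_change_existing_spikes(self):
        cfg = small_config(seed=6)
        base = generate_session(cfg)
        cfg2 = small_config(seed=6)
        cfg2.units = cfg2.units + [UnitSpec("extra", baseline_hz_by_context=8.0)]
        bigger = generate_session(cfg2)
        for u in base.units:
            assert bigger.unit(u.unit_id) == u


class TestHeart:
    def test_constant_rate_gives_exact_ibis(self):
        blocks = [Block(0, "airflow", 0, 120_000)]
        spec = HeartSpec(mean_hr_by_context=100.0, rsa_depth_by_context=0.0)
        trace = simulate_heart(spec, blocks)
        ibis = np.diff(trace.r_wave_times_ms)
        assert np.all(np.abs(ibis - 600) <= 1)

    def test_block_mean_hr_within_2_bpm_at_5_min_blocks(self):
        blocks = [Block(0, "airflow", 0, 300_000),
                  Block(1, "grooming", 300_000, 600_000)]
        spec = HeartSpec(mean_hr_by_context={"airflow": 110.0, "grooming": 92.0,
                                             "airflow_groomer_present": 110.0},
                         rsa_depth_by_context=0.05)
        trace = simulate_heart(spec, blocks)
        t = trace.r_wave_times_ms
        for b, want in ((blocks[0], 110.0), (blocks[1], 92.0)):
            n = np.searchsorted(t, b.end_ms) - np.searchsorted(t, b.start_ms)
            bpm = n / (b.duration_ms / 60000.0)
            assert abs(bpm - want) < 2.0

    def test_mean_ibi_within_2pct_of_configured(self):
        blocks = [Block(0, "grooming", 0, 600_000)]
        spec = HeartSpec(mean_hr_by_context=80.0, rsa_depth_by_context=0.1)
        trace = simulate_heart(spec, blocks)
        mean_ibi = float(np.mean(np.diff(trace.r_wave_times_ms)))
        assert abs(mean_ibi - 60000.0 / 80.0) / (60000.0 / 80.0) < 0.02


class TestComposition:
    def test_same_config_and_seed_byte_identical(self, tmp_path):
        from groomctx.session import write_session
        for d in ("a", "b"):
            write_session(generate_session(small_config(seed=12)), tmp_path / d)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_standard_design_five_alternating_blocks(self):
        session = generate_session(demo_config(seed=2))
        assert [b.kind for b in session.blocks] == \
            ["airflow", "grooming", "airflow", "grooming", "airflow"]

    def test_groomer_present_block_kind_preserved(self):
        cfg = small_config(seed=8)
        cfg.block_kinds = ("airflow", "grooming", "airflow_groomer_present")
        session = generate_session(cfg)
        assert session.blocks[2].kind == "airflow_groomer_present"
        # groomer-present blocks still carry airflow-style stimulation
        ev = session.events_in_block(2)
        assert {e.modality for e in ev} == {"airflow", "sham"}
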