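"""Synthetic session generator.

Emulates the grooming/airflow block design: alternating blocks
(typically airflow-grooming-airflow-grooming-airflow), airflow puffs of
1 s with 3 s ISI delivered in pseudo-random sets over 11 nozzle
locations (location 11 = sham) repeated ``n_airflow_repeats`` times per
block, grooming sweeps of 1-2 s with 2-4 s ISI in 5 sets of 10 sweeps
per groomed location, block-dependent baseline firing, phasic evoked
responses, and an EKG R-wave train with context-dependent mean heart
rate and ~0.3 Hz respiratory sinus arrhythmia.

Spike trains are inhomogeneous-Poisson draws from
``rate(t) = baseline(block kind at t) + sum of evoked kernels``;
R waves come from integrate-to-threshold over the instantaneous heart
rate.  Everything is reproducible from ``(config, seed)``; each unit
gets its own RNG substream keyed by a stable hash of its id, so adding
a unit never changes another unit's spikes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import SchedulingError, SessionValidationError
from .session import (
    BLOCK_KINDS, SHAM_LOCATION, Block, HeartTrace, Session, SpikeTrain,
    StimulusEvent, canonical_spike_times,
)

AIRFLOW_LIKE = ("airflow", "airflow_groomer_present")


def _per_context(value, name: str) -> dict[str, float]:
    """Accept a scalar or a {block_kind: value} mapping."""
    if isinstance(value, dict):
        bad = set(value) - set(BLOCK_KINDS)
        if bad:
            raise SessionValidationError(f"{name}: unknown block kinds {bad}")
        return {k: float(v) for k, v in value.items()}
    return {k: float(value) for k in BLOCK_KINDS}


def _per_location(value) -> dict[int, float]:
    """Accept a scalar gain (all locations) or a {location: gain} mapping."""
    if isinstance(value, dict):
        return {int(k): float(v) for k, v in value.items()}
    return {loc: float(value) for loc in range(1, 12)}


@dataclass
class UnitSpec:
    """Generative description of one unit.

    ``baseline_hz_by_context`` sets the context-dependent baseline rate;
    evoked gains are additive rates (Hz) applied per event via the
    response kernel.  ``transient_plus_sustained`` adds the sustained
    gain over the stimulus plus a 100-ms onset transient at 3x gain
    (airflow-like); ``ramp`` is a triangular profile peaking mid-stimulus
    at the gain (grooming-like, tracking finger pressure).
    """

    unit_id: str
    baseline_hz_by_context: dict[str, float] | float = 5.0
    evoked_gain_airflow: dict[int, float] | float = 0.0
    evoked_gain_grooming: dict[int, float] | float = 0.0
    evoked_gain_sham: float = 0.0
    response_shape: str = "transient_plus_sustained"
    latency_ms: int = 0
    region: str = "amygdala"
    stable: bool = True

    def validate(self) -> None:
        if self.response_shape not in ("transient_plus_sustained", "ramp"):
            raise SessionValidationError(
                f"unit {self.unit_id}: unknown response shape {self.response_shape!r}")
        if self.latency_ms < 0:
            raise SessionValidationError(f"unit {self.unit_id}: negative latency")
        for v in _per_context(self.baseline_hz_by_context, "baseline").values():
            if v < 0:
                raise SessionValidationError(f"unit {self.unit_id}: negative baseline")
        for gains in (self.evoked_gain_airflow, self.evoked_gain_grooming):
            for v in _per_location(gains).values():
                if v < 0:
                    raise SessionValidationError(f"unit {self.unit_id}: negative gain")
        if float(self.evoked_gain_sham) < 0:
            raise SessionValidationError(f"unit {self.unit_id}: negative sham gain")

    def gain_for(self, modality: str, location: int) -> float:
        if modality == "sham":
            return float(self.evoked_gain_sham)
        gains = (self.evoked_gain_airflow if modality == "airflow"
                 else self.evoked_gain_grooming)
        return _per_location(gains).get(location, 0.0)


@dataclass
class HeartSpec:
    """Context-dependent mean heart rate (BPM) plus sinusoidal RSA.

    ``rsa_depth_by_context`` is the fractional rate-modulation amplitude
    (0-1); ``episodes`` inject transient tachycardia as
    ``(start_ms, duration_ms, delta_bpm)`` rate offsets.
    """

    mean_hr_by_context: dict[str, float] | float = 100.0
    rsa_depth_by_context: dict[str, float] | float = 0.05
    rsa_freq_hz: float = 0.30
    episodes: list[tuple[int, int, float]] = field(default_factory=list)

    def validate(self) -> None:
        for v in _per_context(self.mean_hr_by_context, "mean HR").values():
            if not 40 <= v <= 240:
                raise SessionValidationError(f"mean HR {v} BPM outside [40, 240]")
        for v in _per_context(self.rsa_depth_by_context, "RSA depth").values():
            if not 0 <= v < 1:
                raise SessionValidationError(f"RSA depth {v} outside [0, 1)")
        if not 0 < self.rsa_freq_hz <= 0.5:
            raise SessionValidationError(
                f"RSA frequency {self.rsa_freq_hz} Hz outside (0, 0.5]")


@dataclass
class SessionConfig:
    """Block schedule, stimulus structure, unit specs, and heart spec.

    Defaults reproduce the standard design: three ~7.5-min airflow blocks
    interspersed with two ~9-min grooming blocks; airflow in 10 permuted
    sets of the 11 locations (1 s on, 3 s ISI) with juice after each set;
    grooming as 5 sets of 10 sweeps to each of two face locations
    (1-2 s sweeps, 2-4 s ISI) with reward at block end.
    """

    seed: int
    session_id: str = "synthetic"
    block_kinds: Sequence[str] = ("airflow", "grooming", "airflow",
                                  "grooming", "airflow")
    block_durations_ms: Sequence[int] | None = None  # None: fit to schedule
    n_airflow_repeats: int = 10
    airflow_duration_ms: int = 1000
    airflow_isi_ms: int = 3000
    grooming_locations: Sequence[int] = (2, 3)  # upper muzzle, brow
    n_grooming_sets: int = 5
    sweeps_per_set: int = 10
    sweep_duration_range_ms: tuple[int, int] = (1000, 2000)
    sweep_isi_range_ms: tuple[int, int] = (2000, 4000)
    reward_airflow_set_ms: int = 1000
    reward_grooming_block_ms: int = 3000
    inter_block_gap_ms: int = 20000
    units: list[UnitSpec] = field(default_factory=list)
    heart: HeartSpec | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise SessionValidationError("seed is mandatory")
        for k in self.block_kinds:
            if k not in BLOCK_KINDS:
                raise SessionValidationError(f"unknown block kind {k!r}")
        for v in (self.n_airflow_repeats, self.airflow_duration_ms,
                  self.airflow_isi_ms, self.n_grooming_sets, self.sweeps_per_set):
            if v <= 0:
                raise SessionValidationError("structure parameters must be positive")
        if self.inter_block_gap_ms < 0:
            raise SessionValidationError("inter_block_gap_ms must be >= 0")
        if (self.block_durations_ms is not None
                and len(self.block_durations_ms) != len(self.block_kinds)):
            raise SessionValidationError(
                "block_durations_ms length must match block_kinds")
        for u in self.units:
            u.validate()
        if self.heart is not None:
            self.heart.validate()

    def to_dict(self) -> dict:
        """JSON-safe dict (tuples become lists) for manifests/metadata."""
        d = asdict(self)
        return _jsonify(d)


def _jsonify(x):
    if isinstance(x, dict):
        return {str(k): _jsonify(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonify(v) for v in x]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    return x


def config_from_dict(d: dict) -> SessionConfig:
    """Inverse of :meth:`SessionConfig.to_dict` (also reads YAML/JSON mappings)."""
    d = dict(d)
    d["units"] = [UnitSpec(**u) if not isinstance(u, UnitSpec) else u
                  for u in d.get("units", [])]
    if d.get("heart") is not None and not isinstance(d["heart"], HeartSpec):
        h = dict(d["heart"])
        h["episodes"] = [tuple(e) for e in h.get("episodes", [])]
        d["heart"] = HeartSpec(**h)
    for key in ("sweep_duration_range_ms", "sweep_isi_range_ms"):
        if key in d:
            d[key] = tuple(d[key])
    return SessionConfig(**d)


def _unit_seed(seed: int, unit_id: str) -> np.random.SeedSequence:
    # stable across processes, unlike hash()
    return np.random.SeedSequence([int(seed), 1, zlib.crc32(unit_id.encode())])


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------

def make_schedule(config: SessionConfig
                  ) -> tuple[list[Block], list[StimulusEvent]]:
    """Lay out blocks, stimulus events, and reward windows.

    Airflow(-like) blocks: ``n_airflow_repeats`` permuted sets of the 11
    locations, fixed stimulus duration and ISI, a reward window after
    each set.  Grooming blocks: ``n_grooming_sets`` sets of
    ``sweeps_per_set`` sweeps at each groomed location in turn, sweep
    durations uniform in ``sweep_duration_range_ms``, ISIs uniform in
    ``sweep_isi_range_ms``, one reward window at block end.
    """
    config.validate()
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence([int(config.seed), 0])))
    blocks: list[Block] = []
    events: list[StimulusEvent] = []
    t = 0
    eid = 0
    for bi, kind in enumerate(config.block_kinds):
        start = t
        rewards: list[tuple[int, int]] = []
        if kind in AIRFLOW_LIKE:
            for _ in range(config.n_airflow_repeats):
                for loc in rng.permutation(np.arange(1, 12)):
                    loc = int(loc)
                    modality = "sham" if loc == SHAM_LOCATION else "airflow"
                    events.append(StimulusEvent(
                        eid, bi, modality, loc, t, t + config.airflow_duration_ms))
                    eid += 1
                    t += config.airflow_duration_ms + config.airflow_isi_ms
                # juice after each completed set, inside the running ISI
                rewards.append((t, t + config.reward_airflow_set_ms))
                t += config.reward_airflow_set_ms
        else:
            for _ in range(config.n_grooming_sets):
                for loc in config.grooming_locations:
                    for _ in range(config.sweeps_per_set):
                        dur = int(rng.integers(config.sweep_duration_range_ms[0],
                                               config.sweep_duration_range_ms[1] + 1))
                        isi = int(rng.integers(config.sweep_isi_range_ms[0],
                                               config.sweep_isi_range_ms[1] + 1))
                        events.append(StimulusEvent(
                            eid, bi, "grooming", int(loc), t, t + dur))
                        eid += 1
                        t += dur + isi
            rewards.append((t, t + config.reward_grooming_block_ms))
            t += config.reward_grooming_block_ms
        end = t
        if config.block_durations_ms is not None:
            configured_end = start + int(config.block_durations_ms[bi])
            if configured_end < end:
                raise SchedulingError(
                    f"block {bi} ({kind}): schedule needs {end - start} ms but "
                    f"only {configured_end - start} ms configured")
            end = configured_end
        blocks.append(Block(bi, kind, start, end, tuple(rewards)))
        t = end + config.inter_block_gap_ms
    return blocks, events


# ---------------------------------------------------------------------------
# Spikes
# ---------------------------------------------------------------------------

def rate_profile_ms(spec: UnitSpec, blocks: list[Block],
                    events: list[StimulusEvent]) -> np.ndarray:
    """Intensity function in Hz on the 1-ms grid over [0, session extent)."""
    extent = max(b.end_ms for b in blocks)
    baseline = _per_context(spec.baseline_hz_by_context, "baseline")
    rate = np.zeros(extent, dtype=float)
    for b in blocks:
        rate[b.start_ms:b.end_ms] = baseline.get(b.kind, 0.0)
    for e in events:
        gain = spec.gain_for(e.modality, e.location)
        if gain <= 0:
            continue
        s = min(e.onset_ms + spec.latency_ms, e.offset_ms)
        # airflow/sham kernels are always transient+sustained; grooming
        # events follow the unit's configured shape (ramp tracks the
        # gradual rise and fall of finger pressure)
        if spec.response_shape == "transient_plus_sustained" or e.modality != "grooming":
            rate[s:e.offset_ms] += gain
            rate[s:min(s + 100, e.offset_ms)] += 2.0 * gain  # transient = 3x total
        else:  # ramp: triangular, peaking at the gain mid-stimulus
            n = e.offset_ms - s
            if n > 0:
                x = np.arange(n) / max(n - 1, 1)
                rate[s:e.offset_ms] += gain * (1.0 - np.abs(2.0 * x - 1.0))
    return rate


def simulate_spike_train(spec: UnitSpec, blocks: list[Block],
                         events: list[StimulusEvent], seed) -> SpikeTrain:
    """Inhomogeneous-Poisson spike train, rounded to ms and deduplicated.

    ``seed`` may be an int or a ``SeedSequence``; sessions pass a
    substream keyed by the unit id.
    """
    spec.validate()
    rng = np.random.Generator(np.random.PCG64(seed))
    rate = rate_profile_ms(spec, blocks, events)
    counts = rng.poisson(rate / 1000.0)
    times = np.flatnonzero(counts)  # >=2 spikes in 1 ms collapse to one
    return SpikeTrain(spec.unit_id, spec.region,
                      canonical_spike_times(times), spec.stable)


# ---------------------------------------------------------------------------
# Heart
# ---------------------------------------------------------------------------

def simulate_heart(spec: HeartSpec, blocks: list[Block], seed=0) -> HeartTrace:
    """R-wave train by integrate-to-threshold over the instantaneous rate.

    ``r(t) = mean_rate(block kind) * (1 + depth(kind) * sin(2*pi*f*t))``
    in beats/ms, with injected episodes added as rate offsets; an R wave
    is emitted each time the integral crosses the next integer.  Between
    blocks the rate holds the session-average BPM.  The draw is
    deterministic given (spec, blocks); ``seed`` is accepted for
    interface uniformity.
    """
    spec.validate()
    extent = max(b.end_ms for b in blocks)
    hr = _per_context(spec.mean_hr_by_context, "mean HR")
    depth = _per_context(spec.rsa_depth_by_context, "RSA depth")
    bpm = np.full(extent, np.mean([hr[b.kind] for b in blocks]))
    dep = np.zeros(extent)
    for b in blocks:
        bpm[b.start_ms:b.end_ms] = hr[b.kind]
        dep[b.start_ms:b.end_ms] = depth[b.kind]
    for (s, d, delta) in spec.episodes:
        bpm[int(s):min(int(s) + int(d), extent)] += float(delta)
    t = np.arange(extent, dtype=float) / 1000.0
    rate = (bpm / 60000.0) * (1.0 + dep * np.sin(2 * np.pi * spec.rsa_freq_hz * t))
    integral = np.cumsum(rate)
    n_beats = int(np.floor(integral[-1]))
    beat_times = np.searchsorted(integral, np.arange(1, n_beats + 1))
    return HeartTrace(np.unique(beat_times.astype(np.int64)))


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def demo_config(seed: int, n_null: int = 3, n_ctx_up: int = 2,
                n_ctx_down: int = 2, n_airflow_resp: int = 2,
                n_grooming_resp: int = 1, n_airflow_repeats: int = 10,
                n_grooming_sets: int = 5, with_heart: bool = True,
                episodes: list[tuple[int, int, float]] | None = None
                ) -> SessionConfig:
    """A small mixed population on the standard 5-block design.

    Context units carry a Poisson-rate step between airflow (5 Hz) and
    grooming (~6.27 Hz up / ~3.86 Hz down), a standardized shift of
    about 0.5 on 1-s bins; the groomer-present rate sits midway, so the
    groomer-presence analysis has a recoverable intermediate step.
    Airflow responders gain +10 Hz; the grooming responder ramps to
    +8 Hz; one unit responds to the sham puff only.
    """
    units: list[UnitSpec] = []

    def _ctx_rates(base: float, shift_sd: float) -> dict[str, float]:
        # solve lam_g so that (lam_g - base)/sqrt((lam_g + base)/2) = shift_sd
        lam = base
        for _ in range(40):
            lam = base + shift_sd * np.sqrt((lam + base) / 2.0)
        return {"airflow": base, "grooming": float(lam),
                "airflow_groomer_present": float((base + lam) / 2.0)}

    for i in range(n_airflow_resp):
        units.append(UnitSpec(f"af{i}", baseline_hz_by_context=5.0,
                              evoked_gain_airflow=10.0))
    for i in range(n_grooming_resp):
        units.append(UnitSpec(f"gr{i}", baseline_hz_by_context=5.0,
                              evoked_gain_grooming=8.0, response_shape="ramp"))
    units.append(UnitSpec("sham0", baseline_hz_by_context=5.0,
                          evoked_gain_sham=10.0))
    for i in range(n_ctx_up):
        units.append(UnitSpec(f"up{i}", baseline_hz_by_context=_ctx_rates(5.0, 0.5)))
    for i in range(n_ctx_down):
        units.append(UnitSpec(f"down{i}",
                              baseline_hz_by_context=_ctx_rates(5.0, -0.5)))
    for i in range(n_null):
        units.append(UnitSpec(f"null{i}", baseline_hz_by_context=5.0))
    heart = None
    if with_heart:
        heart = HeartSpec(
            mean_hr_by_context={"airflow": 110.0, "grooming": 95.0,
                                "airflow_groomer_present": 105.0},
            rsa_depth_by_context={"airflow": 0.02, "grooming": 0.10,
                                  "airflow_groomer_present": 0.02},
            rsa_freq_hz=0.30, episodes=list(episodes or []))
    return SessionConfig(seed=seed, session_id=f"demo-{seed}",
                         n_airflow_repeats=n_airflow_repeats,
                         n_grooming_sets=n_grooming_sets,
                         units=units, heart=heart)


def generate_session(config: SessionConfig) -> Session:
    """Schedule + spikes + heart, fully reproducible from (config, seed)."""
    blocks, events = make_schedule(config)
    units = [simulate_spike_train(u, blocks, events,
                                  _unit_seed(config.seed, u.unit_id))
             for u in config.units]
    heart = (simulate_heart(config.heart, blocks,
                            np.random.SeedSequence([int(config.seed), 2]))
             if config.heart is not None else None)
    session = Session(session_id=config.session_id, blocks=blocks,
                      events=events, units=units, heart=heart,
                      metadata={"seed": int(config.seed),
                                "generator": "groomctx.synth",
                                "config": config.to_dict()})
    session.validate()
    return session
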