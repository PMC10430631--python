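"""Shared fixtures: small deterministic sessions, random-session builders,
and the brute-force 1-ms baseline oracle."""

from __future__ import annotations

import numpy as np
import pytest

from groomctx.baseline import BIN_MS, STIM_BUFFER_MS
from groomctx.session import Block, Session, SpikeTrain, StimulusEvent
from groomctx.synth import SessionConfig, demo_config, generate_session


def small_config(seed: int, **overrides) -> SessionConfig:
    """A reduced 5-block session: full airflow sets (10 repeats keep every
    location at the >=10-trial inclusion floor) but only 2 grooming sets,
    so every block still clears 60 baseline bins."""
    cfg = demo_config(seed, n_null=1, n_ctx_up=1, n_ctx_down=0,
                      n_airflow_resp=1, n_grooming_resp=0,
                      n_airflow_repeats=10, n_grooming_sets=2, with_heart=True)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture()
def small_session() -> Session:
    return generate_session(small_config(seed=3))


def random_small_session(rng: np.random.Generator) -> Session:
    """A structurally random but valid session for oracle comparisons:
    2-4 short blocks, random events/rewards, homogeneous Poisson spikes."""
    n_blocks = int(rng.integers(2, 5))
    blocks, events, t, eid = [], [], 0, 0
    for bi in range(n_blocks):
        kind = ("airflow", "grooming")[bi % 2]
        dur = int(rng.integers(8000, 25000))
        start, end = t, t + dur
        rewards = []
        if rng.random() < 0.5:
            rs = int(rng.integers(start, end - 1000))
            rewards.append((rs, rs + int(rng.integers(200, 1000))))
        pos = start + int(rng.integers(0, 2000))
        while pos + 2000 < end:
            if kind == "airflow":
                mod, loc, d = "airflow", int(rng.integers(1, 11)), 1000
            else:
                mod, loc, d = "grooming", int(rng.integers(2, 4)), int(rng.integers(1000, 2001))
            if pos + d > end:
                break
            events.append(StimulusEvent(eid, bi, mod, loc, pos, pos + d))
            eid += 1
            pos += d + int(rng.integers(500, 4000))
        blocks.append(Block(bi, kind, start, end, tuple(rewards)))
        t = end + int(rng.integers(0, 3000))
    extent = blocks[-1].end_ms
    spikes = np.flatnonzero(rng.random(extent) < 0.01)  # ~10 Hz
    units = [SpikeTrain.from_times("u0", "amygdala", spikes)]
    s = Session("rand", blocks, events, units)
    s.validate()
    return s


def baseline_bins_oracle(session: Session, train: SpikeTrain,
                         block_ids=None):
    """Brute-force reference for extract_baseline_bins: mark every
    baseline millisecond on a boolean timeline, concatenate per block,
    and count spikes per full 1-s bin."""
    if block_ids is None:
        block_ids = [b.block_id for b in session.blocks]
    spikes = set(train.spike_times_ms.tolist())
    out = []
    for bid in block_ids:
        block = session.block_by_id(bid)
        mask = np.ones(block.end_ms - block.start_ms, dtype=bool)
        for e in session.events:
            lo = max(e.onset_ms - STIM_BUFFER_MS, block.start_ms)
            hi = min(e.offset_ms + STIM_BUFFER_MS, block.end_ms)
            if hi > lo:
                mask[lo - block.start_ms:hi - block.start_ms] = False
        for b in session.blocks:
            for (s, e) in b.reward_windows:
                lo, hi = max(s, block.start_ms), min(e, block.end_ms)
                if hi > lo:
                    mask[lo - block.start_ms:hi - block.start_ms] = False
        baseline_ms = np.flatnonzero(mask) + block.start_ms
        n_bins = len(baseline_ms) // BIN_MS
        for k in range(n_bins):
            chunk = baseline_ms[k * BIN_MS:(k + 1) * BIN_MS]
            count = sum(1 for m in chunk.tolist() if m in spikes)
            out.append((bid, count * 1000.0 / BIN_MS))
    return out
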