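"""Session data model and on-disk CSV/JSON readers and writers.

A *session* is one recording: an ordered sequence of blocks (airflow,
grooming, or airflow with the groomer present), a table of stimulus
events (airflow puffs, grooming sweeps, sham puffs), per-unit spike
trains, and optionally a train of EKG R-wave times.

Conventions
-----------
* All times are integer milliseconds from session start (0-based).
* Intervals are half-open ``[start, end)``.
* Spike times are rounded to the nearest millisecond and 1-ms
  duplicates are collapsed to a single spike.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SessionLoadError, SessionValidationError

BLOCK_KINDS = ("airflow", "grooming", "airflow_groomer_present")
MODALITIES = ("airflow", "grooming", "sham")
REGIONS = ("amygdala", "SI")

#: Nozzle/sweep location codes. 1-10 are face locations; 11 is the sham
#: nozzle pointed away from the animal.
SHAM_LOCATION = 11

#: Allowed stimulus durations in ms, by modality.  Airflow is 1 s in most
#: sessions and 1.5 s in some early ones; grooming sweeps last 1-2 s.
DURATION_BOUNDS_MS = {
    "airflow": (1000, 1500),
    "sham": (1000, 1500),
    "grooming": (1000, 2000),
}


@dataclass(frozen=True)
class Block:
    block_id: int
    kind: str
    start_ms: int
    end_ms: int
    reward_windows: tuple[tuple[int, int], ...] = ()

    def validate(self) -> None:
        if self.kind not in BLOCK_KINDS:
            raise SessionValidationError(
                f"block {self.block_id}: unknown kind {self.kind!r}")
        if not self.start_ms < self.end_ms:
            raise SessionValidationError(
                f"block {self.block_id}: start_ms {self.start_ms} >= end_ms {self.end_ms}")
        for (s, e) in self.reward_windows:
            if not (self.start_ms <= s < e <= self.end_ms):
                raise SessionValidationError(
                    f"block {self.block_id}: reward window [{s}, {e}) outside block")

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class StimulusEvent:
    event_id: int
    block_id: int
    modality: str
    location: int
    onset_ms: int
    offset_ms: int

    def validate(self, block: Block | None = None) -> None:
        if self.modality not in MODALITIES:
            raise SessionValidationError(
                f"event {self.event_id}: unknown modality {self.modality!r}")
        if not 1 <= self.location <= 11:
            raise SessionValidationError(
                f"event {self.event_id}: location {self.location} outside 1-11")
        if (self.location == SHAM_LOCATION) != (self.modality == "sham"):
            raise SessionValidationError(
                f"event {self.event_id}: location {self.location} inconsistent "
                f"with modality {self.modality!r} (location 11 <=> sham)")
        if self.offset_ms <= self.onset_ms:
            raise SessionValidationError(
                f"event {self.event_id}: offset {self.offset_ms} <= onset {self.onset_ms}")
        lo, hi = DURATION_BOUNDS_MS[self.modality]
        dur = self.offset_ms - self.onset_ms
        if not lo <= dur <= hi:
            raise SessionValidationError(
                f"event {self.event_id}: {self.modality} duration {dur} ms "
                f"outside [{lo}, {hi}] ms")
        if block is not None:
            if not (block.start_ms <= self.onset_ms and self.offset_ms <= block.end_ms):
                raise SessionValidationError(
                    f"event {self.event_id}: [{self.onset_ms}, {self.offset_ms}) "
                    f"outside block {block.block_id}")

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms


def canonical_spike_times(times_ms) -> np.ndarray:
    """Round to nearest ms, sort, and collapse 1-ms duplicates."""
    t = np.asarray(np.rint(np.asarray(times_ms, dtype=float)), dtype=np.int64)
    return np.unique(t)


@dataclass(eq=False)
class SpikeTrain:
    unit_id: str
    region: str
    spike_times_ms: np.ndarray  # int64, strictly increasing
    stable: bool = True

    @classmethod
    def from_times(cls, unit_id: str, region: str, times_ms, stable: bool = True
                   ) -> "SpikeTrain":
        return cls(unit_id, region, canonical_spike_times(times_ms), stable)

    def validate(self, extent_ms: int | None = None) -> None:
        if self.region not in REGIONS:
            raise SessionValidationError(
                f"unit {self.unit_id}: unknown region {self.region!r}")
        t = self.spike_times_ms
        if len(t) and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise SessionValidationError(
                f"unit {self.unit_id}: spike times not strictly increasing and non-negative")
        if extent_ms is not None and len(t) and t[-1] >= extent_ms:
            raise SessionValidationError(
                f"unit {self.unit_id}: spike at {t[-1]} ms beyond session extent {extent_ms}")

    def __eq__(self, other) -> bool:
        return (isinstance(other, SpikeTrain)
                and self.unit_id == other.unit_id
                and self.region == other.region
                and self.stable == other.stable
                and np.array_equal(self.spike_times_ms, other.spike_times_ms))

    def __len__(self) -> int:
        return len(self.spike_times_ms)


@dataclass(eq=False)
class HeartTrace:
    r_wave_times_ms: np.ndarray  # int64, strictly increasing

    def validate(self) -> None:
        t = np.asarray(self.r_wave_times_ms)
        if len(t) and np.any(np.diff(t) <= 0):
            raise SessionValidationError("R-wave times not strictly increasing")

    def __eq__(self, other) -> bool:
        return (isinstance(other, HeartTrace)
                and np.array_equal(self.r_wave_times_ms, other.r_wave_times_ms))


@dataclass(eq=False)
class Session:
    session_id: str
    blocks: list[Block]
    events: list[StimulusEvent]
    units: list[SpikeTrain]
    heart: HeartTrace | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def extent_ms(self) -> int:
        return max(b.end_ms for b in self.blocks) if self.blocks else 0

    def block_by_id(self, block_id: int) -> Block:
        for b in self.blocks:
            if b.block_id == block_id:
                return b
        raise SessionValidationError(f"block_id {block_id} does not resolve")

    def blocks_of_kind(self, kind: str) -> list[Block]:
        return [b for b in self.blocks if b.kind == kind]

    def unit(self, unit_id: str) -> SpikeTrain:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def events_in_block(self, block_id: int) -> list[StimulusEvent]:
        return [e for e in self.events if e.block_id == block_id]

    def validate(self) -> None:
        if not self.blocks:
            raise SessionValidationError("session has no blocks")
        by_id: dict[int, Block] = {}
        for b in self.blocks:
            b.validate()
            if b.block_id in by_id:
                raise SessionValidationError(f"duplicate block_id {b.block_id}")
            by_id[b.block_id] = b
        ordered = sorted(self.blocks, key=lambda b: b.start_ms)
        if ordered != self.blocks:
            raise SessionValidationError("blocks not time-ordered")
        for prev, nxt in zip(self.blocks, self.blocks[1:]):
            if nxt.start_ms < prev.end_ms:
                raise SessionValidationError(
                    f"blocks {prev.block_id} and {nxt.block_id} overlap")
        for e in self.events:
            if e.block_id not in by_id:
                raise SessionValidationError(
                    f"event {e.event_id}: block_id {e.block_id} does not resolve")
            e.validate(by_id[e.block_id])
        seen = set()
        for u in self.units:
            if u.unit_id in seen:
                raise SessionValidationError(f"duplicate unit_id {u.unit_id}")
            seen.add(u.unit_id)
            u.validate(self.extent_ms)
        if self.heart is not None:
            self.heart.validate()

    def __eq__(self, other) -> bool:
        return (isinstance(other, Session)
                and self.session_id == other.session_id
                and self.blocks == other.blocks
                and self.events == other.events
                and self.units == other.units
                and self.heart == other.heart
                and self.metadata == other.metadata)


# ---------------------------------------------------------------------------
# On-disk layout: blocks.csv, rewards.csv, events.csv, spikes.csv,
# rwaves.csv, meta.json.  UTF-8, comma-separated, header row mandatory.
# ---------------------------------------------------------------------------

_FILES = ("blocks.csv", "rewards.csv", "events.csv", "spikes.csv",
          "rwaves.csv", "meta.json")


def write_session(session: Session, path) -> None:
    """Write ``session`` to ``path`` in the documented CSV/JSON layout.

    Output is byte-stable for a fixed session: fixed column order, integer
    formatting, ``\\n`` line endings, and sorted JSON keys.
    """
    session.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    kw = dict(index=False, lineterminator="\n")

    pd.DataFrame(
        [(b.block_id, b.kind, b.start_ms, b.end_ms) for b in session.blocks],
        columns=["block_id", "kind", "start_ms", "end_ms"],
    ).to_csv(path / "blocks.csv", **kw)

    rewards = [(b.block_id, s, e) for b in session.blocks
               for (s, e) in b.reward_windows]
    pd.DataFrame(rewards, columns=["block_id", "start_ms", "end_ms"]
                 ).to_csv(path / "rewards.csv", **kw)

    pd.DataFrame(
        [(e.event_id, e.block_id, e.modality, e.location, e.onset_ms, e.offset_ms)
         for e in session.events],
        columns=["event_id", "block_id", "modality", "location",
                 "onset_ms", "offset_ms"],
    ).to_csv(path / "events.csv", **kw)

    spikes: list[tuple[str, str, int, int]] = []
    for u in session.units:
        if len(u) == 0:
            # a unit with no spikes still needs a row so region/stability
            # round-trip; -1 marks the placeholder
            spikes.append((u.unit_id, u.region, int(u.stable), -1))
        else:
            spikes.extend((u.unit_id, u.region, int(u.stable), t)
                          for t in u.spike_times_ms.tolist())
    pd.DataFrame(spikes,
                 columns=["unit_id", "region", "stable", "spike_time_ms"]
                 ).to_csv(path / "spikes.csv", **kw)

    rw = (session.heart.r_wave_times_ms.tolist()
          if session.heart is not None else [])
    pd.DataFrame(rw, columns=["r_wave_time_ms"]).to_csv(path / "rwaves.csv", **kw)

    meta = {"session_id": session.session_id,
            "has_heart": session.heart is not None,
            "metadata": session.metadata}
    (path / "meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_session(path) -> Session:
    """Read a session from the documented CSV/JSON layout and validate it."""
    path = Path(path)
    for name in _FILES:
        if not (path / name).exists():
            raise SessionLoadError(f"missing file: {path / name}")

    meta = json.loads((path / "meta.json").read_text(encoding="utf-8"))

    bdf = pd.read_csv(path / "blocks.csv")
    rdf = pd.read_csv(path / "rewards.csv")
    rewards_by_block: dict[int, list[tuple[int, int]]] = {}
    for row in rdf.itertuples(index=False):
        rewards_by_block.setdefault(int(row.block_id), []).append(
            (int(row.start_ms), int(row.end_ms)))
    blocks = [Block(int(r.block_id), str(r.kind), int(r.start_ms), int(r.end_ms),
                    tuple(rewards_by_block.get(int(r.block_id), [])))
              for r in bdf.itertuples(index=False)]

    edf = pd.read_csv(path / "events.csv")
    events = [StimulusEvent(int(r.event_id), int(r.block_id), str(r.modality),
                            int(r.location), int(r.onset_ms), int(r.offset_ms))
              for r in edf.itertuples(index=False)]

    sdf = pd.read_csv(path / "spikes.csv")
    units: list[SpikeTrain] = []
    if len(sdf):
        for (uid, region, stable), grp in sdf.groupby(
                ["unit_id", "region", "stable"], sort=False):
            t = grp["spike_time_ms"].to_numpy(dtype=np.int64)
            t = t[t >= 0]  # -1 marks an empty unit's placeholder row
            units.append(SpikeTrain(str(uid), str(region), np.sort(t), bool(stable)))

    hdf = pd.read_csv(path / "rwaves.csv")
    heart = None
    if meta.get("has_heart", len(hdf) > 0):
        heart = HeartTrace(hdf["r_wave_time_ms"].to_numpy(dtype=np.int64))

    session = Session(session_id=str(meta["session_id"]), blocks=blocks,
                      events=events, units=units, heart=heart,
                      metadata=meta.get("metadata", {}))
    session.validate()
    return session
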