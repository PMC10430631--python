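"""Baseline extraction, Cohen's d_s effect sizes, and context classification.

Baseline activity is the spiking between stimuli.  Per block, the
timeline minus (stimulus windows padded by a 300-ms buffer on each
side, reward windows, inter-block gaps) is concatenated and cut into
consecutive full 1-s bins; trailing partial bins are dropped.  Bin
rates are spike counts per 1-s bin (Hz); Z-scores are computed per unit
over all retained bins jointly.

A unit shows *context-related* baseline activity when the
grooming-vs-airflow effect size d_GA clears the conventional 0.2
minimum and is at least 1.5x the largest within-condition effect size
(grooming1-vs-grooming2, airflow1-vs-airflow2) — the within-condition
comparisons guard against slow drift masquerading as context.  Effect
sizes use Cohen's d for independent samples:

    d_s = (mean(x1) - mean(x2)) / s_pooled,
    s_pooled = sqrt(((n1-1)*SD1^2 + (n2-1)*SD2^2) / (n1 + n2 - 2))

computed on raw Hz (d_s is scale-invariant, so raw vs jointly Z-scored
bins give identical values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._intervals import merge, subtract
from .errors import InsufficientDataError
from .session import Block, Session, SpikeTrain

STIM_BUFFER_MS = 300
BIN_MS = 1000
MIN_BINS_PER_BLOCK = 60
DS_MIN = 0.2
DS_RATIO = 1.5


@dataclass(eq=False)
class BaselineSeries:
    """Per-unit 1-s binned baseline rates with block labels and Z-scores."""

    unit_id: str
    block_ids: np.ndarray      # int, per bin
    block_kinds: np.ndarray    # str, per bin
    bin_start_ms: np.ndarray   # real-time start of each bin's first segment
    rates_hz: np.ndarray       # float, spikes per 1-s bin

    @property
    def z_rates(self) -> np.ndarray:
        sd = np.std(self.rates_hz, ddof=0)
        if sd == 0:
            return np.zeros_like(self.rates_hz)
        return (self.rates_hz - np.mean(self.rates_hz)) / sd

    def rates_for_block(self, block_id: int) -> np.ndarray:
        return self.rates_hz[self.block_ids == block_id]

    def rates_for_kind(self, kind: str) -> np.ndarray:
        return self.rates_hz[self.block_kinds == kind]

    def n_bins_by_block(self) -> dict[int, int]:
        ids, counts = np.unique(self.block_ids, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    def __len__(self) -> int:
        return len(self.rates_hz)


def baseline_segments(session: Session, block: Block) -> list[tuple[int, int]]:
    """Half-open baseline intervals of one block: block span minus padded
    stimulus windows and reward windows."""
    exclusions = [(e.onset_ms - STIM_BUFFER_MS, e.offset_ms + STIM_BUFFER_MS)
                  for e in session.events]
    exclusions += [list(w) for b in session.blocks for w in b.reward_windows]
    exclusions = [(int(s), int(e)) for s, e in exclusions]
    return subtract([(block.start_ms, block.end_ms)], merge(exclusions))


def context_analysis_block_ids(session: Session) -> list[int]:
    """The four analysis blocks: first two airflow and first two grooming,
    in session order.  Raises if fewer than two of either exist."""
    airflow = [b.block_id for b in session.blocks if b.kind == "airflow"][:2]
    grooming = [b.block_id for b in session.blocks if b.kind == "grooming"][:2]
    if len(airflow) < 2 or len(grooming) < 2:
        raise InsufficientDataError(
            f"session {session.session_id}: needs >=2 airflow and >=2 grooming "
            f"blocks for the context analysis")
    return sorted(airflow + grooming)


def extract_baseline_bins(session: Session, train: SpikeTrain,
                          block_ids: list[int] | None = None) -> BaselineSeries:
    """Cut 1-s baseline bins per block and count spikes in each.

    Bins are cut from the *concatenated* baseline of each block, so
    segments shorter than 1 s contribute jointly; the trailing partial
    bin of each block is dropped.
    """
    if block_ids is None:
        block_ids = [b.block_id for b in session.blocks]
    spikes = train.spike_times_ms
    ids, kinds, starts, rates = [], [], [], []
    for bid in block_ids:
        block = session.block_by_id(bid)
        segs = baseline_segments(session, block)
        lengths = np.array([e - s for s, e in segs], dtype=np.int64)
        total = int(lengths.sum())
        n_bins = total // BIN_MS
        if n_bins == 0:
            continue
        cum = np.concatenate([[0], np.cumsum(lengths)])
        # concatenated coordinate of every spike falling inside a segment
        coords = []
        for (s, e), c0 in zip(segs, cum[:-1]):
            lo, hi = np.searchsorted(spikes, [s, e])
            coords.append(spikes[lo:hi] - s + c0)
        coords = np.concatenate(coords) if coords else np.empty(0, dtype=np.int64)
        coords = coords[coords < n_bins * BIN_MS]
        counts = np.bincount(coords // BIN_MS, minlength=n_bins)
        # real-time position of each bin's first millisecond
        bin_edges = np.arange(n_bins) * BIN_MS
        seg_idx = np.searchsorted(cum, bin_edges, side="right") - 1
        real_starts = np.array([segs[i][0] + (edge - cum[i])
                                for i, edge in zip(seg_idx, bin_edges)])
        ids.append(np.full(n_bins, bid))
        kinds.append(np.full(n_bins, block.kind, dtype=object))
        starts.append(real_starts)
        rates.append(counts.astype(float) * (1000.0 / BIN_MS))
    if not ids:
        return BaselineSeries(train.unit_id, np.empty(0, dtype=int),
                              np.empty(0, dtype=object), np.empty(0, dtype=int),
                              np.empty(0))
    return BaselineSeries(train.unit_id, np.concatenate(ids),
                          np.concatenate(kinds), np.concatenate(starts),
                          np.concatenate(rates))


def cohens_ds(x1, x2) -> float:
    """Cohen's d for independent samples (pooled n-1 SD in the denominator).

    Zero pooled SD with equal means returns 0; with unequal means the
    effect size is undefined and raises.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("cohens_ds needs >=2 samples per group")
    num = float(np.mean(x1) - np.mean(x2))
    pooled_var = (((n1 - 1) * np.var(x1, ddof=1) + (n2 - 1) * np.var(x2, ddof=1))
                  / (n1 + n2 - 2))
    if pooled_var == 0:
        if num == 0:
            return 0.0
        raise ValueError("pooled SD is 0 with unequal means: d_s undefined")
    return num / float(np.sqrt(pooled_var))


@dataclass(frozen=True)
class ContextResult:
    unit_id: str
    ds_GA: float   # grooming vs airflow (pooled blocks)
    ds_GG: float   # grooming block 1 vs 2
    ds_AA: float   # airflow block 1 vs 2
    label: str     # context_groom_up | context_groom_down | not_context
    n_bins_by_block: dict[int, int] = field(default_factory=dict)


def classify_from_effect_sizes(unit_id: str, ds_GA: float, ds_GG: float,
                               ds_AA: float,
                               n_bins_by_block: dict[int, int] | None = None
                               ) -> ContextResult:
    """Apply the classification rule to three already-computed effect sizes."""
    within = max(abs(ds_GG), abs(ds_AA))
    if abs(ds_GA) > DS_MIN and abs(ds_GA) >= DS_RATIO * within:
        label = "context_groom_up" if ds_GA > 0 else "context_groom_down"
    else:
        label = "not_context"
    return ContextResult(unit_id, float(ds_GA), float(ds_GG), float(ds_AA),
                         label, n_bins_by_block or {})


def classify_context(series: BaselineSeries,
                     min_bins: int = MIN_BINS_PER_BLOCK) -> ContextResult:
    """Compute d_GA, d_GG, d_AA on raw-Hz baseline bins and classify.

    Requires at least ``min_bins`` 1-s bins in each of two airflow and
    two grooming blocks; otherwise the unit is excluded
    (:class:`InsufficientDataError`).
    """
    af_ids = sorted({int(b) for b, k in zip(series.block_ids, series.block_kinds)
                     if k == "airflow"})[:2]
    gr_ids = sorted({int(b) for b, k in zip(series.block_ids, series.block_kinds)
                     if k == "grooming"})[:2]
    if len(af_ids) < 2 or len(gr_ids) < 2:
        raise InsufficientDataError(
            f"unit {series.unit_id}: needs two airflow and two grooming blocks")
    n_bins = {bid: len(series.rates_for_block(bid)) for bid in af_ids + gr_ids}
    short = {b: n for b, n in n_bins.items() if n < min_bins}
    if short:
        raise InsufficientDataError(
            f"unit {series.unit_id}: fewer than {min_bins} baseline bins in "
            f"block(s) {sorted(short)}: {short}")
    groom = np.concatenate([series.rates_for_block(b) for b in gr_ids])
    airflow = np.concatenate([series.rates_for_block(b) for b in af_ids])
    ds_GA = cohens_ds(groom, airflow)
    ds_GG = cohens_ds(series.rates_for_block(gr_ids[0]),
                      series.rates_for_block(gr_ids[1]))
    ds_AA = cohens_ds(series.rates_for_block(af_ids[0]),
                      series.rates_for_block(af_ids[1]))
    return classify_from_effect_sizes(series.unit_id, ds_GA, ds_GG, ds_AA, n_bins)


@dataclass(frozen=True)
class PairedStep:
    """Mean paired difference in Hz between two baseline conditions."""
    mean_hz: float
    sd_hz: float
    p_value: float
    n: int


def groomer_presence_effect(mean_hz_by_condition: dict[str, dict[str, float]]
                            ) -> dict[str, PairedStep]:
    """Paired steps across the three conditions for one group of units.

    ``mean_hz_by_condition`` maps unit_id -> dict with keys ``airflow``,
    ``airflow_groomer_present``, ``grooming`` holding the unit's mean
    baseline rate (raw Hz) in each condition.  Returns the two paired
    contrasts: ``presence`` (groomer-present vs groomer-absent airflow)
    and ``grooming`` (grooming vs groomer-present airflow), each with a
    paired t test across units.
    """
    units = sorted(mean_hz_by_condition)
    if len(units) < 2:
        raise InsufficientDataError("groomer_presence_effect needs >=2 units")
    a = np.array([mean_hz_by_condition[u]["airflow"] for u in units])
    gp = np.array([mean_hz_by_condition[u]["airflow_groomer_present"] for u in units])
    g = np.array([mean_hz_by_condition[u]["grooming"] for u in units])
    out = {}
    for name, x, y in (("presence", gp, a), ("grooming", g, gp)):
        d = x - y
        if np.std(d, ddof=1) == 0:
            p = 1.0 if d[0] == 0 else 0.0
        else:
            p = float(stats.ttest_rel(x, y).pvalue)
        out[name] = PairedStep(float(np.mean(d)), float(np.std(d, ddof=1)),
                               p, len(units))
    return out
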