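"""Stimulus-responsivity testing and tactile-response classification.

A unit is *responsive* at a (modality, location) when a two-sided paired
t test of per-trial pre- vs post-stimulus firing rates is significant at
p < 0.05 AND the mean rate change is at least 1 Hz in magnitude.  The
pre-stimulus window is 1000-250 ms before onset; the post window runs
from 200 ms after onset to stimulus offset (so variable-duration
grooming sweeps get variable windows; rates, not counts, are compared).

Tactile classification (airflow_only / grooming_only / both / none)
considers airflow responses only at locations that were also groomed,
so the two modalities are compared on the same patches of skin.  Sham
responsivity is assessed separately and never pooled with airflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .session import Session, SpikeTrain, StimulusEvent

PRE_WINDOW_MS = (1000, 250)   # before onset: [onset-1000, onset-250)
POST_START_MS = 200           # after onset: [onset+200, offset)
MIN_TRIALS = 10
ALPHA = 0.05
MIN_DELTA_HZ = 1.0
MIN_MEAN_RATE_HZ = 1.0


@dataclass(frozen=True)
class ResponseTest:
    unit_id: str
    location: int
    modality: str
    n_trials: int
    mean_pre_hz: float
    mean_post_hz: float
    delta_hz: float
    p_value: float
    responsive: bool


@dataclass(frozen=True)
class ResponsivityLabel:
    unit_id: str
    label: str  # airflow_only | grooming_only | both | none
    sham_responsive: bool


def _window_rate(train: SpikeTrain, start_ms: int, end_ms: int) -> float:
    t = train.spike_times_ms
    n = np.searchsorted(t, end_ms) - np.searchsorted(t, start_ms)
    return 1000.0 * n / (end_ms - start_ms)


def unit_inclusion(train: SpikeTrain, events: list[StimulusEvent],
                   extent_ms: int,
                   required_pairs: list[tuple[str, int]] | None = None) -> bool:
    """Inclusion rule: >=1 Hz mean rate over the session, stability flag set,
    and >=10 trials at every required (modality, location) pair.

    When ``required_pairs`` is None, every non-sham pair present in the
    event table must have at least 10 trials.
    """
    if not train.stable:
        return False
    if extent_ms <= 0:
        return False
    mean_rate = 1000.0 * len(train) / extent_ms
    if mean_rate < MIN_MEAN_RATE_HZ:
        return False
    counts: dict[tuple[str, int], int] = {}
    for e in events:
        counts[(e.modality, e.location)] = counts.get((e.modality, e.location), 0) + 1
    if required_pairs is None:
        required_pairs = [p for p in counts if p[0] != "sham"]
    return all(counts.get(p, 0) >= MIN_TRIALS for p in required_pairs)


def test_stimulus_response(train: SpikeTrain,
                           events: list[StimulusEvent]) -> ResponseTest:
    """Paired pre/post rate comparison across trials of one (modality, location)."""
    if len(events) < MIN_TRIALS:
        raise InsufficientDataError(
            f"unit {train.unit_id}: {len(events)} trials < {MIN_TRIALS}")
    mods = {e.modality for e in events}
    locs = {e.location for e in events}
    if len(mods) != 1 or len(locs) != 1:
        raise ValueError("events must share one modality and one location")
    pre = np.array([_window_rate(train, e.onset_ms - PRE_WINDOW_MS[0],
                                 e.onset_ms - PRE_WINDOW_MS[1]) for e in events])
    post = np.array([_window_rate(train, e.onset_ms + POST_START_MS,
                                  e.offset_ms) for e in events])
    diffs = post - pre
    if np.std(diffs, ddof=1) == 0:
        p = 1.0 if diffs[0] == 0 else 0.0
    else:
        p = float(stats.ttest_rel(post, pre).pvalue)
    delta = float(np.mean(post) - np.mean(pre))
    return ResponseTest(
        unit_id=train.unit_id, location=int(locs.pop()), modality=mods.pop(),
        n_trials=len(events), mean_pre_hz=float(np.mean(pre)),
        mean_post_hz=float(np.mean(post)), delta_hz=delta, p_value=p,
        responsive=bool(p < ALPHA and abs(delta) >= MIN_DELTA_HZ))


def test_unit_responses(train: SpikeTrain, events: list[StimulusEvent],
                        min_trials: int = MIN_TRIALS) -> list[ResponseTest]:
    """Run the response test at every (modality, location) with enough trials."""
    groups: dict[tuple[str, int], list[StimulusEvent]] = {}
    for e in events:
        groups.setdefault((e.modality, e.location), []).append(e)
    out = []
    for (mod, loc) in sorted(groups):
        if len(groups[(mod, loc)]) >= min_trials:
            out.append(test_stimulus_response(train, groups[(mod, loc)]))
    return out


def classify_tactile_responsivity(tests: list[ResponseTest],
                                  groomed_locations: list[int]
                                  ) -> ResponsivityLabel:
    """Label a unit from its per-location tests, restricted to groomed sites.

    ``both`` requires a responsive test in >=1 groomed location under each
    modality; otherwise airflow_only / grooming_only / none.  Sham is
    reported separately.
    """
    if not tests:
        raise ValueError("no tests supplied")
    unit_id = tests[0].unit_id
    groomed = set(groomed_locations)
    af = [t for t in tests if t.modality == "airflow" and t.location in groomed]
    gr = [t for t in tests if t.modality == "grooming" and t.location in groomed]
    if not af or not gr:
        raise ValueError(
            f"unit {unit_id}: need airflow and grooming tests at groomed locations")
    af_resp = any(t.responsive for t in af)
    gr_resp = any(t.responsive for t in gr)
    label = {(True, True): "both", (True, False): "airflow_only",
             (False, True): "grooming_only", (False, False): "none"}[(af_resp, gr_resp)]
    sham = any(t.responsive for t in tests if t.modality == "sham")
    return ResponsivityLabel(unit_id=unit_id, label=label, sham_responsive=sham)


def compare_proportions(k1: int, n1: int, k2: int, n2: int
                        ) -> tuple[float, float]:
    """Chi-squared test of two proportions on the 2x2 table, no continuity
    correction.

    Returns ``(chi2, p)``.  Degenerate margins (all successes or all
    failures pooled) give chi2 = 0, p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    a, b = k1, n1 - k1
    c, d = k2, n2 - k2
    n = n1 + n2
    m1, m0 = a + c, b + d  # success / failure margins
    if m1 == 0 or m0 == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / (n1 * n2 * m1 * m0)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
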