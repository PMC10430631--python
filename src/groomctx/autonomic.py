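"""Heart-rate processing, RSA spectral analysis, and high-heart-rate
episode detection.

Instantaneous heart rate is 60000/IBI (BPM) per inter-beat interval.
IBIs outside the biologically plausible open interval (250, 1500) ms —
i.e. heart rates outside (40, 240) BPM — are masked as artifacts; the
retained values are interpolated to a 1-ms grid with a modified Akima
cubic Hermite scheme.

Heart-rate variability is estimated in sliding 60-s windows with a 3-s
step using a multitaper power spectral density with 7 Slepian (DPSS)
tapers (time-bandwidth product NW = 4, so K = 2NW-1 = 7 and the
smoothing half-bandwidth is NW/T = 4/60 ~ 0.067 Hz, within the nominal
+-0.07 Hz).  The respiratory sinus arrhythmia (RSA) band is
0.25-0.5 Hz (15-30 breaths/min); per window, RSA strength is the mean
power within +- one half-bandwidth of the in-band spectral peak,
normalized across windows as (strength - mu)/mu with mu the median
strength over all time steps.

High-heart-rate episodes are maximal spans within grooming blocks where
HR exceeds the stable-period mean by more than 2 SD for at least 10 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.interpolate import Akima1DInterpolator
from scipy.signal.windows import dpss

from .errors import InsufficientDataError
from .session import Block, HeartTrace, SpikeTrain, StimulusEvent
from .responsivity import ResponseTest, test_stimulus_response

IBI_BOUNDS_MS = (250.0, 1500.0)  # exclusive retention bounds
HR_BOUNDS_BPM = (40.0, 240.0)
SPEC_WINDOW_S = 60.0
SPEC_STEP_S = 3.0
N_TAPERS = 7
NW = 4.0                         # time-bandwidth product; K = 2*NW - 1
SPEC_FS_HZ = 4.0                 # analysis sampling rate for the PSD
RSA_BAND_HZ = (0.25, 0.5)
EPISODE_SD_FACTOR = 2.0
EPISODE_MIN_MS = 10_000
STABLE_RANGE_MIN = (6.0, 20.0)   # minutes


def half_bandwidth_hz(window_s: float = SPEC_WINDOW_S, nw: float = NW) -> float:
    """Multitaper smoothing half-bandwidth W = NW/T in Hz."""
    return nw / window_s


@dataclass(eq=False)
class HeartSeries:
    """Cleaned IBIs plus instantaneous HR interpolated to a 1-ms grid."""

    ibi_end_times_ms: np.ndarray   # time of each retained IBI's closing R wave
    ibis_ms: np.ndarray            # retained IBI durations
    hr_bpm: np.ndarray             # 1-ms grid over [t0_ms, t0_ms + len)
    t0_ms: int
    artifact_spans: list[tuple[int, int]]  # rejected-IBI spans, half-open ms

    @property
    def hr_at_beats(self) -> np.ndarray:
        return 60000.0 / self.ibis_ms

    def hr_in_span(self, start_ms: int, end_ms: int) -> np.ndarray:
        lo = max(int(start_ms) - self.t0_ms, 0)
        hi = min(int(end_ms) - self.t0_ms, len(self.hr_bpm))
        return self.hr_bpm[lo:hi] if hi > lo else np.empty(0)


@dataclass(eq=False)
class Spectrogram:
    window_centers_s: np.ndarray
    freqs_hz: np.ndarray
    psd: np.ndarray  # (n_windows, n_freqs)
    half_bandwidth_hz: float

    @property
    def empty(self) -> bool:
        return self.psd.size == 0


@dataclass(eq=False)
class RSASeries:
    window_centers_s: np.ndarray
    peak_freq_hz: np.ndarray     # NaN where no in-band local maximum
    rsa_strength: np.ndarray
    rsa_norm: np.ndarray         # (strength - median) / median


@dataclass(frozen=True)
class Episode:
    start_ms: int
    end_ms: int
    mean_hr_bpm: float
    stable_mean_bpm: float
    stable_sd_bpm: float

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.start_ms


def instantaneous_hr(heart: HeartTrace) -> HeartSeries:
    """IBIs -> artifact-masked instantaneous HR on a 1-ms grid."""
    t = np.asarray(heart.r_wave_times_ms, dtype=float)
    if len(t) < 2:
        raise InsufficientDataError("need >= 2 R waves")
    ibis = np.diff(t)
    ok = (ibis > IBI_BOUNDS_MS[0]) & (ibis < IBI_BOUNDS_MS[1])
    if not np.any(ok):
        raise InsufficientDataError("all inter-beat intervals rejected as artifacts")
    end_times = t[1:][ok]
    kept = ibis[ok]
    artifact_spans = [(int(t[i]), int(t[i + 1]))
                      for i in np.flatnonzero(~ok)]
    hr = 60000.0 / kept
    t0 = int(np.ceil(end_times[0]))
    t1 = int(np.floor(end_times[-1]))
    grid = np.arange(t0, t1 + 1, dtype=float)
    if len(kept) < 3:
        hr_grid = np.interp(grid, end_times, hr)
    else:
        interp = Akima1DInterpolator(end_times, hr, method="makima")
        hr_grid = interp(grid)
    return HeartSeries(end_times.astype(np.int64), kept, hr_grid, t0,
                       artifact_spans)


def block_hr_comparison(sessions: list[tuple[HeartSeries, list[Block]]],
                        kinds: tuple[str, str] = ("airflow", "grooming")
                        ) -> dict:
    """Per-session mean HR per block kind, compared with a paired t test
    across sessions.  A single session yields descriptive means only."""
    if not sessions:
        raise InsufficientDataError("no sessions supplied")
    means = {k: [] for k in kinds}
    for hs, blocks in sessions:
        for k in kinds:
            vals = [hs.hr_in_span(b.start_ms, b.end_ms)
                    for b in blocks if b.kind == k]
            vals = [v for v in vals if len(v)]
            if not vals:
                raise InsufficientDataError(f"no HR samples in {k} blocks")
            means[k].append(float(np.mean(np.concatenate(vals))))
    out = {f"mean_{k}_bpm": float(np.mean(means[k])) for k in kinds}
    out["per_session"] = {k: means[k] for k in kinds}
    out["n_sessions"] = len(sessions)
    if len(sessions) >= 2:
        d = np.asarray(means[kinds[0]]) - np.asarray(means[kinds[1]])
        if np.std(d, ddof=1) < 1e-9:  # degenerate: (near-)identical sessions
            out["t"], out["p"] = 0.0, 1.0
        else:
            res = stats.ttest_rel(means[kinds[0]], means[kinds[1]])
            out["t"] = float(res.statistic)
            out["p"] = float(res.pvalue)
    return out


def hr_spectrogram(series: HeartSeries, fs_hz: float = SPEC_FS_HZ,
                   window_s: float = SPEC_WINDOW_S,
                   step_s: float = SPEC_STEP_S) -> Spectrogram:
    """Sliding-window multitaper PSD of the mean-removed instantaneous HR.

    The 1-ms HR series is decimated to ``fs_hz`` (4 Hz resolves the
    0-0.5 Hz RSA band with margin) before estimation.
    """
    stride = int(round(1000.0 / fs_hz))
    x = series.hr_bpm[::stride]
    n_win = int(round(window_s * fs_hz))
    n_step = int(round(step_s * fs_hz))
    freqs = np.fft.rfftfreq(n_win, d=1.0 / fs_hz)
    if len(x) < n_win:
        return Spectrogram(np.empty(0), freqs, np.empty((0, len(freqs))),
                           half_bandwidth_hz(window_s))
    tapers = dpss(n_win, NW, N_TAPERS)  # (K, n_win), unit-energy tapers
    starts = np.arange(0, len(x) - n_win + 1, n_step)
    psd = np.empty((len(starts), len(freqs)))
    for i, s0 in enumerate(starts):
        seg = x[s0:s0 + n_win]
        seg = seg - seg.mean()
        spec = np.fft.rfft(tapers * seg, axis=1)
        p = (np.abs(spec) ** 2) / fs_hz
        p[:, 1:-1] *= 2.0  # one-sided
        psd[i] = p.mean(axis=0)
    centers_s = (series.t0_ms / 1000.0) + (starts + n_win / 2.0) / fs_hz
    return Spectrogram(centers_s, freqs, psd, half_bandwidth_hz(window_s))


def rsa_strength(spec: Spectrogram,
                 band_hz: tuple[float, float] = RSA_BAND_HZ) -> RSASeries:
    """Per-window RSA strength: mean power within one half-bandwidth of
    the largest in-band local maximum (ties toward lower frequency).

    Windows with no in-band local maximum fall back to the band mean and
    carry ``peak_freq_hz = NaN``.  ``rsa_norm`` is (strength - mu)/mu
    with mu the median strength across windows.
    """
    if spec.empty:
        raise InsufficientDataError("empty spectrogram")
    f = spec.freqs_hz
    in_band = (f >= band_hz[0]) & (f <= band_hz[1])
    w = spec.half_bandwidth_hz
    peaks = np.full(len(spec.psd), np.nan)
    strength = np.empty(len(spec.psd))
    for i, p in enumerate(spec.psd):
        local = np.flatnonzero(in_band[1:-1]
                               & (p[1:-1] >= p[:-2]) & (p[1:-1] >= p[2:])) + 1
        if len(local):
            best = local[np.argmax(p[local])]
            # argmax returns the first (lowest-frequency) maximal bin
            peaks[i] = f[best]
            sel = (f >= f[best] - w) & (f <= f[best] + w)
        else:
            sel = in_band
        strength[i] = float(np.mean(p[sel]))
    mu = float(np.median(strength))
    norm = (strength - mu) / mu if mu > 0 else np.zeros_like(strength)
    return RSASeries(spec.window_centers_s, peaks, strength, norm)


def select_stable_period(series: HeartSeries,
                         grooming_spans: list[tuple[int, int]]
                         ) -> tuple[int, int]:
    """Longest artifact-free grooming span with HR within +-2 SD of its
    own mean, clipped to 6-20 minutes."""
    best: tuple[int, int] | None = None
    for (s, e) in grooming_spans:
        s = max(int(s), series.t0_ms)
        e = min(int(e), series.t0_ms + len(series.hr_bpm))
        for (a_s, a_e) in series.artifact_spans:
            # split around artifacts: keep the pre-artifact part
            if a_s < e and a_e > s:
                e = max(s, a_s)
        if e - s <= 0:
            continue
        hr = series.hr_in_span(s, e)
        m, sd = float(np.mean(hr)), float(np.std(hr))
        if sd > 0:
            ok = np.abs(hr - m) <= 2 * sd
            # trim to the longest run of within-band samples
            run_s, run_e = _longest_true_run(ok)
            s, e = s + run_s, s + run_e
        max_ms = int(STABLE_RANGE_MIN[1] * 60000)
        if e - s > max_ms:
            e = s + max_ms
        if best is None or (e - s) > (best[1] - best[0]):
            best = (s, e)
    if best is None or best[1] - best[0] <= 0:
        raise InsufficientDataError("no stable grooming period available")
    return best


def _longest_true_run(mask: np.ndarray) -> tuple[int, int]:
    if not np.any(mask):
        return 0, 0
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    i = np.argmax(ends - starts)
    return int(starts[i]), int(ends[i])


def detect_high_hr_episodes(series: HeartSeries,
                            grooming_spans: list[tuple[int, int]],
                            stable_period: tuple[int, int] | None = None
                            ) -> list[Episode]:
    """Maximal >=10 s spans within grooming where HR > stable mean + 2 SD."""
    if stable_period is None:
        stable_period = select_stable_period(series, grooming_spans)
    stable_hr = series.hr_in_span(*stable_period)
    if len(stable_hr) == 0:
        raise InsufficientDataError("stable period has no HR samples")
    m, sd = float(np.mean(stable_hr)), float(np.std(stable_hr))
    thresh = m + EPISODE_SD_FACTOR * sd
    episodes: list[Episode] = []
    for (s, e) in grooming_spans:
        s = max(int(s), series.t0_ms)
        e = min(int(e), series.t0_ms + len(series.hr_bpm))
        if e <= s:
            continue
        hr = series.hr_in_span(s, e)
        above = hr > thresh
        padded = np.concatenate([[False], above, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        for run_s, run_e in zip(edges[::2], edges[1::2]):
            if run_e - run_s >= EPISODE_MIN_MS:
                episodes.append(Episode(
                    start_ms=s + int(run_s), end_ms=s + int(run_e),
                    mean_hr_bpm=float(np.mean(hr[run_s:run_e])),
                    stable_mean_bpm=m, stable_sd_bpm=sd))
    return episodes


def grooming_response_during_episodes(train: SpikeTrain,
                                      grooming_events: list[StimulusEvent],
                                      episodes: list[Episode]
                                      ) -> ResponseTest | None:
    """Stimulus-response test restricted to sweeps whose onsets fall in a
    high-HR episode; None when fewer than 10 such sweeps exist."""
    in_ep = [e for e in grooming_events
             if any(ep.start_ms <= e.onset_ms < ep.end_ms for ep in episodes)]
    if len(in_ep) < 10:
        return None
    # pool across locations: episode sweep counts are small
    loc = in_ep[0].location
    pooled = [StimulusEvent(e.event_id, e.block_id, e.modality, loc,
                            e.onset_ms, e.offset_ms) for e in in_ep]
    return test_stimulus_response(train, pooled)
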