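"""Orchestration: simulate -> responsivity -> context -> decoding ->
autonomic, with a run manifest, exclusion logging, and CSV/JSON outputs.

All statistics are reported raw (no multiple-comparison correction),
matching the analysis conventions of the upstream modules; resampling
counts default to desk-scale values (1,000 permutations / 500
bootstraps) with ``full=True`` restoring 10,000.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .autonomic import (detect_high_hr_episodes, grooming_response_during_episodes,
                        hr_spectrogram, instantaneous_hr, rsa_strength)
from .baseline import (classify_context, context_analysis_block_ids,
                       extract_baseline_bins)
from .decoding import (DecodingResult, decode_unit, population_curve,
                       accuracy_rate_correlation, z_rate_difference)
from .errors import GroomctxError, InsufficientDataError
from .responsivity import (classify_tactile_responsivity, test_unit_responses,
                           unit_inclusion)
from .session import Session, read_session, write_session
from .synth import SessionConfig, generate_session

log = logging.getLogger("groomctx")

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """One reproducible run: where the session comes from, which stages
    run, and the resampling scale."""

    out_dir: str | Path
    session_config: SessionConfig | None = None
    session_path: str | Path | None = None
    seed: int = 0
    run_responsivity: bool = True
    run_context: bool = True
    run_decoding: bool = True
    run_autonomic: bool = True
    n_perm: int = 1000
    n_boot: int = 500
    full: bool = False
    population_set_sizes: list[int] | None = None
    decoding_threshold: float = 0.95

    def resolved_counts(self) -> tuple[int, int]:
        return (10000, 10000) if self.full else (self.n_perm, self.n_boot)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def _load_session(config: RunConfig) -> Session:
    if config.session_config is not None:
        return generate_session(config.session_config)
    if config.session_path is not None:
        return read_session(config.session_path)
    raise ValueError("RunConfig needs session_config or session_path")


def summarize_overlap(context_labels: dict[str, str],
                      decoding: dict[str, DecodingResult]) -> dict[str, int]:
    """Four-way counts of effect-size vs SVM context detection.

    Keys: ``both``, ``svm_only``, ``effect_size_only``, ``neither``.
    The two result sets must cover the same units.
    """
    if set(context_labels) != set(decoding):
        raise ValueError("context and decoding results cover different units")
    counts = {"both": 0, "svm_only": 0, "effect_size_only": 0, "neither": 0}
    for uid, label in context_labels.items():
        es = label != "not_context"
        svm = decoding[uid].significant
        key = {(True, True): "both", (True, False): "svm_only",
               (False, True): "effect_size_only", (False, False): "neither"}[(svm, es)]
        counts[key] += 1
    return counts


def run_all(config: RunConfig) -> dict:
    """Run every enabled stage on one session and write outputs to
    ``config.out_dir``.  Returns the summary report (also written as
    ``summary.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_perm, n_boot = config.resolved_counts()
    session = _load_session(config)
    if config.session_config is not None:
        write_session(session, out / "session")
    manifest = {
        "groomctx_version": __version__,
        "seed": int(config.seed),
        "n_perm": n_perm,
        "n_boot": n_boot,
        "session_id": session.session_id,
        "session_source": ("generated" if config.session_config is not None
                           else str(config.session_path)),
        "stages": {"responsivity": config.run_responsivity,
                   "context": config.run_context,
                   "decoding": config.run_decoding,
                   "autonomic": config.run_autonomic},
        "session_config": (config.session_config.to_dict()
                           if config.session_config is not None else None),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")

    summary: dict = {"session_id": session.session_id, "exclusions": {}}
    groomed_locations = sorted({e.location for e in session.events
                                if e.modality == "grooming"})

    included = []
    for u in session.units:
        if unit_inclusion(u, session.events, session.extent_ms):
            included.append(u)
        else:
            summary["exclusions"][u.unit_id] = "rate floor / trial count / stability"
            log.info("excluded %s: rate floor, trial count, or stability", u.unit_id)
    summary["n_units"] = len(session.units)
    summary["n_included"] = len(included)

    # ---- responsivity -----------------------------------------------------
    if config.run_responsivity:
        rows = []
        label_counts: dict[str, int] = {}
        for u in included:
            tests = test_unit_responses(u, session.events)
            try:
                lab = classify_tactile_responsivity(tests, groomed_locations)
            except ValueError:
                summary["exclusions"][u.unit_id] = "missing modality tests"
                continue
            for t in tests:
                rows.append(dict(unit_id=t.unit_id, region=u.region,
                                 location=t.location, modality=t.modality,
                                 mean_pre_hz=t.mean_pre_hz,
                                 mean_post_hz=t.mean_post_hz,
                                 delta_hz=t.delta_hz, p=t.p_value,
                                 responsive=t.responsive, label=lab.label,
                                 sham_responsive=lab.sham_responsive))
            label_counts[lab.label] = label_counts.get(lab.label, 0) + 1
        _write_csv(pd.DataFrame(rows), out / "responses.csv")
        summary["responsivity_labels"] = dict(sorted(label_counts.items()))

    # ---- baseline context -------------------------------------------------
    context_results = {}
    series_by_unit = {}
    if config.run_context or config.run_decoding:
        try:
            ctx_blocks = context_analysis_block_ids(session)
        except InsufficientDataError as err:
            ctx_blocks = None
            log.info("context analysis skipped: %s", err)
        if ctx_blocks is not None:
            for u in included:
                series = extract_baseline_bins(session, u, ctx_blocks)
                series_by_unit[u.unit_id] = series
                if config.run_context:
                    try:
                        context_results[u.unit_id] = classify_context(series)
                    except InsufficientDataError as err:
                        summary["exclusions"][u.unit_id] = "bin count"
                        log.info("context exclusion: %s", err)
    if config.run_context and context_results:
        df = pd.DataFrame([
            dict(unit_id=r.unit_id,
                 **{f"n_bins_block{b}": n for b, n in sorted(r.n_bins_by_block.items())},
                 ds_GA=r.ds_GA, ds_GG=r.ds_GG, ds_AA=r.ds_AA, label=r.label)
            for r in context_results.values()])
        _write_csv(df, out / "context.csv")
        counts = {"context_groom_up": 0, "context_groom_down": 0, "not_context": 0}
        for r in context_results.values():
            counts[r.label] += 1
        summary["context_labels"] = counts

    # ---- decoding ---------------------------------------------------------
    if config.run_decoding and series_by_unit:
        dec_results: dict[str, DecodingResult] = {}
        z_diffs: dict[str, float] = {}
        rows = []
        usable = {uid: s for uid, s in series_by_unit.items()
                  if uid in context_results}
        for i, (uid, series) in enumerate(sorted(usable.items())):
            res = decode_unit(series, n_perm=n_perm,
                              seed=np.random.SeedSequence([config.seed, 10, i]))
            dec_results[uid] = res
            z_diffs[uid] = z_rate_difference(series)
            rows.append(dict(unit_id=uid, cv_accuracy=res.cv_accuracy,
                             null_mean=res.null_mean,
                             null_ci_upper=res.null_ci_upper,
                             significant=res.significant, z_diff=z_diffs[uid]))
        _write_csv(pd.DataFrame(rows), out / "decoding.csv")
        summary["n_svm_significant"] = sum(r.significant
                                           for r in dec_results.values())
        if config.run_context and dec_results:
            labels = {uid: context_results[uid].label for uid in dec_results}
            summary["overlap"] = summarize_overlap(labels, dec_results)
        if len(dec_results) >= 3:
            rho_neg, rho_pos = accuracy_rate_correlation(
                [dec_results[u].cv_accuracy for u in sorted(dec_results)],
                [z_diffs[u] for u in sorted(dec_results)])
            summary["accuracy_z_correlation"] = {"neg": rho_neg, "pos": rho_pos}
        if len(usable) >= 1:
            sizes = (config.population_set_sizes
                     or list(range(1, len(usable) + 1)))
            curve = population_curve(
                [usable[u] for u in sorted(usable)], set_sizes=sizes,
                n_boot=n_boot, threshold=config.decoding_threshold,
                seed=np.random.SeedSequence([config.seed, 11]))
            _write_csv(pd.DataFrame(dict(
                set_size=curve.set_sizes, mean_accuracy=curve.mean_accuracy,
                ci_lower=curve.ci_lower, ci_upper=curve.ci_upper)),
                out / "population_curve.csv")
            summary["population_min_n"] = curve.min_n_for_threshold
            (out / "population_summary.json").write_text(json.dumps(
                {"threshold": config.decoding_threshold,
                 "min_n_for_threshold": curve.min_n_for_threshold},
                indent=2, sort_keys=True) + "\n", encoding="utf-8")

    # ---- autonomic --------------------------------------------------------
    if config.run_autonomic and session.heart is not None:
        hs = instantaneous_hr(session.heart)
        hr_rows = []
        for b in session.blocks:
            hr = hs.hr_in_span(b.start_ms, b.end_ms)
            hr_rows.append(dict(block_id=b.block_id, kind=b.kind,
                                mean_hr_bpm=float(np.mean(hr)) if len(hr) else np.nan,
                                sd_hr_bpm=float(np.std(hr)) if len(hr) else np.nan))
        _write_csv(pd.DataFrame(hr_rows), out / "hr.csv")
        summary["hr_by_kind"] = {}
        for kind in {b.kind for b in session.blocks}:
            vals = np.concatenate([hs.hr_in_span(b.start_ms, b.end_ms)
                                   for b in session.blocks if b.kind == kind])
            summary["hr_by_kind"][kind] = float(np.mean(vals))
        spec = hr_spectrogram(hs)
        if not spec.empty:
            rsa = rsa_strength(spec)
            _write_csv(pd.DataFrame(dict(
                window_center_s=rsa.window_centers_s,
                peak_freq_hz=rsa.peak_freq_hz,
                rsa_strength=rsa.rsa_strength, rsa_norm=rsa.rsa_norm)),
                out / "rsa.csv")
            block_of = np.full(len(rsa.window_centers_s), "", dtype=object)
            for b in session.blocks:
                in_b = ((rsa.window_centers_s * 1000 >= b.start_ms)
                        & (rsa.window_centers_s * 1000 < b.end_ms))
                block_of[in_b] = b.kind
            summary["rsa_norm_by_kind"] = {
                kind: float(np.mean(rsa.rsa_norm[block_of == kind]))
                for kind in {b.kind for b in session.blocks}
                if np.any(block_of == kind)}
        grooming_spans = [(b.start_ms, b.end_ms)
                          for b in session.blocks if b.kind == "grooming"]
        episodes = []
        if grooming_spans:
            try:
                episodes = detect_high_hr_episodes(hs, grooming_spans)
            except InsufficientDataError as err:
                log.info("episode detection skipped: %s", err)
        _write_csv(pd.DataFrame([
            dict(start_ms=e.start_ms, end_ms=e.end_ms,
                 mean_hr_bpm=e.mean_hr_bpm, stable_mean_bpm=e.stable_mean_bpm,
                 stable_sd_bpm=e.stable_sd_bpm) for e in episodes]),
            out / "episodes.csv")
        summary["n_high_hr_episodes"] = len(episodes)
        grooming_events = [e for e in session.events if e.modality == "grooming"]
        ep_resp = {}
        for u in included:
            res = grooming_response_during_episodes(u, grooming_events, episodes)
            if res is not None:
                ep_resp[u.unit_id] = bool(res.responsive)
        summary["episode_grooming_responsive"] = ep_resp

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return summary
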