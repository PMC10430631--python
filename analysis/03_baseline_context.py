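#!/usr/bin/env python
"""Context-related baseline modulation and the groomer-presence effect.

Computes the three Cohen's d_s effect sizes per unit (grooming vs
airflow, and the two within-condition controls), classifies units as
context-related, and — on the groomer-present session — measures the
paired baseline steps airflow -> airflow-with-groomer -> grooming for
the groom-up and groom-down groups.

Writes results/context/{context.csv,groomer_presence.json}.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from groomctx.baseline import (classify_context, context_analysis_block_ids,
                               extract_baseline_bins, groomer_presence_effect)
from groomctx.errors import InsufficientDataError
from groomctx.pipeline import RunConfig, run_all
from groomctx.session import read_session

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--sessions", type=Path, default=ROOT / "results" / "sessions")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "context")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    run_all(RunConfig(out_dir=args.out, session_path=args.sessions / "standard",
                      seed=args.seed, run_responsivity=False,
                      run_decoding=False, run_autonomic=False))
    summary = json.loads((args.out / "summary.json").read_text())
    labels = summary["context_labels"]
    print("context classification (standard session):", labels)

    # groomer-presence analysis on the session with the groomer-present block
    session = read_session(args.sessions / "groomer_present")
    ctx_ids = context_analysis_block_ids(session)
    groups: dict[str, dict[str, dict[str, float]]] = {"up": {}, "down": {}}
    for u in session.units:
        series4 = extract_baseline_bins(session, u, ctx_ids)
        try:
            res = classify_context(series4)
        except InsufficientDataError:
            continue
        if res.label == "not_context":
            continue
        grp = "up" if res.label == "context_groom_up" else "down"
        all_series = extract_baseline_bins(session, u)
        groups[grp][u.unit_id] = {
            kind: float(np.mean(all_series.rates_for_kind(kind)))
            for kind in ("airflow", "airflow_groomer_present", "grooming")}

    out = {}
    for grp, means in groups.items():
        if len(means) < 2:
            print(f"groom-{grp} group too small (n={len(means)}); skipped")
            continue
        steps = groomer_presence_effect(means)
        out[grp] = {name: dict(mean_hz=s.mean_hz, sd_hz=s.sd_hz,
                               p=s.p_value, n=s.n)
                    for name, s in steps.items()}
        print(f"groom-{grp} (n={steps['presence'].n}): "
              f"groomer presence {steps['presence'].mean_hz:+.2f} Hz "
              f"(p={steps['presence'].p_value:.3g}), "
              f"grooming {steps['grooming'].mean_hz:+.2f} Hz "
              f"(p={steps['grooming'].p_value:.3g})")
    (args.out / "groomer_presence.json").write_text(
        json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
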