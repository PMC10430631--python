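#!/usr/bin/env python
"""Autonomic state during grooming vs airflow.

Across the seven EKG sessions: paired t test of mean heart rate per
condition.  On the standard session: RSA spectrogram and normalized RSA
strength per block kind, high-heart-rate episode detection, and the
grooming-responsivity check during those episodes.

Writes results/autonomic/{hr_by_session.csv,summary.json} plus the
standard-session hr/rsa/episodes CSVs.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from groomctx.autonomic import block_hr_comparison, instantaneous_hr
from groomctx.pipeline import RunConfig, run_all
from groomctx.session import read_session

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--sessions", type=Path, default=ROOT / "results" / "sessions")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "autonomic")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    pairs = []
    for d in sorted(args.sessions.glob("heart_*")):
        s = read_session(d)
        pairs.append((instantaneous_hr(s.heart), s.blocks))
    res = block_hr_comparison(pairs)
    print(f"heart rate across {res['n_sessions']} sessions: "
          f"airflow {res['mean_airflow_bpm']:.1f} BPM, "
          f"grooming {res['mean_grooming_bpm']:.1f} BPM "
          f"(paired t = {res['t']:.2f}, p = {res['p']:.2g})")
    pd.DataFrame(res["per_session"]).to_csv(args.out / "hr_by_session.csv",
                                            index=False, lineterminator="\n")

    run_all(RunConfig(out_dir=args.out / "standard",
                      session_path=args.sessions / "standard", seed=args.seed,
                      run_responsivity=False, run_context=False,
                      run_decoding=False))
    summary = json.loads((args.out / "standard" / "summary.json").read_text())
    print("mean HR by block kind (standard session):",
          {k: round(v, 1) for k, v in summary["hr_by_kind"].items()})
    print("normalized RSA strength by block kind:",
          {k: round(v, 3) for k, v in summary.get("rsa_norm_by_kind", {}).items()})
    print(f"high-HR episodes in grooming: {summary['n_high_hr_episodes']}")

    out = {"across_sessions": {k: v for k, v in res.items()
                               if k != "per_session"},
           "standard_session": {k: summary[k] for k in
                                ("hr_by_kind", "rsa_norm_by_kind",
                                 "n_high_hr_episodes")
                                if k in summary}}
    (args.out / "summary.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
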