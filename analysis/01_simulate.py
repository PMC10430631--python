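#!/usr/bin/env python
"""Generate the synthetic sessions used by the downstream analyses.

Writes to results/sessions/:
  standard/        5-block airflow/grooming session, 11 units, EKG
  groomer_present/ variant with an airflow-with-groomer-present block,
                   for the groomer-presence baseline analysis
  heart_XX/        7 light sessions (no units) with jittered heart rates,
                   for the across-session paired HR comparison
"""

import argparse
from pathlib import Path

import numpy as np

from groomctx.session import write_session
from groomctx.synth import HeartSpec, demo_config, generate_session

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "sessions")
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    standard = generate_session(demo_config(seed=args.seed))
    write_session(standard, out / "standard")
    print(f"standard: {len(standard.units)} units, "
          f"{len(standard.events)} events, {standard.extent_ms / 60000:.1f} min")

    gp = demo_config(seed=args.seed + 1)
    gp.block_kinds = ("airflow", "grooming", "airflow_groomer_present",
                      "grooming", "airflow")
    gp.session_id = f"demo-groomer-present-{args.seed + 1}"
    write_session(generate_session(gp), out / "groomer_present")
    print("groomer_present: airflow block with the groomer in the booth")

    rng = np.random.default_rng(args.seed)
    for i in range(7):
        cfg = demo_config(seed=args.seed + 10 + i, n_null=0, n_ctx_up=0,
                          n_ctx_down=0, n_airflow_resp=0, n_grooming_resp=0)
        cfg.units = []
        hr_air = 110.0 + rng.normal(0, 4)
        cfg.heart = HeartSpec(
            mean_hr_by_context={"airflow": hr_air,
                                "grooming": hr_air - 12 + rng.normal(0, 2),
                                "airflow_groomer_present": hr_air},
            rsa_depth_by_context={"airflow": 0.02, "grooming": 0.10,
                                  "airflow_groomer_present": 0.02})
        cfg.session_id = f"heart-{i}"
        write_session(generate_session(cfg), out / f"heart_{i:02d}")
    print("heart_00..heart_06: EKG-only sessions for the paired HR test")


if __name__ == "__main__":
    main()
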