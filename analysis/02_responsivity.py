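#!/usr/bin/env python
"""Stimulus responsivity of the simulated population.

Tests every included unit at each (modality, location), labels tactile
responsivity (airflow-only / grooming-only / both / none, sham
separately), and compares responsive proportions between the standard
and groomer-present sessions with the chi-squared test of proportions.

Writes results/responsivity/{responses.csv,summary.json}.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from groomctx.pipeline import RunConfig, run_all
from groomctx.responsivity import compare_proportions

ROOT = Path(__file__).resolve().parents[1]


def _label_counts(out_dir: Path, session_dir: Path, seed: int) -> dict:
    run_all(RunConfig(out_dir=out_dir, session_path=session_dir, seed=seed,
                      run_context=False, run_decoding=False,
                      run_autonomic=False))
    return json.loads((out_dir / "summary.json").read_text())


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--sessions", type=Path, default=ROOT / "results" / "sessions")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "responsivity")
    args = ap.parse_args()

    std = _label_counts(args.out / "standard", args.sessions / "standard",
                        args.seed)
    gp = _label_counts(args.out / "groomer_present",
                       args.sessions / "groomer_present", args.seed)

    print("responsivity labels (standard):", std["responsivity_labels"])
    print("responsivity labels (groomer present):", gp["responsivity_labels"])

    def _airflow_responsive(s):
        lab = s["responsivity_labels"]
        return lab.get("airflow_only", 0) + lab.get("both", 0), s["n_included"]

    k1, n1 = _airflow_responsive(std)
    k2, n2 = _airflow_responsive(gp)
    chi2, p = compare_proportions(k1, n1, k2, n2)
    print(f"airflow-responsive: {k1}/{n1} (standard) vs {k2}/{n2} "
          f"(groomer present); chi2 = {chi2:.3f}, p = {p:.3f}")

    df = pd.read_csv(args.out / "standard" / "responses.csv")
    sham = df[df.modality == "sham"]
    print(f"sham-responsive units: "
          f"{sham[sham.responsive].unit_id.nunique()} of {df.unit_id.nunique()}")

    summary = {"standard": std["responsivity_labels"],
               "groomer_present": gp["responsivity_labels"],
               "airflow_proportion_chi2": chi2, "airflow_proportion_p": p}
    (args.out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")


if __name__ == "__main__":
    main()
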