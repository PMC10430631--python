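#!/usr/bin/env python
"""Decode context from baseline firing with a linear SVM.

Per unit: balanced 10-fold CV accuracy against its own permutation
null.  Population: bootstrap pseudo-population accuracy vs set size and
the minimum set size for 95% decoding; PCA/k-means separability; the
four-way overlap between effect-size and SVM criteria.

Writes results/decoding/{decoding.csv,population_curve.csv,summary.json}.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from groomctx.baseline import context_analysis_block_ids, extract_baseline_bins
from groomctx.decoding import pca_separability
from groomctx.pipeline import RunConfig, run_all
from groomctx.session import read_session

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--nperm", type=int, default=500)
    ap.add_argument("--nboot", type=int, default=200)
    ap.add_argument("--full", action="store_true",
                    help="use 10,000 permutations/bootstraps")
    ap.add_argument("--sessions", type=Path, default=ROOT / "results" / "sessions")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "decoding")
    args = ap.parse_args()

    run_all(RunConfig(out_dir=args.out, session_path=args.sessions / "standard",
                      seed=args.seed, n_perm=args.nperm, n_boot=args.nboot,
                      full=args.full, run_responsivity=False,
                      run_autonomic=False))
    summary = json.loads((args.out / "summary.json").read_text())
    print(f"SVM-significant units: {summary['n_svm_significant']} "
          f"of {sum(summary['overlap'].values())}")
    print("overlap with effect-size criteria:", summary["overlap"])
    print("accuracy vs Z-difference correlations:",
          summary.get("accuracy_z_correlation"))
    print(f"minimum set size for >95% decoding: "
          f"{summary.get('population_min_n')}")

    # PCA separability of the pseudo-population (60 bins/block per unit)
    session = read_session(args.sessions / "standard")
    ctx_ids = context_analysis_block_ids(session)
    rng = np.random.default_rng(args.seed)
    cols, labels = [], None
    for u in session.units:
        s = extract_baseline_bins(session, u, ctx_ids)
        rows, labs = [], []
        for kind in ("airflow", "grooming"):
            ids = sorted({int(b) for b, k in zip(s.block_ids, s.block_kinds)
                          if k == kind})
            for bid in ids[:2]:
                r = s.rates_for_block(bid)
                rows.append(rng.choice(r, 60, replace=False))
                labs.extend([kind] * 60)
        cols.append(np.concatenate(rows))
        labels = np.array(labs)
    acc = pca_separability(np.column_stack(cols), labels, seed=args.seed)
    print(f"PCA + 2-means separability: {acc:.3f}")
    summary["pca_separability"] = acc
    (args.out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                      sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
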