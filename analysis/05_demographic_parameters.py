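"""Refit the winning model across bootstrap spectra; report physical units.

Takes the winner from step 04 (or a named model), refits it to every
bootstrap spectrum, converts each fit to physical units via
Ne = theta / (4 mu L), and writes 2.5/50/97.5 percentile intervals under
results/model_selection/.

The sequence length L defaults to the simulated dataset's total length
(contigs x contig length); mu and generation time default to the study
constants (3.92e-9 per base per generation, 4 years).

Usage: python analysis/05_demographic_parameters.py [--model sc2ns]
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from demosfs.fit import PhysicalScale, bootstrap_uncertainty, fit_model  # noqa: E402
from demosfs.sfs import read_sfs  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--sfs-dir", default=str(ROOT / "scratch/sfs"))
    ap.add_argument("--model", default=None, help="defaults to the step-04 winner")
    ap.add_argument("--mu", type=float, default=3.92e-9)
    ap.add_argument("--G", type=float, default=4.0)
    ap.add_argument("--L", type=float, default=None)
    ap.add_argument("--boots", type=int, default=20)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    model = args.model
    if model is None:
        ranking = pd.read_csv(ROOT / "results/model_selection/ranking.tsv", sep="\t")
        model = ranking.iloc[0]["model"]
        print(f"winner from step 04: {model}")

    L = args.L
    if L is None:
        meta = json.loads((ROOT / "results/simulated_dataset.json").read_text())
        L = meta["n_contigs"] * meta["contig_length"]
        print(f"L from simulated dataset: {L:.0f} bp")

    sfs_dir = Path(args.sfs_dir)
    obs = read_sfs(sfs_dir / "observed.fs")
    reps = [read_sfs(p) for p in sorted(sfs_dir.glob("boot_*.fs"))[: args.boots]]

    point = fit_model(obs, model, restarts=4, seed=args.seed, guard=0, maxiter=400)
    print(f"point fit: ll={point.log_likelihood:.2f} theta={point.theta_hat:.2f}")

    scale = PhysicalScale(mu=args.mu, G=args.G, L=L)
    intervals = bootstrap_uncertainty(
        model, reps, scale, seed=args.seed + 1, guard=0, restarts=1, start=point.params
    )
    out = ROOT / "results" / "model_selection"
    out.mkdir(parents=True, exist_ok=True)
    intervals.to_csv(out / f"physical_params_{model}.tsv", sep="\t")
    print(intervals.to_string(float_format=lambda x: f"{x:.4g}"))


if __name__ == "__main__":
    main()
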