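"""Bootstrap-median AIC model selection over the seven-candidate catalog.

Fits every candidate demographic model to each bootstrap spectrum from
step 03 with multi-start optimization, ranks models by the median AIC
across replicates, and writes the ranking table (model, median_AIC,
delta_AIC, rel_likelihood, AIC_weight) under results/model_selection/.

Usage: python analysis/04_model_selection.py [--boots 5] [--restarts 3]
"""

import argparse
import sys
import time
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from demosfs.experiments import SELECTION_CATALOG  # noqa: E402
from demosfs.fit import fit_model, rank_models  # noqa: E402
from demosfs.sfs import read_sfs  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--sfs-dir", default=str(ROOT / "scratch/sfs"))
    ap.add_argument("--boots", type=int, default=5, help="bootstrap replicates to fit")
    ap.add_argument("--restarts", type=int, default=3)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    sfs_dir = Path(args.sfs_dir)
    reps = [read_sfs(p) for p in sorted(sfs_dir.glob("boot_*.fs"))[: args.boots]]
    if not reps:
        sys.exit("no bootstrap spectra found; run analysis/03_build_spectra.py first")

    rows = []
    for b, rep in enumerate(reps):
        for name in SELECTION_CATALOG:
            t0 = time.time()
            fit = fit_model(
                rep, name, restarts=args.restarts, seed=args.seed + 13 * b, guard=0, maxiter=400
            )
            rows.append({"replicate": b, "model": name, "AIC": fit.aic, "ll": fit.log_likelihood})
            print(f"boot {b} {name}: ll={fit.log_likelihood:.2f} AIC={fit.aic:.2f} ({time.time()-t0:.1f}s)")
    fits = pd.DataFrame(rows)
    aic_table = fits.pivot(index="replicate", columns="model", values="AIC")
    ranking = rank_models(aic_table)

    out = ROOT / "results" / "model_selection"
    out.mkdir(parents=True, exist_ok=True)
    fits.to_csv(out / "fits.tsv", sep="\t", index=False)
    ranking.to_csv(out / "ranking.tsv", sep="\t")
    print("\nranking by median AIC:")
    print(ranking.to_string(float_format=lambda x: f"{x:.4g}"))


if __name__ == "__main__":
    main()
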