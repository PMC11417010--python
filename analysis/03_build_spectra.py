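"""Build the observed folded joint SFS and its contig-bootstrap replicates.

Projects each deme down to the analysis size (small grids keep the model
fits tractable; pass --project 36 36 for the publication-style size),
folds, and writes the observed spectrum plus B bootstrap replicates in the
plain-text SFS format under scratch/sfs/.

Usage: python analysis/03_build_spectra.py [--project 12 12] [--B 100]
"""

import argparse
import sys
import warnings
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from demosfs.genotypes import read_vcf  # noqa: E402
from demosfs.sfs import bootstrap_contigs, observed_sfs, write_sfs  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--vcf", default=str(ROOT / "scratch/dataset/simulated.vcf"))
    ap.add_argument("--popmap", default=str(ROOT / "scratch/dataset/popmap.tsv"))
    ap.add_argument("--project", nargs=2, type=int, default=(12, 12))
    ap.add_argument("--B", type=int, default=100)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    gm = read_vcf(args.vcf, args.popmap)
    n1, n2 = args.project
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        obs = observed_sfs(gm, n1, n2).fold()
    out = ROOT / "scratch" / "sfs"
    out.mkdir(parents=True, exist_ok=True)
    write_sfs(obs, out / "observed.fs")
    print(f"observed folded SFS at ({n1},{n2}): mass {obs.mass:.1f} -> {out}/observed.fs")

    reps = bootstrap_contigs(gm, n1, n2, B=args.B, seed=args.seed, fold=True)
    for b, rep in enumerate(reps):
        write_sfs(rep, out / f"boot_{b:03d}.fs")
    print(f"wrote {args.B} contig-bootstrap replicates")


if __name__ == "__main__":
    main()
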