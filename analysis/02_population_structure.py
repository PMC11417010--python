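"""Population-structure pass: filters, IBS, PCoA, PERMANOVA, FST.

Reads the simulated VCF from analysis step 01, applies the site filters
(call rate >= 0.75, pooled MAF >= 0.025), and writes ordination
coordinates, the PERMANOVA summary, and per-site/global Hudson FST under
results/structure/.

Usage: python analysis/02_population_structure.py [--nperm 999] [--seed S]
"""

import argparse
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from demosfs.genotypes import (  # noqa: E402
    SiteFilterConfig,
    apply_site_filters,
    ibs_distance,
    read_vcf,
    sample_heterozygosity,
)
from demosfs.popstructure import fst, pcoa, permanova  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--vcf", default=str(ROOT / "scratch/dataset/simulated.vcf"))
    ap.add_argument("--popmap", default=str(ROOT / "scratch/dataset/popmap.tsv"))
    ap.add_argument("--nperm", type=int, default=999)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    gm = read_vcf(args.vcf, args.popmap)
    filtered, audit = apply_site_filters(
        gm, SiteFilterConfig(min_call_fraction=0.75, min_maf=0.025), return_audit=True
    )
    print(f"filters: {filtered.n_sites}/{gm.n_sites} sites retained")

    out = ROOT / "results" / "structure"
    out.mkdir(parents=True, exist_ok=True)
    audit.to_csv(out / "site_audit.tsv", sep="\t", index=False)

    dist = ibs_distance(filtered)
    ordn = pcoa(dist)
    coords = ordn.coordinates.copy()
    coords.insert(0, "deme", filtered.demes)
    coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    print(
        f"PCoA: axis 1 explains {100 * ordn.proportion_explained[0]:.1f}% "
        f"of positive-eigenvalue variance"
    )

    perm = permanova(dist, filtered.demes, n_perm=args.nperm, seed=args.seed)
    with open(out / "permanova.tsv", "w") as fh:
        fh.write("R2\tpseudo_F\tp_value\tn_permutations\n")
        fh.write(f"{perm.R2:.6g}\t{perm.pseudo_F:.6g}\t{perm.p_value:.6g}\t{perm.n_permutations}\n")
    print(f"PERMANOVA: R2={perm.R2:.5f} F={perm.pseudo_F:.3f} p={perm.p_value:.4f}")

    het = sample_heterozygosity(filtered)
    het.to_csv(out / "heterozygosity.tsv", sep="\t")

    global_fst, per_site = fst(filtered)
    per_site.to_csv(out / "fst_per_site.tsv", sep="\t", index=False)
    (out / "fst_global.txt").write_text(f"{global_fst:.6f}\n")
    print(f"global Hudson FST = {global_fst:.6f} (per-site max {per_site['fst'].max():.3f})")


if __name__ == "__main__":
    main()
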