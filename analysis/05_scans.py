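"""Three genotype-environment association scans and their consensus.

Runs redundancy analysis (loading outliers beyond 2.5 SD, 999
permutations for model significance), the PCA outlier scan (K=5, robust
Mahalanobis, q < 0.1) and the latent-factor ridge scan (BH FDR 5% and
raw p < 0.001 per predictor), then keeps loci flagged by at least two
methods.  Writes per-method statistics, the predictor-by-method outlier
count grid, and the consensus locus list.
"""

import json
from pathlib import Path

import pandas as pd

import geascan as g
from geascan import io
from geascan.scans import outlier_count_grid

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
# bulky per-locus intermediates live outside the curated results
DATA = ROOT / "scratch" / "data"
SEED = 55


def main() -> None:
    data = DATA
    ind_meta = pd.read_csv(data / "individuals_qc.csv", index_col=0)
    matrix = io.read_genotype_csv(data / "genotypes_qc.csv", ind_meta)
    env = io.read_env_csv(data / "env.csv")
    k_lfmm = json.loads((RESULTS / "ancestry.json").read_text())["best_K"]

    rda = g.rda_scan(matrix, env, sd_cutoff=2.5, n_permutations=999, seed=SEED)
    print(f"RDA: {len(rda.outliers)} outliers, model p = {rda.metadata['model_p']:.3f}")
    pca = g.pcadapt_scan(matrix, K=5, alpha=0.1, mode="qvalue")
    print(f"PCA outlier scan: {len(pca.outliers)} outliers "
          f"(inflation factor {pca.metadata['gif']:.2f})")
    lf = g.lfmm_scan(matrix, env, K=k_lfmm)
    print(f"LFMM (K={k_lfmm}): {len(lf.outliers)} outliers across predictors")

    grid = outlier_count_grid([rda, lf])
    print("outlier counts per environmental predictor:")
    print(grid.to_string())

    cs = g.consensus([rda, pca, lf], min_methods=2)
    planted = set((data / "planted_loci.txt").read_text().split())
    found = {l for l in cs.consensus if l in planted}
    print(f"consensus (>=2 methods): {len(cs.consensus)} loci; "
          f"recovers {len(found)}/{len(planted & set(matrix.locus_meta.index))} "
          "planted loci surviving QC")

    for res in (rda, pca, lf):
        res.stats.to_csv(DATA / f"scan_{res.method}.tsv", sep="\t")
    grid.to_csv(RESULTS / "outlier_counts.csv")
    (RESULTS / "consensus_loci.txt").write_text("\n".join(sorted(cs.consensus)))


if __name__ == "__main__":
    main()
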