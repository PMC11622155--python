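"""Per-meadow zygosity composition along the dominant gradient.

For the consensus loci, classifies every meadow x locus cell into
reference-homozygote / heterozygote / alternate-homozygote proportions
and orders meadows along the most important predictor so the stacked
profiles line up with the turnover curve.
"""

import json
from pathlib import Path

import pandas as pd

import geascan as g
from geascan import io

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
# bulky per-locus intermediates live outside the curated results
DATA = ROOT / "scratch" / "data"


def main() -> None:
    data = DATA
    ind_meta = pd.read_csv(data / "individuals_qc.csv", index_col=0)
    matrix = io.read_genotype_csv(data / "genotypes_qc.csv", ind_meta)
    env = io.read_env_csv(data / "env.csv")
    candidates = (RESULTS / "consensus_loci.txt").read_text().split()
    rel = json.loads((RESULTS / "turnover_importance.json").read_text())["relative_importance"]
    top_var = max(rel, key=rel.get)

    profiles = g.zygosity_proportions(matrix, candidates)
    ordered = g.order_by_gradient(profiles, env, top_var)
    ordered.to_csv(RESULTS / "zygosity_profiles.tsv", sep="\t", index=False,
                   float_format="%.4f")

    per_meadow = ordered.groupby("meadow", observed=True)[
        ["p_ref_hom", "p_het", "p_alt_hom"]
    ].mean()
    gradient = env[top_var].reindex(per_meadow.index)
    print(f"mean zygosity composition per meadow, ordered by {top_var}:")
    print(pd.concat([gradient.rename(top_var), per_meadow.round(3)], axis=1).to_string())


if __name__ == "__main__":
    main()
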