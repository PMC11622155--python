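"""Per-meadow zygosity composition at candidate loci.

Each meadow x locus cell is summarised as the proportions of reference
homozygotes (0), heterozygotes (1) and alternate homozygotes (2) over
non-missing calls, and profiles can be ordered along an environmental
gradient so they align with the corresponding turnover curve.  The
"reference" allele is purely the designated reference of the locus
record; no claim about ancestral state is made.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MISSING


def zygosity_proportions(
    matrix: GenotypeMatrix, candidate_loci: list[str] | None = None
) -> pd.DataFrame:
    """Zygosity-class proportions per meadow x locus.

    Returns a long DataFrame with columns ``meadow, locus, n, p_ref_hom,
    p_het, p_alt_hom, undefined``; a meadow with zero non-missing calls at
    a locus is kept as a flagged (``undefined=True``) record with NaN
    proportions.
    """
    if candidate_loci is None:
        candidate_loci = list(matrix.locus_meta.index)
    idx = matrix.locus_meta.index.get_indexer(candidate_loci)
    if (idx < 0).any():
        bad = [l for l, i in zip(candidate_loci, idx) if i < 0]
        raise KeyError(f"candidate loci not in matrix: {bad[:5]}")
    sites = matrix.ind_meta["site"].to_numpy()
    rows = []
    for meadow in dict.fromkeys(sites):
        sub = matrix.calls[sites == meadow][:, idx]
        n = (sub != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p0 = (sub == 0).sum(axis=0) / n
            p1 = (sub == 1).sum(axis=0) / n
            p2 = (sub == 2).sum(axis=0) / n
        for j, locus in enumerate(candidate_loci):
            undefined = n[j] == 0
            rows.append(
                {
                    "meadow": meadow,
                    "locus": locus,
                    "n": int(n[j]),
                    "p_ref_hom": np.nan if undefined else float(p0[j]),
                    "p_het": np.nan if undefined else float(p1[j]),
                    "p_alt_hom": np.nan if undefined else float(p2[j]),
                    "undefined": bool(undefined),
                }
            )
    return pd.DataFrame(rows)


def order_by_gradient(
    profiles: pd.DataFrame, env_table: pd.DataFrame, variable: str
) -> pd.DataFrame:
    """Sort profiles by a predictor's value, annotating gradient positions.

    Meadows are ordered ascending in ``variable`` (ties broken by meadow
    name) and each profile row gains a ``gradient_value`` column so the
    stacked-histogram data can be aligned with the turnover curve.
    """
    if variable not in env_table.columns:
        raise KeyError(f"unknown environmental variable: {variable}")
    unknown = set(profiles["meadow"]) - set(env_table.index)
    if unknown:
        raise KeyError(f"meadows without environmental values: {sorted(unknown)}")
    out = profiles.copy()
    out["gradient_value"] = out["meadow"].map(env_table[variable])
    meadows = list(dict.fromkeys(out["meadow"]))
    order = sorted(meadows, key=lambda m: (env_table.loc[m, variable], m))
    out["meadow"] = pd.Categorical(out["meadow"], categories=order, ordered=True)
    return out.sort_values(["meadow", "locus"], kind="stable").reset_index(drop=True)
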