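"""Small population-genetic utilities shared across the pipeline."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MISSING


def weir_cockerham_fst(matrix: GenotypeMatrix) -> float:
    """Multilocus Weir-Cockerham theta over the matrix's site labels.

    Per-locus variance components a (among demes), b (among individuals
    within demes) and c (within individuals) are computed from sample
    sizes, allele frequencies and heterozygote frequencies per deme, and
    the multilocus estimate is ``sum(a) / sum(a + b + c)`` over loci with
    defined components.  Missing calls are excluded per deme per locus.
    """
    sites = matrix.ind_meta["site"].to_numpy()
    demes = list(dict.fromkeys(sites))
    r = len(demes)
    if r < 2:
        raise ValueError("need at least two demes for F_ST")

    calls = matrix.calls
    n_i = np.zeros((r, matrix.n_loci))
    p_i = np.zeros((r, matrix.n_loci))
    h_i = np.zeros((r, matrix.n_loci))
    for k, deme in enumerate(demes):
        sub = calls[sites == deme]
        ok = sub != MISSING
        n = ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, np.where(ok, sub, 0).sum(axis=0) / (2 * n), np.nan)
            h = np.where(n > 0, np.where(ok, sub == 1, False).sum(axis=0) / n, np.nan)
        n_i[k], p_i[k], h_i[k] = n, p, h

    usable = (n_i > 0).all(axis=0)
    n_i, p_i, h_i = n_i[:, usable], p_i[:, usable], h_i[:, usable]

    n_bar = n_i.mean(axis=0)
    n_total = n_i.sum(axis=0)
    nc = (n_total - (n_i**2).sum(axis=0) / n_total) / (r - 1)
    p_bar = (n_i * p_i).sum(axis=0) / n_total
    s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum(axis=0) / n_total

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar / nc) * (
            s2
            - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2

    denom_ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    a, b, c = a[denom_ok], b[denom_ok], c[denom_ok]
    total = (a + b + c).sum()
    if total == 0:
        return 0.0
    return float(a.sum() / total)


def site_allele_freqs(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-site alternate-allele frequencies (sites x loci)."""
    sites = matrix.ind_meta["site"].to_numpy()
    demes = list(dict.fromkeys(sites))
    rows = {}
    for deme in demes:
        sub = np.ma.masked_equal(matrix.calls[sites == deme], MISSING)
        rows[deme] = np.asarray(sub.mean(axis=0) / 2.0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=matrix.locus_meta.index)
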