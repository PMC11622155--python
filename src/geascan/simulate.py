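"""Synthetic genotype-environment datasets with known truth.

The generator emulates the structure of a reduced-representation SNP panel
from a set of estuarine meadows: a handful of demes differentiated to a
target F_ST (Balding-Nichols deme frequencies), a subset of loci whose
allele frequencies track a deme-level environmental covariate, missing
data, technical-replicate pairs with a small call-error rate, and clonal
duplicates.  Every operation is fully reproducible from its seed.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MISSING, SyntheticTruth

_BASES = np.array(list("ACGT"))


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _make_locus_meta(n_loci: int, rng: np.random.Generator) -> pd.DataFrame:
    """DArT-style locus metadata with ids ``<cloneid>-<pos>-<ref>/<alt>``."""
    clone_ids = rng.choice(np.arange(100_000_000, 110_000_000), size=n_loci, replace=False)
    pos = rng.integers(5, 70, size=n_loci)
    ref_idx = rng.integers(0, 4, size=n_loci)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_loci)) % 4
    ref = _BASES[ref_idx]
    alt = _BASES[alt_idx]
    ids = [f"{c}-{p}-{r}/{a}" for c, p, r, a in zip(clone_ids, pos, ref, alt)]
    # Reproducibility concentrated near 1 and read depth log-normal around
    # ~7x so that the default QC thresholds have realistic work to do.
    reproducibility = np.clip(1.0 - rng.exponential(0.004, size=n_loci), 0.90, 1.0)
    mean_depth = rng.lognormal(mean=np.log(7.0), sigma=0.75, size=n_loci)
    return pd.DataFrame(
        {
            "ref": ref,
            "alt": alt,
            "call_rate": np.ones(n_loci),
            "reproducibility": reproducibility,
            "mean_depth": mean_depth,
        },
        index=pd.Index(ids, name="locus"),
    )


def gen_admixed_genotypes(
    n_pops: int,
    n_per_pop: int,
    n_loci: int,
    fst: float,
    seed: int,
    site_names: list[str] | None = None,
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Draw diploid 0/1/2 genotypes for ``n_pops`` demes at target F_ST.

    Ancestral allele frequencies are Uniform(0.05, 0.95); per-deme
    frequencies follow the Balding-Nichols beta parameterization
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` (``fst=0`` collapses to identical
    deme frequencies).  Genotypes are independent Binomial(2, p_deme)
    draws per individual per locus, with no missing data.
    """
    if n_pops < 1 or n_per_pop < 1 or n_loci < 1:
        raise ValueError("n_pops, n_per_pop and n_loci must all be >= 1")
    if not (0.0 <= fst < 1.0):
        raise ValueError("fst must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, size=n_loci)
    if fst == 0.0:
        deme_freqs = np.tile(p_anc, (n_pops, 1))
    else:
        scale = (1.0 - fst) / fst
        deme_freqs = rng.beta(p_anc * scale, (1.0 - p_anc) * scale, size=(n_pops, n_loci))
    n_ind = n_pops * n_per_pop
    deme_of = np.repeat(np.arange(n_pops), n_per_pop)
    calls = rng.binomial(2, deme_freqs[deme_of, :]).astype(np.int16)

    if site_names is None:
        site_names = [f"deme_{i + 1:02d}" for i in range(n_pops)]
    if len(site_names) != n_pops:
        raise ValueError("site_names must have one entry per deme")
    ind_meta = pd.DataFrame(
        {
            "site": [site_names[d] for d in deme_of],
            "replicate_pair": pd.array([pd.NA] * n_ind, dtype="Int64"),
            "clone_id": pd.array([pd.NA] * n_ind, dtype="Int64"),
        },
        index=pd.Index([f"ind_{i + 1:04d}" for i in range(n_ind)], name="individual"),
    )
    locus_meta = _make_locus_meta(n_loci, rng)
    truth = SyntheticTruth(k_true=n_pops, fst=fst, seed=seed, deme_freqs=deme_freqs)
    return GenotypeMatrix(calls, ind_meta, locus_meta), truth


def plant_env_effects(
    matrix: GenotypeMatrix,
    truth: SyntheticTruth,
    env_values: np.ndarray,
    seed: int,
) -> GenotypeMatrix:
    """Re-draw calls at ``truth.adaptive_loci`` along an environmental cline.

    The covariate is standardized across demes; at each adaptive locus the
    deme frequency becomes ``inv_logit(logit(p) + beta * z)`` and the calls
    of every individual at those loci are re-drawn.  Non-adaptive loci are
    untouched.  ``truth.deme_freqs`` is updated in place to the planted
    frequencies so it remains the generative truth.
    """
    env_values = np.asarray(env_values, dtype=float)
    sites = matrix.ind_meta["site"]
    deme_names = list(dict.fromkeys(sites))  # first-appearance order
    if len(env_values) != len(deme_names):
        raise ValueError(
            f"need one env value per deme ({len(deme_names)}), got {len(env_values)}"
        )
    if truth.deme_freqs is None:
        raise ValueError("truth must carry deme_freqs")
    adaptive = np.asarray(truth.adaptive_loci, dtype=int)
    if adaptive.size and (adaptive.min() < 0 or adaptive.max() >= matrix.n_loci):
        raise ValueError("adaptive_loci out of range")

    z = (env_values - env_values.mean()) / env_values.std()
    p = truth.deme_freqs[:, adaptive]
    p_new = _inv_logit(_logit(np.clip(p, 1e-6, 1 - 1e-6)) + truth.beta * z[:, None])

    rng = np.random.default_rng(seed)
    out = matrix.copy()
    deme_of = sites.map({name: i for i, name in enumerate(deme_names)}).to_numpy()
    if adaptive.size:
        out.calls[:, adaptive] = rng.binomial(2, p_new[deme_of, :]).astype(np.int16)
        truth.deme_freqs = truth.deme_freqs.copy()
        truth.deme_freqs[:, adaptive] = p_new
    return out


def degrade(
    matrix: GenotypeMatrix,
    missing_rate: float = 0.0,
    replicate_pairs: int = 0,
    replicate_error: float = 0.0,
    clone_pairs: int = 0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Add missingness, technical-replicate pairs and clonal duplicates.

    Technical replicates are copies of randomly chosen individuals with
    each call flipped to a different valid call with probability
    ``replicate_error``; clones are exact copies.  Missingness is then
    applied independently at ``missing_rate`` to every entry (originals
    and duplicates alike), and the per-locus call-rate metadata is
    recomputed.
    """
    for name, rate in [("missing_rate", missing_rate), ("replicate_error", replicate_error)]:
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    if replicate_pairs < 0 or clone_pairs < 0:
        raise ValueError("pair counts must be non-negative")
    rng = np.random.default_rng(seed)

    calls = [matrix.calls]
    meta_rows = [matrix.ind_meta.copy()]
    n = matrix.n_ind

    chosen = rng.choice(n, size=replicate_pairs + clone_pairs, replace=False)
    rep_src, clone_src = chosen[:replicate_pairs], chosen[replicate_pairs:]

    rep_pair_col = meta_rows[0]["replicate_pair"].copy()
    for pair_id, src in enumerate(rep_src):
        dup = matrix.calls[src].copy()
        flip = rng.random(matrix.n_loci) < replicate_error
        # flip to a different valid call, uniformly over the two others
        offsets = rng.integers(1, 3, size=matrix.n_loci)
        dup[flip] = (dup[flip] + offsets[flip]) % 3
        calls.append(dup[None, :])
        row = matrix.ind_meta.iloc[[src]].copy()
        row.index = [f"{matrix.ind_meta.index[src]}_rep"]
        row["replicate_pair"] = pair_id
        rep_pair_col.iloc[src] = pair_id
        meta_rows.append(row)
    meta_rows[0]["replicate_pair"] = rep_pair_col

    clone_col = meta_rows[0]["clone_id"].copy()
    for clone_id, src in enumerate(clone_src):
        calls.append(matrix.calls[src][None, :].copy())
        row = matrix.ind_meta.iloc[[src]].copy()
        row.index = [f"{matrix.ind_meta.index[src]}_clone"]
        row["clone_id"] = clone_id
        clone_col.iloc[src] = clone_id
        meta_rows.append(row)
    meta_rows[0]["clone_id"] = clone_col

    all_calls = np.vstack(calls).astype(np.int16)
    if missing_rate > 0:
        mask = rng.random(all_calls.shape) < missing_rate
        all_calls[mask] = MISSING
    out = GenotypeMatrix(all_calls, pd.concat(meta_rows), matrix.locus_meta.copy())
    out.refresh_call_rates()
    return out


def load_nsw_env_table() -> pd.DataFrame:
    """The 13-meadow x 9-variable NSW environmental summary table.

    Per-meadow warm-season summaries (AvTemp, MaxTemp, TempRange in deg C;
    pHRange, MinpH in pH units; MaxSal, AvSal in PSU; TurbRange, MinTurb
    in NTU) used throughout the association scans and the donor registry.
    """
    with resources.files("geascan.data").joinpath("nsw_meadows_env.csv").open() as fh:
        table = pd.read_csv(fh, index_col="meadow")
    return table


def load_published_registry() -> pd.DataFrame:
    """Published donor-registry grid (projections and donors) for NSW.

    Long format: one row per meadow x variable with the current value,
    the assumed +0.2 per-year rate, the printed decadal projections and
    the printed donor meadows ('NA' = no pre-adapted donor printed).
    """
    with resources.files("geascan.data").joinpath("nsw_published_registry.csv").open() as fh:
        return pd.read_csv(fh, keep_default_na=False)
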