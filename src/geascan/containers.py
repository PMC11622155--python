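"""Core in-memory containers for genotype and environmental data.

Genotypes are biallelic SNP calls coded against the reference allele:
0 = reference homozygote, 1 = heterozygote, 2 = alternate homozygote,
with a single reserved sentinel (:data:`MISSING`) for no-calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reserved missing-call sentinel, distinct from the valid calls {0, 1, 2}.
MISSING: int = -9

VALID_CALLS = (0, 1, 2)


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated genotype-environment dataset.

    Attributes
    ----------
    k_true : number of ancestral demes the genotypes were drawn from.
    fst : target Weir-Cockerham differentiation among demes, in [0, 1).
    adaptive_loci : indices of loci whose deme allele frequencies were
        shifted along the environmental covariate.
    beta : per-adaptive-locus effect of the standardized covariate on the
        logit of the alternate-allele frequency.
    seed : seed the generator was called with.
    deme_freqs : k_true x n_loci alternate-allele frequencies actually used
        to draw the calls (post any planted environmental effect).
    """

    k_true: int
    fst: float
    adaptive_loci: list[int] = field(default_factory=list)
    beta: float = 0.0
    seed: int = 0
    deme_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")


@dataclass
class GenotypeMatrix:
    """Individuals x loci matrix of {0,1,2,MISSING} calls with metadata.

    ``ind_meta`` is indexed by individual id and carries at least a ``site``
    column; ``replicate_pair`` and ``clone_id`` are optional nullable
    columns.  ``locus_meta`` is indexed by locus id
    (``"<cloneid>-<pos>-<ref>/<alt>"``) and carries ``ref``, ``alt``,
    ``call_rate``, ``reproducibility`` and ``mean_depth``.
    """

    calls: np.ndarray
    ind_meta: pd.DataFrame
    locus_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        if self.calls.shape != (len(self.ind_meta), len(self.locus_meta)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match metadata "
                f"({len(self.ind_meta)} individuals, {len(self.locus_meta)} loci)"
            )
        bad = ~np.isin(self.calls, VALID_CALLS + (MISSING,))
        if bad.any():
            raise ValueError("calls contain values outside {0,1,2,MISSING}")
        if self.locus_meta.index.duplicated().any():
            raise ValueError("locus ids must be unique")

    # -- basic geometry -------------------------------------------------
    @property
    def n_ind(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def sites(self) -> pd.Series:
        return self.ind_meta["site"]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls.copy(), self.ind_meta.copy(), self.locus_meta.copy()
        )

    # -- derived quantities ---------------------------------------------
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def locus_call_rate(self) -> np.ndarray:
        """Fraction of individuals with a call, per locus."""
        return 1.0 - self.missing_mask().mean(axis=0)

    def individual_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per locus over non-missing calls."""
        calls = np.ma.masked_equal(self.calls, MISSING)
        return np.asarray(calls.mean(axis=0) / 2.0)

    def minor_allele_freq(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def refresh_call_rates(self) -> None:
        """Recompute the per-locus call-rate metadata from the calls."""
        self.locus_meta["call_rate"] = self.locus_call_rate()

    def subset(self, ind=None, loci=None) -> "GenotypeMatrix":
        """Positional subset along individuals and/or loci."""
        ind = np.arange(self.n_ind) if ind is None else np.asarray(ind)
        loci = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        return GenotypeMatrix(
            self.calls[np.ix_(ind, loci)],
            self.ind_meta.iloc[ind].copy(),
            self.locus_meta.iloc[loci].copy(),
        )


def bitwise_distance(
    a: np.ndarray, b: np.ndarray, per_allele: bool = False
) -> float:
    """Proportion of differing calls between two individuals.

    Computed over loci where both calls are non-missing.  With
    ``per_allele=True`` a het/hom difference counts half as much as a
    hom/hom difference (differences are |a-b| allele copies out of 2).

    Raises
    ------
    ValueError
        If the two individuals share no jointly non-missing locus.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    shared = (a != MISSING) & (b != MISSING)
    n = int(shared.sum())
    if n == 0:
        raise ValueError("no jointly non-missing loci between the pair")
    if per_allele:
        return float(np.abs(a[shared] - b[shared]).sum() / (2 * n))
    return float((a[shared] != b[shared]).sum() / n)


def pairwise_distance_matrix(calls: np.ndarray) -> np.ndarray:
    """All-pairs bitwise distance; ``inf`` where no loci are shared."""
    n = calls.shape[0]
    present = calls != MISSING
    out = np.zeros((n, n))
    for i in range(n):
        shared = present[i] & present
        diff = (calls[i] != calls) & shared
        n_shared = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = diff.sum(axis=1) / n_shared
        d[n_shared == 0] = np.inf
        out[i] = d
    np.fill_diagonal(out, 0.0)
    return out
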