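"""Gradient-forest-style allelic turnover along environmental gradients.

For every candidate locus a random regression forest is fit to the
environmental predictors (bootstrap rows, random predictor subset per
split, variance-reduction splitting); each split's impurity reduction is
logged against the (predictor, threshold) at which it occurred.  Split
importances are standardized by the density of observed split
opportunities along each predictor, weighted by the locus's out-of-bag
R^2, and accumulated along the sorted threshold axis into monotone
cumulative-importance ("turnover") curves.  Loci with out-of-bag R^2 <= 0
carry no signal and are excluded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .popgen import site_allele_freqs


@dataclass
class TurnoverModel:
    """Aggregated split importances per predictor, binned over its range."""

    predictors: list[str]
    r2: pd.Series                       # OOB R^2 per contributing locus
    bin_edges: dict[str, np.ndarray]    # n_bins + 1 edges per predictor
    bin_importance: dict[str, np.ndarray]
    total_importance: dict[str, float]
    n_trees: int
    seed: int
    n_loci_fit: int = 0
    dropped_predictors: list[str] = field(default_factory=list)

    def relative_importance(self) -> pd.Series:
        total = sum(self.total_importance.values())
        if total == 0:
            return pd.Series(dtype=float)
        return pd.Series(self.total_importance).sort_values(ascending=False) / total


def _tree_split_importances(tree, n_features: int):
    """(feature, threshold, weighted impurity decrease) for every split."""
    t = tree.tree_
    node_w = t.weighted_n_node_samples / t.weighted_n_node_samples[0]
    internal = t.children_left != -1
    left, right = t.children_left[internal], t.children_right[internal]
    gain = (
        node_w[internal] * t.impurity[internal]
        - node_w[left] * t.impurity[left]
        - node_w[right] * t.impurity[right]
    )
    return t.feature[internal], t.threshold[internal], np.maximum(gain, 0.0)


def fit_turnover(
    matrix: GenotypeMatrix,
    env_table: pd.DataFrame,
    candidate_loci: list[str] | None = None,
    n_trees: int = 500,
    seed: int = 0,
    response: str = "individual",
    n_bins: int = 200,
    min_samples_leaf: int = 5,
    max_features: int | None = None,
) -> TurnoverModel:
    """Fit per-locus regression forests and aggregate turnover importance.

    ``response="individual"`` fits genotype calls (0/1/2) per individual
    with site-level predictors replicated; ``response="site_freq"`` fits
    per-site alternate-allele frequencies.  Predictors with fewer than two
    distinct values are dropped with a warning.
    """
    from sklearn.ensemble import RandomForestRegressor

    if candidate_loci is None:
        candidate_loci = list(matrix.locus_meta.index)
    missing = set(candidate_loci) - set(matrix.locus_meta.index)
    if missing:
        raise KeyError(f"candidate loci not in matrix: {sorted(missing)[:5]}")

    if response == "individual":
        sites = matrix.ind_meta["site"]
        X = env_table.loc[sites].to_numpy(dtype=float)
        idx = matrix.locus_meta.index.get_indexer(candidate_loci)
        Y = matrix.calls[:, idx].astype(float)
    elif response == "site_freq":
        freqs = site_allele_freqs(matrix)[candidate_loci]
        X = env_table.loc[freqs.index].to_numpy(dtype=float)
        Y = freqs.to_numpy()
    else:
        raise ValueError("response must be 'individual' or 'site_freq'")

    predictors = list(env_table.columns)
    distinct = [len(np.unique(X[:, k])) for k in range(X.shape[1])]
    dropped = [p for p, d in zip(predictors, distinct) if d < 2]
    if dropped:
        warnings.warn(f"dropping constant predictors: {dropped}", stacklevel=2)
        keep = [k for k, d in enumerate(distinct) if d >= 2]
        X = X[:, keep]
        predictors = [predictors[k] for k in keep]
    p = len(predictors)
    if p == 0:
        raise ValueError("no usable predictors")
    if max_features is None:
        max_features = max(1, math.ceil(p / 3))

    # split-opportunity density: candidate thresholds are midpoints of
    # consecutive sorted distinct values of each predictor
    edges: dict[str, np.ndarray] = {}
    opportunity: dict[str, np.ndarray] = {}
    for k, name in enumerate(predictors):
        vals = np.unique(X[:, k])
        edges[name] = np.linspace(vals.min(), vals.max(), n_bins + 1)
        mids = (vals[:-1] + vals[1:]) / 2.0
        opportunity[name] = np.histogram(mids, bins=edges[name])[0].astype(float)

    rng = np.random.SeedSequence(seed)
    locus_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(len(candidate_loci))]

    r2_kept: dict[str, float] = {}
    binned = {name: np.zeros(n_bins) for name in predictors}
    totals = {name: 0.0 for name in predictors}
    for j, locus in enumerate(candidate_loci):
        y = Y[:, j]
        if np.all(y == y[0]):
            continue
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,
            bootstrap=True,
            oob_score=True,
            random_state=locus_seeds[j],
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            forest.fit(X, y)
        r2 = forest.oob_score_
        if not np.isfinite(r2) or r2 <= 0.0:
            continue
        # raw split importance per (predictor, bin) for this locus
        locus_bins = {name: np.zeros(n_bins) for name in predictors}
        for tree in forest.estimators_:
            feats, thresholds, gains = _tree_split_importances(tree, p)
            for k, name in enumerate(predictors):
                sel = feats == k
                if sel.any():
                    locus_bins[name] += np.histogram(
                        thresholds[sel], bins=edges[name], weights=gains[sel]
                    )[0]
        locus_total = sum(b.sum() for b in locus_bins.values())
        if locus_total == 0:
            continue
        r2_kept[locus] = r2
        for name in predictors:
            raw = locus_bins[name]
            raw_sum = raw.sum()
            if raw_sum == 0:
                continue
            dens = opportunity[name]
            std = np.where(dens > 0, raw / np.maximum(dens, 1e-12), 0.0)
            if std.sum() > 0:
                std *= raw_sum / std.sum()  # conserve the locus's raw total
            else:
                std = raw
            # scale so this locus contributes R^2 split across predictors
            binned[name] += std * (r2 / locus_total)
            totals[name] += raw_sum * (r2 / locus_total)

    return TurnoverModel(
        predictors=predictors,
        r2=pd.Series(r2_kept, dtype=float),
        bin_edges=edges,
        bin_importance=binned,
        total_importance=totals,
        n_trees=n_trees,
        seed=seed,
        n_loci_fit=len(candidate_loci),
        dropped_predictors=dropped,
    )


def predictor_importance(model: TurnoverModel) -> list[tuple[str, float]]:
    """Predictors ranked by total aggregated importance, descending.

    Ties break lexicographically; an all-null model yields an empty list.
    """
    if len(model.r2) == 0:
        return []
    items = [(name, model.total_importance[name]) for name in model.predictors]
    return sorted(items, key=lambda kv: (-kv[1], kv[0]))


def cumulative_curve(
    model: TurnoverModel, predictor: str, grid: np.ndarray
) -> pd.DataFrame:
    """Right-continuous cumulative importance evaluated on ``grid``.

    The curve is the running sum of binned importance; values below the
    first bin are 0 and the value at (or beyond) the maximum observed
    predictor value equals the predictor's total importance.
    """
    if predictor not in model.bin_importance:
        raise KeyError(f"unknown predictor: {predictor}")
    grid = np.asarray(grid, dtype=float)
    edges = model.bin_edges[predictor]
    cum = np.concatenate([[0.0], np.cumsum(model.bin_importance[predictor])])
    # position of each grid point among the bin upper edges
    pos = np.searchsorted(edges[1:], grid, side="right")
    values = cum[np.clip(pos, 0, len(cum) - 1)]
    values[grid >= edges[-1]] = cum[-1]
    return pd.DataFrame({"x": grid, "cumulative_importance": values})
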