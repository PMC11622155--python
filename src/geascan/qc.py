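"""SNP quality control: replicate error, sequential filtering, imputation.

The filter pipeline applies, in order: locus call rate, individual call
rate (locus call rates are recomputed afterwards), locus reproducibility,
mean read depth window, and minor-allele frequency over the retained
individuals.  Technical replicates are assessed by bitwise distance before
any filtering; clone handling is deliberately off by default because
outlier scans are run on the complete dataset (clonal ramets can carry
adaptive somatic variation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MISSING, bitwise_distance, pairwise_distance_matrix

#: Replicate-pair bitwise-distance threshold above which a pair is flagged.
REPLICATE_ERROR_THRESHOLD = 0.009


@dataclass
class QCReport:
    """Per-step retention counts plus the thresholds that produced them."""

    steps: list[dict] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    replicate_distances: pd.DataFrame | None = None

    def record(self, name: str, n_loci: int, n_ind: int) -> None:
        if self.steps:
            prev = self.steps[-1]
            if n_loci > prev["n_loci"] or n_ind > prev["n_individuals"]:
                raise ValueError("retained counts must be non-increasing")
        self.steps.append({"step": name, "n_loci": n_loci, "n_individuals": n_ind})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    def to_json(self) -> str:
        payload = {"steps": self.steps, "thresholds": self.thresholds}
        if self.replicate_distances is not None:
            payload["replicate_distances"] = self.replicate_distances.to_dict("records")
        return json.dumps(payload, indent=2)


def replicate_error_rate(
    matrix: GenotypeMatrix,
    pairs: list[tuple[str, str]] | None = None,
    threshold: float = REPLICATE_ERROR_THRESHOLD,
    per_allele: bool = False,
) -> pd.DataFrame:
    """Bitwise distance per technical-replicate pair, with error flags.

    ``pairs`` defaults to the pairs recorded in ``ind_meta['replicate_pair']``.
    Distance is the proportion of differing calls over jointly non-missing
    loci; pairs with distance above ``threshold`` (default 0.9%) are flagged.
    """
    if pairs is None:
        col = matrix.ind_meta["replicate_pair"]
        pairs = [
            tuple(matrix.ind_meta.index[col == pid])
            for pid in col.dropna().unique()
        ]
    if not pairs:
        raise ValueError("no replicate pairs supplied or recorded in metadata")
    rows = []
    idx = {name: i for i, name in enumerate(matrix.ind_meta.index)}
    for a, b in pairs:
        if a not in idx or b not in idx:
            raise KeyError(f"replicate pair ({a}, {b}) not present in matrix")
        d = bitwise_distance(matrix.calls[idx[a]], matrix.calls[idx[b]], per_allele)
        rows.append({"ind_a": a, "ind_b": b, "distance": d, "flagged": d > threshold})
    return pd.DataFrame(rows)


def drop_replicates(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Remove the duplicated member of each technical-replicate pair."""
    keep = ~matrix.ind_meta.index.str.endswith("_rep")
    return matrix.subset(ind=np.flatnonzero(keep))


def dedup_clones(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Remove clonal duplicates (OFF by default in the scan pipeline)."""
    keep = ~matrix.ind_meta.index.str.endswith("_clone")
    return matrix.subset(ind=np.flatnonzero(keep))


def filter_pipeline(
    matrix: GenotypeMatrix,
    locus_callrate: float = 0.67,
    ind_callrate: float = 0.25,
    reproducibility: float = 0.99,
    depth_min: float = 2.0,
    depth_max: float = 50.0,
    maf: float = 0.01,
) -> tuple[GenotypeMatrix, QCReport]:
    """Sequential locus/individual filtering with a per-step report.

    Order: locus call rate >= ``locus_callrate``; individual call rate >=
    ``ind_callrate`` (locus call rates recomputed afterwards);
    reproducibility >= ``reproducibility``; ``depth_min`` <= mean depth <=
    ``depth_max``; minor-allele frequency >= ``maf`` computed over
    non-missing calls of the retained individuals.
    """
    report = QCReport(
        thresholds={
            "locus_callrate": locus_callrate,
            "ind_callrate": ind_callrate,
            "reproducibility": reproducibility,
            "depth_min": depth_min,
            "depth_max": depth_max,
            "maf": maf,
        }
    )
    m = matrix.copy()
    report.record("input", m.n_loci, m.n_ind)

    def check(step: str, mm: GenotypeMatrix) -> None:
        if mm.n_loci == 0 or mm.n_ind == 0:
            raise ValueError(f"no data left after step '{step}'")

    m = m.subset(loci=np.flatnonzero(m.locus_call_rate() >= locus_callrate))
    check("locus_callrate", m)
    report.record("locus_callrate", m.n_loci, m.n_ind)

    m = m.subset(ind=np.flatnonzero(m.individual_call_rate() >= ind_callrate))
    check("ind_callrate", m)
    m.refresh_call_rates()
    report.record("ind_callrate", m.n_loci, m.n_ind)

    # loci with unknown (NaN) reproducibility or depth metadata pass through
    rep = m.locus_meta["reproducibility"].to_numpy(dtype=float)
    m = m.subset(loci=np.flatnonzero(~(rep < reproducibility)))
    check("reproducibility", m)
    report.record("reproducibility", m.n_loci, m.n_ind)

    depth = m.locus_meta["mean_depth"].to_numpy(dtype=float)
    m = m.subset(loci=np.flatnonzero(~((depth < depth_min) | (depth > depth_max))))
    check("read_depth", m)
    report.record("read_depth", m.n_loci, m.n_ind)

    m = m.subset(loci=np.flatnonzero(m.minor_allele_freq() >= maf))
    check("maf", m)
    report.record("maf", m.n_loci, m.n_ind)
    return m, report


def impute_nearest_neighbour(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Fill each missing call from the nearest individual with a call there.

    Nearness is bitwise distance over jointly non-missing loci, searched
    globally over all individuals; ties break toward the lowest individual
    index.  If the nearest neighbour is itself missing at the target locus
    the search falls through to the next nearest.  A locus missing in every
    individual is an error.
    """
    out = matrix.copy()
    miss = out.missing_mask()
    if not miss.any():
        return out
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = out.locus_meta.index[all_missing][:5].tolist()
        raise ValueError(f"loci missing in every individual cannot be imputed: {bad}")

    dist = pairwise_distance_matrix(out.calls)
    np.fill_diagonal(dist, np.inf)
    # stable argsort => ties broken by lowest index
    neighbour_order = np.argsort(dist, axis=1, kind="stable")
    calls = out.calls
    for i in np.flatnonzero(miss.any(axis=1)):
        for j in np.flatnonzero(miss[i]):
            for k in neighbour_order[i]:
                if not np.isfinite(dist[i, k]):
                    break
                if calls[k, j] != MISSING:
                    calls[i, j] = calls[k, j]
                    break
            else:  # pragma: no cover - guarded by all_missing check above
                raise ValueError("no neighbour with a call found")
            if calls[i, j] == MISSING:
                raise ValueError(
                    f"individual {out.ind_meta.index[i]} shares loci with no "
                    f"individual called at locus {out.locus_meta.index[j]}"
                )
    out.refresh_call_rates()
    return out
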