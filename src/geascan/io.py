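"""Readers and writers for genotype matrices and environment tables.

Genotypes round-trip through VCF (diploid GT on a single contig,
positions = locus index, 1-based, with per-locus QC metadata in INFO)
and through a simple CSV layout (individuals as rows, loci as columns,
missing encoded "NA").  Environment tables are plain site-by-variable
CSV, matching the layout of the NSW meadow summary table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MISSING

_GT_CODES = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write calls + locus metadata as an uncompressed single-contig VCF."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##source=geascan")
    header.contigs.add("1", length=matrix.n_loci + 1)
    header.add_line(
        '##INFO=<ID=CR,Number=1,Type=Float,Description="Locus call rate">'
    )
    header.add_line(
        '##INFO=<ID=REP,Number=1,Type=Float,Description="Locus reproducibility">'
    )
    header.add_line(
        '##INFO=<ID=MDP,Number=1,Type=Float,Description="Mean read depth">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for ind in matrix.ind_meta.index:
        header.add_sample(str(ind))

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, (locus, meta) in enumerate(matrix.locus_meta.iterrows()):
            rec = vcf.new_record(
                contig="1",
                start=j,
                stop=j + 1,
                alleles=(str(meta["ref"]), str(meta["alt"])),
                id=str(locus),
            )
            rec.info["CR"] = float(meta["call_rate"])
            rec.info["REP"] = float(meta["reproducibility"])
            rec.info["MDP"] = float(meta["mean_depth"])
            for i, ind in enumerate(matrix.ind_meta.index):
                rec.samples[str(ind)]["GT"] = _GT_CODES[int(matrix.calls[i, j])]
            vcf.write(rec)


def read_vcf(path: str | Path, ind_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a VCF written by :func:`write_vcf` back into a GenotypeMatrix.

    Sample site labels are not stored in VCF; pass ``ind_meta`` to restore
    them, else every individual is assigned site "unknown".
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls_cols, meta_rows, ids = [], [], []
    for var in vcf:
        gts = np.asarray(var.genotype.array())[:, :2]
        col = gts.sum(axis=1).astype(np.int16)
        col[(gts < 0).any(axis=1)] = MISSING
        calls_cols.append(col)
        ids.append(var.ID)
        meta_rows.append(
            {
                "ref": var.REF,
                "alt": var.ALT[0],
                "call_rate": float(var.INFO.get("CR", np.nan)),
                "reproducibility": float(var.INFO.get("REP", np.nan)),
                "mean_depth": float(var.INFO.get("MDP", np.nan)),
            }
        )
    vcf.close()
    calls = np.column_stack(calls_cols)
    locus_meta = pd.DataFrame(meta_rows, index=pd.Index(ids, name="locus"))
    if ind_meta is None:
        ind_meta = pd.DataFrame(
            {
                "site": ["unknown"] * len(samples),
                "replicate_pair": pd.array([pd.NA] * len(samples), dtype="Int64"),
                "clone_id": pd.array([pd.NA] * len(samples), dtype="Int64"),
            },
            index=pd.Index(samples, name="individual"),
        )
    else:
        ind_meta = ind_meta.loc[samples]
    return GenotypeMatrix(calls, ind_meta, locus_meta)


def write_genotype_csv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Individuals-as-rows CSV with a locus-id header; missing -> "NA"."""
    df = pd.DataFrame(
        matrix.calls.astype(float),
        index=matrix.ind_meta.index,
        columns=matrix.locus_meta.index,
    )
    df[matrix.calls == MISSING] = np.nan
    df.to_csv(path, na_rep="NA", float_format="%.0f")


def read_genotype_csv(
    path: str | Path,
    ind_meta: pd.DataFrame | None = None,
    locus_meta: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Read the CSV layout written by :func:`write_genotype_csv`."""
    df = pd.read_csv(path, index_col=0)
    calls = df.to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int16)
    if ind_meta is None:
        ind_meta = pd.DataFrame(
            {
                "site": ["unknown"] * len(df),
                "replicate_pair": pd.array([pd.NA] * len(df), dtype="Int64"),
                "clone_id": pd.array([pd.NA] * len(df), dtype="Int64"),
            },
            index=df.index.rename("individual"),
        )
    if locus_meta is None:
        n = df.shape[1]
        locus_meta = pd.DataFrame(
            {
                "ref": ["N"] * n,
                "alt": ["N"] * n,
                "call_rate": np.ones(n),
                "reproducibility": np.ones(n),
                "mean_depth": np.full(n, np.nan),
            },
            index=df.columns.rename("locus"),
        )
    m = GenotypeMatrix(calls, ind_meta, locus_meta)
    m.refresh_call_rates()
    return m


def write_env_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Site-by-variable environment table to CSV."""
    table.to_csv(path, index_label="meadow")


def read_env_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
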