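"""Readers and writers for the pipeline's plain-text formats.

Everything is TSV at desk scale: dosage panels (one row per SNP with a
companion .info file), phenotype tables, METAL-style summary statistics
and a GCTA-compatible gzipped text GRM.  Summary statistics round-trip
losslessly (17 significant digits).
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .greml import Grm
from .synthgen import DosagePanel

SUMMARY_COLUMNS = ["MarkerName", "Allele1", "Allele2", "Freq1", "Effect", "StdErr", "P", "N"]


class SchemaError(ValueError):
    pass


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"summary table missing mandatory column(s): {', '.join(missing)}")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    return df


def write_dosage(panel: DosagePanel, path: str | Path, info_path: str | Path | None = None) -> None:
    """Dosage TSV: SNP_ID, CHR, POS, EA, NEA then one column per IID."""
    path = Path(path)
    head = pd.DataFrame(
        {
            "SNP_ID": panel.snp_ids,
            "CHR": panel.chrom,
            "POS": panel.pos,
            "EA": panel.ea,
            "NEA": panel.nea,
        }
    )
    dos = pd.DataFrame(panel.dosages, columns=panel.iids)
    pd.concat([head, dos], axis=1).to_csv(path, sep="\t", index=False, float_format="%.6g")
    info = pd.DataFrame(
        {"SNP_ID": panel.snp_ids, "EAF": panel.eaf(), "imputation_quality": 1.0}
    )
    info.to_csv(info_path or path.with_suffix(".info"), sep="\t", index=False, float_format="%.6g")


def read_dosage(path: str | Path) -> DosagePanel:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["SNP_ID", "CHR", "POS", "EA", "NEA"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    iids = [c for c in df.columns if c not in meta_cols]
    return DosagePanel(
        snp_ids=df["SNP_ID"].to_numpy(dtype=object),
        chrom=df["CHR"].to_numpy(),
        pos=df["POS"].to_numpy(),
        ea=df["EA"].to_numpy(dtype=object),
        nea=df["NEA"].to_numpy(dtype=object),
        dosages=df[iids].to_numpy(dtype=float),
        iids=np.array(iids, dtype=object),
    )


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "IID" not in df.columns:
        raise SchemaError(f"{path}: missing IID column")
    return df


def write_grm(grm: Grm, prefix: str | Path) -> None:
    """GCTA text-GRM: gzipped (i, j, m_snps, a) triples plus an .id file."""
    prefix = Path(prefix)
    n = grm.matrix.shape[0]
    with gzip.open(prefix.with_suffix(".grm.gz"), "wt") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.m_snps}\t{grm.matrix[i, j]:.10g}\n")
    with open(prefix.with_suffix(".grm.id"), "w") as fh:
        for iid in grm.ids:
            fh.write(f"{iid}\n")


def read_grm(prefix: str | Path) -> Grm:
    prefix = Path(prefix)
    ids = np.array(
        [line.strip() for line in open(prefix.with_suffix(".grm.id")) if line.strip()],
        dtype=object,
    )
    n = ids.size
    a = np.zeros((n, n))
    m_snps = 0
    with gzip.open(prefix.with_suffix(".grm.gz"), "rt") as fh:
        for line in fh:
            i, j, m, v = line.split()
            i, j = int(i) - 1, int(j) - 1
            a[i, j] = a[j, i] = float(v)
            m_snps = int(m)
    return Grm(matrix=a, ids=ids, m_snps=m_snps)
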